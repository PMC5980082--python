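"""Two-tier WRKY group/subgroup assignment.

Tier 1 (rules): domain count plus zinc-finger type decides Group I
(two complete domains, C2H2), Group III (one domain, C2HC) and a
provisional Group II (one domain, C2H2).  Tier 2 (placement): provisional
Group II members — and truncated single-domain proteins that may be
Group I — are placed on a joint neighbor-joining tree with a labeled
reference panel (classically the Arabidopsis AtWRKYs); the subgroup is the
label of the smallest clade containing the query whose non-query leaves
carry one uniform label, falling back to the nearest reference by
corrected distance.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import phylogeny as phy
from .scanner import (
    CANONICAL_VARIANTS,
    DEFAULT_GRAMMARS,
    DEFAULT_WINDOW,
    WrkyDomain,
    extract_domain_sequences,
    scan_protein,
)
from .seq_io import ProteinRecord

logger = logging.getLogger(__name__)

#: Panel labels accepted at load time; IIf/IIg and anything else are rejected.
PANEL_LABELS = ("I-N", "I-C", "IIa", "IIb", "IIc", "IId", "IIe", "III")

GROUP_LABELS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III", "unclassified")

SUPERCLADES: dict[str, tuple[str, ...]] = {
    "IIa+b": ("IIa", "IIb"),
    "IIc": ("IIc",),
    "IId+e": ("IId", "IIe"),
}


class PanelError(ValueError):
    pass


class PlacementError(ValueError):
    pass


@dataclass(frozen=True)
class GroupAssignment:
    """Group/subgroup call for one protein with its evidence path."""

    protein_id: str
    label: str                     # I | IIa..IIe | III | II | unclassified
    tier: str                      # "rule" or "placement"
    evidence: str = ""
    nearest_refs: tuple[str, ...] = ()
    support: float | None = None


@dataclass
class ReferencePanel:
    """Labeled reference WRKY-domain records for placement.

    ``records`` maps reference id -> domain :class:`ProteinRecord`;
    ``labels`` maps reference id -> one of :data:`PANEL_LABELS`.
    """

    records: dict[str, ProteinRecord]
    labels: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.records) != set(self.labels):
            raise PanelError("panel records and labels must cover the same ids")
        bad = {v for v in self.labels.values()} - set(PANEL_LABELS)
        if bad:
            raise PanelError(
                f"unsupported panel label(s) {sorted(bad)}; allowed: {PANEL_LABELS}"
            )

    def subgroup_of(self, ref_id: str) -> str:
        """Panel label collapsed to a group label (I-N/I-C -> I)."""
        lab = self.labels[ref_id]
        return "I" if lab in ("I-N", "I-C") else lab

    @classmethod
    def from_files(cls, fasta_path, labels_path, *, sep: str = "\t") -> "ReferencePanel":
        from .seq_io import read_fasta

        records = {r.id: r for r in read_fasta(fasta_path)}
        df = pd.read_csv(labels_path, sep=sep, header=None, names=["id", "label"],
                         comment="#")
        labels = dict(zip(df["id"].astype(str), df["label"].astype(str)))
        missing = set(records) ^ set(labels)
        if missing:
            raise PanelError(f"panel FASTA/labels id mismatch: {sorted(missing)}")
        return cls(records, labels, provenance=str(fasta_path))


def rule_classify(domains: Sequence[WrkyDomain]) -> str:
    """Structural preliminary label from one protein's domain list.

    >= 2 complete C2H2 domains -> "I"; one complete C2HC -> "III"; one
    complete C2H2 -> "II" (subgroup pending placement); otherwise
    "unclassified".  Pure function of the (unordered) domain list.
    """
    complete = [d for d in domains if d.zf_type in ("C2H2", "C2HC")]
    n_h2 = sum(d.zf_type == "C2H2" for d in complete)
    if len(complete) >= 2 and n_h2 >= 2:
        return "I"
    if len(complete) == 1 and complete[0].zf_type == "C2HC":
        return "III"
    if len(complete) == 1 and complete[0].zf_type == "C2H2":
        return "II"
    return "unclassified"


@dataclass
class PhyloConfig:
    variants: tuple[str, ...] = CANONICAL_VARIANTS
    correction: str = "poisson"
    bootstrap_reps: int = 0
    seed: int = 0


def _smallest_uniform_clade(
    tree: phy.PhyloTree,
    query_leaf: str,
    query_ids: frozenset[str],
    panel: ReferencePanel,
) -> tuple[str | None, tuple[str, ...], phy.TreeNode | None]:
    """Walk rootward from a query leaf; return the label of the smallest
    clade whose non-query leaves are uniformly labeled (collapsing
    I-N / I-C to I), the reference ids in it, and the clade node."""
    parent: dict[phy.TreeNode, phy.TreeNode] = {}
    target = None
    for node in tree.postorder():
        for ch in node.children:
            parent[ch] = node
        if node.is_leaf and node.name == query_leaf:
            target = node
    if target is None:
        raise PlacementError(f"query {query_leaf!r} not in tree")
    clades = tree.clade_leafsets()
    node = target
    while node in parent:
        node = parent[node]
        members = clades[node]
        refs = sorted(m for m in members if m not in query_ids)
        if not refs:
            continue
        labels = {panel.subgroup_of(r) for r in refs}
        if len(labels) == 1:
            return labels.pop(), tuple(refs), node
    return None, (), None


def placement_classify(
    queries: Sequence[ProteinRecord],
    panel: ReferencePanel,
    config: PhyloConfig | None = None,
) -> dict[str, GroupAssignment]:
    """Place query domain records on one joint NJ tree with the panel.

    Returns query id -> assignment.  Queries lacking a heptapeptide anchor
    raise :class:`PlacementError` (they cannot be aligned).
    """
    config = config or PhyloConfig()
    if not queries:
        return {}
    panel_records = [panel.records[k] for k in sorted(panel.records)]
    all_records = list(queries) + panel_records
    try:
        aln = phy.align_domains(all_records, variants=phy.EXTENDED_VARIANTS)
    except phy.AlignmentError as exc:
        raise PlacementError(str(exc)) from exc
    dm = phy.distance_matrix(aln, correction=config.correction)
    if config.bootstrap_reps > 0:
        tree = phy.bootstrap_support(
            aln, n_reps=config.bootstrap_reps, seed=config.seed,
            correction=config.correction,
        )
    else:
        tree = phy.neighbor_joining(dm)
    query_ids = frozenset(q.id for q in queries)
    clades = tree.clade_leafsets()
    out: dict[str, GroupAssignment] = {}
    for q in queries:
        label, refs, node = _smallest_uniform_clade(tree, q.id, query_ids, panel)
        if label is not None:
            support = node.support if node is not None else None
            out[q.id] = GroupAssignment(
                protein_id=q.id,
                label=label,
                tier="placement",
                evidence=f"clade with {len(refs)} reference(s): "
                         + ",".join(refs[:5]),
                nearest_refs=refs[:5],
                support=support,
            )
        else:
            # no uniform clade below the root: nearest reference by distance
            dists = sorted(
                (dm.pair(q.id, r), r) for r in panel.records
            )
            best_d, best_r = dists[0]
            out[q.id] = GroupAssignment(
                protein_id=q.id,
                label=panel.subgroup_of(best_r),
                tier="placement",
                evidence=f"nearest reference {best_r} at d={best_d:.4f}",
                nearest_refs=(best_r,),
                support=None,
            )
    return out


def classify_all(
    records: Sequence[ProteinRecord],
    panel: ReferencePanel | None = None,
    config: PhyloConfig | None = None,
    *,
    grammars=DEFAULT_GRAMMARS,
    variants: Sequence[str] = CANONICAL_VARIANTS,
    window: int = DEFAULT_WINDOW,
) -> list[GroupAssignment]:
    """Scan and classify a whole candidate set.

    Rule tier runs first.  Provisional Group II members and ambiguous
    single-domain proteins go to placement (one joint tree for the batch)
    when a panel is supplied; single-domain queries that clade with I-N/I-C
    references are rescued into Group I (truncated two-domain proteins).
    Without a panel, provisional members keep the bare "II" label.
    """
    config = config or PhyloConfig()
    rec_by_id = {r.id: r for r in records}
    domains_by_id = {
        r.id: scan_protein(r, grammars=grammars, variants=variants, window=window)
        for r in records
    }
    prelim = {pid: rule_classify(doms) for pid, doms in domains_by_id.items()}

    out: dict[str, GroupAssignment] = {}
    pending: list[str] = []
    for pid, label in prelim.items():
        doms = domains_by_id[pid]
        summary = ";".join(f"{d.zf_type}@{d.start}" for d in doms) or "no domains"
        if label in ("I", "III"):
            out[pid] = GroupAssignment(pid, label, "rule", evidence=summary)
        elif label == "II":
            pending.append(pid)
        else:
            out[pid] = GroupAssignment(
                pid, "unclassified", "rule",
                evidence=f"no complete WRKY domain ({summary})",
            )

    if pending and panel is not None:
        queries = []
        for pid in pending:
            doms = [d for d in domains_by_id[pid] if d.zf_type != "incomplete"]
            queries.extend(
                extract_domain_sequences(rec_by_id, doms[:1], flank=0)
            )
        placed = placement_classify(queries, panel, config)
        for pid in pending:
            asg = placed[pid]
            out[pid] = asg
    else:
        for pid in pending:
            doms = domains_by_id[pid]
            summary = ";".join(f"{d.zf_type}@{d.start}" for d in doms)
            out[pid] = GroupAssignment(
                pid, "II", "rule",
                evidence=f"single C2H2 domain, no panel for subgrouping ({summary})",
            )

    return [out[r.id] for r in records]


def count_summary(assignments: Iterable[GroupAssignment]) -> dict[str, int]:
    """Per-label tallies (I, IIa..IIe, III, II, unclassified, total)."""
    counts = Counter(a.label for a in assignments)
    summary = {lab: counts.get(lab, 0) for lab in GROUP_LABELS}
    if counts.get("II"):
        summary["II"] = counts["II"]
    summary["total"] = sum(counts.values())
    return summary


def superclade_check(
    tree: phy.PhyloTree,
    labels_by_leaf: Mapping[str, str],
) -> dict[str, bool]:
    """Monophyly report for the classical Group II superclades.

    For each of IIa+b, IIc and IId+e: whether the leaves carrying those
    subgroup labels form a connected subtree of the unrooted tree (vacuously
    true when <= 1 such leaf).  Leaves without a label entry are ignored
    only if absent from the tree check — every tree leaf must be labeled.
    """
    leaf_set = tree.leaf_set()
    missing = leaf_set - set(labels_by_leaf)
    if missing:
        raise ValueError(f"unlabeled tree leaves: {sorted(missing)[:5]}")

    def collapse(lab: str) -> str:
        return "I" if lab in ("I-N", "I-C") else lab

    report: dict[str, bool] = {}
    for name, members in SUPERCLADES.items():
        chosen = [lf for lf in leaf_set if collapse(labels_by_leaf[lf]) in members]
        report[name] = phy.is_monophyletic(tree, chosen)
    return report


def assignments_to_rows(assignments: Iterable[GroupAssignment]) -> list[dict]:
    return [
        {
            "protein_id": a.protein_id,
            "label": a.label,
            "tier": a.tier,
            "nearest_refs": ",".join(a.nearest_refs),
            "support": "" if a.support is None else f"{a.support:.1f}",
            "evidence": a.evidence,
        }
        for a in assignments
    ]
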