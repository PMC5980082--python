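"""Ground-truth-labeled synthetic data emulating a WRKY survey.

The generator writes grammar-conforming WRKY proteins per group (two
domains for Group I, one otherwise), low-divergence labeled reference
panels, expression matrices with planted regulation over the three study
contrasts, and qPCR Ct tables with known fold changes — everything the
analysis modules need for offline, oracle-checked testing.

Construction rules that make ground truth exactly recoverable:

* domain filler residues exclude C, H, W and L, so the planted
  zinc-finger anchors are the only grammar-compatible arrangement, the
  planted heptapeptide is the only anchor, and no leucine motif can arise
  inside a domain;
* background (non-domain) residues exclude W, L and C, so no accidental
  heptapeptides, no spurious zinc-finger starts, and no accidental
  leucine motifs;
* planted accessory motifs are separated by 7 background residues, a
  spacing at which their leucines cannot combine into extra motif cores.

Templates are built deterministically at import time from a hierarchical
scheme (clade-level and subgroup-level signature residues), giving the
classical IIa+b / IIc / IId+e superclade structure on the reference panel.
The generator never calls the scanner, classifier or motif code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_io import CtTable, ExpressionMatrix, ProteinRecord

# residue pools (see module docstring for why letters are excluded)
DOMAIN_FILLER = "ADEFGIKMNPQRSTVY"          # no C, H, W, L
BACKGROUND = "ADEFGHIKMNPQRSTVY"            # no C, W, L

HEPTAPEPTIDE = "WRKYGQK"

#: label -> (clade signature, clade filler letter, subgroup signature,
#:           subgroup filler letter, zinc-finger kind)
_TEMPLATE_SCHEME: dict[str, tuple[str, str, str, str, str]] = {
    "I-N": ("ADEFG", "A", "KIKIK", "K", "C2H2"),
    "I-C": ("ADEFG", "A", "MNMNM", "M", "C2H2"),
    "IIa": ("IKMNP", "K", "EAEAE", "E", "C2H2"),
    "IIb": ("IKMNP", "K", "FDFDF", "F", "C2H2"),
    "IIc": ("QRSTV", "Q", "RGRGR", "R", "C2H2"),
    "IId": ("YVTSR", "Y", "STSTS", "S", "C2H2"),
    "IIe": ("YVTSR", "Y", "TVTVT", "T", "C2H2"),
    "III": ("GFEDA", "G", "PYPYP", "P", "C2HC"),
}

_SPACER_RANGES = {"C2H2": ((4, 5), (22, 23)), "C2HC": ((7, 7), (23, 23))}

GROUPS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")

#: which groups carry which accessory motif (mirrors the survey's findings:
#: EAR repression motifs in Group IIb, HARF in IId, LxxLL spread over
#: I / IId / III, leucine zipper in IIb)
DEFAULT_MOTIF_PLAN: dict[str, tuple[str, ...]] = {
    "EAR_LxLxL": ("IIb",),
    "EAR_DLNxxP": (),
    "LxxLL": ("I", "IId", "III"),
    "HARF": ("IId",),
    "LeucineZipper": ("IIb",),
}

_MOTIF_LITERALS = {
    "EAR_LxLxL": "LKLDLY",
    "EAR_DLNxxP": "DLNHNP",
    "LxxLL": "LSQLL",
    "HARF": "RTGHARFRRAP",
}

_MOTIF_ORDER = ("HARF", "EAR_LxLxL", "EAR_DLNxxP", "LxxLL", "LeucineZipper")


@dataclass(frozen=True)
class DomainTruth:
    """Planted domain, coordinates relative to the domain sequence start."""

    label: str            # I-N | I-C | IIa..IIe | III
    variant: str          # heptapeptide string used
    zf_type: str
    hept_start: int
    zf_positions: tuple[int, ...]
    length: int


@dataclass(frozen=True)
class MotifTruth:
    motif_class: str
    start: int
    end: int
    literal: str


@dataclass(frozen=True)
class ProteinTruth:
    protein_id: str
    group: str
    domains: tuple[DomainTruth, ...]        # absolute coordinates
    domain_offsets: tuple[int, ...]         # start of each domain in protein
    motifs: tuple[MotifTruth, ...]          # absolute coordinates


@dataclass
class SyntheticSpec:
    """Study conditions for the generator; identical spec + seed gives
    byte-identical outputs."""

    seed: int = 0
    counts: dict = field(
        default_factory=lambda: {g: 100 for g in GROUPS}
    )
    substitution_rate: float = 0.0
    background_length: tuple[int, int] = (40, 80)
    linker_length: tuple[int, int] = (20, 40)
    motif_plan: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_PLAN))
    panel_per_label: int = 3
    panel_rate: float = 0.02
    # expression plan (fractions mirror the reported direction counts)
    n_genes: int = 61
    contrast_fractions: dict = field(
        default_factory=lambda: {
            "MeJA-vs-control": (0.11, 0.70),
            "GA-vs-control": (0.16, 0.74),
            "NA-vs-CA": (0.25, 0.69),
        }
    )
    effect_range: tuple[float, float] = (1.5, 4.0)
    mask_fraction: float = 0.05
    expression_noise_sd: float = 0.1
    # qPCR plan: gene -> {(treatment, timepoint_h): fold change}
    ct_plan: dict = field(
        default_factory=lambda: {
            "TcW44-like": {("MeJA", 0.0): 1.0, ("MeJA", 1.0): 4.0,
                           ("MeJA", 3.0): 16.5, ("MeJA", 6.0): 2.0},
            "TcW8-like": {("MeJA", 0.0): 1.0, ("MeJA", 1.0): 3.0,
                          ("MeJA", 3.0): 12.1, ("MeJA", 6.0): 1.5},
            "TcW47-like": {("SA", 0.0): 1.0, ("SA", 1.0): 0.8,
                           ("SA", 3.0): 0.6, ("SA", 6.0): 4.8},
        }
    )
    ct_noise_sd: float = 0.05
    ct_replicates: int = 3

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution rate must be in [0, 1)")
        if self.ct_noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _build_template(label: str, s1: int, s2: int) -> tuple[str, DomainTruth]:
    clade_sig, clade_letter, sub_sig, sub_letter, zf = _TEMPLATE_SCHEME[label]
    f1 = clade_sig + sub_sig                      # 10 residues after the anchor
    last = "H" if zf == "C2H2" else "C"
    seq = (
        HEPTAPEPTIDE
        + f1
        + "C" + clade_letter * s1
        + "C" + sub_letter * s2
        + "H" + "A" + last
    )
    c1 = 7 + len(f1)
    c2 = c1 + 1 + s1
    h1 = c2 + 1 + s2
    z = h1 + 2
    truth = DomainTruth(
        label=label, variant=HEPTAPEPTIDE, zf_type=zf,
        hept_start=0, zf_positions=(c1, c2, h1, z), length=len(seq),
    )
    return seq, truth


def make_domain(
    label: str,
    rate: float,
    rng: np.random.Generator,
    *,
    variant: str = HEPTAPEPTIDE,
    spacers: tuple[int, int] | None = None,
) -> tuple[str, DomainTruth]:
    """One grammar-conforming WRKY domain sequence plus its truth record.

    ``label`` is I (alias for I-N), I-N, I-C, IIa..IIe or III.  Spacer
    lengths are drawn uniformly from the grammar ranges unless fixed via
    ``spacers``.  Substitutions at ``rate`` hit filler positions only —
    never the heptapeptide or the zinc-finger anchors — and are drawn from
    the domain filler pool.
    """
    if label == "I":
        label = "I-N"
    if label not in _TEMPLATE_SCHEME:
        raise ValueError(f"unknown group label {label!r}")
    zf = _TEMPLATE_SCHEME[label][4]
    (r1lo, r1hi), (r2lo, r2hi) = _SPACER_RANGES[zf]
    if spacers is None:
        s1 = int(rng.integers(r1lo, r1hi + 1))
        s2 = int(rng.integers(r2lo, r2hi + 1))
    else:
        s1, s2 = spacers
    seq, truth = _build_template(label, s1, s2)
    if len(variant) != 7:
        raise ValueError("heptapeptide variant must be 7 letters")
    seq = variant + seq[7:]
    truth = DomainTruth(
        label=truth.label, variant=variant, zf_type=truth.zf_type,
        hept_start=0, zf_positions=truth.zf_positions, length=truth.length,
    )
    if rate > 0:
        protected = set(range(7)) | set(truth.zf_positions)
        chars = list(seq)
        for i in range(len(chars)):
            if i in protected:
                continue
            if rng.random() < rate:
                choices = [c for c in DOMAIN_FILLER if c != chars[i]]
                chars[i] = choices[int(rng.integers(len(choices)))]
        seq = "".join(chars)
    return seq, truth


def _background(n: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(BACKGROUND), size=n)
    seg = "".join(BACKGROUND[i] for i in idx)
    assert HEPTAPEPTIDE not in seg  # impossible (no W in pool); guard anyway
    return seg


def _zipper_literal(rng: np.random.Generator, period: int = 7,
                    repeats: int = 4) -> str:
    parts = []
    for k in range(repeats):
        parts.append("L")
        if k < repeats - 1:
            parts.append(_background(period - 1, rng))
    return "".join(parts)


def make_protein(
    group: str,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    protein_id: str = "syn1",
    *,
    variant: str = HEPTAPEPTIDE,
) -> tuple[ProteinRecord, ProteinTruth]:
    """One synthetic protein for ``group`` with its full truth record.

    Group I proteins embed an N- then a C-terminal domain separated by a
    >= 20-residue linker; other groups embed one domain.  Accessory motifs
    listed for the group in the motif plan are planted in the C-terminal
    background, 7 background residues apart.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rate = spec.substitution_rate
    blo, bhi = spec.background_length
    pre = _background(int(rng.integers(blo, bhi + 1)), rng)

    parts: list[str] = [pre]
    dom_truths: list[DomainTruth] = []
    offsets: list[int] = []
    pos = len(pre)
    if group == "I":
        for lab in ("I-N", "I-C"):
            seq, t = make_domain(lab, rate, rng, variant=variant)
            parts.append(seq)
            dom_truths.append(t)
            offsets.append(pos)
            pos += len(seq)
            if lab == "I-N":
                llo, lhi = spec.linker_length
                linker = _background(int(rng.integers(llo, lhi + 1)), rng)
                parts.append(linker)
                pos += len(linker)
    else:
        lab = "III" if group == "III" else group
        seq, t = make_domain(lab, rate, rng, variant=variant)
        parts.append(seq)
        dom_truths.append(t)
        offsets.append(pos)
        pos += len(seq)

    # C-terminal background with planted motifs
    tail = [_background(int(rng.integers(blo, bhi + 1)), rng)]
    pos += len(tail[0])
    motif_truths: list[MotifTruth] = []
    for cls in _MOTIF_ORDER:
        groups_with = spec.motif_plan.get(cls, ())
        if group not in groups_with:
            continue
        literal = (
            _zipper_literal(rng) if cls == "LeucineZipper"
            else _MOTIF_LITERALS[cls]
        )
        motif_truths.append(
            MotifTruth(cls, pos, pos + len(literal), literal)
        )
        tail.append(literal)
        pos += len(literal)
        sep = _background(7, rng)
        tail.append(sep)
        pos += len(sep)
    parts.extend(tail)
    sequence = "".join(parts)

    abs_domains = tuple(
        DomainTruth(
            label=t.label, variant=t.variant, zf_type=t.zf_type,
            hept_start=off + t.hept_start,
            zf_positions=tuple(off + p for p in t.zf_positions),
            length=t.length,
        )
        for t, off in zip(dom_truths, offsets)
    )
    record = ProteinRecord(id=protein_id, description=f"synthetic {group}",
                           sequence=sequence)
    truth = ProteinTruth(
        protein_id=protein_id, group=group, domains=abs_domains,
        domain_offsets=tuple(offsets), motifs=tuple(motif_truths),
    )
    return record, truth


def make_proteins(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[list[ProteinRecord], list[ProteinTruth]]:
    """The full candidate set: ``spec.counts[g]`` proteins per group."""
    records, truths = [], []
    i = 0
    for group in GROUPS:
        for _ in range(spec.counts.get(group, 0)):
            i += 1
            rec, tr = make_protein(group, spec, rng, protein_id=f"syn{i:04d}")
            records.append(rec)
            truths.append(tr)
    return records, truths


def make_reference_panel(
    spec: SyntheticSpec, rng: np.random.Generator
):
    """A labeled synthetic reference panel (stand-in for a real AtWRKY
    panel): ``panel_per_label`` low-divergence domain records per label."""
    from .classify import PANEL_LABELS, ReferencePanel

    if spec.panel_per_label < 2:
        raise ValueError("need >= 2 references per subgroup")
    records: dict[str, ProteinRecord] = {}
    labels: dict[str, str] = {}
    for lab in PANEL_LABELS:
        for k in range(spec.panel_per_label):
            seq, _ = make_domain(lab, spec.panel_rate, rng)
            rid = f"REF_{lab}_{k + 1}"
            records[rid] = ProteinRecord(id=rid, description=f"panel {lab}",
                                         sequence=seq)
            labels[rid] = lab
    return ReferencePanel(records, labels,
                          provenance="synthetic reference panel")


def make_expression(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Log2-scale expression matrix over the three study contrasts with
    planted regulation; returns (matrix, truth).

    Truth is a DataFrame (gene x contrast) of planted log2 fold changes
    with NaN where the gene is masked in that contrast.
    """
    genes = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    columns = ["control", "MeJA", "GA", "CA", "NA"]
    contrast_cols = {
        "MeJA-vs-control": ("MeJA", "control"),
        "GA-vs-control": ("GA", "control"),
        "NA-vs-CA": ("NA", "CA"),
    }
    base = rng.normal(5.0, 1.0, size=spec.n_genes)
    values = pd.DataFrame(
        {c: base.copy() for c in columns}, index=genes, dtype=float
    )
    truth = pd.DataFrame(0.0, index=genes, columns=list(spec.contrast_fractions))
    for contrast, (f_up, f_down) in spec.contrast_fractions.items():
        num, _den = contrast_cols[contrast]
        n_up = int(round(f_up * spec.n_genes))
        n_down = int(round(f_down * spec.n_genes))
        order = rng.permutation(spec.n_genes)
        lo, hi = spec.effect_range
        for j in order[:n_up]:
            lfc = float(rng.uniform(lo, hi))
            values.iloc[j, values.columns.get_loc(num)] += lfc
            truth.iloc[j, truth.columns.get_loc(contrast)] = lfc
        for j in order[n_up:n_up + n_down]:
            lfc = -float(rng.uniform(lo, hi))
            values.iloc[j, values.columns.get_loc(num)] += lfc
            truth.iloc[j, truth.columns.get_loc(contrast)] = lfc
    if spec.expression_noise_sd > 0:
        values += rng.normal(0.0, spec.expression_noise_sd, size=values.shape)
    mask = pd.DataFrame(
        rng.random(values.shape) < spec.mask_fraction,
        index=genes, columns=columns,
    )
    for contrast, (num, den) in contrast_cols.items():
        hidden = mask[num] | mask[den]
        truth.loc[hidden.values, contrast] = np.nan
    values = values.mask(mask)
    return ExpressionMatrix(values=values, mask=mask), truth


def make_ct(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[CtTable, dict]:
    """Replicated qPCR Ct table with known fold changes.

    Samples are named ``{treatment}_{timepoint:g}h``; the reference gene is
    ``Actin``; the calibrator for each treatment is its 0 h sample.  Truth
    maps (gene, sample) -> planted fold change.
    """
    rows = []
    truth: dict[tuple[str, str], float] = {}
    samples: dict[str, tuple[str, float]] = {}
    for gene, plan in spec.ct_plan.items():
        for (treatment, tp), _fc in plan.items():
            samples[f"{treatment}_{tp:g}h"] = (treatment, tp)
    ref_base = 20.0
    target_base = 24.0
    for sample, (treatment, tp) in sorted(samples.items()):
        for _ in range(spec.ct_replicates):
            rows.append(
                dict(sample=sample, gene="Actin",
                     ct=ref_base + rng.normal(0, spec.ct_noise_sd),
                     treatment=treatment, timepoint=tp)
            )
    for gene, plan in spec.ct_plan.items():
        for (treatment, tp), fc in plan.items():
            sample = f"{treatment}_{tp:g}h"
            truth[(gene, sample)] = fc
            true_ct = target_base - np.log2(fc)
            for _ in range(spec.ct_replicates):
                rows.append(
                    dict(sample=sample, gene=gene,
                         ct=true_ct + rng.normal(0, spec.ct_noise_sd),
                         treatment=treatment, timepoint=tp)
                )
    return CtTable(pd.DataFrame(rows)), truth


def truths_to_frame(truths: Iterable[ProteinTruth]) -> pd.DataFrame:
    """Flatten protein truths for TSV output."""
    rows = []
    for t in truths:
        rows.append(
            {
                "protein_id": t.protein_id,
                "group": t.group,
                "n_domains": len(t.domains),
                "zf_types": ";".join(d.zf_type for d in t.domains),
                "domain_starts": ";".join(str(o) for o in t.domain_offsets),
                "motifs": ";".join(
                    f"{m.motif_class}@{m.start}" for m in t.motifs
                ),
            }
        )
    return pd.DataFrame(rows)


def simulate_bundle(spec: SyntheticSpec, out_dir) -> dict[str, Path]:
    """Write the full synthetic bundle (FASTA, truth TSV, panel, expression,
    Ct) under ``out_dir``; returns the file map.  Deterministic in
    (spec, spec.seed)."""
    from .seq_io import write_ct_table, write_expression_table, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    records, truths = make_proteins(spec, rng)
    panel = make_reference_panel(spec, rng)
    expr, expr_truth = make_expression(spec, rng)
    ct, ct_truth = make_ct(spec, rng)

    paths = {
        "proteins": out / "proteins.fasta",
        "truth": out / "truth.tsv",
        "panel_fasta": out / "panel.fasta",
        "panel_labels": out / "panel_labels.tsv",
        "expression": out / "expression.tsv",
        "expression_truth": out / "expression_truth.tsv",
        "ct": out / "ct.tsv",
        "ct_truth": out / "ct_truth.tsv",
    }
    write_fasta(records, paths["proteins"])
    truths_to_frame(truths).to_csv(paths["truth"], sep="\t", index=False)
    write_fasta(list(panel.records.values()), paths["panel_fasta"])
    with paths["panel_labels"].open("w") as fh:
        for rid in panel.records:
            fh.write(f"{rid}\t{panel.labels[rid]}\n")
    write_expression_table(expr, paths["expression"])
    expr_truth.to_csv(paths["expression_truth"], sep="\t", na_rep="NA")
    write_ct_table(ct, paths["ct"])
    pd.DataFrame(
        [{"gene": g, "sample": s, "fold_change": fc}
         for (g, s), fc in ct_truth.items()]
    ).to_csv(paths["ct_truth"], sep="\t", index=False)
    return paths
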