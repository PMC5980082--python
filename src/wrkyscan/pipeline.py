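"""End-to-end orchestration: scan -> classify -> motifs -> tree -> expression.

:func:`run_all` drives the whole analysis from a :class:`RunConfig` and
writes a plain-text report bundle (TSV / JSON / newick) plus a run log.
Everything is deterministic given the config and seed; the seed and the
serialized config are recorded alongside the results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as cls
from . import expression as expr_mod
from . import motifs as motif_mod
from . import phylogeny as phy
from . import scanner as scan_mod
from .seq_io import read_ct_table, read_expression_table, read_fasta

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    fasta: str
    out_dir: str
    panel_fasta: str | None = None
    panel_labels: str | None = None
    expression: str | None = None
    ct: str | None = None
    variants: str = "canonical"            # "canonical" | "extended"
    window: int = scan_mod.DEFAULT_WINDOW
    bootstrap_reps: int = 0
    seed: int = 0
    lfc_threshold: float = 1.0
    contrasts: dict = field(
        default_factory=lambda: {
            "MeJA-vs-control": ["MeJA", "control"],
            "GA-vs-control": ["GA", "control"],
            "NA-vs-CA": ["NA", "CA"],
        }
    )
    ddct_target: str | None = None
    ddct_reference: str = "Actin"
    ddct_calibrator: str | None = None

    def variant_tuple(self) -> tuple[str, ...]:
        if self.variants == "canonical":
            return scan_mod.CANONICAL_VARIANTS
        if self.variants == "extended":
            return scan_mod.EXTENDED_VARIANTS
        raise PipelineError(f"config: unknown variant set {self.variants!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("scan")
def _run_scan(records, config: RunConfig, out: Path):
    variants = config.variant_tuple()
    domains_by_id = scan_mod.scan_all(records, variants=variants,
                                      window=config.window)
    rows = []
    for pid in domains_by_id:
        rows.extend(scan_mod.domains_to_rows(domains_by_id[pid]))
    pd.DataFrame(
        rows, columns=["protein_id", "start", "end", "heptapeptide",
                       "variant", "zf_type", "zf_positions", "terminal",
                       "ambiguous"],
    ).to_csv(out / "domains.tsv", sep="\t", index=False)
    return domains_by_id


@_stage("classify")
def _run_classify(records, panel, config: RunConfig, out: Path):
    phylo_cfg = cls.PhyloConfig(
        variants=config.variant_tuple(),
        bootstrap_reps=config.bootstrap_reps,
        seed=config.seed,
    )
    assignments = cls.classify_all(
        records, panel, phylo_cfg,
        variants=config.variant_tuple(), window=config.window,
    )
    pd.DataFrame(cls.assignments_to_rows(assignments)).to_csv(
        out / "assignments.tsv", sep="\t", index=False
    )
    summary = cls.count_summary(assignments)
    (out / "group_counts.json").write_text(json.dumps(summary, indent=2))
    return assignments


@_stage("motifs")
def _run_motifs(records, out: Path):
    hits, counts = motif_mod.annotate_all(records)
    pd.DataFrame(
        motif_mod.hits_to_rows(hits),
        columns=["protein_id", "class", "subtype", "start", "end"],
    ).to_csv(out / "motifs.tsv", sep="\t", index=False)
    (out / "motif_counts.json").write_text(json.dumps(counts, indent=2))
    return hits


@_stage("tree")
def _run_tree(records, domains_by_id, config: RunConfig, out: Path):
    all_domains = [
        d for doms in domains_by_id.values() for d in doms
        if d.zf_type != "incomplete"
    ]
    if len(all_domains) < 3:
        logger.info("tree stage skipped: fewer than 3 complete domains")
        return None
    dom_records = scan_mod.extract_domain_sequences(records, all_domains)
    aln = phy.align_domains(dom_records, variants=phy.EXTENDED_VARIANTS)
    if config.bootstrap_reps > 0:
        tree = phy.bootstrap_support(aln, n_reps=config.bootstrap_reps,
                                     seed=config.seed)
    else:
        tree = phy.neighbor_joining(phy.distance_matrix(aln))
    (out / "domains.nwk").write_text(tree.to_newick() + "\n")
    return tree


@_stage("expression")
def _run_expression(config: RunConfig, out: Path):
    results = {}
    if config.expression:
        mat = read_expression_table(config.expression)
        contrasts = {k: tuple(v) for k, v in config.contrasts.items()}
        usable = {
            k: v for k, v in contrasts.items()
            if set(v) <= set(mat.values.columns)
        }
        contrast_results = expr_mod.contrast_matrix(
            mat, usable, lfc_threshold=config.lfc_threshold
        )
        pd.DataFrame(
            [dataclasses.asdict(r) for r in contrast_results]
        ).to_csv(out / "contrasts.tsv", sep="\t", index=False)
        expr_mod.direction_counts(contrast_results).to_csv(
            out / "direction_counts.tsv", sep="\t"
        )
        try:
            clust = expr_mod.cluster_genes(mat)
            (out / "gene_order.tsv").write_text(
                "\n".join(clust.gene_order) + "\n"
            )
            (out / "dendrogram.nwk").write_text(
                expr_mod.dendrogram_newick(clust) + "\n"
            )
            results["cluster"] = clust
        except ValueError as exc:
            logger.info("clustering skipped: %s", exc)
        results["contrasts"] = contrast_results
    if config.ct and config.ddct_target and config.ddct_calibrator:
        ct = read_ct_table(config.ct)
        fc = expr_mod.ddct(ct, config.ddct_target, config.ddct_reference,
                           config.ddct_calibrator)
        pd.DataFrame([dataclasses.asdict(r) for r in fc]).to_csv(
            out / "fold_changes.tsv", sep="\t", index=False
        )
        results["fold_changes"] = fc
    return results


def run_all(config: RunConfig) -> dict:
    """Run every configured stage; returns the in-memory results and writes
    the report bundle under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("wrkyscan")
    root.addHandler(handler)
    try:
        logger.info("seed=%d", config.seed)
        logger.info("config=%s", json.dumps(dataclasses.asdict(config)))
        (out / "config.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(config))
        )

        records = read_fasta(config.fasta)
        panel = None
        if config.panel_fasta and config.panel_labels:
            panel = cls.ReferencePanel.from_files(
                config.panel_fasta, config.panel_labels
            )
        elif bool(config.panel_fasta) != bool(config.panel_labels):
            raise PipelineError(
                "stage 'config' failed: panel requires both --panel-fasta "
                "and --panel-labels"
            )

        domains_by_id = _run_scan(records, config, out)
        assignments = _run_classify(records, panel, config, out)
        hits = _run_motifs(records, out)
        tree = _run_tree({r.id: r for r in records}, domains_by_id,
                         config, out)
        expr_results = _run_expression(config, out)
        return {
            "records": records,
            "domains": domains_by_id,
            "assignments": assignments,
            "motifs": hits,
            "tree": tree,
            "expression": expr_results,
        }
    finally:
        root.removeHandler(handler)
        handler.close()
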