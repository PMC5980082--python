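"""Expression analytics: contrasts, clustering, and the 2^-ddCt calculator.

Transcriptome-side, expression matrices hold log2-scale values; a contrast
is a (numerator, denominator) column pair and its log2 fold change is the
column difference.  qPCR-side, relative expression is computed by the plain
2^-ddCt method: replicate Ct values are averaged per (sample, gene), the
reference gene subtracted (dCt), the calibrator sample subtracted (ddCt),
and 2**(-ddCt) reported (calibrator = 1 by construction).  No
amplification-efficiency correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .seq_io import CtTable, ExpressionMatrix


class NormalizationError(ValueError):
    pass


class ContrastError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastResult:
    gene: str
    contrast: str
    log2fc: float
    direction: str      # up | down | unchanged | missing
    missing: bool = False


@dataclass(frozen=True)
class FoldChangeResult:
    """Relative expression 2^-ddCt for one sample (control = 1)."""

    gene: str
    sample: str
    relative_expression: float
    ddct: float
    dispersion: float   # sd of target-gene replicate Ct in this sample
    treatment: str | None = None
    timepoint: float | None = None


def ddct(
    ct: CtTable,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
) -> list[FoldChangeResult]:
    """2^-ddCt relative expression of ``target_gene`` for every sample.

    Replicates are averaged (arithmetic mean of Ct) before normalization.
    Every sample must carry reference-gene wells; the calibrator sample maps
    to exactly 1.
    """
    means = ct.replicate_means().set_index(["sample", "gene"])
    samples = sorted({s for s, _ in means.index})
    for needed in (target_gene, reference_gene):
        have = {s for s, g in means.index if g == needed}
        miss = set(samples) - have
        if needed == reference_gene and miss:
            raise NormalizationError(
                f"reference gene {reference_gene!r} missing for sample(s) "
                f"{sorted(miss)}"
            )
    if calibrator_sample not in samples:
        raise NormalizationError(f"calibrator sample {calibrator_sample!r} absent")

    def dct(sample: str) -> float:
        try:
            t = means.loc[(sample, target_gene), "mean"]
        except KeyError:
            raise NormalizationError(
                f"target {target_gene!r} missing for sample {sample!r}"
            )
        r = means.loc[(sample, reference_gene), "mean"]
        return float(t - r)

    cal = dct(calibrator_sample)
    meta_cols = [c for c in ("treatment", "timepoint") if c in ct.data.columns]
    meta = (
        ct.data.drop_duplicates("sample").set_index("sample")[meta_cols]
        if meta_cols else None
    )
    out = []
    for sample in samples:
        if (sample, target_gene) not in means.index:
            continue
        dd = dct(sample) - cal
        sd = means.loc[(sample, target_gene), "sd"]
        treatment = timepoint = None
        if meta is not None and sample in meta.index:
            treatment = meta.loc[sample].get("treatment")
            timepoint = meta.loc[sample].get("timepoint")
            timepoint = None if pd.isna(timepoint) else float(timepoint)
        out.append(
            FoldChangeResult(
                gene=target_gene,
                sample=sample,
                relative_expression=float(2.0 ** (-dd)),
                ddct=float(dd),
                dispersion=0.0 if pd.isna(sd) else float(sd),
                treatment=treatment,
                timepoint=timepoint,
            )
        )
    return out


def contrast_matrix(
    expr: ExpressionMatrix,
    contrasts: Mapping[str, tuple[str, str]],
    lfc_threshold: float = 1.0,
) -> list[ContrastResult]:
    """Per-gene log2 fold changes for named (numerator, denominator) contrasts.

    Direction is the sign of the log2FC when |log2FC| >= ``lfc_threshold``,
    else "unchanged"; genes masked in either column are flagged missing and
    excluded from up/down tallies.
    """
    for name, (num, den) in contrasts.items():
        for col in (num, den):
            if col not in expr.values.columns:
                raise ContrastError(f"contrast {name!r}: unknown column {col!r}")
    results: list[ContrastResult] = []
    for name, (num, den) in contrasts.items():
        lfc = expr.values[num] - expr.values[den]
        masked = expr.mask[num] | expr.mask[den]
        for gene in expr.genes:
            if bool(masked[gene]):
                results.append(ContrastResult(gene, name, float("nan"),
                                              "missing", missing=True))
                continue
            v = float(lfc[gene])
            if abs(v) >= lfc_threshold:
                direction = "up" if v > 0 else "down"
            else:
                direction = "unchanged"
            results.append(ContrastResult(gene, name, v, direction))
    return results


def direction_counts(results: Iterable[ContrastResult]) -> pd.DataFrame:
    """Tally up/down/unchanged/missing per contrast; rows sum to gene count."""
    df = pd.DataFrame(
        [(r.contrast, r.direction) for r in results],
        columns=["contrast", "direction"],
    )
    tab = (
        df.groupby(["contrast", "direction"]).size().unstack(fill_value=0)
        .reindex(columns=["up", "down", "unchanged", "missing"], fill_value=0)
    )
    tab.columns.name = None
    return tab


@dataclass
class ClusterResult:
    gene_order: list[str]     # dendrogram leaf order
    linkage: np.ndarray       # scipy linkage matrix over used genes
    genes_used: list[str]
    genes_dropped: list[str]


def cluster_genes(
    expr: ExpressionMatrix,
    *,
    linkage_method: str = "average",
    metric: str = "euclidean",
    impute_zero: bool = False,
) -> ClusterResult:
    """Deterministic agglomerative clustering of genes for heatmap ordering.

    Genes with any masked value are dropped by default (``impute_zero=True``
    fills them with 0 instead).  Distance ties are resolved by scipy's
    stable merge order, i.e. by lowest row index.
    """
    values = expr.values.where(~expr.mask, other=np.nan)
    if impute_zero:
        used = values.fillna(0.0)
        dropped: list[str] = []
    else:
        complete = ~values.isna().any(axis=1)
        used = values.loc[complete]
        dropped = [g for g in expr.genes if not complete[g]]
    if len(used) < 2:
        raise ValueError("need >= 2 usable gene rows to cluster")
    Z = hierarchy.linkage(used.to_numpy(), method=linkage_method, metric=metric)
    order = hierarchy.leaves_list(Z)
    genes_used = list(used.index)
    return ClusterResult(
        gene_order=[genes_used[i] for i in order],
        linkage=Z,
        genes_used=genes_used,
        genes_dropped=dropped,
    )


def dendrogram_newick(res: ClusterResult) -> str:
    """Render the merge tree as newick (heights as branch lengths)."""
    tree = hierarchy.to_tree(res.linkage)

    def render(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{res.genes_used[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
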