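# wrkyscan

Transcriptome-wide identification, classification and expression analysis
of **WRKY transcription factors** — the plant-specific regulator family
named after the conserved WRKYGQK heptapeptide of its DNA-binding domain.

WRKY surveys of non-model plants (conifers such as *Taxus*, where no
reference genome exists) start from assembled transcripts and proceed
through a well-worn manual workflow: find WRKY domains, count them, type
their zinc fingers, place them on a tree with the labeled Arabidopsis
family to call subgroups, annotate repression motifs, and relate the genes
to treatment-response expression data. `wrkyscan` turns that workflow into
a tested, reproducible pipeline for anyone running such a survey.

## What it computes

**Domain grammar.** A WRKY domain is an N-terminal heptapeptide anchor
(canonically `WRKYGQK`, with `WRKYGKK` the common variant) followed by a
zinc finger:

* C2H2 type — `C-X(4,5)-C-X(22,23)-H-X(1)-H` (Groups I and II)
* C2HC type — `C-X(7)-C-X(23)-H-X(1)-C` (Group III)

The scanner matches heptapeptide variants exactly, then finds the earliest
downstream arrangement of coordinating residues satisfying the spacer
ranges (window: 80 residues).

**Classification.** Two tiers, as in the classical scheme:

1. *Rules*: two complete C2H2 domains → Group I; one C2HC → Group III;
   one C2H2 → Group II, subgroup pending.
2. *Placement*: pending proteins are cut to their domain, aligned by
   anchor-pinning, and placed on a joint neighbor-joining tree with a
   labeled reference panel (e.g. the AtWRKYs). The subgroup (IIa–IIe) is
   the label of the smallest uniformly-labeled clade containing the query;
   truncated single-domain proteins that clade with Group I N-/C-terminal
   domains are rescued into Group I.

**Phylogenetics.** In-repo anchored alignment, p-distance with pairwise
deletion, Poisson correction `d = −ln(1 − p)`, Saitou–Nei neighbor
joining, column-resampling bootstrap, newick I/O.

**Motifs.** EAR repression motifs (LxLxL and DLNxxP classes, literal
subtypes such as LKLDLY reported), LxxLL, HARF (`RTGHARFRR(A/G)P`), and a
heuristic leucine-zipper caller (≥ 4 leucines at exact heptad spacing).

**Expression.** Log2 fold-change contrasts with direction calls,
hierarchical clustering for heatmap ordering, and the 2^−ΔΔCt qPCR
calculator (reference-gene normalized, calibrator = 1).

**Synthetic data.** A generator that emits grammar-conforming proteins per
group with planted motifs, labeled reference panels, expression matrices
and replicated Ct tables — all with known ground truth, so the whole
pipeline is testable offline.

## Worked example

Simulate a labeled survey, classify it, and quantify a planted qPCR
response:

```bash
wrkyscan simulate --seed 7 --out demo/sim
wrkyscan classify --fasta demo/sim/proteins.fasta \
    --panel-fasta demo/sim/panel.fasta \
    --panel-labels demo/sim/panel_labels.tsv --out demo/cls
# {"I": 100, "IIa": 100, "IIb": 100, "IIc": 100, "IId": 100,
#  "IIe": 100, "III": 100, "unclassified": 0, "total": 700}

wrkyscan expr ddct --table demo/sim/ct.tsv \
    --target TcW44-like --calibrator MeJA_0h --out demo/fc.tsv
```

The classification JSON shows every synthetic protein recovered to its
generating group (100 per group). The fold-change table reads:

```
gene        sample   relative_expression  ddct     ...
TcW44-like  MeJA_0h  1.0                   0.000
TcW44-like  MeJA_1h  3.996                -1.999
TcW44-like  MeJA_3h  16.181               -4.016
TcW44-like  MeJA_6h  2.076                -1.054
```

The calibrator (0 h) is exactly 1 by construction; the planted 16.5-fold
induction at 3 h is recovered as 16.18 under replicate Ct noise
(sd 0.05 cycles). `wrkyscan run-all` chains every stage into one report
directory (domain TSV, assignments + counts, motif TSV, newick tree,
contrast/cluster/ddCt outputs, run log).

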