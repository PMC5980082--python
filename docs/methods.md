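# Methods

This note documents the models, parameter choices and numerical decisions
behind `wrkyscan`, and what the synthetic benchmark does and does not show
about real data.

## Domain model and scanner

A WRKY domain is modeled as an exact heptapeptide anchor followed by a
zinc-finger grammar: anchor residues C, C, H, then H (C2H2) or C (C2HC),
with inclusive spacer ranges 4–5 / 22–23 / 1 (C2H2) and 7 / 23 / 1
(C2HC). Matching is exact-string for the heptapeptide — variants are an
enumerated list, not a distance class — because surveys treat variants as
discrete observations. The default variant set is `{WRKYGQK, WRKYGKK}`,
the two forms seen in conifers; five further angiosperm variants
(`WRKYGEK, WRKYGKR, WRKYEDK, WKKYGQK, WHQYGLK`) are available behind the
`extended` switch.

*Search window*: 80 residues downstream of the heptapeptide end. The
canonical domain is ~60 aa, so 80 covers complete fingers with margin
while preventing a truncated domain from borrowing the next domain's
cysteines. *Tie-break*: an anchor whose downstream region satisfies both
grammars is flagged ambiguous and typed C2H2, the overwhelming majority
class; the flag is retained so classification can consult placement.
*Overlaps* keep the leftmost anchor — deterministic and order-independent.
All coordinates are 0-based half-open throughout; 1-based prose belongs in
reporting layers only.

## Classification

Rule tier: ≥ 2 complete C2H2 domains → I; exactly one complete domain →
III (C2HC) or provisional II (C2H2); no complete domain → unclassified
with the scan summary as the reason.

Placement tier: provisional Group II members are excised to their domain,
anchor-aligned together with a labeled reference panel, and placed on a
single joint NJ tree per batch (cheaper than per-query trees and the same
procedure a manual survey uses). The call is the label of the smallest
clade above the query whose non-query leaves are uniformly labeled,
walking rootward from the query leaf; if no uniform clade exists below
the root the nearest reference by corrected distance decides. Reference
labels `I-N`/`I-C` collapse to Group I, which is what rescues truncated
single-domain Group I proteins. Panels carrying labels outside
`{I-N, I-C, IIa..IIe, III}` are rejected at load time (IIf/IIg are not
part of the supported scheme). Bootstrap support is evidence only — it
never gates a label — and defaults to 0 replicates inside `classify_all`
because a thousand-replicate bootstrap on a several-hundred-leaf batch
tree buys nothing for the call itself; the `tree` command computes
supports explicitly when asked.

## Phylogenetics

*Anchored alignment* replaces progressive alignment: WRKY domains are
short and share an invariant heptapeptide, so pinning the anchor column
and padding flanks with terminal gaps approximates a published alignment
without re-implementing ClustalW. Indel-rich domains would misalign
downstream of an insertion; this is a documented approximation, and the
comparison target for trees is topology, not column identity.

*Distances*: proportion of differing sites with pairwise deletion (so
truncated domains keep their comparable columns), then Poisson correction
d = −ln(1 − p), which errors on saturation (p ≥ 1) rather than returning
infinity. *NJ*: standard Q-criterion with Saitou–Nei branch lengths;
negative length estimates are clamped to 0 with the deficit logged at
DEBUG; exact Q ties break on the lexicographically lowest label pair, so
output is permutation-invariant. The returned tree is rooted at the final
trifurcation. *Bootstrap*: columns resampled with replacement, equal
weights, one seeded generator per run; supports are mapped onto the
point-estimate tree's bipartitions only. Replicates whose resampled
columns saturate a distance are skipped (counted against support, never
crashing the run).

## Motifs

EAR motifs are matched by structural class — `L-x-L-x-L` and
`D-L-N-x-x-P` — rather than by the handful of named 6-mers in the
literature; the literal matched core (plus one residue of trailing
context for the LxLxL class) is reported as the subtype, which reproduces
conventional names like LKLDLY while generalizing to unseen subtypes. The
`LXLXLX` spelling sometimes used for the repression core is the same
5-residue class with context, not a separate pattern. Overlapping hits of
one class are all reported (double EAR motifs are biologically
meaningful). The leucine-zipper caller is a spacing heuristic (≥ 4
leucines at exact 7-residue period, I/V tolerated internally behind a
flag) constructed for this package — real zipper annotations usually come
from profile databases, and profile-HMM domains (Plant_zf_clust, CaMBD,
HSF) are deliberately not computed here; they can be merged from a
pre-computed TSV.

## Expression

Contrast log2 fold changes are column differences of a log2-scale matrix;
"significant" is a |log2FC| ≥ threshold call (default 1.0), not a
statistical test — read-level quantification is out of scope, and survey
heatmaps are typically thresholded exactly this way. Masked cells
propagate to a `missing` direction and are excluded from up/down tallies.
Clustering is scipy average-linkage on Euclidean distances with genes
dropped (default) or zero-imputed (flag) when masked; leaf order comes
from scipy's deterministic merge order, which resolves distance ties by
lowest row index. The ddCt calculator averages replicate Ct arithmetically,
subtracts the reference gene per sample and the calibrator per
comparison, and reports 2^−ΔΔCt with the replicate sd carried as
dispersion; no amplification-efficiency correction is applied (the plain
method assumes efficiency 2).

## Synthetic data: what it emulates, and what it does not

The generator emulates the study conditions of a transcriptome WRKY
survey: 100 proteins per group (700 total) at zero mutation load for the
recovery benchmark, a reference panel of 3 domains per label diverged at
rate 0.02, expression over three contrasts (hormone treatment vs control
twice, new vs long-term cell line) with planted up/down fractions
mirroring reported direction counts (≈ 11–25 % up, ≈ 69–74 % down),
effect sizes of 1.5–4 log2 units, 5 % missing cells, and triplicate Ct
tables whose planted inductions include a 16.5-fold response at 3 h — the
largest reported hormone response in the motivating survey — with
replicate noise sd 0.05 cycles.

Domain templates are built deterministically from a hierarchical scheme:
a clade-level signature and filler letter (I; IIa+b; IIc; IId+e; III)
plus a subgroup-level signature and filler letter, so panel distances
reproduce the classical superclade structure. Spacer lengths are drawn
uniformly from the grammar ranges; spacer-block fillers are
single-letter runs so a one-residue spacer difference costs only a few
mismatched columns under anchored alignment.

Deliberate restrictions that make ground truth exactly recoverable:
domain filler excludes C, H, W and L; background excludes C, W and L;
planted motifs sit 7 background residues apart. Consequently synthetic
sequences have no accidental anchors, no spurious zinc-finger
arrangements, no accidental leucine motifs — and a correspondingly
unrealistic residue composition. Passing the recovery benchmark therefore
shows the analyzers implement their stated grammars exactly; it does not
show robustness to the ambiguity of real proteomes (degenerate fingers,
variant-rich anchors, compositional bias), and no indel evolution is
simulated inside domains. The generator writes sequences purely from
templates and never calls the scanner/classifier/motif code, so
generator and analyzers are independent code paths.

## Problem sizes and determinism

The bundled benchmark sizes — 700 proteins, 24-reference panels, 200
random additive matrices of 4–8 taxa, 100 seeded ddCt replicates — run in
a few seconds and were chosen as the package's standard benchmark
configuration. Every stochastic step takes a single seeded
`numpy.random.Generator`; identical spec + seed reproduces outputs
byte-for-byte, and `run_all` serializes its config and seed next to the
results.

## Known limitations

* Anchored alignment degrades on indel-rich or anchor-less domains
  (anchor-less records are a hard error by design).
* Placement quality is bounded by the reference panel; a panel with
  mislabeled or sparse subgroups shifts calls silently (support values
  are reported but do not gate).
* The rule tier trusts the grammar: genuinely degenerate zinc fingers
  type as `incomplete` and land in `unclassified` unless rescued by
  placement.
* Profile-based domain annotation and de novo motif discovery are out of
  scope; the motif set is the classical regex-class set.
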