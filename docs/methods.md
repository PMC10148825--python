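# Methods

## The decision model

PROMETHEE-II ranks m alternatives scored on k criteria by pairwise
outranking. The package implements the method in seven stages.

**Normalization.** Raw scores C_ij are min-max normalized per criterion:
beneficial criteria map through t_j = (C − min)/(max − min), cost criteria
through (max − C)/(max − min). Normalization is affine-invariant: rescaling
a raw column x → a·x + b (a > 0) leaves t_j, and hence everything downstream,
unchanged. A degenerate column (max = min) divides by zero under either
formula; it is mapped to all zeros and flagged, which matches its semantics —
a constant criterion expresses indifference between all alternatives, so it
contributes no preference regardless of its weight.

**Deviations and preference functions.** For each ordered pair (z, y) and
criterion j the deviation is w_j(z,y) = t_j(z) − t_j(y). A preference
function maps deviations to degrees P_j(z,y) ∈ [0, 1], with P = 0 whenever
w ≤ 0 (behaviour at exactly 0 is the zero branch). Seven kinds are
available: the six classical generalized criteria (usual; U-shape with
indifference threshold q; V-shape with preference threshold p; level with
q and p; V-shape-with-indifference with q and p; Gaussian with inflection s)
and `paper-linear`, the identity on positive deviations (clamped at 1).
On min-max normalized scores, deviations already lie in [−1, 1], so
paper-linear coincides with a V-shape criterion whose preference threshold
spans the full score range; it is the default and is what the packaged case
study realizes. Thresholds are validated per kind (q ≥ 0, q ≤ p, s > 0).

**Aggregation and flows.** π(z,y) = Σ_j d_j P_j(z,y) with weights d_j
normalized to sum to 1 (weights already summing to 1 within 1e-9 are left
untouched; otherwise they are rescaled proportionally — never silently, the
validation report says so). Positive and negative flows average π over the
n − 1 opponents; the net flow φ = φ⁺ − φ⁻ induces the complete ranking.
Conservation (Σφ⁺ = Σφ⁻, hence Σφ = 0) and range (φ⁺, φ⁻ ∈ [0, 1]) hold by
construction and are asserted as properties on random problems, alongside
equality with an independent naive double-loop recomputation to 1e-12.

**Ranking.** Competition ranking on descending φ: tied alternatives share
the smallest applicable rank and the next rank skips. Ties are compared
exactly (no tolerance): identical score rows produce bit-identical flows, and
near-ties produced by distinct inputs are genuine distinctions at float
precision. The packaged case study contains two identical alternatives
(In1/In2); they share rank 7, deliberately — identical inputs must receive
identical outputs, even where a published tabulation broke such a tie
arbitrarily.

## Paper mode vs full precision

Published worked examples of this method are tabulated at 3 decimals, and
their flow tables are computed **from the rounded intermediates** (e.g. the
In4 row of the aggregated preference table sums to 4.230, and 4.230/8 =
0.528750 is exactly the printed φ⁺(In4), while the unrounded pipeline gives
0.528498). `mode="paper"` therefore rounds half-up to 3 decimals after
normalization and after aggregation; `mode="full-precision"` (the default
for new analyses, and for all sensitivity and simulation work) applies no
intermediate rounding. Rounding is half *up* on the decimal representation —
ties away from zero, not banker's rounding: the case study contains four
exact 3-dp ties (0.7125, 0.0875, 0.2625, 0.5375) and all four are printed
rounded up. The implementation pre-quantizes at 9 decimals to absorb binary
float noise before applying the half-up rule, so exact decimal ties round
correctly even when their float representation falls an ulp short.

### Corrections to the reference flow table

Two entries of the published flow table for the packaged case study are
inconsistent with the same publication's aggregated preference table:
φ⁻(In5) prints 0.383900 where the column sum gives 3.839/8 = 0.479875
(a division by 10 instead of n−1 = 8 reproduces the printed value), and
φ(In6) prints 0.439125 where φ⁺ − φ⁻ = 0.426625 − 0.043750 = 0.382875.
The package reproduces every arithmetically consistent entry exactly and
reports the recomputed values for these two. Consequence: In9 (φ = 0.420500)
outranks In6 (φ = 0.382875), so ranks 2 and 3 swap relative to the reference
narrative; rank 1 (In4) and ranks 4–9 are unaffected.

## Linguistic elicitation

The 5-point verbal scale maps High→1.000, Average→0.666, Low→0.333,
Very Low→0.250, Null→0.000. Label matching is case-insensitive and
whitespace-trimmed (robustness to hand-edited files). The inverse map
(`from_crisp`) snaps a value in [0, 1] to the nearest scale value, breaking
exact ties toward the better label (deterministic, and compared with 1e-12
slack so decimal ties are recognized despite float representation).

How a 72-expert panel was collapsed into the published decision matrix is
not recorded anywhere; the default here is the **modal label** per cell with
ties toward the better label, selectable against mean-of-crisp and
median-of-crisp. The mode is the default because it preserves membership in
the scale — and every cell of the published matrix is a scale value, which
is consistent with (though not proof of) modal aggregation. The chosen
method is recorded in the output matrix's metadata.

## Sensitivity analysis

`weight_sweep` perturbs the base weights one criterion at a time by a grid
of deltas, renormalizes, and reruns the full-precision pipeline; the base
scenario is always included. One-at-a-time sweeps answer the practical
question ("what if this criterion mattered a bit more/less?") without the
combinatorial blowup of a full factorial. `criterion_knockout` removes each
criterion and renormalizes the remaining weights proportionally — preserving
the decision-maker's relative priorities — rather than equally. Reports
carry each scenario's order, per-alternative rank ranges, reversal pairs,
and Kendall tau-b (tie-corrected) against the base.

Measured on the case study: the top choice In4 is stable to every ±0.05
shift, but it does not dominate In9 (normalized GF2: In9 = 1.000 > In4 =
0.666), and shifting GF3's weight by −0.10 (to 0.111 after renormalization)
promotes In9 to rank 1. The advantage of nintedanib over lenvatinib in this
model rests on the PDGF criterion.

## Synthetic panels

`PanelSpec` defaults mirror the study design: 9 alternatives × 3 criteria ×
72 experts on the 5-point scale. Each alternative has a latent utility
(default: evenly spaced 1 → 0); each criterion applies a loading in [0, 1]
(default 1) to the min-max-scaled utility and snaps to the nearest scale
value; each expert reports the true label except that with probability
`noise` the response slips to an adjacent label (up/down equally, clamped at
the scale ends). Adjacent-label slips, not uniform relabeling, model ordinal
elicitation error: a rater confuses "Low" with "Very Low", not with "High".
The default noise of 0.1 represents mild disagreement; no empirical estimate
of real panel noise exists, so conclusions should be read across the noise
grid, not at the default. Replicate r of an experiment uses seed
`spec.seed + r`, making replicates independent but fully reproducible.

**What recovery means.** Snapping to a 5-level scale is monotone but not
injective: with nine evenly spaced utilities, several distinct utilities
share a label, so even a noiseless panel yields a ranking with ties — the
quotient of the latent order that the instrument can resolve. A replicate
counts as an exact recovery when its ranking equals that noiseless-pipeline
reference ranking; the reported mean Kendall tau-b is computed against the
latent order itself, so it is capped below 1 by quantization (9/√90 ≈ 0.949
for the 5-alternative design) before any noise is added. With this
definition, noiseless recovery is exactly 1.0 — a correctness property, not
an empirical finding. The empirical findings (200 replicates, seed 1):
recovery stays at 1.0 through noise 0.3 for both the 9×3 and 5×3 designs
(the modal label over 72 experts is a very strong estimator), degrades at
0.5 (0.865 / 0.925), and collapses at 0.8; mean tau decreases monotonically
in noise.

**What the generator does not model:** expert covariance (responses are
independent given the truth), per-expert reliability weights, criterion
correlation beyond shared latent utilities, and systematic (biased) rather
than symmetric label error. Passing recovery tests therefore show the
pipeline is a consistent estimator under independent ordinal noise — not
that any real panel of experts behaves this way.

## Numerical and design choices

- Problem sizes: the case study is 9 × 3 and runs in milliseconds; property
  tests use m ≤ 6, k ≤ 3 integer-valued matrices (exact affine-invariance
  checks need lattice inputs); recovery experiments use 200 replicates per
  noise level, a few seconds each.
- The aggregated preference table stores NaN on the diagonal: π(z,z) is
  undefined and excluded from flow sums, not treated as 0.
- The valued outranking graph exports every ordered pair with π ≥ threshold
  (default 0, i.e. both arcs per pair) as an edge list or DOT text.
- Configuration (criteria, scale) is JSON or YAML with hand-rolled
  validation producing named errors; result files are tab-separated with 3
  (paper-mode intermediates) or 6 (flows) decimals, and every run writes a
  `run_manifest.json` (mode, rounding, seed, criteria, warnings, timestamp)
  from which the run can be reproduced.

## Known limitations

- PROMETHEE-I partial preorders and the III–VI/TRI/Cluster/GAIA variants are
  out of scope, as is threshold elicitation from data.
- Verbal-scale arithmetic is crisp: labels carry point values, not fuzzy
  membership functions.
- Sensitivity scenarios are one-at-a-time; the package does not compute
  exact weight-stability intervals.
- The case-study ranking is a model of expert judgement on three growth
  factors; it says nothing about clinical efficacy.
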