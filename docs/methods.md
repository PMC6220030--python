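# Methods

This note records the statistical model, the defaults and the design
choices behind `regiospec`, and what the synthetic validation does and
does not establish.

## Region model and variance moderation

Each probe's log2 expression is fitted by ordinary least squares against
a shared design: intercept, `n_donors − 1` donor indicators, and an
indicator for the focal region. The focal coefficient `beta` is the
probe's log2 enrichment in the region; donors that lack the focal region
still contribute samples (their indicator is 0 throughout), which keeps
the donor baseline estimable from the rest of the brain. The design is
identical for all probes, so the fit is a single matrix solve; a
rank-deficient design (e.g. all of a donor's samples are focal) raises an
error naming the collinearity rather than silently dropping a column.

Residual variances are moderated with a scaled inverse-chi-square prior
`sigma^2 ~ s0^2 d0 / chi^2_{d0}` fitted by moments of log variances:
with `e_g = log s_g^2 − psi(d/2) + log(d/2)`, solve
`psi'(d0/2) = var(e) − psi'(d/2)` when the right side is positive
(trigamma inversion by Newton iteration, bisection fallback, tolerance
1e-8), and `log s0^2 = mean(e) + psi(d0/2) − log(d0/2)`. When the
observed spread of log variances does not exceed chi-square sampling
noise, `d0` is infinite and `s0^2` is the geometric mean of the positive
variances — complete shrinkage, with the moderated t referred to the
normal distribution. Zero-variance probes are excluded from prior
estimation but remain analyzable (`s2_tilde = d0 s0^2/(d0+d)`).

Probe-level p-values are two-sided, with the positive-direction filter
(`beta > 0`) applied after BH adjustment, and strict inequality at the
FDR threshold. Benjamini–Hochberg runs through
`statsmodels.stats.multitest.multipletests`; the test suite checks it
against an independent step-up evaluation.

## Ranking and enrichment

Genes inherit the statistics of their lowest-p probe (ties: larger |t|,
then lexicographically smaller probe id). The genome-wide order is
descending `sign(t)·(−log10 p)` with p floored at 1e-300 before the log
so underflow cannot scramble the top of the list; residual ties fall
back on |t| and then the gene symbol, making the order a deterministic
total order. Genes with exactly zero effect sit between the positive and
negative blocks — a measure-zero case where any deterministic convention
serves.

Gene sets are intersected with the ranking's universe and filtered to
sizes in the inclusive interval [10, 200] (both bounds are exposed).
AUROC is computed from midranks of the signed scores, so tied scores
contribute half a win per pair; `AUROC = U/(n1·n2)`. The one-sided
Mann–Whitney p uses exact enumeration of the U distribution when
`n1·n2 ≤ 500` and the scores are tie-free, and otherwise the normal
approximation with continuity correction and the standard tie correction
`sigma_U^2 = n1 n2 (N+1)/12 − n1 n2 Σ(t^3−t)/(12 N (N−1))`. Sets with
AUROC ≤ 0.5 keep their statistics but are flagged as not examined,
reflecting the one-sided focus on specific (not depleted) expression.
BH correction spans whatever collection is scored in one call;
correcting across collections is deliberately left to the caller, since
the appropriate family depends on the analysis.

## Specificity sweep and cross-dataset validation

The sweep re-runs the identical procedure — fit, prior estimation,
moderation, collapse, ranking, AUROC — with every named region as focal.
The variance prior is re-estimated per region because the residual
structure changes with the design. A set's specificity rank is the count
of *other* regions with a strictly higher AUROC (ties are not counted,
and sibling subdivisions of the focal structure are ordinary competitors).
Rank-deficient regions are skipped with a warning and excluded from
ranks. The cross-dataset filter keeps sets that are BH-significant in
the primary atlas, have specificity rank at most a chosen bound
(0 by default, relaxable to 1), and show nominal one-sided replication
(p < alpha with AUROC > 0.5) in the second atlas.

## Concordance tails

Overlap of two significant-gene lists in a universe of N genes is tested
with the exact upper-tail hypergeometric sum; replication of k of n
findings at null rate p0 with the exact upper-tail binomial sum. Both
accumulate log-pmfs via logsumexp, and report log10(p) alongside p so
values far below the double-precision underflow threshold (~1e-308)
remain comparable. The universe defaults to the genes entering both
rankings and is overridable.

## Marker-gene proportions

For one donor and one cell type, marker genes are collapsed probe→gene
by the highest-mean probe (a representativeness criterion — unlike the
ranking's min-p rule, there is no test here), standardized across the
donor's samples, and summarized by the first principal component of the
samples-by-markers matrix. The component is flipped if the sum of marker
loadings is negative, so higher scores always mean more of the cell
type; the marker-expression transform is the identity. Cell types with
fewer than two usable markers in a donor are skipped with a warning, and
zero-variance markers are dropped. Donor scores are averaged per region,
z-scored across regions within the donor, averaged across donors (regions
absent from a donor use the remaining donors), and ranked per cell type
by the strictly-greater count, so rank 0 is the region with the highest
estimate and full ties all receive rank 0.

## Synthetic study conditions

The generator draws
`y = mu_gene + shift[gene, donor] + delta·1[focal] + eps`, with
`mu_gene ~ N(7, 1.5^2)` log2 units, gene-by-donor shifts
`N(0, 0.5^2)` (a per-gene draw per donor, so the donor covariate is
non-trivial), probe variances from the inverse-chi-square prior with
`(d0, s0^2) = (4, 0.25)`, and `delta = 2` log2 units in 5% of genes.
Defaults: 1,500 genes with 1–3 probes each (60/30/10%), 3 donors, 25
regions — the focal region with 3 samples per donor, decoys with 1–3 —
five spiked sets (90% of members spiked) and five size-matched null sets
of 10–30 genes. One root seed feeds every stream. The marker mixture
uses 30 regions, 3 donors, 3 samples per region, Dirichlet-distributed
true proportions, marker effect `lambda = 1` and noise sd 0.3. These
sizes keep a full 20-replicate sweep comfortably within a desktop run
while leaving each region as sparsely sampled as real atlases.

What the generator does *not* emulate: raw-intensity physics, batch or
dissection artifacts, spatial autocorrelation between neighboring
regions, correlated gene modules, or probe-specific binding biases.
Passing the synthetic checks therefore demonstrates the statistical
machinery is correct and calibrated under the assumed model, not that
atlas-specific artifacts cannot distort real-data results.

## Numerical choices

OLS via the normal equations on the shared design (one inverse, all
probes vectorized), checked against an independent solver to 1e-10 in
tests. Exact U tail by dynamic programming over placements; the p floor
1e-300; BH q clipped to [0, 1]; hypergeometric/binomial tails in log
space. All sort-based operations use stable sorts with explicit
tie-break keys so every output is reproducible bit-for-bit under a fixed
seed.

## Known limitations

- No array weights, duplicate-correlation, or surrogate-variable
  adjustment: input atlases are assumed pre-normalized.
- Enrichment is AUROC/Mann–Whitney only; no permutation-based or
  walking-statistic alternatives.
- Min-p probe collapse ignores information in a gene's other probes.
- Cell-type scores are relative (first-PC projections), not absolute
  proportions, and depend on marker list quality.
- The specificity sweep is exhaustive and exact but O(regions) refits;
  no caching or approximation is attempted.
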