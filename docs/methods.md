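# Methods

This note documents the models, estimators and numerical choices behind
`neurocoex`, what the synthetic generator does and does not emulate, and
the design decisions taken where the procedure was genuinely open.

## Risk-gene mapping

A disorder's risk genes are all genes whose interval overlaps a target
block: the window (default ±250 kb, configurable) around a tag SNP with
association p below the disorder's threshold (5e-8 for the well-powered
GWAS; 1e-5 for the underpowered one). Overlapping blocks on a chromosome
are merged, keeping the most significant tag. The window is an explicit
approximation: reconstructing empirical LD block boundaries requires a
genotype reference panel, which is out of scope, so block extent is a
single tunable length. An optional `max_tag_distance` drops genes whose
midpoint lies far from the tag, a guard against marginal genes in very
large blocks; it is off by default because no principled default exists.
Coordinates follow the named standards: BED is 0-based half-open, GWAS
positions 1-based, and overlap tests convert the latter to half-open
intervals, so a gene `[100, 150)` does not overlap a block starting at
150.

## Coexpression networks

Genes are kept when they have nonzero expression in at least half the
samples and a coefficient of variation (sd/mean on the raw scale) above
0.3, then transformed as `log10(x + 1)` — the `+1` keeps zeros finite,
which the bare log transform leaves unspecified. The network is signed:
`a_ij = ((1 + r_ij)/2)^β` with Pearson `r` (the field's default; nothing
in the analysis requires a robust correlation). β is chosen as the
smallest power whose signed scale-free fit index reaches 0.8, where the
index is `−sign(slope) · R²` of the log–log regression of the binned
degree distribution (10 equal-width connectivity bins, empty bins
dropped); a decreasing distribution therefore scores positively. A
configured β overrides the fit, and the pipeline's epoch networks
default to the reference powers (12 prenatal, 16 postnatal): on block-
structured data the scale-free index is uninformative (see the note on
scale-freeness below), so its argmax is an unstable basis for β, while
the fixed powers are part of the reference study's stated conditions.
Auto-selection remains available via `soft_power_auto`.

Topological overlap is computed densely:
`TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`l_ij = Σ_u a_iu a_uj` and `k_i = Σ_u a_iu`; the matrix product form is
exact because the adjacency diagonal is zeroed, and the result is
symmetrized and clipped to `[0, 1]` against floating drift. Modules are
flat clusters of average-linkage trees on `1 − TOM` cut at a fixed
height (default 0.3); clusters under 20 genes become unassigned, and
clusters over 1000 are re-cut at progressively lower heights (factor
0.75 per step), falling back, for indivisible clusters, to keeping the
best-connected core by within-cluster TOM rank — the connectivity
analogue of kME available before eigengenes exist. The fixed-height cut
replaces dynamic tree cutting deliberately: it is a one-parameter,
exactly reproducible rule, and the planted-structure tests show it
recovers block modules whenever within-module topological overlap
exceeds `1 − h`. Everything is processed in one block; block-wise
machinery in reference implementations is a memory workaround, not
method. Module labels M1, M2, … are assigned by decreasing size and
carry no meaning across runs or epochs.

Module eigengenes are the first right singular vector of the module's
gene-standardized expression (unit norm, sign-aligned to correlate
positively with the module's mean profile), with variance explained
`s₁²/Σs²`. kME is the Pearson correlation of each gene with each
eigengene; zero-variance genes get kME 0 and are flagged. Eigengene
trajectories across developmental stages use LOWESS (locally weighted
linear regression, tricube weights, span 0.75) on the stage rank,
averaged per stage; with fewer than four distinct stages the fit
degenerates to stage means.

A note on scale-freeness: planted-block data has an intrinsically
bimodal connectivity distribution (background genes near zero, module
genes on a plateau proportional to module size), so the scale-free fit
index stays low on the default generator no matter the power — as it
should. The fit machinery itself is validated on data with a heavy-tailed
continuum of gene–factor couplings, where the index exceeds 0.8 at an
intermediate power.

## Enrichment statistics

Risk-gene × module enrichment uses the two-sided Fisher exact test (the
sidedness is configurable; two-sided is the conservative default), with
the background defined as the full network universe — every gene
surviving the expression filter, unassigned genes included — because
risk lists are restricted to that universe first. Odds ratios are
`ad/bc` with a Haldane 0.5 correction when a cell is zero. BH adjustment
runs across modules per disorder, and the minimal-p module is flagged.
Negative controls repeat the test in the disease module with
disorder-size-matched random gene sets (standing in for trait sets such
as height/BMI); a control passes when its nominal p exceeds 0.05.

Gene-set over-representation is the upper-tail hypergeometric
`P(X ≥ k)` with the set intersected against the background; sets of ≤10
genes are dropped before testing, and the reporting filter (adjusted
p < 0.05, 20 < size < 500) is applied after BH — mirroring the two
separate filters the procedure states.

The primary-module rule: for each disorder, take the genes shared by its
prenatal and postnatal enriched modules and bootstrap their specificity
across the eight stages; each epoch's evidence is its best stage result
among folds > 1, the significant epoch's module wins, and exact ties or
double nulls return "undetermined" (the pipeline then falls back to the
lowest-p enriched module).

## Specificity bootstrap

The specificity matrix divides each gene's condition mean by its sum
over conditions (rows sum to 1; all-zero rows are dropped with a
warning). The enrichment statistic is the target set's mean specificity
— equivalent to the sum at fixed set size. B random same-size sets are
drawn from the background *without replacement within a draw* (a gene
set cannot repeat a gene), independently across draws; one family of
draws is scored against every condition. `p = (r + 1)/(B + 1)` with `r`
the number of draws at least as large, so p is never zero and B = 10⁴
bottoms out at 10⁻⁴ — the convention behind "p < 0.0001" reports. Stage,
region and cell-type tests are independent runs of the same machinery
with different condition keys.

## Moderated differential expression

One least-squares model per gene against the shared design (intercept,
treatment-coded three-level group with controls as baseline, RIN, pH,
age in years, PMI in hours, sex as 0/1), with both disease contrasts
read off the same fit so they share the variance estimate. The
empirical-Bayes prior (d0, s0²) is estimated by moment-matching the
scaled-F model of the sample variances on the log scale: with
`e_g = log s²_g − ψ(d/2) + log(d/2)`, the excess of `var(e)` over
`ψ′(d/2)` equals `ψ′(d0/2)`, solved by Newton iteration on the trigamma
function, and `s0²` follows from `mean(e)`. Non-positive excess takes
the `d0 = ∞` branch (all genes share `s0²`, normal reference
distribution); `d0 = 0` is an explicit override that recovers the
ordinary t exactly (the test suite asserts the identity to 1e-10).
The moderated t uses the posterior variance on `d0 + d` degrees of
freedom, BH within each contrast, and DEGs are adjusted p < 0.05.
Cross-disorder convergence is the Pearson correlation of the full logFC
vectors plus the upper-tail hypergeometric test of the DEG-list overlap
against the tested-gene background.

## Preranked GSEA

Genes are ranked by descending logFC with lexicographic tie-breaking
(fully deterministic). The enrichment score is the weighted KS walk with
exponent 1: hits add `|metric| / Σ_hits|metric|`, misses subtract
`1/(N − N_hits)`; the running sum ends at zero by construction, and ES
is its signed extremum, positive preferred on exact |ties| (with a
1e-12 tolerance so the vectorized and sequential paths agree bit-level).
The leading edge is the hits up to a positive extremum, or from a
negative extremum onward. The null is gene-label permutation — B random
same-size sets, with sets of equal size sharing one null batch — because
the input is a preranked list and no phenotype labels exist. NES divides
ES by the mean |ES| of same-sign permutations, and the nominal p is the
same-sign tail proportion `(r + 1)/(n_same + 1)`: the conditional
denominator is what makes the null p uniform (an unconditional `B + 1`
denominator caps p near 0.5 and breaks calibration), while the
no-zero-p floor is preserved since `n_same ≤ B`. BH runs across tested
sets; module GSEA feeds each coexpression module through the same
engine.

## Subnetworks and hubs

From a module's TOM, the subnetwork keeps the module's risk genes plus
every gene whose best TOM *to a risk gene* meets the cutoff (default
0.1) — anchoring is strictly risk-gene based, never transitive — and all
intra-node edges at the same cutoff. Degrees are stored and re-validated
against the edge list. Hubs must clear both a degree quantile (default
0.9) and a kME floor (default 0.8); the reference analysis reports
exemplar hub values but no rule, so both thresholds are explicit
parameters. Node annotations (risk flag, up/down DEG flags, set
memberships) are boolean columns, exportable to GraphML.

## Synthetic data

Expression is a factor model on the log10 scale. Module m has a latent
trajectory `F_m`: a Gaussian bump over the eight ordinal stages (four
prenatal, four postnatal; peak stage planted per module, width 2
stages), multiplied by a region weight (1 in the module's preferred
region class — cortex, limbic or cerebellum — 0.4 elsewhere), plus
sample-level jitter (sd 0.3) playing the role of donor variation, then
standardized. Gene g in module m is
`z_g = μ_g + λ_g F_m + ε`, with μ_g ~ N(1.5, 0.25), loadings
λ ~ U(0.9, 1.1) and noise sd 0.15; background genes are pure noise
(sd 0.3); a further 15% of genes are constant or mostly-zero filler so
the expression filter has work to do. RPKM output is `10^z − 1` floored
at zero, which `log10(x + 1)` inverts exactly. The noise scale is
deliberately low relative to the factor: strongly trajectory-driven
developmental expression has near-deterministic stage profiles, and it
puts within-module topological overlap above the 0.7 the fixed 0.3 cut
height requires — the regime the fixed-height design targets.

Designated disorder modules sit mid-epoch (OCD: peak stage 3, cortical,
excitatory-neuron elevated; AN: peak stage 6, limbic, endothelium
elevated) so that each is fully recoverable in its own epoch's network
and partially in the other's — giving the cross-epoch module pairs the
primary-module rule needs. Risk lists (92 AN, 51 OCD, matching the
source counts) place a fraction f = 0.3 inside the designated module and
the rest uniformly elsewhere; each planted risk gene carries one tag SNP
inside its interval with log-uniform sub-threshold p, on a toy genome of
10 kb genes tiled 50 kb apart on two chromosomes. The emitted config
sets the block window to 20 kb to match that tiling, so recovered risk
lists equal the planted ones exactly.

The case/control cohort (102/16/15, mirroring the source groups) draws
covariates from plausible ranges (RIN 5–9, pH 6–7, age 16–70 y, PMI
5–40 h, sex Bernoulli), small per-gene covariate coefficients, residual
variances from scaled-inv-χ²(d0 = 4, s0² = 0.04), and 300 DE genes whose
(ED, OCD) effect pairs come from a bivariate normal with sd 0.8 and
correlation ρ = 0.7; 20% of DE genes are drawn from the AN module with a
−0.8 mean shift, so that module reads out as downregulated in ED cortex
(negative module NES, concentrated down-DEG flags in the AN
subnetwork). With these defaults the observed all-gene logFC correlation
sits near 0.7: the planted signal dominates, while estimation noise and
the shared control group perturb it by only a few hundredths.

What the generator does **not** emulate: batch or donor-identity
structure beyond the shared factor jitter, microarray probe chemistry
and probe-to-gene collapse, LD beyond a fixed window, overlapping or
hierarchical modules, and realistic scale-free degree continua (block
models are bimodal in connectivity by construction). Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated model, not robustness to those real-data complications.

## Problem sizes and determinism

Default study sizes (2000 genes, 216 developmental samples, 133 cohort
samples) keep every stage dense-matrix in memory; statistical tests in
the suite use 20–50 seeded replicates, bootstrap/permutation counts of
300–2000, and reduced gene counts (600–800) where many replicates are
needed — sizes chosen so planted-recovery rates and null calibrations
are measured with useful precision. All randomness flows from a single
seed through named child streams; pipeline runs are byte-identical
under a fixed config, and every output table carries the seed and
parameter echo in its header.

## Known limitations

* The fixed-height cut requires strong modules; diffuse modules (within-
  module TOM below `1 − h`) dissolve into unassigned genes rather than
  being found at a different height.
* The Fisher background ("network universe, unassigned included") is one
  defensible choice among several; the enrichment tables record it.
* Bootstrap and permutation p-values inherit the `1/(B + 1)`-type floors;
  claims beyond the floor require raising B.
* The OCD-style GWAS quality filter (per-SNP case/control counts) applies
  only when those optional columns exist; synthetic summaries omit them.
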