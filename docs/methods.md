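# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `clonarch`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## CCF posterior and the clonality rule

The CCF model assumes a single mutated copy (multiplicity m, estimated as
`clamp(round(vaf·D/ρ), 1, major)` with `D = ρ·(major+minor) + (1−ρ)·2`) in a
tumor of purity ρ. The posterior is the binomial likelihood of the observed
alt count evaluated on a uniform grid c = 0.01 … 1.00 under a flat prior.

Two conventions matter:

* **Super-clonal folding.** The likelihood is evaluated on a grid extended to
  2× the clonal CCF, and all mass above c = 1 is folded into the c = 1 bin.
  Without folding, a truly clonal mutation whose sampled VAF lands above its
  expectation would paradoxically lose posterior mass at high CCF, and even a
  perfectly balanced het observation (a/d = 50/100 at ρ = 1) would be called
  subclonal. Folding mirrors how purity/ploidy callers accumulate a clonal
  peak. The exported posterior still lives on the 100-point grid and sums
  to 1.
* **Strict thresholds.** Clonal iff Pr(CCF ≥ 0.95) > 0.5, with strict
  inequality; Pr exactly 0.5 is subclonal.

**Decisiveness depends on depth.** The posterior standard deviation in CCF
space is roughly `(2/ρ)·sqrt(f(1−f)/d)`. Exact computation over the binomial
sampling distribution shows that at 100× (whole-exome-like depth) a truly
clonal SNV is called clonal only ~30–60% of the time across purities
0.6–1.0, so cohort subclonal fractions at that depth are dominated by
classification noise, not biology. The clonality-recovery study in the
acceptance suite therefore uses deep-targeted-panel conditions — depth ~
Poisson(4000), purity ~ Beta(40, 8) (mean 0.83) — under which the
misclassification rate is below half a percent and a planted subclonal
fraction is recovered to within a fraction of a percentage point. The
generator's *default* depth remains Poisson(100) truncated at 10, matching
exome-like data; results computed at that depth should be read as noisy by
construction.

SCNA clonality: an event's CCF is the length-weighted mean of its member
segments' CCFs (supplied by the generator's truth table, or by any caller
the user trusts); the event is clonal at CCF ≥ 0.95.

## Clonal/subclonal enrichment and temporal ordering

Per feature (gene or arm event), each permutation redraws the feature's
clonality labels from the cohort-wide label pool without replacement,
holding the call count fixed — equivalently the permuted clonal count is
hypergeometric, which is how it is sampled. Both one-sided empirical P
values carry the +1 correction (never zero); BH adjustment runs across
features, significance at q < 0.1.

Temporal ordering is a documented stand-in, not a reconstruction of any
published tool: features ranked by mean carrier CCF (descending), bootstrap
percentile intervals on the mean, rank tertiles labeled
early/intermediate/late, ties broken lexicographically, features with fewer
than 3 carriers excluded.

## Heterogeneity metrics

MATH = 100·MAD/median of mutant-allele fractions, with MAD scaled by 1.4826
(normal-consistency constant, the convention of the metric's ecosystem).
CCF entropy uses the MAP CCF per mutation, ten equal-width bins over (0,1],
natural log; both the bin count and the use of point estimates (rather than
posterior-weighted bins) are configurable/documented choices.

## Signature extraction (ARD KL-NMF)

The 96 contexts order pyrimidine-strand substitutions C>A, C>G, C>T, T>A,
T>C, T>G by 5' then 3' flank, `A[C>A]A … T[T>G]T`; purine-strand records are
reverse-complemented. Indels never enter spectra.

Extraction minimises the KL divergence D(V ‖ WH) plus an automatic-relevance
penalty: component k has scale λ_k with exponential (ℓ1) priors on its W
column and H row; the MAP updates are the standard multiplicative rules with
`1/λ_k` added to the denominators and
`λ_k = (ΣW_k + ΣH_k + b)/(F + N + a + 1)`. Hyper-parameters: shape a = 10,
scale b = sqrt(mean(V)) (matched to the per-entry data scale); both
configurable. The objective is monotone under these updates and asserted
non-increasing every sweep (tolerance 1e-6 relative, covering float noise).
After convergence, components holding less than 1% of the reconstructed
mutation mass are pruned (configurable), W columns are normalised to sum 1
with the scale moved into H, and the best of `n_restarts` runs by final
objective is returned. The exact prior family of ARD variants differs
between published implementations (exponential vs half-normal); the
exponential form is used here and the recovery properties are what the
tests pin down: rank-1 data collapse to one component, and a 3-signature
300-sample cohort with ≥100 mutations/sample is recovered exactly
(K = 3, cosine ≥ 0.95 per signature) in ≥ 9/10 seeds.

Per-mutation attribution assigns signature argmax_k W[context,k]·H[k,sample]
(ties to the lowest index, for determinism), aggregated separately within
clonal and subclonal calls; counts are conserved by construction.

MSig clustering transforms activities per signature as z(log10(count+1))
— a monotone, zero-safe reading of "log-scaled z-scores" — and applies Ward
linkage on Euclidean distance. K is chosen by the elbow on total
within-cluster sum of squares, implemented as the smallest K whose
improvement from K to K+1 falls below 10% *of the total sum of squares*
(wss at K = 1). Measuring the drop relative to wss(K) instead — a literal
per-K ratio — never triggers on Gaussian-like data, because splitting pure
noise keeps reducing wss by 25–40% of its current value at every K; the
fraction-of-total-variance form is the standard usable elbow.

## Gene–signature association (curveball permutation test)

Tested genes: union of genes with non-silent carrier frequency ≥ 5% and any
supplied panels (SMGs, APOBEC family, DNA-repair lists) present in the
matrix. The null model preserves both margins of the binary mutation matrix
exactly via curveball trades: two random rows exchange a random subset of
their symmetric difference, preserving row sums by construction and column
sums because entries only swap rows. Default 5×n_rows trades between
ensemble draws with a 5× burn-in; ensemble uniformity is verified against an
exhaustively enumerated 4×4 fixed-margins ensemble (χ² goodness of fit).

The discrepancy measure is the one-tailed Wilcoxon rank-sum P (carriers
higher; the opposite tail available via the activity sign). Observed and
null statistics use the identical computation per gene: SciPy's exact null
when both groups have ≤ 20 untied observations, otherwise midrank normal
approximation with continuity and tie correction. `p_perm =
(1 + #{P_null ≤ P_obs})/(n_perm + 1)`; BH across all (gene, signature)
pairs; genes with zero carriers or zero non-carriers are flagged untestable
rather than tested. Under an exchangeable null the p_perm distribution is
uniform (Kolmogorov–Smirnov checked in the acceptance suite).

## SCNA scoring

Allele states: 0 = deletion, 1 = normal, ≥2 = amplification. The segment
score covers four overlapping prose clauses with one deterministic mapping;
note the homozygous (0,0) case scores +1 ("both altered, same direction"),
made explicit because the clauses overlap. Scoring operates on *maximal
runs*: contiguous same-state segments within an arm are coalesced first, so
splitting a segment into identical-copy pieces can never change any score.

Arm events require the cumulative altered length of one sign to strictly
exceed 50% of the arm; chromosome events require every arm modeled for that
chromosome to pass with the same sign — on acrocentric chromosomes (q-only
in the default arm model) the q arm alone suffices. Scope partition:
chromosome > arm > focal, each altered segment counted exactly once.
Segments must be fully contained in one modeled arm (input segmentation is
split at arm boundaries); sex chromosomes are simply omitted from the
default arm model. Frequent arm events keep (arm, sign) features at ≥ 30%
carrier frequency, chromosome events counting for their arms.

## Subtyping

The CCF feature matrix uses raw CCFs in [0, 1] (no row standardisation), so
clonal-vs-subclonal magnitude is what the factorisation sees. Rank-2
Lee–Seung NMF (squared Euclidean loss, multiplicative updates, objective
asserted non-increasing, best of 10 restarts) labels samples by argmax
coefficient; the label-swap ambiguity is removed by naming the cluster with
the higher mean ArmL "A" (the SCNA-high, worse-architecture cluster
semantics). Contrasts: Fisher's exact per binary feature with the sample
odds ratio, +0.5 Haldane correction applied and flagged whenever a cell is
zero (reported rather than "not applicable"); two-sided rank-sum per
continuous metric; BH within each family, significance q < 0.1.

## ssGSEA

Genes are ranked by expression descending, ties broken by gene name for
determinism. With rank values N…1, the in-set ECDF accumulates
|rank value|^0.25 and the out-of-set ECDF accumulates uniformly; the score
is the sum over positions of their difference. No cross-sample rescaling is
applied. Any monotone per-sample normalisation of the expression input
leaves the weight-0 statistic invariant and only reweights the default
statistic; inputs are therefore accepted as-is. One caution shown by the
tests: strongly shifting one gene set displaces every other gene's ranks,
so other sets' scores shift too — between-group comparisons of untouched
sets are only a clean null when nothing in the sample was perturbed.

## Synthetic cohorts: what they emulate, and what they do not

The generator produces populations differing *only* through configured
parameters: per-population signature mixtures (per-sample mixtures are
Dirichlet draws centred on the population mixture, concentration 1.0 —
without tumor-to-tumor exposure variability the cohort count matrix is
rank-1 and no method could recover the mixture), clone structure (one clonal
population plus 0–3 subclones with CCFs in (0.1, 0.8); each mutation
subclonal with probability 0.3 by default), purity ~ Beta(8, 4), depth ~
Poisson(100) clamped at ≥ 10, driver-gene Bernoulli rates (clonal with
probability 0.9), arm/chromosome/focal SCNA events (arm coverage 60–95%,
focal 5–30%), and log-normal expression with additive log-scale immune-set
shifts per planted subtype. Mutation multiplicity is fixed at 1 on a (1,1)
background by default so CCF inference is isolated from copy-number
confounding; a configurable copy state produces the copy-number-aware case.

Not emulated: read-level artifacts, germline contamination, mutation
hotspots, signature–clonality coupling beyond what is planted, batch
effects, subclonal copy-number mosaic within a segment, and realistic
gene-to-position mapping (positions are uniform, genes are a label pool).
Passing tests therefore demonstrate correctness of the *methods* under the
stated generative assumptions, not robustness to real-data artifacts.

Problem sizes used by the test and acceptance runs (chosen to keep the
statistical checks decisive at desk scale): clonality recovery N = 200
samples × ~100 mutations; null calibrations 150–200 simulated features at
n_perm = 1000–2000; signature recovery 300 samples × ~120 mutations × 10
seeds; subtyping N = 200 × 10 seeds; curveball uniformity 10⁴ draws.

## Determinism

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from the config seed, and generator stages use independent
substreams over a shared sample table so stages can run in any order.
Re-running with the same config yields byte-identical TSVs (verified by the
acceptance suite).

## Known limitations

* The clonality rule is depth-limited (quantified above); no cohort-level
  shrinkage or multi-mutation pooling is attempted.
* ARD pruning at 1% mass can absorb a genuinely tiny signature into a
  larger one at small cohort sizes (the README example shows two minor
  signatures merging at N = 60).
* The elbow and the rank-2 choice are heuristics; K is exposed, not
  inferred, for subtyping.
* Arm-event CCFs trust the supplied segment CCFs; no independent SCNA CCF
  inference from read counts is performed.
* Survival modeling, WGD inference, expression-subtype concordance and raw
  read processing are intentionally outside the package.
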