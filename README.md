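# clonarch

Clonal-architecture analysis of tumor cohorts, built around the kind of
multi-population bladder-cancer study in which per-patient somatic data
(mutations with read counts, allelic copy-number segments, purity, expression)
are integrated into: clonality calls for every somatic event, mutational-
signature activities, copy-number burden scores, intra-tumor heterogeneity
metrics, molecular subtypes derived from the clonal feature matrix, and
immune-infiltration scores. A synthetic-cohort generator with full ground
truth makes every stage testable without any external data.

## What it computes

**Cancer cell fraction (CCF) and clonality.** For an event with `a` variant
reads of depth `d` in a tumor of purity ρ on a segment with integer allelic
copies (major, minor), the expected VAF at CCF `c` is

    f(c) = ρ·m·c / (ρ·(major+minor) + (1−ρ)·2)

with multiplicity `m = clamp(round(vaf·D/ρ), 1, major)`. The posterior over a
100-point CCF grid is the binomial likelihood `Bin(a | d, f(c))` under a flat
prior, with super-clonal likelihood mass folded into the CCF = 1 bin. An
event is **clonal** iff Pr(CCF ≥ 0.95) > 0.5, else **subclonal**.

**Mutational signatures.** Per-sample 96-trinucleotide-context spectra are
factorised by multiplicative-update NMF under the KL (Poisson) divergence
with automatic relevance determination: each component carries a relevance
scale λ_k with exponential priors on its loadings, so unneeded components
collapse and are pruned — the number of signatures is inferred. Extracted
spectra are matched to a reference catalog by cosine similarity; each
mutation is attributed to the signature maximising `W[context,k]·H[k,sample]`,
split by clonality. Samples are clustered on `z(log10(activity+1))` with
Ward linkage (MSig clusters), K picked by a within-cluster-sum-of-squares
elbow.

**Gene–signature associations.** The binary gene × sample non-silent
mutation matrix is randomized by the **curveball** algorithm (margins kept
exactly: every gene's carrier count, every sample's mutation burden). The
discrepancy per (gene, signature) pair is the one-tailed rank-sum P comparing
carriers' attributed burden with non-carriers'; the permutation P is the
fraction of randomized matrices at least as extreme, BH-adjusted (q < 0.1).

**SCNA burden.** Per segment, score S ∈ {0,1,2}: 0 both alleles normal, +1
one allele altered or both altered in the same direction, +2 one amplified
and one deleted. An arm event needs > 50% of the arm altered in one sign;
chromosome events need every modeled arm to pass in the same sign; other
altered segments are focal. ChromL / ArmL / FocalL sum S within each scope
(cohort z-normalised); the total normalized SCNA level is ΣS over all
segments divided by total segment length.

**Heterogeneity.** MATH = 100·MAD/median of VAFs (MAD with the 1.4826
constant) and the Shannon entropy of CCFs over ten equal-width bins.

**Subtyping.** The feature × sample matrix of CCFs (driver genes: max CCF;
frequent arm events: length-weighted mean segment CCF; absent = 0) is
factorised at rank 2 by Lee–Seung multiplicative updates; each sample's
cluster is the argmax coefficient, and the SCNA-high cluster is named "A".
Clusters are contrasted by Fisher's exact test (odds ratios, Haldane-corrected
and flagged when a cell is zero) and two-sided rank-sum tests, BH-adjusted.

**Immune scoring.** ssGSEA: genes ranked by expression, weighted running sum
(weight 0.25) of in-set vs out-of-set empirical CDFs per cell-type gene set,
compared between groups by rank-sum + BH.

## Worked example

```bash
clonarch run --outdir demo --seed 42   # synthetic cohort + full pipeline
```

or, configured from Python — a 60-sample three-population cohort with two
planted architectures (A: TP53/RB1, del(9p), del(17p); B: FGFR3/HRAS,
amp(1q)) and immune shifts (B: CD8/Th17 up; A: Th2/macrophages up):

```python
from clonarch.pipeline import PipelineConfig, Thresholds, run_pipeline
cfg = PipelineConfig(outdir="demo", rng_seed=42, synthetic=dict(
    populations={"Asian": 20, "Black": 10, "White": 30},
    driver_genes={"KDM6A": 0.3, "ARID1A": 0.25},
    arm_event_probs={"del(8p)": (0.25, 0.1)},
    subtype_driver_rates={"A": {"TP53": 0.9, "RB1": 0.8},
                          "B": {"FGFR3": 0.9, "HRAS": 0.8}},
    subtype_arm_rates={"A": {"del(9p)": (0.9, 0.05), "del(17p)": (0.8, 0.05)},
                       "B": {"amp(1q)": (0.85, 0.05)}},
    immune_shifts={"B": {"CD8 T cells": 1.2, "Th17 cells": 1.2},
                   "A": {"Th2 cells": 1.0, "Macrophages": 1.0}}),
    thresholds=Thresholds(n_perm=1000, nmf_restarts=2))
run_pipeline(cfg)
```

Selected outputs this run prints to `demo/`:

```
clonality_summary.tsv
  event_class  n_clonal  n_subclonal  subclonal_fraction
        indel        88           96            0.521739
         scna        91           10            0.099010
          snv      2818         3199            0.531660

signature_matches.tsv
  signature best_match   cosine
       SIG1       REF1 0.998026
       SIG2       REF2 0.997929
       SIG3       REF3 0.994853
       SIG4       REF4 0.763782

subtype_contrasts_binary.tsv (q < 0.1)
   feature  prevalence_A  prevalence_B  odds_ratio
     TP53        0.9375         0.000       695.4
  del(9p)        0.9688         0.000      1197.0
    FGFR3        0.0000         0.857         0.003
  amp(1q)        0.0000         0.821         0.004

immune_contrasts.tsv
    cell_type  median_A  median_B            q
  CD8 T cells   -26.1      151.5     5.0e-11
   Th17 cells    14.8      161.0     5.0e-11
    Th2 cells   203.5       56.2     5.0e-11
```

The rank-2 NMF labels match the planted subtypes exactly (ARI = 1.0 against
the generator's truth table, `truth_samples.tsv`). The high subclonal SNV
fraction (53%) reflects genuine posterior uncertainty at 100× depth: a
truly clonal mutation at that depth often cannot reach Pr(CCF ≥ 0.95) > 0.5;
deep-panel depths make the rule decisive (see `docs/methods.md`). Three of
the five reference spectra are recovered at cosine ≥ 0.99; the two minor
Asian-only signatures merge at this cohort size (SIG4), which resolves at
larger N.

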