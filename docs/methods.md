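# Methods

## Scope

`haplopred` covers the pipeline from phased SNP panels to evaluated genomic
predictions: pairwise LD (D, D′, r²), marker QC, haploblock partitioning at
a D′ threshold, block-variant enumeration, three design encodings,
pedigree relationship matrix, two Bayesian linear models fit by Gibbs
sampling, and an evaluation layer (reliability, bias slope, Hotelling's
dependent-correlation test, top-k overlap) driven over a 13-scenario grid.
Imputation and phasing are out of scope: panels enter phased and complete.

## LD measures

For loci A and B with reference-allele frequencies p_A, p_B and joint
haplotype frequency f(A₁B₁) counted directly over all 2n phased haplotypes,

    D  = f(A₁B₁) − p_A p_B
    D′ = |D| / D_max,  D_max = min(p_A(1−p_B), (1−p_A)p_B)  if D > 0
                        D_max = min(p_A p_B, (1−p_A)(1−p_B)) if D < 0
    r² = D² / (p_A(1−p_A) p_B(1−p_B))

D′ = 0 is returned at exact independence (avoiding 0/0), and LD against a
monomorphic locus raises an error rather than returning a value — callers
are expected to MAF-filter first.  D′ = 1 whenever a haplotype class is
absent, which is why D′ runs high at rare alleles; this is the property
that lets D′-based blocks absorb low-MAF markers that r² would isolate.

## Marker QC

Two sequential filters mirror standard editing of an imputed HD panel:
(1) drop markers with MAF < 0.01 (computed over all panel animals, before
any train/test split); (2) scan each chromosome left-to-right and drop any
marker whose r² with the nearest retained marker to its left is 1 within
1e−12 (keep-left, deterministic).  r² rather than D′ defines "complete LD"
because r² = 1 means the two markers are informationally identical, which
is the stated purpose of the edit.  On noise-free synthetic data this exact
filter is much more aggressive than on real (imputed, noisy) data, where
true duplicates rarely reach r² = 1 exactly; consequences for the
variable-reduction measurement are discussed below.

## Haploblocks

A haploblock is a contiguous run of ≥ 2 markers on one chromosome in which
*every* pair has D′ ≥ d.  The all-pairs criterion defines membership; the
search procedure is greedy left-to-right maximal extension: grow the
candidate while the next adjacent marker clears the threshold against every
current member, emit, restart at the failing marker.  This is deterministic,
respects physical contiguity, and matches the triangular-heat-map picture of
LD blocks.  Singletons are "non-blocked" SNPs, a separate variable class.
At d = 0 each whole chromosome is one block; above the panel's maximum
pairwise D′ every SNP is non-blocked.  Thresholds conventionally span
0.25–0.75 in steps of 0.1.

Variants are the distinct haplotype strings observed in a block over all 2n
panel haplotypes (training and test together, so prediction never meets an
unseen variant; an unseen variant from external data encodes as all-zero
columns with a logged warning).  Variants are ordered by descending
frequency, ties lexicographic.  No rare-variant collapsing is applied, and
no reference variant is dropped for identifiability: both models are
shrinkage estimators and tolerate the within-block sum-to-2 collinearity.

## Models

Both models are

    y = 1μ + M g + Z a + ε,  ε_i ~ N(0, σ²_ε / w_i),  w_i = r²_i/(1−r²_i)

with a ~ N(0, A σ²_a) over the pedigree A-matrix (tabular method; unknown
parents drop their term; one-unknown-parent keeps the known parent's half).
Test animals appear in A without records; their polygenic effect is sampled
from its conditional prior given relatives, so pedigree-consistent
predictions need no separate projection.  μ carries a flat prior and y is
not pre-centred.

Priors on effects: BLUP g_j ~ N(0, σ²_g); mixture g_j ~ Σ π_k N(0, σ²_k)
with π = (0.889, 0.1, 0.01, 0.001) fixed and σ²_1 ≤ σ²_2 ≤ σ²_3 ≤ σ²_4.
Variance components (σ²_g or σ²_1..4, σ²_a, σ²_ε) carry bounded-uniform
priors on (0, v_max] with v_max = 10⁴·var(y) — wide enough never to bind in
practice while keeping every conditional proper.

### Gibbs sampler

Single chain; default schedule 50,000 cycles / 20,000 burn-in (tests and the
acceptance script use 1,200–6,000-cycle chains on their smaller instances).
Per cycle: scalar update of μ; a fixed-map-order sweep over columns of g
(single-site normal conditionals, residual updated incrementally; in the
mixture, the component indicator k_j is drawn from its categorical
conditional given the current g_j, then g_j given k_j); a single-site sweep
over a using rows of A⁻¹ (computed once by Cholesky); then variance updates.

A flat prior on a variance with m attached effects and sum of squares S has
conditional density v^{−m/2} exp(−S/2v) on (0, v_max]:

* m ≥ 3 — inverse-gamma(m/2 − 1, S/2), drawn directly and redrawn if above
  v_max;
* m ∈ {1, 2} — the density is not inverse-gamma-proper; a log-scale
  random-walk Metropolis step (step 0.4) targets it exactly;
* m = 0 — flat, drawn uniformly on the admissible interval.

The mixture's ordering constraint is enforced by rejection: a candidate
component variance outside the interval bounded by its neighbours keeps the
previous value (a valid Metropolis move whose target includes the ordering
indicator); rejections are counted in the fit diagnostics.  All-zero design
columns fall back to prior draws.  Chains are exactly reproducible given
the seed (one integer; the scenario driver derives per-scenario seeds as
seed + 7919·index).

Fixing the variance components turns the sampler's posterior mean into the
weighted mixed-model-equation solution; the test suite verifies this
equivalence against a directly solved Henderson system, and verifies that
the mixture with proportions (1,0,0,0) reproduces BLUP within Monte-Carlo
error.

## Evaluation

GEBV_i = Σ_j m_ij ĝ_j + â_i (posterior means).  Reliability is
cor(DRP, GEBV)² / mean(r²_DRP) — the arithmetic mean of the test animals'
DRP reliabilities is used as the correction ("reliability of the average
DRP" being the alternative reading).  Bias is the OLS slope of DRP on GEBV.
Two predictors sharing the DRP vector are compared with Hotelling's
statistic

    t = (r₁y − r₂y) √( (n−3)(1+r₁₂) / (2|R|) ),  df = n − 3,

|R| the determinant of the 3×3 correlation matrix; t = 0, p = 1 when the
predictors coincide, and a degenerate |R| ≤ 0 with unequal correlations maps
to p = 0.  Both two-sided (H₀: equal) and one-sided (p = P(T ≥ t), small p
meaning the first predictor is significantly better) forms are exposed.
Top-k overlap ranks by descending GEBV with ties broken by animal id.
The scenario driver enumerates 1 + 2·(number of thresholds) scenarios per
trait (13 at the conventional six) and reports each model's metrics plus
Hotelling p and top-10 overlap against the SNP baseline of the same model.

## Synthetic data

The generator emulates a progeny-tested dairy population at desk scale.

* **Founder haplotypes.**  Per chromosome, allele values follow a
  first-order Markov chain: locus j+1 copies locus j with probability
  `adjacent_corr` (default 0.95), else draws fresh at that locus's MAF
  (uniform on `maf_range`, default 0.05–0.5).  A fraction `weak_ld_prob`
  (default 0.05) of intervals are weak-LD breakpoints with copy probability
  `weak_ld_corr` (default 0.3) — the hotspot-like gaps that delimit blocks
  and supply a non-blocked SNP class that grows with d.  Founder haplotypes
  are drawn with replacement from a pool of `n_ancestral_haplotypes`
  (default 30) such chains: real HD panels descend from a small effective
  population, and it is this bottleneck — not the marginal LD decay — that
  keeps per-block variant counts below the block's SNP count.  Setting the
  pool to `None` gives every haplotype an independent chain (the right
  null for LD-decay calibration tests, e.g. adjacent_corr = 0 ⇒
  permutation-null D′).
* **Pedigree and gene dropping.**  Generation g ≥ 1 forms ⌊prev/2⌋ random
  sire×dam matings (distinct parents) with `offspring_per_mating` (default
  2 — stable census) offspring each.  Each non-founder inherits one gamete
  per parent; gametes start on a random parental haplotype and switch with
  probability `recomb_prob_per_interval` per adjacent-locus interval
  (default 5e−4 ≈ 0.05 cM, HD-like spacing), never across chromosomes.
* **Phenotypes.**  QTL positions are sampled without replacement; effects
  come from the four-component mixture (`mixture_props`, `mixture_sds`);
  TBV is the centred dosage sum.  The environmental deviate is standardized
  so realized var(TBV)/var(TBV+E) matches `h2` up to the TBV–E sampling
  covariance.  DRP = TBV + e with var(e) = var(TBV)(1−r²)/r² for per-animal
  reliability r² drawn uniformly from `drp_reliability_range` (default
  0.75–0.95, progeny-tested-bull territory) — the standard de-regression
  error-variance relation.  The uniform reliability distribution is a
  stand-in; real reliability distributions are trait- and cohort-specific.
* **Train/test split** is by birth generation (the cut-off-date analogue):
  the last generation(s) form the validation set.

What the generator does *not* emulate: deep coalescent history, mutation,
selection and the resulting MAF spectrum; genotyping or imputation noise
(panels are noise-free, which makes the exact r²=1 QC filter far more
aggressive than on real data); non-additive genetic effects; overlapping
generations and assortative mating.  Passing tests therefore demonstrate
algorithmic correctness and the qualitative regime (variable reduction,
shrinkage behaviour, calibration), not field-data reliability levels — the
compact populations here have few independent chromosome segments per
training animal, so prediction reliabilities run much higher than any
realistic application.

## Problem sizes and numerical choices

Tests and the acceptance script use populations of 300–1,400 animals,
panels of 100–1,000 markers and chains of 1,200–6,000 cycles; the
acceptance script masks the causal loci out of the genotyped panel so
markers tag QTL only through LD.  The variable-reduction property is
measured on MAF-edited panels (without the exact complete-LD edit, for the
noise-free-data reason above) and the non-blocked-vs-d trend on counts
summed over replicate panels, since a single desk-scale panel yields single-
digit non-blocked counts.  Monte-Carlo standard errors in sampler-vs-oracle
comparisons come from batch means (20 batches); accuracy comparisons
between models use the Fisher large-sample SE (1−r²)/√(n−3).  Frequency-sum
and reliability-identity invariants are enforced at 1e−12; A is accepted as
PSD down to an eigenvalue floor of −1e−8 with a 1e−8 jitter before
Cholesky when needed.

## Known limitations

* The block search is greedy and left-anchored; a different (e.g. dynamic
  programming) partition could trade block boundaries, though the all-pairs
  certificate holds for whatever it emits.
* Single-site polygenic updates mix slowly on very deep pedigrees; the
  intended scale is a few thousand animals.
* The mixture's small-count component variances move by Metropolis steps
  and can mix slowly when a component holds 1–2 effects; the ordering
  rejection rate is reported in the diagnostics.
* One record per animal per trait; multi-trait models, REML variance
  estimation and genomic relationship matrices are out of scope.
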