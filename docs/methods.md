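# Methods

This note documents the statistical procedures, the synthetic data model
behind the tests, the numerical choices, and the known limitations of
`rhizomarker`.

## Study design and data model

The pipeline targets aligned untargeted LC-MS feature tables from a
two-condition soil experiment: plant-hosting ("rhizosphere") soil versus
control soil without roots, extracted with acidified solutions of 0, 50 or
95% MeOH and measured in positive and negative electrospray mode. The
design is deliberately small — 5 plant and 3 control replicates per
solution — and every statistical choice below is made with that sample
size in mind. Intensities are treated as arbitrary non-negative units;
retention times are seconds throughout (the 10-s grouping tolerance is
stated in seconds). Missing cells are distinct from zeros: a zero is "not
detected", a missing cell is "no aligned value".

## Preprocessing

Fixed order: impute → normalize → transform → scale, each stage at most
once per table (the chain is not idempotent, so tables carry a record of
applied stages and re-application raises).

- **Imputation**: each missing cell gets half the feature's minimum
  observed positive intensity — the metabolomics-community default when
  the censoring mechanism is unknown. Features observed nowhere are
  dropped with a warning.
- **Median normalization**: each sample column is scaled so that all
  sample medians equal the median of sample medians. Medians include
  imputed cells, for determinism.
- **Cube-root transform** and **Pareto scaling**
  ((x − mean)/√sd, sd with n−1) feed the multivariate models only.
  Constant features scale to zero rows rather than NaN.

Volcano statistics run on the imputed, median-normalized, *untransformed*
intensities: a fold change after cube-root/Pareto would not be an
intensity ratio. The presence/absence accounting runs on raw intensities
(an ion is present in a soil type if positive and non-missing in at least
one of its samples).

## Multivariate models

PCA is the SVD of the column-centered samples × features matrix, with a
deterministic sign convention (largest-magnitude loading positive).
Clustering uses d = 1 − Pearson r between sample profiles with average
linkage. PLS-DA is NIPALS PLS1 against a centered 0/1 class indicator;
R²Y = 1 − RSS/TSS on the indicator and Q² = 1 − PRESS/TSS with PRESS from
cross-validation that refits everything per fold, including centering.
Leave-one-out is the default because n ≤ 8 per dataset; a seeded k-fold
option exists for larger designs. Components default to 2 (3 for PCA
display): with eight samples, more would be unsafe. These component and CV
choices are this package's documented defaults, not claims about any
particular published analysis.

## Volcano selection and the marker funnel

Per ion, a two-sided Welch unequal-variance t-test (Welch–Satterthwaite
df) compares plant against control; ions with zero variance in both groups
and equal means get t = 0, p = 1. Selection applies strict cuts:
*P* < 0.01 and |log₂ FC| > 1.

Within each volcano plot, qualifying ions are ranked by ascending p,
ties broken by descending |log₂ FC| then feature id (a fold-change-first
ordering is available, since published descriptions of "ranked by fold
change and statistical significance" leave the order ambiguous). The top
k = 20 per plot (k = 50 in the single-solution design) are pooled across
plots; entries from different plots remain distinct even when ids
coincide, because each solution × mode dataset is its own alignment
namespace. In the synthetic data the three solutions of one mode share
their feature namespace (ion identity is seeded per mode), which is what
lets the refinement step see every soil × solution group of a candidate.

Refinement: classical equal-variance one-way ANOVA across the dataset's
soil × solution groups (six in the three-solution design), then
Benjamini–Hochberg q-values computed within each direction's candidate
pool, keeping q < α = 0.01. Welch's heteroscedastic ANOVA and pool-wide
joint correction are available behind flags.

## Adduct/isotope deconvolution and annotation

Marker ions are binned by retention time (single linkage, 10 s). Within a
bin, isotopologues are identified first: an ion attaches to the nearest
lighter non-isotope ion whose m/z deficit matches k × 1.00336 Da
(k ≤ 2) within 0.1 Da. Among the remaining parents, every ion pair and
every ordered pair of *distinct* adduct rules is tested: if the two
implied neutral masses agree within 0.1 Da the pair becomes an edge, and
connected components become compound groups. Allowing identical rule pairs
would merge any two ions within 0.1 Da of the same m/z and invite
chaining, so it is excluded by design. The group's neutral mass is the
mean over the supporting assignments; per-ion labels are assigned by
majority vote over edge evidence. Ungrouped ions become singletons
interpreted as [M+H]⁺ / [M−H]⁻. Rule sets default to
{[M+H]⁺, [M+Na]⁺, [M+K]⁺, [M+NH₄]⁺} and {[M−H]⁻, [M+HCOO]⁻, [M+Cl]⁻} —
appropriate for formic-acid-acidified electrospray — and are
configurable; only singly charged ions are considered. This grouping
scheme is this package's own construction, validated against spiked
synthetic ground truth (100% sibling-set recovery, neutral mass exact to
numerical precision).

Annotation lists every library record within 0.1 Da of the neutral mass,
sorted by absolute error. Records flagged implausible in soil (synthetic
drugs, mammalian hormones — the library bundles such decoys) stay listed
but are excluded from composition; a group matching nothing is "unknown".
Class composition counts one unit per annotated group; several groups
resolving to the same compound each count (additive counting). Whether a
published "additive" count tallies groups or raw ions is ambiguous; the
group-level count is used because deconvolution exists precisely to
collapse redundant ions.

## Microbial diversity

OTUs are kept when their count exceeds 5 in at least 30% of samples *and*
their total exceeds 20 (strict inequalities, configurable to ≥). Shannon
uses natural log (configurable to log2). Rarefaction draws without
replacement via multivariate hypergeometric sampling. Bray–Curtis is the
provided distance; the one-way PERMANOVA (Anderson's pseudo-F from total
and within-group sums of squared distances, seeded label permutations,
p = (1 + #{F* ≥ F})/(1 + n_perm)) accepts any externally supplied distance
matrix, so tree-based distances such as weighted UniFrac can be plugged
in; tree handling itself is out of scope.

With 4 + 4 samples a permutation test has only 35 distinct label splits,
so the smallest attainable p is ≈ 0.029 and a 0.05-level test is
conservative by discreteness alone; the calibration checks therefore use
6 samples per group, where the permutation distribution is dense and the
empirical type-I error sits near nominal (0.036–0.048 in [0.03, 0.07]).

## Damage-control statistics

Electrolyte leakage is expressed as a percentage of the conductivity of
fully lysed tissue. Treatments are compared by Welch's heteroscedastic
one-way ANOVA (Welch 1951 weights nⱼ/sⱼ², df₂ = 1/Λ) on jointly
rank-transformed data (mid-ranks for ties), which is invariant under
monotone transforms. Zero-variance groups get a 1e-12 variance floor on
ranks, with a warning, to keep weights finite. Games–Howell post-hoc
tests use q = |x̄ᵢ − x̄ⱼ|/√((sᵢ²/nᵢ + sⱼ²/nⱼ)/2) with Welch–Satterthwaite
df and the studentized-range distribution (scipy's implementation,
cross-validated against a nested-quadrature oracle to 1e-6); letters come
from the standard insert–absorb compact-letter-display algorithm with
alphabetical assignment in group-input order. CFU comparisons are
pooled-variance Student t-tests, optionally on log10 counts (raw by
default).

Limitation: at n = 4 per group with extreme variance ratios (1:6) the
rank + Welch combination runs liberal (empirical α ≈ 0.09 at nominal
0.05); calibration is good (≈ 0.06) from n = 6 per group with moderate
heteroscedasticity. The unranked Welch ANOVA is calibrated at both sizes.

## Synthetic data model

The generator emulates the study conditions, not raw spectra:

- Baseline feature intensities are log-normal (log₁₀ mean 4, sd 0.8 —
  a typical untargeted dynamic range; both configurable). m/z is uniform
  on [80, 1200] Da and RT uniform on [30, 900] s; the generator reports
  how many ion pairs collide with an adduct mass delta within the
  grouping tolerances by chance.
- Enriched ions multiply the plant (or control) group mean by 2^f with
  f ~ U(1.5, 4), so every true effect clears the 2-fold cut.
- Replicate noise is multiplicative log-normal with mean 1 and CV 0.2 by
  default; the 95% MeOH solution doubles the noise *variance*, emulating
  its higher between-replicate variation.
- Missingness is MCAR (default 2%); intensity-dependent censoring is out
  of scope. Calibration checks of test size use missing-rate 0, because
  half-minimum imputation of a null table injects signal that is not part
  of the hypothesis being calibrated.
- Spiked compounds add one ion per adduct plus a ¹³C isotopologue at 10%
  of the parent intensity, all within ±2 s RT and correlated through a
  common per-sample factor.
- OTU tables are multinomial over Dirichlet-perturbed base proportions
  (concentration 200); effect OTUs multiply their proportions in the root
  group before renormalization. Conductivity replicates are gamma with
  given mean and CV.

All generators are pure functions of (parameters, seed); the pipeline
fans one top-level seed out to stages via `SeedSequence` spawning.

What passing tests show — and do not show: the synthetic model has
independent features, no retention-time drift, no batch structure, no
ionization suppression and no intensity-dependent missingness, so the
results certify the statistical machinery (calibration, power, recovery,
determinism) rather than performance on any particular instrument's data.

Power is direction-asymmetric by design arithmetic, not by
implementation: with 5 plant vs 3 control replicates and multiplicative
noise, a control-enriched ion has its high-variance group at n = 3, the
Welch df collapses toward 2, and volcano recovery of ≥ 2-fold
control-direction effects is only ~40–50%, versus ~100% for the
rhizosphere direction. Recovery guarantees are therefore stated for
rhizosphere-direction spikes, and both rates are reported by the
acceptance script.

## Problem sizes used in checks

The shipped checks run at desk scale: 2,000 ions per mode for the
workflow drivers (10,000 for null-calibration tables), 20 seeds for
Monte-Carlo rates, 500 seeds × 999 permutations for PERMANOVA
calibration, 500-OTU tables at depth 20,000 for the diversity driver.
All scale linearly to full study sizes (≈ 17,500–19,500 ions per mode).
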