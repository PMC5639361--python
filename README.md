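# rhizomarker

Untargeted metabolite profiling of non-sterile rhizosphere soil compares
LC-MS extracts of soil hosting a plant against control soil without roots,
and asks which ions — and ultimately which metabolite classes — the roots
(and their microbiome) add to the soil. `rhizomarker` implements that
analysis as a tested, reusable pipeline for aligned feature tables
(ion m/z, retention time, ionization mode × per-sample intensities), for
researchers who have their own aligned LC-MS data or want to study the
statistical behaviour of the workflow on simulated data with known ground
truth.

## What the pipeline computes

For each dataset (extraction solution × ESI⁺/ESI⁻ mode), with *n* = 5 plant
vs 3 control replicates:

- **Preprocessing** — half-minimum imputation, median normalization,
  cube-root transform and Pareto scaling
  ((x − x̄)/√s per feature), applied in that fixed order. Fold-change
  statistics use the imputed, median-normalized (untransformed)
  intensities; the multivariate models use the fully processed matrix.
- **Multivariate models** — 3-component PCA, average-linkage clustering on
  d = 1 − Pearson r between sample profiles, and two-component PLS-DA
  (NIPALS PLS1 on a centered 0/1 class indicator) with
  R² = 1 − RSS/TSS and leave-one-out Q² = 1 − PRESS/TSS.
- **Volcano selection** — per ion, a two-sided Welch unequal-variance
  t-test and log₂(mean_plant/mean_control); enriched ions must pass
  *P* < 0.01 **and** a greater-than-twofold change (both strict).
- **Marker funnel** — the top-20 qualifying ions of each of the six volcano
  plots are pooled (120 candidates per soil type; the single-solution maize
  design pools the top 50 of two plots, 100 ions), then refined by a
  one-way ANOVA across all soil × solution groups with a Benjamini–Hochberg
  FDR cut at *q* < 0.01.
- **Deconvolution & annotation** — co-eluting markers (RT tolerance 10 s)
  are grouped into adduct/¹³C-isotope families (m/z tolerance 0.1 Da),
  a neutral mass is inferred per group, matched against a bundled compound
  library (benzoxazinoids DIMBOA/DIBOA/HBOA/HMBOA, flavonoids,
  phenylpropanoids, lipids, alkaloids, organic/amino acids, plus
  implausible decoys), and class composition percentages are reported with
  implausible-in-soil matches (synthetic drugs, mammalian hormones)
  excluded.
- **Supporting statistics** — microbial diversity (OTU
  prevalence/abundance filtering, Shannon index, richness, rarefaction,
  Bray–Curtis + one-way PERMANOVA) and extraction-damage controls
  (relative conductivity, RWC = (W − DW)/(SW − DW), Welch's F-test on
  ranked data with Games–Howell post-hoc letters, Student t-tests on
  CFU/g).

A seeded synthetic-data module generates feature tables, OTU tables and
damage-assay replicates with known ground truth (enriched ions with known
log₂ fold changes, spiked adduct/isotope sibling ions, OTU group effects),
so every stage is testable without any external data.

## Worked example

```python
from rhizomarker.pipeline import PipelineConfig, run_differential_workflow
from rhizomarker.synthetic import SyntheticConfig

config = PipelineConfig(mode="arabidopsis",
                        synthetic=SyntheticConfig(seed=1), seed=1)
report = run_differential_workflow(config)
print({d: len(m) for d, m in report.markers.items()})
print(report.multivariate_summary["positive:50"])
```

prints

```
{'plant': 120, 'control': 120}
{'pca_explained_pct': [39.66343457919472, 11.052057745902282, 10.71779890426353],
 'r2': 0.99999573691651, 'q2': 0.881109588124502}
```

i.e. each soil type yields exactly 120 pooled marker candidates
(top-20 × 6 volcano plots), and in the 50% MeOH / ESI⁺ dataset PC1–3
explain ~40/11/11 % of the variance while the PLS-DA separates plant from
control soil with R² ≈ 1.00 and cross-validated Q² ≈ 0.88.

The same steps are available as numbered drivers under `analysis/`
(01 simulate → 02 multivariate → 03 volcano/markers → 04 annotation →
05 diversity → 06 damage controls), each writing its tables under
`results/`, and as a CLI
(`rhizomarker simulate|preprocess|multivariate|volcano|annotate|diversity|damage|run`).

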