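# histotype

Imaging-subtype discovery from single-cell maps of H&E-stained tumor
tissue.

Histology provides what bulk molecular profiling cannot: the *positions*
of tumor cells and tumor-infiltrating lymphocytes (TILs). Given a typed
single-cell map of a specimen — one polygon, centroid, and class
(tumor / lymphocyte / other) per nucleus, with whole-tumor, tumor-core,
and tumor-periphery regions — `histotype` computes a 246-feature spatial
phenotype, discovers patient subtypes by consensus clustering, validates
them across cohorts, and tests their clinical associations. It is aimed at
computational-pathology groups who already run nucleus
segmentation/classification (that step is out of scope here) and want the
downstream spatial-statistics and subtyping machinery as a reusable,
tested library. A built-in synthetic cohort generator with planted
subtypes makes every stage runnable and testable without any slide data.

## What it computes

**Phenotype (246 features per patient).** Tumor-nucleus morphometry,
intensity-histogram, GLCM texture (13 Haralick statistics at offsets 1
and 2 px, 32 gray levels), and RGB color descriptors, each aggregated
over nuclei by mean and SD (150); density and quadrat-based spatial
homogeneity (count mean/SD, CV, empty fraction, Morisita index,
nearest-neighbor distance) for tumor cells and lymphocytes in core and
periphery (28); statistics of the tumor-cell-centered *spatial
interaction matrix* — for each tumor nucleus, the number of tumor and of
lymphocyte nuclei within r = 50 or 100 px — in both regions (64); and
lymphocyte:tumor ratio plus total counts (4).

**Subtyping.** Consensus clustering: B resampling replicates (80% of
specimens, 80% of features) × PAM (k-medoids, BUILD+SWAP) under the
Spearman distance d(i,j) = 1 − ρ_s(xᵢ, xⱼ); the consensus matrix M(i,j)
is the fraction of co-sampled replicates in which i and j co-cluster; K
is selected where the relative gain in the area under the consensus CDF,
Δ(K) = (A(K) − A(K−1))/A(K−1), last exceeds a threshold. Reproducibility
across cohorts is quantified by the in-group proportion (IGP): the
fraction of validation specimens assigned to a discovery centroid whose
nearest validation neighbor is assigned to the same centroid, with a
label-permutation p-value.

**Cohort statistics.** Per-feature ANOVA / Kruskal–Wallis with
Benjamini–Hochberg correction; chi-squared tests against external label
sets (Yates-corrected on 2×2); Pearson correlation; Kaplan–Meier +
log-rank; multivariable Cox proportional hazards (Breslow ties,
configurable baselines).

## Worked example

```python
from histotype import (CohortSpec, simulate_cohort, extract_cohort,
                       prepare_features, consensus_cluster, km_logrank)

spec = CohortSpec(n_per_subtype=10, seed=7)     # 30 specimens, 3 planted subtypes
cohort = simulate_cohort(spec)
F = extract_cohort(cohort.specimens())          # 30 x 246 feature matrix
row = F.iloc[0]
print(f"{F.index[0]}: tumor_density_CT={row['tumor_density_CT']:.2f}  "
      f"tumor_lymph_relation_mean_CT={row['tumor_lymph_relation_mean_CT']:.2f}  "
      f"tumor_equivalent_diameter_mean={row['tumor_equivalent_diameter_mean']:.2f}")

res = consensus_cluster(prepare_features(F), n_resamples=200, seed=7)
print("optimal K:", res.optimal_k)
print("delta areas:", {k: round(v, 3) for k, v in res.delta_areas.items()})

clin = cohort.clinical.set_index("specimen_id").loc[F.index]
fit = km_logrank(clin, res.labels)
print(f"log-rank chi2={fit.logrank_statistic:.2f} (df={fit.logrank_df}), "
      f"p={fit.logrank_p:.3f}")
```

prints

```
S1_000: tumor_density_CT=3.18  tumor_lymph_relation_mean_CT=2.39  tumor_equivalent_diameter_mean=12.26
optimal K: 3
delta areas: {2: 0.46, 3: 0.499, 4: 0.078, 5: 0.035, 6: 0.028}
log-rank chi2=2.47 (df=2), p=0.290
```

Reading the output: the first specimen has ~3.2 tumor cells per 10⁴ px²
in the core, on average 2.4 lymphocytes within 50 px of each tumor cell
(it belongs to the infiltrated subtype), and a mean tumor-nucleus
equivalent diameter of 12.3 px. The delta-area trace drops sharply after
K = 3 (0.499 → 0.078), so three subtypes are selected — matching the
three planted ones exactly (adjusted Rand index 1.0 against the
generator's truth labels). The log-rank test on 30 patients is
underpowered (p = 0.29); the planted hazard ratio of 2 becomes
significant at realistic cohort sizes, as the survival-recovery tests
assert.

The same pipeline is scriptable from the shell:

```bash
histotype simulate --n-per-subtype 20 --seed 0 --out cohort/
histotype run --cohort cohort/ --out run/ --B 200 --seed 0
```

`run/` then contains `features.csv` (60×246), the per-K consensus
matrices, `subtypes.csv`, `clustering_report.json`, the feature–subtype
test table, Kaplan–Meier step tables, the Cox table, and a manifest that
reproduces the run bit-for-bit. `histotype igp` compares subtypes between
a discovery and a validation feature matrix.

## Layout

* `src/histotype/cellmap.py` — data model, GeoJSON I/O, ROI assignment
* `src/histotype/nuclei.py`, `spatial.py`, `features.py`, `registry.py` —
  the 246-feature extractor and its registry
* `src/histotype/cluster.py` — Spearman distance, PAM, consensus
  clustering, delta-area K selection, IGP
* `src/histotype/stats.py` — association and survival statistics
* `src/histotype/synthetic.py` — cohort generator with planted subtypes
* `src/histotype/pipeline.py`, `cli.py` — orchestration and CLI
* `docs/methods.md` — models, parameters, conventions, and limitations
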