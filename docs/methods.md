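# Methods

`histotype` quantifies the spatial phenotype of tumors and their immune
microenvironment from typed single-cell maps of H&E-stained tissue, groups
patients into imaging subtypes by consensus clustering, validates the
subtypes across cohorts, and relates them to clinical outcome. This note
documents the model and procedure, the parameters that matter, the
numerical conventions, and what the synthetic cohort generator does and
does not emulate.

## Input model

A specimen is a *cell map*: every segmented nucleus carries a polygon
(closed pixel-coordinate ring), a centroid, and one of three classes —
tumor cell, lymphocyte, or other non-malignant cell — plus three regions
of interest: the whole tumor, the tumor core, and the tumor periphery (an
annular band at the tumor edge; stored as an outer ring with a hole).
Coordinates are 0-based pixels, x right / y down; point-in-polygon
membership counts the boundary as inside (a deterministic tie rule).
Nucleus segmentation itself is out of scope: the cell map is the input
contract, produced upstream by a segmentation/classification model or by
the built-in generator.

## The 246-feature phenotype

The patient-level phenotype is a fixed, ordered vector of 246 named
features, defined in a machine-readable registry
(`histotype.registry`, exported as TSV alongside every feature CSV).

**Nuclear features (150).** For every *tumor* nucleus in the whole-tumor
region we compute 75 base descriptors and aggregate each over nuclei by
mean and sample SD (n−1), giving patient-level category counts of
morphology 20, intensity histogram 14, texture 62, and color 54:

* *Morphology (10)* — area, perimeter, equivalent diameter
  (2·sqrt(area/π)), major/minor axis (ellipse-of-equal-second-moments
  convention, full axis = 4·sqrt(eigenvalue of the coordinate
  covariance)), eccentricity, solidity (area / convex-hull area), extent
  (area / bounding-box area), circularity (4πA/P²), aspect ratio. All are
  computed from the polygon itself (shoelace area, exact polygon second
  moments), not from a raster, so they are resolution-independent and
  exactly translation/rotation invariant.
* *Histogram (7)* — mean, population SD, skewness, excess kurtosis,
  Shannon entropy (bits, 32 equal bins on [0, 255]), and the 10th/90th
  percentiles of the luminance (0.299 R + 0.587 G + 0.114 B) inside the
  polygon. Skewness and kurtosis of constant pixel sets are defined as 0.
* *Texture (31)* — 13 Haralick statistics (energy, contrast, correlation,
  variance, homogeneity, sum average, sum variance, sum entropy, entropy,
  difference variance, difference entropy, and the two information
  measures of correlation) of the gray-level co-occurrence matrix at
  offsets 1 and 2 px (32 gray levels of width 8, symmetric, pooled over
  the four axis/diagonal directions with exact d-pixel diagonal steps,
  normalized after pooling; only pixel pairs with both ends inside the
  nucleus mask contribute), plus 5 Sobel-gradient statistics inside the
  mask (mean, SD, skewness, 90th percentile, and the fraction of gradient
  pixels above the Otsu threshold of the whole patch's gradient image).
  Masks under 4 pixels yield a missing texture row.
* *Color (27)* — per RGB channel: mean, population SD, skewness, entropy,
  10th percentile, median, 90th percentile, min, max.

**Density and homogeneity (28).** For each cell class in {tumor,
lymphocyte} and each region in {core (CT), periphery (PT)}: density
(cells per 10⁴ px² of ROI area) and quadrat statistics on a square grid —
count mean and SD ("uniformity"), coefficient of variation, fraction of
empty quadrats, the Morisita aggregation index, and the mean
nearest-neighbor distance. Quadrats tile the ROI bounding box and enter
the statistics only when at least half their area lies inside the ROI.
Under complete spatial randomness the Morisita index is ~1 and the
quadrat CV ~1/sqrt(mean count); clustering pushes both up. The default
quadrat side is 96 px, chosen so that the desk-scale core region holds a
4×4 grid; it is configurable and should scale with the ROI.

**Tumor–lymphocyte interaction (64).** Every tumor nucleus in a region is
a focal point; the counts of tumor and of lymphocyte nuclei whose
centroids lie within 50 or 100 px (Euclidean, focal excluded, neighbors
restricted to the same region) form the spatial interaction matrix. Radius
expansion is centroid-to-centroid rather than polygon dilation — a
deterministic, segmentation-independent reading. Eight statistics per
neighbor class (mean, SD, median, max, skewness, 75th percentile,
fraction of zeros, and the Shannon entropy of the count distribution) ×
2 classes × 2 radii × 2 regions give 64 features. The feature
`tumor_lymph_relation_mean_CT` — the mean lymphocyte count around tumor
cells at 50 px in the core — is the headline tumor/immune relation
measure. Counts come from a k-d tree but are bit-identical to the naive
all-pairs scan (asserted in tests).

**Composite (4).** Lymphocyte:tumor count ratio and total nucleus count
in CT and PT. These reconcile the published category counts
(20+14+62+54+28+64 = 242) with the published total of 246 and are flagged
`reconciliation` in the registry so the accounting is auditable.

Missing values (degenerate specimens: e.g. fewer than two lymphocytes in
a region) propagate as NaN with a log entry; `prepare_features` imputes
them with cohort medians and drops cohort-constant features before
clustering.

## Subtype discovery

Specimens are compared by **Spearman distance** d(i,j) = 1 − ρ_s between
their raw feature rows (midrank ties). Because the distance is rank-based,
no feature scaling is required (column z-scoring is available but off by
default); it is invariant to feature order and to any common monotone
transformation. The clustering engine is **PAM** (k-medoids): greedy BUILD
then steepest-descent SWAP until no single medoid/non-medoid exchange
lowers the total distance to nearest medoids, ties broken by lowest index.
PAM is a local search: on random small instances it attains the
brute-force optimum in the large majority of cases (the test suite
asserts at least 90%) but not always; this is intrinsic to BUILD+SWAP,
not an implementation artifact.

**Consensus clustering.** Each of B replicates draws 80% of the specimens
and 80% of the features (both without replacement), recomputes the
Spearman distance on the subset, and runs PAM at every K in 2..6. The
consensus value of a specimen pair is its co-clustering count divided by
its co-sampling count. Final labels at each K come from average-linkage
hierarchical clustering of 1 − consensus (the convention of the
consensus-clustering method this follows, which does not itself prescribe
label extraction). B defaults to 10,000; the studies in this repository use B = 200, at
which the selected K is already stable across independent cohorts (the
acceptance study selects the same K in 20 of 20 replicate cohorts).

**Choice of K (delta-area rule).** A(K) is the area under the empirical
CDF of the upper-triangle consensus values over [0, 1] (equal to
1 − mean consensus); Δ(2) = A(2) and Δ(K) = (A(K) − A(K−1))/A(K−1). The
selected K is the largest candidate with Δ(K) > δ_min. The default
δ_min = 0.1 is derived, not arbitrary: a *perfectly stable* split of one
of K equal clusters at K+1 changes the area by about
(n/K)² · 2/(n(n−1)) / A(K), ≈ 0.08 for n = 60 and K = 3 — any threshold
below that can never reject over-partitioning on clean data, while the
delta at a true K is several times larger. Two
limitations follow from the same analysis and are deliberate:

* On structureless data, resampled PAM partitions of the same points are
  nearly deterministic, so the areas track the balanced-partition ladder
  A(K) ≈ 1 − 1/K and the deltas its decay 1/(K(K−2)); the rule therefore
  cannot certify the *absence* of structure (it reports a K regardless) —
  the consensus matrices themselves must be inspected.
* Because Δ(3) on the ladder is 1/3 > δ_min, true two-cluster data is
  over-partitioned by the constant-threshold rule. The rule is reliable
  for K_true ≥ 3, which is the regime this pipeline targets.

**Cross-cohort validation (IGP).** Discovery-cluster centroids
(feature-wise means) classify each validation specimen by nearest
centroid under 1 − Spearman; IGP(g) is the fraction of specimens
classified to g whose nearest *validation* neighbor (same distance) is
also classified to g. Significance comes from permuting the classified
labels (N = 1,000 by default; p = (1 + #{IGP_perm ≥ IGP_obs})/(N + 1)).
This label-permutation null replaces the original method's rotated-
centroid null: it is simpler and assumption-light, but it conditions on
the classification being spatially coherent — which nearest-centroid
assignment produces to some degree even for noise centroids — so its
p-values answer "are these groups more coherent than shuffled labels?",
not "is there any structure at all?". Cluster correspondence between
cohorts is reported via optimal one-to-one matching of centroid Spearman
correlations.

## Downstream statistics

Feature–subtype association: one-way ANOVA and Kruskal–Wallis (midrank
ties) per feature, Benjamini–Hochberg correction across all features;
constant features get p = 1 by convention. Categorical associations:
Pearson chi-squared with expected counts from the margins, Yates
continuity correction on by default for 2×2 tables only (this convention
reproduces the published cohort-comparison p-value of 0.44 for the
gender margins); rows labeled "unknown" are excluded. Correlation:
Pearson product-moment with the t-based p. Survival: Kaplan–Meier
product-limit curves per group with the k-sample log-rank test
(df = groups − 1), and multivariable Cox proportional-hazards regression
(Breslow tie handling by default, Efron available), dummy-coded against
stated baselines (subtype 1, stage pT1, grade G1, female), Wald 95% CIs
exp(β ± 1.96 se). ANOVA/KW/chi-squared/Pearson are delegated to scipy,
BH to statsmodels, KM/log-rank to lifelines, and the Cox fit to
statsmodels PHReg; the pipeline owns the conventions (Yates rule, unknown
handling, baselines) and the result schema.

## Synthetic cohorts

The generator plants exactly the structure the pipeline is built to
detect, at desk scale, and is the basis of every end-to-end test.

* **Tumor cells**: homogeneous Poisson (uniform growth) or a Thomas
  cluster process (Poisson parents, Poisson(μ) offspring scattered
  N(0, σ²); parents simulated on a 4σ-padded window to avoid edge bias).
* **Lymphocytes**: inhomogeneous Poisson with intensity
  λ(x) = λ₀ · max(0.05, 1 + α·Σᵢ exp(−|x − tᵢ|²/2h²)) over tumor cells
  tᵢ — α > 0 plants tumor–immune colocalization, α < 0 immune exclusion;
  simulated by thinning a dominating homogeneous process.
* **Other cells**: homogeneous Poisson.
* **Nuclei**: 32-vertex ellipses; equivalent diameter log-normal around a
  subtype median, eccentricity U(0, 0.8), uniform orientation; overlaps
  allowed. The 32-gon's area deficit vs. the ellipse is 0.64% (0.32% in
  diameter).
* **Rendering**: eosin-pink background (230, 180, 200), tumor nuclei
  hematoxylin purple (90, 60, 140), lymphocytes darker and more compact
  (50, 40, 110), other cells pale mauve; smoothed Gaussian texture inside
  nuclei (amplitude 10, smoothing σ 2 px) and white Gaussian pixel noise
  (σ 8) everywhere.
* **Survival**: exponential event times with subtype-specific hazards and
  independent uniform censoring on [0, 120] months.

The three default subtypes mirror the qualitative signature of the
published imaging subtypes, with effect sizes chosen once so the planted
structure is recoverable at cohort size 60:

| | tumor process | tumor κ (/10⁴ px²) | λ₀ | α | nucleus Ø (px) | hazard (/mo) |
|---|---|---|---|---|---|---|
| S1 | Poisson | 3.5 | 1.8 | +1.5 | 12.0 | 0.010 |
| S2 | Thomas (σ=70) | 5.4 | 1.5 | −0.2 | 13.8 | 0.020 |
| S3 | Thomas (σ=25) | 7.9 | 0.7 | 0 | 15.6 | 0.020 |

S1: sparse, spatially uniform tumor with a heavy colocalized lymphocyte
infiltrate and the smallest nuclei and best prognosis. S2: denser,
diffusely clustered tumor with an immune-excluded microenvironment. S3:
densest, most aggregated tumor, sparse lymphocytes, largest nuclei
(the nuclear-size/aneuploidy axis). S2 and S3 share the planted hazard
(ratio 2 vs S1), matching the observation that the two poorer-prognosis
subtypes do not separate in survival.

Geometry defaults are desk-scale: 896×896 px patches, whole-tumor ROI
inset 12 px, core = whole eroded by 250 px, periphery = the outer 150-px
band, ≈ 600–1,000 cells per specimen. These are proportional miniatures
of whole-slide regions; the package's own studies (60 specimens, 20
replicate cohorts) complete in minutes on one CPU at this scale. All
randomness flows from one master seed through spawned per-specimen
sequences recorded in the cohort manifest; regeneration is bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real H&E: realistic chromatin texture and stain variation
(nuclear texture here is smoothed noise); segmentation errors and
misclassification (class labels are exact); irregular, pathologist-drawn
ROI geometry; nucleus shape irregularity beyond ellipses; tissue
artifacts (folds, necrosis, stroma structure); and any correlation
between clinical covariates (stage/grade/sex are independent of subtype
by construction, so the planted subtype effect in the Cox model is
unconfounded by design).

## Numerical conventions and edge cases

* Population (n) SD for within-nucleus pixel statistics; sample (n−1) SD
  for across-nucleus aggregation and quadrat/interaction SDs.
* Constant pixel sets: SD/skewness/kurtosis/entropy all 0 (constant
  detection is exact, via min == max, not via a tolerance).
* GLCM degenerate cases: correlation 0 when the marginal variance is 0;
  information measures of correlation 0 when the marginal entropy is 0.
* Percentiles use linear interpolation (numpy's default convention).
* Empty interaction matrices, regions with < 2 cells, and zero-tumor
  ratios yield missing values with a log entry, never silent drops.
* PAM ties (equal objective in BUILD or SWAP, equidistant medoids in
  assignment) resolve to the lowest index.
* Consensus pairs never co-sampled (possible only at very small B) get
  consensus 0; the diagonal is fixed at 1.
* The per-nucleus GLCM accumulation, Haralick statistics, and pixel-
  moment/entropy loops are JIT-compiled; each has an array-based
  reference implementation asserted equal in the test suite.

## Known limitations

* The delta-area rule's constant threshold is only reliable for
  K_true ≥ 3 (see derivation above); it never reports "no structure".
* PAM finds local optima in a small fraction of instances, as any
  BUILD+SWAP implementation does.
* The IGP permutation null is anti-conservative as a test of *existence*
  of structure; interpret it as a label-coherence test.
* Feature ranks, not scales, drive the Spearman distance; a planted
  effect confined to features whose values never overlap other features'
  value ranges is invisible to it. The 246-feature panel mixes scales
  densely enough that the planted subtype axes (density, infiltration,
  heterogeneity, nuclear size) are all visible, but this is a property of
  the panel, not of the distance.
* Patient-level aggregation by mean/SD discards within-tumor spatial
  organization beyond what the quadrat and interaction summaries capture.
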