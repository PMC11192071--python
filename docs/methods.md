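# Methods

## The problem and the model

Lithic-mulch rock gardens are spectrally close to the natural bedrock and
colluvium they were built from. In the visible/near-infrared (VNIR,
0.40–1.04 μm) the two are nearly inseparable; in the shortwave infrared
(SWIR, 1.195–2.365 μm) the moisture and mineralogy differences between
freshly broken and weathered rock produce a usable contrast. The pipeline
therefore treats garden mapping as supervised land-cover classification of
multispectral pixels, compares band sets (8 VNIR bands at 1.2 m vs 8 SWIR
bands at 3.7 m, Worldview-3 style), post-processes the mulch class into a
polygon map product, and feeds the mapped area into a sweet-potato
carrying-capacity model.

## Synthetic scenes

Because the original commercial imagery and field-survey training polygons
cannot be redistributed, the package generates synthetic scenes with the
statistical structure the analysis assumes, and every claim about classifier
behaviour is made on those scenes.

**Spectral library.** Each of the six classes (bare soil,
bedrock/colluvium, forest/trees, grass, mulch, urban/developed) is a
16-band multivariate Gaussian in 8-bit digital numbers (0–255, clipped not
wrapped). Covariances are compound-symmetric per class
(σ² [(1−ρ)I + ρJ], ρ = 0.3, σ = 8–12 DN) — the simplest positive-definite
structure with controllable class separation. The means are constructed so
that:

- mulch vs bedrock/colluvium pooled Mahalanobis distance is ≥ 3 on the SWIR
  bands alone but ≤ 1 on the VNIR bands alone (measured: 9.4 and 0.17), and
  mulch is ≥ 3 from every class on SWIR — this encodes the premise that
  SWIR separates what VNIR cannot;
- VNIR band shapes follow the material (vegetation red edge, bright built
  surfaces) while each class's broadband VNIR intensity is approximately an
  affine function of its SWIR brightness, with mulch and bedrock forced
  equal. Real sensors see one scene, so cross-sensor brightness coherence
  is the physically realistic choice; it is also what makes
  component-substitution pan-sharpening meaningful at all.

Only *relative* (SWIR vs VNIR) performance claims are meaningful: the paper
behind this design reports no spectral statistics, so absolute accuracies on
synthetic scenes are properties of the stipulated library.

**Scene assembly.** Truth maps are built by stamping axis-aligned ellipses
with jittered boundaries onto a grass background (grass is the dominant
natural cover) until per-class pixel-share targets are met; default
fractions are bare soil 0.10, bedrock 0.12, forest 0.15, urban 0.08, mulch
0.08, remainder grass. Mulch patch centres are biased toward the bottom map
edge (the "coast") so density surfaces have the clustered structure the
mapped distribution shows. SWIR pixels draw from the class's SWIR marginal;
the VNIR raster is drawn on the finer grid (truth upsampled by cell-centre
lookup) from the VNIR marginals — VNIR and SWIR noise are therefore
independent given the class, which understates the cross-sensor texture
correlation of real imagery. The default grid is 128×128 SWIR pixels
(474 m × 474 m, ~0.22 km²) — an island-subscene, not the island.

**Training polygons.** The generator reproduces the field survey's polygon
counts per class (27/66/25/36/40/30 = 224) with total areas scaled to the
scene (default ×0.12 of the survey's km² figures). Polygons are rectangles
placed wholly inside single-class truth regions, with an adaptive
per-feature cell budget so per-class totals land within ±25 % of target.

**What passing tests do not show.** Synthetic scenes have no mixed pixels,
no atmosphere or terrain, no spatial autocorrelation of noise, and no
class-internal heterogeneity beyond one Gaussian per class. Accuracies near
0.98 on SWIR say the pipeline is correct, not that real imagery behaves this
well; the real-data analogue reported OA ≈ 0.82 for MaxEnt on SWIR.

## Classifiers and protocol

- **Split**: whole polygons (never pixels) are assigned to train or
  validation per class, targeting 80/20 by polygon count, both sides kept
  non-empty; polygon-level splitting prevents spatial leakage between
  training and validation pixels. A pixel-level split is not offered as a
  default anywhere.
- **Maximum likelihood**: per-class sample means and covariances (ddof 1),
  diagonal ridge ε = 1e-6 × mean diagonal for invertibility, uniform priors
  by default (class-frequency priors selectable). Prediction is the argmax
  of the Gaussian Bayes discriminant; posteriors are the softmax of
  discriminants.
- **Maximum entropy**: multinomial logistic regression on z-scored linear
  band features, fitted by L-BFGS on the penalised mean negative
  log-likelihood. λ = 1e-4 by default, tolerance 1e-8, max 500 iterations
  (best iterate returned with a warning on non-convergence). The L2 penalty
  covers the intercept column too, so the strong-penalty limit is exactly
  uniform class probabilities; at the default λ the intercept shrinkage is
  negligible. Linear features are the minimal maximum-entropy model; the
  feature transforms of species-distribution MaxEnt packages are out of
  scope.
- **Random forest**: bootstrapped CART trees, Gini-impurity splits over
  ⌊√B⌋ randomly drawn features per node, majority vote. Defaults: 500
  trees, leaves down to 1 sample, depth cap 64.
- Hyperparameters are fixed at one setting per model (no grid search).
- **Tie-breaking** everywhere: the lowest class index wins (numpy argmax
  semantics), documented and tested.

## Pan-sharpening

PCA component substitution: cubic-resample SWIR to the VNIR grid, PCA
across the 8 bands, replace PC1 with the per-pixel mean of the 8 VNIR bands
after affine (mean/variance) matching to PC1, invert. PC1's sign is
canonicalised to load positively on brightness so the substituted intensity
has the right orientation. Mean/variance matching was chosen over full CDF
matching as sufficient at this scale. If PC1 variance is zero the resampled
raster is returned unchanged. Consistency is assessed by *block-averaging*
the sharpened product back to the native SWIR grid (plain mean of member
cells); per-band correlation with the original is ≥ 0.95 on default scenes.

## Accuracy assessment

Confusion matrices are tallied over (true, predicted) pairs; unclassified
predictions are tracked in a separate per-true-class tally and count as
errors unless explicitly ignored. Per-class recall = TP/(TP+FN), precision
= TP/(TP+FP), F1 = 2PR/(P+R) (0 when P+R = 0), TNR = TN/(TN+FP); overall
accuracy = trace/total; kappa = (p_o − p_e)/(1 − p_e) with
p_e = Σ row_i·col_i / total². Zero-denominator ratios return 0 with an
explicit flag, never NaN, so aggregates stay total and auditable. Published
accuracy tables print single recall/precision/F1 rows for a multiclass
problem without naming the averaging rule; the report exposes macro averages
and the mulch-class values so either reading is checkable.

The SWIR-vs-VNIR benchmark (`evaluate.swir_vnir_benchmark`) runs the whole
chain per replicate — scene, polygons, extraction from both band stacks,
polygon-level split, three classifiers per band set, held-out scoring. For
affordability across 20 replicates it caps training pixels at 1000 per class
(seeded subsample), uses 100 trees, leaf size 10 and depth 16 for the
forest; these are benchmark problem sizes, not changes to model defaults.

## Garden product

Pipeline order is fixed and documented: polygonize → exclusion mask →
min-area filter. Components use 4-connectivity (standard GIS
raster-to-polygon behaviour; 8-connectivity behind a flag); polygon area is
cell count × pixel-size², conserving classified area exactly. The 10 m²
minimum mapping unit removes polygons *strictly below* 10 m²; on a pure
3.7 m product (13.69 m²/cell) it is a no-op by construction and only bites
on pan-sharpened 1.2 m products (1.44 m²/cell). Masking drops polygons by
centroid containment (deterministic and fast; geometric intersection is out
of scope). The density surface offers two modes on a 500 m lattice:
`cellsum` (area apportioned to the cell holding each centroid — parameter
free and exactly conservative; the default) and `quartic`
(K(d) = (1−(d/h)²)² for d < h, h = 500 m, area-weighted over centroids),
since a bare "500 m cell size" specification does not pin down a kernel.

## Carrying capacity

Constants: 1 ton/year of sweet potato yields 2809 kcal/day; one person
requires at most 2785 kcal/day. Yields (t/ha/yr) by regime × soil-N:
continuous 1.46/5.09, shifting 5-off/5-on 2.38/8.00, shifting 15-off/3-on
5.61/17.60. Design choices that the published record itself discriminates:

- The 15/3 land fraction is the duty cycle 3/18 = 1/6, not the 25 % a
  caption states: 1/6 exactly reproduces the printed per-regime land areas
  (126.67 from 760; 522.3 from 3133.9) while 25 % does not. The 25 %
  convention remains available behind `use_quarter_for_15_3`.
- Individuals use **floor** division, not rounding — three printed rows
  (…4614.9 → 4614, …3901.8 → 3901, …9271.8 → 9271) discriminate the two.
- The printed energy column derives from the *display-precision* land
  values (1566.9, not 1566.95; truncated at 1 decimal above 500 ha, rounded
  at 2 decimals below). `capacity_table` follows that convention, which
  reproduces 9 of the 12 printed energy cells to ±0.1 kcal/day; the other
  three printed cells are internally inconsistent by < 0.005 % (presumed
  transcription artifacts) and are flagged `energy_discrepant` rather than
  emulated. All 12 individuals values reproduce exactly either way.
- The diet adjustment takes the unweighted mean of the six scenario
  populations (1993.7 for the 760 ha source) and multiplies by 1 +
  supplement fraction (default 0.5 → 2990.5), reported raw and rounded to
  the nearest thousand (~2000 / ~3000).

The model is deliberately just the yield-to-population arithmetic: no age
structure, fertility/mortality dynamics, crop mixes, or temporal dynamics
of garden construction.

## Numerical and I/O choices

- Grids are 0-based row/col, north-up, projected metres (default EPSG:32712);
  cell membership is centre-containment; overlapping polygons resolve to the
  first listed; areas are m² internally, ha/km² only at reporting edges.
- GeoTIFF I/O is implemented on `tifffile` with standard GeoTIFF tags
  (pixel scale, tiepoint, geokey directory, GDAL nodata) plus a JSON image
  description carrying band names, so round-trips are bit-exact. Vector I/O
  is GeoJSON (`shapely` geometries); sample tables are CSV.
- Cubic resampling uses spline interpolation on output cell centres
  (`scipy.ndimage.map_coordinates`, edge-clamped); nodata propagates by
  nearest-neighbour and nodata cells are mean-filled before interpolation
  so they cannot bleed values.
- Model persistence is plain JSON for all three classifier types.
- Seeds are explicit arguments everywhere; no global random state; equal
  config + seed means bit-identical scenes.

## Problem sizes used in the checks

The test suite and the acceptance script run on 48–128 px SWIR grids, 20
benchmark replicates with ≤ 1000 training pixels per class, and a 10×10
grid for brute-force oracle comparisons. These sizes were chosen as the
smallest at which the statistical properties under test are stable.

## Known limitations

- Absolute synthetic-scene accuracies do not transfer to real imagery (see
  above); the package asserts only relative band-set behaviour and exact
  formula-level results.
- No CRS reprojection; inputs must already share a projected CRS.
- MaxEnt is linear-feature only; the random forest has no
  out-of-bag/importance machinery; no boosting or deep models.
- Exclusion masking is centroid-based, so a polygon straddling a mask edge
  is kept or dropped whole.
- ESRI Shapefile input is not supported; convert to GeoJSON first.
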