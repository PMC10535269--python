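# Methods

This note documents the models implemented in `eumap`, the parameter
choices that matter, the design of the synthetic study conditions, and the
limits of what the passing tests establish. It states nothing the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic study area

All stages run on generated data with known parameters
(`eumap.synthdata`). One `SyntheticTruth` object fixes everything; a fixed
seed regenerates every artifact byte-identically (scene, climate, sample
and occurrence streams are keyed by independent seed offsets, so a change
to one stage's draw leaves the others untouched).

**Land-cover mosaic.** Five classes (cropland, other forest, urban, water,
and the target tree species) are laid out as a seeded Voronoi tessellation
of 60 random sites, classes assigned round-robin. Contiguous patches —
rather than salt-and-pepper pixels — make the 20 m point-spacing rule
meaningful. The default grid is 160×160 pixels at 16 m.

**Spectra.** Each class carries a per-date (9 May / 28 June / 9 September),
per-band Gaussian reflectance model over the 8-band schema B1 blue, B2
green, B3 red, B4 NIR, B5 red edge 1 (690–730 nm), B6 red edge 2
(730–770 nm), B7 violet, B8 yellow. Within-class spread is 0.015
reflectance (0.010 for water); the red band of the two closed-canopy tree
classes gets 0.004 because red absorption saturates in dense canopies —
this also keeps the red-edge indices (which divide by B3) informative.

The decisive design property is the target-vs-forest pair. Its mean
separation was budgeted in closed form from the univariate Bhattacharyya
distance, per band (September values): non-red-edge bands contribute
B ≈ 0.67 in total (mostly B4), while B5+B6 contribute B ≈ 1.46 — the red
edge dominates by construction, which is the study condition the screening
and ranking stages are meant to exhibit. The resulting configured J–M
distances are: combination 1 (no red edge) 0.97, combination 2 (all bands)
1.76; the three red-edge indices add enough for the full feature set to
clear 1.8. May and June use scaled-down red-edge separations (June
smallest, both trees at full canopy), so 9 September is the optimal window
by construction. Empirical J–M estimates from ~40–50 samples per class in
6–11 dimensions sit systematically above these closed-form values
(small-sample inflation of the Mahalanobis term); the ordering is
unaffected.

A second preset (`well_separated_truth`) halves every σ, making all ten
configured pairwise 8-band J–M distances exceed 1.9 on the September scene;
it is the condition for the full-raster classification-recovery
experiment.

**Samples.** Points are drawn per class from the mosaic by seeded greedy
rejection with a global minimum pairwise spacing (default 20 m, all pairs,
not just within-class), then split 3:1: the held-out quarter is
`round(n/4)` (half-up), train gets the complement — so 39 points split
29/10. Default counts per class are the field-survey analogue
(43, 53, 45, 28, 39). Infeasible spacing raises an error naming the class.

**Climate and NDVI.** Monthly grids follow
`mean + amplitude·cos(2π(m − peak)/12)` plus a static smoothed spatial
field (Gaussian-filtered white noise — a stand-in for topography) and
per-pixel noise. Defaults emulate a temperate monsoon climate: temperature
14 ± 13 °C peaking in July, precipitation 57.5 ± 50 mm month⁻¹ (annual
≈ 690 mm, summer-concentrated, floored at 0), solar radiation
480 ± 220 MJ m⁻² month⁻¹. Monthly NDVI is a per-class seasonal curve
(forest 0.25→0.85, target tree 0.28→0.80, cropland 0.25→0.65, urban
0.10→0.18, water −0.05) with σ = 0.02.

**SDM inputs.** Nineteen covariate layers named BIO1–BIO19 are independent
Gaussian-filtered white-noise fields (kernel 6 px on a 90×90 1-km grid),
standardized and rescaled to loosely realistic means/ranges. Occurrences
are sampled without replacement with probability proportional to
`expit(5·z(BIO17) − 9)` — a steep logistic in the standardized driver that
concentrates presences in its upper tail. The steepness was set so that
scoring held-out presences by the *true* surface gives AUC well above 0.9
(observed 0.95–0.97 across seeds), i.e. the generated data genuinely
contain a recoverable signal; a gentler surface does not meet that
condition. Background (default 2000 points) is uniform over non-presence
cells.

## Separability

`B` for one feature is `⅛(μᵢ−μⱼ)²·2/(σᵢ²+σⱼ²) + ½ln((σᵢ²+σⱼ²)/(2σᵢσⱼ))`;
`J = 2(1−e^(−B)) ∈ [0,2]`. For feature sets the default is the full
multivariate Gaussian Bhattacharyya with pooled covariance `(Σᵢ+Σⱼ)/2`;
a `univariate-mean` mode (average per-feature B) is retained for
diagnosis, since small samples make the multivariate estimate optimistic.
Covariances are ridged by `1e-8·trace/d` before inversion (28–53 samples
against up to 11 features can be singular, particularly with derived
indices nearly collinear with their bands). The 1-D closed form is
verified against direct numerical integration of the Bhattacharyya
coefficient to 1e-6 over 200 random Gaussian pairs; `B = ln 2 ⇒ J = 1`
exactly. The optimal time window maximizes J–M for the designated hardest
pair under the richest combination; ties go to the earliest date and are
logged.

## Classification

The forest is scikit-learn's `RandomForestClassifier` — the bespoke layer
is schema control, the shared-split comparison, and raster application.
Fixed settings: 500 trees, `max_features = max(1, ⌊√p⌋)`, seeded, single
fixed 3:1 split shared by all compared models (asserted by a partition
hash). The winner is argmax OA, ties broken by target-class PA, then
lowest model id. Metrics come from one split, not cross-validation, and
say so in the output metadata.

Two experiment sizes are used deliberately: the screening and recovery
experiments run at the field-survey sample counts (208 points), but the
eight-model ranking experiment uses 120 points per class. Its point is to
resolve OA differences of a few tenths of a percent between nested feature
sets; a 52-point test set quantizes OA in 1.9 % steps and ties frequently,
whereas 150 test points (0.67 % steps) resolve the ordering in every
seeded world tested.

## Accuracy

Confusion matrices are oriented rows = mapped, columns = reference (row
totals → user's accuracy, column totals → producer's accuracy); segments
may carry positive area weights Sᵢ, count mode being Sᵢ = 1 and identical
to unit-weight area mode. OA, PA, UA are percentages, F1 on 0–1, Kappa is
Cohen's (the field convention where the source names it without a
formula). Reported percentages round half-up to two decimals. The
published five-class confusion table used as a regression fixture is
internally inconsistent (two row totals disagree with their cells, and the
grand total with both); only its internally consistent entries are
asserted — urban, waterbody and target-species UA/PA/F1 and cropland PA —
and its printed OA is not reproducible from the printed cells and is
excluded.

## NPP (light-use efficiency)

Monthly `NPP = 0.5·SOL·FPAR · Tε1·Tε2·Wε · εmax` in g C m⁻² month⁻¹;
annual NPP is the 12-month sum. Functional forms follow the widely used
regional CASA implementation and are pluggable on `CasaModel`:

- **FPAR**: mean (α = 0.5) of linear stretches of NDVI and of the simple
  ratio SR = (1+NDVI)/(1−NDVI) between per-type bounds, clamped to
  [0.001, 0.95]. Bounds are auto-configured as the 5th/95th percentiles of
  each vegetation type's NDVI time series (a documented rule standing in
  for the reference tool's unstated "automatic configuration").
- **Tε1** `= 0.8 + 0.02·Topt − 0.0005·Topt²`, clamped ≥ 0 and zeroed below
  −10 °C; **Topt** is each pixel's mean temperature in its greenest
  (maximum-NDVI) month — the standard convention.
- **Tε2** `= 1.1814 / [(1+e^{0.2(Topt−10−T)})(1+e^{0.3(T−Topt−10)})]`:
  asymmetric cold/heat shoulders with ceiling 1.1814. Its maximum over T
  sits within ~1 °C above Topt (the shoulders are asymmetric), which the
  tests check by grid scan rather than asserting an exact peak at Topt.
- **Wε** `= 0.5 + 0.5·EET/PET ∈ [0.5, 1]`, with Thornthwaite potential
  evapotranspiration Ep0 (annual heat index `I = Σ(max(T,0)/5)^1.514`),
  net radiation `Rn = √(Ep0·P)·(0.369 + 0.598·√(Ep0/P))`, the regional
  estimated evapotranspiration
  `EET = P·Rn·(P²+Rn²+P·Rn) / ((P+Rn)(P²+Rn²))`, and `PET = (Ep0+EET)/2`;
  pixels with PET = 0 get Wε = 0.5 and are counted in the log.
- **εmax** (g C MJ⁻¹) per vegetation type ships as literature defaults
  (broadleaf forest and the plantation tree 0.692, cropland/grass 0.542,
  shrub 0.429, other 0.389). These are configuration, not ground truth.

NPP is therefore bounded by `0.5·SOL·0.95·Tε1·1.1814·εmax`, an envelope
checked on 10⁶ random pixels. Carbon totals are
`Σ NPP·pixel_area·10⁻⁶ t C a⁻¹` over a class mask. Point validation
samples n = 30 seeded valid pixels and reports RMSE, Pearson r, and r² —
both correlation quantities are reported because the field sometimes
labels the correlation itself as R².

**Natural breaks** use the exact Fisher–Jenks dynamic program (O(kn²)),
verified against exhaustive search on short arrays; breaks are reported as
the largest member of each lower class. Above 3000 values the DP runs on
an evenly spaced order-statistic subsample and the resulting breaks are
applied to the full raster — class boundaries can then miss a few extreme
fringe values, which is acceptable for raster zoning.

## Maximum-entropy SDM

The model is the Gibbs distribution `q(x) ∝ exp(λ·f(x))` over the
background sample, fitted by maximizing the L1-regularized mean presence
log-likelihood. Features per covariate (scaled to [0,1] by background
range): linear, quadratic, and forward/reverse hinges at knots
0.25/0.5/0.75. Penalty `βⱼ = β·max(sⱼ, 0.05)/√n_presence` with sⱼ the
presence standard deviation of feature j and β = 1 by default — the
conventional shape of the reference tool's schedule, not a reproduction of
its interpolation tables. The optimizer is cyclic coordinate-wise proximal
Newton (soft-threshold step, halved on non-improvement), converging when a
full cycle improves the regularized gain by < 1e-5, capped at 1000 cycles;
it is deterministic given the data. The raw output sums to 1 over
background by construction; logistic output is
`p = c·e^η/(1+c·e^η)` with `c = e^H`, H the entropy of the fitted
distribution.

Evaluation: rank-based AUC (ties half credit) of presence vs background
scores; 10 replicates, each a fresh random 75/25 presence split.
Importance diagnostics: *percent contribution* credits each coordinate's
objective-gain increments to its owning variable and normalizes to 100
(an attribution along this optimizer's path — like the reference tool's,
it is path-dependent and not comparable across implementations);
*permutation importance* is the training-AUC drop after shuffling one
variable, floored at 0 and normalized to 100 (the reference tool
normalizes differently, which is why its printed columns need not sum to
100); *jackknife* refits with-only and without each variable and reports
gains. Zoning offers exact Fisher–Jenks (k = 4) and fixed published-style
breaks applied as half-open intervals [0,0.16), [0.16,0.35), [0.35,0.5),
[0.5,1] — the printed bounds leave rounding gaps (0.35→0.36, 0.5→0.51)
that half-open tiling resolves. Areas are pixel counts × resolution².

## Problem sizes and determinism

Default sizes were chosen so the whole suite and the acceptance script
each run in a few minutes on one CPU while keeping every statistical check
well-powered: 160×160 scene pixels, 208 or 600 sample points, 90×90 SDM
grid with 2000 background points, 10 replicates/seeds per stochastic
experiment, 10⁶ pixels for the NPP envelope. All randomness flows from
explicit seeds; every generator and the pipeline manifest are regeneration-
stable (content hashes, not file bytes, so TIFF encoding details don't
matter).

## Limitations

- The synthetic scenes have Gaussian, spatially independent within-class
  noise: no texture, mixed pixels, clouds, terrain illumination, or sensor
  artifacts. Passing recovery tests shows the chain is correct and
  well-calibrated under its stated conditions, not that the same accuracy
  would be reached on real imagery.
- Radiometric calibration (`L = gain·DN + bias`) is provided but the
  synthetic path generates reflectance-like values directly; indices are
  computed on whatever calibrated surface is supplied, and no atmospheric
  correction is modelled.
- The CASA stress formulations are one published lineage; alternates can
  be swapped via `CasaModel`'s pluggable functions, and εmax values are
  literature defaults.
- The SDM reports model-internal diagnostics; percent contribution in
  particular is optimizer-path-dependent. Bioclim layers are mutually
  independent by construction except for sampling correlation, unlike real
  climate surfaces whose collinearity would spread contribution across
  correlated variables.
- Areas are pixel counts times nominal resolution on one shared grid; no
  projection or datum handling is attempted.
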