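# eumap

Mapping a target tree species (*Eucommia ulmoides*, a medicinal/rubber
tree grown in plantations) from multi-date 8-band imagery, and assessing
its carbon sequestration and ecological suitability — as a fully synthetic,
ground-truth-controlled pipeline.

The package reimplements a four-stage remote-sensing analysis chain for
imagery with GF-6 WFV band semantics (blue, green, red, NIR, two red-edge
bands, violet, yellow):

1. **Band screening** — Jeffries–Matusita separability
   `J = 2(1 − e^(−B))` with the Gaussian Bhattacharyya distance
   `B = ⅛(μᵢ−μⱼ)²·2/(σᵢ²+σⱼ²) + ½ln((σᵢ²+σⱼ²)/(2σᵢσⱼ))`
   (full multivariate form for band sets), computed per acquisition date and
   band combination to pick the optimal time window; `J ≥ 1.8` marks
   excellent separability.
2. **Classification** — a random forest (500 trees, `⌊√p⌋` features per
   split) compared across eight band-combination models on one shared 3:1
   train/test split, scored with confusion-matrix OA / Kappa / producer's /
   user's accuracy / F1, then applied to the full raster.
3. **Carbon** — light-use-efficiency NPP (CASA):
   `NPP = APAR · Tε1 · Tε2 · Wε · εmax` with `APAR = 0.5·SOL·FPAR`,
   FPAR an NDVI/simple-ratio stretch blend, two temperature stresses and a
   water stress `Wε = 0.5 + 0.5·EET/PET`; annual NPP is graded with exact
   Fisher–Jenks natural breaks and summed to a carbon total (t C a⁻¹) over
   the species mask, with 30-point RMSE/r validation against a reference
   raster.
4. **Suitability** — an in-package maximum-entropy species distribution
   model (Gibbs distribution over background, L1-regularized coordinate-wise
   fit over linear/quadratic/hinge features of BIO1–BIO19, logistic output),
   evaluated by held-out ROC AUC over 10 bootstrap replicates, with percent
   contribution / permutation / jackknife variable importance, four-class
   zoning and pixel-count area accounting.

Because no real scenes ship with the package, a first-class synthetic-data
module generates every input with known parameters — per-class Gaussian
spectra over a seeded Voronoi land-cover mosaic (with the red-edge bands
carrying the dominant separation between the target tree and other forest,
by construction), seasonal climate grids, monthly NDVI, spatially
autocorrelated bioclim layers, and occurrences drawn from a known logistic
suitability surface — so every stage is testable against ground truth.

## Worked example

The analysis is organised as numbered scripts over the library
(`src/eumap/`); each regenerates its inputs deterministically from a seed
and writes small tables under `results/`:

```
python analysis/01_simulate.py      --seed 0
python analysis/02_separability.py  --seed 0
python analysis/03_classify.py      --seed 0
python analysis/04_npp_carbon.py    --seed 0
python analysis/05_suitability.py   --seed 0
```

Band screening (script 02) prints the J–M table; the hard pair is the
target tree vs other forest:

```
combination                       combination1  combination2  combination3
2021-09-09 eucommia-other_forest         1.147         1.894         1.990
target vs other-forest on 2021-09-09 (best window)
```

Conventional bands alone (combination 1) leave the pair poorly separable;
adding the two red-edge bands (combination 2) and the red-edge indices
NDVI/NDVI710/NDVI750 (combination 3) lifts it past the 1.8 threshold, and
September is the best window — so the screening stage recovers exactly the
structure built into the scene. The model comparison (script 03) agrees:

```
 model                              bands             oa  kappa    pa     ua
model1                 B1+B2+B3+B4+B7+B8           92.31   0.90  80.0  80.00
model4           B1+B2+B3+B4+B5+B6+B7+B8          100.00   1.00 100.0 100.00
winner on 2021-09-09: model4
test-set OA 100.00%, kappa 1.000; full-raster agreement with generator truth 98.95%
```

Script 04 estimates annual NPP of 51.6–893.1 g C m⁻² a⁻¹, grades it into
four natural-breaks classes, and accounts 940.11 t C a⁻¹ over the
5038-pixel species mask; 30-point validation against a reference raster
with injected noise sd 50 gives RMSE 56.94 and r 0.9414. Script 05 fits
the MaxEnt stage: held-out AUC 0.965 (mean of 10 replicates), and the true
generating driver BIO17 (precipitation of the driest quarter) tops the
percent-contribution table at 26.5%.

The same stages can be run as one orchestrated pipeline with a manifest of
content-hashed artifacts:

```python
from eumap.pipeline import RunConfig, run
manifest = run(RunConfig(seed=0, out_dir="scratch/run"))
```

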