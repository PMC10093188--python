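# trabmorph

Quantitative analysis of trabecular (cancellous) bone microstructure from 3D
volumes, with a fully synthetic, seeded test bed for studying how scanner
resolution changes the numbers.

## The problem

The mechanical quality of cancellous bone depends not just on how much bone
there is but on how it is arranged: thin interconnected plates and rods of
the order of 0.1–0.3 mm. Micro-CT resolves these struts directly, but only
ex vivo. Clinical CT can image patients, at the price of voxels comparable
to the strut size, so every measured parameter is distorted by
partial-volume blur in a parameter-specific way: apparent strut thickness
and bone volume fraction inflate, connectivity drops, and some quantities
(like the total tissue volume examined) should not change at all. Knowing
the direction and size of these biases — and which parameters survive a
resolution change — is essential before clinical-resolution morphometry can
be interpreted.

`trabmorph` implements the full chain:

1. **Volume I/O** — TIFF stacks, MetaImage, NIfTI; voxel spacing is always
   explicit, never defaulted.
2. **Synthetic phantoms** with closed-form ground truth: plates, rods,
   spheres, cubic rod lattices, and seeded Gaussian-random-field textures
   with an exactly controlled bone volume fraction.
3. **Binarization** by discriminant (Otsu) thresholding on the intensity
   histogram.
4. **An eight-segment VOI layout**: eight cylindrical volumes of interest
   (by default 16 mm diameter × 12 mm height) at the octants of a specimen,
   labelled cranial/caudal × ventral/dorsal × left/right.
5. **Fourteen morphometric parameters** per VOI: TV, BV, BS, BV/TV, Conn.D,
   TSL, Tb.Th, Tb.N, Tb.Sp, fractal dimension, trabecular bone pattern
   factor (TBPf), structure model index (SMI), and the star volumes of the
   marrow space and of the trabeculae.
6. **Resolution degradation**: anisotropic Gaussian point-spread blur,
   resampling to a clinical ultra-high-resolution CT grid (0.25 mm slices,
   0.15625 mm in-plane), additive noise, and independent re-thresholding —
   a digital twin of scanning the same specimen on two devices.
7. **Statistics**: per-parameter two-sided Mann–Whitney rank tests between
   the two resolution branches, and per-parameter linear regressions
   (hi-res as explanatory variable) with F-test, R² and 95 % confidence
   band.
8. **A deterministic pipeline and CLI**: a run is a pure function of its
   JSON-serializable config; identical configs produce byte-identical
   output files.

## Worked example

```python
from trabmorph import study_config, run_pipeline

# Reduced-geometry study: a seeded Gaussian-field phantom at 0.05 mm voxels
# (BV/TV ~ 9.5 %, mean strut thickness ~ 0.22 mm), eight cylindrical VOIs,
# measured as-is and after degradation to the clinical grid.
cfg = study_config(scale=0.2, seed=1)
run_pipeline(cfg, "out/")
```

`out/table_means.csv` from this exact config (values your machine will
reproduce bit-for-bit):

| parameter | hi-res mean ± sd | degraded mean ± sd | p (rank test) |
|---|---|---|---|
| TV (mm³)    | 19.44 ± 0.21  | 19.25 ± 1.08   | 1.000 |
| BV/TV (%)   | 9.73 ± 2.14   | 25.23 ± 7.72   | 0.00016 |
| Tb.Th (µm)  | 220.3 ± 16.9  | 441.5 ± 96.4   | 0.00016 |
| Conn.D (1/mm³) | 2.57 ± 0.42 | 0.59 ± 0.21   | 0.00092 |
| TBPf (1/mm) | 7.61 ± 0.78   | 1.78 ± 1.01    | 0.00016 |
| SMI         | 4.21 ± 0.24   | 3.90 ± 0.86    | 0.382 |

The same physical cylinders are measured in both branches, so TV is
statistically indistinguishable (p = 1.0) while partial-volume blur inflates
apparent bone fraction and strut thickness roughly 2.5-fold and erases
connectivity — the characteristic signature of measuring 0.2 mm struts with
0.25 mm slices. p = 0.00016 is the exact two-sided floor 2/C(16,8) for
fully separated 8-vs-8 samples.

The same run is available from the command line:

```sh
trabmorph run --scale 0.2 --seed 1 --out out/
```

and the individual stages as `trabmorph convert | phantom | binarize | voi |
measure`.

## Validation

The test suite (≈190 tests, a few minutes on one CPU) checks the numerics
against independent oracles rather than against itself, for example:

- sphere/cylinder/plate surface areas and volumes vs. closed forms;
- SMI of an ideal plate/rod/sphere = 0 / 3 / 4 and TBPf of a plate = 0,
  at 0.02 mm voxels;
- local thickness vs. an exhaustive sphere-fitting oracle on small grids;
- star volume of a convex body = the body's volume;
- Otsu thresholds vs. exact rational-arithmetic enumeration;
- Mann–Whitney p-values vs. enumeration of all label assignments;
- regression coefficients vs. the normal equations at 1e-10;
- byte-identical pipeline reruns.

To regenerate the headline anchor values from scratch:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which rebuilds the ideal-structure phantoms at 0.02 mm voxels and reports
the measured SMI plate/rod/sphere values, plate TBPf, and the sampling
interval required to resolve a 0.1 mm trabecula (expected 0, 3, 4, 0 and
0.05 mm).

See `docs/methods.md` for the estimator definitions, numerical conventions
and known limitations.
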