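# Methods

Definitions, numerical conventions and limitations of the `trabmorph`
estimators. Everything here is implemented against synthetic phantoms with
closed-form ground truth; the unit and acceptance tests cite the exact
tolerances.

## Conventions

- **Axes and units.** Arrays are indexed `(slice, row, col)` = `(z, y, x)`.
  All physical quantities are millimetres; voxel centre `i` sits at
  `origin + i * spacing`. Spacing is mandatory everywhere — there is no
  implicit 1 mm default, and TIFF stacks cannot be read without supplying
  it.
- **Determinism.** Every stochastic component (phantom noise field, star
  volume sampling, degradation noise) takes an explicit seed. A pipeline
  run is a pure function of its `RunConfig`; reruns are byte-identical.
- **Degenerate inputs raise.** Empty phases, VOIs outside the grid, grids
  too small for an estimator's preconditions, or non-discriminable
  histograms raise `ValueError` with a message naming the offending
  dimension or quantity. The per-VOI aggregator records such failures per
  parameter (value NaN + error string) instead of aborting the whole VOI;
  the statistics stage then drops non-finite pairs and reports `n`.

## Phantoms

- **Plate / rod / sphere** primitives are rasterized by voxel-centre
  membership and carry their analytic volume/surface in `meta`. A feature
  thinner than two voxels is refused. Rods and plates that span the full
  grid have open ends (no caps) — meshing generates no faces on the array
  boundary, which is what makes an "infinite" plate or rod representable on
  a finite grid.
- **Rod lattice**: three orthogonal rod families on a cubic grid with the
  inclusion–exclusion closed-form fill fraction attached as ground truth.
- **Gaussian random field**: seeded white noise smoothed with an isotropic
  Gaussian whose FWHM is the correlation length `corr_length`, then
  thresholded at the exact quantile giving the requested bone fraction.
  The study default is `corr_length = 0.35 mm` at `BV/TV = 9.5 %`, which
  yields a measured mean strut thickness of ~0.22–0.26 mm — inside the
  0.1–0.3 mm range of human trabeculae. (With larger correlation lengths
  the same fraction produces unrealistically thick struts: 0.6 mm gives
  ~0.49 mm.) The phantom reproduces plausible strut thickness, spacing and
  volume fraction; it does **not** reproduce the anisotropy, plate/rod
  mixture or cortical shell of real vertebral bone, and its SMI sits in the
  hyperbolic/sparse regime (~4) rather than the plate–rod transition.

## Binarization

Discriminant (Otsu) thresholding on a 256-bin histogram: the threshold
maximizing the between-class variance `w0·w1·(μ0 − μ1)²`, evaluated at
every interior bin edge. Candidates within 1e-12 relative of the maximum
are treated as exact ties (the cumulative-sum formulation carries ~1e-16
rounding noise) and the lowest threshold wins. Comparison is inclusive
(`intensity ≥ t` is bone), preserving thin bright struts. Each modality
branch is thresholded on its own histogram, as with two real scanners.

## VOI layout

Eight cylinders (default 16 mm diameter × 12 mm height, axis along the
slice direction) centred at the octants of the specimen bounding box,
labelled {cranial, caudal} × {ventral, dorsal} × {left, right}. Bounds too
small for the cylinders raise an error naming the deficient dimension.
Rasterization is by voxel-centre membership; the indicator's volume
converges to `π r² h` as spacing shrinks (1 % at 0.05 mm for a 3.2 mm
cylinder) but is quantized by up to one slice in height and one boundary
cell ring in-plane — relevant when cylinders are small relative to voxels.

## Parameters

All surface-based quantities mesh a Gaussian-regularized (σ = 1 voxel)
version of the binary mask with marching cubes at level 0.5. Regularization
is what makes mesh differentials meaningful on voxel data: meshing the raw
binary staircase overestimates a sphere's area by ~9 % and its SMI by ~25 %.

- **TV, BV, BV/TV** — voxel counting inside the VOI indicator.
- **BS** — area of the mesh faces whose centroids fall inside the VOI.
- **SMI** = `6·V·S′/S²`, with `S′` estimated by offsetting mesh vertices
  half a voxel outward along vertex normals: plate → 0, rod → 3, sphere →
  4 (measured 0.000 / 2.986 / 3.997 at 0.02 mm voxels). Concave junctions
  contribute negatively (a dense rod lattice scores well below 3).
- **TBPf** = `(S1 − S2)/(V1 − V2)` across a one-voxel Euclidean dilation:
  0 for a plate, `2/R` for a sphere, negative for concave (honeycomb)
  geometry.
- **Tb.Th, Tb.Sp** — maximal-inscribed-sphere local thickness of the bone
  (resp. marrow) phase: anisotropic EDT, spheres painted largest-first with
  radii quantized to quarter-voxel bins (≤128 levels). Reported diameter is
  `2·max(dt − half-voxel, half-voxel)`: an isolated voxel reads exactly one
  voxel, and an even-width slab whose optimal centre falls between voxel
  centres may read up to one voxel under truth.
- **Conn.D, TSL** — the bone phase is thinned to a medial skeleton;
  skeleton voxels with one 26-neighbour are termini, with ≥3 junctions
  (adjacent junction voxels collapse to one node), and endpoints within
  their local strut radius (+1 voxel) of a volume face are cortical
  attachments. Conn.D = branches/TV; TSL = summed polyline arc length.
  The thinning includes a rescue for a known scikit-image behaviour where
  a component with fully even-width cross-section is deleted outright: such
  components are re-thinned after a one-voxel one-sided dilation (parity
  flip; medial axis moves ≤1 voxel). The Euler-characteristic alternative
  `(1 − χ)/TV` is reported separately, never silently substituted.
- **Tb.N** — marrow→bone transitions per unit grid-line length, averaged
  over the three axis directions; the derived estimate `(BV/TV)/Tb.Th` is
  recorded alongside.
- **FD** — box counting over the surface voxel set (bone voxels with a
  6-connected marrow neighbour), dyadic box sizes from 2 to min-dim/4; at
  least 3 sizes required (min grid dimension ≥ 16), otherwise the parameter
  errors out — which legitimately happens for very coarse degraded VOIs.
- **V\*m.space, V\*tr** — Monte-Carlo star volume `(π/3)·⟨ℓ³⟩`: seeded
  uniform sample points in the phase, isotropic directions, rays marched at
  quarter-voxel steps. Rays leaving the VOI or grid while still inside the
  phase are truncated there and flagged; the censored fraction is reported
  with the estimate. For a convex body the estimator returns the body
  volume (the oracle used in tests).

## Resolution degradation

Binary phantoms are cast to 0/100 intensity, blurred with an anisotropic
Gaussian PSF, linearly resampled to the clinical grid (0.25 mm slices,
0.15625 mm in-plane — a 160 mm field of view on a 1024 matrix), and given
seeded additive Gaussian noise. Refinement (resampling to a finer grid than
the input) is refused. The true reconstruction-kernel PSF of the emulated
scanner is not published; the default FWHM of **0.8 mm slice / 0.5 mm
in-plane** is the one free parameter of the model, calibrated once so the
direction of partial-volume effects (thickness and volume-fraction
inflation after independent re-thresholding) is reproduced. With weaker
blur the Otsu threshold shift and the blur cancel almost exactly and the
thickness bias direction is not stable. Magnitudes of bias are not
calibrated and should not be read as device-accurate.

A feature of size `f` requires a sampling interval ≤ `f/2`
(Nyquist): resolving 0.1 mm trabeculae needs ≤ 0.05 mm sampling — an order
below the clinical slice pitch, which is the core of the problem.

## Statistics

Per parameter, the eight hi-res VOI values and eight degraded VOI values
are compared with a two-sided Mann–Whitney U test — exact enumeration when
`n1 + n2 ≤ 20` and untied (the fully separated 8-vs-8 floor is
`2/C(16,8) ≈ 1.55e-4`), tie-corrected normal approximation otherwise. The
groups are treated as unpaired by design, matching the common two-scanner
study layout; a paired sign-flip permutation test is available separately.
Each parameter also gets an OLS regression of degraded on hi-res values
with F-test, R² and the parameters of the 95 % confidence band for the mean
response. Non-finite pairs (e.g. FD on too-coarse VOIs) are dropped and the
remaining `n` reported.

## Reduced problem sizes

The default `study_config(scale=0.2)` shrinks the physical geometry
(phantom extent ~9.6×12.8×12.8 mm, VOIs 3.2 mm × 2.4 mm) while keeping
voxel size, strut scale and fill fraction — so the microstructure and its
partial-volume physics are unchanged, only fewer struts per VOI. This is a
deliberate package choice to keep a full study run around a minute on one
CPU; `scale=1` gives the full-size geometry. Consequences at small scale:
VOI volumes are quantized by the coarse grid (up to ~20 % per octant at
scale 0.2, ~2 % at full scale), and FD is undefined on degraded VOIs with
fewer than 16 slices.

## Limitations

- The phantom is an isotropic Gaussian-field texture: no anisotropy,
  plate/rod architecture, cortical shell, or marrow-density gradients.
- The scanner model is blur + resample + white noise: no beam hardening,
  no reconstruction-kernel ringing, no spatially varying PSF.
- PSF FWHM is calibrated to bias direction only; magnitudes are synthetic.
- Skeleton-based Conn.D counts branches, which is sensitive to thinning
  artifacts at coarse resolution; the Euler alternative is provided for
  cross-checking.
- Star volume truncates censored rays rather than reweighting them, which
  biases V* downward when the phase extends far beyond the VOI; the
  censored fraction is always reported so this is visible.
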