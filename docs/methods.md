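# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `chiptaxis`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Device geometry

All physical dimensions live in `DeviceGeometry` (micrometres). Defaults
describe the two device families the package targets: a migration chip
whose gel channel spans 1300 µm between two media channels (ROI
2200 × 1300 µm), and a vascularized-well chip imaged as a 3 × 3 mm field
with a 1.5 mm central well and ~40 µm microvessels. The default pixel
size is 4 µm/px; construction rejects geometries whose vessels would span
fewer than 3 pixels.

## Image quantification

The pipeline mirrors a classical ImageJ-style morphological analysis of a
max-projected confocal field:

1. **z-collapse** — per-pixel maximum over z.
2. **Vessel segmentation** — Otsu threshold by default (the mask is then
   invariant to affine intensity changes); a manual threshold is
   available when staining is uneven.
3. **Well localization** — `n_iterations` binary dilations followed by
   the same number of erosions (disk radius 3 px, 10 iterations by
   default) close the dark inter-vessel ECM gaps; inverting then exposes
   holes, and the largest interior (non-border) background component with
   area ≥ 0.2 mm² is the well. The defaults close gaps up to ~240 µm —
   several times the typical inter-vessel spacing — while a 1.5 mm well
   survives, which is why the detected well is insensitive to doubling
   the iteration count. The well is finally dilated by 50 µm so cells
   pressed against its rim count as recruited.
4. **Spot detection** — the monocyte channel is smoothed with a Gaussian
   of σ = 3 µm (a matched filter at roughly half the 12 µm cell width;
   without it, single-pixel noise maxima at snr 10 pass the prominence
   gate), min–max normalized, and regional maxima with normalized
   prominence ≥ 0.25 are kept. Peaks closer than 15 µm are thinned
   brightest-first, ties broken by (row, column) order, so detection is
   deterministic.
5. **Classification** — recruited if inside the (dilated) well, else
   luminal if inside the *original* vessel mask (the closed mask contains
   filled gel gaps that are not lumen), else extravasated. Well beats
   vessel on overlap. Conservation (luminal + extravasated + recruited =
   total) is structural.

Batch runs isolate failures: an image whose well cannot be found yields a
flagged NaN row, never an aborted batch. The spheroid size helper returns
the circle-equivalent diameter 2·√(area/π) of a projected mask.

## Forward Keller–Segel model

Cell density in the gel channel follows ∂n/∂t = ∂/∂x(D ∂n/∂x − χ n ∂c/∂x)
on [0, L] with zero-flux walls; the chemoattractant profile c is
prescribed (zero, uniform, or linear 0→1), not solved, because the
conditioned-media source is continuously replenished and the channel is
short. Concentration is normalized to [0, 1], so χ carries units µm²/h
per unit normalized concentration and is only compared across conditions;
the induced drift is v = χ·dc/dx.

Discretization: node-centred finite volumes with half cells at the walls,
chosen so the trapezoid integral of nodal densities *is* the conserved
finite-volume mass. Diffusion uses Crank–Nicolson with two implicit-Euler
start-up steps (Rannacher smoothing) to damp the checkerboard mode excited
by the near-delta initial condition (all mass at the entry interface);
advection uses first-order upwinding in flux form. Default grid L/104
(12.5 µm); the time step obeys both the advective Courant bound
v·dt/dx ≤ 0.5 and the positivity bound D·dt/dx² ≤ 0.5 and is chosen
automatically unless supplied. Mass is conserved to rounding error and
density stays nonnegative. Against the reflected-Gaussian closed form
(D = 1000 µm²/h, t = 6 h) the error is ~0.17% of peak on the default grid
and 0.026% at dx = 5 µm; the error is dominated by the O(dx²) spatial
term.

## Simulation of migration data

The microscopic counterpart of the PDE: Euler–Maruyama steps
dx = χ·(dc/dx)·dt + √(2D dt)·ξ with mirror reflection at both walls,
all cells starting at x = 0, default dt = 0.01 h (the per-step
displacement must stay below L/20, enforced). Snapshot times default to
24 h and 48 h, matching day-1/day-2 imaging. With χ = 0 the positions are
half-normal while the diffusion length stays below the channel; the test
suite checks the first two moments against that law within Monte-Carlo
error.

## Estimation

* **D (controls only)** — the moment estimator D̂ = ⟨x²⟩/(2t) is exact for
  reflected diffusion from the wall while √(2D̂t) < L/4 (a validity flag
  is set otherwise); the likelihood estimator bins positions into 26
  equal bins and maximizes the multinomial log-likelihood of bin counts
  under the forward model, searching over log D (bounded Brent,
  10⁻²–10⁶ µm²/h). The two agree within 10% whenever the moment condition
  holds. Binned rather than continuous likelihood is deliberately robust
  to detection jitter in image-derived positions.
* **Pooling** — control D̂s are averaged unweighted and the pooled value
  is frozen for every χ fit; random motility is treated as
  device-independent.
* **χ (gradient conditions)** — bounded scalar search of the same binned
  likelihood over χ ∈ [−χ_max, χ_max] (default 10·D·L), signed, negative
  meaning repulsion. With no gradient χ multiplies zero and is
  unidentifiable; the estimator refuses rather than returning noise.
  Optional bootstrap (resampling cells, seeded) provides standard errors.
* **Migrating percentage** — 100 × (cells with x > L/2)/total; the
  midline counts as not migrated.

At the study conditions (n = 5000 cells, t = 24 h, L = 1300 µm) the
likelihood estimators recover D within 10% over 500–2000 µm²/h and χ
within 15% at drifts of 5–10 µm/h; with χ = 0 the fitted effective drift
stays within ±2 µm/h (the "null band"), with a false-exceedance rate
under 10% across 50 simulated ROIs.

## Chemotaxis vs chemokinesis

The three-arm design — gradient, uniform stimulus, no stimulus — is
analysed by `compare_chemokinesis`: migrating percentages per ROI for all
arms, D fit separately for control and uniform arms, and χ for the
gradient arm. χ is fit twice, deliberately:

* with the pooled **control** D — the convention used to compare χ across
  conditions;
* with the **uniform-arm** D — the *chemokinesis-adjusted* fit used for
  the detection call. If the stimulus genuinely raises motility, freezing
  D at the control value forces the likelihood to explain the extra
  spread with spurious positive drift (measured: +3.4–5.3 µm/h when the
  true D is doubled). The uniform arm measures motility under the same
  saturated stimulus without a gradient, so fixing D there isolates the
  directional component; under pure chemokinesis the adjusted drift falls
  back inside the null band while D_uniform/D_control ≈ 2.

## Synthetic image generator

The generator emulates what the quantification pipeline needs to be
tested against, not the biology of vasculogenesis. Vessel texture: the
median level-set contours of two independent Gaussian random fields
(correlation length 40 µm), dilated to the target width — two loop
families cross each other, so the union forms a single anastomosed
network (largest component ≥ 98% of vessel area) with median ribbon width
40 µm and ECM pockets on the ~100 µm scale. A vessel ribbon hugs the well
rim, as networks do along the gel–well interface; without it the rim
pockets merge into the well under closing. Cells are isotropic Gaussian
spots (FWHM 12 µm, unit amplitude) placed by dart-throwing with ≥ 2 spot
widths of separation: luminal on vessels, recruited ≥ 40 µm inside the
well, extravasated ≥ 16 µm from vessels and ≥ 70 µm from the well (clear
of the pipeline's 50 µm rim dilation). Both channels get additive
Gaussian noise of σ = 1/snr. Everything is a deterministic function of
the seed.

What the generator does **not** emulate: uneven illumination, staining
heterogeneity, vessel brightness variation, overlapping or out-of-focus
cells, z-dependent structure (it is max-projection-equivalent 2D only),
and autofluorescence. Passing recovery tests therefore demonstrates the
pipeline's logic and calibration on clean-but-noisy fields, not
performance on arbitrary real microscopy — thresholds and prominences
will need per-dataset tuning there.

## Problem sizes and determinism

Tests and the acceptance script use 20 synthetic fields of 100 cells for
count recovery, 5000-cell snapshots for estimator checks, 3000-cell arms
for the chemokinesis screen, and 500-cell ROIs × 50 replicates for null
calibration — sizes at which Monte-Carlo error is comfortably below every
tolerance asserted. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configuration and seed reproduce
byte-identical tables, which the demo-determinism test asserts literally.

## Known limitations

* Inference is 1D along the migration axis; no 2D/3D chemotaxis fitting.
* D and χ are never fit jointly from a single treated condition; if the
  control arm is missing, χ cannot be reported.
* The linear steady gradient is an idealization; transient source
  kinetics are out of scope.
* The moment D estimator biases low once cells feel the far wall; the
  likelihood estimator handles that regime but inherits the forward
  model's first-order advection error at extreme drifts.
* Luminal/extravasated/recruited calls are projection-based; a cell
  floating above a vessel in z is called luminal.
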