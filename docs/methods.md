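# Methods

`demar` simulates a dual-energy cone-beam CT (DE-CBCT) metal-artifact
study end to end: phantom definition, polychromatic acquisition,
projection-domain material decomposition, virtual monochromatic image
(VMI) synthesis, inpainting-based metal artifact reduction (MAR), and
ROI-based artifact scoring with paired statistics. This note records the
models, the defaults and why they were chosen, and what the desk-scale
simulation does and does not establish about real scanners.

## Physical model

**Spectra.** Tube spectra use a Kramers-type bremsstrahlung shape,
`N(E) ∝ (kVp − E)/E` on a 1 keV grid from 5 keV to the tube voltage,
filtered through Beer–Lambert attenuation of the configured layers
(default 2.5 mm Al + 0.2 mm Cu). Characteristic anode lines, heel effect
and off-focal radiation are omitted. Real vendor spectra are proprietary;
the decomposition only requires that simulation and inversion share one
spectrum model, which holds exactly here. A CSV import path
(`Spectrum.from_csv`) lets users substitute measured spectra and probe
spectrum-mismatch sensitivity.

**Attenuation tables.** Mass attenuation coefficients are bundled as
coarse 15-point log-log tables (5–300 keV) per element/compound, with
absorption edges encoded as duplicate-energy rows; interpolation is
log-log and never bridges an edge pair. Water, H, Al, Cu and Fe carry
standard reference grids; the remaining elements come from a piecewise
power-law photoelectric model plus a Klein–Nishina-scaled incoherent
term anchored at published reference values (accuracy a few percent for
low-Z, ~10% for high-Z). This is sufficient because every quantitative
claim in the package is internally consistent: the simulator and the
solver use the same tables.

**Detector.** Ideal energy-integrating response: a photon of energy `E`
contributes signal `∝ E`. The measured signal for a ray is
`Σ_E S(E)·E·exp(−Σ_m μ_m(E)·A_m)` with `A_m` the projected mass density
(g/cm²) of basis/phantom material `m`. Counting noise scales the signal
to an expected photon count at a configurable flat-field budget, draws
one Poisson variate per pixel (floored at one count so logarithms stay
finite) and scales back. Scatter, detector lag, glare and electronic
noise are not modeled.

**Geometry.** Parallel-beam, 360 views over 180°, one detector channel
per image pixel plus diagonal padding (363 channels at the default
256×256 grid, 0.45 mm pixels). Forward projection and filtered
back-projection use `skimage.transform.radon`/`iradon` with a
cosine-apodized ramp filter. The 2D central-slice analog stands in for
cone-beam FDK: artifact scoring is slice-wise anyway, and in-plane
streak physics is what the method manipulates.

## Phantoms

Each phantom is a 10 cm gelatine cylinder (PLA shell, 2 mm) with
surrogate dental inserts, rasterized by deterministic pixel-center
sampling. The six study materials and their surrogate compositions:
titanium (pure Ti), zirconia (ZrO₂), amalgam (Hg/Ag/Sn 50/30/20),
cobalt-chrome (Co/Cr/Mo 60/30/10), high-gold alloy (Au/Pt/Pd 75/15/10),
composite resin (polymer with Al/Ca/Zr filler). Compositions and
densities are config-editable surrogates for physical specimens of
unknown exact composition.

Insert layouts mirror the restorations they emulate: fillings and the
implant screw are single discs (4, 4 and 3 mm radii for amalgam,
composite and titanium), while the three fixed-dental-prosthesis
materials are three-unit bridges — three 3.5 mm discs on an arc. The
multi-unit layout matters: a single convex disc is the degenerate
easiest case for trace inpainting (one smooth sinogram band per view),
whereas interleaved unit shadows are what make real inpainting MAR
introduce new streaks. Inserts sit ~12 mm off the rotation axis because
an exactly centered insert is a measure-zero configuration whose metal
trace degenerates to the same channel band in every view.

## Material decomposition

Each sinogram pixel measured at 80 and 120 kV is inverted for
`(A_water, A_iron)` by minimizing the intensity-domain l2 residual
between flat-field-normalized measurements and the polychromatic model.
The solver is damped Gauss–Newton from `A = 0` with analytic Jacobians,
a fixed budget of 200 iterations, per-pixel step halving until the
residual is non-increasing (to a 1e-12 relative band), and early exit
when the step norm falls below 1e-12 g/cm². The intensity domain (not
log) is used because that is where the energy-integrating measurement
model is linear in fluence; normalization removes the arbitrary fluence
scale.

Steps are projected onto a feasibility box, default −2 to 50 g/cm² per
basis. Rationale: fully photon-starved rays quantize both measurements
at the counting floor, a spectrally impossible pair (equal attenuation
at both tube voltages), and the unconstrained least-squares path runs
down a water-positive/iron-negative valley toward path lengths
equivalent to meters of water. The box keeps such rays at bounded,
physically scaled values; every feasible ray — including small
noise-driven negative excursions, which are deliberately not clipped so
the downstream VMI stays unbiased — is unaffected. Non-convergence is
reported through the residual map, never as an exception.

On noiseless self-generated data the inversion is exact to machine
precision (the acceptance suite checks 1e-6 relative), and with two
single-bin spectra it reproduces the closed-form 2×2 log-linear solution
to 1e-10.

## VMI, MAR and the four arms

VMI line integrals are `p_E = μ_water(E)·A_water + μ_iron(E)·A_iron`,
synthesized at 200 keV by default — high enough that both basis
coefficients are nearly flat, which is what removes beam hardening.
`p_E` is already a line integral; it goes to FBP without exponentiation.

The MAR chain is the classical inpainting structure: reconstruct,
convert to HU, threshold-segment metal (isolated single pixels removed),
forward-project the mask to a metal trace, discard and linearly
interpolate traced pixels within each view (edge runs extend the nearest
value), reconstruct again, and reinsert the first-pass values at metal
pixels. On metal-free data the mask is empty and the output equals plain
FBP exactly.

Two robustness parameters: the metal threshold defaults to 2500 HU —
below the lowest metal plateau across arms (titanium reconstructs to
≈3300 HU in the 200 keV arm, and band-limited blur pulls much of its
footprint under 3000) yet above every non-metal material (composite
resin peaks near 2200 HU at 100 kV) — and the trace is widened by a
3-channel margin, matching the ~2–3 pixel skirt of the cosine-windowed
PSF, so rays grazing blur-clipped metal rims are covered.

Hounsfield references: the 100 kV arms use the energy-fluence-weighted
effective water attenuation of the 100 kV spectrum; the VMI arms use
water's linear attenuation at the synthesis energy. Both keep gelatine
near 0 HU in their own arm.

The four arms per phantom and noise replicate: (1) plain FBP of the
100 kV scan, (2) FBP of the 200 keV VMI from the 80+120 kV pair, (3) the
MAR chain on the 100 kV scan, (4) the MAR chain on the VMI sinogram.
All four arms of a replicate consume the same noisy measurements,
preserving the paired structure.

## Scoring and statistics

The artifact score of a reconstruction is the mean over four ROIs of
`|mean(ROI) − mean(uniformity ROI)|` in HU, the uniformity reference
being the same arm's reconstruction of an insert-free phantom processed
with the same noise seed. ROIs are 5-pixel-radius discs at ±45°/±135°
around the insert-group centroid, placed just clear of the outermost
insert edge (clearance = ROI radius + 3 px) so they sample the most
artifact-affected neighborhood without touching metal; the placement
rule is automatic for reproducibility and fully overridable. The
uniformity ROI is an 8-pixel disc at the uniformity image center.

Arms are compared with classical paired t-tests on scores paired by
(phantom, replicate), aggregated across all six materials; the pairwise
matrix reports two-sided p-values with a directionality sign ((+) in
cell (X, Y) meaning Y scores lower than X). Significance level 0.01, no
multiple-testing correction (raw pairwise p-values are reported, as is
conventional for this design); eight noise replicates per phantom stand
in for the multiple scored slices of a physical study. Ties between
arms that coincide exactly (e.g. MAR = routine on a metal-free phantom)
report p = 1.

## Problem sizes and runtime

Defaults were chosen so the full study runs on one CPU in minutes:
256×256 phantoms, 360×363 sinograms, three acquisitions and one
decomposition per phantom-replicate, 6 phantoms + 1 uniformity × 8
replicates. The complete four-arm study takes roughly 7–8 minutes; the
closed-form checks run in seconds. The decomposition dominates the
cost; its active-set Gauss–Newton drops converged pixels each
iteration.

## What the simulation shows — and what it does not

Passing tests establish that the pipeline's mathematics is right
(exact round trips, closed-form agreements, contract identities) and
that, under the stated study conditions, the combined VMI+MAR arm
reduces artifact scores significantly below both the routine protocol
and MAR alone, with the full directionality pattern
routine > MAR > VMI-alone-vs-routine and VMI+MAR best of all.

They do not establish performance on real scanners. The simulation has
no scatter, no electronic noise floor, a 2D geometry, homogeneous
gelatine, and ideal spectral knowledge (the solver uses the true
simulation spectrum). Two consequences deserve emphasis. First,
inpainting MAR benefits from the homogeneous background: its residuals
here are smaller than on anatomical data. Second, VMI-alone inherits
photon-starvation damage: behind the densest surrogates (gold alloy,
amalgam) both dual-energy measurements hit the counting floor, the
decomposition saturates at its feasibility box, and the VMI sinogram is
locally wrong. On real systems the scatter floor bounds this
differently. The combined VMI+MAR arm is robust to it by construction —
the corrupted rays lie inside the metal trace that MAR discards — which
is precisely the mechanism the hybrid method exploits.

## Known limitations

- 210° short-scan and fan/cone-beam geometries are recorded in configs
  but not implemented; reconstruction assumes 180° parallel coverage.
- Basis-material representability is exact only for water/iron objects;
  for other materials the decomposition returns the model-defined
  least-squares equivalent, so exactness tests use water/iron phantoms.
- The dental-material compositions are documented surrogates; swapping
  in better compositions is a registry edit, not a code change.
- High-Z fixture tables are ~10% accurate; absolute HU of metal
  plateaus should not be over-interpreted.
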