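# Methods

This note records the models, parameter choices, and numerical decisions
behind `arrayqa`, and what the synthetic test bench does and does not show
about real measurements.

## Array geometry and averaging

The array is modelled as 32×32 chambers at 7.62 mm pitch (configurable),
1-based indices, grid centre at physical (0, 0) mm; column j runs along
cross-line x, row i along in-line y. The physical device lacks its four
corner chambers; `DetectorGrid.device_mask()` provides that mask, while the
default mask is all-true because the correction and gamma chains index the
full 32×32 lattice.

Three dose estimators mirror clinical cross-comparison practice: the
central-detector dose (mean of the 2×2 central block), the off-axis pair
dose (rows 16–17 mean per column), and a 1×1 cm² ROI mean emulating a
0.125 cc thimble-chamber reading. The ROI mean is computed on a bilinear
interpolation of the plane, sampled on a 0.5 mm sub-grid (both
configurable); whether ROI averaging should act on raw chamber values or an
interpolated plane is genuinely open, and the interpolated-plane choice is
flagged here deliberately — on smooth composite distributions the
difference is far below the accuracy bounds tested.

## Correction factors

CF_j(θ) = N_j · D_j^meas(θ)/D_j^ref(θ) on the calibration grid
{0°, 10°, …, 180°} ∪ {90°, …, 110° in 1° steps} (37 angles), with N_j
fixed by CF_j(0°) = 1 — realised as the per-column scalar
N_j = D^ref(0°)/D^meas(0°), the only reading consistent with
normalisation at 0°. The central curve uses the 2×2 central block the
same way.

Decisions where the procedure is underdetermined:

* **Interpolation.** Piecewise-linear in θ on the union grid; exact at
  grid angles. The dense 1° segment is what captures the sharp 90°→92°
  response flip; linear interpolation through a 10° gap there would not.
* **Mirror assumption.** θ > 180° maps to 360° − θ. The synthetic
  response model is mirror-symmetric by construction, so the assumption is
  exact in the test bench; on a real device it is an approximation that a
  well-aligned phantom justifies.
* **Row extent of "entire".** Column CFs are derived from rows 16–17 only
  and broadcast over all 32 rows; per-row tables are deliberately not
  supported (cross-line vs in-line differences are known to be small and
  are outside this model).
* **Angle/energy hygiene.** Frames between calibration angles use
  interpolated CFs; a movie frame must carry its own sensor angle (no
  intra-frame angular spread is modelled). Applying a table to a
  mismatched energy is the caller's responsibility.

Corrected dose divides by CF (reading / CF), per frame, before
accumulation.

## Gamma evaluation

γ(r) = min over evaluated positions e of
√((D_ev(e) − D_ref(r))²/ΔD² + |r − e|²/dta²), reference pixels below the
threshold excluded; a pixel passes when γ ≤ 1 (inclusive — whether
commercial software counts γ = 1 as passing is unknown, so the inclusive
convention is documented here). Both distributions are bilinearly resampled
onto the intersection extent at 1 mm before evaluation.

Numerical choices: normalisation dose defaults to the global maximum of
the reference (local normalisation provided, flagged experimental); the
threshold is applied to the reference distribution; the DTA search is
capped at 3×DTA radius and samples the evaluated distribution bilinearly
at a DTA/10 step (all configurable). Offsets are visited in increasing
distance with early termination once the spatial term alone exceeds the
current worst minimum, which makes the exhaustive search affordable at
1 mm resolution. Reference pixels near the boundary search only the
clipped neighbourhood. The metric is asymmetric in its two arguments;
tests pin the implementation to an exhaustive all-pairs oracle on small
instances and check the criteria-monotonicity of pass rates.

## Synthetic dose model

Ground truth per detector: product of error-function penumbra profiles of
the stated field size at the point's off-axis position in the beam's
rotated frame (σ = 3 mm), × exp(−μ·depth) along the ray from the phantom
entry surface (slab ray-box intersection), × inverse square from a
1000 mm source-axis distance. The phantom is a 34 × 31.4 × 22 cm box with
the detector plane at mid-height. μ defaults to 0.0049 mm⁻¹ (6 MV) and
0.0041 mm⁻¹ (10 MV); μ, SAD, penumbra width and the 100 cGy axis scale are
stand-in defaults, clearly parameterised, not fitted to any machine. The
model's fidelity claims are limited to smoothness and geometry — no
scatter, no couch (the calibration protocol it emulates avoided the couch
by design), no MLC modulation, no heterogeneity.

## Angular response model

The packaged response profiles anchor the central-column curve at unity at
0°, at the reported extrema +6%/−15%/−8% (6 MV) and +4%/−11%/−5% (10 MV)
at 90°/92°/180°, with smooth monotone fill-in between anchors (anchors on
the calibration grid; linear between). Column curves are
R_j(θ) = C(θ)·(1 + w_j·A(θ)) with w_j = (j − 16.5)/15.5 a linear
cross-array ramp and A(θ) an amplitude peaking at 7%/6% near 92° and small
(≤ 2%) elsewhere, reproducing the observed central-vs-off-axis spread
structure. Only the anchored extrema are claimed to match the device;
intermediate values are plausible fill-in. Reading noise is multiplicative
Gaussian, σ = 0.3% per chamber per snapshot, independent across frames —
real chamber noise is also dose-rate- and leakage-structured, which this
does not emulate.

Simulation conditions: static beams are split into 5 frames at 0.2 s per
snapshot; arcs are discretised at 2° per frame (segment midpoints). The
2° default is a discretisation of a continuous delivery, and its adequacy
is a convergence property checked by the arc tests rather than an
assumption.

## What the test bench shows — and does not

Because the simulator generates measurements *with* the same response
family the correction estimates, the noiseless calibration round trip is
exact by construction up to one real effect: on lateral beams the dose is
not symmetric across the central 2×2 block (depth attenuation across
7.62 mm), leaving an O(10⁻⁵) residual in the central curve. Passing
round-trip tests therefore validates the estimator chain (averaging,
normalisation, interpolation, application, accumulation), not the physical
correctness of any particular CF curve. The noisy benchmarks (static
sweeps ≤ 2% central-axis error, six-plan composites ≤ 1.2%) show the
chain holds those bounds under the stated noise; real measurements add
setup error, sensor-angle error, and response drift that the bench does
not contain.

Problem sizes used by the validation studies: 37-angle calibrations per
energy, 19-angle static sweeps × 2 energies, 6 plan geometries × 2
energies (the full arc contributing 175 frames), and gamma at 1 mm on
~237×237 grids — all chosen to exercise the full chain at the study's
own conditions while keeping a complete run in seconds.

## Degenerate inputs and tie-breaks

Doses must be finite and non-negative; reference doses must be positive
wherever a ratio is formed. A CF table must contain 0° and positive CFs
equal to 1 there within 1e−9. Gantry angles are normalised modulo 360°
(with a warning when out of range at CF lookup). In the gamma search,
equidistant equal-γ candidates are resolved by the first-visited (nearest)
offset; NaN samples outside the evaluated grid are ignored via NaN-aware
minima.

## Known limitations

* No per-row (i-indexed) CF variation; no field-size- or depth-dependent
  CFs (one calibration geometry serves all fields).
* No 3D or time-resolved gamma; no film-chain simulation.
* The synthetic dose engine is not commissioned against any TPS; absolute
  dose scales are arbitrary-but-consistent, so only relative statements
  (deviations, pass rates) are meaningful.
* DICOM RT-Dose import handles single-plane extraction with isotropic
  in-plane spacing only.
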