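# Methods

This note records the models behind each stage, the estimator and
parameter choices that were genuinely open, and what the synthetic tests
do and do not establish about real data.

## Coordinate and sign conventions

Images are indexed `[row, col]` with x rightward, y downward; physical
coordinates are µm from the top-left pixel centre. For an expanding
monolayer, x is perpendicular to the moving front and y parallel to it;
the free margin sits on the +x side at `L(t)`, the mean over rows of the
outermost cell-covered position. Traction `t` is the stress the
monolayer exerts **on the substrate**; the monolayer's force balance then
reads `div σ = t`, and with a front pulling rearward the integrated
tension `τ¹ᴰ(x) = ∫_L^x ⟨t_x⟩_y dx′` is non-negative going into the bulk.
Pixel size defaults to 1.294 µm/px so that the 16 px PIV nodal distance
equals a 20.7 µm grid step; the traction grid uses 20.72 µm. (Only the
derived conversions are fixed by the imaging configuration; the pixel
size itself is inferred from them.)

## PIV

Zero-normalised FFT cross-correlation of 32 × 32 px windows at 50%
overlap. The raw linear correlation is normalised by the per-lag overlap
area — without this the taper biases the sub-pixel fit toward zero lag —
and the peak search is limited to |lag| ≤ window/2. Sub-pixel peak
localisation is the 3-point Gaussian fit per axis (parabolic fallback for
non-positive neighbours). A second interrogation pass re-windows the
second frame at the integer lag (discrete window offset); this removes
the loss-of-pairs asymmetry and brings integer-shift errors to the
0.02 px level and uniform sub-pixel RMS errors to ~0.06 px on clean bead
images. Windows are masked invalid when (a) their intensity s.d. is
below 5% of the whole frame's s.d. (no texture — e.g. cell-free
substrate), or (b) the first-to-second correlation peak ratio is below
1.2, with the second peak sought outside a window/8 neighbourhood of the
first (a fixed 3 × 3 exclusion lands on the shoulder of broad peaks).
Invalid vectors are never inpainted. Raw vectors sit at window centres;
cubic splines (scipy `RectBivariateSpline`) resample to the nodal grid,
which coincides with the window centres under the default settings, so
resampling is near-identity there.

## Collectivity

Per frame pair, the lateral velocity component (y when the front moves
along x) has its whole-field mean removed; the double sum defining the
mean runs over all valid nodes, not per column. `C(r)` is averaged over
node pairs separated along the front-parallel axis within the same
front-perpendicular column, with the lag-dependent denominator
`√(⟨u(r′)²⟩⟨u(r′+r)²⟩)` taken over the same contributing pairs — the
literal normalised form, not the global variance. An isotropic all-pairs
variant is available behind `pairs="isotropic"` but is not the default.
The correlation length is the first downward crossing of 0.01, located
by linear interpolation between lags; profiles that never cross are
reported as undefined, never clamped, and excluded (but counted) in
downstream statistics.

On 256-node-long fields (5.3 mm) the median estimate over 50 random
fields is within ~10% of the analytic threshold length for underlying
scales of 30–80 µm; the residual negative bias grows with scale (the
crossing sits where C ≈ 0.01 meets an O(1/√N_eff) noise floor), and the
median's seed-to-seed scatter at 80 µm is a further ±4–5%. On a single
~1 mm field of view the same estimator is much noisier (the C tail's
noise floor exceeds the threshold), which is why per-frame lengths are
aggregated over many time points before comparing groups — with the
unpaired Welch t-test (statistic, Welch–Satterthwaite df, two-sided p).

## Traction force microscopy

The substrate is a homogeneous, incompressible (ν = 0.5, standard for
polyacrylamide), semi-infinite elastic solid of Young's modulus 200 Pa.
Surface displacement and traction are related in Fourier space by the
Boussinesq Green tensor

    Ĝ(k) = 2(1+ν)/(E k³) [ (1−ν)k² + ν k_y²,  −ν k_x k_y ;
                            −ν k_x k_y,        (1−ν)k² + ν k_x² ].

Both directions are computed on a grid zero-padded to twice the field
size; the k = 0 mode (uniform traction, infinite half-space response) is
pinned to zero rather than divided by, which doubles as the no-net-force
constraint. The inverse (FTTC) solves the 2 × 2 per-wavevector system
with zeroth-order Tikhonov regularisation λ (units µm/Pa).

Practical notes, all quantified by the round-trip tests:

- The forward/inverse pair is not exactly mutually inverse because the
  measured displacement is truncated at the field of view; sources whose
  displacement decays within the FOV (zero net force, feature scale
  ≲ 1/4 of the FOV) round-trip to ~6% relative L2 error at λ = 0.
- With white displacement noise of 5% of the peak displacement, plain
  small-λ inversion is useless (noise amplification grows ∝ k); the
  shipped calibration (`calibrate_regularization`) pairs a mild Gaussian
  pre-filter of the displacement field (σ = 1.3 grid nodes by default)
  with a λ chosen by minimising the true error on an internal synthetic
  calibration scene matched to the stated noise level and feature scale.
  With 100 µm features this yields ~18–23% relative error; sharper
  (50 µm) features at the same noise remain substantially worse — an
  intrinsic resolution limit of regularised FTTC at 20.72 µm sampling,
  consistent with published benchmark studies.
- Spectral inversion rings at the field border where the zero padding
  abuts non-decaying displacement; the pipeline drops 2 border nodes of
  the reconstructed traction (`crop_border_nodes`) before any integral
  statistic.

Bead-image displacement uses the same PIV engine against the relaxed
reference image, with optional rigid drift correction (median vector of a
designated cell-free margin subtracted).

## Stress inversion

`A` is the discrete divergence: centred differences in the interior,
first-order one-sided at edges (both exact on linear fields), all three
stress components collocated on the traction grid. The estimate
minimises `‖Aσ′ − t′‖² + Λ‖σ′‖²` in nondimensional variables — traction
scaled by its RMS over valid nodes, lengths by the grid spacing, so Λ is
dimensionless (default 10⁻⁶) — and free-stress conditions `σ·n = 0` are
eliminated exactly (hard constraints) on the designated cell-free edges.
At Λ = 0 the minimum-norm data-consistent solution is computed by LSQR;
a Λ = 0 solve with no constraints at all is refused as ill-posed. The
full posterior covariance of the Bayesian framing is not computed.

Two identifiability facts shape how the inversion is validated and used:

- The force balance leaves σ undetermined up to divergence-free (Airy)
  fields compatible with the boundary conditions, and the ‖σ‖² prior
  resolves the ambiguity toward minimum norm. Accuracy statements
  therefore use truth fields built in the operator's row space
  (`make_stress_field(..., "potential_bumps")`: σ is the symmetric
  gradient of a smooth vector potential, with closed-form divergence).
  On such fields the recovery is essentially exact (componentwise
  Pearson r > 0.999, force-balance residual ~10⁻⁵). Generic stress
  fields with a large null-space component are *not* recoverable by this
  or any traction-only method; their traction is, which is what the
  residual reports.
- With a single constrained edge, a y-invariant load can be carried
  partly by a σxy term growing linearly in y; whether the prior shunts
  force there depends on the distance from the load to the anchoring
  edge relative to the transverse extent. For the island-strip scenario,
  whose monolayer lies entirely inside the field of view and whose
  stress vanishes on every boundary, the faithful configuration frees
  all four edges, which blocks the shunt and recovers the y-averaged σxx
  profile almost exactly. The single-edge default remains appropriate
  when the monolayer extends beyond the field of view on the other
  sides.

## Tension

`y_average` is the per-column mean over valid nodes; `tension_1d`
integrates it by the trapezoidal rule from `L` (signed, so τ(L) = 0 holds
by construction and either side of L is handled); `isotropic_tension` is
`(σxx + σyy)/2`; `bulk_average` keeps nodes strictly farther than 200 µm
from every grid boundary, where boundary conditions and inversion edge
effects are immaterial; time averaging is the mean of per-frame bulk
values. `compare_1d_2d` interpolates `⟨σxx⟩_y` onto the τ¹ᴰ axis and
reports their relative RMS difference over the bulk — on an analytic
x-dependent stress with σxy = 0 the two agree to ~1%, limited only by
the trapezoidal rule at the profile's curvature jumps. Occupancy masks
for front detection come from intensity-variability thresholding (Otsu)
plus morphological closing, or can be supplied externally.

## Junction profiling

Kymographs sample unit-spaced points along a user line by bilinear
interpolation, averaged across a perpendicular band. Cross-section
profiles are recentred so position 0 is the sub-pixel (3-point parabola)
peak of the designated membrane channel — the interface itself is a
reasonable definition of "centre" and is how such profiles are aligned in
practice — then min–max normalised per profile (bounded, comparable
across expression levels) and aggregated as mean ± s.d. Flat profiles
(max = min) are excluded and counted rather than normalised to garbage.

## Synthetic scenes

The generators exist so every estimator can be checked against a known
answer:

- **Beads**: isotropic Gaussians, FWHM equal to the 0.5 µm physical bead
  diameter (σ = 0.5/pixel_size/2.355 px, floored at 1 px), uniform random
  positions, optional white noise. Warping is inverse bilinear sampling,
  so PIV/TFM displacement truth is exact by construction.
- **Velocity fields**: the lateral component is a stationary Gaussian
  random field synthesised by circular convolution with the kernel whose
  autocorrelation equals the target covariance (`sd²·exp(−r²/2ℓ²)` or
  `sd²·exp(−r/ℓ)`), exact up to wraparound; domains ≥ 6ℓ keep the
  wraparound bias small. The analytic threshold-0.01 length (gaussian:
  ℓ√(2 ln 100); exponential: ℓ ln 100) is attached as truth.
- **Stress fields**: constant, linear ramp, Gaussian bumps, row-space
  potential bumps, and the front profile — all with closed-form
  divergence, so discretisation error downstream is attributable to the
  estimators, never to the oracle.
- **Expanding front**: a monolayer strip `x ∈ [x_back, L(t)]`,
  `L(t) = 700 µm + 0.3 µm/min · t`, entirely inside a ~1 mm field of
  view at 5-min frames. Its stress is uniaxial coherent tension
  `σxx = A·f(x)` — the C¹ plateau `f = s((x−x_back)/w)·s((L−x)/w)`,
  `s(u) = u²/(1+u²)`, rising over w = 100 µm to A = 100 Pa·µm (bulk
  isotropic tension ≈ 27 Pa·µm after halving and margin-averaging; the
  tens-of-Pa·µm range reported for junction-coupled epithelia) — plus an
  incoherent field of ~25 µm random traction dipoles scaled to 1.5 Pa
  RMS, giving the couple-of-Pa local traction floor real monolayers show
  while contributing no net tension. The lateral velocity field uses
  ℓ = 55 µm (threshold length ≈ 167 µm, the scale measured for epithelial
  sheets). Substrate displacements are the forward Boussinesq solution of
  the total traction; bead frames are warps of one reference; a dense
  speckle texture advected by the velocity field stands in for the
  phase-contrast movie. A `modulation` parameter can impose a coherent
  front-parallel variation of σxx; it defaults to 0 because expanding
  fronts are approximately y-invariant and the incoherent dipoles already
  supply the cell-scale y-structure.

What the scene does **not** emulate: phase-contrast optics, cell shapes
and rearrangements, temporal evolution of the stress pattern beyond the
front's motion, out-of-plane displacement, and finite gel thickness.
Passing the end-to-end test therefore demonstrates the correctness and
composability of the estimators under realistic magnitudes and noise, not
robustness to every artifact of live imaging.

## Numerical choices and degenerate inputs

Identically-zero fluctuation fields raise an explicit degenerate-field
error (never a silent 0 or 1); empty or full occupancy masks refuse front
detection; a margin that consumes the whole field refuses the bulk
average; zero traction makes the inversion return exactly zero stress and
the residual is then reported absolute and flagged. All generators are
bit-reproducible per seed (`numpy.random.default_rng`). Linear systems:
sparse normal equations via `spsolve` for Λ > 0, LSQR (atol = btol =
10⁻¹²) for the Λ = 0 minimum-norm solution.

## Known limitations

- Regularised FTTC at 20.72 µm sampling cannot reconstruct 50 µm-scale
  traction features to better than ~30–40% under 5%-of-peak displacement
  noise; the calibration helper makes the trade-off explicit rather than
  removing it.
- The stress estimate is a point estimate under an isotropic prior;
  stress components invisible to the traction (null-space content) are
  returned as ~0, and no posterior uncertainty is attached.
- The correlation-length estimator's threshold definition makes single
  field-of-view estimates noisy whenever the true length approaches the
  field size; only aggregates over many frames are meaningful there.
- The 1D tension assumes approximate translation invariance along the
  front; strongly fingered fronts violate it.
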