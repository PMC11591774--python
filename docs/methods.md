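# Methods

## The physical problem and the model

The package analyses the passive spread of an opaque marker out of a
fluid-filled channel (a microvessel mimic, radius R ≈ 0.9 mm including the
soaked perivascular collar) into a surrounding porous hydrogel that stands in
for brain parenchyma. Recordings of such systems show a two-stage spread: an
early flow-like stage followed by ordinary axisymmetric diffusion. Plain
diffusion cannot produce the first stage, and the porous, biphasic hydrogel
both relaxes and traps solute, so the transport model is the telegraph
(Cattaneo) equation extended with a linear sink:

    τ ∂²C/∂t² + ∂C/∂t = D ∇²C − k C

with

- `D` (mm²/s): diffusion coefficient; governs the late, diffusive stage.
  Reference value 4×10⁻⁵ mm²/s.
- `τ` (s): flux relaxation time; for a short period after release the
  concentration front propagates like a wave with speed √(D/τ)
  (6.3×10⁻³ mm/s at the reference values D = 4×10⁻⁵ mm²/s, τ = 1 s).
- `k` (1/s): first-order leakage into the bulk of the sample or trapping in
  pores; reference value 1.5×10⁻⁴ 1/s. Without it the late-time relaxation
  of the central concentration is quantitatively wrong even though the
  two-stage shape survives.

The initial state is a smoothed disk,

    C(r, 0) = (C0/2) (1 + tanh((R² − r²)/s)),

with `s` = 0.44 mm² controlling the sharpness of the edge. The smooth edge is
both physical (the transition layer around the channel is soaked with marker)
and numerically benign. The marker starts at rest: ∂C/∂t(·, 0) = 0. This
initial rate is a modelling choice, stored in the solver state so
alternatives can be tested; the exponential-decomposition check exercises a
non-zero initial rate.

All concentrations are normalized (C0 = 1 at the center at release); the
physical marker concentration is metadata. Lengths are mm, times s, origin at
the spot center.

## Numerical solution

- **Domain/grid**: square of side L = 10 mm (or its radius for the 1-D
  axisymmetric solver), cell-centered equispaced nodes, N = 200 per axis
  (spacing L/N = 0.05 mm). Cell-centering is a convention fixed for
  reproducibility; at this resolution the node-vs-cell distinction is
  invisible in the results.
- **Boundaries**: null-flux (mirror ghost nodes) on all sides. Over 600 s the
  spread stays far from the boundary; doubling L at fixed spacing changes the
  central trace by less than 0.1% (asserted in tests), so the solution is
  effectively the free-plane one.
- **Scheme**: the equation is advanced as the first-order system
  C_t = J, τ J_t = D ∇²C − γ J − k C (γ = 1 except in the decomposition
  check) with a two-level explicit scheme: 5-point Laplacian in 2-D, a
  conservative finite-volume radial Laplacian in 1-D (zero flux through the
  r = 0 face by symmetry, so the discrete mass sum telescopes exactly).
  τ = 0 is an explicit parabolic branch, not a singular limit.
- **Time step**: the stable step is safety × min(wave CFL h/√(D/τ), damping
  bound 2τ, diffusive bound h²/(4D) on the parabolic branch, 1/k), with
  safety 0.4, additionally capped at `dt_max` = 0.5 s so the τ ≈ 1 s
  relaxation transient is temporally resolved even where stability alone
  would allow 0.8 s. Steps shrink to land exactly on save times. The radial
  stepping kernel is numba-compiled; the 2-D kernel is vectorized numpy.
- **Degenerate inputs**: D = τ = k = 0 steps at `dt_max` (nothing moves);
  non-finite values abort with the offending step named; negative
  excursions beyond 10⁻⁶ (discretization undershoot tolerance) abort.

Verification is against independent closed forms rather than a second PDE
code: (i) the central concentration of pure 2-D diffusion from a uniform
disk, C(0,t) = C0(1 − e^{−R²/4Dt}); (ii) the total-mass ODE
τM″ + M′ + kM = 0 (exact under null-flux); (iii) the identity that
e^{+α₁t}·C solves the sink-free telegraph equation with damping 1 − 2τα₁ and
initial rate α₁C(0), where α₁ = (1 − √(1 − 4τk))/(2τ); and (iv) the
radial/Cartesian cross-check of the same axisymmetric problem.

## The crossover diagnostic

The central trace is rescaled as u(t) = −1/ln(1 − C(0,t)/C0). For normal
2-D disk diffusion u = (4D/R²)t exactly, so departure from linearity isolates
the non-diffusive stage. Points where the transform is undefined (C ≥ C0 or
C ≤ 0, e.g. the t = 0 sample of a normed trace) are masked, never imputed.

"Crossover time" needs an operational definition; the one fixed here is:
fit the asymptote by ordinary least squares on t ∈ [300, 600] s of the valid
rescaled points, then take the latest time at which the trace deviates from
that line by more than 5% relative. Both the window and the tolerance are
configurable; the sensitivity of the result to halving/doubling the
tolerance is logged on every run. Least squares (not L1) is used here because
the asymptote is a diagnostic, not the model fit. At the reference
parameters this definition yields a crossover of ≈ 143 s on the N = 200
grid, consistent with the ~150 s two-stage transition the diagnostic is
designed to expose.

## L1 parameter estimation

`(D, τ, k)` are estimated from an observed normed central trace by
minimizing Σᵢ |model(tᵢ) − obsᵢ| — absolute deviations, which are robust to
the heavy-tailed fluctuations of real profile data. The initial condition
(C0, R, s) is held fixed at its configured values: profile-shape fitting is
a separate, earlier step in practice, and coupling it into the transport fit
would blur both.

- Forward model: the 1-D radial solver (the 2-D and radial central traces
  agree to ~4×10⁻⁵ relative at the reference parameters, far below the fit's
  noise floor), with the observation operator (central averaging radius)
  matched to however the observed trace was extracted.
- Search: Nelder–Mead in log₁₀-parameter space from a deterministic
  unscrambled-Halton multi-start lattice (default 8 starts) confined to the
  central 70% of the bounds box, followed by one polish restart from the
  incumbent; out-of-bounds proposals are clipped with a linear penalty.
  No randomness anywhere: identical configurations give bit-identical fits.
- Bounds (log-space): D ∈ [10⁻⁶, 10⁻³] mm²/s, τ ∈ [0.05, 20] s,
  k ∈ [10⁻⁶, 10⁻²] 1/s — the physically plausible decades for solute
  transport in soft hydrogels. An optimum within 10⁻³ of a bound (in
  log-range units) is flagged in the result, as is a constant
  (zero-variation) input trace.
- Identifiability: D and k are strongly identified by the late-time slope
  and overall decay; τ only shapes the first ~100 s and is weakly identified
  at 1 fps sampling. Recovery tests therefore use 0.5 s sampling and accept
  τ to 50% while requiring D and k to 5% (noiseless) / 15% (noise
  σ = 0.005). With noisy data τ routinely collapses to its bound — a
  documented limitation, not a defect.

R² is reported alongside the L1 objective as a familiar goodness-of-fit
summary (it is not the quantity optimized).

## Image quantification chain

For 8-bit grayscale time-lapse stacks (1 frame/s) of a dark spot on a light
background: the background level is the mean grayscale over a spot-free
region (default: four corner boxes, averaged across all frames); every pixel
is subtracted from it, clipping pixels brighter than background to zero so
noise cannot produce negative concentrations; the spot center is the
intensity-weighted centroid of the first inverted frame; the central value
per frame is the mean over the 238 pixels nearest the center (disk-ordered
by radius, ties broken by angle — the count is configurable since the
physical pixel pitch of a given microscope is not fixed here); everything is
normalized by the t = 0 central value. Diametral cross-sections are taken
along the horizontal through the center with ±1-row averaging. The
pseudocolor enhancement for faint structures is
(max(background − pixel, 0)/background)², which lands in [0, 1] by
construction.

The equivalent central-averaging radius pixel_size·√(238/π) is attached to
the extracted trace so that a subsequent fit applies the same observation
operator to its forward model.

## Synthetic data generator

The generator emulates the statistical structure of the recordings, not
their optics: pixel level = clip(round(background − contrast·C + ε), 0, 255)
with ε iid Gaussian (default σ = 1 grayscale level) added before
quantization, background level 200, and a linear concentration-to-darkening
mapping with contrast 150 levels per unit concentration (the spot center
then sits near level 54 — safely inside the dynamic range; a contrast that
clips more than 10% of the spot to level 0 triggers a warning). Frame rate
1 fps, duration 600 s, 8-bit depth. It does **not** model illumination
nonuniformity, spatially correlated detector noise, optical blur, depth
effects in the sample, or the irregular-channel "protuberance" leakage
geometry — so passing round-trip tests demonstrate the correctness of the
quantification chain and the identifiability of the parameters under the
stated noise model, not robustness to every artefact of real microscopy.

Problem sizes: synthetic stacks in the tests and the acceptance script use
0.05 mm/px with 200×200 frames (one pixel per grid node, so the optical
resampling step is exact); the generator itself supports arbitrary pixel
sizes via bilinear resampling of the solution, with 0.01 mm/px as the
nominal default.

## Known limitations

- Constant coefficients only; no heterogeneous or anisotropic transport,
  no 3-D geometry (the analysed process is two-dimensional and axially
  symmetric by construction).
- The complex-root regime 4τk > 1 (oscillatory mass relaxation) is out of
  scope and rejected explicitly.
- First-order explicit time integration: accuracy is driven by the dt cap,
  which the closed-form checks bound at ~10⁻⁴ relative at the default
  settings; a higher-order scheme was not needed at that level.
- The goodness of fit achievable against a *real* recording depends on
  sample heterogeneity the model deliberately averages away; the far tails
  of radial profiles are known to be underestimated by this model class.
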