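# Methods

## The measurement model

A pump–probe transient-absorption experiment measures ΔA(λ, t) in mOD on a
wavelength × delay grid. The package's forward model, shared by the
synthetic-data generator and both analysis methods, is

    ΔA(λ, t) = Σ_k S_k(λ) · c_k(t − t0(λ)) + artifact(λ, t) + noise,

with component spectra S_k, kinetic profiles c_k given by exponential decays
convolved with a Gaussian instrument response function (IRF), a
wavelength-dependent time zero t0(λ) from the chirp of the supercontinuum
probe, and a coherent artifact localized at time zero. Time is picoseconds
everywhere; t = 0 is the IRF center, and negative delays (pre-excitation
baseline) are part of every dataset.

The IRF-convolved exponential has the closed form
c(t) = ½·exp(σ²/2τ² − Δ/τ)·[1 + erf((Δ − σ²/τ)/(σ√2))], Δ = t − t0. It is
evaluated in two branches — the erfcx (scaled complementary error function)
form where the naive exponent overflows (pre-zero delays, τ ≪ σ) and the
plain erfc form past time zero — so it is finite and in [0, 1] for all
arguments. The unit tests pin it against a brute-force numerical convolution
to 10⁻⁶ absolute over σ ∈ [0.02, 0.3] ps and τ ∈ [0.05, 100] ps.

## Synthetic data generator

`synthetic_data.fcc_like_preset` emulates a flavocytochrome pump–probe
measurement at desk scale:

* probe 290–1000 nm at 80 points; delays in 20 fs steps across ±0.5 ps and
  20 points/decade logarithmically to 1 ns (117 delays);
* two parallel kinetic components, defaults 0.4 ps (internal conversion) and
  4.3 ps (vibrational cooling); Gaussian IRF of 0.10 ps FWHM;
* component spectra built from Gaussian bands: the fast component a narrow
  ~410 nm ground-state bleach with an adjacent ~420 nm excited-state
  absorption and a broad ~700 nm positive band; the slow component a 410/420
  negative/positive pair plus a weaker 525/550/575 negative/positive/positive
  hot-ground-state structure;
* a cubic-polynomial chirp t0(λ) spanning roughly −0.08 to +0.10 ps across
  the probe window; a Gaussian coherent artifact at t0(λ) (1 mOD amplitude,
  0.05 ps FWHM); additive homoscedastic Gaussian noise whose SD is quoted as
  a fraction (default 2%) of the clean signal peak |ΔA|.

All randomness flows from one integer seed through a single generator
instance per call, so every dataset is bit-reproducible. Fluorescence decays
are Poisson-sampled from IRF-convolved multiexponential expectations scaled
to a stated total count.

What the generator does **not** emulate: heteroscedastic or correlated
detector noise, pump scatter and solvent Raman lines, anisotropy (the
emulated experiment is at magic angle), wavelength-calibration error, and
scan-to-scan drift. Passing tests therefore demonstrate correctness of the
inference chain under the stated statistical model, not robustness to every
instrument pathology.

## Preprocessing

Chirp is estimated per wavelength as the delay of maximum |d(ΔA)/dt| inside
the IRF window (parabolic sub-step refinement), followed by a least-squares
cubic in normalized wavelength. Markers are weighted by their slope
amplitude so signal-free wavelengths, whose markers are pure noise, barely
influence the curve; the correction is consequently only meaningful where
the sample absorbs, and closure tests evaluate it there. The symmetric
coherent artifact can bias individual markers by a fraction of its width
(~1 time step); the bias is smooth in wavelength and mostly absorbed by the
polynomial. Correction shifts every column by −t0(λ) with linear
interpolation, filling out-of-range cells with the column's pre-zero mean.

Noise is estimated per wavelength from the pre-excitation rows (t < −2 IRF
widths, sample SD, floored at 10⁻⁶ mOD) of the **raw** matrix, before chirp
interpolation: interpolation low-passes the noise and would bias the SD low,
which in turn distorts every χ² downstream.

## Maximum-entropy lifetime distribution analysis

The lifetime grid is log-uniform, by default 0.02–1000 ps at 20 points per
decade (95 points). The design matrix convolves each exponential with the
Gaussian IRF — the grid's shortest lifetimes are far below the IRF width and
would otherwise be pure artifact — and, by default, carries two extra
"coherent artifact" columns (a unit-peak Gaussian at t0 and its first
derivative, the standard cross-phase-modulation model). Without those
columns the artifact masquerades as sub-0.1 ps amplitude, leaks into the
fast component, and flattens the l-curve corner.

Per wavelength, the objective is χ² plus α times the signed-amplitude
(Skilling) entropy R(a) = Σ_j [a_j asinh(a_j/2m) − √(a_j² + 4m²) + 2m],
which is ≥ 0, uniquely minimized at a = 0, quadratic (a²/4m) near zero and
|a| log|a|-like far from it. The zero scale m defaults to 1% of the
column's peak |ΔA| (floored at 10⁻⁹ mOD for empty columns). The problem is
smooth and strictly convex, so each wavelength is solved by a damped Newton
iteration with analytic gradient (asinh(a/2m)) and Hessian
(χ² normal matrix + diag(α/√(a²+4m²))) and an Armijo line search;
convergence is declared at relative Q change < 10⁻¹⁰ or gradient ∞-norm
< 10⁻⁸·max(1, Q), with a 5000-iteration cap per wavelength. Scans are run
from large α down with warm starts.

**Regularization selection.** The α scan (default 25 values over 6 decades)
is centered using the entropy's ridge limit: an SVD ridge solve locates the
weight where the whitened misfit has grown by one χ² unit per data point
above its floor, converted to the entropy scale via α = 4mλ/σ². The corner
is the maximum of the discrete (three-point, parameterization-invariant)
curvature of (log χ², log R); monotonicity of χ²(α) and R(α) along the scan
is verified and violations raise a warning, not an error.

**Components.** D(τ) = √Σ_λ a(λ,τ)². Peaks are local maxima above the
0.15 ps floor with prominence ≥ 5% of max D; a component's window is the
contiguous D ≥ half-peak region clipped at the valley minimum between
neighboring peaks and at the floor. The reported component lifetime is the
D-weighted mean of log τ over the window — on synthetic ground truth this
estimator is unbiased where the raw grid argmax of a regularized
(smeared) map sits systematically high. The grid argmax is kept as
`mode_lifetime`. Because the l-curve corner is flat over a factor of a few
in α, a weak component occasionally smooths into a shoulder exactly at the
selected map; the pipeline therefore also accepts a component that is
detected in **every** scanned map within the decade below the corner
(window taken from the map closest to the corner). DADS are the map summed
over each window.

## Global kinetic analysis

Variable projection: for trial (τ₁…τ_n, t0, IRF width) the DADS are the
exact weighted linear least-squares solution per wavelength, and only the
nonlinear parameters are iterated (lmfit/trust-region least squares;
lifetimes log-parameterized and bounded to [10⁻³, 10⁴] ps). The same
coherent-artifact columns join the linear basis, with their own fitted width
— the artifact is generally narrower than the pump–probe cross-correlation,
and forcing one width produced a compromise that biased the fast lifetime
by up to ~10%. Lifetimes whose ratio collapses below 1.05 trigger a warning
and an automatic refit with n − 1 components.

The component count is chosen by SVD of the noise-whitened matrix: singular
values above the Marchenko–Pastur bulk edge σ̂(√m + √n), with a Tracy–Widom
finite-size allowance at the 1% level and σ̂ estimated by rescaling the
median singular value to the median of the pure-noise law. On preprocessed
matrices that genuinely contain artifact and residual-chirp structure the
rank exceeds the kinetic component count; the rule is exact on
kinetics-only matrices.

Sequential model 1 → 2 → … → n: species populations are analytic
partial-fraction combinations of the convolved exponentials
(c_l = Σ_{j≤l} b_jl conv(k_j)); duplicate rates are an error, not a limit.
EADS solve the triangular system DADS_j = Σ_l b_jl EADS_l exactly, which
enforces the sum rule EADS₁ = Σ DADS and reproduces the identical fitted
surface (checked to 10⁻⁹ relative). Species fractions normalize the
populations row-wise, dropping delays whose total population is below
10⁻¹², i.e. before and long after the pump.

## Fluorescence reconvolution

Model: background + Σ amp_i · (IRF ⊗ exp(−t/τ_i)), with the Gaussian closed
form for an analytic IRF or discrete convolution on an oversampled uniform
grid (plus a fitted sub-bin shift) for a measured IRF trace. Weights are
1/max(counts, 1), the standard Poisson choice that avoids zero-count
singularities. Amplitudes are constrained nonnegative and reported as
fractions summing to one. Multiexponential reconvolution has a local
minimum where lifetimes coalesce; if the first fit lands there (or fails),
the fitter restarts from displaced initial lifetimes and keeps the best
converged solution. Components with lifetime strictly below the IRF FWHM
are flagged `within_irf`: their amplitude is real but their timescale is
not resolvable.

## Numerical and scale choices

* Problem sizes: the default synthetic matrix is 117 delays × 80
  wavelengths with a 95-point lifetime grid and a 25-point α scan; a full
  LDA pipeline runs in a few seconds and the whole test suite in about two
  minutes on one CPU. These sizes were chosen as the smallest that leave
  the two kinetic components clearly resolvable at 2% noise.
* All file I/O is plain CSV or HDF5 with explicit unit-bearing names
  (delays_ps, wavelengths_nm, delta_A_mOD); readers convert from seconds
  when declared and sort axes, rejecting duplicates.
* Degenerate inputs fail loudly: duplicate sequential rates, empty spectral
  slices or lifetime windows, all-zero fluorescence counts, missing
  pre-zero baselines.

## Known limitations

* Per-wavelength independent entropy fits: no spectral smoothness coupling,
  so the density map is noisier along λ than glotaran-style penalized maps.
* The l-curve corner on maximum-entropy trajectories is soft; the
  sub-corner persistence rule compensates for merged shoulders but a
  component weaker than the noise floor of D(τ) is simply not found.
* The sequential scheme is linear and irreversible; no branching, no back
  reactions, no error propagation to EADS.
* The chirp polynomial is only constrained where the sample absorbs;
  extrapolation to signal-free spectral edges is unreliable.
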