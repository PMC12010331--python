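# taglobal

Global and lifetime-distribution analysis of ultrafast transient-absorption
(TA) and time-resolved fluorescence data.

Femtosecond pump–probe spectroscopy of photoactive proteins (heme and flavin
enzymes, photoreceptors) produces a differential-absorbance surface
ΔA(λ, t): a broadband supercontinuum probe (here 290–1000 nm) sampled in
20 fs steps through the instrument-response window and logarithmically out
to ~1 ns. Extracting the few kinetic components buried in such a surface —
for a flavocytochrome-type system, a sub-picosecond internal conversion of
the excited heme and a few-picosecond vibrational cooling of the hot ground
state — requires a chain of corrections and two complementary inverse
methods. This package implements that chain end to end, together with a
synthetic-data generator that emulates the measurement, so every stage is
testable without instrument data.

## Methods

**Lifetime distribution analysis (LDA).** A regularized inverse Laplace
transform: amplitudes a(λ, τ) on a fixed log-spaced lifetime grid (default
0.02–1000 ps, 20 points/decade) minimize, per wavelength,

    Q(a) = Σ_t [(ΔA_t − Σ_j M_tj a_j)/σ_λ]² + α Σ_j [a_j asinh(a_j/2m) − √(a_j²+4m²) + 2m]

where M holds Gaussian-IRF-convolved exponentials and the second term is the
signed-amplitude (Skilling) entropy with zero-scale m. The weight α is set
by the l-curve criterion (corner of maximum curvature of log χ² vs log
penalty). The dynamical content D(τ) = √Σ_λ a(λ,τ)² condenses the map into
one curve; its peak centers above a 0.15 ps floor are the kinetic
components, and decay-associated difference spectra (DADS) are the map
summed over each component's lifetime window.

**Global kinetic analysis (GKA).** A parametric cross-check: n exponentials
convolved with a fitted Gaussian IRF, solved by variable projection (the
DADS are the exact linear solution at every step; only log-lifetimes, t0 and
the IRF width are iterated). The component count comes from SVD of the
noise-whitened matrix. A sequential irreversible scheme 1 → 2 → … → n
converts DADS to evolution-associated difference spectra (EADS) and species
fractions; the first EADS equals the sum of all DADS exactly.

**Supporting stages.** Supercontinuum chirp estimation/correction,
solvent-background subtraction, logarithmic time averaging, baseline noise
estimation, and reconvolution fitting of fluorescence decays
(upconversion/TCSPC style, Poisson weights, within-IRF flagging of
unresolvable components).

The convolution kernel used everywhere is the closed form

    c(t) = ½ exp(σ²/2τ² − Δ/τ) [1 + erf((Δ − σ²/τ)/σ√2)],  Δ = t − t0,

evaluated through erfcx for numerical stability.

## Worked example

Simulate the flavocytochrome-like preset (two parallel components at 0.4 and
4.3 ps, 0.10 ps IRF, supercontinuum chirp, coherent artifact, 2% noise) and
run both analyses:

```python
import numpy as np
from taglobal import synthetic_data as sd, pipelines
from taglobal.core_io import AnalysisConfig

spec = sd.fcc_like_preset(lifetimes=(0.4, 4.3), seed=1)
matrix = sd.simulate_ta(spec, sd.default_wavelengths(), sd.default_delays())

cfg = AnalysisConfig()
lda = pipelines.lda_pipeline(matrix, cfg)
for w in pipelines.top_component_windows(lda, 2):
    print(f"component: {w.peak_lifetime:.3f} ps  (window {w.lo:.3f}-{w.hi:.2f} ps)")

gka = pipelines.gka_pipeline(matrix, cfg, n=2, init_lifetimes=[0.2, 8.0])
print("GKA lifetimes:", np.round(gka["lifetimes"], 3), "ps")
print("fitted IRF FWHM:", round(gka["fit"].irf.fwhm, 3), "ps")
```

prints

```
component: 0.405 ps  (window 0.178-0.89 ps)
component: 4.417 ps  (window 1.781-11.23 ps)
GKA lifetimes: [0.404 4.54 ] ps
fitted IRF FWHM: 0.105 ps
```

Both methods recover the generating lifetimes: the LDA dynamical-content
peak centers sit within one grid step (12%) of 0.4 and 4.3 ps, the global
fit lands within a few percent, and the fitted IRF width matches the 0.10 ps
cross-correlation of the simulation. The same chain is available from the
shell: `taglobal simulate|preprocess|lda|gka|fluorfit --in ... --out ...`.

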