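# Methods

## Model

Each site of a periodic `L × L` lattice holds `n_E` excitatory and `n_I`
inhibitory two-state neurons.  An active neuron deactivates at rate
α (default 0.1 ms⁻¹); a quiescent neuron activates at rate
`f(s) = β tanh(s)` for `s > 0` and 0 otherwise, with gain β = 1 ms⁻¹ (the
gain is named `beta_gain` throughout; `beta_psd` always means the spectral
exponent — the two are never conflated).  The input `s` is a weighted sum
of presynaptic activity plus an external drive h.  Per-neuron weights
depend only on the presynaptic type and on the Euclidean minimum-image
distance r between sites:

    w(e)(r) =  (w̃₀₀ + w̃ₛ₀) / (2 N_E) · g(r)
    w(i)(r) =  (w̃₀₀ − w̃ₛ₀) / (2 N_I) · g(r)

with radial factor `g(r) = exp(−r/λ)` (default), `min(1, r^−ω)`, or 1
(fully connected), and normalizations `N_E, N_I` chosen so the signed
weights incoming to any neuron sum to `w̃₀₀` and the absolute ones to
`w̃ₛ₀`.  These two k = 0 anchors fix the internal sign convention: the
package stores *signed* per-site weights (inhibitory entries negative), so
the transform of the signed kernel is `w̃₀,ₖ` and that of the absolute
kernel `w̃ₛ,ₖ`; both are verified to reproduce the anchors to 10⁻¹⁰.
Aggregated per site (sites are internally fully connected and homogeneous),
the kernel acts on the active fractions, and the per-neuron counts cancel
out of the weights.

Defaults follow the critical reference configuration: `w̃₀₀ = 0.1`,
`w̃ₛ₀ = 13.8`, `h = 10⁻⁸`, `n_E = n_I = 10⁸` per site, bin width
δ = 1 ms.  The critical point of the transcritical bifurcation is
`w̃₀₀ = α/β`, `h = 0`; `h = 10⁻⁸` keeps the k = 0 relaxation time finite
(≈ 1.6×10⁴ ms) while sitting effectively at criticality.

## Linear (large-N) theory

A system-size expansion about the homogeneous fixed point
`αΣ₀ = (1−Σ₀) f(w̃₀₀Σ₀ + h)` yields, per wave vector
`k = (2π/L)(k_x, k_y)`, a two-variable linear Langevin system with

    τ₁,ₖ⁻¹ = α + f(s₀) − (1−Σ₀) f′(s₀) w̃₀,ₖ        (slow)
    τ₂⁻¹   = α + f(s₀)                              (fast, k-independent)
    w̃ff,ₖ = (1−Σ₀) f′(s₀) w̃ₛ,ₖ                     (feed-forward)

and noise intensity `αΣ₀`.  `f′` is the analytic derivative
`β(1−tanh²s)`, with the right derivative β taken at s = 0 so the critical
condition `α = β w̃₀₀` is exact.  The autocorrelation of the
active-fraction fluctuation is the mode sum of
`A₁,ₖ e^{−t/τ₁,ₖ} + A₂,ₖ e^{−t/τ₂}`; the power spectrum is implemented
through the per-mode Ornstein–Uhlenbeck transfer function

    P_k(f) = (αΣ₀/2) · (1 + w̃ff,ₖ²/(ω² + τ₂⁻²)) / (ω² + τ₁,ₖ⁻²),  ω = 2πf,

which is algebraically identical to the `A₁/A₂` Lorentzian pair but stays
finite at modes where `τ₁,ₖ` crosses `τ₂` (the amplitude split has a
`1/(τ₁²−τ₂²)` pole there; the autocorrelation path nudges `τ₁` by 10⁻⁶
relative in that measure-zero case).  The equal-time sum `A₁+A₂` is
validated against an independent Lyapunov-equation solve, and the spectrum
against a numerical cosine transform of the autocorrelation
(Wiener–Khinchin, 10⁻⁶ relative).

Since the observable plotted and simulated is the **firing rate**
`R = (1−Σ) f(s)`, the package also provides its linear-theory spectrum:
`δR_k = u_k ξ_Σ,k + w̃ff,ₖ ξ_Δ,k` with `u_k = α − τ₁,ₖ⁻¹`, assembled from
the exact transfer functions including the Σ–Δ cross term.

**Frequency conventions.** Rates are ms⁻¹ internally; reported spectra use
Hz (×1000).  `f_min = L⁻²D₀` and `f_max = λ⁻²D₀` are *relaxation-rate*
scales; the corresponding spectral knees in cyclic frequency sit at
`f/(2π)`.  Analytic slope fits therefore use the knee band
`[f_min/2π, f_max/2π]`: across that band the firing-rate spectrum of the
L = 100, λ = 1 critical configuration has log-log slope −1.0 (pink noise).
Fitting the active-fraction spectrum literally across `[f_min, f_max]`
instead gives ≈ −1.6, because above the τ₂ knee the slow and fast f⁻²
tails nearly cancel: their difference produces a transient slope ≈ 4
region, and the true f⁻² asymptote re-emerges only about two decades
higher.  For the same reason the fully-connected β = 2 band is fitted
*between* the two knees, `[10/(2πτ₁), 0.1/(2πτ₂)]`.

`D₀` is evaluated from the closed-form/quadrature radial integral of the
**untruncated** continuum kernel.  On the lattice, `τ₁,ₖ⁻¹/|k|² → D₀`
holds within 5 % only for λ ≳ 2 lattice spacings and an untruncated
kernel; at λ = 1 lattice discreteness contributes ≈ 6 % and the default
3λ simulation cutoff lowers the effective diffusion constant by ≈ 45 %.
This is a property of the discretization, not of the theory; the 1/f band
itself is insensitive to it.

The dimension-dependent asymptotics `P(f) ~ f^{(d−4)/2}` (log-decay at
d = 4, white above) are exposed both as the closed-form exponent and as a
band-integral evaluation `f^{(d−4)/2} ∫ x^{(2−d)/2}/(1+x²) dx` computed in
log space.  In d = 3 the x^{−1/2} edge corrections decay slowly, so the
0.5 slope is verified on a wide band (`f_max/f_min = 10⁶`, central two
decades); a 10⁴-wide band only reaches ≈ 0.56.

## Langevin simulation

Euler–Maruyama with drift and diffusion evaluated at the pre-step state;
the square-root argument `αx + (1−x)f(s)` is clamped at 0 and the updated
fractions clipped to [0, 1] — standard regularizations of multiplicative
√rate noise that vanish as n → ∞.  Default step `dt = 0.01` ms
(α·dt = 10⁻³); the 2D desk preset uses `dt = 0.05` ms for tractability.
Both sit well inside the enforced bound `dt ≤ 0.1/(α+β)` and are validated
by a weak-convergence check: halving dt changes the stationary mean and
variance of the rate trace by < 1 %.  Convolution of the kernel with the
activity fields is a direct truncated-offset sum in the compiled path and
an FFT circular convolution in the numpy path; the two agree to 10⁻¹⁰.

Runs start at the fixed point, discard a transient, then per δ-bin
integrate the per-site firing rate and draw the bin's spike count from a
Poisson law with mean `(n_E+n_I) ∫ R dt`.  Spike emission is an observable
only — it never feeds back on the state.  One seeded generator per run;
per-run seeds derive from the master seed by numpy `SeedSequence` state
(recorded in the manifest, kept below 2³¹).

## Avalanche and spectral analysis

Avalanches are per-site maximal runs of bins with ≥ 1 spike; runs touching
either trace boundary are censored and discarded (their size and duration
are unknowable; at protocol run lengths the bias is negligible, but see
limitations).  All sites are pooled.  Distribution exponents use a
continuous truncated-power-law MLE with *explicit* bounds [lo, hi]
(log-normalizer computed stably through a = 1; standard error from the
observed Fisher information); `⟨S⟩(T)` uses exact durations up to 100 bins
and log-binned durations above, and γ is a log-log least-squares slope
over an explicit window — matching how such curves, not joint likelihoods,
are fitted in practice.  Sliding-window exponents (windows `[T, 10T]` for
γ, `[0.1f, f]` for β) diagnose scaling plateaus.  Welch spectra (Hann,
50 % overlap, mean removed per segment, Parseval-normalized within 1 %)
are computed per site on the binned firing-rate traces and averaged over
sites and runs.

The module's principal oracle is a synthetic crackling generator: durations
drawn from a truncated `T^−τ` law, parabolic excursion profiles scaled as
`V = A T^{γ−1} g(t/T)` with optional Poisson bin noise floored at one
spike, so the size exponent `α = 1 + (τ−1)/γ` and the shape-collapse
family are planted exactly.  Extraction plus fitting round-trips τ, γ, α
within stated tolerances, and the collapse error is minimized at the
planted γ.

## Presets and the desk-scale protocol

Full-scale presets encode the reference protocols (fully connected: 60 runs of
3.5×10⁷ ms discarding 10⁷; 2D L = 40, λ = 1: 60 runs of 2.5×10⁵ ms
discarding 4×10⁴; 80/20 variants with `n_E = 1.6×10⁸`, `n_I = 4×10⁷`).
The desk presets used by the test suite are reduced once-chosen protocols:

* `fc_critical_desk` — 5 runs × 10⁶ ms, discard 10⁵ (scaled from the full
  protocol's discard fraction), dt = 0.01 ms.
* `d2_critical_desk` — L = 20, 5 runs × 5×10⁴ ms, discard 10⁴,
  dt = 0.05 ms.

Desk-scale runs shrink the avalanche cutoffs by roughly a decade relative
to the L = 40 full protocol, so the pinned fit windows (chosen once from
sliding-window plateau diagnostics on a calibration dataset whose seeds
differ from any analysis seed) are: durations [10², 10³] ms for both
topologies; sizes [6×10⁵, 6×10⁷] (fully connected; the image of the
duration window under ⟨S⟩(T)) and [10⁵, 2×10⁶] (2D; between the
exponent-≈1 small-avalanche regime and the cutoff bend); γ windows
[10², 10³] ms (fully connected) and [10³, 10⁴] ms (2D ⟨S⟩(T) plateau);
spectral bands [1, 10] Hz and [0.1, 1] Hz.  Exponent expectations carry
±0.1 tolerances at this scale (the full protocols quote ±0.01–0.02).

## What the synthetic data do and do not show

The generator-based tests validate the estimators (extraction, MLE, γ
fits, collapse) on data with known exponents; the Langevin tests validate
the simulator against the linear theory in its domain of validity.  Neither
implies that desk-scale simulations resolve the asymptotic critical
exponents with full-scale precision: the 2D desk protocol in particular
has a duration cutoff within a decade of its scaling window, and its
spectral slope in [0.1, 1] Hz lands near 1.1 rather than 1.0 — a
finite-size/finite-length effect that shrinks with L and run length.
Avalanche censoring at trace boundaries also steepens the extreme tail of
P(T) when runs are short.

## Known limitations

* The Gaussian-noise Langevin description is the model definition here; no
  exact event-driven (Gillespie) simulation of the underlying Markov chain
  is provided.
* Only the transcritical bifurcation at k = 0 is treated; no Hopf or
  oscillatory regimes, and no finite-N corrections to the linear theory.
* d ≠ 2 is supported in the continuum quantities (`D₀`, asymptotic
  exponents), not in lattice mode sums.
* The per-site aggregated homogeneous kernel is the only topology — no
  quenched randomness or neuron-level adjacency.
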