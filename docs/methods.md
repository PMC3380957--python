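# Methods

## The models

A presynaptic neuron fires a spike train x(t) = Σ_j δ(t − t_j) and makes
n synaptic contacts onto a postsynaptic cell, each holding at most one
release-ready vesicle. v(t) ∈ {0, …, n} counts the available vesicles.

**Stochastic model.** At each spike every available vesicle is released
independently with probability p_r, so the number released is
k_j ~ Binomial(v(t_j⁻), p_r); the pool is decremented directly after the
spike (Itô order: the mark is drawn from the pre-spike pool). Each empty
contact refills after an independent exponential waiting time with mean
τ_d. The simulator (`synapse.simulate_stochastic`) is event-driven and
exact: binomial draws at spike times, a heap of exponential recovery
clocks in between; no time-stepping error. The grid enters only when a
trajectory or conductance is sampled.

**Deterministic (trial-average) model.** The standard depressing-synapse
simplification replaces the random increments by their conditional
means: v becomes continuous, k_j = p_r v(t_j⁻), v(t_j⁺) = (1 − p_r) v(t_j⁻),
and v relaxes as n + (v₀ − n) e^{−Δ/τ_d} between spikes. For a *frozen*
input the conditional mean of the stochastic model obeys exactly the same
recursion (the dynamics are linear in v), so the deterministic trace
equals the infinite-trial average of the stochastic model — the property
`trial_average_conductance` verifies empirically.

The release train z(t) = Σ_j k_j δ(t − t_j) drives the conductance
g = z ∗ α with α(t) = Θ(t) e^{−t/τ_s}/τ_s. α is normalized to unit area,
which fixes the conductance unit so that mean conductance = mean release
rate (one "unit" = one vesicle per second); this is the reading we adopt
of the usual rescaling of single-vesicle response amplitude.

## Closed-form spectral theory

For homogeneous Poisson input at rate r the first moments close exactly:

    v̄ = n β,   β = 1/(1 + p_r r τ_d),   τ_eff = τ_d β,
    release rate = mean conductance = p_r r v̄,
    gain ν(r) = d(mean g)/dr = p_r n β².

Second moments use a diffusion approximation of the stochastic model:
recovery noise with intensity σ_r² = p_r r v̄ (the Poisson recovery flux)
and release noise σ_p² = p_r(1 − p_r) v̄ (the binomial variance with v
replaced by its stationary mean). The deterministic model is the same
system with σ_r² = σ_p² = 0 — its remaining variability comes solely from
the Poisson input acting on the depression dynamics. The stationary
second moment is

    ⟨v²⟩ = (2 n v̄/τ_d + σ_r² + r σ_p²) / (2/τ_d + p_r r (2 − p_r)).

A regression argument gives the release auto-covariance as a delta plus
a two-sided exponential with timescale τ_eff,
C_zz(τ) = C₀ δ(τ) + C₁ e^{−|τ|/τ_eff}, with

    C₀ = r (p_r² ⟨v²⟩ + σ_p²),
    C₁ = r² p_r (p_r(1 − p_r) ⟨v²⟩ − σ_p² − p_r v̄²),

and the input→release cross-covariance as a delta plus a *one-sided*
exponential. All spectra are evaluated analytically in ordinary
frequency f (ω = 2πf, transform kernel e^{−iωτ}); with u = ωτ_eff:

    A(f)      = p_r v̄ (β + iu)/(1 + iu)        (high-pass depression kernel)
    α̂(f)      = 1/(1 + iωτ_s)                  (low-pass conductance kernel)
    S_xx      = r
    S_xg      = α̂ A r
    S_zz      = C₀ + 2 C₁ τ_eff/(1 + u²),   S_gg = |α̂|² S_zz.

A(f) rises from A(0) = ν(r) (the gain — slow input fluctuations are
cancelled by pool depletion) to the plateau p_r v̄ (the mean release per
spike — fast fluctuations outrun the pool). |S_xg| is therefore
band-pass, peaking between 1/(2πτ_eff) and 1/(2πτ_s).

**Coherence.** We use the magnitude-squared coherence
C = |S_xg|²/(S_xx S_gg) ∈ [0, 1], the form required by the
Gaussian-channel information bound below. The kernel |α̂|² cancels, and
for the deterministic model an exact algebraic identity
(S_zz ∝ |A|²) makes the coherence *flat*:

    C_det = v̄²/⟨v²⟩_det = 1 − (p_r/2)(1 − β),

independent of frequency — the deterministic filter reshapes the signal
but loses no frequency selectively. The stochastic model's intrinsic
noise (C₁ < 0 in the depressed regime, so S_zz rises with f while
|A|² rises too) yields a high-pass coherence that is nearly zero at low
frequency when p_r r τ_d ≫ 1: over long windows the number of vesicles
released is set by recovery events, not by input spikes. Its
zero-frequency release power approaches n/τ_d (n independent
Poisson-like recovery streams), while the deterministic model's
approaches zero.

The noise decomposition reported by `noise_intensities` writes
S_zz = |A|²(S_xx + Γ₀) + Γ_r(f) + Γ_p(f) with the constant
Γ₀ = r(⟨v²⟩_det − v̄²)/v̄² (input–depression interaction, the only term
surviving in the deterministic model) and Γ_r, Γ_p the exact σ_r²- and
σ_p²-proportional parts of the (affine) dependence of S_zz on the two
intensities.

**Populations.** For n_pop inputs with pairwise shared-spike fraction c
(common-train construction: one common Poisson train of rate c·r plus
independent trains of rate (1−c)·r), the bivariate pool moment is
M = (2n v̄/τ_d)/(2/τ_d + p_r r(2 − c p_r)) and the cross-release spectrum

    S_zizj = c r p_r² M + 2 τ_eff r² p_r² (M(1 − c p_r) − v̄²)/(1 + u²),

identical for the two models (intrinsic noise is independent across
synapses). Population spectra follow by bilinearity. Two exact limits:
at c = 0 the population coherence equals the single-synapse coherence
for every n_pop; for c > 0 and n_pop → ∞ both models' coherences
converge to c|A|²r/S_zizj, so the stochastic/deterministic distinction
washes out only at large *correlated* populations (within 1% by
n_pop = 10⁴ at c = 0.1).

**Rate-coded signals.** A shared zero-mean Gaussian signal s(t) with
two-sided spectrum S_ss(f) = A_s[e^{−(f−f₀)²/2σ_s²} + e^{−(f+f₀)²/2σ_s²}]
modulates every input rate: conditional intensity max(r + s(t), 0), a
doubly stochastic (Cox) Poisson process with S_xx = r + S_ss. For
A_s ≪ r² the synapse is linearized about the Poisson operating point:
ẑ_i = A x̂_i + intrinsic noise, with noise auto-/cross-spectra fixed by
the exact Poisson-input solution (so the formulas reduce to the Poisson
case at A_s = 0). The signal→conductance coherence at n_pop = 1 is

    C_sg = S_ss / (S_ss + r/C_det)                    (deterministic)
    C_sg = S_ss / (S_ss + r + Γ_stoch(f)/|A(f)|²)     (stochastic)

— the deterministic curve depends on the signal's spectrum only through
S_ss and is therefore exactly invariant under shifts of the central
frequency, while the stochastic one improves with f₀ because the
intrinsic noise referred to the input, Γ/|A|², falls with frequency.

**Linear information rate.** The Gaussian-channel lower bound
I = −∫₀^∞ log₂(1 − C(f)) df (bits/s) is integrated by trapezoid over
the positive-frequency grid (default 0–100 Hz at 0.01 Hz, resolving the
0.1 Hz-wide signal bumps; the integrand is negligible beyond the band).
Coherence exactly 1 raises a divergence error.

## Estimators

Spectra are estimated by Welch's method: 20 s Hann segments at 50%
overlap (0.05 Hz resolution — resolving the ~1.8 Hz depression corner),
per-segment mean removal (the theory describes fluctuation spectra),
density scaling without one-sided doubling. Spike trains are binned to
counts/dt at the conductance grid step (floor binning) so all series
share one grid. Standard errors come from a delete-one-segment
jackknife, inflated by Welch's overlap-correlation factor
√(1 + 2 c_ov (n_s−1)/n_s) with c_ov = [Σ w_t w_{t+step}]²/[Σ w_t²]²
(1/9 for Hann at 50%); the jackknife also bias-corrects the nonlinear
coherence statistic, whose raw small-sample floor 1/n_segments is
reported and subtracted before empirical information rates are
integrated. Agreement between theory and estimate is scored as the
fraction of frequency bins whose confidence interval covers the closed
form (pass at ≥ 90%); auto-spectra are compared on the log scale
(delta method) because symmetric intervals on chi-square-distributed
periodogram averages under-cover, and complex cross-spectra are checked
on real and imaginary parts with a Bonferroni-split z.

## Numerical choices

- Default grid dt = 1 ms (requires τ_s ≥ 5 dt); 500 s default runs.
- The discrete conductance kernel uses exponential point samples
  convolved with a two-tap [½, ½] filter and renormalized to exact unit
  discrete area: a sampled exponential is self-similar, so its transfer
  function otherwise leads the continuum α̂ by half a grid step, which
  would bias estimated cross-spectral phases by ωdt/2.
- Cox trains are generated by thinning at r_max = r + max(s, 0) with
  nearest-bin intensity lookup; negative intensities are rectified to
  zero (bias second order in A_s/r²; < 1% at the defaults).
- Signals are synthesized in the frequency domain (complex Gaussian
  coefficients scaled to the target spectrum, inverse FFT), so traces
  are periodic over their duration and hit the spectrum exactly at grid
  resolution.
- Shared spikes in correlated populations are kept exactly coincident;
  the delta mass at zero lag in the pairwise cross-covariance requires
  exact synchrony.
- Event times are kept exact internally; binning happens only at
  spectral estimation and conductance rendering.

## Default parameters

| name | meaning | default |
|---|---|---|
| n_sites | contacts per connection | 5 |
| p_release | release probability | 0.5 |
| tau_rec | vesicle recovery time | 0.7 s |
| tau_syn | conductance decay (AMPA-like) | 5 ms |
| rate | presynaptic Poisson rate | 20 Hz |
| correlation | pairwise shared-spike fraction | 0.1 |
| bandwidth | signal spectral width | 0.1 Hz |
| peak_power | signal spectral peak | 20 Hz |

This operating point is deep in the depressed regime
(p_r r τ_d = 7 ≫ 1): v̄ = 0.625 of 5 sites, τ_eff = 87.5 ms,
C_det = 0.78125, stochastic coherence 0.007 → 0.237 across 0.1–50 Hz.
The values follow measurements reported for cortical
pyramidal-to-pyramidal synapses (recovery ~0.5–0.8 s, release
probability ~0.5, 4–12 contacts). With these defaults the correlated
population's conductance power spectrum has its interior band-pass peak
near 8 Hz; the peak moves into the beta band (15–30 Hz) for faster
conductance kernels (τ_s ≈ 1–2 ms), so its placement — unlike its
existence — is parameter-dependent.

## What the synthetic data does and does not emulate

Inputs are (doubly stochastic) Poisson processes with at most
shared-spike correlations and a Gaussian rate signal. Real spike trains
show refractoriness, bursting and non-Poisson renewal structure, which
interact with depression in ways these generators deliberately do not
reproduce; passing tests therefore validate the *models and their
spectral theory*, not the claim that cortical inputs are Poisson.
Likewise out of scope: facilitation, use-dependent or calcium-dependent
recovery, multivesicular release per site, receptor
saturation/desensitization, heterogeneous synapse parameters within a
population, postsynaptic spiking, and Shannon (as opposed to coherence
lower-bound) information.

## Known limitations

- Stochastic-model second moments rest on the diffusion approximation
  with σ's evaluated at the stationary mean; it is excellent at the
  defaults (simulated spectra cover the closed forms at ~94% of bins)
  but its zero-frequency release power runs a few percent below the
  exact value at moderate depletion (0.92 n/τ_d at p r τ = 35, 0.99 at
  105).
- The linearized signal theory requires A_s ≪ r²; a warning is issued
  when A_s ≥ 0.1 r².
- Jackknife intervals treat overlapped segments as exchangeable; after
  the overlap correction, empirical pointwise coverage is ~93–95%
  rather than exactly nominal.
- Problem sizes in tests and the acceptance script (500 s runs, 2000
  trials, 3× pooled runs for window-count variances) were chosen so
  Monte-Carlo error sits well inside each tolerance band while a full
  run completes in seconds on one CPU.
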