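"""Closed-form theory of synaptic filtering by vesicle depletion.

All quantities follow from a diffusion approximation of the stochastic
vesicle model driven by Poisson input at rate r (Hz).  Writing p for the
release probability, n for the number of sites, tau_d for the recovery
time and

    beta    = 1 / (1 + p r tau_d)
    v_mean  = n beta                       (steady-state pool)
    tau_eff = tau_d beta                   (depression relaxation time)

the release train z(t) has auto-covariance C0 delta(tau) +
C1 exp(-|tau|/tau_eff), the input->release cross-covariance is a delta
plus a one-sided exponential, and in ordinary frequency f (Hz, with
u = 2 pi f tau_eff):

    A(f)      = p v_mean (beta + i u) / (1 + i u)       high-pass depression kernel
    alpha_hat = 1 / (1 + i 2 pi f tau_syn)              low-pass conductance kernel
    S_xz      = A(f) r
    S_zz      = C0 + 2 C1 tau_eff / (1 + u^2)
    S_xg      = alpha_hat A r,   S_gg = |alpha_hat|^2 S_zz

The deterministic (trial-average) model is the same structure with the
two intrinsic noise intensities sigma_r^2 (recovery) and sigma_p^2
(release) set to zero; its magnitude-squared coherence
|S_xg|^2/(S_xx S_gg) = v_mean^2 / <v^2> is exactly flat in f, while the
stochastic model's is high-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SignalSpec, SynapseParams

__all__ = ["SteadyStateMoments", "NoiseIntensities", "SpectralCurves",
           "steady_state", "gain", "depression_kernel", "noise_intensities",
           "single_synapse_spectra", "population_spectra",
           "signal_transfer_spectra", "linear_information_rate"]

_MODELS = ("stochastic", "deterministic")


def _check_model(model: str) -> str:
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
    return model


@dataclass(frozen=True)
class SteadyStateMoments:
    """Stationary first and second moments of the vesicle pool."""

    v_mean: float
    v_second: float
    tau_eff: float
    g_mean: float
    release_rate: float


@dataclass(frozen=True)
class NoiseIntensities:
    """Noise intensities entering the release-train power spectrum.

    ``D_input`` is the constant Gamma_0 produced by Poisson input acting
    on the deterministic depression dynamics (the only noise source of
    the deterministic model); ``D_recovery`` = sigma_r^2 and
    ``D_release`` = sigma_p^2 are the intrinsic intensities of stochastic
    recovery and probabilistic release, zero for the deterministic
    model.  ``covariance_coeffs`` holds the delta-mass area C0, the
    exponential amplitude C1 and tau_eff of the release auto-covariance.
    """

    D_input: float
    D_recovery: float
    D_release: float
    covariance_coeffs: dict


@dataclass(frozen=True)
class SpectralCurves:
    """Theoretical spectra on a positive-frequency grid (Hz).

    One-sided storage without doubling; coherence is magnitude-squared,
    |S_xg|^2 / (S_xx S_gg), invariant to the one/two-sided choice.
    """

    freq: np.ndarray
    S_xx: np.ndarray
    S_xg: np.ndarray
    S_gg: np.ndarray
    coherence: np.ndarray
    A: np.ndarray
    alpha_hat: np.ndarray
    S_ss: np.ndarray | None = None
    S_sg: np.ndarray | None = None
    coherence_signal: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        """Export as a pandas DataFrame (CSV-ready)."""
        import pandas as pd

        cols = {"f": self.freq, "Sxx": self.S_xx, "ReSxg": self.S_xg.real,
                "ImSxg": self.S_xg.imag, "Sgg": self.S_gg,
                "coherence": self.coherence}
        if self.S_ss is not None:
            cols["Sss"] = self.S_ss
            cols["ReSsg"] = self.S_sg.real
            cols["ImSsg"] = self.S_sg.imag
            cols["coherence_signal"] = self.coherence_signal
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# scalar moments

def _moments(params: SynapseParams, rate: float, model: str):
    """Core scalar quantities shared by every spectral formula."""
    n, p, tau = params.n_sites, params.p_release, params.tau_rec
    beta = 1.0 / (1.0 + p * rate * tau)
    v_mean = n * beta
    tau_eff = tau * beta
    if model == "stochastic":
        sig_r2 = p * rate * v_mean            # Poisson recovery flux
        sig_p2 = p * (1.0 - p) * v_mean       # binomial release variance
    else:
        sig_r2 = sig_p2 = 0.0
    denom = 2.0 / tau + p * rate * (2.0 - p)
    v_second = (2.0 * n * v_mean / tau + sig_r2 + rate * sig_p2) / denom
    return beta, v_mean, tau_eff, sig_r2, sig_p2, v_second


def steady_state(params: SynapseParams, rate: float,
                 model: str = "stochastic") -> SteadyStateMoments:
    """Stationary moments of v(t) and the mean release rate/conductance.

    The mean v_mean = n / (1 + p r tau_d) and relaxation time tau_eff
    are shared by both models; the second moment differs (larger for the
    stochastic model).  Mean conductance equals the mean release rate
    p r v_mean because the conductance kernel has unit area.
    """
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    _check_model(model)
    _, v_mean, tau_eff, _, _, v_second = _moments(params, rate, model)
    release_rate = params.p_release * rate * v_mean
    return SteadyStateMoments(v_mean=v_mean, v_second=v_second,
                              tau_eff=tau_eff, g_mean=release_rate,
                              release_rate=release_rate)


def gain(params: SynapseParams, rate: float) -> float:
    """Derivative of the steady-state mean conductance w.r.t. rate.

    nu(r) = p n / (1 + p tau_d r)^2, equal to A(0) — the zero-frequency
    limit of the depression kernel.  Decays like 1/r^2 once the synapse
    saturates.
    """
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    n, p, tau = params.n_sites, params.p_release, params.tau_rec
    return p * n / (1.0 + p * tau * rate) ** 2


def depression_kernel(params: SynapseParams, rate: float, freq) -> np.ndarray:
    """High-pass linear kernel A(f) of short-term depression.

    |A| rises from the gain A(0) = p n beta^2 to the high-frequency
    plateau p v_mean (the mean vesicles released per spike): slow input
    fluctuations are cancelled by pool depletion, fast ones pass through
    before the pool can track them.
    """
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    beta, v_mean, tau_eff, _, _, _ = _moments(params, rate, "stochastic")
    u = 2.0 * np.pi * np.asarray(freq, dtype=float) * tau_eff
    return params.p_release * v_mean * (beta + 1j * u) / (1.0 + 1j * u)


def noise_intensities(params: SynapseParams, rate: float,
                      model: str = "stochastic") -> NoiseIntensities:
    """Noise intensities and release auto-covariance coefficients.

    The release power spectrum decomposes as
    S_zz = |A|^2 (S_xx + Gamma_0) + Gamma_r(f) + Gamma_p(f), where the
    constant Gamma_0 = r (<v^2>_det - v_mean^2) / v_mean^2 survives in
    the deterministic model and Gamma_r/Gamma_p are proportional to
    ``D_recovery``/``D_release``.
    """
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    _check_model(model)
    p = params.p_release
    _, v_mean, tau_eff, sig_r2, sig_p2, v_second = _moments(params, rate, model)
    _, _, _, _, _, v2_det = _moments(params, rate, "deterministic")
    gamma0 = rate * (v2_det - v_mean**2) / v_mean**2 if v_mean > 0 else 0.0
    c0 = rate * (p**2 * v_second + sig_p2)
    c1 = rate**2 * p * (p * (1.0 - p) * v_second - sig_p2 - p * v_mean**2)
    return NoiseIntensities(
        D_input=gamma0, D_recovery=sig_r2, D_release=sig_p2,
        covariance_coeffs={"delta_area": c0, "exp_amplitude": c1,
                           "tau_eff": tau_eff})


# ---------------------------------------------------------------------------
# spectra

def _release_spectrum(params: SynapseParams, rate: float, freq, model: str):
    """S_zz(f) of a single synapse and the kernel A(f)."""
    p = params.p_release
    beta, v_mean, tau_eff, _, sig_p2, v_second = _moments(params, rate, model)
    f = np.asarray(freq, dtype=float)
    u = 2.0 * np.pi * f * tau_eff
    lorentz = 2.0 * tau_eff / (1.0 + u**2)
    c0 = rate * (p**2 * v_second + sig_p2)
    c1 = rate**2 * p * (p * (1.0 - p) * v_second - sig_p2 - p * v_mean**2)
    s_zz = c0 + c1 * lorentz
    a = p * v_mean * (beta + 1j * u) / (1.0 + 1j * u)
    return s_zz, a


def _pair_release_cross_spectrum(params: SynapseParams, rate: float,
                                 correlation: float, freq) -> np.ndarray:
    """S_{z_i z_j}(f) between two synapses sharing a fraction c of spikes.

    Identical for the two models: intrinsic release/recovery noise is
    independent across synapses, so only the shared spikes correlate the
    release trains.  The bivariate pool moment is
    M = (2 n v_mean / tau_d) / (2/tau_d + p r (2 - c p)).
    """
    n, p, tau = params.n_sites, params.p_release, params.tau_rec
    c = correlation
    _, v_mean, tau_eff, _, _, _ = _moments(params, rate, "stochastic")
    m = (2.0 * n * v_mean / tau) / (2.0 / tau + p * rate * (2.0 - c * p))
    u = 2.0 * np.pi * np.asarray(freq, dtype=float) * tau_eff
    lorentz = 2.0 * tau_eff / (1.0 + u**2)
    return (c * rate * p**2 * m
            + rate**2 * p**2 * (m * (1.0 - c * p) - v_mean**2) * lorentz)


def _alpha_hat(params: SynapseParams, freq) -> np.ndarray:
    w = 2.0 * np.pi * np.asarray(freq, dtype=float) * params.kernel.tau_syn
    return 1.0 / (1.0 + 1j * w)


def single_synapse_spectra(params: SynapseParams, rate: float, freq,
                           model: str = "stochastic") -> SpectralCurves:
    """Theoretical S_xx, S_xg, S_gg and coherence for one Poisson-driven synapse.

    The cross-spectrum S_xg = alpha_hat A r is identical for the two
    models; the stochastic model's S_gg is larger at every frequency, so
    its coherence is smaller — flat for the deterministic model,
    high-pass for the stochastic one.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    _check_model(model)
    f = np.asarray(freq, dtype=float)
    s_zz, a = _release_spectrum(params, rate, f, model)
    ahat = _alpha_hat(params, f)
    s_xx = np.full_like(f, float(rate))
    s_xg = ahat * a * rate
    s_gg = np.abs(ahat) ** 2 * s_zz
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(s_zz > 0, np.abs(a) ** 2 * rate / s_zz, 0.0)
    return SpectralCurves(freq=f, S_xx=s_xx, S_xg=s_xg, S_gg=s_gg,
                          coherence=coh, A=a, alpha_hat=ahat,
                          meta={"model": model, "rate": rate, "n": 1,
                                "correlation": 0.0})


def signal_transfer_spectra(params: SynapseParams, rate: float,
                            spec: SignalSpec | None, correlation: float,
                            n: int, freq, model: str = "stochastic",
                            ) -> SpectralCurves:
    """Linearized population spectra with a shared rate-coded signal.

    Each of the ``n`` presynaptic trains is a doubly stochastic Poisson
    process with intensity rate + s(t) (shared signal s with spectrum
    S_ss) and pairwise shared-spike fraction ``correlation``.  The
    synaptic response is linearized around the Poisson operating point:
    z_i = A * x_i + intrinsic noise, with the noise auto-/cross-spectra
    fixed by the exact Poisson-input solution.  Valid for
    peak_power << rate^2; with peak_power = 0 this reduces exactly to
    the population (and, at n=1, single-synapse) formulas.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if not 0.0 <= correlation <= 1.0:
        raise ValueError(f"correlation must lie in [0, 1], got {correlation}")
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    _check_model(model)
    f = np.asarray(freq, dtype=float)
    if spec is not None and spec.peak_power > 0 and spec.peak_power >= 0.1 * rate**2:
        import warnings

        warnings.warn(
            "signal peak power is not small relative to rate^2; the "
            "linearized spectra may be inaccurate", stacklevel=2)
    s_ss = spec.spectrum(f) if spec is not None else np.zeros_like(f)
    s_zz, a = _release_spectrum(params, rate, f, model)
    ahat = _alpha_hat(params, f)
    a2 = np.abs(a) ** 2
    gamma_auto = s_zz - a2 * rate                 # intrinsic noise, one synapse
    npairs = n * (n - 1)
    if npairs:
        s_zizj = _pair_release_cross_spectrum(params, rate, correlation, f)
        gamma_cross = s_zizj - a2 * correlation * rate
    else:
        gamma_cross = np.zeros_like(f)
    # population sums X = sum x_i, Z = sum z_i, G = alpha * Z
    s_xx = n * (rate + s_ss) + npairs * (correlation * rate + s_ss)
    s_xz = a * s_xx
    s_zz_pop = (n * (a2 * (rate + s_ss) + gamma_auto)
                + npairs * (a2 * (correlation * rate + s_ss) + gamma_cross))
    s_xg = ahat * s_xz
    s_gg = np.abs(ahat) ** 2 * s_zz_pop
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(s_zz_pop > 0, a2 * s_xx / s_zz_pop, 0.0)
        coh_sig = np.where(s_zz_pop > 0, n**2 * a2 * s_ss / s_zz_pop, 0.0)
    s_sg = n * ahat * a * s_ss
    return SpectralCurves(freq=f, S_xx=s_xx, S_xg=s_xg, S_gg=s_gg,
                          coherence=coh, A=a, alpha_hat=ahat, S_ss=s_ss,
                          S_sg=s_sg, coherence_signal=coh_sig,
                          meta={"model": model, "rate": rate, "n": n,
                                "correlation": correlation})


def population_spectra(params: SynapseParams, rate: float, correlation: float,
                       n: int, freq, model: str = "stochastic") -> SpectralCurves:
    """Spectra of total input and total conductance for n correlated synapses.

    Equivalent to :func:`signal_transfer_spectra` without a signal; at
    n = 1 it reduces to :func:`single_synapse_spectra`, and at c = 0 the
    population coherence equals the single-synapse coherence for any n.
    """
    return signal_transfer_spectra(params, rate, None, correlation, n, freq,
                                   model=model)


def linear_information_rate(freq, coherence) -> float:
    """Lower-bound information rate −∫ log2(1 − C(f)) df in bits/s.

    Integrates over the supplied positive-frequency grid (trapezoid
    rule); the Gaussian-channel bound requires the magnitude-squared
    coherence C in [0, 1).
    """
    f = np.asarray(freq, dtype=float)
    c = np.asarray(coherence, dtype=float)
    if f.shape != c.shape:
        raise ValueError("freq and coherence must have equal shape")
    if np.any(c < -1e-12):
        raise ValueError("coherence must be nonnegative")
    if np.any(c >= 1.0):
        raise ValueError("coherence reaches 1: information rate diverges")
    c = np.clip(c, 0.0, None)
    return float(np.trapezoid(-np.log2(1.0 - c), f))
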