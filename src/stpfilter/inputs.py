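"""Presynaptic input generators.

Homogeneous Poisson trains, correlated Poisson populations built by the
shared-spike (common train) construction, Gaussian-spectrum rate-coded
signals synthesized in the frequency domain, and doubly stochastic (Cox)
Poisson trains whose intensity is rate + s(t), rectified at zero.
"""

from __future__ import annotations

import numpy as np

from .params import SignalSpec
from .trains import PopulationInput, SignalTrace, SpikeTrain

__all__ = ["simulate_poisson", "simulate_correlated_population",
           "synthesize_signal", "simulate_doubly_stochastic"]


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _poisson_times(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def simulate_poisson(rate: float, duration: float, seed=None) -> SpikeTrain:
    """Homogeneous Poisson spike train.

    Parameters
    ----------
    rate : float
        Event rate (Hz), >= 0.
    duration : float
        Simulated time T (s), > 0.
    seed : int, Generator or None
        Source of randomness; a fixed integer gives bit-reproducible times.
    """
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    return SpikeTrain(times=_poisson_times(rate, duration, _rng(seed)),
                      duration=duration)


def simulate_correlated_population(rate: float, correlation: float, n: int,
                                   duration: float, seed=None) -> PopulationInput:
    """Population of Poisson trains with pairwise shared-spike fraction c.

    Each train is the union of one common Poisson train of rate c*rate
    (copied into every member) and an independent train of rate
    (1 - c)*rate.  Marginals are exactly Poisson(rate) and the pairwise
    long-window spike-count correlation equals c; coincident shared
    spikes are kept exactly synchronous.
    """
    if not 0.0 <= correlation <= 1.0:
        raise ValueError(f"correlation must lie in [0, 1], got {correlation}")
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    rng = _rng(seed)
    common = _poisson_times(correlation * rate, duration, rng)
    trains = []
    for _ in range(n):
        own = _poisson_times((1.0 - correlation) * rate, duration, rng)
        trains.append(SpikeTrain(times=np.sort(np.concatenate([common, own])),
                                 duration=duration))
    return PopulationInput(trains=tuple(trains), rate=rate, correlation=correlation)


def synthesize_signal(spec: SignalSpec, duration: float, dt: float,
                      seed=None) -> SignalTrace:
    """Stationary Gaussian signal with the Gaussian-bump power spectrum.

    Synthesis is by frequency-domain sampling: independent complex
    Gaussian Fourier coefficients are scaled so the expected periodogram
    equals the target two-sided spectrum, then inverse transformed.  The
    trace is circular (periodic over ``duration``) and hits the target
    spectrum exactly at grid resolution.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    nyquist = 0.5 / dt
    if spec.central_frequency >= nyquist:
        raise ValueError(
            f"dt={dt} too coarse: central frequency {spec.central_frequency} Hz "
            f"is at or beyond the Nyquist frequency {nyquist} Hz")
    n = int(round(duration / dt))
    if n < 2:
        raise ValueError("duration must cover at least two grid steps")
    if spec.peak_power == 0.0:
        return SignalTrace(values=np.zeros(n), dt=dt, duration=duration)
    rng = _rng(seed)
    freq = np.fft.rfftfreq(n, dt)
    s_two_sided = spec.spectrum(freq)
    # E|C_k|^2 = n * S(f_k) / dt makes the periodogram unbiased for S.
    coef = np.empty(freq.size, dtype=complex)
    scale = np.sqrt(n * s_two_sided / dt)
    inner = slice(1, -1) if n % 2 == 0 else slice(1, None)
    m = coef[inner].size
    coef[inner] = scale[inner] / np.sqrt(2.0) * (rng.standard_normal(m)
                                                 + 1j * rng.standard_normal(m))
    coef[0] = scale[0] * rng.standard_normal()
    if n % 2 == 0:
        coef[-1] = scale[-1] * rng.standard_normal()
    values = np.fft.irfft(coef, n=n)
    return SignalTrace(values=values, dt=dt, duration=duration)


def simulate_doubly_stochastic(rate: float, signal: SignalTrace,
                               seed=None, duration: float | None = None) -> SpikeTrain:
    """Cox (doubly stochastic) Poisson train with intensity max(rate + s(t), 0).

    Implemented by thinning: a homogeneous train at rate
    ``rate + max(s)`` is generated and each event kept with probability
    ``intensity(t) / r_max``, with the intensity read from the signal
    grid by nearest-bin lookup.  Negative instantaneous rates are
    rectified to zero, as appropriate for a rate-coded signal whose
    fluctuations are small relative to the baseline rate.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if duration is None:
        duration = signal.duration
    if duration > signal.duration + 1e-12:
        raise ValueError("signal grid is shorter than the requested duration")
    rng = _rng(seed)
    intensity = np.maximum(rate + signal.values, 0.0)
    r_max = float(intensity.max())
    if r_max == 0.0:
        return SpikeTrain(times=np.empty(0), duration=duration)
    candidates = _poisson_times(r_max, duration, rng)
    idx = np.clip(np.round(candidates / signal.dt).astype(int), 0,
                  intensity.size - 1)
    keep = rng.uniform(size=candidates.size) < intensity[idx] / r_max
    return SpikeTrain(times=candidates[keep], duration=duration)
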