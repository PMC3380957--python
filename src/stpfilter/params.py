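"""Parameter containers for the depressing-synapse model.

The synapse is described by four numbers: the number of release sites
(functional contacts) ``n_sites``, the per-site release probability
``p_release``, the mean vesicle recovery time ``tau_rec`` and the decay
time constant ``tau_syn`` of the postsynaptic conductance kernel.
Defaults mirror a cortical pyramidal-to-pyramidal operating point and are
stored in ``data/defaults.toml``; every value can be overridden.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources

__all__ = ["KernelSpec", "SynapseParams", "SignalSpec", "default_params",
           "default_signal", "default_input"]


@dataclass(frozen=True)
class KernelSpec:
    """One-sided exponential conductance kernel, normalized to unit area.

    alpha(t) = H(t) * exp(-t / tau_syn) / tau_syn

    With unit area the mean conductance equals the mean vesicle release
    rate, which fixes the conductance units ("one vesicle per second").
    """

    tau_syn: float = 0.005

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError(f"tau_syn must be positive, got {self.tau_syn}")


@dataclass(frozen=True)
class SynapseParams:
    """Release-site count, release probability and recovery timescale."""

    n_sites: int = 5
    p_release: float = 0.5
    tau_rec: float = 0.7
    kernel: KernelSpec = field(default_factory=KernelSpec)

    def __post_init__(self) -> None:
        if int(self.n_sites) != self.n_sites or self.n_sites < 1:
            raise ValueError(f"n_sites must be a positive integer, got {self.n_sites}")
        if not 0.0 <= self.p_release <= 1.0:
            raise ValueError(f"p_release must lie in [0, 1], got {self.p_release}")
        if self.tau_rec <= 0:
            raise ValueError(f"tau_rec must be positive, got {self.tau_rec}")

    def with_(self, **kw) -> "SynapseParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kw)


@dataclass(frozen=True)
class SignalSpec:
    """Gaussian-spectrum rate-coded signal.

    The signal s(t) is a stationary Gaussian process with zero mean and
    two-sided power spectrum

        S_ss(f) = peak_power * [ exp(-(f - f0)^2 / (2 bw^2))
                               + exp(-(f + f0)^2 / (2 bw^2)) ]

    with ``f0 = central_frequency`` and ``bw = bandwidth`` in Hz.  For
    f0 >> bw the (one-sided, undoubled) spectrum peaks at ``peak_power``,
    whose units are Hz (power density of a rate, Hz^2/Hz).
    """

    bandwidth: float = 0.1
    central_frequency: float = 5.0
    peak_power: float = 20.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be positive, got {self.bandwidth}")
        if self.peak_power < 0:
            raise ValueError(f"peak_power must be nonnegative, got {self.peak_power}")
        if self.central_frequency < 0:
            raise ValueError("central_frequency must be nonnegative")
        if self.mean != 0.0:
            raise ValueError("signal bias is fixed to zero in this model")

    def spectrum(self, freq) -> "object":
        """Two-sided power spectrum evaluated on a frequency grid (Hz)."""
        import numpy as np

        f = np.asarray(freq, dtype=float)
        a, f0, bw = self.peak_power, self.central_frequency, self.bandwidth
        return a * (np.exp(-((f - f0) ** 2) / (2 * bw**2))
                    + np.exp(-((f + f0) ** 2) / (2 * bw**2)))

    def variance(self) -> float:
        """Integral of the two-sided spectrum over the whole real line."""
        import math

        return 2.0 * self.peak_power * self.bandwidth * math.sqrt(2.0 * math.pi)


def _load_defaults() -> dict:
    with resources.files("stpfilter.data").joinpath("defaults.toml").open("rb") as fh:
        return tomllib.load(fh)


def default_params(**overrides) -> SynapseParams:
    """Packaged default synapse parameters, optionally overridden."""
    cfg = _load_defaults()["synapse"]
    kw = dict(n_sites=int(cfg["n_sites"]), p_release=cfg["p_release"],
              tau_rec=cfg["tau_rec"], kernel=KernelSpec(cfg["tau_syn"]))
    kernel_tau = overrides.pop("tau_syn", None)
    kw.update(overrides)
    if kernel_tau is not None:
        kw["kernel"] = KernelSpec(kernel_tau)
    return SynapseParams(**kw)


def default_signal(**overrides) -> SignalSpec:
    """Packaged default rate-coded signal specification."""
    cfg = _load_defaults()["signal"]
    kw = dict(bandwidth=cfg["bandwidth"],
              central_frequency=cfg["central_frequency"],
              peak_power=cfg["peak_power"])
    kw.update(overrides)
    return SignalSpec(**kw)


def default_input() -> dict:
    """Packaged default input-side parameters (rate, correlation)."""
    return dict(_load_defaults()["input"])
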