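# stpfilter

**Short-term synaptic depression as a frequency-dependent filter on
synaptic information transfer.**

Synapses communicate spikes by releasing neurotransmitter vesicles, and
a released vesicle takes hundreds of milliseconds to be replaced. This
depletion produces short-term depression, and it is usually modelled
*deterministically*: a fraction p_r of the vesicle pool v is released
per spike and the pool relaxes to n with time constant τ_d. The
deterministic model is exactly the trial average of the underlying
*stochastic* process — binomial release from an integer pool, exponential
single-vesicle recovery — but it discards the trial-to-trial variability
that vesicle dynamics add.

`stpfilter` implements both models and the closed-form spectral theory
of the filter they impose between a presynaptic spike train x(t) and the
postsynaptic conductance g(t) = Σ_j k_j α(t − t_j):

- cross-spectrum S_xg(f) = α̂(f) A(f) S_xx(f), where A(f) is a high-pass
  depression kernel (slow input fluctuations are cancelled by pool
  depletion) and α̂(f) the low-pass conductance kernel — identical for
  both models;
- power spectrum S_gg(f), larger for the stochastic model by intrinsic
  release/recovery noise terms;
- magnitude-squared coherence C(f) = |S_xg|²/(S_xx S_gg): **exactly flat
  in f for the deterministic model, high-pass and much smaller for the
  stochastic model** — stochastic vesicle dynamics suppress slowly
  encoded information far more than fast;
- the linear (Gaussian-channel) information rate
  I = −∫ log₂(1 − C(f)) df for rate-coded Gaussian signals carried by
  doubly stochastic Poisson inputs;
- generalizations to populations of correlated inputs (shared-spike
  construction), where the model distinction survives unless the
  population is both large and correlated.

Every closed form is cross-validated against event-driven simulation
through Welch/jackknife spectral estimators, which are part of the
package (`estimate`), together with input generators (`inputs`),
synapse simulators (`synapse`), theory (`theory`), and experiment
recipes with a CLI (`experiments`, `stpfilter`).

## Worked example

```python
import numpy as np
from stpfilter import (default_params, simulate_poisson, simulate_stochastic,
                       steady_state, single_synapse_spectra, SignalSpec,
                       signal_transfer_spectra, linear_information_rate)

params = default_params()              # 5 sites, p_r=0.5, tau_d=0.7 s, tau_s=5 ms
ss = steady_state(params, rate=20.0)
print(ss.v_mean, ss.release_rate, ss.tau_eff)

train = simulate_poisson(rate=20.0, duration=500.0, seed=1)
release, traj = simulate_stochastic(params, train, seed=2)
print(traj.values.mean(), release.release_rate)

freq = np.array([0.1, 1.0, 10.0, 50.0])
for model in ("deterministic", "stochastic"):
    print(model, single_synapse_spectra(params, 20.0, freq, model).coherence)

f = np.arange(0.0, 100.0, 0.01) + 0.005
for fc in (1.0, 45.0):
    spec = SignalSpec(bandwidth=0.1, central_frequency=fc, peak_power=20.0)
    for model in ("deterministic", "stochastic"):
        th = signal_transfer_spectra(params, 20.0, spec, 0.0, 1, f, model)
        print(fc, model, linear_information_rate(f, th.coherence_signal))
```

prints (values from an actual run):

```
steady state: v_mean = 0.625 vesicles, release rate = 6.25 vesicles/s, tau_eff = 87.5 ms
simulation:   mean(v) = 0.638, release rate = 6.39 vesicles/s over 500 s
deterministic coherence at [ 0.1  1.  10.  50. ] Hz -> [0.781 0.781 0.781 0.781]
   stochastic coherence at [ 0.1  1.  10.  50. ] Hz -> [0.007 0.084 0.232 0.237]
signal at    1 Hz: info rate (bits/s): det 0.2268, sto 0.0294
signal at   45 Hz: info rate (bits/s): det 0.2268, sto 0.0792
```

Reading: at 20 Hz drive the pool holds 0.625 of 5 vesicles on average
and the 500 s simulation reproduces the closed forms to ~2%. The
deterministic model transfers every frequency with coherence 0.78; the
stochastic model transfers 0.1 Hz fluctuations with coherence 0.007 —
slowly encoded signals are almost erased — rising to 0.24 at 50 Hz.
Accordingly a narrowband signal at 45 Hz carries 2.7× more linear
information through the stochastic synapse than the same signal at
1 Hz, while the deterministic model is exactly indifferent (0.2268
bits/s at both).

## Command line

```bash
stpfilter theory --rate 20 --model stochastic --out curves.csv
stpfilter simulate --rate 20 --duration 100 --model stochastic --out run/
stpfilter experiment single-coherence --out results/
stpfilter fixtures --seed 0 --out fixtures/
```

Experiments (`mean-curves`, `single-coherence`, `param-sweep`,
`signal-transfer`, `population`) emit CSV tables, JSON metadata with
the seed, and machine-readable theory-vs-simulation agreement reports;
configs are TOML/JSON with CLI overrides.

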