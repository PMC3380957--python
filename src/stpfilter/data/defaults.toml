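# Default synapse and input parameters (cortical pyramidal-to-pyramidal
# operating point; see docs/methods.md for sources and units).

[synapse]
n_sites = 5        # functional contacts, each holding at most one vesicle
p_release = 0.5    # per-contact release probability given availability
tau_rec = 0.7      # mean vesicle recovery time (s)
tau_syn = 0.005    # conductance decay time constant (s), AMPA-like

[input]
rate = 20.0        # presynaptic Poisson rate r_e (Hz)
correlation = 0.1  # pairwise shared-spike fraction c

[signal]
bandwidth = 0.1        # spectral width of the rate-coded signal (Hz)
central_frequency = 5.0  # default bump location (Hz); swept in experiments
peak_power = 20.0      # spectral peak height (Hz)
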