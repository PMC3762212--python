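{
 "seed": 1,
 "generate": {"timepoints": [null, 50.0, 300.0, 1000.0], "n_synapses": 10},
 "fits": ["docked_recovery", "paired_pulse", "pit_decay"],
 "mixture_n": 200
}
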