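{
 "seed": 0,
 "generate": null,
 "input_paths": [],
 "fits": [],
 "mixture_n": null,
 "budget": {
  "300ms": {"timepoint": 300.0, "n_synapses": 22, "release_low": 6, "release_high": 7,
            "observed_dp_large_vesicles": 14, "departure_fraction": 0.47,
            "n_aj_structures": 29, "aj_area_mode": "stated_constant", "aj_rounding": "none"},
  "1s": {"timepoint": 1000.0, "n_synapses": 23, "release_low": 6, "release_high": 7,
         "observed_dp_large_vesicles": 25, "departure_fraction": 0.50,
         "n_aj_structures": 24, "aj_area_mode": "exact_formula", "aj_rounding": "sig2"}
 }
}
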