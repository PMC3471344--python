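{
 "length": 100000,
 "mu": 2.0,
 "name": "unbiased_small_deletions",
 "phi": 0.5,
 "replicates": 100,
 "seed": 101,
 "stop_theta": 0.1
}
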