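{
 "length": 100000,
 "mu": 11.0,
 "name": "biased_large_deletions",
 "phi": 1.0,
 "replicates": 100,
 "seed": 103,
 "stop_theta": 0.1
}
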