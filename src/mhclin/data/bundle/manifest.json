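{
  "name": "mhclin-builtin",
  "version": "1.0.0",
  "synthetic_exemplars": true,
  "generator_seed": 20140801
}
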