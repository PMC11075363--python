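# Demo pipeline configuration: all stages on synthetic data.
seed: 42
outdir: demo_out
stages: [simulate, dmr, state, de, cargo, domains]
dmr:
  k: 6
  alpha: 0.01
  nperm: 1000
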