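# Study-scale emulation config: sample sizes and generator anchors follow the
# published field/mesocosm design (216 RS + 154 VS stomachs, 40 sites x 3
# cruises, 8/8/6 feeding trials; overlap nulls at 1000 reps).  The generator
# parameters emulate printed summary statistics; they are not the raw data.
simulate:
  stomachs:
    n_per_species: {RS: 216, VS: 154}
  survey:
    n_sites: 40
  trials: {}
  sympatric_prob: 0.67
diet:
  estimator: pooled
  iri_variant: additive
  perms: 999
overlap:
  algorithm: RA3
  reps: 1000
  metrics: [pctIRI, pctN, pctW]
spatial:
  bin_preset: community_20m_bins
  perms: 999
mesocosm:
  method: welch
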