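# Demo configuration: a small end-to-end synthetic run.
seed: 1
outdir: epiline_demo
genome:
  length: 80000
insertion:
  point: 44500
  tsd_length: 7
te:
  inverted: true
  truncation: 600
cross:
  n_f2: 2000
dating:
  n_tips: 30
climate:
  n_accessions: 137
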