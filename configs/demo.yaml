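# Demo pipeline configuration: a reduced-scale synthetic screen that runs
# end to end in a few seconds.
#   traptag run --config configs/demo.yaml
outdir: results/demo_run
seed: 1
synthetic:
  n_scaffolds: 2
  scaffold_length: 120000
  n_genes: 8
  n_insertions_per_construct: 3
  n_read_pairs: 400
  chimera_fraction: 0.05
finder:
  min_reporter_match: 14
  min_mate_match: 47
  min_genomic_tag: 15
pssm_mode: frequency
stats_null: uniform
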