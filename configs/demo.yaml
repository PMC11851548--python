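# Demo mapping experiment: miniature 25 Mb genome, one 3:1-segregating F3
# family, two 30-plant bulks sequenced at 30x.  Run with:
#   bsa run --config configs/demo.yaml --out scratch/demo_cli
seed: 1
genome:
  chromosomes:
    - {name: chr1, length: 5000000}
    - {name: chr2, length: 5000000}
    - {name: chr3, length: 5000000}
    - {name: chr4, length: 5000000}
    - {name: chr5, length: 5000000}
  # miniature-genome map density; see docs/methods.md
  recombination_rate: 40.0
simulate:
  ems_variant_count: 500
  indel_fraction: 0.1
  causal: {chromosome: chr3, position: 2500000, effect: frameshift}
  bulk_size: 30
  mean_depth: 30.0
  sequencing_error: 0.002
  f3_family_size: 200
  n_families: 1
filter:
  min_depth: 20
  drop_parental_het: false
windows:
  window: 500000
  step: 10000
scan:
  k: 3.0
  delta_cutoff: 0.22
  vtype: both
  min_windows: 1
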