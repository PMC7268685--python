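# Demo pipeline: a desk-scale run of every stage on synthetic data.
# Partitions are long enough (800 amino-acid sites) that the standard
# masking thresholds (RCFV >= 0.1, < 30% ambiguous, >= 500 sites) operate in
# their intended regime: the compositionally shifted partition p1 is masked,
# the clean partitions survive.  The whole run takes a couple of minutes.
seed: 1
simulate:
  n_taxa: 12
  tree_height: 1.0
  n_partitions: 3
  partition_length: 800
  gamma_alpha: 1.0
  shift_taxa: 3
  shift_weight: 1.0
  shift_partitions: [p1]
  retention: 0.85
  epsilon: 0.2
  n_gene_trees: 50
  mk_characters: 8
  mk_rate: 0.5
  strengthen_split: 0.3
qc:
  rcfv_threshold: 0.1
  max_ambiguous_fraction: 0.30
  min_sites: 500
fclm:
  cap: 12
  min_sites: 30
  alpha: 1.0            # the generating gamma shape
  n_restarts: 3
qsupport:
  cap_per_edge: 200
charmap:
  n_histories: 1000
  model: auto
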