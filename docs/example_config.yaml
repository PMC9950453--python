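# Example pipeline configuration (all keys optional; defaults shown).
# Use with: bearvoc run-all --config docs/example_config.yaml
peak_table: sim/peak_table.tsv
metadata: sim/metadata.tsv
out_dir: results
n_permutations: 10000
nmds_k: 3
nmds_restarts: 20
simper_cutoff: 2.0
alpha: 0.05
seed: 1
simper_grouping: age_sex_class
balance_class: young_M
balance_n_individuals: 2
exclusions: []          # e.g. [["Y862_pedes_2", "failed file conversion"]]
preprocess:
  incidence_fraction: 0.05
  replicate_rule: both_replicates
  count_threshold_fraction: 0.005
  half_minimum_scope: global
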