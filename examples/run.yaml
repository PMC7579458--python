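# Full-pipeline configuration for `rxanomaly run --config examples/run.yaml`.
# Every key is optional; omitted keys fall back to the benchmark defaults.

generator:
  n_records: 10000
  n_diseases: 1000
  n_drugs: 1000
  zipf_ratio: 120.0          # top disease vs rank-1000 disease frequency
  mean_amount: 300.0         # mean fee of a normal visit
  abnormal_amount_multiplier: 5.0
  anomaly_rate: 0.10
  comorbidity_rate: 0.25
  drugs_per_disease: 10
  # pattern_mix:             # defaults to a uniform mix over the six patterns
  #   dosage_abuse: 0.30
  #   duplicate_test: 0.14
  #   unrelated_drugs: 0.14
  #   unrelated_service: 0.14
  #   similar_effects_abuse: 0.14
  #   excessive_frequency: 0.14

model:
  loss: bce                  # "bce" or "focal"
  gamma: 2.0                 # focal focusing parameter (ignored for bce)
  alpha: 0.25                # focal positive/negative balance
  refine_steps: 2            # gated output-refinement iterations; 0 disables
  learning_rate: 0.003
  epochs: 8
  batch_size: 256

detector:
  method: isolation_forest   # isolation_forest | kmeans | dbscan | lof | traditional_rule
  n_estimators: 100
  subsample: 256

k_d: 1000                    # disease vocabulary size
k_r: 1000                    # drug vocabulary size
n_select: 20                 # features kept by mutual information
label_slice: 1000            # labelled records used for feature selection
top_fraction: 0.10           # detection-rate window
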