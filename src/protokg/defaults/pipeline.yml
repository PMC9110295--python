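# Default analysis pipeline configuration.
# Encodes the pipeline defaults: max-missing filter, median normalization,
# MinProb imputation, BH FDR with FC > 2 / FDR < 0.05 regulation flags,
# 250 permutations when permutation FDR is selected, correlation edges at
# coefficient > 0.5 / FDR < 0.05, top-15 betweenness cap per node label.
seed: 0
thresholds:
  fold_change_min: 2.0
  fdr_max: 0.05
sections:
  - name: proteomics_prep
    tab: proteomics
    operation: prep.process
    data: proteomics
    store: true
    params:
      filter_mode: max_missing
      filter_threshold: 0.3
      normalize: median
      imputation:
        method: minprob
        k: 5
        minprob_quantile: 0.01
        minprob_width: 0.3
        mixed_threshold: 0.5
  - name: summary
    tab: proteomics
    operation: stats.summarize
    data: proteomics_prep
    store: true
    params: {}
  - name: pca
    tab: proteomics
    operation: stats.pca
    data: proteomics_prep
    store: true
    params:
      n_components: 2
  - name: differential
    tab: proteomics
    operation: stats.differential
    data: proteomics_prep
    store: true
    params:
      fdr: bh
      permutations: 250
  - name: correlation_network
    tab: proteomics
    operation: networks.correlation
    data: proteomics_prep
    store: true
    params:
      method: pearson
      min_coefficient: 0.5
      fdr_max: 0.05
  - name: clinical_summary
    tab: clinical
    operation: clinical.summary
    data: clinical
    store: true
    params: {}
  - name: multiomics_network
    tab: multiomics
    operation: networks.multiomics
    data: [proteomics_prep, clinical]
    store: true
    params:
      method: spearman
      min_coefficient: 0.5
      fdr_max: 0.05
  - name: knowledge_summary
    tab: knowledge
    operation: knowledge.subgraph
    data: differential
    store: true
    params:
      k_per_label: 15
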