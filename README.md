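# protokg

An embedded biomedical property graph plus an automated statistics
pipeline for clinical proteomics projects.

Interpreting a quantified proteomics experiment means more than a t-test:
candidate biomarkers need context — which diseases a protein is linked
to, which drugs inhibit it, which publications discuss it, which
pathways it sits in. `protokg` keeps that prior knowledge in a typed
property graph (36 node labels, 47 relationship types, bundled as a
declarative schema) and runs a reproducible analysis pipeline over it:

- **graph store** — schema-validated nodes/edges with TSV, JSON, GML and
  GraphML I/O and pattern queries; no database server required;
- **harmonizer** — OBO ontology ingestion, deterministic identifier
  mapping (name > synonym > xref), minted project/sample identifiers,
  `HAS_QUANTIFIED` experiment ingestion;
- **prep** — missing-value filtering, median/quantile normalization, and
  MNAR/MCAR-aware imputation (KNN, left-censored MinProb with draws from
  N(q₀.₀₁, (0.3·sd)²), or mixed with a strict 50% missingness bound);
- **stats** — design-aware testing (independent/paired t, ANOVA,
  repeated-measures ANOVA), the moderated statistic
  d = Δmean/(SE + s₀), BH and label-permutation FDR (default 250
  permutations), Fisher enrichment, Kaplan–Meier + log-rank with a
  top-25% expression split; regulation flags at fold change > 2 and
  FDR < 0.05;
- **networks** — correlation networks (edges at coefficient > 0.5 and
  FDR < 0.05), Louvain communities, project similarity
  (Jaccard/overlap/Pearson), and a knowledge-summary subgraph keeping
  the top-15 nodes per label by betweenness centrality;
- **drug prioritization** — upregulated disease-linked proteins →
  inhibitory drugs → side-effect Jaccard dissimilarity filter
  (strictly < 0.2 vs the reference regimen) → literature
  (drug, target, disease) triplet co-mention ranking;
- **pipeline + CLI** — YAML-configured orchestration producing a
  multi-tab report (clinical / proteomics / multiomics / knowledge)
  serialized as TSV/JSON/GML files plus a single HDF5 archive,
  byte-identical under a fixed seed.

Seeded generators (`protokg.synthetic_fixtures`) produce a miniature
schema-conformant knowledge graph and simulated experiments (planted
group effects, intensity-dependent MNAR + uniform MCAR missingness,
survival times), so every stage is testable offline.

## Worked example

```python
from protokg.synthetic_fixtures import write_toy_project, KGSpec, SimSpec
from protokg.pipeline import run_default_pipeline, serialize_report

project = write_toy_project("demo/proj", KGSpec(seed=0), SimSpec(seed=0, n_features=60))
report = run_default_pipeline("demo/proj", graph=project["graph"], seed=0)
serialize_report(report, "demo/report")

diff = report.get("proteomics", "differential")
print(diff[diff["regulation"] != "ns"][["feature", "log2fc", "padj", "regulation"]])
```

prints

```
 feature    log2fc         padj regulation
PROT0020 -2.450640 2.235601e-07       down
PROT0028  2.117533 4.959262e-10         up
PROT0050  3.620797 2.244724e-08         up
PROT0051  3.150571 2.645322e-02         up
```

Four of the six planted features are flagged at the default thresholds
(fold change > 2, BH FDR < 0.05); the remaining two were censored below
the detection limit in the shifted group and removed by the
missing-value filter before testing. The knowledge tab then retains, per
label, the most central neighbors of the regulated proteins
(here 2 diseases, 6 drugs, 8 pathways and 6 publications) and emits a
Sankey-ready flow table, e.g.:

```
source_label target_label  weight
        Drug      Protein       9
     Protein      Disease       3
     Protein      Pathway      13
     Protein  Publication       7
```

The same run is available from the shell:

```sh
protokg simulate --preset toy --seed 0 --out demo/proj
protokg analyze --project-dir demo/proj --graph-dir demo/proj/kg --seed 0 --out demo/report
protokg validate demo/proj/kg/nodes.tsv demo/proj/kg/edges.tsv
```

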