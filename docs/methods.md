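# Methods

`protokg` implements the computational core of a clinical proteomics
knowledge-graph platform as an importable Python library: an embedded,
schema-validated property graph standing in for a server-backed graph
database, plus the automated analysis pipeline that turns a quantified
proteomics matrix into a statistics report and a prior-knowledge summary
subgraph. This note documents the models, the defaults and their
rationale, the numerical choices, and what the synthetic data generators
do and do not emulate.

## The data model and graph store

The knowledge substrate is a typed property graph: nodes carry a label
(`Protein`, `Disease`, `Drug`, ...) and an attribute map; directed edges
carry a relationship type (`ASSOCIATED_WITH`, `HAS_QUANTIFIED`, ...) and
an attribute map. The bundled schema (`defaults/data_model.yml`) declares
exactly 36 node labels and 47 relationship types, each type with its
allowed (source label, target label) pairs; that file is the single
authoritative definition of the data model. Schema validation is opt-in
during exploratory loading and mandatory inside the pipeline.

Node identifiers are strings namespaced by their source (ontology or
database accessions verbatim); project-internal entities receive minted
identifiers (below). Edges are directed but association-type queries
default to `direction="both"` because biomedical associations are used
symmetrically. Parallel edges with identical (source, target, type)
collapse into one; when both carry a numeric `score` the maximum is kept,
so redundant knowledge sources strengthen rather than duplicate an edge.

The TSV bulk dialect (columns `ID`/`LABEL` and `START_ID`/`END_ID`/`TYPE`
plus attribute columns) uses UTF-8, a header row, and backslash escaping
for tabs, newlines and backslashes; attribute cells that parse as
integers or floats are restored as numbers, so numeric attributes
round-trip exactly while a string that merely looks numeric is coerced —
an accepted limitation of a text dialect. GML output mangles attribute
names to alphanumerics (non-conforming characters become `_`), as GML
requires; TSV and JSON round-trip losslessly.

## Harmonization

Ontologies are read from OBO flat files (via `obonet`, with a line-level
pre-scan that reports `[Term]` stanzas lacking an `id` by line number and
counts obsolete terms, which are excluded). `is_a` pairs are checked for
acyclicity; cycles are reported, not fatal, since real ontology snapshots
occasionally ship them.

The mapping dictionary sends every term name, synonym and cross-reference
(case-folded) to its canonical term id. Precedence is name > synonym >
xref; same-tier collisions resolve to the lexicographically smallest term
id and are logged. Lookup is exact-match only — determinism was chosen
over recall, so a miss is a visible `None` rather than a silent fuzzy hit.

Project entities are minted deterministic, prefixed, zero-padded internal
ids in manifest order (`P0001`, `S0001`, `BS0001`, `AS0001`; width 4 is a
cosmetic choice). The subject / biological-sample / analytical-sample
hierarchy must be a tree: an analytical sample listed under two
biological samples (or a biological sample under two subjects) is an
integrity error, not a warning. Ingestion writes one `HAS_QUANTIFIED`
edge per non-missing quantified cell with the quantification as the edge
`value` attribute, and is an upsert: re-ingesting the same matrix leaves
the edge count unchanged. Clinical variables follow the same pattern as
`Clinical_variable` nodes quantified on biological samples, with
SNOMED-style identifiers accepted verbatim.

## Data preparation

Intensities are log2-transformed on load; zeros and blanks become
missing. The preparation order is fixed: **filter → normalize → impute**.

- **Filtering** removes features by one of three rules: maximum missing
  fraction (default mode, threshold 0.3 — the mode is standard, the
  fraction is this package's default and is recorded in every report),
  minimum observed count per group, or minimum total count.
- **Normalization** default is per-sample median centering (every sample
  median becomes 0); quantile normalization maps each sample's observed
  values through their plotting positions onto the mean of the
  per-sample quantile functions, so samples with missing cells are
  supported.
- **Imputation** offers three strategies for the two missingness
  mechanisms of label-free proteomics. KNN (MCAR): neighbors are
  samples, distance is Euclidean over mutually observed features, the
  imputed value is the unweighted mean of k = 5 neighbors (k is not
  dictated by the underlying method; 5 is the package default).
  MinProb (MNAR, the pipeline default): per sample, draws from a
  Gaussian centered at the q = 0.01 quantile of that sample's observed
  values with s.d. = 0.3 × the sample s.d. — the standard left-censored
  convention; both q and the width multiplier are exposed. Mixed:
  features missing in strictly less than 50% of samples are treated as
  MCAR (KNN), the rest as MNAR (MinProb); the bound is strict by
  definition. Observed cells are never altered by any method, and
  MinProb draws are seeded.

A caveat worth knowing: MinProb applied globally will place a sporadic
MCAR-missing cell of an abundant protein at the detection limit, creating
a low outlier that inflates that feature's variance and can mask a real
group difference. This is inherent to global left-censored imputation,
not an implementation artifact, and is why the mixed method exists; when
the missingness mechanism is known to be a mixture (as in the synthetic
data below), mixed is the appropriate choice.

## Statistics

`differential_regulation` selects the test from the design: two
independent groups → t-test (pooled variance by default, so the statistic
matches the moderated-statistic denominator at s0 = 0; Welch is an
option); two groups whose samples share subject ids one-to-one → paired
t-test; more than two groups → one-way ANOVA with pairwise post hoc
t-tests, BH-adjusted jointly across all pairs and features; subjects
crossing all conditions → repeated-measures ANOVA (within-subject
one-way ANOVA with subject as blocking factor; unbalanced designs are
rejected rather than approximated — the F is verified against pingouin
in the test suite). Identical degenerate inputs define t = 0, p = 1.

Regulation flags follow fold change > 2 and FDR < 0.05: `up` iff
log2FC > 1 and adjusted p < 0.05, `down` symmetric, both bounds read on
group means of log2 values and applied two-sidedly.

The moderated difference statistic is d = (mean_a − mean_b)/(SE + s0)
with SE the pooled standard error, reducing exactly to the pooled t at
s0 = 0; s0 must be supplied explicitly (no automatic selection rule is
implemented). BH FDR is the standard step-up adjustment. The
permutation FDR permutes group labels (two-group independent designs
only): for each feature's observed |d| cutoff, the estimate is the mean
per-permutation count of null exceedances divided by the observed
exceedance count, clipped to [0, 1], then converted to a q-value (best
achievable estimate at any cutoff still rejecting the feature, which
enforces monotonicity in |d|). The default is 250 permutations; when the
design admits fewer than 10 distinct labelings the estimate would be
unstable, so the function falls back to BH with a warning.

Enrichment is a two-sided Fisher exact test per annotation term against
the supplied universe, BH across terms, sorted by adjusted p then term
id. Survival analysis splits samples at the (1 − split) expression
quantile of a marker (default: top 25% = "high"), fits Kaplan–Meier
curves per group and reports the two-sided log-rank test; a cohort with
no events returns a `no-events` sentinel rather than a p-value.

## Networks and knowledge summarization

The correlation network computes all pairwise Pearson (default) or
Spearman coefficients — within one feature set, or only across the two
blocks of a bipartite split (the clinical-vs-protein network uses
Spearman across blocks) — applies BH over all tested pairs, and keeps an
edge iff coefficient > 0.5 and adjusted p < 0.05. The inclusion rule is
applied to the *signed* coefficient by default (the literal reading of
"coefficient > 0.5"); an absolute-value mode is exposed because strong
anticorrelations are otherwise discarded. Constant features are excluded
with a warning. Louvain communities (resolution 1.0, seeded, community
ids renumbered by smallest member for stable output) are attached;
edgeless graphs yield singleton communities with Q = 0.

Project similarity reports Jaccard and overlap coefficients on
identified-protein sets and Pearson correlation of mean profiles over
shared proteins (NaN sentinel below 3 shared).

The knowledge summary expands one hop from the regulated proteins to
diseases, drugs, pathways, biological processes, publications and — via
substrate edges only — upstream kinases, then prunes per node label to
the top 15 by exact betweenness centrality, computed on the undirected
simple view with unit weights, unnormalized pair counts and endpoints
excluded; ties break by ascending node id, and the regulated proteins
themselves are always retained. Pruning happens after the full one-hop
expansion (so centrality reflects the whole expanded neighborhood), a
deliberate choice where the ordering was open. The summary emits a
Sankey-ready (source label, target label, weight) table aggregating edge
counts between label pairs.

## Drug prioritization

Candidates must inhibit (action ∈ {inhibition, antagonist, blocker}) at
least one upregulated protein with a known association edge to the
studied disease. Each candidate's side-effect set is compared with the
union of the reference regimen's side effects by Jaccard similarity
(a per-regimen-drug maximum mode is exposed; union is the default) and
kept only when strictly below 0.2. Candidates without any side-effect
annotation are flagged and excluded rather than silently kept; an empty
regimen side-effect union makes the filter undefined and is an error.
Survivors are ranked by literature triplet co-mentions — a publication
counts only when it mentions the drug, a target and the disease — with
candidate score the maximum over targets; ties break by ascending
Jaccard, then drug id, giving a total order.

## Synthetic data

The generators are pure functions of their spec (seed included); each
stage draws from its own named RNG stream so adding a stage never shifts
existing draws.

The toy knowledge graph plants Bernoulli-density associations between
typed nodes (defaults: 60 proteins, 8 diseases, 15 drugs, 30 side
effects, 10 pathways, 40 publications, 5 kinases; densities 0.05–0.2)
and records every planted edge in ground-truth tables; it always passes
schema validation.

The proteomics simulator draws feature means from N(25, 2) log2 units
(LFQ-like), per-feature within-group s.d. from U(0.2, 0.6), and plants
|log2 effect| ~ U(2, 4) with random sign on 10% of features in one
non-reference group (defaults: 2 groups × 10 samples × 200 features).
Missingness is a mixture: MNAR probability follows a logistic in the
true log2 intensity, centered at the 0.15 quantile of the intensity
distribution with slope 2 per log2 unit (the MNAR mechanism is assumed,
not prescribed, so a logistic detection-limit model was chosen), plus 5%
uniform MCAR. Survival times are exponential with hazard = baseline ×
HR^z for standardized marker expression z, censored by an independent
exponential clock.

Not emulated: peptide-level structure, retention-time/spectral effects,
batch effects, correlated feature blocks beyond the planted clinical
links. Passing tests therefore demonstrate correctness of the
statistical machinery under a clean generative model, not robustness to
real-data artifacts.

### What the calibration results mean

On null simulations both BH and the permutation FDR flag essentially no
features at FDR < 0.05. For planted-effect recovery the suite measures
the sensitivity of `differential_regulation` on the prepared matrix,
using the mixed imputation — the method matched to the simulation's
explicit MCAR+MNAR mixture — and counting the planted features that
reach the test: features whose MNAR censoring removed them at the
missing-value filter are not recoverable by any downstream test and are
reported separately as filter drops. Under those conditions recovery of
|log2FC| ≥ 2 effects at n = 10/group is complete; with global MinProb
instead, recovery drops for the reason described in the preparation
section, which is a property of the imputation model, not of the test.

## Pipeline and report

The pipeline is configuration-driven: an ordered list of sections, each
naming its input data (a raw data type or an earlier section), a
registry operation, parameters and a store flag. The default
configuration (`defaults/pipeline.yml`) encodes the package defaults
listed above. Configuration errors (unknown operation, unresolvable data
reference) are raised before any execution; sections whose inputs are
absent are skipped with a log entry, so a proteomics-only project has no
clinical or multiomics tab. The whole run is a pure function of (input
files, config, seed).

Reports serialize to per-tab folders (TSV tables, JSON payloads,
GML/GraphML/JSON networks) plus one HDF5 archive: one group per tab, one
dataset per table containing its UTF-8 TSV payload, and a provenance
group holding the config snapshot, seed and package version. Object
timestamps are disabled so identical runs produce byte-identical
archives. Problem sizes in the bundled fixtures (≈200 nodes, 20 samples
× 40–200 features) keep a full pipeline run in the low seconds.

## Known limitations

- The graph store is in-memory and single-writer; there is no query
  language or server protocol, by design.
- Permutation FDR supports two-group independent designs only.
- WGCNA-style co-expression modules, nonlinear embeddings (t-SNE/UMAP)
  and multi-omics similarity-network fusion are out of scope; PCA is the
  in-package dimensionality reduction.
- Numeric-looking string attributes do not survive the TSV dialect as
  strings (coerced to numbers on re-import).
- The mapping dictionary is exact-match; misspelled identifiers simply
  miss.
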