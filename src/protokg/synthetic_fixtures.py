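"""Seeded generators for a miniature knowledge graph and simulated
multi-group proteomics / clinical / survival datasets.

Every generator is a pure function of its spec (the seed included); each
generation stage draws from its own named RNG stream so adding a stage never
shifts the draws of existing ones.  The knowledge-graph generator emits a
schema-conformant toy graph (proteins, diseases, drugs, side effects,
pathways, publications, kinase-substrate edges) together with ground-truth
tables of the planted associations; the proteomics simulator plants group
shifts on a regulated fraction of features and applies a realistic
missingness mixture: uniform MCAR plus intensity-dependent MNAR whose
probability follows a logistic that rises as the true log-intensity falls
below a low quantile of the intensity distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_store import PropertyGraph, default_schema, export_graph, validate_schema
from .prep import ExperimentMatrix

__all__ = [
    "KGSpec",
    "SimSpec",
    "generate_knowledge_graph",
    "simulate_proteomics",
    "simulate_clinical_variables",
    "simulate_clinical_survival",
    "drug_prioritization_fixture",
    "write_toy_project",
]

_HARD_NODE_CAP = 20000

# named RNG stream indices (append-only; never renumber)
_STREAM_KG_SCORES = 0
_STREAM_KG_EDGES = 1
_STREAM_SIM_BASE = 2
_STREAM_SIM_EFFECTS = 3
_STREAM_SIM_MISSING = 4
_STREAM_CLINICAL = 5
_STREAM_SURVIVAL = 6


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass
class KGSpec:
    """Counts and association densities for the toy knowledge graph."""

    n_proteins: int = 60
    n_diseases: int = 8
    n_drugs: int = 15
    n_side_effects: int = 30
    n_pathways: int = 10
    n_publications: int = 40
    n_kinases: int = 5
    protein_disease_density: float = 0.08
    drug_protein_density: float = 0.10
    drug_side_effect_density: float = 0.15
    protein_pathway_density: float = 0.20
    publication_mention_density: float = 0.05
    kinase_substrate_density: float = 0.05
    inhibition_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_proteins, self.n_diseases, self.n_drugs, self.n_side_effects,
                  self.n_pathways, self.n_publications, self.n_kinases)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_kinases > self.n_proteins:
            raise ValueError("n_kinases cannot exceed n_proteins")
        for name in ("protein_disease_density", "drug_protein_density",
                     "drug_side_effect_density", "protein_pathway_density",
                     "publication_mention_density", "kinase_substrate_density",
                     "inhibition_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if sum(counts) > _HARD_NODE_CAP:
            raise ValueError(f"node counts exceed hard cap {_HARD_NODE_CAP}")


@dataclass
class SimSpec:
    """Statistical structure of the simulated proteomics experiment."""

    n_groups: int = 2
    n_samples_per_group: int = 10
    n_features: int = 200
    fraction_regulated: float = 0.10
    effect_low: float = 2.0  # |log2 effect| range for regulated features
    effect_high: float = 4.0
    base_mean: float = 25.0  # log2 intensity center (LFQ-like)
    base_sd: float = 2.0
    noise_sd_low: float = 0.2  # per-feature within-group s.d. range
    noise_sd_high: float = 0.6
    mnar_fraction: float = 0.15  # location quantile of the MNAR logistic
    mnar_slope: float = 2.0  # logistic steepness per log2 unit
    mcar_fraction: float = 0.05
    survival_baseline_hazard: float = 0.05
    survival_hazard_ratio: float = 1.0  # per s.d. of the marker
    survival_censoring_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        for name in ("fraction_regulated", "mnar_fraction", "mcar_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")


# ---------------------------------------------------------------------------
# knowledge graph
# ---------------------------------------------------------------------------


def _bernoulli_pairs(rng, left, right, density):
    if not left or not right or density == 0:
        return []
    draws = rng.random((len(left), len(right))) < density
    return [(left[i], right[j]) for i, j in zip(*np.nonzero(draws))]


def generate_knowledge_graph(spec: KGSpec | None = None):
    """Generate the toy knowledge graph.

    Returns (graph, truth) where ``truth`` maps relationship families to
    DataFrames of the planted associations.  The graph passes schema
    validation against the bundled data model with an empty report.
    """
    spec = spec or KGSpec()
    schema = default_schema()
    graph = PropertyGraph(schema=schema, validate=True)
    proteins = [f"PROT{i + 1:04d}" for i in range(spec.n_proteins)]
    diseases = [f"DIS{i + 1:03d}" for i in range(spec.n_diseases)]
    drugs = [f"DRUG{i + 1:03d}" for i in range(spec.n_drugs)]
    side_effects = [f"SE{i + 1:03d}" for i in range(spec.n_side_effects)]
    pathways = [f"PATH{i + 1:03d}" for i in range(spec.n_pathways)]
    publications = [f"PUB{i + 1:04d}" for i in range(spec.n_publications)]
    kinases = proteins[: spec.n_kinases]

    for pid in proteins:
        graph.add_node(pid, "Protein", {"name": pid})
    for label, ids in (("Disease", diseases), ("Drug", drugs), ("Side_effect", side_effects),
                       ("Pathway", pathways), ("Publication", publications)):
        for nid in ids:
            graph.add_node(nid, label, {"name": nid})

    rng_edges = _rng(spec.seed, _STREAM_KG_EDGES)
    rng_scores = _rng(spec.seed, _STREAM_KG_SCORES)
    truth = {}

    pd_pairs = _bernoulli_pairs(rng_edges, proteins, diseases, spec.protein_disease_density)
    scores = rng_scores.uniform(0.1, 1.0, len(pd_pairs)).round(3)
    for (p, d), score in zip(pd_pairs, scores):
        graph.add_edge(p, d, "ASSOCIATED_WITH", {"score": float(score)})
    truth["protein_disease"] = pd.DataFrame(pd_pairs, columns=["protein", "disease"])

    dp_pairs = _bernoulli_pairs(rng_edges, drugs, proteins, spec.drug_protein_density)
    actions = rng_edges.random(len(dp_pairs)) < spec.inhibition_fraction
    rows = []
    for (drug, prot), inhib in zip(dp_pairs, actions):
        action = "inhibition" if inhib else "activation"
        graph.add_edge(drug, prot, "ACTS_ON", {"action": action})
        rows.append((drug, prot, action))
    truth["drug_protein"] = pd.DataFrame(rows, columns=["drug", "protein", "action"])

    ds_pairs = _bernoulli_pairs(rng_edges, drugs, side_effects, spec.drug_side_effect_density)
    for drug, se in ds_pairs:
        graph.add_edge(drug, se, "HAS_SIDE_EFFECT")
    truth["drug_side_effect"] = pd.DataFrame(ds_pairs, columns=["drug", "side_effect"])

    pp_pairs = _bernoulli_pairs(rng_edges, proteins, pathways, spec.protein_pathway_density)
    for prot, path in pp_pairs:
        graph.add_edge(prot, path, "ANNOTATED_IN_PATHWAY")
    truth["protein_pathway"] = pd.DataFrame(pp_pairs, columns=["protein", "pathway"])

    mention_rows = []
    for entities in (proteins, drugs, diseases):
        for ent, pub in _bernoulli_pairs(rng_edges, entities, publications,
                                         spec.publication_mention_density):
            graph.add_edge(ent, pub, "MENTIONED_IN_PUBLICATION")
            mention_rows.append((ent, pub))
    truth["mentions"] = pd.DataFrame(mention_rows, columns=["entity", "publication"])

    substrates = proteins[spec.n_kinases:]
    ks_pairs = _bernoulli_pairs(rng_edges, substrates, kinases, spec.kinase_substrate_density)
    for substrate, kinase in ks_pairs:
        graph.add_edge(substrate, kinase, "IS_SUBSTRATE_OF")
    truth["kinase_substrate"] = pd.DataFrame(ks_pairs, columns=["substrate", "kinase"])

    report = validate_schema(graph)
    assert report.ok, f"generated graph violates schema: {report}"
    return graph, truth


# ---------------------------------------------------------------------------
# proteomics simulation
# ---------------------------------------------------------------------------


def simulate_proteomics(spec: SimSpec | None = None):
    """Simulate a multi-group log2 intensity matrix with planted effects.

    Returns (matrix, truth) where ``truth`` has one row per regulated
    feature (feature, affected group, true log2 effect) with attributes
    ``truth.attrs['true_values']`` and ``['missing_mask']`` holding the
    complete pre-missingness matrix and the applied mask.
    """
    spec = spec or SimSpec()
    n = spec.n_groups * spec.n_samples_per_group
    features = [f"FEAT{i + 1:04d}" for i in range(spec.n_features)]
    samples = [f"AS{i + 1:03d}" for i in range(n)]
    groups = [f"G{g + 1}" for g in range(spec.n_groups) for _ in range(spec.n_samples_per_group)]

    rng_base = _rng(spec.seed, _STREAM_SIM_BASE)
    feat_mean = rng_base.normal(spec.base_mean, spec.base_sd, spec.n_features)
    feat_sd = rng_base.uniform(spec.noise_sd_low, spec.noise_sd_high, spec.n_features)
    values = feat_mean + rng_base.normal(0.0, 1.0, (n, spec.n_features)) * feat_sd

    rng_eff = _rng(spec.seed, _STREAM_SIM_EFFECTS)
    n_reg = int(round(spec.fraction_regulated * spec.n_features))
    reg_ix = np.sort(rng_eff.choice(spec.n_features, size=n_reg, replace=False))
    rows = []
    group_arr = np.asarray(groups)
    for ix in reg_ix:
        magnitude = rng_eff.uniform(spec.effect_low, spec.effect_high)
        sign = 1.0 if rng_eff.random() < 0.5 else -1.0
        affected = f"G{rng_eff.integers(1, spec.n_groups) + 1}" if spec.n_groups > 1 else "G1"
        values[group_arr == affected, ix] += sign * magnitude
        rows.append((features[ix], affected, sign * magnitude))
    truth = pd.DataFrame(rows, columns=["feature", "affected_group", "log2_effect"])

    rng_miss = _rng(spec.seed, _STREAM_SIM_MISSING)
    loc = np.quantile(values, spec.mnar_fraction) if spec.mnar_fraction > 0 else -np.inf
    with np.errstate(over="ignore"):
        p_mnar = 1.0 / (1.0 + np.exp(spec.mnar_slope * (values - loc)))
    if spec.mnar_fraction == 0:
        p_mnar = np.zeros_like(values)
    mask = rng_miss.random(values.shape) < p_mnar
    mask |= rng_miss.random(values.shape) < spec.mcar_fraction

    observed = values.copy()
    observed[mask] = np.nan
    value_df = pd.DataFrame(observed, index=samples, columns=features)
    sample_meta = pd.DataFrame(
        {"group": groups, "subject": [f"SUBJ{i + 1:03d}" for i in range(n)]}, index=samples
    )
    truth.attrs["true_values"] = pd.DataFrame(values, index=samples, columns=features)
    truth.attrs["missing_mask"] = pd.DataFrame(mask, index=samples, columns=features)
    matrix = ExperimentMatrix(values=value_df, sample_meta=sample_meta)
    return matrix, truth


def simulate_clinical_variables(spec: SimSpec, matrix: ExperimentMatrix,
                                n_variables: int = 6, n_linked: int = 3,
                                noise_sd: float = 0.5) -> pd.DataFrame:
    """Simulate quantitative clinical variables, the first ``n_linked`` of
    which track randomly chosen protein features (plus Gaussian noise) so
    the cross-omics correlation network has planted structure."""
    rng = _rng(spec.seed, _STREAM_CLINICAL)
    complete = matrix.values.ffill().bfill()  # tolerate missing cells
    data = {}
    feat_ix = rng.choice(matrix.n_features, size=min(n_linked, matrix.n_features),
                         replace=False)
    for j in range(n_variables):
        name = f"CLIN{j + 1:02d}"
        if j < len(feat_ix):
            base = complete.iloc[:, int(feat_ix[j])].to_numpy()
            z = (base - base.mean()) / (base.std() or 1.0)
            data[name] = z + rng.normal(0, noise_sd, matrix.n_samples)
        else:
            data[name] = rng.normal(0, 1, matrix.n_samples)
    return pd.DataFrame(data, index=matrix.values.index)


def simulate_clinical_survival(spec: SimSpec, matrix: ExperimentMatrix,
                               marker: str) -> pd.DataFrame:
    """Exponential event times with hazard scaled by marker expression.

    hazard_i = baseline * HR**z_i with z the standardized (imputed-complete)
    marker; censoring by an independent exponential clock.  Returns a frame
    with columns time / event / group indexed by sample.
    """
    if marker not in matrix.values.columns:
        raise KeyError(f"unknown marker {marker!r}")
    rng = _rng(spec.seed, _STREAM_SURVIVAL)
    expr = matrix.values[marker]
    expr = expr.fillna(expr.mean())
    z = (expr - expr.mean()) / (expr.std() or 1.0)
    hazard = spec.survival_baseline_hazard * np.power(spec.survival_hazard_ratio, z)
    t_event = rng.exponential(1.0 / hazard.to_numpy())
    if spec.survival_censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.survival_censoring_rate, matrix.n_samples)
    else:
        t_cens = np.full(matrix.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event, "group": matrix.groups.to_numpy()},
        index=matrix.values.index,
    )


# ---------------------------------------------------------------------------
# drug-prioritization fixture
# ---------------------------------------------------------------------------


def drug_prioritization_fixture(seed: int = 0):
    """Hand-planted graph for the treatment-prioritization workflow.

    Contains one "ideal" drug that inhibits disease-linked upregulated
    proteins, has side effects disjoint from the reference regimen and a
    planted triplet publication, plus distractor drugs that each fail one
    filter.  Returns a dict with graph, differential table, disease id,
    regimen drug set and the ideal drug id.
    """
    del seed  # fixture is fully deterministic; kept for interface symmetry
    graph = PropertyGraph(schema=default_schema(), validate=True)
    disease, other_disease = "DIS900", "DIS901"
    up_proteins = [f"UPPROT{i}" for i in range(1, 6)]
    for pid in up_proteins + ["NSPROT1"]:
        graph.add_node(pid, "Protein", {"name": pid})
    graph.add_node(disease, "Disease", {"name": "studied disease"})
    graph.add_node(other_disease, "Disease", {"name": "unrelated disease"})
    # three of the five upregulated proteins are disease-linked
    for pid in up_proteins[:3]:
        graph.add_edge(pid, disease, "ASSOCIATED_WITH", {"score": 0.9})
    graph.add_edge(up_proteins[3], other_disease, "ASSOCIATED_WITH", {"score": 0.9})

    drugs = {
        "DRUG_IDEAL": [("inhibition", up_proteins[0]), ("inhibition", up_proteins[1]),
                       ("inhibition", up_proteins[2])],
        "DRUG_OK2": [("inhibition", up_proteins[2])],
        "DRUG_SIMILAR_SE": [("inhibition", up_proteins[0])],
        "DRUG_ACTIVATOR": [("activation", up_proteins[1])],
        "DRUG_OFFTARGET": [("inhibition", up_proteins[4])],  # not disease-linked
        "REG1": [], "REG2": [],
    }
    for drug, actions in drugs.items():
        graph.add_node(drug, "Drug", {"name": drug})
        for action, target in actions:
            graph.add_edge(drug, target, "ACTS_ON", {"action": action})

    side_effects = {
        "REG1": ["SE_R1", "SE_R2", "SE_R3"],
        "REG2": ["SE_R3", "SE_R4"],
        "DRUG_IDEAL": ["SE_X1", "SE_X2"],
        "DRUG_OK2": ["SE_X3"],
        "DRUG_SIMILAR_SE": ["SE_R1", "SE_R2", "SE_R3", "SE_X4"],
        "DRUG_OFFTARGET": ["SE_X5"],
    }
    for drug, ses in side_effects.items():
        for se in ses:
            graph.add_node(se, "Side_effect", {})
            graph.add_edge(drug, se, "HAS_SIDE_EFFECT")

    graph.add_node("PUB9001", "Publication", {})
    for ent in ("DRUG_IDEAL", up_proteins[0], disease):
        graph.add_edge(ent, "PUB9001", "MENTIONED_IN_PUBLICATION")
    # a decoy publication missing the target leg of the triplet
    graph.add_node("PUB9002", "Publication", {})
    for ent in ("DRUG_OK2", disease):
        graph.add_edge(ent, "PUB9002", "MENTIONED_IN_PUBLICATION")

    diff = pd.DataFrame({
        "feature": up_proteins + ["NSPROT1"],
        "log2fc": [2.5, 2.2, 3.0, 2.1, 2.8, 0.1],
        "padj": [0.001, 0.002, 0.001, 0.004, 0.003, 0.9],
        "regulation": ["up"] * 5 + ["ns"],
    })
    return {
        "graph": graph,
        "differential": diff,
        "disease": disease,
        "regimen": {"REG1", "REG2"},
        "ideal_drug": "DRUG_IDEAL",
    }


# ---------------------------------------------------------------------------
# project export
# ---------------------------------------------------------------------------


def write_toy_project(out_dir, kg_spec: KGSpec | None = None,
                      sim_spec: SimSpec | None = None) -> dict:
    """Write a complete toy project to disk: knowledge-graph TSVs, manifest,
    proteomics matrix, clinical table and truth tables.  Features are named
    after graph proteins so ingestion maps them directly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kg_spec = kg_spec or KGSpec()
    sim_spec = sim_spec or SimSpec(n_features=min(kg_spec.n_proteins, 200))
    graph, kg_truth = generate_knowledge_graph(kg_spec)
    matrix, truth = simulate_proteomics(sim_spec)
    # rename simulated features to graph protein ids (prefix overlap allowed)
    proteins = graph.nodes_by_label("Protein")
    rename = {
        feat: proteins[i % len(proteins)] if i < len(proteins) else feat
        for i, feat in enumerate(matrix.values.columns)
    }
    matrix = ExperimentMatrix(values=matrix.values.rename(columns=rename),
                              sample_meta=matrix.sample_meta)
    truth["feature"] = truth["feature"].map(lambda f: rename.get(f, f))

    export_graph(graph, out / "kg", format="tsv")
    matrix.values.to_csv(out / "proteomics.tsv", sep="\t", index_label="sample")
    clinical = simulate_clinical_variables(sim_spec, matrix)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index_label="sample")
    manifest = pd.DataFrame({
        "subject": matrix.sample_meta["subject"],
        "biological_sample": ["B" + s for s in matrix.values.index],
        "analytical_sample": matrix.values.index,
        "group": matrix.sample_meta["group"],
    })
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth_regulated.tsv", sep="\t", index=False)
    for name, frame in kg_truth.items():
        frame.to_csv(out / f"truth_kg_{name}.tsv", sep="\t", index=False)
    return {"dir": out, "graph": graph, "matrix": matrix, "truth": truth,
            "clinical": clinical, "manifest": manifest}
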