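"""Configuration-driven orchestration of the default report.

A pipeline configuration is an ordered list of sections; each names its
input data (a raw data type or an earlier section), the registry operation
to run, a parameter map and a store flag.  Execution produces a
:class:`Report` with one tab per data type, a multiomics tab when at least
two data types are present, and a knowledge tab summarizing the regulated
features against the prior-knowledge graph.  The report serializes to a
directory of TSV/JSON/GML/GraphML files plus a single hierarchical HDF5
archive (one group per tab, one dataset per table holding its TSV payload,
plus a provenance group with the config snapshot and seed); identical
inputs, config and seed reproduce the archive byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import networks as net
from . import prep as prep_mod
from . import stats as stats_mod
from .graph_store import PropertyGraph, export_graph
from .prep import ExperimentMatrix, ImputationConfig

__all__ = [
    "AnalysisConfig",
    "Report",
    "ConfigError",
    "default_config",
    "run_default_pipeline",
    "serialize_report",
    "load_report",
]


class ConfigError(ValueError):
    pass


@dataclass
class Section:
    name: str
    tab: str
    operation: str
    data: list
    params: dict = field(default_factory=dict)
    store: bool = True


@dataclass
class AnalysisConfig:
    sections: list
    seed: int = 0
    thresholds: dict = field(default_factory=lambda: {"fold_change_min": 2.0, "fdr_max": 0.05})
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        sections = []
        names = set()
        for entry in raw.get("sections", []):
            for key in ("name", "tab", "operation", "data"):
                if key not in entry:
                    raise ConfigError(f"section missing required field {key!r}: {entry}")
            data = entry["data"]
            section = Section(
                name=entry["name"], tab=entry["tab"], operation=entry["operation"],
                data=list(data) if isinstance(data, list) else [data],
                params=dict(entry.get("params") or {}), store=bool(entry.get("store", True)),
            )
            if section.name in names:
                raise ConfigError(f"duplicate section name {section.name!r}")
            names.add(section.name)
            sections.append(section)
        if not sections:
            raise ConfigError("configuration defines no sections")
        return cls(sections=sections, seed=int(raw.get("seed", 0)),
                   thresholds=dict(raw.get("thresholds") or
                                   {"fold_change_min": 2.0, "fdr_max": 0.05}),
                   raw=raw)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)


def default_config() -> AnalysisConfig:
    ref = resources.files("protokg.defaults").joinpath("pipeline.yml")
    with resources.as_file(ref) as path:
        return AnalysisConfig.from_yaml(path)


@dataclass
class Report:
    """Ordered result payloads per tab, plus provenance."""

    tabs: dict = field(default_factory=dict)  # tab -> list[(name, payload)]
    provenance: dict = field(default_factory=dict)

    def add(self, tab: str, name: str, payload) -> None:
        self.tabs.setdefault(tab, []).append((name, payload))

    def tables(self):
        """Flat iterator over (tab, name, DataFrame) for archive storage."""
        for tab, items in self.tabs.items():
            for name, payload in items:
                if isinstance(payload, pd.DataFrame):
                    yield tab, name, payload

    def get(self, tab: str, name: str):
        for item_name, payload in self.tabs.get(tab, []):
            if item_name == name:
                return payload
        raise KeyError(f"no payload {name!r} in tab {tab!r}")


# ---------------------------------------------------------------------------
# operation registry
# ---------------------------------------------------------------------------


def _op_prep(ctx, section, config):
    matrix = ctx[section.data[0]]
    params = section.params
    imputation = ImputationConfig(seed=config.seed, **params.get("imputation", {}))
    processed, dropped = prep_mod.prepare(
        matrix,
        filter_mode=params.get("filter_mode", "max_missing"),
        filter_threshold=params.get("filter_threshold", 0.3),
        normalize_method=params.get("normalize", "median"),
        imputation=imputation,
    )
    ctx[section.name] = processed
    return {
        "processed_matrix": processed.values.reset_index(names="sample"),
        "dropped_features": pd.DataFrame({"feature": dropped}),
    }


def _op_summarize(ctx, section, config):
    summary = stats_mod.summarize_matrix(ctx[section.data[0]])
    return {
        "group_counts": summary["group_counts"].reset_index(names="group"),
        "dynamic_range": summary["dynamic_range"].reset_index(names="feature"),
        "cv": summary["cv"].reset_index(names="feature"),
    }


def _op_pca(ctx, section, config):
    result = stats_mod.pca(ctx[section.data[0]], **section.params)
    explained = pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(len(result.explained_variance_ratio))],
        "explained_variance_ratio": result.explained_variance_ratio,
    })
    return {
        "pca_scores": result.scores.reset_index(names="sample"),
        "pca_loadings": result.loadings.reset_index(names="feature"),
        "pca_explained": explained,
    }


def _op_differential(ctx, section, config):
    thresholds = stats_mod.SignificanceThresholds(**config.thresholds)
    diff = stats_mod.differential_regulation(
        ctx[section.data[0]], thresholds=thresholds, seed=config.seed, **section.params
    )
    ctx[section.name] = diff
    flagged = diff[diff["regulation"] != "ns"]
    volcano = diff[diff["log2fc"].notna()].copy()
    volcano["neg_log10_padj"] = -np.log10(volcano["padj"].clip(lower=1e-300))
    volcano = volcano[["feature", "contrast", "log2fc", "neg_log10_padj", "regulation"]]
    return {"differential": diff, "regulated": flagged.reset_index(drop=True),
            "volcano": volcano.reset_index(drop=True)}


def _op_correlation(ctx, section, config):
    network = net.correlation_network(ctx[section.data[0]], seed=config.seed,
                                      **section.params)
    clusters = pd.DataFrame(sorted(network.clusters.items()), columns=["node", "cluster"])
    return {"network_edges": network.edges, "network_clusters": clusters,
            "__network__": network}


def _op_clinical_summary(ctx, section, config):
    matrix: ExperimentMatrix = ctx[section.data[0]]
    values, groups = matrix.values, matrix.groups
    rows = []
    unique_groups = sorted(groups.unique())
    for var in values.columns:
        by_group = [values.loc[groups == g, var].dropna() for g in unique_groups]
        if any(len(v) < 2 for v in by_group):
            stat, p = float("nan"), 1.0
        elif len(unique_groups) == 2:
            stat, p = sps.ttest_ind(by_group[0], by_group[1], equal_var=True)
        else:
            stat, p = sps.f_oneway(*by_group)
        if np.isnan(p):
            stat, p = 0.0, 1.0
        row = {"variable": var, "statistic": stat, "pvalue": p}
        for g, vals in zip(unique_groups, by_group):
            row[f"mean_{g}"] = vals.mean()
        rows.append(row)
    table = pd.DataFrame(rows)
    table["padj"] = stats_mod.bh_fdr(table["pvalue"].to_numpy())
    return {"clinical_summary": table}


def _op_multiomics(ctx, section, config):
    proteomics: ExperimentMatrix = ctx[section.data[0]]
    clinical: ExperimentMatrix = ctx[section.data[1]]
    combined_values = pd.concat([clinical.values, proteomics.values], axis=1)
    combined = ExperimentMatrix(values=combined_values.dropna(axis=0),
                                sample_meta=proteomics.sample_meta)
    blocks = (list(clinical.values.columns), list(proteomics.values.columns))
    network = net.correlation_network(combined, blocks=blocks, seed=config.seed,
                                      **section.params)
    clusters = pd.DataFrame(sorted(network.clusters.items()), columns=["node", "cluster"])
    return {"clinical_protein_edges": network.edges, "clinical_protein_clusters": clusters,
            "__network__": network}


def _op_knowledge(ctx, section, config):
    diff = ctx[section.data[0]]
    graph: PropertyGraph = ctx["__graph__"]
    regulated = sorted(set(diff.loc[diff["regulation"] != "ns", "feature"].astype(str)))
    summary = net.build_knowledge_subgraph(graph, regulated, **section.params)
    return {"knowledge_ranking": summary.ranking, "knowledge_sankey": summary.sankey,
            "knowledge_edges": summary.edge_table, "__summary__": summary}


OPERATIONS = {
    "prep.process": _op_prep,
    "stats.summarize": _op_summarize,
    "stats.pca": _op_pca,
    "stats.differential": _op_differential,
    "networks.correlation": _op_correlation,
    "clinical.summary": _op_clinical_summary,
    "networks.multiomics": _op_multiomics,
    "knowledge.subgraph": _op_knowledge,
}

# which raw data types each section ultimately needs
_RAW_TYPES = ("proteomics", "clinical")


def _load_project(project_dir) -> dict:
    project_dir = Path(project_dir)
    ctx = {}
    manifest_path = project_dir / "manifest.tsv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    sample_meta = manifest.set_index("analytical_sample")[["group", "subject"]]
    prot_path = project_dir / "proteomics.tsv"
    if prot_path.exists():
        values = pd.read_csv(prot_path, sep="\t", index_col=0)
        ctx["proteomics"] = ExperimentMatrix(values=values,
                                             sample_meta=sample_meta.loc[values.index])
    clin_path = project_dir / "clinical.tsv"
    if clin_path.exists():
        values = pd.read_csv(clin_path, sep="\t", index_col=0)
        ctx["clinical"] = ExperimentMatrix(values=values,
                                           sample_meta=sample_meta.loc[values.index])
    return ctx


def run_default_pipeline(project_dir, config: AnalysisConfig | None = None,
                         graph: PropertyGraph | None = None,
                         seed: int | None = None) -> Report:
    """Run the configured analysis over a project directory.

    The directory holds ``manifest.tsv`` plus ``proteomics.tsv`` and/or
    ``clinical.tsv``.  Sections whose inputs are absent are skipped with a
    log entry (the multiomics tab therefore only appears when both data
    types are present); a config referencing an unknown operation is
    rejected before any execution.
    """
    config = config or default_config()
    if seed is not None:
        config = AnalysisConfig(sections=config.sections, seed=seed,
                                thresholds=config.thresholds,
                                raw={**config.raw, "seed": seed})
    unknown = [s.operation for s in config.sections if s.operation not in OPERATIONS]
    if unknown:
        raise ConfigError(f"unknown operations in config: {unknown}")
    available = set(_RAW_TYPES) | {s.name for s in config.sections} | {"__graph__"}
    for section in config.sections:
        for ref in section.data:
            if ref not in available:
                raise ConfigError(f"section {section.name!r} references unknown data {ref!r}")

    ctx = _load_project(project_dir)
    if graph is not None:
        ctx["__graph__"] = graph
    report = Report(provenance={
        "config": config.to_yaml(), "seed": config.seed, "skipped": [],
        "version": _package_version(),
    })
    present_types = [t for t in _RAW_TYPES if t in ctx]
    for section in config.sections:
        needs_graph = section.operation.startswith("knowledge.")
        missing = [ref for ref in section.data if ref not in ctx]
        if missing or (needs_graph and "__graph__" not in ctx):
            reason = f"missing inputs {missing}" if missing else "no knowledge graph"
            report.provenance["skipped"].append(f"{section.name}: {reason}")
            continue
        if section.tab == "multiomics" and len(present_types) < 2:
            report.provenance["skipped"].append(f"{section.name}: single data type")
            continue
        outputs = OPERATIONS[section.operation](ctx, section, config)
        if section.store:
            for name, payload in outputs.items():
                report.add(section.tab, name, payload)
    return report


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("protokg")
    except PackageNotFoundError:
        return "0.0.0+local"


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _frame_to_tsv_bytes(frame: pd.DataFrame) -> bytes:
    return frame.to_csv(sep="\t", index=False).encode("utf-8")


def _write_network_files(tab_dir: Path, name: str, graph: nx.Graph) -> None:
    relabeled = nx.relabel_nodes(graph, {n: str(n) for n in graph})
    nx.write_gml(relabeled, tab_dir / f"{name}.gml")
    nx.write_graphml(relabeled, tab_dir / f"{name}.graphml")
    payload = nx.node_link_data(relabeled, edges="links")
    with open(tab_dir / f"{name}.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def serialize_report(report: Report, out_dir, overwrite: bool = False) -> Path:
    """Write the per-tab folders and the HDF5 archive; returns archive path."""
    out_dir = Path(out_dir)
    archive = out_dir / "report.h5"
    if archive.exists() and not overwrite:
        raise FileExistsError(f"{archive} exists; pass overwrite=True to replace")
    out_dir.mkdir(parents=True, exist_ok=True)
    for tab, items in report.tabs.items():
        tab_dir = out_dir / tab
        tab_dir.mkdir(exist_ok=True)
        for name, payload in items:
            if isinstance(payload, pd.DataFrame):
                payload.to_csv(tab_dir / f"{name}.tsv", sep="\t", index=False)
            elif isinstance(payload, net.CorrelationNetwork):
                _write_network_files(tab_dir, "network", payload.graph)
            elif isinstance(payload, net.KnowledgeSummary):
                export_graph(payload.subgraph, tab_dir / "knowledge_subgraph.json",
                             format="json")
                _write_network_files(tab_dir, "knowledge_subgraph",
                                     payload.subgraph.to_networkx(directed=False))
            elif isinstance(payload, dict):
                with open(tab_dir / f"{name}.json", "w", encoding="utf-8") as fh:
                    json.dump(payload, fh, indent=1, sort_keys=True, default=str)
    with h5py.File(archive, "w", track_order=False) as h5:
        for tab, name, frame in report.tables():
            group = h5.require_group(tab)
            data = np.frombuffer(_frame_to_tsv_bytes(frame), dtype=np.uint8)
            group.create_dataset(name, data=data, track_times=False)
        prov = h5.create_group("provenance")
        for key in sorted(report.provenance):
            value = report.provenance[key]
            encoded = json.dumps(value, sort_keys=True, default=str).encode("utf-8")
            prov.create_dataset(key, data=np.frombuffer(encoded, dtype=np.uint8),
                                track_times=False)
    return archive


def load_report(archive_path) -> Report:
    """Rebuild a Report (tables + provenance) from its HDF5 archive."""
    import io

    report = Report()
    with h5py.File(archive_path, "r") as h5:
        for tab in h5:
            if tab == "provenance":
                for key in h5[tab]:
                    raw = bytes(h5[tab][key][()]).decode("utf-8")
                    report.provenance[key] = json.loads(raw)
                continue
            for name in h5[tab]:
                raw = bytes(h5[tab][name][()]).decode("utf-8")
                frame = pd.read_csv(io.StringIO(raw), sep="\t")
                report.add(tab, name, frame)
    return report
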