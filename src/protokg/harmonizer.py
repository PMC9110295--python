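"""Ontology ingestion, identifier mapping and experiment ingestion.

Ontologies arrive as OBO-format flat files and provide both the controlled
vocabulary (term ids, names, synonyms, cross-references) and the ``is_a``
hierarchy that is written into the graph as HAS_PARENT edges.  From a parsed
ontology a deterministic mapping dictionary is built that standardizes
free-text identifiers: primary names take precedence over synonyms, synonyms
over xrefs, and same-tier collisions resolve to the lexicographically
smallest term id (logged).  Lookup is exact-match on case-folded keys — no
fuzzy matching, determinism over recall.

Experiment ingestion mints internal identifiers for the subject /
biological-sample / analytical-sample hierarchy and writes one
HAS_QUANTIFIED edge per non-missing quantified cell, with the quantification
stored as the edge's ``value`` attribute.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

from .graph_store import PropertyGraph
from .prep import ExperimentMatrix

__all__ = [
    "OntologyTable",
    "MappingDictionary",
    "ProjectRegistry",
    "IngestReport",
    "OntologyFormatError",
    "IntegrityError",
    "parse_ontology",
    "build_mapping",
    "mint_identifiers",
    "ingest_experiment",
    "ingest_clinical",
    "ontology_to_graph",
]


class OntologyFormatError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass
class OntologyTable:
    """Parsed ontology: terms, is_a edges, and parse diagnostics."""

    terms: dict  # term_id -> dict(name, synonyms list, xrefs list)
    is_a: list  # (child_id, parent_id)
    obsolete_count: int = 0
    cycles: list = field(default_factory=list)


@dataclass
class MappingDictionary:
    """Case-folded external key -> canonical term id, with provenance."""

    entries: dict = field(default_factory=dict)  # key -> term_id
    provenance: dict = field(default_factory=dict)  # key -> name|synonym|xref
    collisions: list = field(default_factory=list)  # (key, kept_id, dropped_id)

    def lookup(self, key: str):
        """Exact case-folded lookup; returns None for unknown keys."""
        return self.entries.get(str(key).casefold())

    def __len__(self) -> int:
        return len(self.entries)


def _prescan_obo(path) -> tuple:
    """Line-oriented scan for diagnostics obonet does not report: [Term]
    stanzas missing an id (error with line number) and obsolete counts."""
    obsolete = 0
    stanza_line = None
    has_id = True  # header "stanza"
    stanza_obsolete = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("["):
                if not has_id:
                    raise OntologyFormatError(
                        f"{path}: [Term] stanza at line {stanza_line} has no id"
                    )
                obsolete += stanza_obsolete
                stanza_line = lineno
                has_id = line != "[Term]"
                stanza_obsolete = False
            elif line.startswith("id:"):
                has_id = True
            elif line.startswith("is_obsolete:") and line.split(":", 1)[1].strip() == "true":
                stanza_obsolete = True
    if not has_id:
        raise OntologyFormatError(f"{path}: [Term] stanza at line {stanza_line} has no id")
    return obsolete + stanza_obsolete,


def parse_ontology(path) -> OntologyTable:
    """Parse an OBO flat file into an :class:`OntologyTable`.

    Obsolete terms are excluded (count reported); is_a edges are checked for
    acyclicity and any cycles are reported, not fatal.
    """
    (obsolete_count,) = _prescan_obo(path)
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms = {}
    for term_id, data in sorted(graph.nodes(data=True)):
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.search(raw)
            synonyms.append(m.group(1) if m else raw)
        terms[term_id] = {
            "name": data.get("name", ""),
            "synonyms": synonyms,
            "xrefs": list(data.get("xref", [])),
        }
    is_a = sorted(
        (child, parent)
        for child, parent, key in graph.edges(keys=True)
        if key == "is_a" and child in terms and parent in terms
    )
    dag = nx.DiGraph(is_a)
    cycles = [sorted(c) for c in nx.simple_cycles(dag)]
    return OntologyTable(terms=terms, is_a=is_a, obsolete_count=obsolete_count,
                         cycles=sorted(cycles))


def build_mapping(ontology: OntologyTable) -> MappingDictionary:
    """Build the identifier-standardization dictionary from an ontology.

    A pure function of the parsed ontology: keys are case-folded names,
    synonyms and xrefs; precedence name > synonym > xref; same-tier ties go
    to the smallest term id and are logged as collisions.
    """
    mapping = MappingDictionary()
    tiers = (
        ("name", lambda rec: [rec["name"]] if rec["name"] else []),
        ("synonym", lambda rec: rec["synonyms"]),
        ("xref", lambda rec: rec["xrefs"]),
    )
    for tier_name, extractor in tiers:
        for term_id in sorted(ontology.terms):
            for raw_key in extractor(ontology.terms[term_id]):
                key = str(raw_key).casefold()
                if key in mapping.entries:
                    if mapping.entries[key] != term_id:
                        mapping.collisions.append((key, mapping.entries[key], term_id))
                    continue
                mapping.entries[key] = term_id
                mapping.provenance[key] = tier_name
    # every term id maps to itself so already-canonical inputs pass through
    for term_id in ontology.terms:
        mapping.entries.setdefault(term_id.casefold(), term_id)
        mapping.provenance.setdefault(term_id.casefold(), "id")
    return mapping


def ontology_to_graph(graph: PropertyGraph, ontology: OntologyTable, label: str) -> int:
    """Write ontology terms as ``label`` nodes and is_a pairs as HAS_PARENT
    edges; returns the number of edges added."""
    for term_id, rec in ontology.terms.items():
        graph.add_node(term_id, label, {"name": rec["name"]})
    for child, parent in ontology.is_a:
        graph.add_edge(child, parent, "HAS_PARENT")
    return len(ontology.is_a)


# ---------------------------------------------------------------------------
# internal identifiers
# ---------------------------------------------------------------------------


@dataclass
class ProjectRegistry:
    """Internal identifiers and design metadata for one project."""

    project_id: str
    subjects: dict  # external -> internal (S####)
    biological_samples: dict  # external -> internal (BS####)
    analytical_samples: dict  # external -> internal (AS####)
    sample_to_biosample: dict  # AS internal -> BS internal
    biosample_to_subject: dict  # BS internal -> S internal
    groups: dict  # AS internal -> group label
    timepoints: dict = field(default_factory=dict)  # BS internal -> timepoint
    diseases: tuple = ()
    tissues: tuple = ()

    def internal_analytical(self, external: str) -> str:
        return self.analytical_samples[external]


_REQUIRED_MANIFEST = ("subject", "biological_sample", "analytical_sample", "group")


def mint_identifiers(manifest: pd.DataFrame, project_number: int = 1) -> ProjectRegistry:
    """Mint deterministic internal identifiers from a project manifest.

    Internal ids are prefixed and zero-padded (P/S/BS/AS + counter) in
    manifest order; re-running on the same manifest yields an identical
    registry.  An analytical sample listed under two biological samples, or
    a biological sample under two subjects, is an integrity error.
    """
    for col in _REQUIRED_MANIFEST:
        if col not in manifest.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    project_id = f"P{project_number:04d}"
    subjects, biosamples, asamples = {}, {}, {}
    s2subj, a2bio, groups, timepoints = {}, {}, {}, {}
    for _, row in manifest.iterrows():
        subj_ext = str(row["subject"])
        bio_ext = str(row["biological_sample"])
        asm_ext = str(row["analytical_sample"])
        if subj_ext not in subjects:
            subjects[subj_ext] = f"S{len(subjects) + 1:04d}"
        if bio_ext not in biosamples:
            biosamples[bio_ext] = f"BS{len(biosamples) + 1:04d}"
            s2subj[biosamples[bio_ext]] = subjects[subj_ext]
        elif s2subj[biosamples[bio_ext]] != subjects[subj_ext]:
            raise IntegrityError(
                f"biological sample {bio_ext!r} listed under two subjects"
            )
        if asm_ext not in asamples:
            asamples[asm_ext] = f"AS{len(asamples) + 1:04d}"
            a2bio[asamples[asm_ext]] = biosamples[bio_ext]
            groups[asamples[asm_ext]] = str(row["group"])
        elif a2bio[asamples[asm_ext]] != biosamples[bio_ext]:
            raise IntegrityError(
                f"analytical sample {asm_ext!r} listed under two biological samples"
            )
        if "timepoint" in manifest.columns and not pd.isna(row.get("timepoint")):
            timepoints[biosamples[bio_ext]] = str(row["timepoint"])
    diseases = ()
    tissues = ()
    if "disease" in manifest.columns:
        diseases = tuple(sorted(set(manifest["disease"].dropna().astype(str))))
    if "tissue" in manifest.columns:
        tissues = tuple(sorted(set(manifest["tissue"].dropna().astype(str))))
    return ProjectRegistry(
        project_id=project_id, subjects=subjects, biological_samples=biosamples,
        analytical_samples=asamples, sample_to_biosample=a2bio,
        biosample_to_subject=s2subj, groups=groups, timepoints=timepoints,
        diseases=diseases, tissues=tissues,
    )


# ---------------------------------------------------------------------------
# experiment ingestion
# ---------------------------------------------------------------------------


@dataclass
class IngestReport:
    n_quantified_edges: int = 0
    unmapped_features: list = field(default_factory=list)
    mapped_features: int = 0


def _ensure_project_skeleton(graph: PropertyGraph, registry: ProjectRegistry) -> None:
    graph.add_node(registry.project_id, "Project", {"name": registry.project_id})
    for ext, internal in registry.subjects.items():
        graph.add_node(internal, "Subject", {"external_id": ext})
        graph.add_edge(registry.project_id, internal, "HAS_ENROLLED")
    for ext, internal in registry.biological_samples.items():
        graph.add_node(internal, "Biological_sample", {"external_id": ext})
        graph.add_edge(internal, registry.biosample_to_subject[internal], "BELONGS_TO_SUBJECT")
    for ext, internal in registry.analytical_samples.items():
        graph.add_node(internal, "Analytical_sample",
                       {"external_id": ext, "group": registry.groups[internal]})
        graph.add_edge(registry.sample_to_biosample[internal], internal, "SPLITTED_INTO")
    for disease in registry.diseases:
        graph.add_node(disease, "Disease", {})
        graph.add_edge(registry.project_id, disease, "STUDIES_DISEASE")
    for tissue in registry.tissues:
        graph.add_node(tissue, "Tissue", {})
        graph.add_edge(registry.project_id, tissue, "STUDIES_TISSUE")


def ingest_experiment(graph: PropertyGraph, registry: ProjectRegistry,
                      matrix: ExperimentMatrix,
                      mapping: MappingDictionary | None = None) -> IngestReport:
    """Write a quantified matrix into the graph as HAS_QUANTIFIED edges.

    One edge per non-missing (analytical sample, mapped protein) cell with
    the quantification as the edge ``value`` attribute; re-ingestion upserts
    (edge count unchanged).  Samples absent from the registry are an
    integrity error; unmapped features are reported, not fatal.
    """
    unknown = [s for s in matrix.values.index if s not in registry.analytical_samples]
    if unknown:
        raise IntegrityError(f"samples not in project registry: {unknown}")
    _ensure_project_skeleton(graph, registry)
    report = IngestReport()
    feature_targets = {}
    for feature in matrix.values.columns:
        target = mapping.lookup(feature) if mapping is not None else str(feature)
        if target is None:
            report.unmapped_features.append(feature)
        else:
            feature_targets[feature] = target
    report.mapped_features = len(feature_targets)
    for feature, target in feature_targets.items():
        if target not in graph:
            graph.add_node(target, "Protein", {"name": str(feature)})
    for sample_ext in matrix.values.index:
        internal = registry.analytical_samples[sample_ext]
        row = matrix.values.loc[sample_ext]
        for feature, target in feature_targets.items():
            value = row[feature]
            if pd.isna(value):
                continue
            graph.add_edge(internal, target, "HAS_QUANTIFIED", {"value": float(value)})
            report.n_quantified_edges += 1
    return report


def ingest_clinical(graph: PropertyGraph, registry: ProjectRegistry,
                    clinical: pd.DataFrame) -> int:
    """Store clinical variables as Clinical_variable nodes quantified on
    biological samples, mirroring the proteomics pattern; variable ids
    (SNOMED-style or free) are taken verbatim.  Index = biological sample
    external ids.  Returns the number of edges written."""
    n = 0
    _ensure_project_skeleton(graph, registry)
    for var in clinical.columns:
        graph.add_node(str(var), "Clinical_variable", {})
    for bio_ext in clinical.index:
        if str(bio_ext) not in registry.biological_samples:
            raise IntegrityError(f"biological sample {bio_ext!r} not in registry")
        internal = registry.biological_samples[str(bio_ext)]
        for var in clinical.columns:
            value = clinical.loc[bio_ext, var]
            if pd.isna(value):
                continue
            graph.add_edge(internal, str(var), "HAS_QUANTIFIED", {"value": float(value)})
            n += 1
    return n
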