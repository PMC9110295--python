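"""Treatment-prioritization workflow: upregulated proteins -> disease-linked
subset -> inhibitory drugs -> side-effect dissimilarity filter -> literature
triplet co-mention ranking.

Candidate drugs must inhibit at least one upregulated protein with a known
association to the studied disease.  Candidates are then compared with the
reference chemotherapy regimen by Jaccard similarity of side-effect sets
(union of the regimen drugs' side effects by default) and kept only when
strictly dissimilar (Jaccard < 0.2 by default).  Finally, publications
co-mentioning a (drug, target, disease) triplet rank the survivors: score =
maximum triplet co-mention count over the drug's targets, ties broken by
ascending Jaccard, then drug id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .graph_store import PropertyGraph

__all__ = [
    "DrugCandidate",
    "UpregulatedSelection",
    "SideEffectFilterResult",
    "ASSOCIATION_EDGE_TYPES",
    "INHIBITORY_ACTIONS",
    "disease_linked_upregulated",
    "inhibitors_for",
    "side_effect_dissimilarity_filter",
    "triplet_comention_rank",
    "prioritize_drugs",
]

# edge types that count as a protein-disease association
ASSOCIATION_EDGE_TYPES = frozenset({
    "ASSOCIATED_WITH", "ASSOCIATED_WITH_INTEGRATED",
    "DETECTED_IN_PATHOLOGY_SAMPLE", "IS_BIOMARKER_OF",
})
# drug action attribute values that count as inhibitory
INHIBITORY_ACTIONS = frozenset({"inhibition", "antagonist", "blocker"})
MENTION_TYPE = "MENTIONED_IN_PUBLICATION"


@dataclass
class DrugCandidate:
    drug: str
    targets: tuple  # upregulated disease-linked proteins hit
    side_effects: frozenset
    jaccard: float = float("nan")
    comention_count: int = 0
    rank: int = 0
    has_side_effect_data: bool = True


@dataclass
class UpregulatedSelection:
    proteins: set
    n_upregulated: int
    n_disease_linked: int


@dataclass
class SideEffectFilterResult:
    retained: list  # DrugCandidate, ascending jaccard
    excluded: list = field(default_factory=list)
    flagged_no_side_effects: list = field(default_factory=list)


def disease_linked_upregulated(graph: PropertyGraph, differential, disease: str
                               ) -> UpregulatedSelection:
    """Upregulated proteins with a known association to the disease.

    ``differential`` is a differential-regulation table with ``feature``
    and ``regulation`` columns; counts of all upregulated and of the
    disease-linked subset are reported alongside the selected set.
    """
    if disease not in graph:
        raise KeyError(f"unknown disease node {disease!r}")
    up = [str(f) for f in differential.loc[differential["regulation"] == "up", "feature"]]
    linked = set()
    for protein in up:
        if protein not in graph:
            continue
        for nbr, ty in graph.neighbors(protein, edge_types=ASSOCIATION_EDGE_TYPES):
            if nbr == disease:
                linked.add(protein)
                break
    return UpregulatedSelection(proteins=linked, n_upregulated=len(up),
                                n_disease_linked=len(linked))


def inhibitors_for(graph: PropertyGraph, proteins) -> dict:
    """Drugs connected to >= 1 input protein by an inhibitory ACTS_ON edge.

    Returns drug id -> sorted tuple of the input proteins it inhibits
    (multiplicity recorded by tuple length).
    """
    hits = {}
    targets = {p for p in proteins if p in graph}
    for s, t, ty, attrs in graph.edges:
        if ty != "ACTS_ON" or t not in targets:
            continue
        if str(attrs.get("action", "")).casefold() not in INHIBITORY_ACTIONS:
            continue
        hits.setdefault(s, set()).add(t)
    return {drug: tuple(sorted(prots)) for drug, prots in sorted(hits.items())}


def _side_effects_of(graph: PropertyGraph, drug: str) -> frozenset:
    return frozenset(
        nbr for nbr, _ty in graph.neighbors(drug, edge_types={"HAS_SIDE_EFFECT"})
    )


def side_effect_dissimilarity_filter(graph: PropertyGraph, candidates,
                                     reference_regimen, max_jaccard: float = 0.2,
                                     mode: str = "union") -> SideEffectFilterResult:
    """Keep candidates whose side effects are dissimilar to the regimen's.

    Per candidate: Jaccard between its side-effect set and the union of the
    regimen drugs' side effects (``mode='union'``, default) or the maximum
    per-regimen-drug Jaccard (``mode='per_drug'``); retained iff jaccard <
    max_jaccard (strictly).  Candidates without side-effect annotations are
    flagged and excluded rather than silently kept.  ``candidates`` may be a
    drug -> targets mapping (from :func:`inhibitors_for`) or an iterable of
    drug ids.
    """
    if mode not in ("union", "per_drug"):
        raise ValueError("mode must be 'union' or 'per_drug'")
    if isinstance(candidates, dict):
        cand_targets = {d: tuple(t) for d, t in candidates.items()}
    else:
        cand_targets = {d: () for d in candidates}
    regimen_sets = {d: _side_effects_of(graph, d) for d in sorted(reference_regimen)}
    union = frozenset().union(*regimen_sets.values()) if regimen_sets else frozenset()
    if not union:
        raise ValueError("reference regimen has no side-effect annotations; filter undefined")

    def jaccard(a: frozenset, b: frozenset) -> float:
        return len(a & b) / len(a | b) if (a or b) else 0.0

    retained, excluded, flagged = [], [], []
    for drug in sorted(cand_targets):
        ses = _side_effects_of(graph, drug)
        if mode == "union":
            j = jaccard(ses, union)
        else:
            j = max(jaccard(ses, rs) for rs in regimen_sets.values())
        candidate = DrugCandidate(drug=drug, targets=cand_targets[drug],
                                  side_effects=ses, jaccard=j,
                                  has_side_effect_data=bool(ses))
        if not ses:
            flagged.append(candidate)
            warnings.warn(f"candidate {drug} has no side-effect annotations; excluded")
            continue
        if j < max_jaccard:  # strict "less than" cutoff
            retained.append(candidate)
        else:
            excluded.append(candidate)
    retained.sort(key=lambda c: (c.jaccard, c.drug))
    return SideEffectFilterResult(retained=retained, excluded=excluded,
                                  flagged_no_side_effects=flagged)


def _publications_of(graph: PropertyGraph, entity: str) -> set:
    if entity not in graph:
        return set()
    return {nbr for nbr, _ty in graph.neighbors(entity, edge_types={MENTION_TYPE})}


def triplet_comention_rank(graph: PropertyGraph, candidates, disease: str) -> list:
    """Rank candidates by (drug, target, disease) literature co-mentions.

    A publication counts for a triplet only when it mentions all three
    entities.  Candidate score = max triplet count over its targets; final
    order score desc, jaccard asc, drug id asc; ranks are 1-based.
    """
    disease_pubs = _publications_of(graph, disease)
    ranked = []
    for cand in candidates:
        drug_pubs = _publications_of(graph, cand.drug)
        best = 0
        for target in cand.targets:
            best = max(best, len(drug_pubs & _publications_of(graph, target) & disease_pubs))
        ranked.append(replace(cand, comention_count=best))
    ranked.sort(key=lambda c: (-c.comention_count, c.jaccard, c.drug))
    for i, cand in enumerate(ranked, start=1):
        cand.rank = i
    return ranked


def prioritize_drugs(graph: PropertyGraph, differential, disease: str,
                     reference_regimen, max_jaccard: float = 0.2,
                     mode: str = "union") -> dict:
    """The full workflow; returns the ranked candidates plus stage reports."""
    selection = disease_linked_upregulated(graph, differential, disease)
    inhibitors = inhibitors_for(graph, selection.proteins)
    filtered = side_effect_dissimilarity_filter(graph, inhibitors, reference_regimen,
                                                max_jaccard=max_jaccard, mode=mode)
    ranked = triplet_comention_rank(graph, filtered.retained, disease)
    return {
        "selection": selection,
        "inhibitors": inhibitors,
        "filter": filtered,
        "ranked": ranked,
    }
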