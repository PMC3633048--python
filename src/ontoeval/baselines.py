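"""Null and reference predictors, and the normalized-rank aggregator.

None of these is a competing method: the prevalence predictor is a null
(identical output for every gene), the root-only predictor exists to
expose a metric degeneracy, the carry-forward predictor replays
pre-existing weak-evidence annotations, and the aggregator merely
averages other predictors' rankings after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .annotations import AnnotationSet, PredictionSet, TERM_CAP
from .errors import ValidationError
from .ontology import OntologyDAG


def prevalence_predictor(
    corpus: AnnotationSet,
    dag: OntologyDAG,
    targets: Iterable[str] | None = None,
    cap: int = TERM_CAP,
    algorithm: str = "prevalence",
) -> PredictionSet:
    """Score every term by its corpus-wide annotation frequency,
    identically for every target gene.

    The corpus must be propagated, so each namespace root scores exactly
    1.0 over genes annotated in that namespace.  Only the ``cap``
    highest-frequency terms per namespace are kept, ties broken by term
    id ascending.
    """
    if not corpus.propagated:
        raise ValidationError("prevalence requires a propagated corpus")
    if not corpus.assignments:
        raise ValidationError("empty corpus")
    counts: dict[str, int] = {}
    for terms in corpus.assignments.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    n = len(corpus.assignments)
    freq = {t: c / n for t, c in counts.items()}

    by_ns: dict[str, list[str]] = {}
    for t in freq:
        by_ns.setdefault(dag.namespace_of(t), []).append(t)
    kept: dict[str, float] = {}
    for ns, terms in by_ns.items():
        terms.sort(key=lambda t: (-freq[t], t))
        for t in terms[:cap]:
            kept[t] = freq[t]

    if targets is None:
        targets = sorted(corpus.assignments)
    scores = {g: dict(kept) for g in targets}
    return PredictionSet(algorithm=algorithm, scores=scores)


def root_only_predictor(
    dag: OntologyDAG,
    namespace: str,
    targets: Iterable[str],
    algorithm: str = "root-only",
) -> PredictionSet:
    """Predict only the namespace root, with score 1.0, for every target."""
    root = dag.root_of(namespace)
    return PredictionSet(
        algorithm=algorithm, scores={g: {root: 1.0} for g in targets}
    )


def iea_carryforward_predictor(
    prior: AnnotationSet,
    dag: OntologyDAG,
    algorithm: str = "iea-carryforward",
    lenient: bool = False,
) -> PredictionSet:
    """Replay each gene's pre-existing annotations, ancestor-closed, all
    with score 1.0.  Genes with no prior annotations make no predictions."""
    scores: dict[str, dict[str, float]] = {}
    for gene, terms in prior.assignments.items():
        closure = dag.propagate_annotation_set(terms, lenient=lenient)
        if closure:
            scores[gene] = {t: 1.0 for t in closure}
    return PredictionSet(algorithm=algorithm, scores=scores)


def species_incidence_predictor(
    corpus: AnnotationSet,
    dag: OntologyDAG,
    targets: Iterable[str] | None = None,
    species_of: Mapping[str, str] | None = None,
    algorithm: str = "species-incidence",
) -> PredictionSet:
    """Score each (gene, term) by the term's annotation frequency within
    the gene's species; all genes of a species share one ranking.

    A term unused in a species is a non-prediction for its genes.
    """
    if not corpus.propagated:
        raise ValidationError("species incidence requires a propagated corpus")
    species_of = dict(species_of) if species_of else dict(corpus.species_of)

    genes_by_species: dict[str, list[str]] = {}
    for gene in corpus.assignments:
        sp = corpus.species_of.get(gene)
        if sp is not None:
            genes_by_species.setdefault(sp, []).append(gene)

    freq_by_species: dict[str, dict[str, float]] = {}
    for sp, genes in genes_by_species.items():
        counts: dict[str, int] = {}
        for g in genes:
            for t in corpus.assignments[g]:
                counts[t] = counts.get(t, 0) + 1
        freq_by_species[sp] = {t: c / len(genes) for t, c in counts.items()}

    if targets is None:
        targets = sorted(corpus.assignments)
    scores: dict[str, dict[str, float]] = {}
    for gene in targets:
        sp = species_of.get(gene)
        if sp is None or sp not in freq_by_species:
            raise ValidationError(
                f"target {gene!r}: species {sp!r} absent from the corpus"
            )
        scores[gene] = dict(freq_by_species[sp])
    return PredictionSet(algorithm=algorithm, scores=scores)


# -- rank aggregation ----------------------------------------------------


@dataclass(frozen=True)
class AggregationSpec:
    """How to aggregate: rank terms within each gene (feeds the
    gene-centric score) or genes within each term (feeds AUROC).
    Missing items are always tied at the bottom."""

    axis: str = "genes-within-term"

    def __post_init__(self) -> None:
        if self.axis not in ("terms-within-gene", "genes-within-term"):
            raise ValidationError(f"unknown aggregation axis {self.axis!r}")


def _normalized_ranks(
    items: Sequence[str], score_maps: Sequence[Mapping[str, float]]
) -> np.ndarray:
    """Mean over algorithms of mid-rank positions normalized to [0, 1].

    Missing items share the bottom rank.  A single-item axis normalizes
    to 1.0 by convention.
    """
    n = len(items)
    means = np.zeros(n)
    for scores in score_maps:
        present = [scores[i] for i in items if i in scores]
        floor = (min(present) if present else 0.0) - 1.0
        values = np.array([scores.get(i, floor) for i in items])
        ranks = rankdata(values, method="average")
        norm = np.ones(n) if n == 1 else (ranks - 1.0) / (n - 1.0)
        means += norm
    return means / len(score_maps)


def _rerank_to_scores(items: Sequence[str], means: np.ndarray) -> dict[str, float]:
    """Re-rank mean normalized ranks and map into (0, 1] as rank/n."""
    ranks = rankdata(means, method="average")
    n = len(items)
    return {item: float(r / n) for item, r in zip(items, ranks)}


def aggregate_predictions(
    predsets: Sequence[PredictionSet],
    spec: AggregationSpec = AggregationSpec(),
    algorithm: str = "aggregate",
) -> PredictionSet:
    """Combine predictors by averaging normalized rankings.

    Along the chosen axis, each algorithm's items are mid-ranked (missing
    items tied at the bottom), ranks are normalized to [0, 1], averaged
    across algorithms and re-ranked; the final normalized mean ranks are
    emitted as scores in (0, 1].  Only (gene, term) pairs predicted by at
    least one algorithm are emitted.
    """
    if len(predsets) < 2:
        raise ValidationError("aggregation needs at least 2 predictor sets")
    universes = [p.genes for p in predsets if p.genes]
    shared = set.union(*universes) if universes else set()
    if universes and not set.intersection(*universes):
        raise ValidationError("predictor sets have disjoint target universes")

    scores: dict[str, dict[str, float]] = {}

    if spec.axis == "terms-within-gene":
        for gene in sorted(shared):
            terms = sorted(
                set().union(*(p.for_gene(gene).keys() for p in predsets))
            )
            if not terms:
                continue
            means = _normalized_ranks(
                terms, [p.for_gene(gene) for p in predsets]
            )
            final = _rerank_to_scores(terms, means)
            predicted = set().union(
                *(set(p.for_gene(gene)) for p in predsets)
            )
            scores[gene] = {t: final[t] for t in terms if t in predicted}
    else:
        genes = sorted(shared)
        all_terms = sorted(
            set().union(
                *(set(pt) for p in predsets for pt in p.scores.values())
            )
        )
        per_alg_by_term: list[dict[str, dict[str, float]]] = []
        for p in predsets:
            by_term: dict[str, dict[str, float]] = {}
            for g, per_term in p.scores.items():
                for t, s in per_term.items():
                    by_term.setdefault(t, {})[g] = s
            per_alg_by_term.append(by_term)
        for term in all_terms:
            maps = [by_term.get(term, {}) for by_term in per_alg_by_term]
            means = _normalized_ranks(genes, maps)
            final = _rerank_to_scores(genes, means)
            predicted = set().union(*(set(m) for m in maps))
            for g in genes:
                if g in predicted:
                    scores.setdefault(g, {})[term] = final[g]
    scores = {g: per for g, per in scores.items() if per}
    return PredictionSet(algorithm=algorithm, scores=scores)
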