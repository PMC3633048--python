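"""Shared fixtures: the toy DAG, the 4-gene corpus, and independent
brute-force oracles used to cross-check the package implementations.

The oracles deliberately avoid the package's own closure code: they work
on plain child->parents adjacency dicts with breadth-first search.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from ontoeval import AnnotationSet, OntologyDAG, Term

# -- toy world -----------------------------------------------------------
# root R; A, B is_a R; A1 is_a A; B1, B2 is_a B

TOY_EDGES = [("A", "R"), ("B", "R"), ("A1", "A"), ("B1", "B"), ("B2", "B")]
TOY_TERMS = ["R", "A", "B", "A1", "B1", "B2"]


@pytest.fixture(scope="session")
def toy_dag() -> OntologyDAG:
    return OntologyDAG(
        [Term(id=t, namespace="BP") for t in TOY_TERMS], TOY_EDGES
    )


@pytest.fixture(scope="session")
def c4_raw() -> AnnotationSet:
    return AnnotationSet(
        assignments={
            "g1": frozenset({"A1"}),
            "g2": frozenset({"A"}),
            "g3": frozenset({"B1"}),
            "g4": frozenset({"B2"}),
        }
    )


@pytest.fixture(scope="session")
def c4_propagated(toy_dag, c4_raw) -> AnnotationSet:
    return c4_raw.propagate(toy_dag)


# -- independent oracles -------------------------------------------------


def bfs_ancestors(parents_of: dict[str, list[str]], term: str) -> frozenset[str]:
    """Reflexive ancestor set by plain BFS on a child->parents dict."""
    seen = {term}
    queue = deque([term])
    while queue:
        t = queue.popleft()
        for p in parents_of.get(t, []):
            if p not in seen:
                seen.add(p)
                queue.append(p)
    return frozenset(seen)


def oracle_average_precision(
    parents_of: dict[str, list[str]],
    predicted: dict[str, float],
    truth: frozenset[str],
    explicit: set[str] | None = None,
) -> float:
    """Rectangle-sum average precision computed from first principles.

    Term scores are the max over submitted descendants (BFS enumeration),
    except explicitly submitted terms, which keep their submitted score;
    ``explicit=None`` means every submitted term is explicit.
    """
    if not predicted:
        return 0.0
    if explicit is None:
        explicit = set(predicted)
    scores: dict[str, float] = {}
    for term, score in predicted.items():
        for anc in bfs_ancestors(parents_of, term):
            scores[anc] = max(scores.get(anc, 0.0), score)
    for term in explicit:
        scores[term] = predicted[term]
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(predicted.values()), reverse=True):
        pred_set = {term for term, s in scores.items() if s >= t}
        hits = len(pred_set & truth)
        precision = hits / len(pred_set) if pred_set else 1.0
        recall = hits / len(truth)
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def oracle_auroc(
    pos_scores: list[float], neg_scores: list[float]
) -> float:
    """Pairwise (wins + half-ties) / (n_pos * n_neg)."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def oracle_propagated_scores(
    parents_of: dict[str, list[str]],
    all_terms: list[str],
    scored: dict[str, float],
) -> dict[str, float]:
    """Max over submitted descendants, by exhaustive enumeration."""
    out: dict[str, float] = {}
    for term in all_terms:
        implied = [
            s for t, s in scored.items() if term in bfs_ancestors(parents_of, t)
        ]
        if implied:
            out[term] = max(implied)
    return out


# -- random small DAGs for oracle-equivalence suites ---------------------


def random_dag(
    rng: np.random.Generator, n_terms: int, namespace: str = "BP"
) -> tuple[OntologyDAG, dict[str, list[str]]]:
    """Random layered DAG plus its plain adjacency dict for the oracles."""
    ids = [f"T{i}" for i in range(n_terms)]
    parents_of: dict[str, list[str]] = {}
    edges = []
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(3, i) + 1))
        choices = rng.choice(i, size=k, replace=False)
        parents_of[ids[i]] = [ids[int(j)] for j in choices]
        edges.extend((ids[i], ids[int(j)]) for j in choices)
    dag = OntologyDAG([Term(id=t, namespace=namespace) for t in ids], edges)
    return dag, parents_of
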