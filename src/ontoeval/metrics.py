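"""Assessment metrics.

Three families:

* gene-centric precision/recall over up-propagated term sets, summarized
  by average precision (the per-gene score);
* function-centric AUROC per term, via the Mann-Whitney statistic with
  mid-rank tie handling and non-predictions tied at the bottom;
* information-content informativeness of a gene's best prediction against
  a threshold set by the prevalence null, plus multifunctionality
  diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import rankdata, spearmanr

from .annotations import AnnotationSet, PredictionSet
from .errors import ValidationError
from .ontology import (
    InformationContentTable,
    OntologyDAG,
    lin_similarity,
    resnik_similarity,
)


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float


@dataclass
class PRCurve:
    """Precision/recall at each distinct score threshold, descending."""

    points: list[PRPoint]

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)


def gene_pr_curve(
    dag: OntologyDAG,
    predicted: Mapping[str, float],
    truth: frozenset[str] | set[str],
    explicit: Iterable[str] | None = None,
) -> PRCurve:
    """Precision-recall curve for one gene.

    ``predicted`` are the submitted term scores; ``truth`` the gene's
    ancestor-closed gold-standard terms.  Distinct submitted scores are
    swept descending; at each threshold the predicted set is the
    up-propagation of all terms whose (propagated, explicit-aware) score
    reaches the threshold.  Equal-scored terms enter together.
    """
    if not truth:
        raise ValidationError("truth set is empty; gene should be excluded upstream")
    if not predicted:
        return PRCurve(points=[])
    if explicit is None:
        explicit = set(predicted)
    full = dag.propagate_prediction_scores(predicted, explicit)

    thresholds = sorted(set(predicted.values()), reverse=True)
    points = []
    for t in thresholds:
        pred_set = {term for term, s in full.items() if s >= t}
        hits = len(pred_set & set(truth))
        points.append(
            PRPoint(
                threshold=t,
                precision=hits / len(pred_set),
                recall=hits / len(truth),
            )
        )
    return PRCurve(points=points)


def average_precision(curve: PRCurve) -> float:
    """Step-wise area under the PR curve: sum of precision * delta-recall.

    An empty curve (no predictions) scores 0 by convention.
    """
    ap = 0.0
    prev_recall = 0.0
    for pt in curve.points:
        ap += pt.precision * (pt.recall - prev_recall)
        prev_recall = pt.recall
    return ap


def cafa_score_summary(
    ap_by_gene: Mapping[str, float | None],
    missing_policy: str = "zero",
) -> float:
    """Mean per-gene average precision for one algorithm.

    ``None`` marks a gene with no predictions: it contributes 0 under the
    default ``zero`` policy and is dropped under ``exclude``.
    """
    if not ap_by_gene:
        raise ValidationError("no evaluation genes")
    if missing_policy == "zero":
        values = [0.0 if v is None else v for v in ap_by_gene.values()]
    elif missing_policy == "exclude":
        values = [v for v in ap_by_gene.values() if v is not None]
        if not values:
            raise ValidationError("all genes excluded under 'exclude' policy")
    else:
        raise ValidationError(f"unknown missing policy {missing_policy!r}")
    return float(np.mean(values))


# -- function-centric AUROC ----------------------------------------------


@dataclass(frozen=True)
class TermAUROC:
    term: str
    n_pos: int
    n_neg: int
    auroc: float


def term_auroc(
    term: str,
    scores_by_gene: Mapping[str, float],
    labels: Mapping[str, bool],
) -> TermAUROC:
    """AUROC of one term's gene ranking (Mann-Whitney with mid-ranks).

    ``labels`` defines the evaluation genes and their positive/negative
    status; genes absent from ``scores_by_gene`` are non-predictions and
    are imputed a common value below every submitted score, so they all
    tie at the bottom of the ranking.
    """
    genes = list(labels)
    pos = [g for g in genes if labels[g]]
    neg = [g for g in genes if not labels[g]]
    if not pos or not neg:
        raise ValidationError(
            f"term {term!r}: AUROC undefined without both positives and negatives"
        )
    present = [scores_by_gene[g] for g in genes if g in scores_by_gene]
    floor = (min(present) if present else 0.0) - 1.0
    values = np.array([scores_by_gene.get(g, floor) for g in genes])
    ranks = rankdata(values, method="average")
    rank_sum_pos = ranks[[labels[g] for g in genes]].sum()
    n_pos, n_neg = len(pos), len(neg)
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return TermAUROC(
        term=term, n_pos=n_pos, n_neg=n_neg, auroc=float(u / (n_pos * n_neg))
    )


def select_evaluable_terms(
    gold: AnnotationSet, min_members: int = 10, max_members: int = 100
) -> set[str]:
    """Terms annotated to between ``min_members`` and ``max_members``
    evaluation genes, inclusive, in a propagated gold standard."""
    if not gold.assignments:
        raise ValidationError("empty gold standard")
    counts: dict[str, int] = {}
    for terms in gold.assignments.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t for t, c in counts.items() if min_members <= c <= max_members}


# -- informativeness -----------------------------------------------------


@dataclass
class InformativenessResult:
    gene: str
    algorithm: str
    best_score: float
    best_pair: tuple[str, str] | None
    informative: bool = False


def _top_n_terms(predicted: Mapping[str, float], top_n: int) -> list[str]:
    # deterministic: score descending, then term id ascending
    ordered = sorted(predicted.items(), key=lambda kv: (-kv[1], kv[0]))
    return [t for t, _ in ordered[:top_n]]


def informativeness_score(
    dag: OntologyDAG,
    ic: InformationContentTable,
    predicted: Mapping[str, float],
    truth: frozenset[str] | set[str],
    top_n: int = 10,
    measure: str = "resnik",
) -> tuple[float, tuple[str, str] | None]:
    """Best semantic similarity between a top-N predicted term and any
    true term.  A gene with no predictions scores 0 (never informative)."""
    if not truth:
        raise ValidationError("truth set is empty")
    if measure == "resnik":
        sim = resnik_similarity
    elif measure == "lin":
        sim = lin_similarity
    else:
        raise ValidationError(f"unknown similarity measure {measure!r}")
    best = 0.0
    best_pair: tuple[str, str] | None = None
    for p in _top_n_terms(predicted, top_n):
        ns = dag.namespace_of(p)
        for t in truth:
            if dag.namespace_of(t) != ns:
                continue
            s = sim(dag, ic, p, t)
            if best_pair is None or s > best:
                best, best_pair = s, (p, t)
    return best, best_pair


def informativeness_threshold(
    dag: OntologyDAG,
    ic: InformationContentTable,
    prevalence: PredictionSet,
    truths: Mapping[str, frozenset[str]],
    top_n: int = 10,
    measure: str = "resnik",
) -> float:
    """The null threshold: the best informativeness score the prevalence
    predictor achieves on *any* evaluation gene."""
    if not truths:
        raise ValidationError("empty evaluation set")
    tau = 0.0
    for gene, truth in truths.items():
        score, _ = informativeness_score(
            dag, ic, prevalence.for_gene(gene), truth, top_n=top_n, measure=measure
        )
        tau = max(tau, score)
    return tau


def informativeness_results(
    dag: OntologyDAG,
    ic: InformationContentTable,
    predset: PredictionSet,
    truths: Mapping[str, frozenset[str]],
    tau: float,
    top_n: int = 10,
    measure: str = "resnik",
) -> list[InformativenessResult]:
    """Per-gene informativeness flags for one algorithm against a common
    threshold ``tau`` (strict inequality)."""
    results = []
    for gene, truth in truths.items():
        score, pair = informativeness_score(
            dag, ic, predset.for_gene(gene), truth, top_n=top_n, measure=measure
        )
        results.append(
            InformativenessResult(
                gene=gene,
                algorithm=predset.algorithm,
                best_score=score,
                best_pair=pair,
                informative=score > tau,
            )
        )
    return results


def informativeness_rate(results: Iterable[InformativenessResult]) -> float:
    """Fraction of evaluation genes whose best prediction beat the null."""
    results = list(results)
    if not results:
        raise ValidationError("no informativeness results")
    return sum(r.informative for r in results) / len(results)


def informative_overlap_counts(
    results_by_algorithm: Mapping[str, Iterable[InformativenessResult]],
) -> dict[str, int]:
    """Per gene, how many algorithms flagged it informative."""
    counts: dict[str, int] = {}
    for results in results_by_algorithm.values():
        for r in results:
            counts.setdefault(r.gene, 0)
            if r.informative:
                counts[r.gene] += 1
    return counts


# -- multifunctionality --------------------------------------------------


def multifunctionality_score(corpus: AnnotationSet, gene: str) -> int:
    """Number of propagated terms annotated to a gene (0 if unknown)."""
    if not corpus.propagated:
        raise ValidationError("multifunctionality requires a propagated corpus")
    return len(corpus.assignments.get(gene, ()))


def multifunctionality_correlation(
    term_mf: Mapping[str, float],
    informative_gain: Mapping[str, float],
) -> float:
    """Spearman rank correlation between term-level mean member
    multifunctionality and term-level informative-gain counts."""
    common = sorted(set(term_mf) & set(informative_gain))
    if len(common) < 3:
        raise ValidationError("need at least 3 terms with defined values")
    x = [term_mf[t] for t in common]
    y = [informative_gain[t] for t in common]
    rho = spearmanr(x, y).statistic
    return float(rho)
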