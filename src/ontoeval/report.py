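"""End-to-end evaluation pipeline and TSV report writers.

Ties the stages together: target selection, information content from the
prior corpus, the prevalence null and its informativeness threshold, and
per-algorithm gene-centric / term-centric / informativeness tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .annotations import (
    AnnotationSet,
    PredictionSet,
    STRONG_EVIDENCE_CODES,
    select_evaluation_targets,
)
from .baselines import prevalence_predictor
from .errors import ValidationError
from .metrics import (
    InformativenessResult,
    TermAUROC,
    average_precision,
    cafa_score_summary,
    gene_pr_curve,
    informativeness_rate,
    informativeness_results,
    informativeness_threshold,
    select_evaluable_terms,
    term_auroc,
)
from .ontology import InformationContentTable, OntologyDAG, information_content


@dataclass
class RunConfig:
    """Serializable knobs for one evaluation run."""

    namespace: str = "BP"
    strong_codes: tuple[str, ...] = tuple(sorted(STRONG_EVIDENCE_CODES))
    top_n: int = 10
    similarity: str = "resnik"
    term_min: int = 10
    term_max: int = 100
    ap_missing: str = "zero"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class AlgorithmReport:
    algorithm: str
    ap_by_gene: dict[str, float | None]
    mean_ap: float
    aurocs: list[TermAUROC]
    mean_auroc: float | None
    informativeness: list[InformativenessResult]
    informative_rate: float


@dataclass
class EvaluationReport:
    config: RunConfig
    tau: float
    targets: list[str]
    evaluable_terms: list[str]
    algorithms: list[AlgorithmReport] = field(default_factory=list)

    # -- writers ---------------------------------------------------------

    def write_per_gene(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\talgorithm\tap\tbest_sim\tinformative\n")
            for rep in self.algorithms:
                info = {r.gene: r for r in rep.informativeness}
                for gene in self.targets:
                    ap = rep.ap_by_gene.get(gene)
                    r = info.get(gene)
                    fh.write(
                        f"{gene}\t{rep.algorithm}\t"
                        f"{'' if ap is None else format(ap, '.6f')}\t"
                        f"{r.best_score:.6f}\t{int(r.informative)}\n"
                        if r is not None
                        else f"{gene}\t{rep.algorithm}\t"
                        f"{'' if ap is None else format(ap, '.6f')}\t\t\n"
                    )

    def write_per_term(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("term\talgorithm\tn_pos\tn_neg\tauroc\n")
            for rep in self.algorithms:
                for a in rep.aurocs:
                    fh.write(
                        f"{a.term}\t{rep.algorithm}\t{a.n_pos}\t{a.n_neg}\t"
                        f"{a.auroc:.6f}\n"
                    )

    def write_summary(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "algorithm\tmean_ap\tmean_auroc\tinformative_rate\ttau\n"
            )
            for rep in self.algorithms:
                auroc = "" if rep.mean_auroc is None else f"{rep.mean_auroc:.6f}"
                fh.write(
                    f"{rep.algorithm}\t{rep.mean_ap:.6f}\t{auroc}\t"
                    f"{rep.informative_rate:.6f}\t{self.tau:.6f}\n"
                )

    def write_all(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.write_per_gene(out_dir / "per_gene.tsv")
        self.write_per_term(out_dir / "per_term.tsv")
        self.write_summary(out_dir / "summary.tsv")
        (out_dir / "config.json").write_text(self.config.to_json() + "\n")


def evaluation_truths(
    before: AnnotationSet,
    after: AnnotationSet,
    dag: OntologyDAG,
    strong_codes=STRONG_EVIDENCE_CODES,
) -> dict[str, frozenset[str]]:
    """Closure of each evaluation target's newly strong terms."""
    targets = select_evaluation_targets(before, after, strong_codes)
    truths: dict[str, frozenset[str]] = {}
    for gene in sorted(targets):
        new_strong = after.strong_terms(gene, strong_codes) - before.strong_terms(
            gene, strong_codes
        )
        closure = dag.propagate_annotation_set(new_strong, lenient=True)
        if closure:
            truths[gene] = closure
    return truths


def mean_ap_for_predset(
    dag: OntologyDAG,
    predset: PredictionSet,
    truths: Mapping[str, frozenset[str]],
    missing_policy: str = "zero",
) -> tuple[dict[str, float | None], float]:
    """Per-gene average precision and its mean over evaluation genes."""
    ap_by_gene: dict[str, float | None] = {}
    for gene, truth in truths.items():
        predicted = predset.for_gene(gene)
        if not predicted:
            ap_by_gene[gene] = None
            continue
        curve = gene_pr_curve(
            dag, predicted, truth, explicit=predset.explicit_terms.get(gene)
        )
        ap_by_gene[gene] = average_precision(curve)
    return ap_by_gene, cafa_score_summary(ap_by_gene, missing_policy)


def aurocs_for_predset(
    dag: OntologyDAG,
    predset: PredictionSet,
    truths: Mapping[str, frozenset[str]],
    evaluable_terms: Sequence[str],
) -> list[TermAUROC]:
    """Term-centric AUROCs over the evaluation targets.

    Predictions are up-propagated (explicit scores retained) before genes
    are ranked for each term; terms lacking a positive or a negative are
    skipped.
    """
    propagated: dict[str, dict[str, float]] = {}
    for g in truths:
        submitted = predset.for_gene(g)
        if submitted:
            propagated[g] = dag.propagate_prediction_scores(
                submitted, predset.explicit_terms.get(g, set(submitted))
            )
    out = []
    for term in sorted(evaluable_terms):
        labels = {g: term in truth for g, truth in truths.items()}
        if not any(labels.values()) or all(labels.values()):
            continue
        scores = {
            g: propagated[g][term]
            for g in truths
            if g in propagated and term in propagated[g]
        }
        out.append(term_auroc(term, scores, labels))
    return out


def evaluate(
    dag: OntologyDAG,
    before: AnnotationSet,
    after: AnnotationSet,
    predsets: Sequence[PredictionSet],
    config: RunConfig | None = None,
    ic: InformationContentTable | None = None,
    prevalence: PredictionSet | None = None,
) -> EvaluationReport:
    """Run the full assessment for a set of prediction submissions.

    ``before`` and ``after`` are raw annotation sets (mixed evidence)
    around the waiting period; targets, truths, the IC table, the
    prevalence null and its threshold are all derived here unless
    supplied.
    """
    config = config or RunConfig()
    truths = evaluation_truths(
        before, after, dag, strong_codes=set(config.strong_codes)
    )
    if not truths:
        raise ValidationError("no evaluation targets with non-empty truth")
    targets = sorted(truths)

    prior_propagated = before.propagate(dag, lenient=True)
    if ic is None:
        ic = information_content(dag, prior_propagated)
    if prevalence is None:
        prevalence = prevalence_predictor(prior_propagated, dag, targets=targets)

    tau = informativeness_threshold(
        dag, ic, prevalence, truths,
        top_n=config.top_n, measure=config.similarity,
    )

    gold = AnnotationSet(assignments=dict(truths), propagated=True)
    evaluable = sorted(
        select_evaluable_terms(gold, config.term_min, config.term_max)
    )

    report = EvaluationReport(
        config=config, tau=tau, targets=targets, evaluable_terms=evaluable
    )
    for predset in predsets:
        ap_by_gene, mean_ap = mean_ap_for_predset(
            dag, predset, truths, missing_policy=config.ap_missing
        )
        aurocs = aurocs_for_predset(dag, predset, truths, evaluable)
        mean_auroc = (
            sum(a.auroc for a in aurocs) / len(aurocs) if aurocs else None
        )
        info = informativeness_results(
            dag, ic, predset, truths, tau,
            top_n=config.top_n, measure=config.similarity,
        )
        report.algorithms.append(
            AlgorithmReport(
                algorithm=predset.algorithm,
                ap_by_gene=ap_by_gene,
                mean_ap=mean_ap,
                aurocs=aurocs,
                mean_auroc=mean_auroc,
                informativeness=info,
                informative_rate=informativeness_rate(info),
            )
        )
    return report
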