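"""Tests for the assessment metrics: PR curves / average precision,
term-centric AUROC, informativeness against the prevalence null, and
multifunctionality diagnostics."""

import numpy as np
import pytest

from ontoeval import (
    AnnotationSet,
    PredictionSet,
    ValidationError,
    average_precision,
    cafa_score_summary,
    gene_pr_curve,
    information_content,
    informativeness_rate,
    informativeness_results,
    informativeness_score,
    informativeness_threshold,
    multifunctionality_correlation,
    multifunctionality_score,
    prevalence_predictor,
    select_evaluable_terms,
    term_auroc,
)
from ontoeval.metrics import PRCurve, PRPoint

from conftest import (
    oracle_auroc,
    oracle_average_precision,
    random_dag,
)


@pytest.fixture(scope="module")
def truth_g(toy_dag):
    # truth closure of raw {A1}
    return toy_dag.ancestors("A1")


class TestGenePRCurve:
    def test_perfect_single_prediction(self, toy_dag, truth_g):
        curve = gene_pr_curve(toy_dag, {"A1": 0.9}, truth_g)
        assert curve.points == [PRPoint(0.9, 1.0, 1.0)]

    def test_wrong_branch_overlaps_only_at_root(self, toy_dag, truth_g):
        curve = gene_pr_curve(toy_dag, {"B1": 0.9}, truth_g)
        assert curve.points == [
            PRPoint(0.9, pytest.approx(1 / 3), pytest.approx(1 / 3))
        ]

    def test_root_only_always_precise(self, toy_dag, truth_g):
        curve = gene_pr_curve(toy_dag, {"R": 1.0}, truth_g)
        (pt,) = curve.points
        assert pt.precision == 1.0
        assert pt.recall == pytest.approx(1 / 3)

    def test_empty_truth_rejected(self, toy_dag):
        with pytest.raises(ValidationError):
            gene_pr_curve(toy_dag, {"A1": 0.9}, frozenset())

    def test_thresholds_descend_and_recall_never_drops(self, toy_dag, truth_g):
        rng = np.random.default_rng(3)
        terms = toy_dag.active_terms()
        for _ in range(20):
            k = int(rng.integers(1, len(terms) + 1))
            predicted = {
                t: float(rng.uniform(0.01, 1.0))
                for t in rng.choice(terms, size=k, replace=False)
            }
            curve = gene_pr_curve(toy_dag, predicted, truth_g)
            thresholds = [p.threshold for p in curve.points]
            recalls = [p.recall for p in curve.points]
            assert thresholds == sorted(thresholds, reverse=True)
            assert all(b >= a - 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_explicit_lower_score_delays_entry(self, toy_dag, truth_g):
        # A explicitly scored below A1: at threshold 0.9 A is excluded
        curve = gene_pr_curve(
            toy_dag, {"A1": 0.9, "A": 0.4}, truth_g, explicit={"A1", "A"}
        )
        first = curve.points[0]
        # propagated set at 0.9 is {A1, R} (A kept at its submitted 0.4)
        assert first.precision == 1.0
        assert first.recall == pytest.approx(2 / 3)


class TestAveragePrecision:
    def test_perfect_curve(self):
        assert average_precision(PRCurve([PRPoint(0.5, 1.0, 1.0)])) == 1.0

    def test_root_only_toy_curve(self):
        assert average_precision(
            PRCurve([PRPoint(1.0, 1.0, 1 / 3)])
        ) == pytest.approx(1 / 3)

    def test_no_predictions(self):
        assert average_precision(PRCurve([])) == 0.0

    def test_truth_closure_prediction_scores_one(self, toy_dag, truth_g):
        for score in (0.2, 0.77, 1.0):
            curve = gene_pr_curve(
                toy_dag, {t: score for t in truth_g}, truth_g
            )
            assert average_precision(curve) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, toy_dag, truth_g):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            dag, parents_of = random_dag(rng, n)
            terms = dag.active_terms()
            truth_seed = terms[int(rng.integers(len(terms)))]
            truth = dag.ancestors(truth_seed)
            k = int(rng.integers(1, min(8, n) + 1))
            predicted = {
                t: float(rng.integers(1, 11) / 10.0)  # force ties
                for t in rng.choice(terms, size=k, replace=False)
            }
            # explicit = all submitted (default) and explicit = none
            for explicit in (None, set()):
                got = average_precision(
                    gene_pr_curve(dag, predicted, truth, explicit=explicit)
                )
                want = oracle_average_precision(
                    parents_of, predicted, truth, explicit=explicit
                )
                assert got == pytest.approx(want, abs=1e-12)


class TestCafaScoreSummary:
    def test_simple_mean(self):
        assert cafa_score_summary({"g1": 1.0, "g2": 0.0}) == 0.5

    def test_all_perfect(self):
        assert cafa_score_summary({"g1": 1.0, "g2": 1.0}) == 1.0

    def test_three_gene_fixture(self, toy_dag):
        truths = {
            "g1": toy_dag.ancestors("A1"),
            "g2": toy_dag.ancestors("A1"),
            "g3": toy_dag.ancestors("A1"),
        }
        predictions = {
            "g1": {"A1": 0.9},  # AP 1
            "g2": {"R": 1.0},   # AP 1/3
            "g3": {},           # no predictions -> 0
        }
        aps = {
            g: average_precision(gene_pr_curve(toy_dag, p, truths[g]))
            if p
            else None
            for g, p in predictions.items()
        }
        assert cafa_score_summary(aps) == pytest.approx(4 / 9)

    def test_missing_policies(self):
        scores = {"g1": 1.0, "g2": None}
        assert cafa_score_summary(scores, "zero") == 0.5
        assert cafa_score_summary(scores, "exclude") == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            cafa_score_summary({})


class TestTermAUROC:
    def test_perfect_separation(self):
        res = term_auroc(
            "t",
            {"p": 0.9, "n1": 0.1, "n2": 0.2},
            {"p": True, "n1": False, "n2": False},
        )
        assert res.auroc == 1.0
        assert (res.n_pos, res.n_neg) == (1, 2)

    def test_identical_scores_give_half(self):
        genes = {f"g{i}": (i % 2 == 0) for i in range(10)}
        res = term_auroc("t", {g: 0.7 for g in genes}, genes)
        assert res.auroc == 0.5

    def test_enumerated_half(self):
        res = term_auroc(
            "t",
            {"p": 0.5, "n1": 0.9, "n2": 0.1},
            {"p": True, "n1": False, "n2": False},
        )
        assert res.auroc == 0.5

    def test_non_predictions_tied_at_bottom(self):
        # positive unpredicted, negatives predicted -> AUROC 0
        res = term_auroc("t", {"n1": 0.2}, {"p": True, "n1": False})
        assert res.auroc == 0.0
        # both unpredicted -> tie -> 0.5
        res = term_auroc("t", {}, {"p": True, "n1": False})
        assert res.auroc == 0.5

    def test_requires_both_classes(self):
        with pytest.raises(ValidationError):
            term_auroc("t", {"g": 0.5}, {"g": True})

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(4, 15))
            labels = {f"g{i}": bool(rng.integers(2)) for i in range(n)}
            if len(set(labels.values())) < 2:
                labels["g0"], labels["g1"] = True, False
            scores = {
                g: float(rng.integers(1, 6) / 10.0)
                for g in labels
                if rng.random() < 0.8
            }
            base = term_auroc("t", scores, labels).auroc
            squashed = {g: s**3 / 2 + 0.1 for g, s in scores.items()}
            assert term_auroc("t", squashed, labels).auroc == pytest.approx(base)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(2, 21))
            labels = {f"g{i}": bool(rng.integers(2)) for i in range(n)}
            if all(labels.values()) or not any(labels.values()):
                continue
            scores = {
                g: float(rng.integers(1, 8) / 10.0)
                for g in labels
                if rng.random() < 0.7
            }
            got = term_auroc("t", scores, labels).auroc
            floor = min(scores.values(), default=1.0) - 1.0
            pos = [scores.get(g, floor) for g, v in labels.items() if v]
            neg = [scores.get(g, floor) for g, v in labels.items() if not v]
            assert got == pytest.approx(oracle_auroc(pos, neg), abs=1e-12)


class TestSelectEvaluableTerms:
    @pytest.mark.parametrize(
        "n_genes,included", [(9, False), (10, True), (100, True), (101, False)]
    )
    def test_membership_window(self, n_genes, included):
        gold = AnnotationSet(
            assignments={
                f"g{i}": frozenset({"T", f"pad{i}"}) for i in range(n_genes)
            },
            propagated=True,
        )
        terms = select_evaluable_terms(gold)
        assert ("T" in terms) is included


@pytest.fixture(scope="module")
def ic(toy_dag, c4_propagated):
    return information_content(toy_dag, c4_propagated)


@pytest.fixture(scope="module")
def prevalence(toy_dag, c4_propagated):
    return prevalence_predictor(
        c4_propagated, toy_dag, targets=["g1", "g2", "g3", "g4"]
    )


class TestInformativeness:
    def test_score_equals_ic_of_exact_match(self, toy_dag, ic):
        score, pair = informativeness_score(
            toy_dag, ic, {"A1": 0.9}, toy_dag.ancestors("A1")
        )
        assert score == pytest.approx(ic.ic["A1"])
        assert pair == ("A1", "A1")

    def test_wrong_branch_scores_zero(self, toy_dag, ic):
        score, _ = informativeness_score(
            toy_dag, ic, {"B1": 0.9}, toy_dag.ancestors("A1")
        )
        assert score == 0.0

    def test_no_predictions_scores_zero(self, toy_dag, ic):
        score, pair = informativeness_score(
            toy_dag, ic, {}, toy_dag.ancestors("A1")
        )
        assert score == 0.0 and pair is None

    def test_threshold_on_c4_fixture(self, toy_dag, ic, prevalence):
        # prevalence includes A1, so for truth {A1, A, R} tau = ic(A1) = 2
        tau = informativeness_threshold(
            toy_dag, ic, prevalence, {"g1": toy_dag.ancestors("A1")}, top_n=10
        )
        assert tau == pytest.approx(2.0)

    def test_threshold_zero_when_only_root_matches(self, toy_dag, ic):
        root_pred = PredictionSet(algorithm="r", scores={"g1": {"B1": 1.0}})
        tau = informativeness_threshold(
            toy_dag, ic, root_pred, {"g1": toy_dag.ancestors("A1")}
        )
        assert tau == 0.0

    def test_threshold_invariant_to_duplicated_gene(self, toy_dag, ic, prevalence):
        truths = {"g1": toy_dag.ancestors("A1")}
        tau1 = informativeness_threshold(toy_dag, ic, prevalence, truths)
        prev2 = PredictionSet(
            algorithm="prevalence",
            scores={
                "g1": dict(prevalence.for_gene("g1")),
                "g2": dict(prevalence.for_gene("g1")),
            },
        )
        truths2 = {"g1": truths["g1"], "g2": truths["g1"]}
        tau2 = informativeness_threshold(toy_dag, ic, prev2, truths2)
        assert tau1 == tau2

    def test_prevalence_never_informative_against_own_tau(
        self, toy_dag, ic, prevalence, c4_propagated
    ):
        truths = {
            g: c4_propagated.assignments[g] for g in ("g1", "g2", "g3", "g4")
        }
        tau = informativeness_threshold(toy_dag, ic, prevalence, truths)
        results = informativeness_results(
            toy_dag, ic, prevalence, truths, tau
        )
        assert informativeness_rate(results) == 0.0

    def test_rate_counts(self, toy_dag, ic):
        from ontoeval.metrics import InformativenessResult

        results = [
            InformativenessResult("g1", "x", 3.0, None, informative=True),
            InformativenessResult("g2", "x", 0.0, None, informative=False),
            InformativenessResult("g3", "x", 2.5, None, informative=True),
            InformativenessResult("g4", "x", 0.1, None, informative=False),
        ]
        assert informativeness_rate(results) == 0.5


class TestMultifunctionality:
    def test_counts_propagated_terms(self, c4_propagated):
        assert multifunctionality_score(c4_propagated, "g1") == 3

    def test_unknown_gene_zero(self, c4_propagated):
        assert multifunctionality_score(c4_propagated, "nope") == 0

    def test_invariant_under_repropagation(self, toy_dag, c4_propagated):
        again = c4_propagated.propagate(toy_dag)
        for g in c4_propagated.genes:
            assert multifunctionality_score(
                again, g
            ) == multifunctionality_score(c4_propagated, g)

    def test_identical_rankings(self):
        x = {f"t{i}": float(i) for i in range(5)}
        assert multifunctionality_correlation(x, dict(x)) == pytest.approx(1.0)

    def test_reversed_rankings(self):
        x = {f"t{i}": float(i) for i in range(5)}
        y = {f"t{i}": float(-i) for i in range(5)}
        assert multifunctionality_correlation(x, y) == pytest.approx(-1.0)

    def test_one_swap_brute_force_spearman(self):
        # ranks x = 1..5, y swaps the last two: d^2 sums to 2
        x = {f"t{i}": float(i) for i in range(1, 6)}
        y = {"t1": 1.0, "t2": 2.0, "t3": 3.0, "t4": 5.0, "t5": 4.0}
        expected = 1 - 6 * 2 / (5 * (25 - 1))
        assert multifunctionality_correlation(x, y) == pytest.approx(expected)

    def test_too_few_terms_rejected(self):
        with pytest.raises(ValidationError):
            multifunctionality_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
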