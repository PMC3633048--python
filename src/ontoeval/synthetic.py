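"""Synthetic benchmark worlds with known ground truth.

Generates a layered random ontology, a mixed-evidence annotation corpus
with heavy-tailed per-gene term counts, a waiting-period gold-standard
update restricted to strong evidence codes, and families of simulated
predictors.  Everything is driven by one integer seed that fans out to
per-component sub-seeds, so regenerating a world is bit-identical and
adding a predictor does not perturb the corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np

from .annotations import (
    AnnotationSet,
    PredictionSet,
    STRONG_EVIDENCE_CODES,
    merge_annotation_sets,
)
from .baselines import prevalence_predictor
from .errors import ValidationError
from .ontology import OntologyDAG, Term

PREDICTOR_FAMILIES = (
    "noisy_oracle",
    "homology_copy",
    "prevalence_mimic",
    "binary_oracle",
)

_STRONG_CHOICES = ("EXP", "TAS", "IC")


def generate_ontology(
    n_terms: int,
    max_parents: int = 3,
    namespaces: Sequence[str] = ("BP",),
    seed: int | np.random.SeedSequence = 0,
) -> OntologyDAG:
    """Layered random DAG with ``n_terms`` terms per namespace.

    Each namespace gets a single root on layer 0; every other term is
    placed on a random deeper layer and receives 1..max_parents parents
    from strictly shallower layers, which guarantees acyclicity.
    """
    if n_terms < 1:
        raise ValidationError("need at least 1 term per namespace")
    if max_parents < 1:
        raise ValidationError("max_parents must be >= 1")
    rng = np.random.default_rng(seed)
    terms: list[Term] = []
    edges: list[tuple[str, str]] = []
    n_layers = max(1, int(np.ceil(np.log2(n_terms + 1))))
    for ns in namespaces:
        ids = [f"{ns}:{i:07d}" for i in range(n_terms)]
        layers = np.zeros(n_terms, dtype=int)
        for i in range(1, n_terms):
            layers[i] = rng.integers(1, n_layers + 1)
        for i, tid in enumerate(ids):
            terms.append(Term(id=tid, name=f"synthetic term {tid}", namespace=ns))
            if i == 0:
                continue
            shallower = [j for j in range(n_terms) if layers[j] < layers[i]]
            if not shallower:
                shallower = [0]
            k = int(rng.integers(1, max_parents + 1))
            k = min(k, len(shallower))
            chosen = rng.choice(shallower, size=k, replace=False)
            for j in sorted(int(c) for c in chosen):
                edges.append((tid, ids[j]))
    return OntologyDAG(terms, edges)


def _term_weights(
    dag: OntologyDAG, terms: Sequence[str], rng: np.random.Generator,
    species_boost: frozenset[str] = frozenset(), skew: float = 0.0,
) -> np.ndarray:
    # bias toward leaves: weight grows with closure size (depth proxy)
    w = np.array([len(dag.ancestors(t)) for t in terms], dtype=float)
    if skew > 0.0 and species_boost:
        boost = np.array([t in species_boost for t in terms], dtype=float)
        w = w * (1.0 + 9.0 * skew * boost)
    return w / w.sum()


def generate_corpus(
    dag: OntologyDAG,
    n_genes: int,
    mf_dispersion: float = 3.0,
    n_species: int = 3,
    seed: int | np.random.SeedSequence = 0,
    species_skew: float = 0.0,
    strong_fraction: float = 0.3,
) -> AnnotationSet:
    """Raw mixed-evidence corpus with heavy-tailed per-gene term counts.

    Per-gene raw term counts are geometric with mean ``mf_dispersion``
    (1.0 degenerates to exactly one term per gene).  Terms are drawn with
    probability increasing toward the leaves; with ``species_skew`` > 0
    each species over-samples its own preferred term subset.  Evidence is
    IEA with probability 1 - strong_fraction, else EXP/TAS/IC.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if mf_dispersion < 1.0:
        raise ValidationError("mf_dispersion must be >= 1.0")
    rng = np.random.default_rng(seed)
    candidates = sorted(
        t for t in dag.active_terms() if t not in dag.roots.values()
    ) or sorted(dag.active_terms())

    species = [f"taxon{i}" for i in range(n_species)]
    boosts: dict[str, frozenset[str]] = {}
    for sp in species:
        k = max(1, len(candidates) // 5)
        boosts[sp] = frozenset(
            rng.choice(candidates, size=k, replace=False).tolist()
        )

    assignments: dict[str, frozenset[str]] = {}
    species_of: dict[str, str] = {}
    evidence: dict[str, dict[str, frozenset[str]]] = {}
    weight_cache: dict[str, np.ndarray] = {}
    for i in range(n_genes):
        gene = f"g{i:05d}"
        sp = species[i % n_species]
        if sp not in weight_cache:
            weight_cache[sp] = _term_weights(
                dag, candidates, rng, boosts[sp], species_skew
            )
        n_raw = int(rng.geometric(1.0 / mf_dispersion))
        n_raw = min(n_raw, len(candidates))
        drawn = rng.choice(
            candidates, size=n_raw, replace=False, p=weight_cache[sp]
        ).tolist()
        codes: dict[str, frozenset[str]] = {}
        for t in drawn:
            if rng.random() < strong_fraction:
                codes[t] = frozenset({_STRONG_CHOICES[rng.integers(3)]})
            else:
                codes[t] = frozenset({"IEA"})
        assignments[gene] = frozenset(drawn)
        species_of[gene] = sp
        evidence[gene] = codes
    return AnnotationSet(
        assignments=assignments,
        propagated=False,
        species_of=species_of,
        evidence=evidence,
    )


def generate_gold_update(
    dag: OntologyDAG,
    corpus_before: AnnotationSet,
    n_targets: int,
    confirmation_bias: float = 0.5,
    seed: int | np.random.SeedSequence = 0,
    terms_per_target: int = 2,
    strong_codes: frozenset[str] = STRONG_EVIDENCE_CODES,
) -> AnnotationSet:
    """Waiting-period update: genes gaining new strong-evidence terms.

    Each draw is, with probability ``confirmation_bias``, an "upgrade" of
    one of the gene's existing weak-evidence (IEA-only) terms to a strong
    code; otherwise a fresh term sampled near the gene's existing closure
    (siblings and children of closure members).  Every selected gene gains
    at least one strong term it did not strongly carry before.
    """
    if not (0.0 <= confirmation_bias <= 1.0):
        raise ValidationError("confirmation_bias must be in [0, 1]")
    genes = sorted(corpus_before.assignments)
    if n_targets > len(genes):
        raise ValidationError("n_targets exceeds corpus size")
    rng = np.random.default_rng(seed)

    def upgrade_candidates(gene: str) -> list[str]:
        per_term = corpus_before.evidence.get(gene, {})
        return sorted(
            t
            for t, codes in per_term.items()
            if not (codes & strong_codes) and t in dag.terms
            and not dag.terms[t].obsolete
        )

    def fresh_candidates(gene: str) -> list[str]:
        closure = dag.propagate_annotation_set(
            corpus_before.assignments[gene], lenient=True
        )
        near: set[str] = set()
        for t in closure:
            for parent in dag.parents(t):
                near |= dag.children(parent)  # siblings (and t itself)
            near |= dag.children(t)
        strong_before = corpus_before.strong_terms(gene, strong_codes)
        near -= strong_before
        near -= set(dag.roots.values())
        return sorted(near)

    if confirmation_bias > 0.0:
        eligible = [g for g in genes if upgrade_candidates(g)]
    else:
        eligible = [g for g in genes if fresh_candidates(g)]
    if len(eligible) < n_targets:
        raise ValidationError(
            f"only {len(eligible)} genes eligible for {n_targets} targets; "
            "grow the corpus or adjust confirmation_bias"
        )
    chosen = rng.choice(eligible, size=n_targets, replace=False).tolist()

    assignments: dict[str, frozenset[str]] = {}
    evidence: dict[str, dict[str, frozenset[str]]] = {}
    species_of: dict[str, str] = {}
    for gene in sorted(chosen):
        new_terms: set[str] = set()
        strong_before = corpus_before.strong_terms(gene, strong_codes)
        for _ in range(terms_per_target):
            want_upgrade = rng.random() < confirmation_bias
            pool: list[str] = []
            if want_upgrade:
                pool = [
                    t for t in upgrade_candidates(gene) if t not in new_terms
                ]
                if not pool and confirmation_bias >= 1.0:
                    continue  # never emit a non-upgrade at bias 1
            if not pool:
                pool = [
                    t
                    for t in fresh_candidates(gene)
                    if t not in new_terms and t not in strong_before
                ]
            if not pool:
                continue
            new_terms.add(pool[int(rng.integers(len(pool)))])
        if not new_terms:  # guaranteed reachable: gene was eligible
            pool = upgrade_candidates(gene) or fresh_candidates(gene)
            new_terms.add(pool[0])
        code = _STRONG_CHOICES[int(rng.integers(3))]
        assignments[gene] = frozenset(new_terms)
        evidence[gene] = {t: frozenset({code}) for t in new_terms}
        if gene in corpus_before.species_of:
            species_of[gene] = corpus_before.species_of[gene]
    return AnnotationSet(
        assignments=assignments,
        propagated=False,
        species_of=species_of,
        evidence=evidence,
    )


@dataclass
class BenchmarkWorld:
    """A complete, reproducible benchmark: ontology, corpus, gold update
    and simulated predictors, with the generating parameters recorded."""

    dag: OntologyDAG
    corpus_before: AnnotationSet
    gold_update: AnnotationSet
    predictors: list[PredictionSet] = field(default_factory=list)
    truth_params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def targets(self) -> set[str]:
        return self.gold_update.genes

    def evaluation_truths(self) -> dict[str, frozenset[str]]:
        """Per-target ancestor closure of the gold-standard update."""
        return {
            g: self.dag.propagate_annotation_set(terms)
            for g, terms in self.gold_update.assignments.items()
        }

    def corpus_after(self) -> AnnotationSet:
        return merge_annotation_sets(self.corpus_before, self.gold_update)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_terms": len(self.dag.terms),
            "n_genes": len(self.corpus_before.assignments),
            "n_targets": len(self.gold_update.assignments),
            "predictors": [
                {
                    "algorithm": p.algorithm,
                    **self.truth_params.get("predictors", {}).get(
                        p.algorithm, {}
                    ),
                }
                for p in self.predictors
            ],
            "params": {
                k: v for k, v in self.truth_params.items() if k != "predictors"
            },
        }

    def write_manifest(self, stream: IO[str]) -> None:
        json.dump(self.manifest(), stream, indent=2, sort_keys=True)
        stream.write("\n")


def simulate_predictor(
    world: BenchmarkWorld,
    family: str,
    noise: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    algorithm: str | None = None,
) -> PredictionSet:
    """Simulate one predictor over the world's evaluation targets.

    Families: ``noisy_oracle`` scores the true gold terms high, replacing
    a ``noise`` fraction with random same-namespace terms; ``homology_copy``
    copies the annotations of a "homolog" (the target itself, or with
    probability ``noise`` a random other gene), ancestor-closed;
    ``prevalence_mimic`` reproduces the prevalence null exactly;
    ``binary_oracle`` is a noisy oracle with every score snapped to 1.0.
    """
    if family not in PREDICTOR_FAMILIES:
        raise ValidationError(
            f"unknown predictor family {family!r}; choose from {PREDICTOR_FAMILIES}"
        )
    if not (0.0 <= noise <= 1.0):
        raise ValidationError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    name = algorithm or f"{family}-{noise:g}"
    dag = world.dag
    targets = sorted(world.targets)

    if family == "prevalence_mimic":
        corpus = world.corpus_before.propagate(dag, lenient=True)
        pred = prevalence_predictor(corpus, dag, targets=targets, algorithm=name)
        return pred

    scores: dict[str, dict[str, float]] = {}
    if family in ("noisy_oracle", "binary_oracle"):
        by_ns = {ns: sorted(dag.active_terms(ns)) for ns in dag.roots}
        for gene in targets:
            per_term: dict[str, float] = {}
            for t in sorted(world.gold_update.assignments[gene]):
                if rng.random() < noise:
                    ns = dag.namespace_of(t)
                    t = by_ns[ns][int(rng.integers(len(by_ns[ns])))]
                score = 1.0 if family == "binary_oracle" else float(
                    rng.uniform(0.5, 1.0)
                )
                per_term[t] = max(per_term.get(t, 0.0), score)
            scores[gene] = per_term
    else:  # homology_copy
        corpus_genes = sorted(world.corpus_before.assignments)
        for gene in targets:
            homolog = gene
            if rng.random() < noise or gene not in world.corpus_before.assignments:
                homolog = corpus_genes[int(rng.integers(len(corpus_genes)))]
            closure = dag.propagate_annotation_set(
                world.corpus_before.assignments.get(homolog, ()), lenient=True
            )
            if not closure:
                continue
            scores[gene] = {t: float(rng.uniform(0.5, 1.0)) for t in sorted(closure)}
    return PredictionSet(algorithm=name, scores=scores)


def generate_world(
    seed: int,
    n_terms: int = 300,
    namespaces: Sequence[str] = ("BP",),
    max_parents: int = 3,
    n_genes: int = 2000,
    n_targets: int = 200,
    mf_dispersion: float = 3.0,
    n_species: int = 3,
    species_skew: float = 0.0,
    confirmation_bias: float = 0.5,
    terms_per_target: int = 2,
    predictor_specs: Sequence[tuple[str, float]] = (),
) -> BenchmarkWorld:
    """Build a full benchmark world from one integer seed.

    The seed fans out through ``numpy.random.SeedSequence`` children, one
    per component, so each artifact is independently reproducible.
    """
    root_ss = np.random.SeedSequence(seed)
    onto_ss, corpus_ss, gold_ss, pred_root = root_ss.spawn(4)
    dag = generate_ontology(
        n_terms, max_parents=max_parents, namespaces=namespaces, seed=onto_ss
    )
    corpus = generate_corpus(
        dag,
        n_genes,
        mf_dispersion=mf_dispersion,
        n_species=n_species,
        seed=corpus_ss,
        species_skew=species_skew,
    )
    gold = generate_gold_update(
        dag,
        corpus,
        n_targets,
        confirmation_bias=confirmation_bias,
        seed=gold_ss,
        terms_per_target=terms_per_target,
    )
    world = BenchmarkWorld(
        dag=dag,
        corpus_before=corpus,
        gold_update=gold,
        seed=seed,
        truth_params={
            "n_terms": n_terms,
            "namespaces": list(namespaces),
            "n_genes": n_genes,
            "n_targets": n_targets,
            "mf_dispersion": mf_dispersion,
            "n_species": n_species,
            "species_skew": species_skew,
            "confirmation_bias": confirmation_bias,
            "terms_per_target": terms_per_target,
            "predictors": {},
        },
    )
    pred_seeds = pred_root.spawn(len(predictor_specs)) if predictor_specs else []
    for (family, noise), pseed in zip(predictor_specs, pred_seeds):
        pred = simulate_predictor(world, family, noise=noise, seed=pseed)
        world.predictors.append(pred)
        world.truth_params["predictors"][pred.algorithm] = {
            "family": family,
            "noise": noise,
        }
    return world
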