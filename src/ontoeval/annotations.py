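"""Readers, writers and data models for annotation corpora (GAF 2.x) and
prediction submissions (three-column TSV), plus evidence-code filtering
and waiting-period target selection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .errors import ParseError, ValidationError
from .ontology import OntologyDAG

#: Evidence codes treated as "strong" (experimental / traceable / curator).
STRONG_EVIDENCE_CODES = frozenset({"EXP", "TAS", "IC"})

#: Default per-gene, per-namespace cap on scored terms.
TERM_CAP = 1000

_ASPECT_TO_NAMESPACE = {"P": "BP", "F": "MF", "C": "CC"}
_NAMESPACE_TO_ASPECT = {v: k for k, v in _ASPECT_TO_NAMESPACE.items()}


@dataclass(frozen=True)
class GeneAnnotationRecord:
    """One row of a gene association file, reduced to the fields we use."""

    gene: str
    term: str
    evidence: str
    species: str = ""
    negated: bool = False


@dataclass
class AnnotationSet:
    """Mapping gene -> term set, with species labels and evidence codes.

    ``evidence`` maps gene -> term -> set of evidence codes for the *raw*
    records that produced the assignment; it is not propagated along the
    ontology.  ``propagated`` marks whether each gene's term set is its
    own ancestor closure.
    """

    assignments: dict[str, frozenset[str]]
    propagated: bool = False
    species_of: dict[str, str] = field(default_factory=dict)
    evidence: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.assignments.items():
            if not terms:
                raise ValidationError(f"gene {gene!r} maps to an empty term set")

    @property
    def genes(self) -> set[str]:
        return set(self.assignments)

    def propagate(self, dag: OntologyDAG, lenient: bool = False) -> "AnnotationSet":
        """Ancestor-close every gene's term set.  Idempotent."""
        closed: dict[str, frozenset[str]] = {}
        for gene, terms in self.assignments.items():
            closure = dag.propagate_annotation_set(terms, lenient=lenient)
            if closure:
                closed[gene] = closure
        return AnnotationSet(
            assignments=closed,
            propagated=True,
            species_of=dict(self.species_of),
            evidence={g: dict(v) for g, v in self.evidence.items()},
        )

    def strong_terms(self, gene: str, strong_codes: Iterable[str]) -> frozenset[str]:
        """Terms of ``gene`` carrying at least one strong evidence code."""
        strong = set(strong_codes)
        per_term = self.evidence.get(gene, {})
        return frozenset(t for t, codes in per_term.items() if codes & strong)


def records_to_annotation_set(
    records: Iterable[GeneAnnotationRecord],
) -> AnnotationSet:
    """Group positive records by gene into a raw AnnotationSet."""
    assignments: dict[str, set[str]] = {}
    species_of: dict[str, str] = {}
    evidence: dict[str, dict[str, set[str]]] = {}
    for rec in records:
        if rec.negated:
            continue
        assignments.setdefault(rec.gene, set()).add(rec.term)
        evidence.setdefault(rec.gene, {}).setdefault(rec.term, set()).add(
            rec.evidence
        )
        if rec.species:
            species_of[rec.gene] = rec.species
    return AnnotationSet(
        assignments={g: frozenset(t) for g, t in assignments.items()},
        propagated=False,
        species_of=species_of,
        evidence={
            g: {t: frozenset(c) for t, c in per.items()}
            for g, per in evidence.items()
        },
    )


def read_gaf(
    stream: IO[str] | Iterable[str],
    evidence_whitelist: Iterable[str] | None,
    namespace: str | None = None,
) -> AnnotationSet:
    """Read a GAF stream into a raw AnnotationSet.

    Keeps rows whose evidence code is whitelisted and whose aspect matches
    ``namespace`` (P=BP, F=MF, C=CC; ``None`` keeps all aspects); rows
    with a NOT qualifier are dropped.  ``evidence_whitelist=None`` keeps
    every evidence code.
    """
    whitelist = None if evidence_whitelist is None else set(evidence_whitelist)
    if whitelist is not None and not whitelist:
        raise ValidationError("evidence whitelist may not be empty")
    want_aspect = _NAMESPACE_TO_ASPECT.get(namespace) if namespace else None

    kept: list[GeneAnnotationRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            raise ParseError(
                f"expected >=15 tab-separated columns, got {len(cols)}", lineno
            )
        if "NOT" in cols[3].split("|"):
            continue
        if whitelist is not None and cols[6] not in whitelist:
            continue
        if want_aspect is not None and cols[8] != want_aspect:
            continue
        taxon = cols[12].split("|")[0].removeprefix("taxon:")
        kept.append(
            GeneAnnotationRecord(
                gene=cols[1], term=cols[4], evidence=cols[6], species=taxon
            )
        )
    if not kept:
        return AnnotationSet(assignments={}, propagated=False)
    return records_to_annotation_set(kept)


def write_gaf(
    annset: AnnotationSet,
    stream: IO[str],
    namespace_of=None,
    db: str = "ontoeval",
) -> None:
    """Serialize a raw AnnotationSet to GAF 2.2.

    ``namespace_of`` maps a term id to BP/MF/CC for the aspect column; by
    default aspect is written as P.
    """
    stream.write("!gaf-version: 2.2\n")
    for gene in sorted(annset.assignments):
        taxon = annset.species_of.get(gene, "0")
        for term in sorted(annset.assignments[gene]):
            codes = annset.evidence.get(gene, {}).get(term, frozenset({"IEA"}))
            ns = namespace_of(term) if namespace_of else "BP"
            aspect = _NAMESPACE_TO_ASPECT[ns]
            for code in sorted(codes):
                cols = [
                    db, gene, gene, "", term, f"{db}:ref", code, "",
                    aspect, "", "", "protein", f"taxon:{taxon}",
                    "20110101", db, "", "",
                ]
                stream.write("\t".join(cols) + "\n")


# -- prediction sets -----------------------------------------------------


@dataclass
class PredictionSet:
    """Per-algorithm scored term predictions.

    ``scores`` maps gene -> (term -> score in (0, 1]); a missing pair is a
    non-prediction, never a zero.  ``explicit_terms`` records which terms
    were submitted verbatim (as opposed to implied by up-propagation).
    """

    algorithm: str
    scores: dict[str, dict[str, float]]
    explicit_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, per_term in self.scores.items():
            for term, score in per_term.items():
                if not (0.0 < score <= 1.0):
                    raise ValidationError(
                        f"score {score!r} for ({gene!r}, {term!r}) outside (0, 1]"
                    )
            if gene not in self.explicit_terms:
                self.explicit_terms[gene] = frozenset(per_term)

    @property
    def genes(self) -> set[str]:
        return set(self.scores)

    def for_gene(self, gene: str) -> dict[str, float]:
        return self.scores.get(gene, {})


def _check_term_cap(
    per_gene_ns_counts: dict[tuple[str, str], int],
    gene: str,
    ns: str,
    cap: int,
    lineno: int | None,
) -> None:
    per_gene_ns_counts[(gene, ns)] = per_gene_ns_counts.get((gene, ns), 0) + 1
    if per_gene_ns_counts[(gene, ns)] > cap:
        raise ValidationError(
            f"target {gene!r} exceeds the {cap}-term cap in namespace {ns}"
            + (f" (line {lineno})" if lineno else "")
        )


def read_predictions(
    stream: IO[str] | Iterable[str],
    dag: OntologyDAG,
    algorithm: str = "unnamed",
    cap: int = TERM_CAP,
) -> PredictionSet:
    """Parse whitespace-separated ``target term score`` lines.

    Lines starting with '#' are comments.  Scores must lie in (0.00, 1.00]
    — 0.00 is not allowed, a missing pair being the only way to express a
    non-prediction.  The per-namespace term cap is enforced per target.
    """
    scores: dict[str, dict[str, float]] = {}
    counts: dict[tuple[str, str], int] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ParseError(
                f"expected 3 whitespace-separated fields, got {len(fields)}",
                lineno,
            )
        gene, term, score_text = fields
        try:
            score = float(score_text)
        except ValueError:
            raise ParseError(f"unparseable score {score_text!r}", lineno) from None
        if score == 0.0:
            raise ValidationError(
                f"line {lineno}: score 0.00 is not allowed "
                f"(omit the line to express a non-prediction): {line!r}"
            )
        if not (0.0 < score <= 1.0):
            raise ValidationError(
                f"line {lineno}: score {score} outside (0.00, 1.00]: {line!r}"
            )
        ns = dag.namespace_of(term)
        per_term = scores.setdefault(gene, {})
        if term not in per_term:
            _check_term_cap(counts, gene, ns, cap, lineno)
        per_term[term] = score
    return PredictionSet(algorithm=algorithm, scores=scores)


def write_predictions(predset: PredictionSet, stream: IO[str]) -> None:
    """Write a PredictionSet as tab-separated lines, scores to 4 decimals."""
    stream.write(f"# algorithm: {predset.algorithm}\n")
    for gene in sorted(predset.scores):
        per_term = predset.scores[gene]
        for term in sorted(per_term):
            stream.write(f"{gene}\t{term}\t{per_term[term]:.4f}\n")


def select_evaluation_targets(
    before: AnnotationSet,
    after: AnnotationSet,
    strong_codes: Iterable[str] = STRONG_EVIDENCE_CODES,
) -> set[str]:
    """Genes that gained a strongly-evidenced term during the waiting period.

    A gene qualifies if ``after`` gives it at least one term with a strong
    evidence code that was not strongly evidenced in ``before``.
    """
    strong = set(strong_codes)
    selected = set()
    for gene in after.genes:
        new_strong = after.strong_terms(gene, strong)
        old_strong = before.strong_terms(gene, strong)
        if new_strong - old_strong:
            selected.add(gene)
    return selected


def filter_by_evidence(
    annset: AnnotationSet, codes: Iterable[str]
) -> AnnotationSet:
    """Restrict a raw AnnotationSet to assignments carrying one of the
    given evidence codes; genes left with nothing are dropped."""
    if annset.propagated:
        raise ValidationError("evidence filtering operates on raw sets")
    codes = set(codes)
    assignments: dict[str, frozenset[str]] = {}
    evidence: dict[str, dict[str, frozenset[str]]] = {}
    species: dict[str, str] = {}
    for gene, per_term in annset.evidence.items():
        kept = {
            t: c & codes for t, c in per_term.items() if c & codes
        }
        if not kept:
            continue
        assignments[gene] = frozenset(kept)
        evidence[gene] = {t: frozenset(c) for t, c in kept.items()}
        if gene in annset.species_of:
            species[gene] = annset.species_of[gene]
    return AnnotationSet(
        assignments=assignments,
        propagated=False,
        species_of=species,
        evidence=evidence,
    )


def merge_annotation_sets(a: AnnotationSet, b: AnnotationSet) -> AnnotationSet:
    """Union two raw AnnotationSets (assignments, species, evidence)."""
    if a.propagated or b.propagated:
        raise ValidationError("merge operates on raw annotation sets")
    assignments = {g: set(t) for g, t in a.assignments.items()}
    evidence = {g: {t: set(c) for t, c in per.items()} for g, per in a.evidence.items()}
    species = dict(a.species_of)
    for g, terms in b.assignments.items():
        assignments.setdefault(g, set()).update(terms)
    for g, per in b.evidence.items():
        dest = evidence.setdefault(g, {})
        for t, codes in per.items():
            dest.setdefault(t, set()).update(codes)
    species.update(b.species_of)
    return AnnotationSet(
        assignments={g: frozenset(t) for g, t in assignments.items()},
        propagated=False,
        species_of=species,
        evidence={
            g: {t: frozenset(c) for t, c in per.items()}
            for g, per in evidence.items()
        },
    )
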