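"""Ontology data model: is_a DAG, ancestor closure, score propagation,
information content and semantic similarity.

The ontology is a rooted, acyclic graph of terms partitioned into
namespaces (BP, MF, CC).  Edges point child -> parent.  Closure queries
are reflexive: a term is its own ancestor.  All annotation and score
propagation in this package runs through :class:`OntologyDAG`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

from .errors import (
    OntologyStructureError,
    TermLookupError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Canonical namespace labels.
NAMESPACES = ("BP", "MF", "CC")

_NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}


@dataclass(frozen=True)
class Term:
    """A single ontology term."""

    id: str
    name: str = ""
    namespace: str = "BP"
    obsolete: bool = False


class OntologyDAG:
    """Rooted acyclic is_a graph with one root per namespace.

    Parameters
    ----------
    terms:
        All terms, including obsolete ones.
    edges:
        Directed child -> parent ``is_a`` pairs.  Obsolete terms must not
        appear in any edge.
    """

    def __init__(self, terms: Iterable[Term], edges: Iterable[tuple[str, str]]):
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self.terms:
                raise OntologyStructureError(f"duplicate term id {t.id!r}")
            self.terms[t.id] = t

        self._graph = nx.DiGraph()
        for tid, term in self.terms.items():
            if not term.obsolete:
                self._graph.add_node(tid)
        for child, parent in edges:
            for tid in (child, parent):
                if tid not in self.terms:
                    raise OntologyStructureError(
                        f"edge references unknown term {tid!r}"
                    )
                if self.terms[tid].obsolete:
                    raise OntologyStructureError(
                        f"obsolete term {tid!r} may not carry edges"
                    )
            self._graph.add_edge(child, parent)

        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise OntologyStructureError(
                f"ontology contains a cycle through {cycle[0][0]!r}"
            )

        # one root (parentless active term) per namespace
        self.roots: dict[str, str] = {}
        for tid in self._graph.nodes:
            if self._graph.out_degree(tid) == 0:
                ns = self.terms[tid].namespace
                if ns in self.roots:
                    raise OntologyStructureError(
                        f"namespace {ns} has multiple roots: "
                        f"{self.roots[ns]!r} and {tid!r}"
                    )
                self.roots[ns] = tid

        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- basic queries ---------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def active_terms(self, namespace: str | None = None) -> list[str]:
        """Non-obsolete term ids, optionally restricted to one namespace."""
        return [
            tid
            for tid in self._graph.nodes
            if namespace is None or self.terms[tid].namespace == namespace
        ]

    def namespace_of(self, term_id: str) -> str:
        self._check_active(term_id)
        return self.terms[term_id].namespace

    def root_of(self, namespace: str) -> str:
        try:
            return self.roots[namespace]
        except KeyError:
            raise OntologyStructureError(
                f"namespace {namespace!r} has no root"
            ) from None

    def parents(self, term_id: str) -> set[str]:
        self._check_active(term_id)
        return set(self._graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        self._check_active(term_id)
        return set(self._graph.predecessors(term_id))

    def _check_active(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise TermLookupError(f"unknown term {term_id!r}")
        if self.terms[term_id].obsolete:
            raise TermLookupError(f"term {term_id!r} is obsolete")

    # -- closure ---------------------------------------------------------

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive closure over is_a edges (includes the term)."""
        self._check_active(term_id)
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term_id)) | {term_id}
            self._ancestor_cache[term_id] = cached
        return cached

    def descendants(self, term_id: str) -> frozenset[str]:
        """Reflexive set of terms that imply ``term_id`` (includes it)."""
        self._check_active(term_id)
        return frozenset(nx.ancestors(self._graph, term_id)) | {term_id}

    def propagate_annotation_set(
        self, terms: Iterable[str], lenient: bool = False
    ) -> frozenset[str]:
        """Union of reflexive ancestor closures over ``terms``; idempotent.

        With ``lenient=True`` unknown or obsolete ids are skipped with a
        warning instead of raising (real annotation files contain retired
        ids).
        """
        out: set[str] = set()
        for t in terms:
            try:
                out |= self.ancestors(t)
            except TermLookupError:
                if not lenient:
                    raise
                logger.warning("skipping unknown/obsolete term %r", t)
        return frozenset(out)

    def propagate_prediction_scores(
        self,
        scored: Mapping[str, float],
        explicit: Iterable[str] = (),
    ) -> dict[str, float]:
        """Propagate scores to ancestors, keeping the max over descendants.

        Every ancestor of a scored term receives the maximum score among
        the submitted terms that imply it — except terms in ``explicit``,
        which keep their submitted score verbatim even when that breaks
        child<=parent consistency (submitted intent is preserved rather
        than re-normalized).
        """
        explicit = set(explicit)
        if not explicit <= set(scored):
            extra = explicit - set(scored)
            raise ValidationError(
                f"explicit terms without submitted scores: {sorted(extra)}"
            )
        for t, s in scored.items():
            if not (0.0 < s <= 1.0):
                raise ValidationError(
                    f"score {s!r} for term {t!r} outside (0, 1]"
                )
        out: dict[str, float] = {}
        for t, s in scored.items():
            for anc in self.ancestors(t):
                if s > out.get(anc, 0.0):
                    out[anc] = s
        for t in explicit:
            out[t] = scored[t]
        return out


# -- OBO parsing ---------------------------------------------------------


def load_obo(stream: IO[str] | Iterable[str], include_part_of: bool = False) -> OntologyDAG:
    """Parse OBO 1.2-style text into an :class:`OntologyDAG`.

    Only the tags needed here are read: ``id``, ``name``, ``namespace``,
    ``is_a``, ``relationship: part_of`` and ``is_obsolete``.  Obsolete
    terms are retained as metadata but carry no edges.  ``part_of``
    relationships are ignored unless ``include_part_of`` is set.
    """
    terms: list[Term] = []
    edges: list[tuple[str, str]] = []

    stanza: dict[str, list[str]] | None = None

    def flush() -> None:
        if stanza is None or "id" not in stanza:
            return
        tid = stanza["id"][0]
        obsolete = stanza.get("is_obsolete", ["false"])[0].lower() == "true"
        ns_raw = stanza.get("namespace", ["BP"])[0]
        ns = _NAMESPACE_ALIASES.get(ns_raw, ns_raw)
        terms.append(
            Term(
                id=tid,
                name=stanza.get("name", [""])[0],
                namespace=ns,
                obsolete=obsolete,
            )
        )
        if obsolete:
            return
        for val in stanza.get("is_a", []):
            parent = val.split("!")[0].strip()
            edges.append((tid, parent))
        if include_part_of:
            for val in stanza.get("relationship", []):
                fields = val.split("!")[0].split()
                if len(fields) == 2 and fields[0] == "part_of":
                    edges.append((tid, fields[1]))

    in_term = False
    for line in stream:
        line = line.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            stanza = {} if in_term else None
            continue
        if not in_term or not line or ":" not in line:
            continue
        tag, _, value = line.partition(":")
        assert stanza is not None
        stanza.setdefault(tag.strip(), []).append(value.strip())
    flush()

    return OntologyDAG(terms, edges)


def write_obo(dag: OntologyDAG, stream: IO[str]) -> None:
    """Serialize a DAG back to minimal OBO 1.2 text."""
    stream.write("format-version: 1.2\n")
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        stream.write("\n[Term]\n")
        stream.write(f"id: {term.id}\n")
        if term.name:
            stream.write(f"name: {term.name}\n")
        stream.write(f"namespace: {term.namespace}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")
        else:
            for parent in sorted(dag.parents(tid)):
                stream.write(f"is_a: {parent}\n")


# -- information content and semantic similarity -------------------------


@dataclass
class InformationContentTable:
    """Per-term annotation frequency and information content in bits.

    Frequencies are computed on an ancestor-closed corpus, so every
    namespace root present has p = 1 and ic = 0, and ic is monotone
    non-decreasing from root to leaves.
    """

    p: dict[str, float]
    ic: dict[str, float] = field(default_factory=dict)
    corpus_size: int = 0

    def __post_init__(self) -> None:
        if not self.ic:
            self.ic = {t: -math.log2(p) for t, p in self.p.items()}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.p


def information_content(dag: OntologyDAG, corpus) -> InformationContentTable:
    """Build an IC table from a propagated annotation corpus.

    p(t) = (# genes annotated to t) / (# genes annotated to the namespace
    root of t); ic = -log2 p.  Terms never used are absent from the table.
    """
    if not corpus.propagated:
        raise ValidationError("information content requires a propagated corpus")
    if not corpus.assignments:
        raise ValidationError("empty corpus")

    counts: dict[str, int] = {}
    for terms in corpus.assignments.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1

    root_counts = {
        ns: counts.get(root, 0) for ns, root in dag.roots.items()
    }
    p: dict[str, float] = {}
    for t, c in counts.items():
        denom = root_counts.get(dag.namespace_of(t), 0)
        if denom:
            p[t] = c / denom
    return InformationContentTable(p=p, corpus_size=len(corpus.assignments))


def _mica_ic(
    dag: OntologyDAG, ic: InformationContentTable, a: str, b: str
) -> float:
    ns_a, ns_b = dag.namespace_of(a), dag.namespace_of(b)
    if ns_a != ns_b:
        raise ValidationError(
            f"terms {a!r} ({ns_a}) and {b!r} ({ns_b}) are in different namespaces"
        )
    common = dag.ancestors(a) & dag.ancestors(b)
    # the namespace root is always a common ancestor with IC 0; common
    # ancestors missing from the table are skipped
    best = 0.0
    for t in common:
        val = ic.ic.get(t)
        if val is not None and val > best:
            best = val
    return best


def resnik_similarity(
    dag: OntologyDAG, ic: InformationContentTable, a: str, b: str
) -> float:
    """IC (bits) of the most informative common ancestor of ``a`` and ``b``."""
    return _mica_ic(dag, ic, a, b)


def lin_similarity(
    dag: OntologyDAG, ic: InformationContentTable, a: str, b: str
) -> float:
    """2*IC(MICA) / (IC(a) + IC(b)), in [0, 1]; 0 when both terms are roots."""
    mica = _mica_ic(dag, ic, a, b)
    denom = ic.ic.get(a, 0.0) + ic.ic.get(b, 0.0)
    if denom == 0.0:
        return 0.0
    return 2.0 * mica / denom
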