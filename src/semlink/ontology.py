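"""Ontology handling: term DAG, ancestor queries, annotation propagation, IC.

The substrate is a Gene-Ontology-like structure: terms linked to parents by
``is_a`` or ``part_of`` edges, acyclic, with one root per namespace
(biological_process / molecular_function / cellular_component, abbreviated
BP / MF / CC).  Annotations are propagated upward along both relation types
by default (the true-path rule), and the information content of a term is
the negative log of its annotation probability in the corpus,

    IC(t) = -ln( n_t / n_root )

where ``n_t`` counts distinct genes annotated to ``t`` or any of its
descendants and ``n_root`` is the count at the namespace root.  Natural-log
units; IC(root) = 0 by construction.
"""

from __future__ import annotations

import logging
import math
import os
from collections import defaultdict
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import networkx as nx

from ._io import read_lines

logger = logging.getLogger(__name__)

Relation = str
IS_A: Relation = "is_a"
PART_OF: Relation = "part_of"
#: Default relation set: both edge types propagate annotations and define
#: ancestry, matching the graph-based similarity measure's treatment.
BOTH_RELATIONS: frozenset[Relation] = frozenset({IS_A, PART_OF})

_NAMESPACE_MAP = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}
_NAMESPACE_LONG = {"BP": "biological_process", "MF": "molecular_function",
                   "CC": "cellular_component"}


def namespace_code(name: str) -> str:
    """Map an OBO namespace name to BP/MF/CC, anything else to 'other'."""
    return _NAMESPACE_MAP.get(name, "other")


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term with typed parent edges.

    ``parents`` holds ``(parent_term_id, relation)`` pairs with relation in
    {is_a, part_of}.  Obsolete terms carry no parents and are excluded from
    every computation.
    """

    term_id: str
    name: str = ""
    namespace: str = "other"
    parents: tuple[tuple[str, Relation], ...] = ()
    obsolete: bool = False


class OntologyDAG:
    """Rooted acyclic term graph with typed (is_a/part_of) parent edges.

    Validates on construction: parent references must be declared, edges may
    not cross namespaces, the graph restricted to is_a/part_of must be
    acyclic, and each namespace has exactly one root among non-obsolete
    terms.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.term_id in self.terms:
                raise ValueError(f"duplicate term id {term.term_id!r}")
            self.terms[term.term_id] = term
        self._children: dict[str, list[tuple[str, Relation]]] = defaultdict(list)
        self._ancestor_cache: dict[tuple[str, frozenset], frozenset[str]] = {}
        self.namespace_roots: dict[str, str] = {}
        self._validate()

    def active_terms(self) -> list[OntologyTerm]:
        """Non-obsolete terms, the only ones that take part in computation."""
        return [t for t in self.terms.values() if not t.obsolete]

    def _validate(self) -> None:
        graph = nx.DiGraph()
        for term in self.active_terms():
            graph.add_node(term.term_id)
            for parent_id, relation in term.parents:
                if parent_id not in self.terms:
                    raise ValueError(
                        f"term {term.term_id!r} references undeclared parent "
                        f"{parent_id!r}")
                if relation not in BOTH_RELATIONS:
                    raise ValueError(f"unsupported relation {relation!r} on "
                                     f"{term.term_id!r}")
                parent = self.terms[parent_id]
                if parent.namespace != term.namespace:
                    raise ValueError(
                        f"edge {term.term_id}->{parent_id} crosses namespaces "
                        f"({term.namespace} vs {parent.namespace})")
                graph.add_edge(term.term_id, parent_id)
                self._children[parent_id].append((term.term_id, relation))
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(
                f"ontology contains a cycle through term {cycle[0][0]!r}")
        roots: dict[str, list[str]] = defaultdict(list)
        for term in self.active_terms():
            if not term.parents:
                roots[term.namespace].append(term.term_id)
        for namespace, ids in roots.items():
            if len(ids) > 1:
                raise ValueError(
                    f"namespace {namespace!r} has multiple roots: {sorted(ids)}")
            self.namespace_roots[namespace] = ids[0]

    # -- queries -------------------------------------------------------------
    def ancestors(self, term_id: str,
                  relations: Iterable[Relation] = BOTH_RELATIONS
                  ) -> frozenset[str]:
        """All terms reachable upward via edges whose relation is allowed.

        The query term itself is excluded.  Deterministic regardless of
        traversal order; results are memoized per (term, relation set).
        """
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r}")
        rels = frozenset(relations)
        key = (term_id, rels)
        cached = self._ancestor_cache.get(key)
        if cached is not None:
            return cached
        seen: set[str] = set()
        stack = [term_id]
        while stack:
            for parent_id, relation in self.terms[stack.pop()].parents:
                if relation in rels and parent_id not in seen:
                    seen.add(parent_id)
                    stack.append(parent_id)
        result = frozenset(seen)
        self._ancestor_cache[key] = result
        return result

    def closure(self, term_id: str,
                relations: Iterable[Relation] = BOTH_RELATIONS
                ) -> frozenset[str]:
        """Ancestors of ``term_id`` plus the term itself."""
        return self.ancestors(term_id, relations) | {term_id}

    def children(self, term_id: str) -> tuple[tuple[str, Relation], ...]:
        """Direct (child, relation) edges below a term."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r}")
        return tuple(self._children.get(term_id, ()))

    def descendants(self, term_id: str,
                    relations: Iterable[Relation] = BOTH_RELATIONS
                    ) -> frozenset[str]:
        """All terms below ``term_id`` via allowed relations (term excluded)."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r}")
        rels = frozenset(relations)
        seen: set[str] = set()
        stack = [term_id]
        while stack:
            for child_id, relation in self._children.get(stack.pop(), ()):
                if relation in rels and child_id not in seen:
                    seen.add(child_id)
                    stack.append(child_id)
        return frozenset(seen)


def ancestors(dag: OntologyDAG, term_id: str,
              relations: Iterable[Relation] = BOTH_RELATIONS) -> frozenset[str]:
    """Functional alias for :meth:`OntologyDAG.ancestors`."""
    return dag.ancestors(term_id, relations)


# ---------------------------------------------------------------------------
# OBO-dialect parsing
# ---------------------------------------------------------------------------

def parse_obo(source: str | os.PathLike | IO[str]) -> OntologyDAG:
    """Parse a minimal OBO dialect into an :class:`OntologyDAG`.

    Recognised lines inside ``[Term]`` stanzas: ``id:``, ``name:``,
    ``namespace:``, ``is_a:``, ``relationship: part_of <id>`` and
    ``is_obsolete:``; a ``default-namespace:`` header is honoured; anything
    else (including other relationship types) is ignored.  Obsolete terms
    are loaded but stripped of parents.
    """
    lines = read_lines(source)
    default_ns = "other"
    terms: list[OntologyTerm] = []
    stanza: dict | None = None
    in_term = False

    def flush() -> None:
        nonlocal stanza
        if stanza is None:
            return
        if "id" not in stanza:
            raise ValueError("[Term] stanza without an id: line")
        obsolete = stanza.get("obsolete", False)
        terms.append(OntologyTerm(
            term_id=stanza["id"],
            name=stanza.get("name", ""),
            namespace=stanza.get("namespace", default_ns),
            parents=() if obsolete else tuple(stanza.get("parents", [])),
            obsolete=obsolete,
        ))
        stanza = None

    for raw in lines:
        line = raw.split(" ! ")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            if in_term:
                stanza = {"parents": []}
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        if stanza is None or not in_term:
            if tag == "default-namespace":
                default_ns = namespace_code(value)
            continue
        if tag == "id":
            stanza["id"] = value
        elif tag == "name":
            stanza["name"] = value
        elif tag == "namespace":
            stanza["namespace"] = namespace_code(value)
        elif tag == "is_a":
            stanza["parents"].append((value.split()[0], IS_A))
        elif tag == "relationship":
            fields = value.split()
            if len(fields) >= 2 and fields[0] == PART_OF:
                stanza["parents"].append((fields[1], PART_OF))
            # other relationship types dropped
        elif tag == "is_obsolete":
            stanza["obsolete"] = value.lower().startswith("true")
    flush()
    return OntologyDAG(terms)


# ---------------------------------------------------------------------------
# Annotation corpus and information content
# ---------------------------------------------------------------------------

@dataclass
class AnnotationCorpus:
    """Gene→term annotations with true-path-propagated per-term gene counts.

    ``direct`` maps each gene to its directly annotated terms;
    ``propagated_counts[t]`` is the number of distinct genes annotated to
    ``t`` or any descendant; ``universe`` is every gene with at least one
    valid annotation — the default resampling universe for the Monte Carlo
    null.
    """

    direct: dict[str, frozenset[str]]
    universe: frozenset[str]
    propagated_counts: dict[str, int]
    dag: OntologyDAG
    term_genes: dict[str, frozenset[str]]

    def annotated_genes(self, namespace: str | None = None) -> frozenset[str]:
        """Genes with >=1 annotation, optionally restricted to a namespace."""
        if namespace is None:
            return self.universe
        root = self.dag.namespace_roots.get(namespace)
        if root is None:
            return frozenset()
        return self.term_genes.get(root, frozenset())

    def terms_of(self, gene: str, namespace: str | None = None) -> frozenset[str]:
        """Direct annotation terms of a gene, optionally namespace-filtered."""
        terms = self.direct.get(gene, frozenset())
        if namespace is None:
            return terms
        return frozenset(t for t in terms
                         if self.dag.terms[t].namespace == namespace)


def propagate_counts(dag: OntologyDAG,
                     corpus_direct: Mapping[str, Iterable[str]]
                     ) -> AnnotationCorpus:
    """Propagate direct annotations up the DAG (distinct-gene counting).

    Each gene contributes at most once to each term's count, via either
    relation type.  Annotations to unknown or obsolete terms are skipped
    with a logged warning.
    """
    term_genes: dict[str, set[str]] = defaultdict(set)
    direct: dict[str, frozenset[str]] = {}
    for gene in corpus_direct:
        kept: set[str] = set()
        for term_id in corpus_direct[gene]:
            term = dag.terms.get(term_id)
            if term is None or term.obsolete:
                logger.warning("skipping annotation of %r to %s term %r",
                               gene, "obsolete" if term else "unknown", term_id)
                continue
            kept.add(term_id)
        if not kept:
            continue
        direct[gene] = frozenset(kept)
        reached: set[str] = set()
        for term_id in kept:
            reached.update(dag.closure(term_id))
        for term_id in reached:
            term_genes[term_id].add(gene)
    counts = {term.term_id: len(term_genes.get(term.term_id, ()))
              for term in dag.active_terms()}
    return AnnotationCorpus(
        direct=direct,
        universe=frozenset(direct),
        propagated_counts=counts,
        dag=dag,
        term_genes={t: frozenset(g) for t, g in term_genes.items()},
    )


@dataclass(frozen=True)
class ICTable:
    """Per-term information content (natural-log units) for one namespace.

    Terms with zero propagated count are absent (their IC is undefined);
    ``ic[root] == 0`` holds by construction.
    """

    ic: dict[str, float]
    max_ic: float
    namespace: str
    root: str

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]


def compute_ic(corpus: AnnotationCorpus, namespace: str = "BP") -> ICTable:
    """IC(t) = -ln(count[t] / count[root]) over one namespace."""
    root = corpus.dag.namespace_roots.get(namespace)
    if root is None:
        raise ValueError(f"no root for namespace {namespace!r}")
    root_count = corpus.propagated_counts.get(root, 0)
    if root_count == 0:
        raise ValueError(f"no annotations in namespace {namespace!r}")
    ic: dict[str, float] = {}
    for term in corpus.dag.active_terms():
        if term.namespace != namespace:
            continue
        count = corpus.propagated_counts.get(term.term_id, 0)
        if count > 0:
            ic[term.term_id] = -math.log(count / root_count) + 0.0
    return ICTable(ic=ic, max_ic=max(ic.values()), namespace=namespace,
                   root=root)


def load_annotations(source: str | os.PathLike | IO[str]
                     ) -> dict[str, set[str]]:
    """Read a two-column ``gene<TAB>term`` table.

    ``#`` comment lines are allowed; a header is auto-detected by the
    literal ``gene`` in the first cell.  Returns gene → set of term ids.
    """
    direct: dict[str, set[str]] = defaultdict(set)
    first_data_line = True
    for number, raw in enumerate(read_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if first_data_line and fields[0] == "gene":
            first_data_line = False
            continue
        first_data_line = False
        if len(fields) < 2 or not fields[0] or not fields[1]:
            logger.warning("skipping malformed annotation line %d: %r",
                           number, raw)
            continue
        direct[fields[0]].add(fields[1])
    return dict(direct)
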