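"""Gene Ontology DAG handling: OBO parsing, true-path propagation, term filters.

The Gene Ontology is a directed acyclic graph of terms in three namespaces
(biological_process, cellular_component, molecular_function).  Annotation data
obeys the true-path rule: a protein annotated with a term is implicitly
annotated with every ancestor of that term.  This module parses OBO 1.2 flat
files into a :class:`GODag`, closes annotation matrices under the ancestor
relation, and applies the standard preprocessing filters (drop namespace
roots, drop terms with no annotated protein).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Canonical roots of the three GO namespaces.
NAMESPACE_ROOTS = {
    "biological_process": "GO:0008150",
    "cellular_component": "GO:0005575",
    "molecular_function": "GO:0003674",
}

#: Short namespace selectors used on the command line.
NAMESPACE_ALIASES = {
    "BP": "biological_process",
    "CC": "cellular_component",
    "MF": "molecular_function",
}

_ACCESSION_RE = re.compile(r"^GO:\d{7}$")

#: Relationship types that propagate annotations.  GO practice propagates
#: both is_a and part_of; part_of can be switched off.
PROPAGATING_RELATIONS = ("is_a", "part_of")


@dataclass
class GOTerm:
    """One ontology term: accession, name, namespace and parent accessions."""

    id: str
    name: str = ""
    namespace: str = "biological_process"
    parents: set[str] = field(default_factory=set)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not _ACCESSION_RE.match(self.id):
            raise ValidationError(f"malformed GO accession: {self.id!r}")
        if self.obsolete and self.parents:
            raise ValidationError(
                f"obsolete term {self.id} must not retain parents"
            )


class GODag:
    """An acyclic parent graph over non-obsolete GO terms.

    Parameters
    ----------
    terms
        Mapping from accession to :class:`GOTerm`.  Obsolete terms may be
        included; they carry no edges and are excluded from the active DAG.
    """

    def __init__(self, terms: dict[str, GOTerm]):
        self.terms = terms
        self._graph = nx.DiGraph()  # edges point child -> parent
        for term in terms.values():
            if term.obsolete:
                continue
            self._graph.add_node(term.id)
            for parent in term.parents:
                if parent not in terms or terms[parent].obsolete:
                    raise ValidationError(
                        f"term {term.id} references unknown parent {parent}"
                    )
                self._graph.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise ValidationError(
                f"parent relation contains a cycle through {cycle[0][0]}"
            )

    @property
    def roots(self) -> set[str]:
        """Accessions of active terms with no parents."""
        return {n for n in self._graph.nodes if self._graph.out_degree(n) == 0}

    def active_terms(self) -> list[str]:
        """Accessions of non-obsolete terms, sorted."""
        return sorted(self._graph.nodes)

    def __contains__(self, accession: str) -> bool:
        return accession in self._graph

    def namespace_of(self, accession: str) -> str:
        return self.terms[accession].namespace

    def ancestors(self, accession: str) -> set[str]:
        """Transitive closure of the parent relation, excluding the term."""
        if accession not in self._graph:
            raise KeyError(f"unknown accession: {accession}")
        return set(nx.descendants(self._graph, accession))

    def children(self, accession: str) -> set[str]:
        if accession not in self._graph:
            raise KeyError(f"unknown accession: {accession}")
        return {c for c, _ in self._graph.in_edges(accession)}

    def topological_order(self) -> list[str]:
        """Active terms ordered so every term precedes its parents."""
        return list(nx.topological_sort(self._graph))


def parse_obo(path, *, include_part_of: bool = True) -> GODag:
    """Parse an OBO 1.2 file into a :class:`GODag`.

    is_a edges and (by default) ``relationship: part_of`` edges become parent
    edges.  Obsolete terms are recorded but stripped of all edges.
    Cross-namespace parent edges are dropped with a warning.

    Raises
    ------
    ValidationError
        If the file contains no terms or the parent relation is cyclic.
    OSError
        If the file cannot be read.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    if graph.number_of_nodes() == 0:
        raise ValidationError(f"no terms found in OBO file {path!r}")

    node_ns = {}
    obsolete = set()
    for node, data in graph.nodes(data=True):
        if not _ACCESSION_RE.match(str(node)):
            continue
        node_ns[node] = data.get("namespace", "biological_process")
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
    if not node_ns:
        raise ValidationError(f"no GO terms found in OBO file {path!r}")

    relations = PROPAGATING_RELATIONS if include_part_of else ("is_a",)
    terms: dict[str, GOTerm] = {}
    for node in node_ns:
        data = graph.nodes[node]
        parents: set[str] = set()
        if node not in obsolete:
            for child, parent, key in graph.out_edges(node, keys=True):
                if key not in relations:
                    continue
                if parent not in node_ns or parent in obsolete:
                    continue
                if node_ns[parent] != node_ns[node]:
                    logger.warning(
                        "dropping cross-namespace parent edge %s -> %s",
                        node,
                        parent,
                    )
                    continue
                parents.add(parent)
        terms[node] = GOTerm(
            id=node,
            name=data.get("name", ""),
            namespace=node_ns[node],
            parents=parents,
            obsolete=node in obsolete,
        )
    return GODag(terms)


def ancestors(dag: GODag, term: str) -> set[str]:
    """All ancestors of *term* under the propagating parent relation."""
    return dag.ancestors(term)


def propagate_true_path(matrix, dag: GODag):
    """Close an annotation matrix under the true-path rule.

    Every annotation to a term is copied to all of the term's ancestors that
    have a column in the matrix.  Idempotent; never removes an annotation.

    Parameters
    ----------
    matrix : AnnotationMatrix
        Binary protein x term matrix whose columns are accessions in *dag*.
    """
    missing = [t for t in matrix.terms if t not in dag]
    if missing:
        raise ValidationError(
            f"matrix columns not in ontology: {sorted(missing)}"
        )
    col = {t: i for i, t in enumerate(matrix.terms)}
    values = matrix.values.astype(bool).copy()
    # Children precede parents in topological order, so a single pass of
    # OR-ing each column into its parents' columns yields the full closure.
    for term in dag.topological_order():
        if term not in col:
            continue
        for parent in dag.terms[term].parents:
            if parent in col:
                values[:, col[parent]] |= values[:, col[term]]
    return matrix.with_values(values.astype(np.int8))


def filter_terms(matrix, dag: GODag):
    """Drop namespace-root columns and columns with no annotated protein."""
    roots = set(NAMESPACE_ROOTS.values()) | dag.roots
    keep = [
        j
        for j, t in enumerate(matrix.terms)
        if t not in roots and matrix.values[:, j].any()
    ]
    if not keep:
        raise ValidationError(
            "no terms remain after removing roots and unannotated columns"
        )
    return matrix.select_columns(keep)
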