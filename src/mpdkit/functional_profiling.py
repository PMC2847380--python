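"""Functional categorization: GO-slim rollup and cross-comparison matrices.

Detailed ontology annotations are too fine-grained to compare data sets at a
glance.  A *slim* is a small subset of ontology terms giving a broad
overview; an annotation rolls up to every slim term reachable from it via
child→parent edges (ancestor closure intersected with the slim set, the term
itself included).

Category frequencies use multi-membership counting: a protein annotated with
k categories contributes 1 to each of the k counts ("number of occurrences"
semantics), and a protein with no category counts once under
``uncategorized``.  The conservation identity

    sum over rows of a column  ==  sum over proteins of max(1, #categories)

therefore holds for every column of a cross-comparison matrix and is checked
in the tests.

The ontology input contract is a plain child/parent edge TSV, not OBO;
pathway categorization (KEGG/BioCarta-style) uses a flat protein→pathway
table with no hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

UNCATEGORIZED = "uncategorized"


class OntologyDag:
    """A term DAG given as child→parent edges, with a designated slim set."""

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        slim: Iterable[str] = (),
        extra_terms: Iterable[str] = (),
    ):
        self._parents: dict[str, set[str]] = {}
        self.terms: set[str] = set(extra_terms)
        for child, parent in edges:
            if not child or not parent:
                raise ValidationError("ontology edge endpoints must be non-empty")
            self._parents.setdefault(child, set()).add(parent)
            self.terms.add(child)
            self.terms.add(parent)
        self._assert_acyclic()
        self.slim: set[str] = set(slim)
        missing = self.slim - self.terms
        if missing:
            raise ValidationError(
                f"slim term(s) not in ontology: {sorted(missing)}"
            )
        self._rollup_cache: dict[str, frozenset[str]] = {}

    def _assert_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.terms}
        for root in self.terms:
            if color[root] != WHITE:
                continue
            stack = [(root, iter(sorted(self._parents.get(root, ()))))]
            color[root] = GRAY
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if color[parent] == GRAY:
                        raise ValidationError(
                            f"ontology edges contain a cycle through {parent!r}"
                        )
                    if color[parent] == WHITE:
                        color[parent] = GRAY
                        stack.append((parent, iter(sorted(self._parents.get(parent, ())))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` via parent edges, excluding it."""
        if term not in self.terms:
            raise ValidationError(f"unknown ontology term {term!r}")
        seen: set[str] = set()
        frontier = list(self._parents.get(term, ()))
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            frontier.extend(self._parents.get(node, ()))
        return seen

    def rollup_term(self, term: str) -> frozenset[str]:
        """Slim terms reachable from ``term`` (the term itself included)."""
        cached = self._rollup_cache.get(term)
        if cached is None:
            cached = frozenset(({term} | self.ancestors(term)) & self.slim)
            self._rollup_cache[term] = cached
        return cached

    @classmethod
    def from_tsv(
        cls, edges_path: str | Path, slim_path: str | Path | None = None
    ) -> "OntologyDag":
        """Edges TSV ``child<TAB>parent``; slim list one term per line."""
        edges = []
        with open(edges_path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("child\t"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise FormatError(
                        f"expected 2 tab-separated fields, got {len(fields)}",
                        str(edges_path), lineno,
                    )
                edges.append((fields[0], fields[1]))
        slim: list[str] = []
        if slim_path is not None:
            with open(slim_path, encoding="utf-8") as handle:
                for line in handle:
                    term = line.strip()
                    if term and not term.startswith("#"):
                        slim.append(term)
        return cls(edges, slim=slim)


def rollup_to_slim(terms: Iterable[str], dag: OntologyDag) -> set[str]:
    """Union of per-term slim rollups; errors list every unknown term."""
    terms = list(terms)
    unknown = sorted(set(terms) - dag.terms)
    if unknown:
        raise ValidationError(f"unknown ontology term(s): {unknown}")
    out: set[str] = set()
    for term in terms:
        out |= dag.rollup_term(term)
    return out


def load_annotations(
    path: str | Path, namespace: str | None = None
) -> dict[str, set[str]]:
    """Read annotation TSV ``accession<TAB>category_namespace<TAB>category_id``
    into accession → category-id sets, optionally keeping one namespace."""
    annotations: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("accession\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"expected 3 tab-separated fields, got {len(fields)}",
                    str(path), lineno,
                )
            accession, ns, category = fields
            if namespace is not None and ns != namespace:
                continue
            annotations.setdefault(accession, set()).add(category)
    return annotations


def categories_of(
    accession: str,
    annotations: Mapping[str, Iterable[str]],
    dag: OntologyDag | None = None,
) -> set[str]:
    """A protein's effective categories: its annotation terms, rolled up to
    the slim when a DAG is supplied.  May be empty (→ uncategorized)."""
    raw = set(annotations.get(accession, ()))
    if dag is None:
        return raw
    return rollup_to_slim(raw, dag)


def category_frequencies(
    proteins: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    dag: OntologyDag | None = None,
) -> list[tuple[str, int]]:
    """Per-category protein counts under multi-membership, sorted by count
    descending then category ascending; always includes ``uncategorized``."""
    counts: dict[str, int] = {UNCATEGORIZED: 0}
    for accession in set(proteins):
        cats = categories_of(accession, annotations, dag)
        if not cats:
            counts[UNCATEGORIZED] += 1
            continue
        for cat in cats:
            counts[cat] = counts.get(cat, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def cross_compare(
    data_sets: Sequence[tuple[str, Iterable[str]]] | Mapping[str, Iterable[str]],
    annotations: Mapping[str, Iterable[str]],
    dag: OntologyDag | None = None,
) -> pd.DataFrame:
    """Cross-comparison matrix: categories × data sets, integer counts, plus
    a ``total`` column.  Rows sorted by total descending then category; the
    ``uncategorized`` row is always present."""
    if isinstance(data_sets, Mapping):
        pairs = list(data_sets.items())
    else:
        pairs = list(data_sets)
    labels = [label for label, _ in pairs]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate data-set label(s): {dupes}")
    if len(pairs) < 2:
        raise ValidationError("cross-comparison requires at least 2 data sets")

    columns: dict[str, dict[str, int]] = {}
    categories: set[str] = {UNCATEGORIZED}
    for label, proteins in pairs:
        freqs = dict(category_frequencies(proteins, annotations, dag))
        columns[label] = freqs
        categories |= set(freqs)

    matrix = pd.DataFrame(
        {label: [columns[label].get(cat, 0) for cat in sorted(categories)] for label in labels},
        index=sorted(categories),
        dtype=int,
    )
    matrix["total"] = matrix.sum(axis=1)
    matrix = matrix.sort_values(
        by=["total"], ascending=False, kind="stable"
    )
    # stable tie-break on category id
    matrix = matrix.loc[
        sorted(matrix.index, key=lambda cat: (-int(matrix.at[cat, "total"]), cat))
    ]
    matrix.index.name = "category"
    return matrix
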