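"""Hub-and-spoke protein identifier mapping.

Cross-referencing results from different laboratories requires translating
between the many accession systems in use (NCBI GI numbers, RefSeq, gene
names, ...).  This module routes every translation through a single canonical
*hub* namespace — UniProtKB accessions by default — supporting two mapping
kinds:

* **object mapping**: protein identifier → protein identifier (e.g. GI number
  to UniProtKB accession), composed as exactly two hops through the hub;
* **attribute mapping**: protein identifier → annotation value attached to
  the hub protein (GO term, pathway id, PDB id, taxon, ...).

Restricting composition to two hops through the hub prevents silent drift
through chains of partially-consistent cross-references.  Object edges may be
many-to-one and one-to-many: several aliases can point at one hub accession
(the common "multiple IDs for the same protein" situation) and an ambiguous
alias may point at several hub accessions; all matches are surfaced and
filtering is left to the caller.

Identifier values are compared case-sensitively after trimming surrounding
whitespace; namespaces are case-sensitive.  An object edge may carry a
``verified`` flag (sequence/taxonomy-checked provenance); strict queries drop
unverified edges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import FormatError, NamespaceError, ValidationError

#: Namespace registry seeds: identifier systems commonly bridged through a
#: UniProtKB-centric warehouse, tagged by mapping kind.
DEFAULT_OBJECT_NAMESPACES: tuple[str, ...] = (
    "UniProtKB_AC",
    "UniProtKB_ID",
    "UniParc_AC",
    "GI_Number",
    "GenBank_AC",
    "Genpept_AC",
    "RefSeq_AC",
    "IPI_ID",
    "PIR-PSD_ID",
    "PIR-PSD_AC",
    "SGD_ID",
    "MGI_ID",
    "FLY_ID",
    "TIGR_ID",
    "Entrez_Gene_ID",
    "Gene_Name",
)

DEFAULT_ATTRIBUTE_NAMESPACES: tuple[str, ...] = (
    "GO_ID",
    "KEGG_Pathway_ID",
    "EC_Number",
    "PDB_ID",
    "Taxon_ID",
    "PIRSF_ID",
    "Pfam_ID",
    "OMIM_ID",
    "PubMed_ID",
    "UniRef90_ID",
)

_WS = re.compile(r"\s")


@dataclass(frozen=True, order=True)
class Identifier:
    """A namespaced identifier value, e.g. ``Identifier("GI_Number", "111")``."""

    namespace: str
    value: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", self.value.strip())
        if not self.namespace:
            raise ValidationError("identifier namespace must be non-empty")
        if not self.value:
            raise ValidationError("identifier value must be non-empty")
        if _WS.search(self.value):
            raise ValidationError(
                f"identifier value {self.value!r} contains internal whitespace"
            )


@dataclass(frozen=True)
class MappingResult:
    """Outcome of mapping one query identifier into a target namespace.

    ``status`` is ``"mapped"`` iff ``matches`` is non-empty; matches are
    deduplicated and sorted lexicographically by value.
    """

    query: Identifier
    matches: tuple[Identifier, ...]
    status: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", "mapped" if self.matches else "unmapped")


class MappingStore:
    """In-memory edge store for hub-and-spoke identifier mapping.

    Parameters
    ----------
    hub_namespace:
        The canonical namespace every translation is routed through.
    register_defaults:
        Seed the namespace registry with the common identifier systems
        (``DEFAULT_OBJECT_NAMESPACES`` / ``DEFAULT_ATTRIBUTE_NAMESPACES``).
    """

    def __init__(self, hub_namespace: str = "UniProtKB_AC", register_defaults: bool = True):
        self.hub_namespace = hub_namespace
        self._registry: dict[str, str] = {}  # namespace -> "object" | "attribute"
        # (namespace, source_id) -> {hub_accession: verified}
        self._object_fwd: dict[tuple[str, str], dict[str, bool]] = {}
        # hub_accession -> {(namespace, source_id): verified}
        self._object_rev: dict[str, dict[tuple[str, str], bool]] = {}
        # hub_accession -> {(namespace, value)}
        self._attr: dict[str, set[tuple[str, str]]] = {}
        if register_defaults:
            for name in DEFAULT_OBJECT_NAMESPACES:
                self.register_namespace(name, "object")
            for name in DEFAULT_ATTRIBUTE_NAMESPACES:
                self.register_namespace(name, "attribute")
            if hub_namespace not in self._registry:
                self.register_namespace(hub_namespace, "object")
        else:
            self.register_namespace(hub_namespace, "object")

    # -- registry -----------------------------------------------------------

    def register_namespace(self, name: str, kind: str) -> None:
        if not name:
            raise NamespaceError("namespace name must be non-empty")
        if kind not in ("object", "attribute"):
            raise NamespaceError(f"namespace kind must be 'object' or 'attribute', got {kind!r}")
        if name in self._registry:
            raise NamespaceError(f"namespace {name!r} is already registered")
        self._registry[name] = kind

    def namespace_kind(self, name: str) -> str:
        try:
            return self._registry[name]
        except KeyError:
            raise NamespaceError(f"namespace {name!r} is not registered") from None

    @property
    def namespaces(self) -> Mapping[str, str]:
        return dict(self._registry)

    # -- edges --------------------------------------------------------------

    def add_object_edge(
        self, namespace: str, source_id: str, hub_accession: str, verified: bool = True
    ) -> None:
        if self.namespace_kind(namespace) != "object":
            raise NamespaceError(f"namespace {namespace!r} is not an object namespace")
        source_id = source_id.strip()
        hub_accession = hub_accession.strip()
        if not source_id or not hub_accession:
            raise ValidationError("object edge endpoints must be non-empty")
        self._object_fwd.setdefault((namespace, source_id), {})[hub_accession] = verified
        self._object_rev.setdefault(hub_accession, {})[(namespace, source_id)] = verified

    def add_attribute_edge(self, hub_accession: str, namespace: str, value: str) -> None:
        if self.namespace_kind(namespace) != "attribute":
            raise NamespaceError(f"namespace {namespace!r} is not an attribute namespace")
        hub_accession = hub_accession.strip()
        value = value.strip()
        if not hub_accession or not value:
            raise ValidationError("attribute edge fields must be non-empty")
        self._attr.setdefault(hub_accession, set()).add((namespace, value))

    def iter_object_edges(self) -> Iterator[tuple[str, str, str, bool]]:
        """Yield (namespace, source_id, hub_accession, verified), sorted."""
        rows = [
            (ns, src, hub, verified)
            for (ns, src), hubs in self._object_fwd.items()
            for hub, verified in hubs.items()
        ]
        return iter(sorted(rows))

    def iter_attribute_edges(self) -> Iterator[tuple[str, str, str]]:
        """Yield (hub_accession, namespace, value), sorted."""
        rows = [
            (hub, ns, val) for hub, pairs in self._attr.items() for (ns, val) in pairs
        ]
        return iter(sorted(rows))

    def hub_accessions(self) -> set[str]:
        return set(self._object_rev) | set(self._attr)

    # -- queries ------------------------------------------------------------

    def _hubs_for(self, ident: Identifier, strict: bool) -> set[str]:
        if ident.namespace == self.hub_namespace:
            return {ident.value}
        hubs = self._object_fwd.get((ident.namespace, ident.value), {})
        return {hub for hub, verified in hubs.items() if verified or not strict}

    def map_ids(
        self,
        ids: Sequence[Identifier],
        target_namespace: str,
        strict: bool = False,
    ) -> list[MappingResult]:
        """Map identifiers into ``target_namespace`` through the hub.

        Object targets compose exactly two hops (source → hub → target);
        attribute targets read the hub's attribute edges.  A query already in
        the hub namespace skips the first hop.  Every input id yields exactly
        one result, in input order; matches are deduplicated and sorted.
        """
        target_kind = self.namespace_kind(target_namespace)
        results: list[MappingResult] = []
        for ident in ids:
            self.namespace_kind(ident.namespace)  # raises if unregistered
            hubs = self._hubs_for(ident, strict)
            values: set[str] = set()
            if target_namespace == self.hub_namespace:
                # second hop is the identity; a hub id maps to itself only if
                # it participates in the store at all (or is the query itself)
                values = hubs
            elif target_kind == "object":
                for hub in hubs:
                    for (ns, src), verified in self._object_rev.get(hub, {}).items():
                        if ns == target_namespace and (verified or not strict):
                            values.add(src)
            else:  # attribute
                for hub in hubs:
                    for ns, val in self._attr.get(hub, set()):
                        if ns == target_namespace:
                            values.add(val)
            matches = tuple(
                Identifier(target_namespace, v) for v in sorted(values)
            )
            results.append(MappingResult(query=ident, matches=matches))
        return results

    def reverse_map(
        self,
        ids: Sequence[Identifier],
        source_namespace: str,
        strict: bool = False,
    ) -> list[MappingResult]:
        """For hub-namespace ids, list the ``source_namespace`` aliases that
        reach each of them through object edges."""
        for ident in ids:
            if ident.namespace != self.hub_namespace:
                raise ValidationError(
                    f"reverse_map expects {self.hub_namespace} identifiers, "
                    f"got namespace {ident.namespace!r}"
                )
        return self.map_ids(ids, source_namespace, strict=strict)

    # -- I/O ----------------------------------------------------------------

    def load_object_edges(self, path: str | Path) -> int:
        """Load 3- or 4-column TSV ``namespace<TAB>source_id<TAB>hub_accession
        [<TAB>verified|unverified]``; '#' comment lines skipped.  Returns the
        number of edges loaded."""
        n = 0
        for lineno, fields in _iter_tsv(path):
            if len(fields) not in (3, 4):
                raise FormatError(
                    f"expected 3 or 4 tab-separated fields, got {len(fields)}",
                    str(path), lineno,
                )
            verified = True
            if len(fields) == 4:
                flag = fields[3].strip().lower()
                if flag not in ("verified", "unverified"):
                    raise FormatError(
                        f"verification flag must be 'verified' or 'unverified', got {fields[3]!r}",
                        str(path), lineno,
                    )
                verified = flag == "verified"
            try:
                self.add_object_edge(fields[0], fields[1], fields[2], verified=verified)
            except ValidationError as exc:
                raise FormatError(str(exc), str(path), lineno) from exc
            n += 1
        return n

    def load_attribute_edges(self, path: str | Path) -> int:
        """Load TSV ``hub_accession<TAB>namespace<TAB>value``."""
        n = 0
        for lineno, fields in _iter_tsv(path):
            if len(fields) != 3:
                raise FormatError(
                    f"expected 3 tab-separated fields, got {len(fields)}",
                    str(path), lineno,
                )
            try:
                self.add_attribute_edge(fields[0], fields[1], fields[2])
            except ValidationError as exc:
                raise FormatError(str(exc), str(path), lineno) from exc
            n += 1
        return n


def _iter_tsv(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def format_results(results: Iterable[MappingResult]) -> str:
    """Render mapping results as the canonical TSV with header
    ``query_id<TAB>matches<TAB>status`` (matches ';'-joined)."""
    lines = ["query_id\tmatches\tstatus"]
    for res in results:
        joined = ";".join(m.value for m in res.matches)
        lines.append(f"{res.query.value}\t{joined}\t{res.status}")
    return "\n".join(lines) + "\n"
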