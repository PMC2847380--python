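"""Structured assertions: the queryable core of a master protein directory.

High-throughput studies bury their conclusions ("protein V increased under
condition W") in supplementary tables.  A *structured assertion* captures
exactly that minimal result — protein, experiment, condition keywords, and
an expression status from the closed vocabulary {increase, decrease,
present} — so results from mass spectrometry, microarray, interaction,
clone, and structure experiments become jointly queryable.

The headline query is the cross-data-type intersection: "which proteins of
taxon T have data from interaction AND microarray AND mass spectrometry?" —
set-intersection semantics over the per-type assertion coverage.

Status aggregation collapses a protein's assertions over a set of data types
into a single call for display (a network node gets one color):

* any increase together with any decrease → ``conflict`` (surfaced, never
  majority-voted away);
* increase or decrease dominates ``present``;
* all present → ``present``; no assertions → ``none``.

For presence-style filters, a protein asserted increased or decreased is
also considered present (a change implies detection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DATA_TYPES = frozenset(
    {"mass_spectrometry", "microarray", "interaction", "clone", "structure"}
)

EXPRESSION_STATUSES = ("increase", "decrease", "present")

#: Aggregation policies by name; only the conflict-surfacing collapse is
#: implemented, but the policy is named so callers state their intent.
AGGREGATION_POLICIES = ("surface_conflict",)


@dataclass(frozen=True)
class Experiment:
    experiment_id: str
    data_type: str
    taxon: int
    center: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.experiment_id:
            raise ValidationError("experiment id must be non-empty")
        if self.data_type not in DATA_TYPES:
            raise ValidationError(
                f"unknown data type {self.data_type!r}; allowed: {sorted(DATA_TYPES)}"
            )


@dataclass(frozen=True)
class Assertion:
    """`accession` had `status` in `experiment_id` under `keywords`."""

    accession: str
    experiment_id: str
    keywords: frozenset[str]
    status: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "keywords", frozenset(k.strip().lower() for k in self.keywords if k.strip())
        )
        if self.status not in EXPRESSION_STATUSES:
            raise ValidationError(
                f"unknown expression status {self.status!r}; "
                f"allowed: {{{', '.join(EXPRESSION_STATUSES)}}}"
            )

    @property
    def key(self) -> tuple[str, str, frozenset[str]]:
        return (self.accession, self.experiment_id, self.keywords)


def aggregate_statuses(statuses: Iterable[str]) -> str:
    """Collapse a multiset of statuses (may include 'conflict') into one of
    increase | decrease | present | conflict | none."""
    seen = set(statuses)
    if not seen:
        return "none"
    unknown = seen - {"increase", "decrease", "present", "conflict"}
    if unknown:
        raise ValidationError(f"cannot aggregate unknown status(es) {sorted(unknown)}")
    if "conflict" in seen or {"increase", "decrease"} <= seen:
        return "conflict"
    if "increase" in seen:
        return "increase"
    if "decrease" in seen:
        return "decrease"
    return "present"


@dataclass(frozen=True)
class QueryHit:
    """One accession satisfying a cross-data-type query, with the qualifying
    experiment ids grouped by data type."""

    accession: str
    experiments_by_type: Mapping[str, tuple[str, ...]]


class AssertionStore:
    """Validated in-memory store of experiments and assertions."""

    def __init__(self) -> None:
        self._experiments: dict[str, Experiment] = {}
        self._assertions: dict[tuple, Assertion] = {}

    # -- loading ------------------------------------------------------------

    def add_experiment(self, experiment: Experiment) -> None:
        if experiment.experiment_id in self._experiments:
            raise ValidationError(f"duplicate experiment id {experiment.experiment_id!r}")
        self._experiments[experiment.experiment_id] = experiment

    def add_assertion(self, assertion: Assertion) -> None:
        if assertion.experiment_id not in self._experiments:
            raise ValidationError(
                f"assertion references unknown experiment {assertion.experiment_id!r}"
            )
        existing = self._assertions.get(assertion.key)
        if existing is not None:
            if existing.status == assertion.status:
                logger.warning(
                    "duplicate assertion for %s in %s collapsed",
                    assertion.accession, assertion.experiment_id,
                )
                return
            raise ValidationError(
                f"conflicting duplicate assertion for {assertion.accession!r} in "
                f"{assertion.experiment_id!r}: {existing.status} vs {assertion.status}"
            )
        self._assertions[assertion.key] = assertion

    @classmethod
    def load(
        cls,
        experiments_path: str | Path,
        assertions_path: str | Path,
        known_accessions: Iterable[str] | None = None,
    ) -> "AssertionStore":
        """Load the two-table TSV representation.

        Experiments: ``experiment_id<TAB>data_type<TAB>taxon<TAB>center<TAB>description``.
        Assertions: ``accession<TAB>experiment_id<TAB>keywords(;-joined)<TAB>status``.
        ``known_accessions``, when given, enforces referential integrity of
        assertion accessions against a protein store.
        """
        store = cls()
        for lineno, fields in _iter_tsv(experiments_path, expected=5, header="experiment_id"):
            try:
                store.add_experiment(
                    Experiment(
                        experiment_id=fields[0],
                        data_type=fields[1],
                        taxon=int(fields[2]),
                        center=fields[3],
                        description=fields[4],
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise FormatError(str(exc), str(experiments_path), lineno) from exc
        known = set(known_accessions) if known_accessions is not None else None
        for lineno, fields in _iter_tsv(assertions_path, expected=4, header="accession"):
            accession = fields[0]
            if known is not None and accession not in known:
                raise FormatError(
                    f"assertion references unknown accession {accession!r}",
                    str(assertions_path), lineno,
                )
            keywords = frozenset(k for k in fields[2].split(";") if k)
            try:
                store.add_assertion(
                    Assertion(
                        accession=accession,
                        experiment_id=fields[1],
                        keywords=keywords,
                        status=fields[3],
                    )
                )
            except ValidationError as exc:
                raise FormatError(str(exc), str(assertions_path), lineno) from exc
        return store

    def dump(self, experiments_path: str | Path, assertions_path: str | Path) -> None:
        """Canonical (sorted) TSV serialization; load→dump→load is stable."""
        with open(experiments_path, "w", encoding="utf-8") as out:
            out.write("experiment_id\tdata_type\ttaxon\tcenter\tdescription\n")
            for eid in sorted(self._experiments):
                e = self._experiments[eid]
                out.write(f"{e.experiment_id}\t{e.data_type}\t{e.taxon}\t{e.center}\t{e.description}\n")
        rows = sorted(
            (a.accession, a.experiment_id, ";".join(sorted(a.keywords)), a.status)
            for a in self._assertions.values()
        )
        with open(assertions_path, "w", encoding="utf-8") as out:
            out.write("accession\texperiment_id\tcondition_keywords\texpression_status\n")
            for row in rows:
                out.write("\t".join(row) + "\n")

    # -- access -------------------------------------------------------------

    @property
    def experiments(self) -> Mapping[str, Experiment]:
        return dict(self._experiments)

    def assertions(self) -> list[Assertion]:
        return [self._assertions[k] for k in sorted(self._assertions, key=_key_sort)]

    def assertions_for(self, accession: str) -> list[Assertion]:
        return [a for a in self.assertions() if a.accession == accession]

    def __len__(self) -> int:
        return len(self._assertions)

    # -- queries ------------------------------------------------------------

    def _qualifying(
        self,
        taxon: int | None,
        keywords: Iterable[str] | None,
        status: str | None,
    ) -> list[Assertion]:
        wanted_keywords = (
            frozenset(k.strip().lower() for k in keywords) if keywords else frozenset()
        )
        if status is not None and status not in EXPRESSION_STATUSES:
            raise ValidationError(
                f"unknown expression status {status!r}; "
                f"allowed: {{{', '.join(EXPRESSION_STATUSES)}}}"
            )
        out = []
        for assertion in self._assertions.values():
            experiment = self._experiments[assertion.experiment_id]
            if taxon is not None and experiment.taxon != taxon:
                continue
            if wanted_keywords and not wanted_keywords <= assertion.keywords:
                continue
            if status is not None:
                if status == "present":
                    pass  # increase/decrease imply presence
                elif assertion.status != status:
                    continue
            out.append(assertion)
        return out

    def query_proteins(
        self,
        required_types: Iterable[str] = (),
        taxon: int | None = None,
        keywords: Iterable[str] | None = None,
        status: str | None = None,
    ) -> list[QueryHit]:
        """Accessions with at least one qualifying assertion in EVERY
        required data type, sorted lexicographically.

        With no required types, returns every accession holding at least one
        qualifying assertion.  Each hit carries its qualifying experiment ids
        grouped by data type (all types, not only the required ones).
        """
        required = set(required_types)
        unknown = required - DATA_TYPES
        if unknown:
            raise ValidationError(
                f"unknown data type(s) {sorted(unknown)}; allowed: {sorted(DATA_TYPES)}"
            )
        by_acc: dict[str, dict[str, set[str]]] = {}
        for assertion in self._qualifying(taxon, keywords, status):
            dtype = self._experiments[assertion.experiment_id].data_type
            by_acc.setdefault(assertion.accession, {}).setdefault(dtype, set()).add(
                assertion.experiment_id
            )
        hits = []
        for acc in sorted(by_acc):
            per_type = by_acc[acc]
            if required <= set(per_type):
                hits.append(
                    QueryHit(
                        accession=acc,
                        experiments_by_type={
                            t: tuple(sorted(ids)) for t, ids in sorted(per_type.items())
                        },
                    )
                )
        return hits

    def expression_status_of(
        self,
        accession: str,
        data_types: Iterable[str],
        aggregation: str = "surface_conflict",
    ) -> str:
        """Collapse the accession's assertions over the given data types to a
        single status (increase | decrease | present | conflict | none)."""
        if aggregation not in AGGREGATION_POLICIES:
            raise ValidationError(
                f"unknown aggregation policy {aggregation!r}; allowed: {AGGREGATION_POLICIES}"
            )
        wanted = set(data_types)
        unknown = wanted - DATA_TYPES
        if unknown:
            raise ValidationError(f"unknown data type(s) {sorted(unknown)}")
        statuses = [
            a.status
            for a in self._assertions.values()
            if a.accession == accession
            and self._experiments[a.experiment_id].data_type in wanted
        ]
        return aggregate_statuses(statuses)


def _key_sort(key: tuple) -> tuple:
    accession, experiment_id, keywords = key
    return (accession, experiment_id, tuple(sorted(keywords)))


def _iter_tsv(path: str | Path, expected: int, header: str):
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(header + "\t"):
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise FormatError(
                    f"expected {expected} tab-separated fields, got {len(fields)}",
                    str(path), lineno,
                )
            yield lineno, fields


def format_query_hits(hits: Iterable[QueryHit]) -> str:
    """TSV ``accession<TAB>data_type<TAB>experiment_ids(;-joined)`` — one row
    per (accession, data type)."""
    lines = ["accession\tdata_type\texperiment_ids"]
    for hit in hits:
        for dtype, ids in hit.experiments_by_type.items():
            lines.append(f"{hit.accession}\t{dtype}\t{';'.join(ids)}")
    return "\n".join(lines) + "\n"
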