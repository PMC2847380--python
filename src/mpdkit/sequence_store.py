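"""FASTA-backed protein store and exact peptide-match search.

Peptide sequences observed in MS/MS experiments can be used as queries to
find every protein containing an exact substring match, optionally restricted
to a taxon or set of taxa.  Matching is strictly literal: ambiguity codes
(B, X, Z, J) are ordinary residues, never wildcards, and I/L are distinct.
Overlapping occurrences are all reported.

The multi-pattern search runs a single-pass Aho-Corasick automaton over each
sequence; below a configurable pattern-count threshold a naive per-record
substring scan is used instead (cheaper than building the automaton for one
or two peptides).  Both paths implement the same contract and are checked
against each other in the test suite.

FASTA header dialect::

    >ACCESSION taxon=<int> <organism free text>

Unknown ``key=value`` tokens are ignored.  Coordinates in hits are 1-based
inclusive, following protein feature-table convention.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .errors import FormatError, ValidationError

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

#: Below this many distinct query peptides the naive scan is used.
NAIVE_FALLBACK_THRESHOLD = 4


@dataclass(frozen=True)
class ProteinRecord:
    """One canonical protein: hub accession, taxon, organism, sequence."""

    accession: str
    taxon: int
    organism: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.accession:
            raise ValidationError("protein accession must be non-empty")
        if not self.sequence:
            raise ValidationError(f"protein {self.accession}: sequence is empty")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.accession}: illegal residue(s) {sorted(bad)}"
            )


@dataclass(frozen=True, order=True)
class PeptideHit:
    """An exact occurrence of a query peptide, 1-based inclusive coordinates."""

    accession: str
    start: int
    end: int
    peptide: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.peptide):
            raise ValidationError(
                f"hit span [{self.start},{self.end}] inconsistent with "
                f"peptide length {len(self.peptide)}"
            )


class SequenceStore:
    """Mapping of accession → :class:`ProteinRecord` with peptide search."""

    def __init__(self, records: Iterable[ProteinRecord] = ()):
        self._records: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self._records:
            raise ValidationError(f"duplicate accession {record.accession!r}")
        self._records[record.accession] = record

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._records[accession]

    def get(self, accession: str) -> ProteinRecord | None:
        return self._records.get(accession)

    def records(self) -> Iterator[ProteinRecord]:
        """Records in sorted accession order."""
        for acc in sorted(self._records):
            yield self._records[acc]

    def accessions(self) -> list[str]:
        return sorted(self._records)

    def taxa(self) -> set[int]:
        return {rec.taxon for rec in self._records.values()}

    def subset(self, taxa: int | Iterable[int]) -> "SequenceStore":
        """New store restricted to the given taxon id(s)."""
        wanted = {taxa} if isinstance(taxa, int) else set(taxa)
        return SequenceStore(
            rec for rec in self.records() if rec.taxon in wanted
        )

    # -- FASTA I/O ----------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceStore":
        store = cls()
        for entry in SeqIO.parse(str(path), "fasta"):
            accession = entry.id
            taxon, organism = _parse_header(entry.description, path, accession)
            try:
                store.add(
                    ProteinRecord(
                        accession=accession,
                        taxon=taxon,
                        organism=organism,
                        sequence=str(entry.seq),
                    )
                )
            except ValidationError as exc:
                raise FormatError(str(exc), str(path)) from exc
        return store

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as out:
            for rec in self.records():
                out.write(f">{rec.accession} taxon={rec.taxon} {rec.organism}\n")
                for i in range(0, len(rec.sequence), 60):
                    out.write(rec.sequence[i : i + 60] + "\n")

    # -- peptide match ------------------------------------------------------

    def peptide_match(
        self,
        peptides: Sequence[str],
        taxa: int | Iterable[int] | None = None,
        naive_threshold: int = NAIVE_FALLBACK_THRESHOLD,
    ) -> list[PeptideHit]:
        """Report every exact (possibly overlapping) occurrence of every
        query peptide, sorted by (accession, start, peptide).

        ``taxa`` restricts the search to records of the given taxon id(s).
        """
        queries = _validate_peptides(peptides)
        store = self if taxa is None else self.subset(taxa)
        if len(queries) < naive_threshold:
            hits = _naive_scan(store.records(), queries)
        else:
            hits = _automaton_scan(store.records(), queries)
        return sorted(hits)


def _validate_peptides(peptides: Sequence[str]) -> list[str]:
    queries: list[str] = []
    seen: set[str] = set()
    for pep in peptides:
        if not pep:
            raise ValidationError("empty peptide query")
        bad = set(pep.upper()) - AMINO_ALPHABET
        if bad:
            raise ValidationError(
                f"peptide {pep!r}: illegal character(s) {sorted(bad)}"
            )
        pep = pep.upper()
        if pep not in seen:
            seen.add(pep)
            queries.append(pep)
    return queries


def _naive_scan(records: Iterable[ProteinRecord], queries: list[str]) -> list[PeptideHit]:
    hits: list[PeptideHit] = []
    for rec in records:
        seq = rec.sequence
        for pep in queries:
            pos = seq.find(pep)
            while pos != -1:
                hits.append(
                    PeptideHit(rec.accession, pos + 1, pos + len(pep), pep)
                )
                pos = seq.find(pep, pos + 1)
    return hits


class AhoCorasick:
    """Dict-based Aho-Corasick automaton over the amino-acid alphabet.

    Reports every (end position, pattern) pair in one left-to-right pass,
    including overlapping and nested occurrences (via output links).
    """

    def __init__(self, patterns: Iterable[str]):
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._out: list[list[str]] = [[]]
        for pat in patterns:
            self._insert(pat)
        self._build_links()

    def _insert(self, pattern: str) -> None:
        state = 0
        for ch in pattern:
            nxt = self._goto[state].get(ch)
            if nxt is None:
                nxt = len(self._goto)
                self._goto[state][ch] = nxt
                self._goto.append({})
                self._fail.append(0)
                self._out.append([])
            state = nxt
        self._out[state].append(pattern)

    def _build_links(self) -> None:
        queue: deque[int] = deque()
        for state in self._goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                fallback = self._fail[state]
                while fallback and ch not in self._goto[fallback]:
                    fallback = self._fail[fallback]
                self._fail[nxt] = self._goto[fallback].get(ch, 0)
                if self._fail[nxt] == nxt:
                    self._fail[nxt] = 0
                # merge output link: suffix matches end here too
                self._out[nxt] = self._out[nxt] + self._out[self._fail[nxt]]

    def scan(self, text: str) -> Iterator[tuple[int, str]]:
        """Yield (0-based end index, pattern) for every occurrence."""
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for pat in self._out[state]:
                yield i, pat


def _automaton_scan(
    records: Iterable[ProteinRecord], queries: list[str]
) -> list[PeptideHit]:
    automaton = AhoCorasick(queries)
    hits: list[PeptideHit] = []
    for rec in records:
        for end_idx, pep in automaton.scan(rec.sequence):
            start = end_idx - len(pep) + 2  # 1-based inclusive
            hits.append(PeptideHit(rec.accession, start, end_idx + 1, pep))
    return hits


def format_hits(hits: Iterable[PeptideHit], store: SequenceStore) -> str:
    """Canonical TSV ``peptide<TAB>accession<TAB>start<TAB>end<TAB>taxon``."""
    lines = ["peptide\taccession\tstart\tend\ttaxon"]
    for hit in hits:
        taxon = store[hit.accession].taxon
        lines.append(f"{hit.peptide}\t{hit.accession}\t{hit.start}\t{hit.end}\t{taxon}")
    return "\n".join(lines) + "\n"


def _parse_header(description: str, path: str | Path, accession: str):
    taxon: int | None = None
    organism_tokens: list[str] = []
    tokens = description.split()
    for tok in tokens[1:]:  # tokens[0] is the accession
        if "=" in tok:
            key, _, value = tok.partition("=")
            if key == "taxon":
                try:
                    taxon = int(value)
                except ValueError:
                    raise FormatError(
                        f"record {accession!r}: taxon={value!r} is not an integer",
                        str(path),
                    ) from None
            # unknown key=value tokens are ignored
        else:
            organism_tokens.append(tok)
    if taxon is None:
        raise FormatError(
            f"record {accession!r}: header lacks required taxon=<int> token",
            str(path),
        )
    return taxon, " ".join(organism_tokens)
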