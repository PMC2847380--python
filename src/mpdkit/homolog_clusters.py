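"""UniRef90-style homolog clustering for cross-species bridging.

Interaction screens are often run against one host species (e.g. human)
while expression data come from a model host (e.g. mouse macrophages).
Clustering all sequences at high ungapped identity groups close homologs,
letting a human interactor "bridge" to the mouse proteins that carry the
expression signal.

Identity definition
-------------------
Production reference clusters are built with gapped-alignment tools and
coverage rules; here "no gaps" is taken literally: the identity between two
sequences is the best *ungapped sliding alignment* of the shorter within the
longer::

    identity(a, b) = max over offsets of  (#identical positions) / len(shorter)

This tolerates terminal extensions but admits no internal gaps, and makes
substitution-only synthetic families land at exactly their planted identity.

Clustering is greedy and incremental: records are taken longest-first
(ties broken by accession), each joining the first existing cluster whose
*representative* it matches at >= threshold, else founding its own cluster.
Representatives are therefore mutually below threshold by construction, and
the member sets partition the input.  Complexity is O(n^2 * L) worst case;
intended for stores up to ~1,000 sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, ValidationError
from .sequence_store import SequenceStore

CLUSTER_ID_PREFIX = "UR90-"
DEFAULT_THRESHOLD = 0.90


def ungapped_identity(a: str, b: str) -> float:
    """Best ungapped sliding-window identity of the shorter sequence within
    the longer, as a fraction of the shorter sequence's length."""
    if not a or not b:
        raise ValidationError("identity is undefined for empty sequences")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    s = np.frombuffer(short.encode("ascii"), dtype=np.uint8)
    l = np.frombuffer(long_.encode("ascii"), dtype=np.uint8)
    n = len(s)
    best = 0
    for offset in range(len(l) - n + 1):
        matches = int(np.count_nonzero(s == l[offset : offset + n]))
        if matches > best:
            best = matches
            if best == n:
                break
    return best / n


@dataclass(frozen=True)
class HomologCluster:
    """A representative accession plus the members grouped under it."""

    cluster_id: str
    representative: str
    members: tuple[str, ...]  # sorted, includes representative
    threshold: float

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValidationError(
                f"cluster {self.cluster_id}: representative not among members"
            )


class ClusterSet:
    """The clusters over a store, plus per-member taxon ids for bridging."""

    def __init__(self, clusters: Sequence[HomologCluster], member_taxa: Mapping[str, int]):
        self.clusters = sorted(clusters, key=lambda c: c.cluster_id)
        self.member_taxa = dict(member_taxa)
        self._cluster_of: dict[str, HomologCluster] = {}
        for cluster in self.clusters:
            for member in cluster.members:
                if member in self._cluster_of:
                    raise ValidationError(
                        f"accession {member!r} appears in more than one cluster"
                    )
                self._cluster_of[member] = cluster

    def __len__(self) -> int:
        return len(self.clusters)

    def cluster_of(self, accession: str) -> HomologCluster | None:
        return self._cluster_of.get(accession)

    def partition(self) -> list[tuple[str, ...]]:
        """Member sets as sorted tuples, sorted by first member."""
        return sorted(cluster.members for cluster in self.clusters)

    def bridge(
        self, accessions: Iterable[str], target_taxon: int
    ) -> dict[str, list[str]]:
        """For each query accession, the co-cluster members of the target
        taxon (excluding the query itself), sorted.  Accessions absent from
        every cluster map to an empty list; :meth:`unbridged` lists them."""
        out: dict[str, list[str]] = {}
        for acc in accessions:
            cluster = self._cluster_of.get(acc)
            if cluster is None:
                out[acc] = []
                continue
            out[acc] = sorted(
                m
                for m in cluster.members
                if m != acc and self.member_taxa.get(m) == target_taxon
            )
        return out

    def unbridged(self, accessions: Iterable[str]) -> list[str]:
        return sorted(a for a in accessions if a not in self._cluster_of)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as out:
            out.write("cluster_id\trepresentative\tmember\tmember_taxon\n")
            for cluster in self.clusters:
                for member in cluster.members:
                    taxon = self.member_taxa.get(member, "")
                    out.write(
                        f"{cluster.cluster_id}\t{cluster.representative}\t{member}\t{taxon}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = DEFAULT_THRESHOLD) -> "ClusterSet":
        rows: dict[str, dict] = {}
        taxa: dict[str, int] = {}
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("cluster_id\t"):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise FormatError(
                        f"expected 4 tab-separated fields, got {len(fields)}",
                        str(path), lineno,
                    )
                cid, rep, member, taxon = fields
                entry = rows.setdefault(cid, {"rep": rep, "members": []})
                if entry["rep"] != rep:
                    raise FormatError(
                        f"cluster {cid}: conflicting representatives", str(path), lineno
                    )
                entry["members"].append(member)
                if taxon:
                    try:
                        taxa[member] = int(taxon)
                    except ValueError:
                        raise FormatError(
                            f"member_taxon {taxon!r} is not an integer", str(path), lineno
                        ) from None
        clusters = [
            HomologCluster(cid, entry["rep"], tuple(sorted(entry["members"])), threshold)
            for cid, entry in rows.items()
        ]
        return cls(clusters, taxa)


def cluster_sequences(
    store: SequenceStore, threshold: float = DEFAULT_THRESHOLD
) -> ClusterSet:
    """Greedy incremental clustering of a sequence store at an ungapped
    identity threshold; see module docstring for the exact procedure."""
    if len(store) == 0:
        raise ValidationError("cannot cluster an empty store")
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")

    order = sorted(store.records(), key=lambda r: (-len(r.sequence), r.accession))
    reps: list[tuple[str, str]] = []  # (accession, sequence), creation order
    members: list[list[str]] = []
    for rec in order:
        for idx, (_rep_acc, rep_seq) in enumerate(reps):
            if ungapped_identity(rec.sequence, rep_seq) >= threshold:
                members[idx].append(rec.accession)
                break
        else:
            reps.append((rec.accession, rec.sequence))
            members.append([rec.accession])

    clusters = [
        HomologCluster(
            cluster_id=CLUSTER_ID_PREFIX + rep_acc,
            representative=rep_acc,
            members=tuple(sorted(mem)),
            threshold=threshold,
        )
        for (rep_acc, _), mem in zip(reps, members)
    ]
    taxa = {rec.accession: rec.taxon for rec in store.records()}
    return ClusterSet(clusters, taxa)


def bridge_homologs(
    accessions: Sequence[str], clusters: ClusterSet, target_taxon: int
) -> dict[str, list[str]]:
    """Convenience wrapper around :meth:`ClusterSet.bridge`."""
    return clusters.bridge(accessions, target_taxon)
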