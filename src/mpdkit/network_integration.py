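"""Pathogen-host interaction network with expression-status overlay.

A yeast two-hybrid screen yields binary pathogen protein ↔ host protein
edges.  Expression responses to infection, however, are usually measured in
a model host (mouse macrophages), so a host interactor's status is read off
its close homologs in the assay species, found via the homolog clusters.

Node status uses the assertion-store aggregation over microarray and mass
spectrometry assertions: a pathogen node from its own assertions, a host
node from assertions on itself plus every bridged assay-species homolog
(conflicting directions across homologs surface as ``conflict``); nodes with
no signal get ``none``.

*Prioritized interactions* are the edges whose host protein decreased on
infection; the highest tier additionally has an increased pathogen partner —
concordant expression changes on both sides of a physical interaction being
the strongest desk-screen evidence that the interaction matters in vivo.

Export targets Cytoscape: a SIF edge file (pathogen → host) and a node
attribute TSV; both are written deterministically so reruns are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .assertion_store import AssertionStore, aggregate_statuses
from .errors import FormatError, ValidationError
from .homolog_clusters import ClusterSet
from .sequence_store import SequenceStore

EXPRESSION_DATA_TYPES = frozenset({"microarray", "mass_spectrometry"})


@dataclass(frozen=True, order=True)
class InteractionEdge:
    pathogen: str
    host: str
    experiment_id: str
    method: str = "Y2H"

    def __post_init__(self) -> None:
        if not self.pathogen or not self.host:
            raise ValidationError("interaction edge endpoints must be non-empty")


@dataclass(frozen=True)
class NodeInfo:
    accession: str
    role: str  # "pathogen" | "host"
    status: str  # increase | decrease | present | conflict | none
    taxon: int | None


@dataclass
class OverlayNetwork:
    nodes: dict[str, NodeInfo]
    edges: list[InteractionEdge]
    #: host accession -> bridged assay-species accessions that contributed
    #: a (non-none) status
    bridging: dict[str, list[str]]

    def status_of(self, accession: str) -> str:
        return self.nodes[accession].status


@dataclass(frozen=True)
class PrioritizedInteraction:
    pathogen: str
    host: str
    pathogen_status: str
    host_status: str
    #: highest tier: host decreased AND pathogen increased
    pathogen_increased: bool


def load_interactions(path: str | Path) -> list[InteractionEdge]:
    """TSV ``pathogen_acc<TAB>host_acc<TAB>experiment_id<TAB>method``."""
    edges: list[InteractionEdge] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("pathogen_acc\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(
                    f"expected 4 tab-separated fields, got {len(fields)}",
                    str(path), lineno,
                )
            edges.append(InteractionEdge(*fields))
    return edges


def write_interactions(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("pathogen_acc\thost_acc\texperiment_id\tmethod\n")
        for e in edges:
            out.write(f"{e.pathogen}\t{e.host}\t{e.experiment_id}\t{e.method}\n")


def build_overlay(
    edges: Sequence[InteractionEdge],
    assertions: AssertionStore,
    clusters: ClusterSet,
    assay_taxon: int,
    protein_store: SequenceStore | None = None,
) -> OverlayNetwork:
    """Construct the overlay network; see module docstring for semantics.

    ``protein_store``, when given, validates edge endpoints (errors list all
    offenders) and supplies node taxon ids; otherwise taxa come from the
    cluster table where known.
    """
    if protein_store is not None:
        missing = sorted(
            {e.pathogen for e in edges if e.pathogen not in protein_store}
            | {e.host for e in edges if e.host not in protein_store}
        )
        if missing:
            raise ValidationError(
                f"interaction endpoint(s) missing from protein store: {missing}"
            )
    for e in edges:
        experiment = assertions.experiments.get(e.experiment_id)
        if experiment is not None and experiment.data_type != "interaction":
            raise ValidationError(
                f"edge experiment {e.experiment_id!r} has data type "
                f"{experiment.data_type!r}, expected 'interaction'"
            )

    pathogens = sorted({e.pathogen for e in edges})
    hosts = sorted({e.host for e in edges})
    overlap = set(pathogens) & set(hosts)
    if overlap:
        raise ValidationError(
            f"accession(s) appear on both sides of the network: {sorted(overlap)}"
        )

    def taxon_of(acc: str) -> int | None:
        if protein_store is not None and acc in protein_store:
            return protein_store[acc].taxon
        return clusters.member_taxa.get(acc)

    nodes: dict[str, NodeInfo] = {}
    bridging: dict[str, list[str]] = {}

    for acc in pathogens:
        status = assertions.expression_status_of(acc, EXPRESSION_DATA_TYPES)
        nodes[acc] = NodeInfo(acc, "pathogen", status, taxon_of(acc))

    homologs = clusters.bridge(hosts, assay_taxon)
    for acc in hosts:
        contributors: list[str] = []
        statuses: list[str] = []
        own = assertions.expression_status_of(acc, EXPRESSION_DATA_TYPES)
        if own != "none":
            statuses.append(own)
            contributors.append(acc)
        for homolog in homologs.get(acc, []):
            st = assertions.expression_status_of(homolog, EXPRESSION_DATA_TYPES)
            if st != "none":
                statuses.append(st)
                contributors.append(homolog)
        nodes[acc] = NodeInfo(acc, "host", aggregate_statuses(statuses), taxon_of(acc))
        bridging[acc] = contributors

    return OverlayNetwork(nodes=nodes, edges=sorted(edges), bridging=bridging)


def prioritize_interactions(network: OverlayNetwork) -> list[PrioritizedInteraction]:
    """Edges whose host protein decreased on infection, sorted by
    (pathogen, host); ``pathogen_increased`` marks the highest tier."""
    seen: set[tuple[str, str]] = set()
    out: list[PrioritizedInteraction] = []
    for edge in sorted(network.edges):
        pair = (edge.pathogen, edge.host)
        if pair in seen:
            continue
        seen.add(pair)
        host_status = network.nodes[edge.host].status
        if host_status != "decrease":
            continue
        pathogen_status = network.nodes[edge.pathogen].status
        out.append(
            PrioritizedInteraction(
                pathogen=edge.pathogen,
                host=edge.host,
                pathogen_status=pathogen_status,
                host_status=host_status,
                pathogen_increased=pathogen_status == "increase",
            )
        )
    return out


def export_cytoscape(network: OverlayNetwork, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.sif`` (pathogen → host, interaction type from the
    edge method, lowercased) and ``<prefix>.node_attrs.tsv``; deterministic
    ordering, byte-identical on re-export."""
    out_prefix = Path(out_prefix)
    sif_path = out_prefix.with_name(out_prefix.name + ".sif")
    attrs_path = out_prefix.with_name(out_prefix.name + ".node_attrs.tsv")

    sif_lines = sorted(
        (e.pathogen, (e.method or "y2h").lower(), e.host) for e in network.edges
    )
    with open(sif_path, "w", encoding="utf-8") as out:
        for source, itype, target in sif_lines:
            out.write(f"{source}\t{itype}\t{target}\n")

    with open(attrs_path, "w", encoding="utf-8") as out:
        out.write("accession\trole\tstatus\ttaxon\n")
        for acc in sorted(network.nodes):
            node = network.nodes[acc]
            taxon = "" if node.taxon is None else str(node.taxon)
            out.write(f"{acc}\t{node.role}\t{node.status}\t{taxon}\n")
    return sif_path, attrs_path


def parse_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a SIF file back as (source, interaction type, target) rows."""
    rows: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"expected 3 tab-separated fields, got {len(fields)}",
                    str(path), lineno,
                )
            rows.append((fields[0], fields[1], fields[2]))
    return rows
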