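"""Network overlay: status tracing through homolog bridges, prioritization
against planted ground truth, and Cytoscape export round trips."""

import random

import pytest

from mpdkit.assertion_store import Assertion, AssertionStore, Experiment
from mpdkit.errors import ValidationError
from mpdkit.homolog_clusters import cluster_sequences
from mpdkit.network_integration import (
    InteractionEdge,
    build_overlay,
    export_cytoscape,
    load_interactions,
    parse_sif,
    prioritize_interactions,
)
from mpdkit.sequence_store import ProteinRecord, SequenceStore

PATHOGEN, HOST, ASSAY = 1392, 9606, 10090


def tiny_world(mouse_statuses=("decrease",), pathogen_status="increase"):
    """One pathogen-host edge; the host's mouse homolog(s) carry the signal."""
    seq = "MKVLAGHEWRTYIPQSDNCF" * 4
    records = [
        ProteinRecord("PA0001", PATHOGEN, "", "WWCCPPYYHHGGKKRRDDEE" * 4),
        ProteinRecord("HS0001", HOST, "", seq),
    ]
    store = AssertionStore()
    store.add_experiment(Experiment("Y2H1", "interaction", PATHOGEN))
    store.add_experiment(Experiment("MA_P", "microarray", PATHOGEN))
    store.add_experiment(Experiment("MA_M", "microarray", ASSAY))
    if pathogen_status:
        store.add_assertion(Assertion("PA0001", "MA_P", frozenset({"infection"}), pathogen_status))
    mice = []
    rng = random.Random(0)
    for i, status in enumerate(mouse_statuses):
        acc = f"MM{i:04d}"
        mice.append(acc)
        mutated = list(seq)
        for pos in rng.sample(range(len(seq)), 4):  # 0.95 identity
            mutated[pos] = "A" if mutated[pos] != "A" else "G"
        records.append(ProteinRecord(acc, ASSAY, "", "".join(mutated)))
        if status:
            store.add_assertion(Assertion(acc, "MA_M", frozenset({"infection"}), status))
    seq_store = SequenceStore(records)
    clusters = cluster_sequences(seq_store, 0.9)
    edges = [InteractionEdge("PA0001", "HS0001", "Y2H1")]
    return edges, store, clusters, seq_store


class TestOverlay:
    def test_statuses_trace_through_the_bridge(self):
        edges, astore, clusters, sstore = tiny_world()
        net = build_overlay(edges, astore, clusters, ASSAY, sstore)
        assert net.nodes["PA0001"].status == "increase"
        assert net.nodes["HS0001"].status == "decrease"
        assert net.bridging["HS0001"] == ["MM0000"]

    def test_no_assertions_means_all_none(self):
        edges, astore, clusters, sstore = tiny_world(mouse_statuses=("",), pathogen_status="")
        net = build_overlay(edges, astore, clusters, ASSAY, sstore)
        assert {n.status for n in net.nodes.values()} == {"none"}
        assert net.bridging["HS0001"] == []

    def test_disagreeing_homologs_surface_conflict(self):
        edges, astore, clusters, sstore = tiny_world(mouse_statuses=("increase", "decrease"))
        net = build_overlay(edges, astore, clusters, ASSAY, sstore)
        assert net.nodes["HS0001"].status == "conflict"
        assert sorted(net.bridging["HS0001"]) == ["MM0000", "MM0001"]

    def test_missing_endpoint_error_lists_offenders(self):
        edges, astore, clusters, sstore = tiny_world()
        bad = edges + [InteractionEdge("PA9999", "HS9999", "Y2H1")]
        with pytest.raises(ValidationError) as err:
            build_overlay(bad, astore, clusters, ASSAY, sstore)
        assert "PA9999" in str(err.value) and "HS9999" in str(err.value)

    def test_non_interaction_experiment_rejected(self):
        edges, astore, clusters, sstore = tiny_world()
        bad = [InteractionEdge("PA0001", "HS0001", "MA_P")]
        with pytest.raises(ValidationError, match="MA_P"):
            build_overlay(bad, astore, clusters, ASSAY, sstore)


class TestPrioritization:
    def _fixture_network(self, bundle):
        src = bundle["dir"]
        sstore = SequenceStore.from_fasta(src / "proteins.fasta")
        astore = AssertionStore.load(src / "experiments.tsv", src / "assertions.tsv")
        clusters = cluster_sequences(sstore, bundle["spec"].threshold)
        edges = load_interactions(src / "interactions.tsv")
        return build_overlay(edges, astore, clusters, bundle["spec"].assay_taxon, sstore)

    def test_planted_edges_and_flags_recovered(self, small_bundle):
        manifest = small_bundle["manifest"]
        net = self._fixture_network(small_bundle)
        pri = prioritize_interactions(net)
        assert sorted([p.pathogen, p.host] for p in pri) == manifest["prioritized_edges"]
        flagged = sorted([p.pathogen, p.host] for p in pri if p.pathogen_increased)
        assert flagged == manifest["flagged_edges"]

    def test_brute_force_filter_agrees(self, small_bundle):
        net = self._fixture_network(small_bundle)
        expected = sorted(
            {
                (e.pathogen, e.host)
                for e in net.edges
                if net.nodes[e.host].status == "decrease"
            }
        )
        got = [(p.pathogen, p.host) for p in prioritize_interactions(net)]
        assert got == expected
        for p in prioritize_interactions(net):
            assert p.pathogen_increased == (net.nodes[p.pathogen].status == "increase")

    def test_all_none_network_prioritizes_nothing(self):
        edges, astore, clusters, sstore = tiny_world(mouse_statuses=("",), pathogen_status="")
        net = build_overlay(edges, astore, clusters, ASSAY, sstore)
        assert prioritize_interactions(net) == []

    def test_invariant_under_edge_permutation(self, small_bundle):
        src = small_bundle["dir"]
        sstore = SequenceStore.from_fasta(src / "proteins.fasta")
        astore = AssertionStore.load(src / "experiments.tsv", src / "assertions.tsv")
        clusters = cluster_sequences(sstore, small_bundle["spec"].threshold)
        edges = load_interactions(src / "interactions.tsv")
        baseline = None
        for seed in (0, 1, 2):
            shuffled = edges[:]
            random.Random(seed).shuffle(shuffled)
            net = build_overlay(shuffled, astore, clusters, small_bundle["spec"].assay_taxon, sstore)
            result = prioritize_interactions(net)
            if baseline is None:
                baseline = result
            assert result == baseline

    def test_flagged_tier_is_subset_of_prioritized(self, small_bundle):
        net = self._fixture_network(small_bundle)
        pri = prioritize_interactions(net)
        pairs = {(p.pathogen, p.host) for p in pri}
        flagged = {(p.pathogen, p.host) for p in pri if p.pathogen_increased}
        assert flagged <= pairs
        edge_pairs = {(e.pathogen, e.host) for e in net.edges}
        assert pairs <= edge_pairs


class TestExport:
    def test_two_node_network_export_counts(self, tmp_path):
        edges, astore, clusters, sstore = tiny_world()
        net = build_overlay(edges, astore, clusters, ASSAY, sstore)
        sif, attrs = export_cytoscape(net, tmp_path / "net")
        assert sif.read_text() == "PA0001\ty2h\tHS0001\n"
        lines = attrs.read_text().splitlines()
        assert lines[0] == "accession\trole\tstatus\ttaxon"
        assert len(lines) == 1 + 2

    def test_re_export_is_byte_identical(self, tmp_path, small_bundle):
        src = small_bundle["dir"]
        sstore = SequenceStore.from_fasta(src / "proteins.fasta")
        astore = AssertionStore.load(src / "experiments.tsv", src / "assertions.tsv")
        clusters = cluster_sequences(sstore, 0.9)
        edges = load_interactions(src / "interactions.tsv")
        net = build_overlay(edges, astore, clusters, small_bundle["spec"].assay_taxon, sstore)
        sif1, attrs1 = export_cytoscape(net, tmp_path / "a")
        sif2, attrs2 = export_cytoscape(net, tmp_path / "b")
        assert sif1.read_bytes() == sif2.read_bytes()
        assert attrs1.read_bytes() == attrs2.read_bytes()

    def test_sif_round_trip_reconstructs_edge_multiset(self, tmp_path, small_bundle):
        src = small_bundle["dir"]
        sstore = SequenceStore.from_fasta(src / "proteins.fasta")
        astore = AssertionStore.load(src / "experiments.tsv", src / "assertions.tsv")
        clusters = cluster_sequences(sstore, 0.9)
        edges = load_interactions(src / "interactions.tsv")
        net = build_overlay(edges, astore, clusters, small_bundle["spec"].assay_taxon, sstore)
        sif, _ = export_cytoscape(net, tmp_path / "net")
        parsed = parse_sif(sif)
        assert sorted(parsed) == sorted(
            (e.pathogen, e.method.lower(), e.host) for e in edges
        )
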