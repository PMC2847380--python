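"""Structured assertions: vocabulary enforcement, cross-data-type query
semantics against a brute-force oracle, and status aggregation."""

import itertools

import pytest

from mpdkit.assertion_store import (
    Assertion,
    AssertionStore,
    Experiment,
    aggregate_statuses,
)
from mpdkit.errors import FormatError, ValidationError


def make_store():
    store = AssertionStore()
    store.add_experiment(Experiment("MS1", "mass_spectrometry", 1392))
    store.add_experiment(Experiment("MA1", "microarray", 1392))
    store.add_experiment(Experiment("Y2H1", "interaction", 1392))
    store.add_experiment(Experiment("MS_MOUSE", "mass_spectrometry", 10090))
    return store


def brute_force_query(store, required_types, taxon=None, keywords=None, status=None):
    """Independent oracle: per-type accession sets intersected by hand."""
    def qualifying(a):
        e = store.experiments[a.experiment_id]
        if taxon is not None and e.taxon != taxon:
            return False
        if keywords and not set(k.lower() for k in keywords) <= a.keywords:
            return False
        if status is not None and status != "present" and a.status != status:
            return False
        return True

    per_type = {}
    for a in store.assertions():
        if qualifying(a):
            dtype = store.experiments[a.experiment_id].data_type
            per_type.setdefault(dtype, set()).add(a.accession)
    universe = set().union(*per_type.values()) if per_type else set()
    result = universe
    for dtype in required_types:
        result = result & per_type.get(dtype, set())
    return sorted(result)


class TestVocabulary:
    def test_unknown_status_rejected_quoting_allowed_set(self):
        with pytest.raises(ValidationError) as err:
            Assertion("P1", "MS1", frozenset(), "upregulated")
        message = str(err.value)
        assert "upregulated" in message
        for allowed in ("increase", "decrease", "present"):
            assert allowed in message

    def test_unknown_data_type_rejected(self):
        with pytest.raises(ValidationError, match="proteomics"):
            Experiment("X", "proteomics", 1)

    def test_dangling_experiment_rejected(self):
        store = make_store()
        with pytest.raises(ValidationError, match="NOEXP"):
            store.add_assertion(Assertion("P1", "NOEXP", frozenset(), "present"))


class TestLoading:
    def test_tsv_load_and_byte_stable_round_trip(self, tmp_path, bundle):
        src = bundle["dir"]
        store = AssertionStore.load(src / "experiments.tsv", src / "assertions.tsv")
        e1, a1 = tmp_path / "e1.tsv", tmp_path / "a1.tsv"
        store.dump(e1, a1)
        again = AssertionStore.load(e1, a1)
        e2, a2 = tmp_path / "e2.tsv", tmp_path / "a2.tsv"
        again.dump(e2, a2)
        assert e1.read_bytes() == e2.read_bytes()
        assert a1.read_bytes() == a2.read_bytes()

    def test_empty_assertion_table_is_valid(self, tmp_path):
        exp = tmp_path / "e.tsv"
        exp.write_text("E1\tmicroarray\t1392\tc\td\n")
        ass = tmp_path / "a.tsv"
        ass.write_text("")
        store = AssertionStore.load(exp, ass)
        assert len(store) == 0

    def test_identical_duplicate_rows_collapse_with_warning(self, tmp_path, caplog):
        exp = tmp_path / "e.tsv"
        exp.write_text("E1\tmicroarray\t1392\tc\td\n")
        ass = tmp_path / "a.tsv"
        ass.write_text("P1\tE1\tinfection\tincrease\nP1\tE1\tinfection\tincrease\n")
        with caplog.at_level("WARNING"):
            store = AssertionStore.load(exp, ass)
        assert len(store) == 1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_conflicting_duplicate_rows_error(self, tmp_path):
        exp = tmp_path / "e.tsv"
        exp.write_text("E1\tmicroarray\t1392\tc\td\n")
        ass = tmp_path / "a.tsv"
        ass.write_text("P1\tE1\tinfection\tincrease\nP1\tE1\tinfection\tdecrease\n")
        with pytest.raises(FormatError, match="conflicting"):
            AssertionStore.load(exp, ass)

    def test_error_names_file_and_line(self, tmp_path):
        exp = tmp_path / "e.tsv"
        exp.write_text("E1\tmicroarray\t1392\tc\td\n")
        ass = tmp_path / "a.tsv"
        ass.write_text("P1\tE1\tinfection\tpresent\nP1\tE1\tx\tupregulated\n")
        with pytest.raises(FormatError, match=r"a\.tsv:2"):
            AssertionStore.load(exp, ass)


class TestQuery:
    def test_triple_intersection_matches_planted_set(self, bundle):
        src = bundle["dir"]
        store = AssertionStore.load(src / "experiments.tsv", src / "assertions.tsv")
        hits = store.query_proteins(
            {"interaction", "microarray", "mass_spectrometry"},
            taxon=bundle["spec"].pathogen_taxon,
        )
        assert [h.accession for h in hits] == bundle["manifest"]["triple_type_proteins"]

    def test_query_equals_brute_force_for_all_type_combinations(self, bundle):
        src = bundle["dir"]
        store = AssertionStore.load(src / "experiments.tsv", src / "assertions.tsv")
        types = ["interaction", "microarray", "mass_spectrometry"]
        for r in range(len(types) + 1):
            for combo in itertools.combinations(types, r):
                got = [h.accession for h in store.query_proteins(set(combo))]
                assert got == brute_force_query(store, set(combo))

    def test_intersection_decomposes_over_required_types(self, bundle):
        src = bundle["dir"]
        store = AssertionStore.load(src / "experiments.tsv", src / "assertions.tsv")
        both = {h.accession for h in store.query_proteins({"microarray", "interaction"})}
        a = {h.accession for h in store.query_proteins({"microarray"})}
        b = {h.accession for h in store.query_proteins({"interaction"})}
        assert both == a & b

    def test_adding_required_types_never_enlarges_result(self, bundle):
        src = bundle["dir"]
        store = AssertionStore.load(src / "experiments.tsv", src / "assertions.tsv")
        chain = [set(), {"microarray"}, {"microarray", "mass_spectrometry"},
                 {"microarray", "mass_spectrometry", "interaction"}]
        sizes = [len(store.query_proteins(req)) for req in chain]
        assert sizes == sorted(sizes, reverse=True)

    def test_keyword_filter_returns_subset(self, bundle):
        src = bundle["dir"]
        store = AssertionStore.load(src / "experiments.tsv", src / "assertions.tsv")
        unfiltered = {h.accession for h in store.query_proteins()}
        filtered = {h.accession for h in store.query_proteins(keywords=["infection"])}
        assert filtered <= unfiltered
        assert filtered == set(brute_force_query(store, set(), keywords=["infection"]))

    def test_unknown_data_type_in_filter_is_an_error(self):
        store = make_store()
        with pytest.raises(ValidationError, match="proteomics"):
            store.query_proteins({"proteomics"})

    def test_no_required_types_returns_everything_asserted(self):
        store = make_store()
        store.add_assertion(Assertion("P2", "MA1", frozenset({"x"}), "present"))
        store.add_assertion(Assertion("P1", "MS1", frozenset(), "increase"))
        assert [h.accession for h in store.query_proteins()] == ["P1", "P2"]


class TestAggregation:
    def test_single_increase_dominates(self):
        store = make_store()
        store.add_assertion(Assertion("P1", "MA1", frozenset(), "increase"))
        assert store.expression_status_of("P1", {"microarray"}) == "increase"

    def test_concordant_types_agree(self):
        store = make_store()
        store.add_assertion(Assertion("P1", "MA1", frozenset(), "increase"))
        store.add_assertion(Assertion("P1", "MS1", frozenset(), "increase"))
        assert store.expression_status_of("P1", {"microarray", "mass_spectrometry"}) == "increase"

    def test_no_assertions_is_none(self):
        assert make_store().expression_status_of("P1", {"microarray"}) == "none"

    def test_data_type_restriction_is_respected(self):
        store = make_store()
        store.add_assertion(Assertion("P1", "Y2H1", frozenset(), "present"))
        assert store.expression_status_of("P1", {"microarray", "mass_spectrometry"}) == "none"

    @pytest.mark.parametrize(
        "pair",
        list(itertools.product(["increase", "decrease", "present"], repeat=2)),
    )
    def test_pairwise_aggregation_table(self, pair):
        """Exhaustive enumeration over all 3x3 status pairs fixes the
        collapse rule: opposing directions conflict, a direction dominates
        presence, and agreement is preserved."""
        a, b = pair
        got = aggregate_statuses([a, b])
        if {a, b} == {"increase", "decrease"}:
            assert got == "conflict"
        elif "increase" in (a, b):
            assert got == "increase"
        elif "decrease" in (a, b):
            assert got == "decrease"
        else:
            assert got == "present"

    def test_conflict_input_propagates(self):
        assert aggregate_statuses(["conflict", "increase"]) == "conflict"
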