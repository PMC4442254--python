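import pytest

from treatkit import (
    FilterQuery,
    GeneratorConfig,
    QueryError,
    aggregate,
    apply_filter,
    attribute_collectors,
    fig12_fixture,
    generate,
    summarize,
)
from treatkit.facets import FILTER_KEYS, escape_label


class TestFilterQuery:
    def test_unknown_key_rejected_at_construction(self):
        with pytest.raises(QueryError, match="mat.color"):
            FilterQuery.make({"mat.color": "red"})

    def test_query_string_round_trip(self):
        q = FilterQuery.from_string("FILTER_tax.orderEpithet=Araneae&FILTER_mat.country=Russia")
        assert q.clauses == (("tax.orderEpithet", "Araneae"), ("mat.country", "Russia"))
        assert q.to_string() == "FILTER_tax.orderEpithet=Araneae&FILTER_mat.country=Russia"

    def test_malformed_clause_rejected(self):
        with pytest.raises(QueryError):
            FilterQuery.from_string("FILTER_mat.country")


class TestApplyFilter:
    def test_empty_query_is_identity(self, toy_corpus):
        assert apply_filter(toy_corpus, FilterQuery()) == toy_corpus

    def test_order_filter_keeps_only_spiders(self, mixed_order_corpus):
        view = apply_filter(mixed_order_corpus, FilterQuery.make({"tax.orderEpithet": "Araneae"}))
        ids = [t.treatment_id for _, t in view.iter_treatments()]
        assert ids == ["T1", "T2"]

    def test_country_filter_selects_citations(self, toy_corpus):
        view = apply_filter(toy_corpus, FilterQuery.make({"mat.country": "Russia"}))
        citations = [c for _, _, c in view.iter_citations()]
        assert len(citations) == 2
        assert all(c.country == "Russia" for c in citations)
        assert [t.treatment_id for _, t in view.iter_treatments()] == ["T1"]

    def test_author_clause_matches_lead_author_only(self, toy_corpus):
        lead = apply_filter(toy_corpus, FilterQuery.make({"doc.author": "X.-P. Wang"}))
        contributing = apply_filter(toy_corpus, FilterQuery.make({"doc.author": "P. Jäger"}))
        assert len(lead.articles) == 1
        assert contributing.articles == []
        any_scope = apply_filter(
            toy_corpus, FilterQuery.make({"doc.author": "P. Jäger"}), author_scope="any"
        )
        assert len(any_scope.articles) == 1

    @pytest.mark.parametrize("seed", [0, 4, 8])
    def test_filter_composition(self, seed):
        """Sequential filtering equals filtering by the conjunction."""
        corpus, _ = generate(GeneratorConfig(seed=seed, n_articles=5))
        a = FilterQuery.make({"tax.rank": "species"})
        b = FilterQuery.make({"mat.country": "Russia"})
        assert apply_filter(apply_filter(corpus, a), b) == apply_filter(corpus, a & b)


class TestAggregate:
    def test_country_specimens(self, toy_corpus):
        table = aggregate(toy_corpus, "mat.country")
        assert table.as_dict() == {"Russia": 4, "China": 1}
        assert [r.label for r in table.rows] == ["Russia", "China"]

    def test_collection_specimens_ambiguity_goes_to_missing(self, toy_corpus):
        table = aggregate(toy_corpus, "mat.collectionCode")
        assert table.as_dict() == {"IBPN": 3, "ZMMU": 1, "missing": 1}

    def test_collection_treatment_presence(self, toy_corpus):
        table = aggregate(toy_corpus, "mat.collectionCode", measure="treatments")
        # the ambiguous citation marks T1 present in both listed codes
        assert table.as_dict() == {"IBPN": 1, "ZMMU": 2}

    def test_fig12_pattern(self):
        corpus = fig12_fixture()
        spec = aggregate(corpus, "mat.collectionCode")
        assert spec.as_dict() == {"missing": 154}
        treat = aggregate(corpus, "mat.collectionCode", measure="treatments")
        assert treat.as_dict() == {c: 1 for c in ["IBPN", "ISEA", "ZMMU", "ZMHU", "NHRS"]}

    def test_unknown_facet_rejected(self, toy_corpus):
        with pytest.raises(QueryError):
            aggregate(toy_corpus, "mat.color")

    def test_rows_sorted_by_measure_then_label(self, toy_corpus):
        table = aggregate(toy_corpus, "mat.collectionCode")
        values = [r.specimens for r in table.rows]
        assert values == sorted(values, reverse=True)
        assert [r.label for r in table.rows] == ["IBPN", "ZMMU", "missing"]

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("facet", ["mat.country", "mat.collectionCode", "mat.decade", "mat.elevationBand"])
    def test_specimen_conservation_including_missing(self, seed, facet):
        """Specimen columns, missing row included, sum to the corpus total."""
        corpus, _ = generate(GeneratorConfig(seed=seed, n_articles=4))
        table = aggregate(corpus, facet)
        assert table.total("specimens") == corpus.total_specimens

    def test_genuine_missing_label_is_escaped(self, toy_corpus):
        toy_corpus.articles[0].treatments[0].citations[0].country = "missing"
        table = aggregate(toy_corpus, "mat.country")
        assert escape_label("missing") in table.as_dict()
        assert table.as_dict()[escape_label("missing")] == 3


class TestCollectorAttribution:
    @pytest.fixture
    def team_corpus(self, toy_corpus):
        t1 = toy_corpus.articles[0].treatments[0]
        from treatkit.model import CountTriple

        t1.citations[0].counts = CountTriple.of(10)
        t1.citations[0].collector_raw = "A & B"
        t1.citations[0].collector_team = ["A", "B"]
        t1.citations[1].counts = CountTriple.of(0)
        return toy_corpus

    def test_raw_mode_uses_verbatim_team_string(self, team_corpus):
        table = attribute_collectors(team_corpus, "raw")
        assert table.as_dict()["A & B"] == 10

    def test_fractional_mode_splits_evenly(self, team_corpus):
        table = attribute_collectors(team_corpus, "fractional")
        assert table.as_dict()["A"] == pytest.approx(5.0)
        assert table.as_dict()["B"] == pytest.approx(5.0)

    def test_full_credit_mode_duplicates(self, team_corpus):
        table = attribute_collectors(team_corpus, "full_credit")
        assert table.as_dict()["A"] == 10
        assert table.as_dict()["B"] == 10

    @pytest.mark.parametrize("seed", range(10))
    def test_fractional_attribution_conserves_total(self, seed):
        corpus, _ = generate(GeneratorConfig(seed=seed, n_articles=4))
        table = attribute_collectors(corpus, "fractional")
        assert table.total("specimens") == pytest.approx(corpus.total_specimens, abs=1e-9)

    @pytest.mark.parametrize("seed", [2, 6])
    def test_mode_ordering(self, seed):
        """full-credit >= raw total; each individual's fractional share
        never exceeds their full-credit share."""
        corpus, _ = generate(GeneratorConfig(seed=seed, n_articles=4))
        raw = attribute_collectors(corpus, "raw")
        frac = attribute_collectors(corpus, "fractional")
        full = attribute_collectors(corpus, "full_credit")
        assert full.total("specimens") >= raw.total("specimens")
        for row in frac.rows:
            full_row = full.get(row.label)
            assert full_row is not None and full_row.specimens >= row.specimens - 1e-9


@pytest.mark.parametrize("seed", [3, 13])
def test_species_page_via_epithet_filter(seed):
    """Cross-article per-species aggregation is just a two-clause filter."""
    from treatkit.synth import FocalSpecies

    config = GeneratorConfig(
        seed=seed,
        n_articles=5,
        focal_species=FocalSpecies(
            genus="Tenuiphantes", species="tenuis", n_articles=3, specimens=60, females=40
        ),
    )
    corpus, _ = generate(config)
    q = FilterQuery.make({"tax.genusEpithet": "Tenuiphantes", "tax.speciesEpithet": "tenuis"})
    view = apply_filter(corpus, q)
    assert len(view.articles) == 3
    assert view.total_specimens == 60
    assert summarize(view).sex_composition.females == 40
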