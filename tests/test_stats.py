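import math

import pytest

from treatkit import (
    Corpus,
    GeneratorConfig,
    description_lag,
    generate,
    rarity,
    summarize,
)
from treatkit.model import (
    ArticleRecord,
    CountTriple,
    MaterialsCitation,
    PartialDate,
    Rank,
    TaxonName,
    TreatmentRecord,
    TreatmentStatus,
)
from treatkit.stats import fmt1, lag_records_frame, rarity_frame


def _species_treatment(tid, citations, new=False, year_suffix="sp"):
    return TreatmentRecord(
        treatment_id=tid,
        taxon=TaxonName.make(
            Rank.SPECIES, genusEpithet="Pardosa", speciesEpithet=f"{year_suffix}{tid}"
        ),
        status=TreatmentStatus.from_raw("sp. nov.") if new else TreatmentStatus(),
        citations=citations,
    )


def _citation(total, locality=None, date=None, collector=None):
    from treatkit.parsing import split_collectors

    return MaterialsCitation(
        counts=CountTriple.of(males=total),
        locality=locality,
        event_date=date,
        collector_raw=collector,
        collector_team=split_collectors(collector),
    )


def _article(aid, year, treatments):
    return ArticleRecord(
        article_id=aid, journal="Zootaxa", year=year, authors=["A"], treatments=treatments
    )


class TestSummarize:
    def test_single_article_single_treatment(self):
        corpus = Corpus(articles=[_article("a", 2010, [_species_treatment("t", [_citation(3)])])])
        s = summarize(corpus)
        assert s.mean_treatments_per_article == 1.0
        assert s.mean_specimens_per_species_treatment == 3.0

    def test_display_rendering_one_decimal(self):
        assert fmt1(254 / 37) == "6.9"
        assert fmt1(4773 / 212) == "22.5"

    def test_empty_corpus_flags_undefined_means(self):
        s = summarize(Corpus())
        assert s.n_articles == 0 and s.undefined_means
        assert math.isnan(s.mean_treatments_per_article)

    @pytest.mark.parametrize("seed", range(5))
    def test_summary_matches_brute_force_recount(self, seed):
        corpus, truth = generate(GeneratorConfig(seed=seed, n_articles=5))
        s = summarize(corpus)
        t = truth.summary
        assert s.n_articles == t["n_articles"]
        assert s.n_treatments == t["n_treatments"]
        assert s.n_species_treatments == t["n_species_treatments"]
        assert s.n_specimens == t["n_specimens"]
        assert s.n_species_specimens == t["n_species_specimens"]
        assert s.n_new_species == t["n_new_species"]
        assert s.n_citations == t["n_citations"]
        assert s.n_coded_citations == t["n_coded_citations"]
        assert s.sex_composition.males == t["males"]
        assert s.sex_composition.females == t["females"]


class TestRarity:
    def test_singleton_and_locality_rates(self):
        # 3 new species: one singleton, one single-locality (non-singleton),
        # one spread over two localities
        t1 = _species_treatment("n1", [_citation(1, locality="L1")], new=True)
        t2 = _species_treatment(
            "n2", [_citation(2, locality="L2"), _citation(3, locality="L2")], new=True
        )
        t3 = _species_treatment(
            "n3", [_citation(2, locality="L3"), _citation(2, locality="L4")], new=True
        )
        corpus = Corpus(articles=[_article("a", 2010, [t1, t2, t3])])
        r = rarity(corpus)
        assert r.n_new_species == 3
        assert r.n_singletons == 1 and r.singleton_rate == pytest.approx(1 / 3)
        assert r.n_single_locality == 2 and r.single_locality_rate == pytest.approx(2 / 3)

    def test_unique_is_event_based_not_abundance_based(self):
        """Two citations sharing locality+date+collector form one event:
        the species is a unique but not a singleton."""
        date = PartialDate(1999, 7, 1)
        t = _species_treatment(
            "n1",
            [
                _citation(2, locality="L1", date=date, collector="A"),
                _citation(3, locality="L1", date=date, collector="A"),
            ],
            new=True,
        )
        r = rarity(Corpus(articles=[_article("a", 2010, [t])]))
        assert r.n_single_collection == 1
        assert r.n_singletons == 0

    def test_zero_new_species_flags_undefined(self, toy_corpus):
        for _, t in toy_corpus.iter_treatments():
            t.status = TreatmentStatus()
        r = rarity(toy_corpus)
        assert r.undefined and math.isnan(r.singleton_rate)

    def test_rarity_frame_has_all_metrics(self, toy_corpus):
        frame = rarity_frame(rarity(toy_corpus))
        assert set(frame["metric"]) >= {"singletons", "uniques", "single_locality"}


class TestDescriptionLag:
    def _corpus(self, pub_year, citation_years):
        citations = [
            _citation(2, date=PartialDate(y) if y else None) for y in citation_years
        ]
        t = _species_treatment("n1", citations, new=True)
        return Corpus(articles=[_article("a", pub_year, [t])])

    def test_same_year_description_has_zero_lag(self):
        records, summary = description_lag(self._corpus(2014, [2014]))
        assert records[0].lag_years == 0
        assert summary.min == summary.max == 0

    def test_century_old_material(self):
        records, _ = description_lag(self._corpus(2011, [1909, 2010]))
        assert records[0].earliest_collection_year == 1909
        assert records[0].lag_years == 102

    def test_undated_species_excluded_and_counted(self):
        _, summary = description_lag(self._corpus(2011, [None]))
        assert summary.n == 0
        assert summary.n_excluded_missing_dates == 1

    def test_summary_statistics_match_direct_arithmetic(self):
        corpus = Corpus(
            articles=[
                _article(
                    "a",
                    2014,
                    [
                        _species_treatment("n1", [_citation(2, date=PartialDate(2014))], new=True),
                        _species_treatment("n2", [_citation(2, date=PartialDate(2007))], new=True),
                        _species_treatment("n3", [_citation(2, date=PartialDate(2000))], new=True),
                    ],
                )
            ]
        )
        _, summary = description_lag(corpus)
        assert summary.n == 3
        assert summary.mean == pytest.approx(7.0)
        assert summary.median == 7
        # sample sd of {0, 7, 14} is 7; SE = 7 / sqrt(3)
        assert summary.standard_error == pytest.approx(7 / math.sqrt(3))
        assert summary.min == 0 and summary.max == 14

    def test_lag_records_frame_columns(self):
        records, _ = description_lag(self._corpus(2011, [1999]))
        frame = lag_records_frame(records)
        assert list(frame["lagYears"]) == [12]
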