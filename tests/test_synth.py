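import pytest

from treatkit import (
    ConfigError,
    GeneratorConfig,
    config_from_dict,
    fig12_fixture,
    generate,
    summarize,
    validate_corpus,
    write_article,
)
from treatkit.synth import ExactTotals, FocalSpecies


def test_zero_articles_yields_empty_corpus():
    corpus, truth = generate(GeneratorConfig(seed=1, n_articles=0))
    assert corpus.articles == []
    assert truth.summary["n_treatments"] == 0


def test_same_seed_means_byte_identical_xml():
    config = GeneratorConfig(seed=42, n_articles=4)
    c1, _ = generate(config)
    c2, _ = generate(GeneratorConfig(seed=42, n_articles=4))
    assert [write_article(a) for a in c1.articles] == [write_article(a) for a in c2.articles]


def test_different_seeds_differ():
    c1, _ = generate(GeneratorConfig(seed=1, n_articles=3))
    c2, _ = generate(GeneratorConfig(seed=2, n_articles=3))
    assert c1 != c2


EXACT_CONFIG = GeneratorConfig(
    seed=7,
    exact_totals=ExactTotals(
        articles=37,
        treatments=254,
        species_treatments=212,
        species_specimens=4773,
        new_species=91,
        singletons_new=34,
        singletons_citing=72,
        single_locality_new=35,
        sex_totals=(2460, 1943, 370),
        citations=1447,
        coded_citations=572,
    ),
)


@pytest.fixture(scope="module")
def corpus_truth():
    return generate(EXACT_CONFIG)


class TestExactTotals:

    def test_headline_counts_achieved_exactly(self, corpus_truth):
        corpus, truth = corpus_truth
        s = summarize(corpus)
        assert s.n_articles == 37
        assert s.n_treatments == 254
        assert s.n_species_treatments == 212
        assert s.n_species_specimens == 4773
        assert s.n_new_species == 91
        assert s.n_citations == 1447
        assert s.n_coded_citations == 572
        assert (s.sex_composition.males, s.sex_composition.females, s.sex_composition.other) == (
            2460, 1943, 370,
        )

    def test_display_means(self, corpus_truth):
        from treatkit.stats import fmt1

        s = summarize(corpus_truth[0])
        assert fmt1(s.mean_treatments_per_article) == "6.9"
        assert fmt1(s.mean_specimens_per_species_treatment) == "22.5"

    def test_rarity_designations_achieved(self, corpus_truth):
        from treatkit import rarity

        r = rarity(corpus_truth[0])
        assert r.n_singletons == 34
        assert r.n_single_locality == 35
        assert r.n_singleton_citing == 72

    def test_ground_truth_records_designations(self, corpus_truth):
        _, truth = corpus_truth
        assert len(truth.intended["new_species_treatments"]) == 91
        assert len(truth.intended["singleton_treatments"]) == 72
        assert len(truth.intended["lags"]) == 91

    def test_valid_corpus(self, corpus_truth):
        findings = validate_corpus(corpus_truth[0])
        assert [f for f in findings if f.severity == "error"] == []


def test_unsatisfiable_totals_raise_config_error():
    with pytest.raises(ConfigError):
        generate(
            GeneratorConfig(
                seed=1,
                exact_totals=ExactTotals(
                    articles=2, treatments=4, species_treatments=4,
                    species_specimens=3, new_species=4, singletons_new=0,
                ),
            )
        )


def test_focal_species_spans_requested_articles():
    config = GeneratorConfig(
        seed=3,
        n_articles=6,
        focal_species=FocalSpecies(
            genus="Tenuiphantes", species="tenuis", n_articles=3, specimens=100, females=70
        ),
    )
    corpus, truth = generate(config)
    focal = [
        (a, t)
        for a, t in corpus.iter_treatments()
        if t.taxon.epithet("speciesEpithet") == "tenuis"
    ]
    assert len(focal) == 3
    assert len({a.article_id for a, _ in focal}) == 3
    assert sum(t.total_specimens for _, t in focal) == 100
    assert sum(c.counts.females for _, t in focal for c in t.citations) == 70


def test_sex_composition_converges_to_split():
    """With no missing data and a (0.5, 0.4, 0.1) split, the corpus-wide
    composition approaches the split within binomial error."""
    config = GeneratorConfig(
        seed=11,
        n_articles=40,
        sex_split=(0.5, 0.4, 0.1),
        species_rank_fraction=1.0,
        missing_rates={k: 0.0 for k in GeneratorConfig().missing_rates},
    )
    corpus, _ = generate(config)
    s = summarize(corpus)
    n = s.sex_composition.total
    assert n > 3000
    for observed, p in zip(
        (s.sex_composition.males, s.sex_composition.females, s.sex_composition.other),
        (0.5, 0.4, 0.1),
    ):
        # 4-sigma binomial envelope
        assert abs(observed / n - p) < 4 * (p * (1 - p) / n) ** 0.5


def test_config_from_dict_round_trip():
    config = config_from_dict(
        {
            "seed": 5,
            "n_articles": 3,
            "treatments_per_article": ["poisson", 4.0],
            "sex_split": [0.5, 0.4, 0.1],
            "exact_totals": {
                "articles": 3, "treatments": 9, "species_treatments": 9,
                "species_specimens": 90, "new_species": 2,
            },
            "focal_species": None,
        }
    )
    assert config.exact_totals.articles == 3
    corpus, _ = generate(config)
    assert len(corpus.articles) == 3
    assert summarize(corpus).n_species_specimens == 90


def test_fig12_fixture_shape():
    corpus = fig12_fixture()
    assert len(corpus.articles) == 1
    citation = corpus.articles[0].treatments[0].citations[0]
    assert citation.counts.total == 154
    assert len(citation.collection_codes) == 5
    assert validate_corpus(corpus) == []
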