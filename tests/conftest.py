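import pytest

from treatkit import (
    ArticleRecord,
    Corpus,
    CountTriple,
    MaterialsCitation,
    Rank,
    TaxonName,
    TreatmentRecord,
    TreatmentStatus,
)


def _citation(males=0, females=0, other=0, **kwargs):
    return MaterialsCitation(counts=CountTriple.of(males, females, other), **kwargs)


@pytest.fixture
def toy_corpus():
    """One article, two spider treatments, three citations.

    T1: c1 (Russia, IBPN, 2 males 1 female) and c2 (Russia, ambiguous
    {ZMMU, IBPN}, 1 female); T2: c3 (China, ZMMU, 1 male).
    """
    t1 = TreatmentRecord(
        treatment_id="T1",
        taxon=TaxonName.make(
            Rank.SPECIES,
            orderEpithet="Araneae",
            familyEpithet="Lycosidae",
            genusEpithet="Pardosa",
            speciesEpithet="prima",
        ),
        status=TreatmentStatus.from_raw("sp. nov."),
        citations=[
            _citation(2, 1, collection_codes=["IBPN"], country="Russia"),
            _citation(0, 1, collection_codes=["ZMMU", "IBPN"], country="Russia"),
        ],
    )
    t2 = TreatmentRecord(
        treatment_id="T2",
        taxon=TaxonName.make(
            Rank.SPECIES,
            orderEpithet="Araneae",
            familyEpithet="Agelenidae",
            genusEpithet="Agelena",
            speciesEpithet="secunda",
        ),
        citations=[_citation(1, 0, collection_codes=["ZMMU"], country="China")],
    )
    article = ArticleRecord(
        article_id="A1",
        journal="Zootaxa",
        year=2010,
        authors=["X.-P. Wang", "P. Jäger"],
        treatments=[t1, t2],
    )
    return Corpus(articles=[article])


@pytest.fixture
def mixed_order_corpus(toy_corpus):
    """Toy corpus plus one insect (non-spider) treatment in a second article."""
    insect = TreatmentRecord(
        treatment_id="T3",
        taxon=TaxonName.make(
            Rank.SPECIES,
            orderEpithet="Hymenoptera",
            familyEpithet="Ichneumonidae",
            genusEpithet="Ichneumon",
            speciesEpithet="tertius",
        ),
        citations=[_citation(0, 0, 6, country="South Africa")],
    )
    article = ArticleRecord(
        article_id="A2",
        journal="Biodiversity Data Journal",
        year=2014,
        authors=["J. A. Miller"],
        treatments=[insect],
    )
    corpus = Corpus(articles=list(toy_corpus.articles) + [article])
    return corpus
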