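"""Corpus-level biodiversity statistics.

Three analyses over a (possibly filtered) corpus:

* :func:`summarize` — headline counts and ratios: articles, treatments,
  species-rank treatments, specimens, new species, sex composition,
  specimen-code coverage.
* :func:`rarity` — prevalence of rare species among new descriptions:
  *singletons* (known from a single specimen), *uniques* (known from a
  single collection event) and single-locality species.
* :func:`description_lag` — per new species, the delay in years between
  the earliest collection of its cited material and its formal
  description (the publication year).

Ratios are kept at full precision; a one-decimal display rendering
(:func:`fmt1`) matches how such summaries are conventionally printed.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import Corpus, CountTriple, TaxonName

#: members of the collection-event identity tuple are normalized with this
def _norm(text: Optional[str]) -> Optional[str]:
    return text.strip().casefold() if text else None


def fmt1(value: float) -> str:
    """One-decimal display rendering of a ratio, e.g. 6.865 -> '6.9'."""
    return f"{value:.1f}"


def pct(numerator: float, denominator: float) -> float:
    return 100.0 * numerator / denominator if denominator else float("nan")


@dataclass
class CorpusSummary:
    n_articles: int = 0
    n_treatments: int = 0
    n_species_treatments: int = 0
    n_citing_species_treatments: int = 0  # species treatments citing >=1 specimen
    n_specimens: int = 0
    n_species_specimens: int = 0
    n_new_species: int = 0
    n_citations: int = 0
    n_coded_citations: int = 0  # citations carrying >=1 specimen code
    mean_treatments_per_article: float = float("nan")
    mean_species_treatments_per_article: float = float("nan")
    mean_specimens_per_species_treatment: float = float("nan")
    pct_new_species_of_species_treatments: float = float("nan")
    pct_coded_citations: float = float("nan")
    sex_composition: CountTriple = field(default_factory=lambda: CountTriple.of())
    pct_males: float = float("nan")
    pct_females: float = float("nan")
    pct_other: float = float("nan")
    undefined_means: bool = False

    def digest(self) -> str:
        """One-screen text rendering."""
        lines = [
            f"articles: {self.n_articles}",
            f"treatments: {self.n_treatments} ({self.n_species_treatments} species rank, "
            f"{self.n_citing_species_treatments} citing specimens)",
            f"specimens: {self.n_specimens} ({self.n_species_specimens} in species treatments)",
            f"new species: {self.n_new_species} "
            f"({fmt1(self.pct_new_species_of_species_treatments)}% of species treatments)",
            f"treatments/article: {fmt1(self.mean_treatments_per_article)} "
            f"({fmt1(self.mean_species_treatments_per_article)} species rank)",
            f"specimens/species treatment: {fmt1(self.mean_specimens_per_species_treatment)}",
            f"sex composition: {self.sex_composition.males} male ({fmt1(self.pct_males)}%), "
            f"{self.sex_composition.females} female ({fmt1(self.pct_females)}%), "
            f"{self.sex_composition.other} other ({fmt1(self.pct_other)}%)",
            f"citations with specimen codes: {self.n_coded_citations}/{self.n_citations} "
            f"({fmt1(self.pct_coded_citations)}%)",
        ]
        return "\n".join(lines)


def summarize(corpus: Corpus) -> CorpusSummary:
    """Exact integer counts and their ratios for a corpus view.

    Sex percentages are computed on the species-treatment specimen
    totals.  An empty corpus yields zero counts with
    ``undefined_means=True`` and NaN ratios.
    """
    s = CorpusSummary()
    s.n_articles = len(corpus.articles)
    males = females = other = 0
    for article, treatment in corpus.iter_treatments():
        s.n_treatments += 1
        specimens = treatment.total_specimens
        s.n_specimens += specimens
        s.n_citations += len(treatment.citations)
        s.n_coded_citations += sum(1 for c in treatment.citations if c.specimen_codes)
        if treatment.is_species_rank:
            s.n_species_treatments += 1
            s.n_species_specimens += specimens
            if treatment.citations:
                s.n_citing_species_treatments += 1
            if treatment.status.is_new_species:
                s.n_new_species += 1
            for c in treatment.citations:
                males += c.counts.males
                females += c.counts.females
                other += c.counts.other
    s.sex_composition = CountTriple.of(males, females, other)
    if s.n_articles:
        s.mean_treatments_per_article = s.n_treatments / s.n_articles
        s.mean_species_treatments_per_article = s.n_species_treatments / s.n_articles
    else:
        s.undefined_means = True
    if s.n_species_treatments:
        s.mean_specimens_per_species_treatment = s.n_species_specimens / s.n_species_treatments
        s.pct_new_species_of_species_treatments = pct(s.n_new_species, s.n_species_treatments)
    else:
        s.undefined_means = True
    if s.n_citations:
        s.pct_coded_citations = pct(s.n_coded_citations, s.n_citations)
    total_sexed = s.sex_composition.total
    if total_sexed:
        s.pct_males = pct(males, total_sexed)
        s.pct_females = pct(females, total_sexed)
        s.pct_other = pct(other, total_sexed)
    return s


# ---------------------------------------------------------------------------
# rarity


@dataclass
class RarityStats:
    """Rarity prevalence among new species, plus the broader singleton share.

    Denominator for the headline rates is the number of new-species
    treatments.  A *singleton* is based on exactly one specimen; a
    *unique* on exactly one collection event (identity: normalized
    locality, event date, verbatim collector); *single-locality* on
    exactly one distinct locality text.  The three extra ``citing``
    fields give the singleton share among all species treatments that
    cite specimens (the natural denominator for faunistic corpora where
    most treatments describe nothing new).
    """

    n_new_species: int = 0
    n_singletons: int = 0
    singleton_rate: float = float("nan")
    n_single_collection: int = 0  # uniques
    unique_rate: float = float("nan")
    n_single_locality: int = 0
    single_locality_rate: float = float("nan")
    n_citing_species_treatments: int = 0
    n_singleton_citing: int = 0
    singleton_citing_rate: float = float("nan")
    undefined: bool = False


def _event_key(citation) -> tuple:
    date = citation.event_date
    return (
        _norm(citation.locality),
        date.isoformat() if date else None,
        _norm(citation.collector_raw),
    )


def rarity(corpus: Corpus) -> RarityStats:
    r = RarityStats()
    for _, treatment in corpus.iter_treatments():
        if not treatment.is_species_rank:
            continue
        total = treatment.total_specimens
        if treatment.citations:
            r.n_citing_species_treatments += 1
            if total == 1:
                r.n_singleton_citing += 1
        if not treatment.status.is_new_species:
            continue
        r.n_new_species += 1
        if total == 1:
            r.n_singletons += 1
        events = {_event_key(c) for c in treatment.citations}
        if len(events) == 1:
            r.n_single_collection += 1
        localities = {_norm(c.locality) for c in treatment.citations if c.locality}
        if len(localities) == 1:
            r.n_single_locality += 1
    if r.n_new_species:
        r.singleton_rate = r.n_singletons / r.n_new_species
        r.unique_rate = r.n_single_collection / r.n_new_species
        r.single_locality_rate = r.n_single_locality / r.n_new_species
    else:
        r.undefined = True
    if r.n_citing_species_treatments:
        r.singleton_citing_rate = r.n_singleton_citing / r.n_citing_species_treatments
    return r


# ---------------------------------------------------------------------------
# description lag


@dataclass
class LagRecord:
    species: TaxonName
    treatment_id: str
    publication_year: int
    earliest_collection_year: Optional[int] = None
    lag_years: Optional[int] = None


@dataclass
class LagSummary:
    n: int = 0
    mean: float = float("nan")
    standard_error: float = float("nan")
    median: float = float("nan")
    min: Optional[int] = None
    max: Optional[int] = None
    n_excluded_missing_dates: int = 0


def description_lag(corpus: Corpus) -> tuple:
    """Per new species, years from earliest cited collection to description.

    Species with no dated citations (or none collected before
    publication, which would imply a negative lag) are excluded and
    counted in ``n_excluded_missing_dates``.  The standard error is the
    sample (n-1) standard deviation over sqrt(n).
    """
    records = []
    lags = []
    summary = LagSummary()
    for article, treatment in corpus.iter_treatments():
        if not (treatment.is_species_rank and treatment.status.is_new_species):
            continue
        years = [c.event_date.year for c in treatment.citations if c.event_date]
        record = LagRecord(
            species=treatment.taxon,
            treatment_id=treatment.treatment_id,
            publication_year=article.year,
        )
        if years:
            earliest = min(years)
            record.earliest_collection_year = earliest
            if earliest <= article.year:
                record.lag_years = article.year - earliest
                lags.append(record.lag_years)
            else:
                summary.n_excluded_missing_dates += 1
        else:
            summary.n_excluded_missing_dates += 1
        records.append(record)
    summary.n = len(lags)
    if lags:
        summary.mean = statistics.fmean(lags)
        summary.median = statistics.median(lags)
        summary.min = min(lags)
        summary.max = max(lags)
        if len(lags) > 1:
            summary.standard_error = statistics.stdev(lags) / math.sqrt(len(lags))
    return records, summary


# ---------------------------------------------------------------------------
# CSV export


def lag_records_frame(records: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "treatmentID": r.treatment_id,
                "scientificName": r.species.scientific_name,
                "publicationYear": r.publication_year,
                "earliestCollectionYear": r.earliest_collection_year,
                "lagYears": r.lag_years,
            }
            for r in records
        ],
        columns=[
            "treatmentID",
            "scientificName",
            "publicationYear",
            "earliestCollectionYear",
            "lagYears",
        ],
    )


def rarity_frame(r: RarityStats) -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("new_species", r.n_new_species, ""),
            ("singletons", r.n_singletons, r.singleton_rate),
            ("uniques", r.n_single_collection, r.unique_rate),
            ("single_locality", r.n_single_locality, r.single_locality_rate),
            ("citing_species_treatments", r.n_citing_species_treatments, ""),
            ("singleton_citing", r.n_singleton_citing, r.singleton_citing_rate),
        ],
        columns=["metric", "count", "rate"],
    )
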