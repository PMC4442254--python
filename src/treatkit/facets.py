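"""Filterable faceted aggregation over a treatment corpus.

This is the computational core behind every dashboard chart: filter the
corpus with conjunctive field clauses, then portion specimen, treatment
and article counts by one categorical dimension (country, collection
code, collector, month, decade, elevation band, ...), with an explicit
"missing" category for records lacking the field.

Two conventions inherited from how legacy materials citations are
structured deserve note:

* A citation listing several collection codes with a single specimen
  count attached to the collecting event (not to any one collection)
  contributes its whole specimen count to "missing" — we know the
  specimens are distributed among those institutions but not how — while
  its treatment counts as *present* in each listed collection.
* Collector strings name whole teams; by default they aggregate as
  verbatim strings ("A & B" is not "B & A").
  :func:`attribute_collectors` additionally offers fractional and
  full-credit attribution to individual team members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import Corpus, TreatmentRecord, TypeStatus
from .parsing import bin_elevation

MISSING = "missing"

FILTER_KEYS = (
    "doc.journal",
    "doc.year",
    "doc.author",
    "tax.rank",
    "tax.status",
    "tax.orderEpithet",
    "tax.familyEpithet",
    "tax.genusEpithet",
    "tax.speciesEpithet",
    "mat.country",
    "mat.collectionCode",
    "mat.collectorName",
    "mat.typeStatus",
    "mat.month",
    "mat.decade",
    "mat.elevationBand",
)

MEASURES = ("specimens", "treatments", "articles")


class QueryError(ValueError):
    """Unknown filter key or facet name."""


def escape_label(value: str) -> str:
    """Quote a genuine facet value that collides with the reserved "missing"."""
    return f'"{value}"' if value == MISSING else value


@dataclass(frozen=True)
class FilterQuery:
    """Conjunction of field=value clauses over the filter-key vocabulary."""

    clauses: tuple = ()  # tuple of (key, value) pairs

    def __post_init__(self) -> None:
        for key, _ in self.clauses:
            if key not in FILTER_KEYS:
                raise QueryError(f"unknown filter key: {key!r}")

    @classmethod
    def make(cls, clauses: Optional[dict] = None, **kwargs: str) -> "FilterQuery":
        merged = dict(clauses or {})
        merged.update(kwargs)
        return cls(tuple(merged.items()))

    @classmethod
    def from_string(cls, query: str) -> "FilterQuery":
        """Parse the dashboard query-string syntax, e.g.
        ``FILTER_tax.orderEpithet=Araneae&FILTER_mat.country=Russia``."""
        pairs = []
        for part in query.split("&"):
            part = part.strip()
            if not part:
                continue
            if "=" not in part:
                raise QueryError(f"malformed filter clause: {part!r}")
            key, value = part.split("=", 1)
            if key.startswith("FILTER_"):
                key = key[len("FILTER_"):]
            pairs.append((key, value))
        return cls(tuple(pairs))

    def to_string(self) -> str:
        return "&".join(f"FILTER_{k}={v}" for k, v in self.clauses)

    def __and__(self, other: "FilterQuery") -> "FilterQuery":
        return FilterQuery(self.clauses + other.clauses)

    @property
    def is_empty(self) -> bool:
        return not self.clauses

    def _level(self, prefix: str) -> list:
        return [(k, v) for k, v in self.clauses if k.startswith(prefix)]


# ---------------------------------------------------------------------------
# clause matching


def _article_matches(article, key: str, value: str, author_scope: str) -> bool:
    if key == "doc.journal":
        return article.journal == value
    if key == "doc.year":
        return str(article.year) == value
    if key == "doc.author":
        if not article.authors:
            return False
        if author_scope == "any":
            return value in article.authors
        return article.authors[0] == value  # lead-author convention
    raise QueryError(f"not an article-level key: {key}")


def _treatment_matches(treatment: TreatmentRecord, key: str, value: str) -> bool:
    if key == "tax.rank":
        return treatment.taxon.rank.value == value
    if key == "tax.status":
        return treatment.status.label == value or treatment.status.raw_status == value
    if key in ("tax.orderEpithet", "tax.familyEpithet", "tax.genusEpithet", "tax.speciesEpithet"):
        return treatment.taxon.epithet(key.split(".", 1)[1]) == value
    raise QueryError(f"not a treatment-level key: {key}")


def _normalize_band(label: str) -> str:
    return label.replace(",", "").replace("-", "–")


def _citation_matches(citation, key: str, value: str) -> bool:
    if key == "mat.country":
        return citation.country == value
    if key == "mat.collectionCode":
        return value in citation.collection_codes
    if key == "mat.collectorName":
        return citation.collector_raw == value
    if key == "mat.typeStatus":
        return citation.type_status.value == value
    if key == "mat.month":
        date = citation.event_date
        return date is not None and date.month is not None and str(date.month) == value
    if key == "mat.decade":
        date = citation.event_date
        if date is None:
            return False
        return date.decade_label == value or str(date.decade) == value
    if key == "mat.elevationBand":
        if citation.elevation_m is None:
            return False
        band = bin_elevation(citation.elevation_m).label
        return _normalize_band(band) == _normalize_band(value)
    raise QueryError(f"not a citation-level key: {key}")


def apply_filter(corpus: Corpus, query: FilterQuery, author_scope: str = "first") -> Corpus:
    """Return the sub-corpus matching every clause (conjunction semantics).

    Document clauses select articles (``doc.author`` matches the lead
    author unless ``author_scope="any"``), taxon clauses select
    treatments, and ``mat.*`` clauses select individual citations within
    surviving treatments.  A treatment emptied by a citation clause (and
    an article emptied by lower-level clauses) is dropped; the empty
    query is the identity.
    """
    doc_clauses = query._level("doc.")
    tax_clauses = query._level("tax.")
    mat_clauses = query._level("mat.")

    articles = []
    for article in corpus.articles:
        if not all(_article_matches(article, k, v, author_scope) for k, v in doc_clauses):
            continue
        if not tax_clauses and not mat_clauses:
            articles.append(article)
            continue
        treatments = []
        for treatment in article.treatments:
            if not all(_treatment_matches(treatment, k, v) for k, v in tax_clauses):
                continue
            if not mat_clauses:
                treatments.append(treatment)
                continue
            citations = [
                c for c in treatment.citations
                if all(_citation_matches(c, k, v) for k, v in mat_clauses)
            ]
            if citations:
                treatments.append(
                    TreatmentRecord(
                        treatment_id=treatment.treatment_id,
                        taxon=treatment.taxon,
                        status=treatment.status,
                        citations=citations,
                    )
                )
        if treatments:
            articles.append(
                type(article)(
                    article_id=article.article_id,
                    journal=article.journal,
                    year=article.year,
                    authors=article.authors,
                    doi=article.doi,
                    lsid=article.lsid,
                    page_count=article.page_count,
                    treatments=treatments,
                )
            )
    return Corpus(articles=articles)


# ---------------------------------------------------------------------------
# aggregation


@dataclass(frozen=True)
class FacetRow:
    label: str
    specimens: float
    treatments: int
    articles: int


@dataclass
class FacetTable:
    """One facet aggregation: rows of (label, specimens, treatments, articles).

    Rows with a zero value in the selected measure are dropped; the rest
    are sorted by that measure descending, ties by label ascending.  The
    reserved "missing" row collects records lacking the facet field, so
    the specimen column (including "missing") always sums to the
    filtered corpus total.
    """

    facet: str
    measure: str
    rows: list = field(default_factory=list)

    def as_dict(self, column: str = None) -> dict:
        column = column or self.measure
        return {r.label: getattr(r, column) for r in self.rows}

    def total(self, column: str = None) -> float:
        column = column or self.measure
        return sum(getattr(r, column) for r in self.rows)

    def get(self, label: str) -> Optional[FacetRow]:
        for r in self.rows:
            if r.label == label:
                return r
        return None


def _specimen_label(article, treatment, citation, facet: str):
    """The single label a citation's *specimens* are attributed to."""
    if facet.startswith("doc.") or facet.startswith("tax."):
        labels = _presence_labels(article, treatment, citation, facet)
        return labels[0]
    if facet == "mat.collectionCode":
        codes = citation.collection_codes
        # ambiguous (0 or >=2 codes): whole count is unassignable
        return escape_label(codes[0]) if len(codes) == 1 else MISSING
    return _presence_labels(article, treatment, citation, facet)[0]


def _presence_labels(article, treatment, citation, facet: str) -> list:
    """The label(s) a citation makes its treatment/article *present* in."""
    if facet == "doc.journal":
        return [escape_label(article.journal)]
    if facet == "doc.year":
        return [str(article.year)]
    if facet == "doc.author":
        return [escape_label(article.authors[0])] if article.authors else [MISSING]
    if facet == "tax.rank":
        return [treatment.taxon.rank.value]
    if facet == "tax.status":
        return [treatment.status.label]
    if facet.startswith("tax."):
        value = treatment.taxon.epithet(facet.split(".", 1)[1])
        return [escape_label(value)] if value else [MISSING]
    if facet == "mat.country":
        return [escape_label(citation.country)] if citation.country else [MISSING]
    if facet == "mat.collectionCode":
        codes = citation.collection_codes
        return [escape_label(c) for c in codes] if codes else [MISSING]
    if facet == "mat.collectorName":
        return [escape_label(citation.collector_raw)] if citation.collector_raw else [MISSING]
    if facet == "mat.typeStatus":
        ts = citation.type_status
        return [ts.value] if ts is not TypeStatus.NONE else [MISSING]
    if facet == "mat.month":
        date = citation.event_date
        return [str(date.month)] if date and date.month else [MISSING]
    if facet == "mat.decade":
        date = citation.event_date
        return [date.decade_label] if date else [MISSING]
    if facet == "mat.elevationBand":
        if citation.elevation_m is None:
            return [MISSING]
        return [bin_elevation(citation.elevation_m).label]
    raise QueryError(f"unknown facet: {facet!r}")


def _build_table(facet: str, measure: str, spec_counts: dict, treat_sets: dict, art_sets: dict) -> FacetTable:
    labels = set(spec_counts) | set(treat_sets) | set(art_sets)
    rows = []
    for label in labels:
        row = FacetRow(
            label=label,
            specimens=spec_counts.get(label, 0),
            treatments=len(treat_sets.get(label, ())),
            articles=len(art_sets.get(label, ())),
        )
        if getattr(row, measure) > 0:
            rows.append(row)
    rows.sort(key=lambda r: (-getattr(r, measure), r.label))
    return FacetTable(facet=facet, measure=measure, rows=rows)


def aggregate(corpus: Corpus, facet: str, measure: str = "specimens") -> FacetTable:
    """Portion the corpus by one facet.

    The specimens column sums each citation's reconciled total under a
    single label (ambiguous multi-collection citations fall under
    "missing"); the treatments and articles columns count distinct
    treatments/articles containing at least one qualifying citation,
    with multi-collection citations marking presence in *each* listed
    code.
    """
    if facet not in FILTER_KEYS:
        raise QueryError(f"unknown facet: {facet!r}")
    if measure not in MEASURES:
        raise QueryError(f"unknown measure: {measure!r}")
    spec_counts: dict = {}
    treat_sets: dict = {}
    art_sets: dict = {}
    for article, treatment, citation in corpus.iter_citations():
        label = _specimen_label(article, treatment, citation, facet)
        spec_counts[label] = spec_counts.get(label, 0) + citation.counts.total
        for plabel in _presence_labels(article, treatment, citation, facet):
            treat_sets.setdefault(plabel, set()).add(treatment.treatment_id)
            art_sets.setdefault(plabel, set()).add(article.article_id)
    return _build_table(facet, measure, spec_counts, treat_sets, art_sets)


ATTRIBUTION_MODES = ("raw", "fractional", "full_credit")


def attribute_collectors(corpus: Corpus, mode: str = "raw") -> FacetTable:
    """Aggregate specimens over collectors under one attribution mode.

    * ``raw`` — verbatim collector strings are the facet values;
    * ``fractional`` — each member of a team of *k* receives total/k
      (the specimen column becomes fractional but conserves the corpus
      total);
    * ``full_credit`` — each member receives the full citation total
      (the column may exceed the corpus total).
    """
    if mode not in ATTRIBUTION_MODES:
        raise QueryError(f"unknown attribution mode: {mode!r}")
    spec_counts: dict = {}
    treat_sets: dict = {}
    art_sets: dict = {}
    for article, treatment, citation in corpus.iter_citations():
        total = citation.counts.total
        if not citation.collector_raw:
            shares = [(MISSING, float(total))]
        elif mode == "raw":
            shares = [(escape_label(citation.collector_raw), float(total))]
        else:
            team = citation.collector_team or [citation.collector_raw]
            per = total / len(team) if mode == "fractional" else float(total)
            shares = [(escape_label(name), per) for name in team]
        for label, amount in shares:
            spec_counts[label] = spec_counts.get(label, 0.0) + amount
            treat_sets.setdefault(label, set()).add(treatment.treatment_id)
            art_sets.setdefault(label, set()).add(article.article_id)
    return _build_table(f"collector[{mode}]", "specimens", spec_counts, treat_sets, art_sets)
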