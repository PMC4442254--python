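"""Dashboard chart-data assembly.

Turns facet aggregations into named chart series — the data behind a
specimen-data dashboard page: sex proportions, collecting phenology by
month and decade, elevation profile, and specimen/treatment portions by
collection, country, collector, family, status and publication year.
Charts are *views* of :mod:`treatkit.facets` tables, never independent
recomputations, and serialize to stable JSON for plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .model import Corpus, Rank, is_primary_type
from .facets import (
    MISSING,
    FacetTable,
    FilterQuery,
    aggregate,
    apply_filter,
    attribute_collectors,
)

PROFILES = ("all-treatments", "species-rank")


@dataclass
class ChartSeries:
    """One chart: x labels plus one or more equally long numeric series."""

    chart_id: str
    kind: str  # pie | bar | stacked-bar | histogram | line
    title: str
    x_labels: list = field(default_factory=list)
    series: dict = field(default_factory=dict)  # series-name -> list of numbers

    def __post_init__(self) -> None:
        for name, values in self.series.items():
            if len(values) != len(self.x_labels):
                raise ValueError(
                    f"chart {self.chart_id!r}: series {name!r} length "
                    f"{len(values)} != {len(self.x_labels)} x labels"
                )


@dataclass
class DashboardPage:
    page_id: str
    filter: FilterQuery
    charts: list = field(default_factory=list)

    def chart(self, chart_id: str) -> Optional[ChartSeries]:
        for c in self.charts:
            if c.chart_id == chart_id:
                return c
        return None


def _table_chart(chart_id: str, kind: str, title: str, table: FacetTable) -> ChartSeries:
    return ChartSeries(
        chart_id=chart_id,
        kind=kind,
        title=title,
        x_labels=[r.label for r in table.rows],
        series={table.measure: [getattr(r, table.measure) for r in table.rows]},
    )


def _sex_totals(corpus: Corpus) -> tuple:
    males = females = other = 0
    for _, _, c in corpus.iter_citations():
        males += c.counts.males
        females += c.counts.females
        other += c.counts.other
    return males, females, other


def _month_by_sex(corpus: Corpus) -> ChartSeries:
    labels = [str(m) for m in range(1, 13)] + [MISSING]
    series = {"male": [0] * 13, "female": [0] * 13, "other": [0] * 13}
    for _, _, c in corpus.iter_citations():
        date = c.event_date
        idx = date.month - 1 if date and date.month else 12
        series["male"][idx] += c.counts.males
        series["female"][idx] += c.counts.females
        series["other"][idx] += c.counts.other
    return ChartSeries(
        chart_id="specimens_by_month_sex",
        kind="stacked-bar",
        title="Specimens by month and sex",
        x_labels=labels,
        series=series,
    )


def _primary_type_subcorpus(corpus: Corpus) -> Corpus:
    """Restrict to citations of primary-type (name-bearing) specimens."""
    sub = Corpus()
    for article in corpus.articles:
        treatments = []
        for treatment in article.treatments:
            citations = [c for c in treatment.citations if is_primary_type(c.type_status)]
            if citations:
                treatments.append(
                    type(treatment)(
                        treatment_id=treatment.treatment_id,
                        taxon=treatment.taxon,
                        status=treatment.status,
                        citations=citations,
                    )
                )
        if treatments:
            sub.articles.append(
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
    return sub


def _treatments_per_article(corpus: Corpus) -> ChartSeries:
    labels = [a.article_id for a in corpus.articles]
    return ChartSeries(
        chart_id="treatments_per_article",
        kind="bar",
        title="Treatments per article",
        x_labels=labels,
        series={"treatments": [len(a.treatments) for a in corpus.articles]},
    )


def build_dashboard(
    corpus: Corpus,
    filter: FilterQuery = FilterQuery(),
    profile: str = "all-treatments",
    collector_mode: str = "raw",
    extra_charts: Optional[list] = None,
    author_scope: str = "first",
) -> DashboardPage:
    """Assemble the canonical 16-chart page for a (filtered) corpus.

    ``profile="species-rank"`` restricts to species-rank treatments
    before charting.  An empty filtered corpus yields a page of all-zero
    charts, not an error.  ``extra_charts`` is a hook: callables taking
    the filtered corpus and returning a :class:`ChartSeries`.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile: {profile!r}")
    view = apply_filter(corpus, filter, author_scope=author_scope)
    if profile == "species-rank":
        view = apply_filter(view, FilterQuery.make({"tax.rank": Rank.SPECIES.value}))

    males, females, other = _sex_totals(view)
    charts = [
        ChartSeries(
            chart_id="specimens_by_sex",
            kind="pie",
            title="Specimens by sex",
            x_labels=["male", "female", "other"],
            series={"specimens": [males, females, other]},
        ),
        _month_by_sex(view),
        _table_chart(
            "specimens_by_decade", "bar", "Specimens by decade of collection",
            aggregate(view, "mat.decade"),
        ),
        _table_chart(
            "specimens_by_elevation", "histogram", "Specimens by elevation band",
            aggregate(view, "mat.elevationBand"),
        ),
        _table_chart(
            "specimens_by_collection", "bar", "Specimens by collection code",
            aggregate(view, "mat.collectionCode"),
        ),
        _table_chart(
            "treatments_by_collection", "bar", "Treatments by collection code",
            aggregate(view, "mat.collectionCode", measure="treatments"),
        ),
        _table_chart(
            "primary_types_by_collection", "bar", "Primary type specimens by collection code",
            aggregate(_primary_type_subcorpus(view), "mat.collectionCode"),
        ),
        _table_chart(
            "specimens_by_country", "bar", "Specimens by country",
            aggregate(view, "mat.country"),
        ),
        _table_chart(
            "treatments_by_country", "bar", "Treatments by country",
            aggregate(view, "mat.country", measure="treatments"),
        ),
        _table_chart(
            "specimens_by_collector", "bar", "Specimens by collector name",
            attribute_collectors(view, collector_mode),
        ),
        _table_chart(
            "treatments_by_collector", "bar", "Treatments by collector name",
            FacetTable(
                facet=f"collector[{collector_mode}]",
                measure="treatments",
                rows=sorted(
                    (r for r in attribute_collectors(view, collector_mode).rows if r.treatments > 0),
                    key=lambda r: (-r.treatments, r.label),
                ),
            ),
        ),
        _table_chart(
            "treatments_by_family", "bar", "Treatments by family",
            aggregate(view, "tax.familyEpithet", measure="treatments"),
        ),
        _table_chart(
            "treatments_by_status", "bar", "Treatments by taxonomic status",
            aggregate(view, "tax.status", measure="treatments"),
        ),
        _table_chart(
            "specimens_by_publication_year", "bar", "Specimens by year of publication",
            aggregate(view, "doc.year"),
        ),
        _table_chart(
            "treatments_by_publication_year", "bar", "Treatments by year of publication",
            aggregate(view, "doc.year", measure="treatments"),
        ),
        _treatments_per_article(view),
    ]
    for maker in extra_charts or []:
        charts.append(maker(view))
    ids = [c.chart_id for c in charts]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate chart_id on page")
    return DashboardPage(
        page_id=f"{profile}:{filter.to_string() or 'all'}",
        filter=filter,
        charts=charts,
    )


def render_json(page: DashboardPage) -> str:
    """Serialize a page to stable JSON (fixed key order, UTF-8 text).

    Schema: ``{"page_id", "filter", "charts": [{"chart_id", "kind",
    "title", "x", "series": {name: [numbers]}}]}``; series keys keep
    insertion order, numbers carry no locale separators.
    """
    doc = {
        "page_id": page.page_id,
        "filter": page.filter.to_string(),
        "charts": [
            {
                "chart_id": c.chart_id,
                "kind": c.kind,
                "title": c.title,
                "x": list(c.x_labels),
                "series": {name: list(values) for name, values in c.series.items()},
            }
            for c in page.charts
        ],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"
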