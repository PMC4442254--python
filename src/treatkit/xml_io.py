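"""Reader/writer for the treatment XML dialect and Darwin Core CSV export.

The dialect is a deliberately small, hand-writable grammar carrying the
same field inventory as marked-up taxonomic literature::

    article[id, journal, year, doi?, lsid?, pageCount?]
      meta > author*
      treatment[id, rank, status?]
        taxon[orderEpithet?, familyEpithet?, genusEpithet?,
              speciesEpithet?, authority?]
        materialsCitation[country?, locality?, elevation?, date?,
                          collectorName?, typeStatus?]
          collectionCode*  specimenCount[type, count]*  specimenCode*

``specimenCount/@type`` is one of male/female/other/total; the total
plays the role of Darwin Core ``individualCount`` and is reconciled with
the per-sex counts on read.  The writer is canonical (fixed attribute
order, 2-space indent, UTF-8) so writing the same corpus twice yields
identical bytes, and ``read(write(c)) == c`` field for field.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from lxml import etree

from .model import (
    ArticleRecord,
    Corpus,
    MaterialsCitation,
    Rank,
    TaxonName,
    TreatmentRecord,
    TreatmentStatus,
    TypeStatus,
)
from .parsing import (
    SexFieldParse,
    compose_sex_text,
    parse_event_date,
    reconcile_counts,
    split_collectors,
)

logger = logging.getLogger("treatkit.xml_io")


class SchemaError(ValueError):
    """Structurally valid XML that violates the dialect grammar."""


_ARTICLE_ATTRS = ("id", "journal", "year", "doi", "lsid", "pageCount")
_TREATMENT_ATTRS = ("id", "rank", "status")
_TAXON_ATTRS = ("orderEpithet", "familyEpithet", "genusEpithet", "speciesEpithet", "authority")
_CITATION_ATTRS = ("country", "locality", "elevation", "date", "collectorName", "typeStatus")
_COUNT_TYPES = ("male", "female", "other", "total")


def _warn_unknown(elem: etree._Element, known_attrs: tuple, known_children: tuple) -> None:
    for attr in elem.attrib:
        if attr not in known_attrs:
            logger.warning("ignoring unknown attribute %r on <%s>", attr, elem.tag)
    for child in elem:
        if not isinstance(child.tag, str):
            continue  # comments / PIs
        if child.tag not in known_children:
            logger.warning("ignoring unknown element <%s> under <%s>", child.tag, elem.tag)


# ---------------------------------------------------------------------------
# reading


def read_article(xml: "str | bytes") -> ArticleRecord:
    """Parse one dialect document into a fully populated :class:`ArticleRecord`.

    Malformed XML raises :class:`lxml.etree.XMLSyntaxError` (with line
    number); a missing required attribute raises :class:`SchemaError`
    naming the element.  Unknown elements and attributes are ignored
    with a logged warning.
    """
    if isinstance(xml, str):
        xml = xml.encode("utf-8")
    root = etree.fromstring(xml)
    if root.tag != "article":
        raise SchemaError(f"root element must be <article>, got <{root.tag}>")
    for required in ("id", "journal", "year"):
        if required not in root.attrib:
            raise SchemaError(f"<article> missing required attribute {required!r}")
    _warn_unknown(root, _ARTICLE_ATTRS, ("meta", "treatment"))

    metas = root.findall("meta")
    if len(metas) != 1:
        raise SchemaError(f"<article> must have exactly one <meta> child, found {len(metas)}")
    authors = [a.text.strip() for a in metas[0].findall("author") if a.text and a.text.strip()]

    article = ArticleRecord(
        article_id=root.get("id"),
        journal=root.get("journal"),
        year=int(root.get("year")),
        authors=authors,
        doi=root.get("doi"),
        lsid=root.get("lsid"),
        page_count=int(root.get("pageCount")) if root.get("pageCount") else None,
    )
    for telem in root.findall("treatment"):
        article.treatments.append(_read_treatment(telem))
    return article


def _read_treatment(elem: etree._Element) -> TreatmentRecord:
    if "id" not in elem.attrib:
        raise SchemaError("<treatment> missing required attribute 'id'")
    if "rank" not in elem.attrib:
        raise SchemaError(f"<treatment id={elem.get('id')!r}> missing required attribute 'rank'")
    _warn_unknown(elem, _TREATMENT_ATTRS, ("taxon", "materialsCitation"))
    try:
        rank = Rank(elem.get("rank"))
    except ValueError:
        raise SchemaError(
            f"<treatment id={elem.get('id')!r}> has unknown rank {elem.get('rank')!r}"
        ) from None

    taxon_elem = elem.find("taxon")
    epithets = {}
    authority = None
    if taxon_elem is not None:
        _warn_unknown(taxon_elem, _TAXON_ATTRS, ())
        authority = taxon_elem.get("authority")
        for key in ("orderEpithet", "familyEpithet", "genusEpithet", "speciesEpithet"):
            if taxon_elem.get(key):
                epithets[key] = taxon_elem.get(key)
    taxon = TaxonName.make(rank, authority=authority, **epithets)

    treatment = TreatmentRecord(
        treatment_id=elem.get("id"),
        taxon=taxon,
        status=TreatmentStatus.from_raw(elem.get("status")),
    )
    for celem in elem.findall("materialsCitation"):
        treatment.citations.append(_read_citation(celem))
    return treatment


def _read_citation(elem: etree._Element) -> MaterialsCitation:
    _warn_unknown(elem, _CITATION_ATTRS, ("collectionCode", "specimenCount", "specimenCode"))
    parse = SexFieldParse()
    individual_count: Optional[int] = None
    for count_elem in elem.findall("specimenCount"):
        ctype = count_elem.get("type")
        count = int(count_elem.get("count", "0"))
        if ctype == "male":
            parse.males += count
        elif ctype == "female":
            parse.females += count
        elif ctype == "other":
            parse.stated_other += count
        elif ctype == "total":
            individual_count = count
        else:
            logger.warning("ignoring specimenCount with unknown type %r", ctype)
    counts, warning = reconcile_counts(parse, individual_count)

    raw_ts = elem.get("typeStatus")
    type_status, type_status_raw = TypeStatus.NONE, None
    if raw_ts:
        try:
            type_status = TypeStatus(raw_ts.strip().lower())
        except ValueError:
            type_status_raw = raw_ts

    date_text = elem.get("date")
    event_date = parse_event_date(date_text)
    collector_raw = elem.get("collectorName")

    citation = MaterialsCitation(
        counts=counts,
        type_status=type_status,
        type_status_raw=type_status_raw,
        collection_codes=[c.text.strip() for c in elem.findall("collectionCode") if c.text],
        country=elem.get("country"),
        locality=elem.get("locality"),
        elevation_m=float(elem.get("elevation")) if elem.get("elevation") else None,
        event_date=event_date,
        event_date_raw=None if event_date and event_date.isoformat() == date_text else date_text,
        collector_raw=collector_raw,
        collector_team=split_collectors(collector_raw),
        specimen_codes=[c.text.strip() for c in elem.findall("specimenCode") if c.text],
    )
    if warning:
        citation.warnings.append(warning)
    if date_text and event_date is None:
        citation.warnings.append(f"unparseable collecting date: {date_text!r}")
    return citation


def load_article(path: "str | Path") -> ArticleRecord:
    return read_article(Path(path).read_bytes())


def read_corpus(paths: Iterable) -> Corpus:
    return Corpus(articles=[load_article(p) for p in paths])


# ---------------------------------------------------------------------------
# writing


def _fmt_elevation(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(value)


def write_article(article: ArticleRecord) -> str:
    """Serialize canonically: fixed attribute order, 2-space indent, UTF-8.

    Absent optional fields are omitted entirely (never written as empty
    attributes) so that the writer is an exact inverse of the reader.
    """
    root = etree.Element("article")
    root.set("id", article.article_id)
    root.set("journal", article.journal)
    root.set("year", str(article.year))
    if article.doi is not None:
        root.set("doi", article.doi)
    if article.lsid is not None:
        root.set("lsid", article.lsid)
    if article.page_count is not None:
        root.set("pageCount", str(article.page_count))
    meta = etree.SubElement(root, "meta")
    for author in article.authors:
        etree.SubElement(meta, "author").text = author
    for treatment in article.treatments:
        _write_treatment(root, treatment)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def _write_treatment(parent: etree._Element, treatment: TreatmentRecord) -> None:
    elem = etree.SubElement(parent, "treatment")
    elem.set("id", treatment.treatment_id)
    elem.set("rank", treatment.taxon.rank.value)
    if treatment.status.raw_status is not None:
        elem.set("status", treatment.status.raw_status)
    taxon = treatment.taxon
    if taxon.epithets or taxon.authority:
        telem = etree.SubElement(elem, "taxon")
        for key, value in taxon.epithets:
            telem.set(key, value)
        if taxon.authority is not None:
            telem.set("authority", taxon.authority)
    for citation in treatment.citations:
        _write_citation(elem, citation)


def _write_citation(parent: etree._Element, citation: MaterialsCitation) -> None:
    elem = etree.SubElement(parent, "materialsCitation")
    if citation.country is not None:
        elem.set("country", citation.country)
    if citation.locality is not None:
        elem.set("locality", citation.locality)
    if citation.elevation_m is not None:
        elem.set("elevation", _fmt_elevation(citation.elevation_m))
    if citation.event_date_raw is not None:
        elem.set("date", citation.event_date_raw)
    elif citation.event_date is not None:
        elem.set("date", citation.event_date.isoformat())
    if citation.collector_raw is not None:
        elem.set("collectorName", citation.collector_raw)
    if citation.type_status_raw is not None:
        elem.set("typeStatus", citation.type_status_raw)
    elif citation.type_status is not TypeStatus.NONE:
        elem.set("typeStatus", citation.type_status.value)
    for code in citation.collection_codes:
        etree.SubElement(elem, "collectionCode").text = code
    counts = citation.counts
    for ctype, value in (("male", counts.males), ("female", counts.females), ("other", counts.other)):
        if value:
            count_elem = etree.SubElement(elem, "specimenCount")
            count_elem.set("type", ctype)
            count_elem.set("count", str(value))
    total_elem = etree.SubElement(elem, "specimenCount")
    total_elem.set("type", "total")
    total_elem.set("count", str(counts.total))
    for code in citation.specimen_codes:
        etree.SubElement(elem, "specimenCode").text = code


def save_article(article: ArticleRecord, path: "str | Path") -> None:
    Path(path).write_text(write_article(article), encoding="utf-8")


def write_corpus(corpus: Corpus, directory: "str | Path") -> list:
    """Write one ``<article_id>.xml`` per article; return the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for article in corpus.articles:
        path = directory / f"{article.article_id}.xml"
        save_article(article, path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Darwin Core export

DWC_COLUMNS = [
    "occurrenceID",
    "scientificName",
    "taxonRank",
    "order",
    "family",
    "genus",
    "specificEpithet",
    "typeStatus",
    "individualCount",
    "sex",
    "institutionCode",
    "country",
    "locality",
    "minimumElevationInMeters",
    "eventDate",
    "year",
    "month",
    "recordedBy",
    "catalogNumber",
    "basisOfRecord",
]


def export_dwc(corpus: Corpus) -> pd.DataFrame:
    """Flatten a corpus to Darwin Core occurrence rows, one per citation.

    ``institutionCode`` (Darwin Core's term for what treatment markup
    calls the collection code) joins multiple depositories with ``"|"``;
    ``sex`` is the composed text form (``"1 male, 4 females"``) omitting
    zero classes.
    """
    rows = []
    for article, treatment in corpus.iter_treatments():
        for idx, citation in enumerate(treatment.citations):
            taxon = treatment.taxon
            date = citation.event_date
            rows.append(
                {
                        "occurrenceID": f"{article.article_id}:{treatment.treatment_id}:{idx}",
                        "scientificName": taxon.scientific_name,
                        "taxonRank": taxon.rank.value,
                        "order": taxon.epithet("orderEpithet") or "",
                        "family": taxon.epithet("familyEpithet") or "",
                        "genus": taxon.epithet("genusEpithet") or "",
                        "specificEpithet": taxon.epithet("speciesEpithet") or "",
                        "typeStatus": "" if citation.type_status is TypeStatus.NONE else citation.type_status.value,
                        "individualCount": str(citation.counts.total),
                        "sex": compose_sex_text(citation.counts.males, citation.counts.females, citation.counts.other),
                        "institutionCode": "|".join(citation.collection_codes),
                        "country": citation.country or "",
                        "locality": citation.locality or "",
                        "minimumElevationInMeters": _fmt_elevation(citation.elevation_m) if citation.elevation_m is not None else "",
                        "eventDate": date.isoformat() if date else (citation.event_date_raw or ""),
                        "year": str(date.year) if date else "",
                        "month": str(date.month) if date and date.month else "",
                        "recordedBy": citation.collector_raw or "",
                        "catalogNumber": "|".join(citation.specimen_codes),
                        "basisOfRecord": "PreservedSpecimen",
                }
            )
    return pd.DataFrame(rows, columns=DWC_COLUMNS, dtype=str)


def write_dwc_csv(corpus: Corpus, path: "str | Path") -> None:
    export_dwc(corpus).to_csv(path, index=False, encoding="utf-8")
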