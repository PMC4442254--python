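"""Domain model for structured taxonomic-treatment data.

The model mirrors how taxonomic literature is organised: an *article*
(one publication) contains *treatments* (one section per taxon), and
each treatment cites the specimen lots it is based on — its *materials
citations*.  A materials citation corresponds to one Darwin Core
occurrence record: a set of specimens (possibly of mixed sex) collected
in one event and deposited in zero, one or several institutional
collections.

Validation is a separate, non-throwing pass (:func:`validate_corpus`)
that returns findings, so that messy legacy data can be loaded first and
audited afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional


class Rank(str, Enum):
    """Taxonomic rank of a treatment's subject taxon."""

    ORDER = "order"
    FAMILY = "family"
    GENUS = "genus"
    SPECIES = "species"
    SPECIES_GROUP = "species-group"
    OTHER_HIGHER = "other-higher"


#: epithet keys in canonical (descending-rank) order
EPITHET_KEYS = ("orderEpithet", "familyEpithet", "genusEpithet", "speciesEpithet")

RANK_TO_EPITHET = {
    Rank.ORDER: "orderEpithet",
    Rank.FAMILY: "familyEpithet",
    Rank.GENUS: "genusEpithet",
    Rank.SPECIES: "speciesEpithet",
}


class TypeStatus(str, Enum):
    """Nomenclatural type status of a cited specimen lot."""

    HOLOTYPE = "holotype"
    PARATYPE = "paratype"
    SYNTYPE = "syntype"
    LECTOTYPE = "lectotype"
    NEOTYPE = "neotype"
    ALLOTYPE = "allotype"
    NONE = "none"


#: name-bearing ("primary") types
PRIMARY_TYPES = frozenset(
    {TypeStatus.HOLOTYPE, TypeStatus.SYNTYPE, TypeStatus.LECTOTYPE, TypeStatus.NEOTYPE}
)


class ValidationError(ValueError):
    """Raised for values outside an operation's domain (unknown enum token, range)."""


def is_primary_type(status: "TypeStatus | str") -> bool:
    """True exactly for the name-bearing types: holotype, syntype, lectotype, neotype.

    Accepts a :class:`TypeStatus` or its string value; an unknown string
    raises :class:`ValidationError` naming the offending token.
    """
    if not isinstance(status, TypeStatus):
        try:
            status = TypeStatus(status)
        except ValueError:
            raise ValidationError(f"unknown type status: {status!r}") from None
    return status in PRIMARY_TYPES


@dataclass(frozen=True)
class PartialDate:
    """Calendar date with reduced precision (year, year-month, or full)."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValidationError(f"month out of range: {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValidationError("day given without month")
            if not 1 <= self.day <= 31:
                raise ValidationError(f"day out of range: {self.day}")

    @property
    def decade(self) -> int:
        return (self.year // 10) * 10

    @property
    def decade_label(self) -> str:
        return f"{self.decade}s"

    def isoformat(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def sort_key(self) -> tuple:
        return (self.year, self.month or 1, self.day or 1)


@dataclass(frozen=True)
class CountTriple:
    """Reconciled specimen counts of one lot, split by sex class.

    ``total == males + females + other`` always holds; the constructor
    enforces it so the invariant cannot drift anywhere downstream.
    """

    males: int
    females: int
    other: int
    total: int

    def __post_init__(self) -> None:
        for name in ("males", "females", "other", "total"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"CountTriple.{name} must be a non-negative integer, got {v!r}")
        if self.total != self.males + self.females + self.other:
            raise ValidationError(
                f"CountTriple total {self.total} != males {self.males} + "
                f"females {self.females} + other {self.other}"
            )

    @classmethod
    def of(cls, males: int = 0, females: int = 0, other: int = 0) -> "CountTriple":
        return cls(males, females, other, males + females + other)


# Treatment-status vocabulary: raw markup token -> flag name.
STATUS_VOCABULARY = {
    "sp. nov.": "is_new_species",
    "new species": "is_new_species",
    "comb. nov.": "is_new_combination",
    "new combination": "is_new_combination",
    "gen. nov.": "is_new_higher_taxon",
    "new genus": "is_new_higher_taxon",
}


@dataclass(frozen=True)
class TreatmentStatus:
    is_new_species: bool = False
    is_new_combination: bool = False
    is_new_higher_taxon: bool = False
    raw_status: Optional[str] = None

    @classmethod
    def from_raw(cls, raw: Optional[str]) -> "TreatmentStatus":
        """Map a raw status token to flags; unknown tokens keep the raw text only."""
        if raw is None or not raw.strip():
            return cls()
        flag = STATUS_VOCABULARY.get(raw.strip().lower())
        kwargs = {flag: True} if flag else {}
        return cls(raw_status=raw.strip(), **kwargs)

    @property
    def label(self) -> str:
        if self.is_new_species:
            return "new-species"
        if self.is_new_combination:
            return "new-combination"
        if self.is_new_higher_taxon:
            return "new-higher-taxon"
        return "none"


@dataclass(frozen=True)
class TaxonName:
    """Rank-keyed epithets of a taxon plus optional authority string."""

    rank: Rank
    epithets: tuple = ()  # tuple of (epithet-key, value) pairs, canonical order
    authority: Optional[str] = None

    @classmethod
    def make(
        cls,
        rank: "Rank | str",
        authority: Optional[str] = None,
        **epithets: str,
    ) -> "TaxonName":
        rank = Rank(rank)
        unknown = set(epithets) - set(EPITHET_KEYS)
        if unknown:
            raise ValidationError(f"unknown epithet keys: {sorted(unknown)}")
        pairs = tuple((k, epithets[k]) for k in EPITHET_KEYS if k in epithets)
        return cls(rank=rank, epithets=pairs, authority=authority)

    def epithet(self, key: str) -> Optional[str]:
        for k, v in self.epithets:
            if k == key:
                return v
        return None

    @property
    def scientific_name(self) -> str:
        genus = self.epithet("genusEpithet")
        species = self.epithet("speciesEpithet")
        if genus and species:
            return f"{genus} {species}"
        for key in reversed(EPITHET_KEYS):
            v = self.epithet(key)
            if v:
                return v
        return ""


@dataclass
class MaterialsCitation:
    """One cited specimen lot with its collecting-event and depository data."""

    counts: CountTriple = field(default_factory=lambda: CountTriple.of())
    type_status: TypeStatus = TypeStatus.NONE
    type_status_raw: Optional[str] = None  # preserved verbatim when unrecognized
    collection_codes: list = field(default_factory=list)
    country: Optional[str] = None
    locality: Optional[str] = None
    elevation_m: Optional[float] = None
    event_date: Optional[PartialDate] = None
    event_date_raw: Optional[str] = None  # verbatim text when not ISO-parseable
    collector_raw: Optional[str] = None
    collector_team: list = field(default_factory=list)
    specimen_codes: list = field(default_factory=list)
    warnings: list = field(default_factory=list, compare=False)


@dataclass
class TreatmentRecord:
    treatment_id: str
    taxon: TaxonName
    status: TreatmentStatus = field(default_factory=TreatmentStatus)
    citations: list = field(default_factory=list)

    @property
    def is_species_rank(self) -> bool:
        return self.taxon.rank is Rank.SPECIES

    @property
    def total_specimens(self) -> int:
        return sum(c.counts.total for c in self.citations)


@dataclass
class ArticleRecord:
    article_id: str
    journal: str
    year: int
    authors: list = field(default_factory=list)
    doi: Optional[str] = None
    lsid: Optional[str] = None
    page_count: Optional[int] = None
    treatments: list = field(default_factory=list)


@dataclass
class Corpus:
    articles: list = field(default_factory=list)

    def iter_treatments(self) -> Iterator[tuple]:
        for a in self.articles:
            for t in a.treatments:
                yield a, t

    def iter_citations(self) -> Iterator[tuple]:
        for a in self.articles:
            for t in a.treatments:
                for c in t.citations:
                    yield a, t, c

    @property
    def total_specimens(self) -> int:
        return sum(c.counts.total for _, _, c in self.iter_citations())

    @classmethod
    def merge(cls, *corpora: "Corpus") -> "Corpus":
        merged = cls()
        for corpus in corpora:
            merged.articles.extend(corpus.articles)
        return merged


@dataclass(frozen=True)
class Finding:
    """One validation finding: a broken invariant, located and described."""

    severity: str  # "error" | "warning"
    record_id: str
    message: str


def validate_corpus(corpus: Corpus) -> list:
    """Check every model invariant; return one finding per violation.

    Never raises and never mutates its input; an empty list means the
    corpus is valid.
    """
    findings: list = []

    def err(record_id: str, message: str) -> None:
        findings.append(Finding("error", record_id, message))

    def warn(record_id: str, message: str) -> None:
        findings.append(Finding("warning", record_id, message))

    seen_articles: set = set()
    seen_treatments: set = set()
    for article in corpus.articles:
        if article.article_id in seen_articles:
            err(article.article_id, "duplicate article_id")
        seen_articles.add(article.article_id)
        if not 1750 <= article.year <= 2100:
            err(article.article_id, f"article year {article.year} outside [1750, 2100]")
        if not article.authors:
            err(article.article_id, "article has no authors")
        for treatment in article.treatments:
            tid = treatment.treatment_id
            if tid in seen_treatments:
                err(tid, "duplicate treatment_id")
            seen_treatments.add(tid)
            taxon = treatment.taxon
            if taxon.rank is Rank.SPECIES and not taxon.epithet("speciesEpithet"):
                err(tid, "species-rank treatment lacks speciesEpithet")
            if taxon.rank is not Rank.SPECIES and taxon.epithet("speciesEpithet"):
                err(tid, "speciesEpithet present on a non-species-rank treatment")
            status = treatment.status
            if status.is_new_species and status.is_new_higher_taxon:
                err(tid, "status flags new-species and new-higher-taxon both set")
            if status.raw_status and STATUS_VOCABULARY.get(status.raw_status.lower()) is None:
                if status.is_new_species or status.is_new_combination or status.is_new_higher_taxon:
                    pass  # flags set explicitly alongside free-text status: fine
                else:
                    warn(tid, f"unrecognized treatment status text: {status.raw_status!r}")
            for i, cit in enumerate(treatment.citations):
                cid = f"{tid}#{i}"
                cnt = cit.counts
                if cnt.total != cnt.males + cnt.females + cnt.other:
                    err(cid, "count triple does not sum")
                if bool(cit.collector_team) != bool(cit.collector_raw):
                    err(cid, "collector_team must be non-empty iff collector_raw present")
                if cit.elevation_m is not None and not 0 <= cit.elevation_m <= 9000:
                    err(cid, f"elevation {cit.elevation_m} outside [0, 9000] m")
                if cit.type_status_raw is not None and cit.type_status is TypeStatus.NONE:
                    warn(cid, f"unrecognized type status text: {cit.type_status_raw!r}")
                for w in cit.warnings:
                    warn(cid, w)
    return findings
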