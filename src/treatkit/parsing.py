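"""Normalization of verbatim materials-citation fields.

Legacy taxonomic text records specimen lots in loosely standardized
prose: a "sex" field like ``"1 male, 4 females"``, an independent
``individualCount``, collector strings naming whole teams, dates at
mixed precision, and spot elevations.  This module turns those verbatim
fields into reconciled model values, surfacing — never guessing away —
anything it cannot interpret.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .model import CountTriple, PartialDate, ValidationError

# ---------------------------------------------------------------------------
# sex field

# class words, lowercase, singular; trailing "s" and "." are stripped on match
_SEX_CLASS = {
    "male": "males",
    "♂": "males",  # ♂
    "female": "females",
    "♀": "females",  # ♀
    "juvenile": "other",
    "juv": "other",
    "imm": "other",
    "immature": "other",
    "subadult": "other",
    "other": "other",
}

_TOKEN_SPLIT = re.compile(r"\s*(?:,|;|\band\b)\s*", re.IGNORECASE)
_TOKEN = re.compile(r"^(?:(\d+)\s*)?(\S.*?)$")


@dataclass
class SexFieldParse:
    """Result of parsing a free-text sex field."""

    males: int = 0
    females: int = 0
    stated_other: int = 0
    unparsed_tokens: list = field(default_factory=list)

    @property
    def stated_sum(self) -> int:
        return self.males + self.females + self.stated_other


def parse_sex_field(text: Optional[str]) -> SexFieldParse:
    """Parse ``"1 male, 4 females"``-style text into per-class counts.

    Tokens are ``<int> <classword>`` separated by commas, semicolons or
    "and"; a bare class word counts 1; juveniles/immatures/subadults go
    to the "other" class.  Unrecognized tokens are preserved verbatim in
    ``unparsed_tokens`` rather than guessed at.
    """
    result = SexFieldParse()
    if not text or not text.strip():
        return result
    for token in _TOKEN_SPLIT.split(text.strip()):
        if not token:
            continue
        m = _TOKEN.match(token)
        count = int(m.group(1)) if m.group(1) else 1
        word = m.group(2).strip().lower().rstrip(".")
        if word.endswith("s") and word not in _SEX_CLASS:
            word = word[:-1]
        cls = _SEX_CLASS.get(word)
        if cls is None:
            result.unparsed_tokens.append(token)
        elif cls == "males":
            result.males += count
        elif cls == "females":
            result.females += count
        else:
            result.stated_other += count
    return result


def compose_sex_text(males: int, females: int, other: int = 0) -> str:
    """Render counts back to canonical sex-field text, omitting zero classes."""
    parts = []
    for count, singular in ((males, "male"), (females, "female"), (other, "other")):
        if count:
            parts.append(f"{count} {singular}{'s' if count != 1 else ''}")
    return ", ".join(parts)


def reconcile_counts(
    parse: SexFieldParse, individual_count: Optional[int] = None
) -> tuple:
    """Reconcile a sex-field parse with an independent individualCount.

    Returns ``(CountTriple, warning)`` where ``warning`` is ``None``
    unless the two sources disagree irreconcilably.  Rules:

    * no individualCount: total is the sum of the stated classes;
    * individualCount >= stated sum: the surplus is unsexed material and
      is added to the "other" class;
    * individualCount < stated sum: the stated classes win (they cannot
      shrink) and a reconciliation warning is returned.
    """
    if individual_count is not None and individual_count < 0:
        raise ValidationError(f"individualCount must be >= 0, got {individual_count}")
    s = parse.stated_sum
    warning = None
    if individual_count is None or individual_count == s:
        other = parse.stated_other
        total = s
    elif individual_count > s:
        other = individual_count - parse.males - parse.females
        total = individual_count
    else:
        other = parse.stated_other
        total = s
        warning = (
            f"individualCount {individual_count} is less than the stated "
            f"sex-class sum {s}; keeping the larger value"
        )
    return CountTriple(parse.males, parse.females, other, total), warning


# ---------------------------------------------------------------------------
# collectors

_COLLECTOR_SPLIT = re.compile(r"\s*(?:&|;|,|\band\b)\s*")


def split_collectors(raw: Optional[str]) -> list:
    """Split a verbatim collector string into an ordered list of names.

    Splits on "&", "and", commas and semicolons, trimming whitespace.
    Order is preserved: "A & B" and "B & A" are distinct teams.
    """
    if not raw or not raw.strip():
        return []
    return [part for part in _COLLECTOR_SPLIT.split(raw.strip()) if part]


# ---------------------------------------------------------------------------
# dates

_MONTHS = {
    name: i + 1
    for i, names in enumerate(
        [
            ("jan", "january"),
            ("feb", "february"),
            ("mar", "march"),
            ("apr", "april"),
            ("may",),
            ("jun", "june"),
            ("jul", "july"),
            ("aug", "august"),
            ("sep", "sept", "september"),
            ("oct", "october"),
            ("nov", "november"),
            ("dec", "december"),
        ]
    )
    for name in names
}

_DASH = r"[‐‒–—-]"  # hyphen and unicode dashes

_DATE_PATTERNS = [
    # ISO, reduced precision allowed
    (re.compile(r"^(\d{4})$"), lambda m: (int(m[1]), None, None)),
    (re.compile(r"^(\d{4})-(\d{1,2})$"), lambda m: (int(m[1]), int(m[2]), None)),
    (
        re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$"),
        lambda m: (int(m[1]), int(m[2]), int(m[3])),
    ),
    # continental numeric: DD.MM.YYYY
    (
        re.compile(r"^(\d{1,2})\.(\d{1,2})\.(\d{4})$"),
        lambda m: (int(m[3]), int(m[2]), int(m[1])),
    ),
    # textual month: "15 Jul 1999", "15 July 1999"
    (
        re.compile(r"^(\d{1,2})\.?\s+([A-Za-z]+)\.?\s+(\d{4})$"),
        lambda m: (int(m[3]), _MONTHS.get(m[2].lower()), int(m[1])),
    ),
    # day range, start date used: "12–15 Jul 1999"
    (
        re.compile(rf"^(\d{{1,2}})\s*{_DASH}\s*\d{{1,2}}\.?\s+([A-Za-z]+)\.?\s+(\d{{4}})$"),
        lambda m: (int(m[3]), _MONTHS.get(m[2].lower()), int(m[1])),
    ),
]


def parse_event_date(text: Optional[str]) -> Optional[PartialDate]:
    """Parse a collecting date at whatever precision the text supports.

    Accepts ISO dates at year/month/day precision, ``DD.MM.YYYY``,
    ``D Month YYYY`` and day ranges (start date used).  Returns ``None``
    for unparseable text — the caller records a validation finding.
    """
    if not text or not text.strip():
        return None
    text = text.strip()
    for pattern, extract in _DATE_PATTERNS:
        m = pattern.match(text)
        if m:
            year, month, day = extract(m)
            if month is None and day is not None:
                return None  # textual month not recognized
            try:
                return PartialDate(year, month, day)
            except ValidationError:
                return None
    return None


# ---------------------------------------------------------------------------
# elevation

BAND_WIDTH_M = 500
MAX_ELEVATION_M = 9000


@dataclass(frozen=True)
class ElevationBand:
    """One 500 m elevation band, upper-inclusive: (lower, lower+500]."""

    lower_m: int
    upper_m: int
    label: str


def bin_elevation(elevation_m: float) -> ElevationBand:
    """Assign an elevation to its 500 m band; 0 maps to the lowest band.

    Bands are the half-open intervals ``(k*500, (k+1)*500]`` and are
    labelled like ``"1,001–1,500"`` as in field convention.
    """
    if not 0 <= elevation_m <= MAX_ELEVATION_M:
        raise ValidationError(
            f"elevation {elevation_m} m outside [0, {MAX_ELEVATION_M}] m"
        )
    k = 0 if elevation_m <= BAND_WIDTH_M else int(-(-elevation_m // BAND_WIDTH_M)) - 1
    lower = k * BAND_WIDTH_M
    upper = lower + BAND_WIDTH_M
    label = f"{lower + 1:,}–{upper:,}"
    return ElevationBand(lower, upper, label)
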