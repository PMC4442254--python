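"""Seeded generator of dialect-valid synthetic corpora with ground truth.

The generator emulates the structure of a mixed legacy/prospective
taxonomic corpus: articles containing treatments (species rank or
higher), each citing specimen lots with sex-structured counts, type
status, zero/one/many collection codes, country, locality, collector
(sometimes a team), date at mixed precision and elevation — with
configurable rates of missing fields and ambiguous multi-collection
citations.

Two features matter for testing:

* **Exact totals.**  ``GeneratorConfig.exact_totals`` pins corpus-level
  counts (articles, treatments, species treatments, specimens, new
  species, singletons, single-locality species, sex totals, citations,
  coded citations) which the generator then achieves *exactly*, so that
  pure functions of printed counts can be reproduced on synthetic data.
* **Ground truth.**  Alongside the corpus, :func:`generate` returns a
  :class:`GroundTruth` computed by a second, independent brute-force
  counting path (plain nested loops over the finished corpus — no code
  shared with the facet engine or stats module), making aggregation
  bugs detectable.

All randomness flows from one seeded :class:`numpy.random.Generator`;
the same config yields byte-identical written XML.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    ArticleRecord,
    Corpus,
    CountTriple,
    MaterialsCitation,
    PartialDate,
    Rank,
    TaxonName,
    TreatmentRecord,
    TreatmentStatus,
    TypeStatus,
)
from .parsing import split_collectors


class ConfigError(ValueError):
    """Unsatisfiable or malformed generator configuration."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ExactTotals:
    """Corpus-level counts the generator must achieve exactly."""

    articles: int
    treatments: int
    species_treatments: int
    species_specimens: int
    citing_species_treatments: Optional[int] = None  # default: all species treatments
    new_species: int = 0
    singletons_new: int = 0  # new species based on exactly one specimen
    singletons_citing: Optional[int] = None  # all citing species treatments on one specimen
    single_locality_new: Optional[int] = None  # new species from one locality (None: free)
    sex_totals: Optional[tuple] = None  # (males, females, other) over species specimens
    citations: Optional[int] = None  # total materials citations
    coded_citations: Optional[int] = None  # citations carrying a specimen code


@dataclass
class FocalSpecies:
    """One species forced to recur across several articles (a per-species
    dashboard subject), with a pinned specimen total and female count."""

    genus: str
    species: str
    n_articles: int
    specimens: int
    females: int
    family: str = "Linyphiidae"


DEFAULT_COUNTRIES = [
    ("Russia", 0.30), ("China", 0.20), ("Mongolia", 0.12), ("South Africa", 0.10),
    ("Canada", 0.08), ("Malaysia", 0.08), ("Portugal", 0.07), ("United States of America", 0.05),
]
DEFAULT_COLLECTIONS = [
    ("CAS", 0.18), ("IBPN", 0.16), ("ZMMU", 0.14), ("ISEA", 0.12), ("HNU", 0.10),
    ("NHRS", 0.08), ("IZAS", 0.08), ("ZMHU", 0.06), ("UMS", 0.05), ("NCA", 0.03),
]
DEFAULT_COLLECTORS = [
    ("Y. M. Marusik", 0.25), ("D. V. Obydov", 0.15), ("Tang Guo", 0.12),
    ("C. Griswold", 0.12), ("T. Kronestedt", 0.10), ("X.-P. Wang", 0.10),
    ("P. Jäger", 0.08), ("J. A. Miller", 0.08),
]
DEFAULT_FAMILIES = [
    ("Agelenidae", 0.28), ("Lycosidae", 0.25), ("Linyphiidae", 0.15),
    ("Salticidae", 0.12), ("Gnaphosidae", 0.10), ("Theridiidae", 0.10),
]
DEFAULT_GENERA = [
    "Pardosa", "Agelena", "Coelotes", "Draconarius", "Pireneitega",
    "Tenuiphantes", "Evarcha", "Gnaphosa", "Theridion", "Alopecosa",
]
DEFAULT_AUTHORS = [
    "J. A. Miller", "P. Jäger", "X.-P. Wang", "T. Kronestedt", "Y. M. Marusik",
    "C. Griswold", "S. Li", "M. Kuntner",
]

# rates calibrated to a legacy spider-literature corpus: ~17% of specimens
# lack a collection, ~4/5 of citations lack elevation, ~60% lack a
# specimen code
DEFAULT_MISSING_RATES = {
    "collection": 0.17,
    "date": 0.15,
    "elevation": 0.79,
    "collector": 0.10,
    "country": 0.02,
    "locality": 0.05,
    "specimen_code": 0.60,
}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_articles: int = 12
    journal: str = "Zootaxa"
    article_id_prefix: str = "art"  # keeps ids unique when merging corpora
    treatments_per_article: object = ("poisson", 6.9)  # int | ("poisson", lam) | ("empirical", [..])
    species_rank_fraction: float = 0.83
    citing_fraction: float = 1.0  # fraction of species treatments citing specimens
    new_species_fraction: float = 0.43
    specimens_per_treatment: object = ("poisson", 21.5)  # drawn value + 1
    citations_per_treatment: object = ("poisson", 2.0)  # clamped to [1, specimens]
    sex_split: tuple = (0.515, 0.407, 0.078)
    countries: list = field(default_factory=lambda: list(DEFAULT_COUNTRIES))
    collections: list = field(default_factory=lambda: list(DEFAULT_COLLECTIONS))
    collectors: list = field(default_factory=lambda: list(DEFAULT_COLLECTORS))
    families: list = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    ambiguity_rate: float = 0.05  # citations listing several collections, counts on the event
    team_rate: float = 0.30
    team_size: object = ("empirical", [2, 2, 2, 3])
    year_range: tuple = (2002, 2014)
    elevation_range: tuple = (100, 4500)
    lag_mean_years: float = 17.0  # geometric collection-to-description delay
    exact_totals: Optional[ExactTotals] = None
    focal_species: Optional[FocalSpecies] = None

    def __post_init__(self) -> None:
        for name in ("species_rank_fraction", "citing_fraction", "new_species_fraction",
                     "ambiguity_rate", "team_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.sex_split) - 1.0) > 1e-9:
            raise ConfigError(f"sex_split must sum to 1, got {self.sex_split}")
        for rate in self.missing_rates.values():
            if not 0 <= rate <= 1:
                raise ConfigError(f"missing rate {rate} outside [0, 1]")


def config_from_dict(data: dict) -> GeneratorConfig:
    """Build a config from a plain (YAML/JSON-loaded) mapping."""
    data = dict(data)
    if "exact_totals" in data and isinstance(data["exact_totals"], dict):
        et = dict(data["exact_totals"])
        if et.get("sex_totals") is not None:
            et["sex_totals"] = tuple(et["sex_totals"])
        data["exact_totals"] = ExactTotals(**et)
    if "focal_species" in data and isinstance(data["focal_species"], dict):
        data["focal_species"] = FocalSpecies(**data["focal_species"])
    for key in ("treatments_per_article", "specimens_per_treatment",
                "citations_per_treatment", "team_size"):
        if isinstance(data.get(key), list):
            data[key] = tuple(data[key]) if data[key] and data[key][0] in ("poisson", "empirical", "fixed") else ("empirical", data[key])
    for key in ("sex_split", "year_range", "elevation_range"):
        if isinstance(data.get(key), list):
            data[key] = tuple(data[key])
    for key in ("countries", "collections", "collectors", "families"):
        if key in data:
            data[key] = [tuple(item) if isinstance(item, (list, tuple)) else (item, 1.0) for item in data[key]]
    return GeneratorConfig(**data)


# ---------------------------------------------------------------------------
# randomness helpers


def _draw(rng: np.random.Generator, spec, minimum: int = 0) -> int:
    if isinstance(spec, int):
        value = spec
    elif isinstance(spec, (tuple, list)) and spec and spec[0] == "fixed":
        value = int(spec[1])
    elif isinstance(spec, (tuple, list)) and spec and spec[0] == "poisson":
        value = int(rng.poisson(spec[1]))
    elif isinstance(spec, (tuple, list)) and spec and spec[0] == "empirical":
        value = int(rng.choice(spec[1]))
    else:
        raise ConfigError(f"bad distribution spec: {spec!r}")
    return max(minimum, value)


def _compose(rng: np.random.Generator, total: int, n: int, minimum: int = 0) -> list:
    """Random composition of ``total`` into ``n`` parts, each >= ``minimum``."""
    if n == 0:
        if total != 0:
            raise ConfigError(f"cannot place {total} items into 0 slots")
        return []
    extra = total - n * minimum
    if extra < 0:
        raise ConfigError(f"cannot split {total} into {n} parts of at least {minimum}")
    parts = rng.multinomial(extra, [1.0 / n] * n)
    return [int(p) + minimum for p in parts]


def _weighted_pool(pool: list) -> tuple:
    names = [name for name, _ in pool]
    weights = np.array([w for _, w in pool], dtype=float)
    return names, weights / weights.sum()


def _pick(rng: np.random.Generator, names: list, probs: np.ndarray) -> str:
    return names[int(rng.choice(len(names), p=probs))]


# ---------------------------------------------------------------------------
# planning


@dataclass
class _TreatmentPlan:
    rank: Rank = Rank.SPECIES
    citing: bool = False
    is_new: bool = False
    focal: bool = False
    singleton: bool = False
    # True: all citations share one locality; False: force >= 2 distinct;
    # None: unconstrained
    single_locality: Optional[bool] = None
    specimens: int = 0
    n_citations: int = 0
    citation_sizes: list = field(default_factory=list)
    females: Optional[int] = None  # pinned female count (focal treatments)


def _plan_exact(config: GeneratorConfig, rng: np.random.Generator) -> list:
    et = config.exact_totals
    focal = config.focal_species
    n_art = et.articles
    if n_art == 0:
        if et.treatments:
            raise ConfigError("treatments > 0 with 0 articles")
        return []
    minimum = 1 if et.treatments >= n_art else 0
    t_per_article = _compose(rng, et.treatments, n_art, minimum=minimum)

    slots = [(a, t) for a, n in enumerate(t_per_article) for t in range(n)]
    n_total = len(slots)
    if et.species_treatments > n_total:
        raise ConfigError("more species treatments than treatments")

    plans = {slot: _TreatmentPlan(rank=Rank.OTHER_HIGHER) for slot in slots}

    # focal slots: one species-rank treatment in each of n_articles distinct articles
    focal_slots: list = []
    if focal is not None:
        eligible = [a for a, n in enumerate(t_per_article) if n > 0]
        if focal.n_articles > len(eligible):
            raise ConfigError("focal species needs more articles than have treatments")
        chosen = rng.choice(len(eligible), size=focal.n_articles, replace=False)
        focal_slots = [(eligible[int(a)], 0) for a in chosen]
        for slot in focal_slots:
            plans[slot].rank = Rank.SPECIES
            plans[slot].focal = True
            plans[slot].citing = True

    # species-rank designation
    remaining_slots = [s for s in slots if not plans[s].focal]
    n_more_species = et.species_treatments - len(focal_slots)
    if n_more_species < 0:
        raise ConfigError("focal articles exceed species treatment count")
    idx = rng.choice(len(remaining_slots), size=n_more_species, replace=False)
    species_slots = [remaining_slots[int(i)] for i in idx]
    for slot in species_slots:
        plans[slot].rank = Rank.SPECIES
    for slot in slots:
        if plans[slot].rank is not Rank.SPECIES:
            plans[slot].rank = Rank(
                rng.choice([Rank.GENUS.value, Rank.FAMILY.value, Rank.SPECIES_GROUP.value])
            )

    # citing / new / singleton designation
    n_citing = et.citing_species_treatments
    if n_citing is None:
        n_citing = et.species_treatments
    n_more_citing = n_citing - len(focal_slots)
    if not 0 <= n_more_citing <= len(species_slots):
        raise ConfigError("citing_species_treatments out of range")
    idx = rng.choice(len(species_slots), size=n_more_citing, replace=False)
    citing_slots = [species_slots[int(i)] for i in idx]
    for slot in citing_slots:
        plans[slot].citing = True

    if et.new_species > len(citing_slots):
        raise ConfigError("new species must cite specimens; too few citing treatments")
    idx = rng.choice(len(citing_slots), size=et.new_species, replace=False)
    new_slots = [citing_slots[int(i)] for i in idx]
    for slot in new_slots:
        plans[slot].is_new = True

    n_single_citing = et.singletons_citing if et.singletons_citing is not None else et.singletons_new
    if et.singletons_new > et.new_species or et.singletons_new > n_single_citing:
        raise ConfigError("singleton counts inconsistent")
    idx = rng.choice(len(new_slots), size=et.singletons_new, replace=False)
    singleton_slots = [new_slots[int(i)] for i in idx]
    old_citing = [s for s in citing_slots if not plans[s].is_new]
    n_extra_singletons = n_single_citing - et.singletons_new
    if n_extra_singletons > len(old_citing):
        raise ConfigError("not enough non-new citing treatments for singletons")
    idx = rng.choice(len(old_citing), size=n_extra_singletons, replace=False)
    singleton_slots += [old_citing[int(i)] for i in idx]
    for slot in singleton_slots:
        plans[slot].singleton = True

    # single-locality designation among new species
    if et.single_locality_new is not None:
        if et.single_locality_new < et.singletons_new:
            raise ConfigError("single-locality count below singleton count (singletons are single-locality)")
        single_new = [s for s in new_slots if plans[s].singleton]
        multi_candidates = [s for s in new_slots if not plans[s].singleton]
        n_extra = et.single_locality_new - len(single_new)
        if n_extra > len(multi_candidates):
            raise ConfigError("single_locality_new exceeds new species count")
        idx = rng.choice(len(multi_candidates), size=n_extra, replace=False)
        extra = {multi_candidates[int(i)] for i in idx}
        for slot in new_slots:
            plans[slot].single_locality = plans[slot].singleton or slot in extra

    # specimen totals
    all_citing = focal_slots + citing_slots
    for slot in singleton_slots:
        plans[slot].specimens = 1
    if focal is not None:
        if focal.specimens < 2 * len(focal_slots):
            raise ConfigError("focal species needs >= 2 specimens per treatment")
        for slot, count in zip(focal_slots, _compose(rng, focal.specimens, len(focal_slots), minimum=2)):
            plans[slot].specimens = count
    plain = [s for s in all_citing if not (plans[s].singleton or plans[s].focal)]
    focal_specimens = focal.specimens if focal else 0
    rest = et.species_specimens - len(singleton_slots) - focal_specimens
    for slot, count in zip(plain, _compose(rng, rest, len(plain), minimum=2)):
        plans[slot].specimens = count

    # citation counts
    min_c = {}
    for slot in all_citing:
        p = plans[slot]
        min_c[slot] = 2 if p.single_locality is False else 1
    if et.citations is None:
        for slot in all_citing:
            p = plans[slot]
            p.n_citations = max(
                min_c[slot], min(p.specimens, _draw(rng, config.citations_per_treatment, minimum=1))
            )
    else:
        base = sum(min_c.values())
        capacity = {slot: plans[slot].specimens - min_c[slot] for slot in all_citing}
        remaining = et.citations - base
        if remaining < 0 or remaining > sum(capacity.values()):
            raise ConfigError(
                f"citations={et.citations} unsatisfiable (needs {base}..{base + sum(capacity.values())})"
            )
        expanded = [slot for slot in all_citing for _ in range(capacity[slot])]
        chosen = rng.choice(len(expanded), size=remaining, replace=False)
        extra_counts: dict = {}
        for i in chosen:
            slot = expanded[int(i)]
            extra_counts[slot] = extra_counts.get(slot, 0) + 1
        for slot in all_citing:
            plans[slot].n_citations = min_c[slot] + extra_counts.get(slot, 0)
    for slot in all_citing:
        p = plans[slot]
        p.citation_sizes = _compose(rng, p.specimens, p.n_citations, minimum=1)

    if focal is not None:
        _assign_focal_females(rng, focal, [plans[s] for s in focal_slots])

    return _group_plans(plans, t_per_article)


def _assign_focal_females(rng: np.random.Generator, focal: FocalSpecies, focal_plans: list) -> None:
    """Pin the focal species' female total across its treatments."""
    sizes = [p.specimens for p in focal_plans]
    if not 0 <= focal.females <= sum(sizes):
        raise ConfigError("focal female count exceeds focal specimen count")
    quota = rng.multivariate_hypergeometric(sizes, focal.females)
    for p, f in zip(focal_plans, quota):
        p.females = int(f)


def _plan_free(config: GeneratorConfig, rng: np.random.Generator) -> list:
    n_art = config.n_articles
    t_per_article = [_draw(rng, config.treatments_per_article, minimum=1) for _ in range(n_art)]
    plans: dict = {}
    focal = config.focal_species
    focal_articles = set(range(min(focal.n_articles, n_art))) if focal else set()
    focal_sizes = (
        _compose(rng, focal.specimens, len(focal_articles), minimum=2) if focal_articles else []
    )
    focal_plans: list = []
    for a in range(n_art):
        for t in range(t_per_article[a]):
            p = _TreatmentPlan()
            if focal and a in focal_articles and t == 0:
                p.rank = Rank.SPECIES
                p.focal = True
                p.citing = True
                p.specimens = focal_sizes[sorted(focal_articles).index(a)]
                focal_plans.append(p)
            elif rng.random() < config.species_rank_fraction:
                p.rank = Rank.SPECIES
                p.citing = rng.random() < config.citing_fraction
                if p.citing:
                    p.is_new = rng.random() < config.new_species_fraction
                    p.specimens = _draw(rng, config.specimens_per_treatment) + 1
            else:
                p.rank = Rank(
                    rng.choice([Rank.GENUS.value, Rank.FAMILY.value, Rank.SPECIES_GROUP.value])
                )
                if rng.random() < 0.1:  # occasional genus-only specimen records
                    p.citing = True
                    p.specimens = _draw(rng, ("poisson", 2.0)) + 1
            if p.citing:
                p.singleton = p.specimens == 1
                p.n_citations = max(1, min(p.specimens, _draw(rng, config.citations_per_treatment)))
                p.citation_sizes = _compose(rng, p.specimens, p.n_citations, minimum=1)
            plans[(a, t)] = p
    if focal_plans:
        _assign_focal_females(rng, focal, focal_plans)
    return _group_plans(plans, t_per_article)


def _group_plans(plans: dict, t_per_article: list) -> list:
    return [
        [plans[(a, t)] for t in range(n)]
        for a, n in enumerate(t_per_article)
    ]


# ---------------------------------------------------------------------------
# materialization


def generate(config: GeneratorConfig) -> tuple:
    """Generate ``(Corpus, GroundTruth)`` deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    article_plans = _plan_exact(config, rng) if config.exact_totals else _plan_free(config, rng)
    corpus, intended = _materialize(config, rng, article_plans)
    truth = ground_truth(corpus)
    truth.intended = intended
    return corpus, truth


def _materialize(config: GeneratorConfig, rng: np.random.Generator, article_plans: list) -> tuple:
    countries, p_country = _weighted_pool(config.countries)
    collections, p_coll = _weighted_pool(config.collections)
    collectors, p_collector = _weighted_pool(config.collectors)
    families, p_family = _weighted_pool(config.families)
    focal = config.focal_species
    et = config.exact_totals
    rates = config.missing_rates

    n_citations_total = sum(p.n_citations for plans in article_plans for p in plans)
    coded_indices: Optional[set] = None
    if et is not None and et.coded_citations is not None:
        if et.coded_citations > n_citations_total:
            raise ConfigError("coded_citations exceeds total citations")
        chosen = rng.choice(n_citations_total, size=et.coded_citations, replace=False)
        coded_indices = {int(i) for i in chosen}

    # remaining sex pools for exact totals (focal females carved out first)
    sex_pool = None
    if et is not None and et.sex_totals is not None:
        males, females, other = et.sex_totals
        if males + females + other != et.species_specimens:
            raise ConfigError("sex_totals must sum to species_specimens")
        sex_pool = [males, females, other]
        if focal is not None:
            sex_pool = [males - (focal.specimens - focal.females), females - focal.females, other]
            if min(sex_pool) < 0:
                raise ConfigError("focal species sex demand exceeds sex_totals")

    corpus = Corpus()
    intended = {
        "seed": config.seed,
        "singleton_treatments": [],
        "single_locality_treatments": [],
        "new_species_treatments": [],
        "lags": {},
        "focal_treatments": [],
    }
    species_counter = 0
    citation_counter = 0
    code_counter = 0

    for a_idx, plans in enumerate(article_plans):
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        n_authors = int(rng.integers(1, 4))
        author_idx = rng.choice(len(DEFAULT_AUTHORS), size=n_authors, replace=False)
        article = ArticleRecord(
            article_id=f"{config.article_id_prefix}{a_idx:04d}",
            journal=config.journal,
            year=year,
            authors=[DEFAULT_AUTHORS[int(i)] for i in author_idx],
            doi=f"10.5281/synth.{config.seed}.{a_idx}" if rng.random() < 0.8 else None,
            page_count=int(rng.integers(4, 80)),
        )
        for t_idx, plan in enumerate(plans):
            tid = f"{article.article_id}-t{t_idx:03d}"
            family = _pick(rng, families, p_family)
            genus = DEFAULT_GENERA[int(rng.choice(len(DEFAULT_GENERA)))]
            if plan.focal:
                family, genus = focal.family, focal.genus
                epithet = focal.species
            else:
                species_counter += 1
                epithet = f"synthetica{species_counter:04d}"
            epithets = {"orderEpithet": "Araneae", "familyEpithet": family}
            if plan.rank in (Rank.SPECIES, Rank.SPECIES_GROUP, Rank.GENUS):
                epithets["genusEpithet"] = genus
            if plan.rank is Rank.SPECIES:
                epithets["speciesEpithet"] = epithet
            if plan.rank is Rank.FAMILY:
                epithets.pop("familyEpithet", None)
                epithets["familyEpithet"] = family
            status_raw = None
            if plan.is_new:
                status_raw = "sp. nov."
            elif plan.rank is Rank.SPECIES and rng.random() < 0.08:
                status_raw = "comb. nov."
            elif plan.rank is Rank.GENUS and rng.random() < 0.1:
                status_raw = "gen. nov."
            treatment = TreatmentRecord(
                treatment_id=tid,
                taxon=TaxonName.make(plan.rank, authority=None, **epithets),
                status=TreatmentStatus.from_raw(status_raw),
            )

            # collecting-event backbone
            lag = None
            earliest_year = None
            if plan.is_new:
                p_geom = 1.0 / (1.0 + config.lag_mean_years)
                lag = int(rng.geometric(p_geom)) - 1
                lag = min(lag, year - 1751)
                earliest_year = year - lag
                intended["lags"][tid] = lag
                intended["new_species_treatments"].append(tid)
            if plan.focal:
                intended["focal_treatments"].append(tid)
            if plan.singleton:
                intended["singleton_treatments"].append(tid)
            if plan.single_locality is True:
                intended["single_locality_treatments"].append(tid)

            shared_country = _pick(rng, countries, p_country)
            shared_locality = f"{shared_country} site {int(rng.integers(1, 7))}"
            force_locality = plan.single_locality is not None

            focal_female_quota: list = []
            if plan.focal:
                focal_female_quota = [
                    int(f)
                    for f in rng.multivariate_hypergeometric(plan.citation_sizes, plan.females)
                ]

            for c_idx, size in enumerate(plan.citation_sizes):
                cit = MaterialsCitation()
                # --- sex counts
                if plan.focal:
                    f = focal_female_quota[c_idx]
                    cit.counts = CountTriple.of(size - f, f, 0)
                elif sex_pool is not None:
                    draw = rng.multivariate_hypergeometric(sex_pool, size)
                    sex_pool[0] -= int(draw[0]); sex_pool[1] -= int(draw[1]); sex_pool[2] -= int(draw[2])
                    cit.counts = CountTriple.of(int(draw[0]), int(draw[1]), int(draw[2]))
                elif plan.rank is Rank.SPECIES:
                    draw = rng.multinomial(size, list(config.sex_split))
                    cit.counts = CountTriple.of(int(draw[0]), int(draw[1]), int(draw[2]))
                else:
                    cit.counts = CountTriple.of(other=size)  # genus-only lots: unsexed
                # --- event fields
                if plan.is_new:
                    cyear = earliest_year if c_idx == 0 else int(rng.integers(earliest_year, year + 1))
                else:
                    cyear = int(rng.integers(max(1751, year - 30), year + 1))
                if rng.random() >= rates.get("date", 0):
                    month = int(rng.integers(1, 13)) if rng.random() < 0.85 else None
                    day = int(rng.integers(1, 29)) if month and rng.random() < 0.6 else None
                    cit.event_date = PartialDate(cyear, month, day)
                if rng.random() >= rates.get("country", 0):
                    cit.country = shared_country if force_locality else _pick(rng, countries, p_country)
                locality_due = force_locality or rng.random() >= rates.get("locality", 0)
                if locality_due:
                    if plan.single_locality is True:
                        cit.locality = shared_locality
                    elif plan.single_locality is False and c_idx < 2:
                        cit.locality = f"{cit.country or shared_country} site F{c_idx}"
                    else:
                        cit.locality = f"{cit.country or shared_country} site {int(rng.integers(1, 7))}"
                if rng.random() >= rates.get("elevation", 0):
                    cit.elevation_m = float(
                        rng.integers(config.elevation_range[0], config.elevation_range[1] + 1)
                    )
                if rng.random() >= rates.get("collector", 0):
                    if rng.random() < config.team_rate:
                        k = min(_draw(rng, config.team_size, minimum=2), len(collectors))
                        members = rng.choice(len(collectors), size=k, replace=False, p=p_collector)
                        cit.collector_raw = " & ".join(collectors[int(i)] for i in members)
                    else:
                        cit.collector_raw = _pick(rng, collectors, p_collector)
                    cit.collector_team = split_collectors(cit.collector_raw)
                # --- depository
                u = rng.random()
                if u < rates.get("collection", 0):
                    cit.collection_codes = []
                elif u < rates.get("collection", 0) + config.ambiguity_rate:
                    k = int(rng.integers(2, 6))
                    chosen = rng.choice(len(collections), size=min(k, len(collections)), replace=False)
                    cit.collection_codes = [collections[int(i)] for i in chosen]
                else:
                    cit.collection_codes = [_pick(rng, collections, p_coll)]
                # --- type status
                if plan.is_new:
                    if c_idx == 0:
                        cit.type_status = TypeStatus.HOLOTYPE
                    elif rng.random() < 0.6:
                        cit.type_status = TypeStatus.PARATYPE
                # --- specimen codes
                coded = (
                    citation_counter in coded_indices
                    if coded_indices is not None
                    else rng.random() >= rates.get("specimen_code", 0)
                )
                if coded:
                    code_counter += 1
                    prefix = cit.collection_codes[0] if cit.collection_codes else "LOT"
                    cit.specimen_codes = [f"{prefix}-{code_counter:05d}"]
                citation_counter += 1
                treatment.citations.append(cit)
            article.treatments.append(treatment)
        corpus.articles.append(article)
    if sex_pool is not None and any(sex_pool):
        raise ConfigError(f"sex totals not exhausted: {sex_pool} left over")
    return corpus, intended


# ---------------------------------------------------------------------------
# ground truth: an independent brute-force counting path
#
# Everything below recomputes, with plain nested loops and dictionaries,
# the quantities the facet engine and stats module are supposed to
# produce.  It deliberately shares no code with those modules.


@dataclass
class GroundTruth:
    """Expected outputs recorded for a generated corpus.

    ``facet_tables[facet][label] = (specimens, treatments, articles)``;
    ``collector_tables[mode]`` likewise over individual (or verbatim)
    collectors.  ``summary``/``rarity``/``lag`` are plain dicts of the
    headline numbers.  ``intended`` preserves the generator's
    designations (which treatments it made singletons, the lag it drew
    per new species) for parameter-recovery checks.
    """

    facet_tables: dict = field(default_factory=dict)
    collector_tables: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    rarity: dict = field(default_factory=dict)
    lag_records: dict = field(default_factory=dict)
    lag_summary: dict = field(default_factory=dict)
    intended: dict = field(default_factory=dict)


TRUTH_FACETS = (
    "doc.journal",
    "doc.year",
    "tax.rank",
    "tax.status",
    "tax.familyEpithet",
    "mat.country",
    "mat.collectionCode",
    "mat.collectorName",
    "mat.typeStatus",
    "mat.month",
    "mat.decade",
    "mat.elevationBand",
)

_PRIMARY = {"holotype", "syntype", "lectotype", "neotype"}


def _band_label(elevation: float) -> str:
    upper = 500 * max(1, int(math.ceil(elevation / 500.0)))
    return f"{upper - 499:,}–{upper:,}"


def _truth_labels(article, treatment, citation, facet: str) -> tuple:
    """(specimen label, presence labels) for one citation, naive version."""
    m = "missing"
    if facet == "doc.journal":
        v = [article.journal]
    elif facet == "doc.year":
        v = [str(article.year)]
    elif facet == "tax.rank":
        v = [treatment.taxon.rank.value]
    elif facet == "tax.status":
        s = treatment.status
        v = ["new-species" if s.is_new_species
             else "new-combination" if s.is_new_combination
             else "new-higher-taxon" if s.is_new_higher_taxon
             else "none"]
    elif facet == "tax.familyEpithet":
        fam = treatment.taxon.epithet("familyEpithet")
        v = [fam] if fam else [m]
    elif facet == "mat.country":
        v = [citation.country] if citation.country else [m]
    elif facet == "mat.collectionCode":
        codes = citation.collection_codes
        spec = codes[0] if len(codes) == 1 else m
        return spec, list(codes) if codes else [m]
    elif facet == "mat.collectorName":
        v = [citation.collector_raw] if citation.collector_raw else [m]
    elif facet == "mat.typeStatus":
        ts = citation.type_status.value
        v = [ts] if ts != "none" else [m]
    elif facet == "mat.month":
        d = citation.event_date
        v = [str(d.month)] if d and d.month else [m]
    elif facet == "mat.decade":
        d = citation.event_date
        v = [f"{(d.year // 10) * 10}s"] if d else [m]
    elif facet == "mat.elevationBand":
        e = citation.elevation_m
        v = [_band_label(e)] if e is not None else [m]
    else:
        raise ValueError(facet)
    return v[0], v


def _truth_facet_tables(corpus: Corpus) -> dict:
    tables = {}
    for facet in TRUTH_FACETS:
        spec: dict = {}
        treat: dict = {}
        art: dict = {}
        for article in corpus.articles:
            for treatment in article.treatments:
                for citation in treatment.citations:
                    slabel, plabels = _truth_labels(article, treatment, citation, facet)
                    spec[slabel] = spec.get(slabel, 0) + citation.counts.total
                    for label in plabels:
                        treat.setdefault(label, set()).add(treatment.treatment_id)
                        art.setdefault(label, set()).add(article.article_id)
        tables[facet] = {
            label: (spec.get(label, 0), len(treat.get(label, ())), len(art.get(label, ())))
            for label in set(spec) | set(treat)
        }
    return tables


def _truth_collectors(corpus: Corpus) -> dict:
    tables = {}
    for mode in ("raw", "fractional", "full_credit"):
        spec: dict = {}
        treat: dict = {}
        art: dict = {}
        for article in corpus.articles:
            for treatment in article.treatments:
                for citation in treatment.citations:
                    total = citation.counts.total
                    if not citation.collector_raw:
                        shares = [("missing", float(total))]
                    elif mode == "raw":
                        shares = [(citation.collector_raw, float(total))]
                    else:
                        team = citation.collector_team or [citation.collector_raw]
                        each = total / len(team) if mode == "fractional" else float(total)
                        shares = [(name, each) for name in team]
                    for name, amount in shares:
                        spec[name] = spec.get(name, 0.0) + amount
                        treat.setdefault(name, set()).add(treatment.treatment_id)
                        art.setdefault(name, set()).add(article.article_id)
        tables[mode] = {
            name: (spec[name], len(treat[name]), len(art[name])) for name in spec
        }
    return tables


def _truth_summary(corpus: Corpus) -> dict:
    s = {
        "n_articles": len(corpus.articles),
        "n_treatments": 0,
        "n_species_treatments": 0,
        "n_citing_species_treatments": 0,
        "n_specimens": 0,
        "n_species_specimens": 0,
        "n_new_species": 0,
        "n_citations": 0,
        "n_coded_citations": 0,
        "males": 0,
        "females": 0,
        "other": 0,
    }
    for article in corpus.articles:
        for treatment in article.treatments:
            s["n_treatments"] += 1
            total = sum(c.counts.total for c in treatment.citations)
            s["n_specimens"] += total
            s["n_citations"] += len(treatment.citations)
            s["n_coded_citations"] += sum(1 for c in treatment.citations if c.specimen_codes)
            if treatment.taxon.rank.value == "species":
                s["n_species_treatments"] += 1
                s["n_species_specimens"] += total
                if treatment.citations:
                    s["n_citing_species_treatments"] += 1
                if treatment.status.is_new_species:
                    s["n_new_species"] += 1
                for c in treatment.citations:
                    s["males"] += c.counts.males
                    s["females"] += c.counts.females
                    s["other"] += c.counts.other
    return s


def _truth_rarity(corpus: Corpus) -> dict:
    r = {
        "n_new_species": 0,
        "n_singletons": 0,
        "n_single_collection": 0,
        "n_single_locality": 0,
        "n_citing_species_treatments": 0,
        "n_singleton_citing": 0,
    }
    for article in corpus.articles:
        for treatment in article.treatments:
            if treatment.taxon.rank.value != "species":
                continue
            total = sum(c.counts.total for c in treatment.citations)
            if treatment.citations:
                r["n_citing_species_treatments"] += 1
                if total == 1:
                    r["n_singleton_citing"] += 1
            if not treatment.status.is_new_species:
                continue
            r["n_new_species"] += 1
            if total == 1:
                r["n_singletons"] += 1
            events = set()
            localities = set()
            for c in treatment.citations:
                loc = c.locality.strip().casefold() if c.locality else None
                date = c.event_date.isoformat() if c.event_date else None
                who = c.collector_raw.strip().casefold() if c.collector_raw else None
                events.add((loc, date, who))
                if loc:
                    localities.add(loc)
            if len(events) == 1:
                r["n_single_collection"] += 1
            if len(localities) == 1:
                r["n_single_locality"] += 1
    return r


def _truth_lag(corpus: Corpus) -> tuple:
    lags = {}
    excluded = 0
    for article in corpus.articles:
        for treatment in article.treatments:
            if not (treatment.taxon.rank.value == "species" and treatment.status.is_new_species):
                continue
            years = [c.event_date.year for c in treatment.citations if c.event_date]
            if years and min(years) <= article.year:
                lags[treatment.treatment_id] = article.year - min(years)
            else:
                excluded += 1
    values = sorted(lags.values())
    summary = {"n": len(values), "n_excluded_missing_dates": excluded}
    if values:
        n = len(values)
        mean = sum(values) / n
        summary["mean"] = mean
        summary["median"] = statistics.median(values)
        summary["min"] = values[0]
        summary["max"] = values[-1]
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            summary["standard_error"] = sd / math.sqrt(n)
    return lags, summary


def ground_truth(corpus: Corpus) -> GroundTruth:
    """Brute-force expected outputs for a corpus (the generator's oracle)."""
    lags, lag_summary = _truth_lag(corpus)
    return GroundTruth(
        facet_tables=_truth_facet_tables(corpus),
        collector_tables=_truth_collectors(corpus),
        summary=_truth_summary(corpus),
        rarity=_truth_rarity(corpus),
        lag_records=lags,
        lag_summary=lag_summary,
    )


# ---------------------------------------------------------------------------
# fixtures


def fig12_fixture() -> Corpus:
    """The classic ambiguous materials citation: one lot of 110 males and
    44 females tied to a single collecting event but distributed, in
    unknown proportion, among five institutional collections."""
    citation = MaterialsCitation(
        counts=CountTriple(110, 44, 0, 154),
        type_status=TypeStatus.PARATYPE,
        collection_codes=["IBPN", "ISEA", "ZMMU", "ZMHU", "NHRS"],
        country="Mongolia",
        locality="Uvs Nuur basin",
        event_date=PartialDate(1991, 7),
        collector_raw="Y. M. Marusik",
        collector_team=["Y. M. Marusik"],
    )
    treatment = TreatmentRecord(
        treatment_id="amb-t001",
        taxon=TaxonName.make(
            Rank.SPECIES,
            orderEpithet="Araneae",
            familyEpithet="Lycosidae",
            genusEpithet="Pardosa",
            speciesEpithet="zyuzini",
        ),
        status=TreatmentStatus.from_raw("sp. nov."),
        citations=[citation],
    )
    article = ArticleRecord(
        article_id="amb-art",
        journal="Zootaxa",
        year=2011,
        authors=["T. Kronestedt", "Y. M. Marusik"],
        treatments=[treatment],
    )
    return Corpus(articles=[article])


# ---------------------------------------------------------------------------
# study-corpus profiles
#
# Exact-totals configurations matching the published headline counts of
# the two spider-literature corpora this toolkit models: 37 open-access
# Zootaxa articles (legacy markup) and 5 Biodiversity Data Journal
# articles (prospective markup).  Everything below the pinned totals
# (which treatment sits in which article, field values, missingness) is
# drawn from the seed.


def zootaxa_spiders_config(seed: int = 0) -> GeneratorConfig:
    """37 articles, 254 treatments (212 species rank, all citing),
    4,773 specimens (2,460 M / 1,943 F / 370 other), 91 new species of
    which 34 singletons (72 singletons overall) and 35 single-locality,
    1,447 citations of which 572 carry specimen codes."""
    return GeneratorConfig(
        seed=seed,
        journal="Zootaxa",
        article_id_prefix="zt",
        year_range=(2002, 2014),
        exact_totals=ExactTotals(
            articles=37,
            treatments=254,
            species_treatments=212,
            species_specimens=4773,
            citing_species_treatments=212,
            new_species=91,
            singletons_new=34,
            singletons_citing=72,
            single_locality_new=35,
            sex_totals=(2460, 1943, 370),
            citations=1447,
            coded_citations=572,
        ),
    )


def bdj_spiders_config(seed: int = 0) -> GeneratorConfig:
    """5 articles, 742 treatments (672 species rank, 496 citing
    specimens), 3,399 specimens, 1 new species, 209 singleton
    treatments, and one species recurring across 3 articles with 352
    specimens of which 223 female; 1,447 citations, 572 with codes."""
    return GeneratorConfig(
        seed=seed,
        journal="Biodiversity Data Journal",
        article_id_prefix="bdj",
        year_range=(2013, 2014),
        exact_totals=ExactTotals(
            articles=5,
            treatments=742,
            species_treatments=672,
            species_specimens=3399,
            citing_species_treatments=496,
            new_species=1,
            singletons_new=0,
            singletons_citing=209,
            citations=1447,
            coded_citations=572,
        ),
        focal_species=FocalSpecies(
            genus="Tenuiphantes",
            species="tenuis",
            n_articles=3,
            specimens=352,
            females=223,
        ),
    )
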