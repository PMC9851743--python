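"""Representation quantities: proportions, dominance/ubiquity, income.

Weighting conventions
---------------------
Author-side proportions are computed per paper first: every author in
the requested authorship category (all / first / senior) carries the
same weight 1/|category|, and an author with k affiliations splits that
weight equally k ways across the affiliations' attribute values
(country, institution or income group).  Disease-area tables are then
the unweighted mean of the per-paper proportion maps over the papers in
the area, so each paper counts once regardless of its author count.

The *dominance score* of an institution is exactly this per-paper
weighted mean share with attribute = institution: how much of the
average paper's authorship the institution fields.  The *ubiquity
score* is the fraction of papers on which the institution appears at
all (at least one category author affiliated); it is a per-institution
frequency and deliberately not normalised across institutions.

Participant-side proportions (recruitment country, broad ancestry,
cohort income) are sample-size weighted: an entry of n individuals
listing m recruitment countries contributes n/m to each (equal-share
assumption for multi-country cohorts), entries marked Not Reported are
excluded before totals, and fractions are quotients against the total
included individuals.

UNRESOLVED affiliations are retained as their own category so every
table's fractions sum to one and data loss stays visible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from ._vocab import NOT_REPORTED, UNRESOLVED
from .catalog_io import AncestryEntry, Publication, assign_author_positions
from .errors import EmptyTableError

__all__ = [
    "RepresentationTable",
    "IncomeTable",
    "load_income_table",
    "classify_income",
    "paper_attribute_proportions",
    "aggregate_area_proportions",
    "dominance_scores",
    "ubiquity_scores",
    "recruitment_proportions",
    "ancestry_proportions",
    "top_categories",
    "write_tables_csv",
]

NOT_APPLICABLE = "none"


@dataclass
class RepresentationTable:
    attribute: str  # country|institution|gender|income|ancestry|recruitment_country
    disease_area: str
    author_category: str  # all|first|senior or NOT_APPLICABLE
    proportions: dict[str, float]
    n_basis: int  # papers (author side) or individuals (participant side)

    def check_sums(self, tol: float = 1e-9) -> bool:
        return abs(sum(self.proportions.values()) - 1.0) <= tol


@dataclass
class IncomeTable:
    """World Bank income-group classification snapshot (GNI per capita)."""

    groups: dict[str, str]
    snapshot_year: int = 2022


def load_income_table(path, snapshot_year: int = 2022) -> IncomeTable:
    groups = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            groups[row["country"]] = row["income_group"]
    return IncomeTable(groups, snapshot_year)


def classify_income(country: str, table: IncomeTable) -> str:
    """Deterministic country -> income-group lookup; UNRESOLVED propagates."""
    if country == UNRESOLVED:
        return UNRESOLVED
    return table.groups.get(country, UNRESOLVED)


def _attribute_value(affiliation, attribute: str, income: IncomeTable | None):
    if attribute == "country":
        return affiliation.country
    if attribute == "institution":
        return affiliation.institution
    if attribute == "income":
        if affiliation.income_group != UNRESOLVED or income is None:
            return affiliation.income_group
        return classify_income(affiliation.country, income)
    raise ValueError(f"unknown author attribute {attribute!r}")


def paper_attribute_proportions(pub: Publication, attribute: str,
                                author_category: str = "all",
                                income: IncomeTable | None = None
                                ) -> dict[str, float]:
    """Per-paper category -> fraction map under the two-level weighting.

    For ``attribute='gender'`` the map is over author labels and
    authors excluded from gender analysis (initials-only names) are
    removed from the denominator; for affiliation attributes an author
    with no affiliations contributes its whole weight to UNRESOLVED.
    """
    authors = assign_author_positions(pub)[author_category]
    if not authors:
        raise EmptyTableError(
            f"publication {pub.pmid}: no authors in category {author_category}"
        )
    acc: dict[str, float] = {}
    if attribute == "gender":
        included = [a for a in authors if a.gender != "excluded"]
        if not included:
            raise EmptyTableError(
                f"publication {pub.pmid}: no gender-eligible authors"
            )
        w = 1.0 / len(included)
        for a in included:
            acc[a.gender] = acc.get(a.gender, 0.0) + w
        return acc
    w = 1.0 / len(authors)
    for a in authors:
        if not a.affiliations:
            acc[UNRESOLVED] = acc.get(UNRESOLVED, 0.0) + w
            continue
        share = w / len(a.affiliations)
        for aff in a.affiliations:
            value = _attribute_value(aff, attribute, income)
            acc[value] = acc.get(value, 0.0) + share
    return acc


def aggregate_area_proportions(paper_maps: list[dict[str, float]],
                               attribute: str = "country",
                               disease_area: str = "all_traits",
                               author_category: str = "all"
                               ) -> RepresentationTable:
    """Unweighted mean of per-paper proportion maps over papers."""
    if not paper_maps:
        raise EmptyTableError("no papers to aggregate")
    acc: dict[str, float] = {}
    for pm in paper_maps:
        for cat, frac in pm.items():
            acc[cat] = acc.get(cat, 0.0) + frac
    n = len(paper_maps)
    for cat in acc:
        acc[cat] /= n
    return RepresentationTable(attribute, disease_area, author_category, acc, n)


def dominance_scores(corpus: list[Publication], author_category: str = "all",
                     disease_area: str = "all_traits") -> dict[str, float]:
    """Institution dominance: per-paper weighted mean share of authorships."""
    maps = [
        paper_attribute_proportions(p, "institution", author_category)
        for p in corpus
    ]
    return aggregate_area_proportions(
        maps, "institution", disease_area, author_category
    ).proportions


def ubiquity_scores(corpus: list[Publication], author_category: str = "all"
                    ) -> dict[str, float]:
    """Fraction of papers with at least one category author per institution."""
    if not corpus:
        raise EmptyTableError("no papers")
    counts: dict[str, int] = {}
    for pub in corpus:
        present: set[str] = set()
        for a in assign_author_positions(pub)[author_category]:
            for aff in a.affiliations:
                present.add(aff.institution)
        for inst in sorted(present):
            counts[inst] = counts.get(inst, 0) + 1
    n = len(corpus)
    return {inst: c / n for inst, c in counts.items()}


def _participant_proportions(entries: list[AncestryEntry], keyfunc,
                             attribute: str, disease_area: str,
                             stages: tuple[str, ...]) -> tuple[
                                 RepresentationTable, int]:
    acc: dict[str, float] = {}
    grand = 0
    excluded = 0
    for e in entries:
        if e.stage not in stages:
            continue
        keys = keyfunc(e)
        if keys is None:
            excluded += e.n_individuals
            continue
        grand += e.n_individuals
        contrib = e.n_individuals / len(keys)
        for k in keys:
            acc[k] = acc.get(k, 0.0) + contrib
    if grand == 0:
        raise EmptyTableError(
            f"all entries excluded (Not Reported) for {attribute}/{disease_area}"
        )
    props = {k: v / grand for k, v in acc.items()}
    table = RepresentationTable(
        attribute, disease_area, NOT_APPLICABLE, props, grand
    )
    return table, excluded


def recruitment_proportions(entries: list[AncestryEntry],
                            disease_area: str = "all_traits",
                            stages: tuple[str, ...] = ("discovery", "replication"),
                            ) -> tuple[RepresentationTable, int]:
    """Country-of-recruitment shares of total included individuals.

    Not Reported entries are excluded before totals (the excluded
    individual count is returned); an entry listing m countries splits
    its n individuals as n/m each.  Discovery and replication stages
    are both included by default; pass ``stages=('discovery',)`` for
    the discovery-only sensitivity analysis.
    """

    def key(e: AncestryEntry):
        if e.recruitment_countries == NOT_REPORTED:
            return None
        return e.recruitment_countries

    return _participant_proportions(
        entries, key, "recruitment_country", disease_area, stages
    )


def ancestry_proportions(entries: list[AncestryEntry],
                         disease_area: str = "all_traits",
                         stages: tuple[str, ...] = ("discovery", "replication"),
                         ) -> tuple[RepresentationTable, int]:
    """Broad-ancestral-category shares of total included individuals."""

    def key(e: AncestryEntry):
        if e.broad_ancestry == NOT_REPORTED:
            return None
        return [e.broad_ancestry]

    return _participant_proportions(
        entries, key, "ancestry", disease_area, stages
    )


def participant_income_proportions(entries: list[AncestryEntry],
                                   income: IncomeTable,
                                   disease_area: str = "all_traits",
                                   stages: tuple[str, ...] = (
                                       "discovery", "replication"),
                                   ) -> tuple[RepresentationTable, int]:
    """Income-group shares of included individuals via recruitment country."""

    def key(e: AncestryEntry):
        if e.recruitment_countries == NOT_REPORTED:
            return None
        return [classify_income(c, income) for c in e.recruitment_countries]

    table, excluded = _participant_proportions(
        entries, key, "income", disease_area, stages
    )
    return table, excluded


AUTHOR_ATTRIBUTES = ("country", "institution", "income", "gender")


def pooled_gender_table(pubs: list[Publication], disease_area: str,
                        author_category: str) -> RepresentationTable:
    """Gender proportions from pooled author counts (one head, one vote),
    the alternative to the default per-paper weighting."""
    counts: dict[str, int] = {}
    total = 0
    for pub in pubs:
        for a in assign_author_positions(pub)[author_category]:
            if a.gender == "excluded":
                continue
            counts[a.gender] = counts.get(a.gender, 0) + 1
            total += 1
    if total == 0:
        raise EmptyTableError(f"no gender-eligible authors in {disease_area}")
    props = {k: v / total for k, v in counts.items()}
    return RepresentationTable(
        "gender", disease_area, author_category, props, total
    )


def compute_corpus_tables(pubs_by_area: dict[str, list[Publication]],
                          income: IncomeTable,
                          gender_weighting: str = "per_paper",
                          author_categories=("all", "first", "senior"),
                          ) -> list[RepresentationTable]:
    """All author-side representation tables: every disease area x
    attribute x authorship category.  Papers with no gender-eligible
    authors are skipped for the gender attribute only."""
    tables = []
    for area in sorted(pubs_by_area):
        pubs = pubs_by_area[area]
        for attribute in AUTHOR_ATTRIBUTES:
            for category in author_categories:
                if attribute == "gender" and gender_weighting == "pooled":
                    try:
                        tables.append(pooled_gender_table(pubs, area, category))
                    except EmptyTableError:
                        pass
                    continue
                maps = []
                for p in pubs:
                    try:
                        maps.append(
                            paper_attribute_proportions(
                                p, attribute, category, income
                            )
                        )
                    except EmptyTableError:
                        continue
                if maps:
                    tables.append(
                        aggregate_area_proportions(maps, attribute, area, category)
                    )
    return tables


def compute_participant_tables(entries_by_area: dict[str, list[AncestryEntry]],
                               income: IncomeTable,
                               stages: tuple[str, ...] = (
                                   "discovery", "replication"),
                               ) -> tuple[list[RepresentationTable],
                                          dict[str, int]]:
    """Recruitment-country, ancestry and cohort-income tables per area,
    plus the Not-Reported individual counts excluded from each."""
    tables = []
    excluded: dict[str, int] = {}
    for area in sorted(entries_by_area):
        entries = entries_by_area[area]
        for fn, label in (
            (recruitment_proportions, "recruitment_country"),
            (ancestry_proportions, "ancestry"),
        ):
            try:
                t, ex = fn(entries, area, stages)
            except EmptyTableError:
                continue
            tables.append(t)
            excluded[f"{label}/{area}"] = ex
        try:
            t, ex = participant_income_proportions(entries, income, area, stages)
        except EmptyTableError:
            continue
        tables.append(t)
        excluded[f"income/{area}"] = ex
    return tables, excluded


def compute_ubiquity_tables(pubs_by_area: dict[str, list[Publication]],
                            author_categories=("all", "first", "senior"),
                            ) -> list[tuple[str, str, dict[str, float]]]:
    """(area, category, institution -> ubiquity score) for every stratum."""
    out = []
    for area in sorted(pubs_by_area):
        for category in author_categories:
            out.append(
                (area, category, ubiquity_scores(pubs_by_area[area], category))
            )
    return out


def write_ubiquity_csv(ubiquity, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["disease_area", "author_category", "institution", "score"])
        for area, category, scores in ubiquity:
            for inst in sorted(scores):
                w.writerow([area, category, inst, repr(scores[inst])])


def top_categories(proportions: dict[str, float], k: int = 10
                   ) -> list[tuple[str, float]]:
    """Top-k categories by score, ties broken alphabetically."""
    ranked = sorted(proportions.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def write_tables_csv(tables: list[RepresentationTable], path) -> None:
    """Tidy CSV: attribute, disease_area, author_category, category,
    proportion, n_basis — one row per category."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow([
            "attribute", "disease_area", "author_category",
            "category", "proportion", "n_basis",
        ])
        for t in tables:
            for cat in sorted(t.proportions):
                w.writerow([
                    t.attribute, t.disease_area, t.author_category,
                    cat, repr(t.proportions[cat]), t.n_basis,
                ])
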