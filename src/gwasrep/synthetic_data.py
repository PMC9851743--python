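"""Synthetic GWAS-catalog corpora with exact, realized ground truth.

The generator emits the two input formats the pipeline consumes — an
ancestry/sample table and publication metadata XML in both dialects —
from configurable mixtures: country and institution composition of
authorships, gender shares with per-category year trends, broad
ancestry and recruitment-country mixtures of the cohorts, Not-Reported
missingness, abbreviated-given-name papers, multi-affiliation and
joint-authorship rates.

Ground truth records the *realized* draws, not the nominal mixture
weights: alongside the input files it writes the exact representation
tables implied by what was actually drawn, so pipeline recovery can be
tested as strict equality rather than statistical closeness.  A
deliberately naive reference script (plain loops over the emitted
files, sharing no code with the pipeline) can recompute the same
tables; see the test suite.

All randomness flows from one root seed; each stage derives its own
stream as ``default_rng([seed, stream_index])`` so adding a stage never
perturbs the draws of another.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from ._vocab import ALL_TRAITS, DISEASE_AREAS, NOT_REPORTED
from .affiliation_extraction import Affiliation
from .catalog_io import (
    AncestryEntry,
    AncestryTable,
    Author,
    Publication,
    StudyRecord,
    assign_author_positions,
    write_ancestry_table,
    write_publication_xml,
)
from .errors import ConfigError
from .representation_stats import (
    IncomeTable,
    classify_income,
    compute_corpus_tables,
    compute_participant_tables,
    compute_ubiquity_tables,
    load_income_table,
    write_tables_csv,
    write_ubiquity_csv,
)

__all__ = [
    "CorpusConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_name_dictionary",
    "load_name_roster",
]

# Defaults emulate the published corpus conditions: authorship
# concentrated in the US/UK/China/Japan/Germany, recruitment led by the
# UK and Nordic countries, ~91% European-ancestry samples, ~10%
# Not-Reported missingness and ~3% of papers with initials-only names.
DEFAULT_COUNTRY_MIXTURE = {
    "United States": 0.37, "United Kingdom": 0.098, "China": 0.082,
    "Japan": 0.066, "Germany": 0.055, "Sweden": 0.05, "Netherlands": 0.04,
    "Australia": 0.04, "South Korea": 0.03, "France": 0.03, "Italy": 0.03,
    "Canada": 0.03, "Iceland": 0.02, "Spain": 0.02, "Finland": 0.015,
    "Denmark": 0.015, "Brazil": 0.004, "India": 0.002,
    "South Africa": 0.002, "Nigeria": 0.001,
}

DEFAULT_RECRUITMENT_MIXTURE = {
    "United Kingdom": 0.34, "United States": 0.16, "Iceland": 0.096,
    "Australia": 0.043, "Norway": 0.037, "Germany": 0.05,
    "Netherlands": 0.04, "Japan": 0.05, "Sweden": 0.04, "Finland": 0.03,
    "Denmark": 0.03, "China": 0.03, "South Korea": 0.02, "Italy": 0.02,
    "Spain": 0.014,
}

DEFAULT_ANCESTRY_MIXTURE = {
    "European": 0.91, "East Asian": 0.049,
    "African American or Afro-Caribbean": 0.012,
    "Hispanic or Latin American": 0.008, "South Asian": 0.008,
    "African unspecified": 0.005,
    "Greater Middle Eastern (Middle Eastern, North African or Persian)": 0.004,
    "Other admixed ancestry": 0.004,
}

# women share at window start and trend (percentage points per year)
DEFAULT_GENDER_START = {"all": 0.34, "first": 0.30, "senior": 0.25}
DEFAULT_GENDER_SLOPE_PP = {"all": 0.0, "first": 0.93, "senior": 0.85}

SURNAMES = (
    "Smith", "Johnson", "Brown", "Taylor", "Wilson", "Andersson",
    "Johansson", "Karlsson", "Tanaka", "Suzuki", "Sato", "Watanabe",
    "Wang", "Chen", "Zhang", "Liu", "Kim", "Park", "Lee", "Mueller",
    "Schmidt", "Fischer", "Weber", "Dubois", "Martin", "Rossi", "Ricci",
    "Garcia", "Martinez", "Silva", "Santos", "Patel", "Sharma",
    "Okafor", "Mensah", "Jonsdottir", "Sigurdsson", "Hansen", "Olsen",
    "Virtanen", "Korhonen", "Visser", "Bakker", "Novak", "Kowalski",
)

DEPARTMENTS = (
    "Department of Clinical Sciences", "Department of Epidemiology",
    "Department of Medical Genetics", "Department of Biostatistics",
    "Institute of Human Genetics", "Department of Public Health",
    "Centre for Genomic Medicine", "Department of Internal Medicine",
    "Division of Endocrinology", "Department of Neurology",
    "Department of Cardiology", "Unit of Molecular Epidemiology",
)


@dataclass
class CorpusConfig:
    """Study conditions for one synthetic corpus.

    Mixtures must sum to one (within 1e-9) and rates lie in [0, 1];
    identical config + seed gives byte-identical output files.
    """

    seed: int = 7
    years: tuple[int, int] = (2005, 2021)
    papers_per_year: int = 135
    country_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_MIXTURE))
    recruitment_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RECRUITMENT_MIXTURE))
    ancestry_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCESTRY_MIXTURE))
    gender_start: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENDER_START))
    gender_slope_pp: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENDER_SLOPE_PP))
    institutions_per_country: int = 2
    not_reported_rate: float = 0.10
    abbreviated_name_rate: float = 0.03
    multi_affiliation_rate: float = 0.20
    joint_authorship_rate: float = 0.10
    multi_country_rate: float = 0.20
    multi_area_rate: float = 0.10
    replication_rate: float = 0.50
    pre2014_rate: float = 1.0  # share of pre-2014 papers in legacy dialect
    # truncated negative-binomial author counts: min + NB(shape, p) with
    # p chosen so the mean is authors_mean, clipped at authors_max
    authors_mean: float = 12.0
    authors_shape: float = 2.0
    authors_min: int = 2
    authors_max: int = 40
    sample_log_mean: float = 8.0
    sample_log_sd: float = 1.0
    dict_conflict_rate: float = 0.03
    dict_unknown_rate: float = 0.04

    def validate(self) -> None:
        for name in ("country_mixture", "recruitment_mixture",
                     "ancestry_mixture"):
            mix = getattr(self, name)
            if not mix:
                raise ConfigError(f"{name} is empty")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} weights sum to {total!r}, not 1")
            if any(w < 0 for w in mix.values()):
                raise ConfigError(f"{name} has negative weights")
        for name in ("not_reported_rate", "abbreviated_name_rate",
                     "multi_affiliation_rate", "joint_authorship_rate",
                     "multi_country_rate", "multi_area_rate",
                     "replication_rate", "pre2014_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.years[0] > self.years[1]:
            raise ConfigError("years window inverted")


@dataclass
class GroundTruth:
    """Exact expected outputs implied by the realized draws."""

    tables: list  # RepresentationTable, same schema as the pipeline emits
    ubiquity: list  # (area, category, institution -> score)
    yearly_gender: dict  # category -> {year: (women, men+women)}
    counts: dict[str, int]
    publications: list[Publication]
    ancestry: AncestryTable
    name_truth: dict[str, str]


def load_name_roster() -> dict[str, list[str]]:
    """Bundled given-name roster keyed by gender (synthetic stand-in)."""
    roster: dict[str, list[str]] = {"men": [], "women": []}
    txt = (
        resources.files("gwasrep.data")
        .joinpath("given_names.synthetic.tsv")
        .read_text(encoding="utf-8")
    )
    for line in txt.splitlines()[1:]:
        name, gender = line.split("\t")
        roster[gender].append(name)
    return roster


def _load_institution_roster() -> dict[str, list[tuple[str, str]]]:
    """country -> [(institution, city), ...] from the bundled table."""
    roster: dict[str, list[tuple[str, str]]] = {}
    path = resources.files("gwasrep.data").joinpath("institutions.tsv")
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["alias"] != row["canonical"]:
                continue
            roster.setdefault(row["country"], []).append(
                (row["canonical"], row["city"])
            )
    return roster


def _load_efo_by_area() -> dict[str, list[str]]:
    by_area: dict[str, list[str]] = {}
    path = resources.files("gwasrep.data").joinpath(
        "disease_area_efo_map.synthetic.tsv"
    )
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            by_area.setdefault(row["disease_area"], []).append(row["efo_code"])
    # drop the deliberately shared comorbidity code from the draw pools so
    # a single code never implies two areas unless multi_area is drawn
    for area, codes in by_area.items():
        by_area[area] = [c for c in codes if c != "EFO:0101099"]
    return by_area


def _nb_author_count(rng, cfg: CorpusConfig) -> int:
    mean_excess = max(cfg.authors_mean - cfg.authors_min, 0.5)
    p = cfg.authors_shape / (cfg.authors_shape + mean_excess)
    n = cfg.authors_min + int(rng.negative_binomial(cfg.authors_shape, p))
    return min(n, cfg.authors_max)


def generate_name_dictionary(name_truth: dict[str, str], seed: int,
                             conflict_rate: float = 0.03,
                             unknown_rate: float = 0.04,
                             path_a=None, path_b=None):
    """Write two name-gender dictionary TSVs with controlled disagreement.

    For a ``conflict_rate`` share of names the two sources disagree and
    the wrong one gets strictly lower accuracy (so reconciliation
    recovers the truth); for an ``unknown_rate`` share one source
    returns unknown.  Source A is written on a 0-1 probability scale,
    source B on a 0-100 accuracy scale, to exercise rescaling.
    Returns realized counts {agree, conflict, unknown}.
    """
    rng = np.random.default_rng([seed, 1])
    rows_a, rows_b = [], []
    counts = {"agree": 0, "conflict": 0, "unknown": 0}
    flip = {"men": "women", "women": "men"}
    for name in sorted(name_truth):
        truth = name_truth[name]
        r = rng.random()
        acc_hi = round(rng.uniform(85.0, 99.0), 1)
        samples_a = int(rng.integers(500, 20000))
        samples_b = int(rng.integers(500, 20000))
        if r < conflict_rate:
            counts["conflict"] += 1
            acc_lo = round(rng.uniform(50.0, 80.0), 1)
            if rng.random() < 0.5:
                rows_a.append((name, flip[truth], acc_lo, samples_a))
                rows_b.append((name, truth, acc_hi, samples_b))
            else:
                rows_a.append((name, truth, acc_hi, samples_a))
                rows_b.append((name, flip[truth], acc_lo, samples_b))
        elif r < conflict_rate + unknown_rate:
            counts["unknown"] += 1
            if rng.random() < 0.5:
                rows_a.append((name, "unknown", 0.0, 0))
                rows_b.append((name, truth, acc_hi, samples_b))
            else:
                rows_a.append((name, truth, acc_hi, samples_a))
                rows_b.append((name, "unknown", 0.0, 0))
        else:
            counts["agree"] += 1
            acc2 = round(rng.uniform(85.0, 99.0), 1)
            rows_a.append((name, truth, acc_hi, samples_a))
            rows_b.append((name, truth, acc2, samples_b))

    def _write(path, rows, unit_scale: bool):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["name", "country", "label", "accuracy", "samples"])
            for name, label, acc, samples in rows:
                value = f"{acc / 100.0:.3f}" if unit_scale else f"{acc:.1f}"
                w.writerow([name, "", label, value, samples])

    if path_a is not None:
        _write(path_a, rows_a, unit_scale=True)
    if path_b is not None:
        _write(path_b, rows_b, unit_scale=False)
    return counts


def _women_prob(cfg: CorpusConfig, category: str, year: int) -> float:
    p = (
        cfg.gender_start[category]
        + cfg.gender_slope_pp[category] / 100.0 * (year - cfg.years[0])
    )
    return min(max(p, 0.0), 1.0)


def generate_corpus(cfg: CorpusConfig, outdir) -> GroundTruth:
    """Generate one corpus under ``outdir`` and return its ground truth.

    Emits ``ancestry.tsv``, ``publications.xml``, the two name-gender
    dictionaries, and a ``ground_truth/`` directory holding the exact
    representation tables, ubiquity scores, yearly gender series and
    bookkeeping counts implied by the realized draws.
    """
    cfg.validate()
    outdir = Path(outdir)
    (outdir / "ground_truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 0])

    roster = load_name_roster()
    inst_roster = _load_institution_roster()
    efo_by_area = _load_efo_by_area()
    income = load_income_table(
        resources.files("gwasrep.data").joinpath("worldbank_income_fy2022.tsv")
    )

    countries = sorted(cfg.country_mixture)
    cweights = np.array([cfg.country_mixture[c] for c in countries])
    cweights = cweights / cweights.sum()
    rec_countries = sorted(cfg.recruitment_mixture)
    rweights = np.array([cfg.recruitment_mixture[c] for c in rec_countries])
    rweights = rweights / rweights.sum()
    ancestries = sorted(cfg.ancestry_mixture)
    aweights = np.array([cfg.ancestry_mixture[a] for a in ancestries])
    aweights = aweights / aweights.sum()

    for c in countries:
        if c not in inst_roster:
            raise ConfigError(f"no institutions in roster for {c!r}")

    publications: list[Publication] = []
    entries: list[AncestryEntry] = []
    studies: list[StudyRecord] = []
    counts = {
        "papers": 0, "abbreviated_papers": 0, "pre2014_papers": 0,
        "joint_first_papers": 0, "joint_last_papers": 0,
        "nr_country_rows": 0, "nr_ancestry_rows": 0,
        "nr_country_individuals": 0, "nr_ancestry_individuals": 0,
        "multi_affiliation_authors": 0,
    }
    name_truth: dict[str, str] = {}
    idx = 0
    for year in range(cfg.years[0], cfg.years[1] + 1):
        for _ in range(cfg.papers_per_year):
            idx += 1
            pmid = f"9{idx:07d}"
            accession = f"GCST{idx + 100000:06d}"
            # disease areas and trait codes
            areas = [DISEASE_AREAS[int(rng.integers(len(DISEASE_AREAS)))]]
            if rng.random() < cfg.multi_area_rate:
                other = DISEASE_AREAS[int(rng.integers(len(DISEASE_AREAS)))]
                if other not in areas:
                    areas.append(other)
            efo_codes = {
                efo_by_area[a][int(rng.integers(len(efo_by_area[a])))]
                for a in areas
            }
            area_set = set(areas) | {ALL_TRAITS}

            n_authors = _nb_author_count(rng, cfg)
            joint_first = (
                n_authors >= 4 and rng.random() < cfg.joint_authorship_rate
            )
            joint_last = (
                n_authors >= 4 and rng.random() < cfg.joint_authorship_rate
            )
            abbreviated = rng.random() < cfg.abbreviated_name_rate
            counts["abbreviated_papers"] += int(abbreviated)
            counts["joint_first_papers"] += int(joint_first)
            counts["joint_last_papers"] += int(joint_last)

            authors: list[Author] = []
            for pos in range(n_authors):
                is_first = pos == 0 or (joint_first and pos == 1)
                is_senior = pos == n_authors - 1 or (
                    joint_last and pos == n_authors - 2
                )
                category = (
                    "first" if is_first
                    else "senior" if is_senior
                    else "all"
                )
                gender = (
                    "women"
                    if rng.random() < _women_prob(cfg, category, year)
                    else "men"
                )
                given = roster[gender][int(rng.integers(len(roster[gender])))]
                name_truth[given] = gender
                surname = SURNAMES[int(rng.integers(len(SURNAMES)))]
                k = 2 if rng.random() < cfg.multi_affiliation_rate else 1
                counts["multi_affiliation_authors"] += int(k > 1)
                affs = []
                for _k in range(k):
                    country = str(rng.choice(countries, p=cweights))
                    insts = inst_roster[country][:cfg.institutions_per_country]
                    inst, city = insts[int(rng.integers(len(insts)))]
                    dept = DEPARTMENTS[int(rng.integers(len(DEPARTMENTS)))]
                    zipcode = int(rng.integers(10000, 99999))
                    raw = f"{dept}, {inst}, {zipcode} {city}, {country}"
                    affs.append(
                        Affiliation(
                            raw_text=raw,
                            institution=inst,
                            country=country,
                            income_group=classify_income(country, income),
                        )
                    )
                authors.append(
                    Author(
                        given_name=given.capitalize(),
                        surname=surname,
                        ordinal=pos + 1,
                        joint_first=joint_first and pos in (0, 1),
                        joint_last=joint_last
                        and pos in (n_authors - 2, n_authors - 1),
                        affiliations=affs,
                        gender="excluded" if abbreviated else gender,
                    )
                )

            dialect = "structured"
            author_block = affiliation_block = None
            if year < 2014 and rng.random() < cfg.pre2014_rate:
                dialect = "pre2014"
                counts["pre2014_papers"] += 1
                # number unique affiliation strings in order of appearance
                numbered: dict[str, int] = {}
                for a in authors:
                    for aff in a.affiliations:
                        if aff.raw_text not in numbered:
                            numbered[aff.raw_text] = len(numbered) + 1
                affiliation_block = "; ".join(
                    f"{n} {text}" for text, n in numbered.items()
                )
                chunks = []
                for a in authors:
                    given_disp = (
                        f"{a.given_name[0]}." if abbreviated else a.given_name
                    )
                    nums = ",".join(
                        str(numbered[aff.raw_text]) for aff in a.affiliations
                    )
                    marks = ("†" if a.joint_first else "") + (
                        "*" if a.joint_last else ""
                    )
                    chunks.append(f"{given_disp} {a.surname} {nums}{marks}")
                author_block = "; ".join(chunks)
            elif abbreviated:
                for a in authors:
                    a.given_name = f"{a.given_name[0]}."

            publications.append(
                Publication(
                    pmid, year, authors, area_set, dialect,
                    author_block, affiliation_block,
                )
            )
            studies.append(
                StudyRecord(accession, pmid, year, efo_codes, area_set)
            )

            # ancestry entries: discovery always, replication sometimes
            stage_plan = ["discovery"]
            if rng.random() < cfg.replication_rate:
                stage_plan.append("replication")
            for stage in stage_plan:
                n_ind = int(rng.lognormal(cfg.sample_log_mean,
                                          cfg.sample_log_sd)) + 50
                if stage == "replication":
                    n_ind = max(n_ind // 2, 50)
                ancestry = str(rng.choice(ancestries, p=aweights))
                if rng.random() < cfg.not_reported_rate:
                    ancestry = NOT_REPORTED
                    counts["nr_ancestry_rows"] += 1
                    counts["nr_ancestry_individuals"] += n_ind
                m = 1
                if rng.random() < cfg.multi_country_rate:
                    m = int(rng.integers(2, 4))
                recruit: list[str] | str = [
                    str(c)
                    for c in rng.choice(
                        rec_countries, size=m, p=rweights, replace=False
                    )
                ]
                if rng.random() < cfg.not_reported_rate:
                    recruit = NOT_REPORTED
                    counts["nr_country_rows"] += 1
                    counts["nr_country_individuals"] += n_ind
                entries.append(
                    AncestryEntry(accession, pmid, stage, n_ind,
                                  ancestry, recruit)
                )
    counts["papers"] = len(publications)

    # ---- emit input files -------------------------------------------------
    table = AncestryTable(entries, studies, [], len(entries))
    write_ancestry_table(table, outdir / "ancestry.tsv")
    write_publication_xml(publications, outdir / "publications.xml")
    dict_counts = generate_name_dictionary(
        name_truth, cfg.seed, cfg.dict_conflict_rate, cfg.dict_unknown_rate,
        outdir / "name_gender_source_a.tsv",
        outdir / "name_gender_source_b.tsv",
    )
    counts["dict_conflict_names"] = dict_counts["conflict"]
    counts["dict_unknown_names"] = dict_counts["unknown"]

    # ---- realized ground truth --------------------------------------------
    pubs_by_area: dict[str, list[Publication]] = {}
    for p in publications:
        for area in p.disease_areas:
            pubs_by_area.setdefault(area, []).append(p)
    areas_by_study = {s.study_id: s.disease_areas for s in studies}
    entries_by_area: dict[str, list[AncestryEntry]] = {}
    for e in entries:
        for area in areas_by_study[e.study_id]:
            entries_by_area.setdefault(area, []).append(e)

    tables = compute_corpus_tables(pubs_by_area, income)
    ptables, _ = compute_participant_tables(entries_by_area, income)
    tables = tables + ptables
    ubiquity = compute_ubiquity_tables(pubs_by_area)

    yearly_gender: dict[str, dict[int, tuple[int, int]]] = {}
    for category in ("all", "first", "senior"):
        by_year: dict[int, tuple[int, int]] = {}
        for p in publications:
            s, t = by_year.get(p.year, (0, 0))
            for a in assign_author_positions(p)[category]:
                if a.gender in ("men", "women"):
                    t += 1
                    s += int(a.gender == "women")
            by_year[p.year] = (s, t)
        yearly_gender[category] = by_year

    gt = GroundTruth(
        tables, ubiquity, yearly_gender, counts,
        publications, table, name_truth,
    )
    write_tables_csv(tables, outdir / "ground_truth" / "representation.csv")
    write_ubiquity_csv(ubiquity, outdir / "ground_truth" / "ubiquity.csv")
    with open(outdir / "ground_truth" / "counts.csv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["key", "value"])
        for k in sorted(counts):
            w.writerow([k, counts[k]])
    with open(outdir / "ground_truth" / "yearly_gender.csv", "w",
              newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["author_category", "year", "women", "total"])
        for category in ("all", "first", "senior"):
            for year in sorted(yearly_gender[category]):
                s, t = yearly_gender[category][year]
                w.writerow([category, year, s, t])
    return gt
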