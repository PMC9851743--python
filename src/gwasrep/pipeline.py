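"""End-to-end orchestration: read -> extract -> gender -> stats -> trends.

``run_pipeline`` executes the stages in a fixed order, keeps per-stage
accounting (rows in = rows kept + rows excluded, with reason codes),
and writes all outputs to a temporary directory that is atomically
moved into place only on success, so a failed run never leaves partial
tables behind.  All randomness (there is none in the analysis itself)
and all hashing flow from the single config; identical config + inputs
give byte-identical outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import os
import shutil
import tempfile
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from ._vocab import ALL_TRAITS, NOT_REPORTED, UNRESOLVED
from .affiliation_extraction import (
    Gazetteer,
    clean_affiliation_text,
    parse_affiliation_block,
    resolve_entities,
)
from .catalog_io import (
    AncestryEntry,
    Publication,
    map_disease_areas,
    read_ancestry_table,
    read_publication_xml,
    load_efo_map,
)
from .errors import ConfigError, GwasRepError, InsufficientDataError
from .gender_inference import NameDictionary, assign_genders
from .representation_stats import (
    IncomeTable,
    classify_income,
    compute_corpus_tables,
    compute_participant_tables,
    compute_ubiquity_tables,
    load_income_table,
    top_categories,
    write_tables_csv,
    write_ubiquity_csv,
)
from .trend_analysis import (
    TrendResult,
    beta_regression_trend,
    cochran_armitage_trend,
    ols_trend,
    yearly_attribute_series,
    yearly_gender_counts,
    yearly_participant_series,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

logger = logging.getLogger("gwasrep")

__version__ = "0.1.0"


def _data(name: str) -> str:
    return str(resources.files("gwasrep.data").joinpath(name))


@dataclass
class RunConfig:
    """Paths and switches for one pipeline run.

    Lookup-table paths default to the bundled tables; the two input
    paths (ancestry table, publication XML) are required.  The config
    round-trips through YAML unchanged.
    """

    ancestry_path: str = ""
    publications_path: str = ""
    efo_map_path: str = field(
        default_factory=lambda: _data("disease_area_efo_map.synthetic.tsv"))
    country_gazetteer_path: str = field(
        default_factory=lambda: _data("country_gazetteer.tsv"))
    institutions_path: str = field(
        default_factory=lambda: _data("institutions.tsv"))
    income_path: str = field(
        default_factory=lambda: _data("worldbank_income_fy2022.tsv"))
    dict_a_path: str = field(
        default_factory=lambda: _data("name_gender_source_a.synthetic.tsv"))
    dict_b_path: str = field(
        default_factory=lambda: _data("name_gender_source_b.synthetic.tsv"))
    outdir: str = "gwasrep_out"
    seed: int = 0
    author_categories: tuple[str, ...] = ("all", "first", "senior")
    gender_weighting: str = "per_paper"  # or "pooled"
    stages: tuple[str, ...] = ("discovery", "replication")
    exclude_year: int | None = None  # final partial year, dropped from trends
    fuzzy_threshold: float = 0.92
    trend_top_k: int = 10
    log_level: str = "INFO"

    def validate(self) -> None:
        for attr in ("ancestry_path", "publications_path", "efo_map_path",
                     "country_gazetteer_path", "institutions_path",
                     "income_path", "dict_a_path", "dict_b_path"):
            p = getattr(self, attr)
            if not p or not os.path.exists(p):
                raise ConfigError(f"{attr}: path does not exist: {p!r}")
        if self.gender_weighting not in ("per_paper", "pooled"):
            raise ConfigError(
                f"gender_weighting={self.gender_weighting!r} not recognised")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["author_categories"] = list(self.author_categories)
        d["stages"] = list(self.stages)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("author_categories", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    tables: list
    ubiquity: list
    trends: list


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    d = asdict(cfg)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


# --------------------------------------------------------------------------
# mining: raw affiliation text -> resolved entities

def mine_affiliations(pubs: list[Publication], gazetteer: Gazetteer,
                      income: IncomeTable) -> dict:
    """Resolve every affiliation in place; returns accounting.

    Legacy records are first paired through their superscript
    dictionaries; every raw string is then cleaned and matched against
    the gazetteer, with misses kept as UNRESOLVED.
    """
    from .affiliation_extraction import Affiliation

    acc = {"affiliations_resolved": 0, "affiliations_unresolved": 0,
           "superscript_issues": 0}
    cache: dict[str, tuple[str, str]] = {}
    for pub in pubs:
        if pub.dialect == "pre2014":
            entries = parse_affiliation_block(pub.affiliation_block or "")
            for author in pub.authors:
                affs = []
                if author.superscripts is None:
                    if None in entries:
                        affs.append(Affiliation(raw_text=entries[None]))
                    else:
                        acc["superscript_issues"] += 1
                        logger.warning(
                            "pmid %s: unnumbered author %s inherits nothing",
                            pub.pmid, author.surname)
                else:
                    for n in author.superscripts:
                        if n in entries:
                            affs.append(Affiliation(raw_text=entries[n]))
                        else:
                            affs.append(Affiliation(raw_text=""))
                            acc["superscript_issues"] += 1
                            logger.warning(
                                "pmid %s: superscript %d missing from block",
                                pub.pmid, n)
                author.affiliations = affs
        for author in pub.authors:
            for aff in author.affiliations:
                if not aff.raw_text:
                    aff.institution = aff.country = UNRESOLVED
                    aff.income_group = UNRESOLVED
                    acc["affiliations_unresolved"] += 1
                    continue
                aff.clean_text = clean_affiliation_text(aff.raw_text)
                if aff.clean_text in cache:
                    aff.institution, aff.country = cache[aff.clean_text]
                else:
                    aff.institution, aff.country = resolve_entities(
                        aff.clean_text, gazetteer)
                    cache[aff.clean_text] = (aff.institution, aff.country)
                aff.income_group = classify_income(aff.country, income)
                if aff.country == UNRESOLVED and aff.institution == UNRESOLVED:
                    acc["affiliations_unresolved"] += 1
                else:
                    acc["affiliations_resolved"] += 1
    return acc


# --------------------------------------------------------------------------
# mined-publication serialization (intermediate format between CLI stages)

def publications_to_json(pubs: list[Publication], path) -> None:
    def enc(pub: Publication) -> dict:
        return {
            "pmid": pub.pmid, "year": pub.year, "dialect": pub.dialect,
            "disease_areas": sorted(pub.disease_areas),
            "authors": [
                {
                    "given_name": a.given_name, "surname": a.surname,
                    "ordinal": a.ordinal, "joint_first": a.joint_first,
                    "joint_last": a.joint_last, "gender": a.gender,
                    "affiliations": [
                        {
                            "raw_text": f.raw_text,
                            "clean_text": f.clean_text,
                            "institution": f.institution,
                            "country": f.country,
                            "income_group": f.income_group,
                        }
                        for f in a.affiliations
                    ],
                }
                for a in pub.authors
            ],
        }

    with open(path, "w", encoding="utf-8") as fh:
        json.dump([enc(p) for p in pubs], fh, indent=1, sort_keys=True)
        fh.write("\n")


def publications_from_json(path) -> list[Publication]:
    from .affiliation_extraction import Affiliation
    from .catalog_io import Author

    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    pubs = []
    for d in data:
        authors = [
            Author(
                given_name=a["given_name"], surname=a["surname"],
                ordinal=a["ordinal"], joint_first=a["joint_first"],
                joint_last=a["joint_last"], gender=a["gender"],
                affiliations=[Affiliation(**f) for f in a["affiliations"]],
            )
            for a in d["authors"]
        ]
        pubs.append(Publication(d["pmid"], d["year"], authors,
                                set(d["disease_areas"]), d["dialect"]))
    return pubs


# --------------------------------------------------------------------------
# trends

def compute_trends(pubs: list[Publication],
                   entries_by_year: dict[int, list[AncestryEntry]],
                   income: IncomeTable, cfg: RunConfig,
                   author_tables) -> list[dict]:
    """Trend tests on the pooled (all-traits) corpus.

    For each authorship category: women's share (count-based
    Cochran–Armitage plus OLS and beta regression on per-paper-weighted
    yearly proportions) and the HIC share; for the top-k countries of
    affiliation and recruitment and the leading ancestries, OLS and
    beta regression on yearly shares.
    """
    rows: list[dict] = []

    def drop_partial(series):
        if cfg.exclude_year is not None:
            return series.exclude_year(cfg.exclude_year)
        return series

    def add(result: TrendResult, attribute, category, author_category):
        rows.append({
            "method": result.method, "attribute": attribute,
            "category": category, "disease_area": ALL_TRAITS,
            "author_category": author_category,
            "slope_pp_per_year": result.slope_pp_per_year,
            "ci_low": result.ci_low, "ci_high": result.ci_high,
            "statistic": result.statistic, "p_value": result.p_value,
            "n_years": result.n_years,
        })

    def safe(fn, series, *a, **kw):
        try:
            return fn(series, *a, **kw)
        except (GwasRepError, InsufficientDataError) as exc:
            logger.warning("trend skipped: %s", exc)
            return None

    table_lookup = {
        (t.attribute, t.disease_area, t.author_category): t
        for t in author_tables
    }
    for category in cfg.author_categories:
        counts = drop_partial(yearly_gender_counts(pubs, category))
        for fn in (cochran_armitage_trend, ols_trend, beta_regression_trend):
            res = safe(fn, counts)
            if res:
                add(res, "gender", "women", category)
        hic = drop_partial(
            yearly_attribute_series(pubs, "income", category, "HIC", income))
        for fn in (ols_trend, beta_regression_trend):
            res = safe(fn, hic)
            if res:
                add(res, "income", "HIC", category)

    all_countries = table_lookup.get(("country", ALL_TRAITS, "all"))
    if all_countries:
        for country, _score in top_categories(
                all_countries.proportions, cfg.trend_top_k):
            if country == UNRESOLVED:
                continue
            series = drop_partial(
                yearly_attribute_series(pubs, "country", "all", country))
            for fn in (ols_trend, beta_regression_trend):
                res = safe(fn, series)
                if res:
                    add(res, "country", country, "all")

    if entries_by_year:
        pooled: dict[str, float] = {}
        for year, entries in entries_by_year.items():
            for e in entries:
                if isinstance(e.recruitment_countries, list):
                    for c in e.recruitment_countries:
                        pooled[c] = pooled.get(c, 0.0) + e.n_individuals
        for country, _n in top_categories(pooled, cfg.trend_top_k):
            series = drop_partial(yearly_participant_series(
                entries_by_year, country, "recruitment_country"))
            res = safe(ols_trend, series)
            if res:
                add(res, "recruitment_country", country, "none")
        for ancestry in ("European", "East Asian",
                         "African unspecified",
                         "Hispanic or Latin American"):
            series = drop_partial(yearly_participant_series(
                entries_by_year, ancestry, "ancestry"))
            res = safe(ols_trend, series)
            if res:
                add(res, "ancestry", ancestry, "none")
    return rows


def write_trends_csv(rows: list[dict], path) -> None:
    cols = ["method", "attribute", "category", "disease_area",
            "author_category", "slope_pp_per_year", "ci_low", "ci_high",
            "statistic", "p_value", "n_years"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(cols)
        for r in rows:
            w.writerow([
                r[c] if not isinstance(r[c], float) else repr(r[c])
                for c in cols
            ])


# --------------------------------------------------------------------------
# the run

def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute all stages and atomically populate ``cfg.outdir``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    cfg.validate()
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "inputs": {
            "ancestry": _sha256(cfg.ancestry_path),
            "publications": _sha256(cfg.publications_path),
        },
        "stages": {},
    }
    stage = "read_ancestry_table"
    try:
        table = read_ancestry_table(cfg.ancestry_path)
        excluded_reasons: dict[str, int] = {}
        for issue in table.issues:
            if issue.reason != "duplicate_row":
                excluded_reasons[issue.reason] = (
                    excluded_reasons.get(issue.reason, 0) + 1)
        manifest["stages"][stage] = {
            "rows_in": table.n_rows,
            "rows_out": len(table.entries),
            "rows_excluded": sum(excluded_reasons.values()),
            "excluded_by_reason": excluded_reasons,
        }

        stage = "map_disease_areas"
        efo_map = load_efo_map(cfg.efo_map_path)
        unmapped: list = []
        studies = [map_disease_areas(s, efo_map, unmapped)
                   for s in table.studies]
        manifest["stages"][stage] = {
            "rows_in": len(studies),
            "rows_out": sum(1 for s in studies if s.disease_areas),
            "rows_excluded": len(unmapped),
            "excluded_by_reason": {"no_efo_match": len(unmapped)},
        }

        stage = "read_publication_xml"
        pubs = read_publication_xml(cfg.publications_path)
        manifest["stages"][stage] = {
            "rows_in": len(pubs), "rows_out": len(pubs),
            "rows_excluded": 0, "excluded_by_reason": {},
        }
        areas_by_pmid: dict[str, set] = {}
        for s in studies:
            areas_by_pmid.setdefault(s.pmid, set()).update(s.disease_areas)
        for p in pubs:
            if not p.disease_areas:
                p.disease_areas = areas_by_pmid.get(p.pmid, set())

        stage = "mine_affiliations"
        gazetteer = Gazetteer.from_tables(
            cfg.country_gazetteer_path, cfg.institutions_path,
            cfg.fuzzy_threshold)
        income = load_income_table(cfg.income_path)
        manifest["stages"][stage] = mine_affiliations(pubs, gazetteer, income)

        stage = "assign_genders"
        dict_a = NameDictionary.from_tsv(cfg.dict_a_path, "source_a")
        dict_b = NameDictionary.from_tsv(cfg.dict_b_path, "source_b")
        gcounts = assign_genders(pubs, dict_a, dict_b)
        n_authors = sum(len(p.authors) for p in pubs)
        manifest["stages"][stage] = {
            "rows_in": n_authors,
            "rows_out": gcounts["labelled"],
            "rows_excluded": gcounts["authors_excluded"],
            "excluded_by_reason": {
                "abbreviated_name": gcounts["authors_excluded"]},
            "papers_excluded": gcounts["papers_excluded"],
        }

        stage = "representation_stats"
        pubs_by_area: dict[str, list[Publication]] = {}
        for p in pubs:
            for area in p.disease_areas:
                pubs_by_area.setdefault(area, []).append(p)
        areas_by_study = {s.study_id: s.disease_areas for s in studies}
        entries_by_area: dict[str, list[AncestryEntry]] = {}
        entries_by_year: dict[int, list[AncestryEntry]] = {}
        year_by_pmid = {p.pmid: p.year for p in pubs}
        for e in table.entries:
            for area in areas_by_study.get(e.study_id, set()):
                entries_by_area.setdefault(area, []).append(e)
            if areas_by_study.get(e.study_id) and e.pmid in year_by_pmid:
                entries_by_year.setdefault(
                    year_by_pmid[e.pmid], []).append(e)
        nr_rows = sum(
            1 for e in table.entries
            if e.recruitment_countries == NOT_REPORTED
        )
        manifest["stages"]["not_reported_filter"] = {
            "rows_in": len(table.entries),
            "rows_out": len(table.entries) - nr_rows,
            "rows_excluded": nr_rows,
            "excluded_by_reason": {"NOT_REPORTED": nr_rows},
        }
        author_tables = compute_corpus_tables(
            pubs_by_area, income, cfg.gender_weighting,
            cfg.author_categories)
        ptables, nr_excluded = compute_participant_tables(
            entries_by_area, income, cfg.stages)
        tables = author_tables + ptables
        ubiquity = compute_ubiquity_tables(pubs_by_area,
                                           cfg.author_categories)
        manifest["stages"][stage] = {
            "rows_in": len(pubs) + len(table.entries),
            "rows_out": len(pubs) + len(table.entries),
            "rows_excluded": 0,
            "excluded_by_reason": {},
            "n_tables": len(tables),
            "not_reported_individuals_excluded": nr_excluded,
        }

        stage = "trend_analysis"
        trends = compute_trends(pubs, entries_by_year, income, cfg,
                                author_tables)
        manifest["stages"][stage] = {
            "rows_in": len(trends), "rows_out": len(trends),
            "rows_excluded": 0, "excluded_by_reason": {},
        }
    except GwasRepError as exc:
        raise GwasRepError(f"stage {stage} failed: {exc}") from exc

    outdir = Path(cfg.outdir)
    tmpdir = Path(tempfile.mkdtemp(
        prefix=".gwasrep-tmp-", dir=outdir.parent if outdir.parent != Path("")
        else "."))
    try:
        write_tables_csv(tables, tmpdir / "representation.csv")
        write_ubiquity_csv(ubiquity, tmpdir / "ubiquity.csv")
        write_trends_csv(trends, tmpdir / "trends.csv")
        with open(tmpdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        cfg.to_yaml(tmpdir / "config.yaml")
        if outdir.exists():
            shutil.rmtree(outdir)
        os.replace(tmpdir, outdir)
    finally:
        if tmpdir.exists():
            shutil.rmtree(tmpdir)
    return PipelineResult(outdir, manifest, tables, ubiquity, trends)
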