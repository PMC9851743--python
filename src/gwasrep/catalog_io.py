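"""Readers/writers for the two corpus input formats and study-level mapping.

Two inputs drive everything downstream:

* an ancestry/sample table (tab-separated, one row per study stage x
  ancestry block, modelled on the GWAS Catalog "all ancestry data"
  download) describing who the study participants were and where they
  were recruited;
* publication metadata XML carrying ordered author lists with
  affiliation free text, in two dialects — a structured per-author
  dialect (post-2014 indexing) and a legacy dialect in which a single
  author-list string carries superscript digits that point into a
  numbered affiliation block.

Every row read is accounted for: entries kept plus issues recorded sum
to the raw row count, so downstream filter manifests can reconcile.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace

from lxml import etree

from ._vocab import ALL_TRAITS, NOT_REPORTED
from .affiliation_extraction import Affiliation, parse_superscript_authors
from .errors import CatalogFormatError, RecordError

__all__ = [
    "AncestryEntry",
    "StudyRecord",
    "Author",
    "Publication",
    "RowIssue",
    "AncestryTable",
    "read_ancestry_table",
    "write_ancestry_table",
    "read_publication_xml",
    "write_publication_xml",
    "load_efo_map",
    "map_disease_areas",
    "assign_author_positions",
]

#: column header set of the ancestry-table dialect
ANCESTRY_COLUMNS = (
    "STUDY ACCESSION",
    "PUBMEDID",
    "STAGE",
    "NUMBER OF INDIVIDUALS",
    "BROAD ANCESTRAL CATEGORY",
    "COUNTRY OF RECRUITMENT",
)
#: optional columns carrying publication year and trait ontology codes
OPTIONAL_COLUMNS = ("DATE", "EFO CODES")

_NR_PATTERN = re.compile(r"^\s*(not\s+reported|nr)\s*$", re.IGNORECASE)

# Country lists in the recruitment field are split on comma and
# semicolon, then trimmed (fixed grammar; matches Catalog free text).
_COUNTRY_SPLIT = re.compile(r"[;,]")


@dataclass
class AncestryEntry:
    """One sample block: a study stage's participants of one broad ancestry."""

    study_id: str
    pmid: str
    stage: str  # "discovery" | "replication"
    n_individuals: int
    broad_ancestry: str  # category label or NOT_REPORTED
    recruitment_countries: list[str] | str  # list of names or NOT_REPORTED


@dataclass
class StudyRecord:
    study_id: str
    pmid: str
    year: int | None = None
    efo_codes: set[str] = field(default_factory=set)
    disease_areas: set[str] = field(default_factory=set)


@dataclass
class Author:
    given_name: str
    surname: str
    ordinal: int  # 1-based position in the author list
    joint_first: bool = False
    joint_last: bool = False
    affiliations: list[Affiliation] = field(default_factory=list)
    gender: str = "unknown"  # men | women | unknown | excluded
    superscripts: list[int] | None = None  # legacy dialect only


@dataclass
class Publication:
    pmid: str
    year: int
    authors: list[Author]
    disease_areas: set[str] = field(default_factory=set)
    dialect: str = "structured"  # "structured" | "pre2014"
    author_block: str | None = None  # legacy dialect raw text, verbatim
    affiliation_block: str | None = None


@dataclass
class RowIssue:
    row: int  # 1-based data-row index
    reason: str
    detail: str = ""


@dataclass
class AncestryTable:
    entries: list[AncestryEntry]
    studies: list[StudyRecord]
    issues: list[RowIssue]
    n_rows: int

    def accounted(self) -> bool:
        excluded = sum(1 for i in self.issues if i.reason != "duplicate_row")
        return len(self.entries) + excluded == self.n_rows


def _parse_stage(raw: str) -> str:
    s = raw.strip().lower()
    if s in ("initial", "discovery", "gwas"):
        return "discovery"
    if s in ("replication", "followup", "follow-up"):
        return "replication"
    raise ValueError(f"unknown stage {raw!r}")


def parse_country_field(raw: str) -> list[str] | str:
    """Parse a recruitment-country free-text field.

    Returns NOT_REPORTED for the Catalog missingness marker, otherwise
    the comma/semicolon-separated country names, trimmed, order kept.
    """
    if _NR_PATTERN.match(raw or ""):
        return NOT_REPORTED
    parts = [p.strip() for p in _COUNTRY_SPLIT.split(raw) if p.strip()]
    return parts


def read_ancestry_table(path, dialect: dict | None = None) -> AncestryTable:
    """Read a tab-separated ancestry/sample table.

    Unparseable sample sizes are recorded as issues, never silently
    dropped; duplicate (study, stage, ancestry, country) rows raise a
    warning but are kept, matching how the Catalog download behaves.
    """
    required = tuple((dialect or {}).get("columns", ANCESTRY_COLUMNS))
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise CatalogFormatError(f"missing mandatory column: {col!r}")
        entries: list[AncestryEntry] = []
        issues: list[RowIssue] = []
        studies: dict[str, StudyRecord] = {}
        seen: set[tuple] = set()
        n_rows = 0
        for idx, row in enumerate(reader, start=1):
            n_rows += 1
            acc = (row["STUDY ACCESSION"] or "").strip()
            pmid = (row["PUBMEDID"] or "").strip()
            try:
                stage = _parse_stage(row["STAGE"] or "")
            except ValueError as exc:
                issues.append(RowIssue(idx, "bad_stage", str(exc)))
                continue
            raw_n = (row["NUMBER OF INDIVIDUALS"] or "").strip().replace(",", "")
            try:
                n = int(raw_n)
                if n < 0:
                    raise ValueError("negative")
            except ValueError:
                issues.append(RowIssue(idx, "unparseable_sample_size", raw_n))
                continue
            anc_raw = (row["BROAD ANCESTRAL CATEGORY"] or "").strip()
            ancestry = NOT_REPORTED if _NR_PATTERN.match(anc_raw) else anc_raw
            countries = parse_country_field(row["COUNTRY OF RECRUITMENT"] or "")
            key = (
                acc,
                stage,
                ancestry,
                tuple(countries) if isinstance(countries, list) else countries,
            )
            if key in seen:
                warnings.warn(f"duplicate ancestry row kept at data row {idx}: {key}")
                issues.append(RowIssue(idx, "duplicate_row", repr(key)))
            seen.add(key)
            entries.append(
                AncestryEntry(acc, pmid, stage, n, ancestry, countries)
            )
            if acc not in studies:
                year = None
                if "DATE" in row and row["DATE"]:
                    year = int(str(row["DATE"]).strip()[:4])
                efo = set()
                if "EFO CODES" in row and row["EFO CODES"]:
                    efo = {c.strip() for c in row["EFO CODES"].split(",") if c.strip()}
                studies[acc] = StudyRecord(acc, pmid, year, efo)
    return AncestryTable(entries, list(studies.values()), issues, n_rows)


def write_ancestry_table(table: AncestryTable | list[AncestryEntry], path,
                         studies: list[StudyRecord] | None = None) -> None:
    """Serialize entries back to the tab-separated dialect (round-trip safe)."""
    if isinstance(table, AncestryTable):
        entries, studies = table.entries, table.studies
    else:
        entries = table
    meta = {s.study_id: s for s in (studies or [])}
    cols = list(ANCESTRY_COLUMNS) + list(OPTIONAL_COLUMNS)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for e in entries:
            country = (
                "Not Reported"
                if e.recruitment_countries == NOT_REPORTED
                else ", ".join(e.recruitment_countries)
            )
            ancestry = "Not Reported" if e.broad_ancestry == NOT_REPORTED else e.broad_ancestry
            s = meta.get(e.study_id)
            w.writerow([
                e.study_id, e.pmid, e.stage, e.n_individuals, ancestry, country,
                (s.year if s and s.year is not None else ""),
                (",".join(sorted(s.efo_codes)) if s else ""),
            ])


# --------------------------------------------------------------------------
# publication XML

def _parse_legacy_author_block(block: str) -> list[Author]:
    authors = []
    for ordinal, (name, superscripts, marks) in enumerate(
        parse_superscript_authors(block), start=1
    ):
        tokens = name.split()
        surname = tokens[-1]
        given = " ".join(tokens[:-1]) if len(tokens) > 1 else ""
        authors.append(
            Author(
                given_name=given,
                surname=surname,
                ordinal=ordinal,
                joint_first="†" in marks,
                joint_last="*" in marks,
                superscripts=superscripts,
            )
        )
    return authors


def read_publication_xml(path) -> list[Publication]:
    """Read publication metadata XML (both dialects).

    Structured records carry per-author ``<affiliation>`` elements and
    explicit joint-authorship attributes.  Legacy ("pre2014") records
    carry the author-list and affiliation-block strings verbatim; the
    author list is parsed for order and joint-mark glyphs, but
    affiliation pairing is deferred to the extraction stage.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CatalogFormatError(f"malformed XML in {path}: {exc}") from exc
    pubs: list[Publication] = []
    for el in tree.getroot().iterfind("publication"):
        pmid = el.get("pmid")
        year = int(el.get("year"))
        dialect = el.get("dialect", "structured")
        areas = {a.text for a in el.iterfind("disease_areas/area") if a.text}
        if dialect == "pre2014":
            ab = el.findtext("author_block") or ""
            fb = el.findtext("affiliation_block") or ""
            authors = _parse_legacy_author_block(ab)
            if not authors:
                raise RecordError(
                    f"publication {pmid}: zero authors "
                    f"(element path {tree.getpath(el)})"
                )
            pubs.append(
                Publication(pmid, year, authors, areas, "pre2014", ab, fb)
            )
            continue
        authors = []
        for ordinal, ael in enumerate(el.iterfind("authors/author"), start=1):
            affs = [
                Affiliation(raw_text=a.text or "")
                for a in ael.iterfind("affiliation")
            ]
            authors.append(
                Author(
                    given_name=ael.findtext("given_name") or "",
                    surname=ael.findtext("surname") or "",
                    ordinal=ordinal,
                    joint_first=ael.get("joint_first", "no") == "yes",
                    joint_last=ael.get("joint_last", "no") == "yes",
                    affiliations=affs,
                )
            )
        if not authors:
            raise RecordError(
                f"publication {pmid}: zero authors "
                f"(element path {tree.getpath(el)})"
            )
        pubs.append(Publication(pmid, year, authors, areas))
    return pubs


def write_publication_xml(pubs: list[Publication], path) -> None:
    root = etree.Element("publications")
    for p in pubs:
        el = etree.SubElement(
            root, "publication", pmid=p.pmid, year=str(p.year)
        )
        if p.dialect == "pre2014":
            el.set("dialect", "pre2014")
        if p.disease_areas:
            da = etree.SubElement(el, "disease_areas")
            for a in sorted(p.disease_areas):
                etree.SubElement(da, "area").text = a
        if p.dialect == "pre2014":
            etree.SubElement(el, "author_block").text = p.author_block
            etree.SubElement(el, "affiliation_block").text = p.affiliation_block
            continue
        au = etree.SubElement(el, "authors")
        for a in p.authors:
            ael = etree.SubElement(au, "author")
            if a.joint_first:
                ael.set("joint_first", "yes")
            if a.joint_last:
                ael.set("joint_last", "yes")
            etree.SubElement(ael, "given_name").text = a.given_name
            etree.SubElement(ael, "surname").text = a.surname
            for aff in a.affiliations:
                etree.SubElement(ael, "affiliation").text = aff.raw_text
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# --------------------------------------------------------------------------
# disease-area mapping and author positions

def load_efo_map(path) -> dict[str, set[str]]:
    """Load an ontology-code -> disease-area table (TSV, one pair per row)."""
    mapping: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            mapping.setdefault(row["efo_code"], set()).add(row["disease_area"])
    return mapping


def map_disease_areas(study: StudyRecord, mapping: dict[str, set[str]],
                      log: list | None = None) -> StudyRecord:
    """Assign a study to every disease area matching one of its trait codes.

    A matched study additionally joins the pooled ``all_traits`` category
    exactly once; a study with no matching code belongs to no area and
    the exclusion is logged.
    """
    areas: set[str] = set()
    for code in study.efo_codes:
        areas |= mapping.get(code, set())
    if areas:
        areas.add(ALL_TRAITS)
    elif log is not None:
        log.append((study.study_id, "no_efo_match"))
    return replace(study, disease_areas=areas)


def assign_author_positions(pub: Publication) -> dict[str, list[Author]]:
    """Partition authors into the three authorship categories.

    ``first`` is the first-listed author plus any joint-first authors;
    ``senior`` the last-listed plus any joint-last; ``all`` every
    co-author.  On a single-author paper the same person necessarily
    fills all three roles.
    """
    if not pub.authors:
        raise RecordError(f"publication {pub.pmid}: zero authors")
    first = [a for a in pub.authors if a.joint_first]
    if pub.authors[0] not in first:
        first = [pub.authors[0]] + first
    senior = [a for a in pub.authors if a.joint_last]
    if pub.authors[-1] not in senior:
        senior = senior + [pub.authors[-1]]
    return {"all": list(pub.authors), "first": first, "senior": senior}
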