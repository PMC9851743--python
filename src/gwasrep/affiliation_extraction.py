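"""Affiliation free text -> resolved (institution, country) pairs.

The extraction follows a deliberately transparent recipe rather than a
learned NER model: normalise the free text to a reduced corpus (strip
diacritics, URLs, punctuation and stop-words), then match token
sequences against an offline gazetteer of country names, aliases, ISO
codes and state/region names, and against an institution synonym table.
Matching proceeds in fixed stages — exact alias, state/region lookup,
then fuzzy (normalized edit similarity) — and never guesses: anything
below threshold stays UNRESOLVED, which downstream code keeps as a
reportable category.

Legacy publication records (one author-list string with superscript
digits pointing into a numbered affiliation block) are paired here via
a number -> affiliation dictionary.
"""

from __future__ import annotations

import csv
import re
import unicodedata
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import edlib

from ._vocab import UNRESOLVED
from .errors import ConfigError

__all__ = [
    "Affiliation",
    "Gazetteer",
    "clean_affiliation_text",
    "pair_superscript_affiliations",
    "parse_affiliation_block",
    "parse_superscript_authors",
    "resolve_entities",
    "load_default_gazetteer",
]

_URL_RE = re.compile(r"(?:https?://|www\.)\S+|\S+@\S+")
_NON_ALNUM = re.compile(r"[^0-9a-z]+")


@dataclass
class Affiliation:
    """One author-affiliation slot, raw through resolved."""

    raw_text: str
    clean_text: str = ""
    institution: str = UNRESOLVED
    country: str = UNRESOLVED
    income_group: str = UNRESOLVED


def _stopwords() -> frozenset[str]:
    txt = (
        resources.files("gwasrep.data")
        .joinpath("affiliation_stopwords.txt")
        .read_text(encoding="utf-8")
    )
    return frozenset(w.strip() for w in txt.splitlines() if w.strip())


_STOPWORDS = _stopwords()


def clean_affiliation_text(raw: str) -> str:
    """Reduce an affiliation string to tidy matchable text.

    Lower-case, diacritics stripped (NFKD), URLs and e-mail addresses
    removed, punctuation runs collapsed to single spaces, stop-words
    dropped.  Idempotent: clean(clean(x)) == clean(x).
    """
    if not raw:
        return ""
    s = _URL_RE.sub(" ", raw)
    s = unicodedata.normalize("NFKD", s)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = s.lower()
    s = _NON_ALNUM.sub(" ", s)
    tokens = [t for t in s.split() if t not in _STOPWORDS]
    return " ".join(tokens)


# --------------------------------------------------------------------------
# gazetteer

@dataclass
class Gazetteer:
    """Offline alias -> canonical lookup for countries, regions, institutions.

    Aliases are stored in cleaned-token form so that lookups against
    cleaned affiliation text are exact.  The alias -> canonical mapping
    is a function per type; an ambiguous alias is a configuration error.
    """

    country_alias: dict[tuple[str, ...], str] = field(default_factory=dict)
    region_alias: dict[tuple[str, ...], str] = field(default_factory=dict)
    institution_alias: dict[tuple[str, ...], str] = field(default_factory=dict)
    institution_info: dict[str, tuple[str, str]] = field(default_factory=dict)
    fuzzy_threshold: float = 0.92

    @staticmethod
    def _key(alias: str) -> tuple[str, ...]:
        return tuple(clean_affiliation_text(alias).split())

    def add_country_alias(self, alias: str, canonical: str, kind: str = "country"):
        key = self._key(alias)
        if not key:
            return
        target = self.region_alias if kind == "region" else self.country_alias
        if key in target and target[key] != canonical:
            raise ConfigError(f"ambiguous {kind} alias {alias!r}")
        target[key] = canonical

    def add_institution_alias(self, alias: str, canonical: str,
                              country: str = "", city: str = ""):
        key = self._key(alias)
        if not key:
            return
        if key in self.institution_alias and self.institution_alias[key] != canonical:
            raise ConfigError(f"ambiguous institution alias {alias!r}")
        self.institution_alias[key] = canonical
        self.institution_info.setdefault(canonical, (country, city))

    @classmethod
    def from_tables(cls, country_path, institution_path,
                    fuzzy_threshold: float = 0.92) -> "Gazetteer":
        gaz = cls(fuzzy_threshold=fuzzy_threshold)
        with open(country_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                kind = "region" if row["type"] == "region" else "country"
                gaz.add_country_alias(row["alias"], row["canonical"], kind)
        with open(institution_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                gaz.add_institution_alias(
                    row["alias"], row["canonical"],
                    row.get("country", ""), row.get("city", ""),
                )
        return gaz


@lru_cache(maxsize=1)
def load_default_gazetteer() -> Gazetteer:
    data = resources.files("gwasrep.data")
    return Gazetteer.from_tables(
        data.joinpath("country_gazetteer.tsv"),
        data.joinpath("institutions.tsv"),
    )


def _exact_matches(tokens: list[str], aliases: dict[tuple[str, ...], str]):
    """All (end_position, n_tokens, canonical) exact alias hits in the text."""
    if not aliases:
        return []
    lengths = sorted({len(k) for k in aliases})
    hits = []
    for i in range(len(tokens)):
        for ln in lengths:
            if i + ln > len(tokens):
                break
            key = tuple(tokens[i:i + ln])
            canon = aliases.get(key)
            if canon is not None:
                hits.append((i + ln, ln, canon))
    return hits


def _pick_last(hits) -> str | None:
    """Postal convention: the last matched alias wins (addresses end with
    the country).  Two distinct canonicals ending at the same position is
    an ambiguity -> None with a warning raised by the caller."""
    if not hits:
        return None
    last_end = max(h[0] for h in hits)
    at_end = {h[2] for h in hits if h[0] == last_end}
    if len(at_end) > 1:
        return "__AMBIGUOUS__"
    return at_end.pop()


def _similarity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _fuzzy_match(tokens: list[str], aliases: dict[tuple[str, ...], str],
                 threshold: float) -> str | None:
    """Best fuzzy alias hit: highest similarity, ties to the longer alias,
    then the later window, then alphabetical canonical."""
    best = None
    for key, canon in aliases.items():
        alias_str = " ".join(key)
        ln = len(key)
        for i in range(len(tokens) - ln + 1):
            window = " ".join(tokens[i:i + ln])
            sim = _similarity(window, alias_str)
            if sim < threshold:
                continue
            cand = (sim, ln, i + ln, canon)
            if best is None or (cand[:3], _neg_alpha(cand[3])) > (
                best[:3], _neg_alpha(best[3])
            ):
                best = cand
    return best[3] if best else None


class _neg_alpha(str):
    """Orders strings reversed so that max() prefers alphabetically first."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def resolve_entities(clean_text: str, gazetteer: Gazetteer | None = None
                     ) -> tuple[str, str]:
    """Resolve (institution, country) from cleaned affiliation text.

    Country: exact alias match first (last match wins), then
    state/region -> country lookup, then fuzzy match at the configured
    normalized-edit-similarity threshold.  Institution: synonym-table
    exact match (longest alias wins), then fuzzy.  No stage guesses:
    a miss returns UNRESOLVED.
    """
    gaz = gazetteer or load_default_gazetteer()
    tokens = clean_text.split()

    country = _pick_last(_exact_matches(tokens, gaz.country_alias))
    if country == "__AMBIGUOUS__":
        warnings.warn(f"ambiguous country in affiliation: {clean_text!r}")
        country = UNRESOLVED
    if country is None:
        country = _pick_last(_exact_matches(tokens, gaz.region_alias))
        if country == "__AMBIGUOUS__":
            warnings.warn(f"ambiguous region in affiliation: {clean_text!r}")
            country = UNRESOLVED
    if country is None:
        country = _fuzzy_match(tokens, gaz.country_alias, gaz.fuzzy_threshold)
    if country is None:
        country = UNRESOLVED

    inst_hits = _exact_matches(tokens, gaz.institution_alias)
    if inst_hits:
        # longest alias is the most specific; break ties by later position
        institution = max(inst_hits, key=lambda h: (h[1], h[0]))[2]
    else:
        institution = _fuzzy_match(
            tokens, gaz.institution_alias, gaz.fuzzy_threshold
        ) or UNRESOLVED
    return institution, country


# --------------------------------------------------------------------------
# legacy superscript pairing

_AUTHOR_CHUNK = re.compile(
    r"^(?P<name>.*?)[\s]*(?P<nums>\d+(?:\s*,\s*\d+)*)?\s*(?P<marks>[†\*]*)$"
)
_BLOCK_ENTRY = re.compile(r"^\s*(\d+)\s*[\.\)]?\s*(.*)$")


def parse_superscript_authors(block: str):
    """Parse a legacy author-list string into (name, superscripts, marks)."""
    out = []
    for chunk in (c.strip() for c in block.split(";") if c.strip()):
        m = _AUTHOR_CHUNK.match(chunk)
        name = m.group("name").strip()
        if not name:
            continue
        nums = m.group("nums")
        sups = [int(x) for x in re.split(r"\s*,\s*", nums)] if nums else None
        out.append((name, sups, m.group("marks") or ""))
    return out


def parse_affiliation_block(block: str) -> dict[int | None, str]:
    """Parse a numbered affiliation block into {number: text}.

    A single entry without a leading number is stored under ``None``
    (the only consistent pairing for unnumbered single-affiliation
    records).
    """
    entries: dict[int | None, str] = {}
    chunks = [c.strip() for c in block.split(";") if c.strip()]
    for chunk in chunks:
        m = _BLOCK_ENTRY.match(chunk)
        if m and m.group(2):
            entries[int(m.group(1))] = m.group(2).strip()
        elif len(chunks) == 1:
            entries[None] = chunk
    return entries


def pair_superscript_affiliations(author_block: str, affiliation_block: str
                                  ) -> tuple[dict[str, list[str]], list[str]]:
    """Pair superscript digits on authors with the numbered affiliations.

    Returns (author name -> affiliation texts, issues).  An author
    annotated with a number absent from the block gets UNRESOLVED in
    that slot; an unnumbered author inherits the block's sole unnumbered
    entry if there is one, else nothing.  Both paths are logged.
    """
    entries = parse_affiliation_block(affiliation_block)
    issues: list[str] = []
    mapping: dict[str, list[str]] = {}
    for name, sups, _marks in parse_superscript_authors(author_block):
        if sups is None:
            if None in entries:
                mapping[name] = [entries[None]]
            else:
                mapping[name] = []
                issues.append(f"unnumbered author {name!r} inherits nothing")
                warnings.warn(issues[-1])
            continue
        affs = []
        for n in sups:
            if n in entries:
                affs.append(entries[n])
            else:
                affs.append(UNRESOLVED)
                issues.append(
                    f"author {name!r}: superscript {n} missing from block"
                )
                warnings.warn(issues[-1])
        mapping[name] = affs
    return mapping, issues
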