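"""Name-to-gender assignment from two offline dictionary sources.

Each author's given name is normalised (diacritics stripped, compound
names split, initial-only names flagged) and looked up in two
independent name-gender dictionaries, each returning a label
(men/women/unknown) with an accuracy and a sample count.  The two
verdicts are reconciled with a fixed rule set:

* equal labels -> that label;
* exactly one source unknown -> the other source's label;
* a men/women conflict -> the higher-accuracy prediction, ties going to
  the larger sample count and then, conservatively, to unknown.

Dictionaries may report accuracy on a 0-1 probability scale or a 0-100
scale; both are rescaled to [0, 100] at load time so the conflict rule
compares like with like.

Papers whose author lists abbreviate given names to initials carry no
usable signal; when more than half of a paper's authors are initials
the whole paper is excluded from gender analysis, otherwise only the
affected authors are.  Excluded authors never enter gender
denominators.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field

__all__ = [
    "ABBREVIATED",
    "GenderPrediction",
    "NameDictionary",
    "NormalizedName",
    "normalize_author_name",
    "lookup_gender",
    "reconcile",
    "assign_genders",
]

ABBREVIATED = "ABBREVIATED"

_SPLIT = re.compile(r"[\s\-]+")


@dataclass(frozen=True)
class GenderPrediction:
    source: str
    label: str  # men | women | unknown
    accuracy: float  # [0, 100]
    samples: int = 0
    country_fallback: bool = False  # country-specific entry absent


@dataclass(frozen=True)
class NormalizedName:
    first_token: str
    tokens: tuple[str, ...]
    flags: frozenset[str] = frozenset()

    @property
    def abbreviated(self) -> bool:
        return ABBREVIATED in self.flags


def _strip_accents(s: str) -> str:
    s = unicodedata.normalize("NFKD", s)
    return "".join(ch for ch in s if not unicodedata.combining(ch))


def normalize_author_name(given: str, surname: str = "") -> NormalizedName:
    """Normalise a given name for dictionary lookup.

    Diacritics are stripped and hyphenated/compound names split; the
    first token is what the dictionaries key on.  A name reduced to
    initials (e.g. "J." or "J M") is flagged ABBREVIATED — such names
    cannot be looked up and the author is excluded downstream.
    """
    raw = (given or "").strip()
    has_period = "." in raw
    cleaned = _strip_accents(raw).lower()
    cleaned = re.sub(r"[^a-z\s\-]", " ", cleaned)
    tokens = tuple(t for t in _SPLIT.split(cleaned) if t)
    flags = set()
    if not tokens or has_period or len(tokens[0]) == 1:
        flags.add(ABBREVIATED)
    first = tokens[0] if tokens else ""
    return NormalizedName(first, tokens, frozenset(flags))


@dataclass
class NameDictionary:
    """(normalized first name, optional country) -> (label, accuracy, samples).

    Lookup with a country falls back to the countryless (global) entry
    when no country-specific row exists.
    """

    source: str
    entries: dict[tuple[str, str], tuple[str, float, int]] = field(
        default_factory=dict
    )

    @classmethod
    def from_tsv(cls, path, source: str) -> "NameDictionary":
        rows = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                rows.append(
                    (
                        row["name"].strip().lower(),
                        (row.get("country") or "").strip(),
                        row["label"].strip(),
                        float(row["accuracy"]),
                        int(row.get("samples") or 0),
                    )
                )
        # rescale a 0-1 probability dictionary to the common 0-100 scale
        if rows and max(r[3] for r in rows) <= 1.0:
            rows = [(n, c, l, a * 100.0, s) for n, c, l, a, s in rows]
        d = cls(source=source)
        for name, country, label, acc, samples in rows:
            d.entries[(name, country)] = (label, acc, samples)
        return d


def lookup_gender(name: NormalizedName | str, country: str | None,
                  dictionary: NameDictionary) -> GenderPrediction:
    """Look a normalised name up, preferring a country-specific entry."""
    key = name.first_token if isinstance(name, NormalizedName) else name
    fallback = False
    hit = None
    if country:
        hit = dictionary.entries.get((key, country))
        if hit is None:
            fallback = True
    if hit is None:
        hit = dictionary.entries.get((key, ""))
    if hit is None:
        return GenderPrediction(dictionary.source, "unknown", 0.0, 0)
    label, acc, samples = hit
    return GenderPrediction(
        dictionary.source, label, acc, samples,
        country_fallback=fallback and bool(country),
    )


def reconcile(pred_a: GenderPrediction, pred_b: GenderPrediction) -> str:
    """Reconcile two sources' verdicts for the same name into one label."""
    a, b = pred_a.label, pred_b.label
    if a == b:
        return a
    if a == "unknown":
        return b
    if b == "unknown":
        return a
    # men/women conflict: higher accuracy wins; tie -> larger sample
    # count; still tied -> unknown (conservative).
    if pred_a.accuracy != pred_b.accuracy:
        return a if pred_a.accuracy > pred_b.accuracy else b
    if pred_a.samples != pred_b.samples:
        return a if pred_a.samples > pred_b.samples else b
    return "unknown"


def assign_genders(publications, dict_a: NameDictionary,
                   dict_b: NameDictionary,
                   abbreviated_paper_threshold: float = 0.5) -> dict:
    """Set ``author.gender`` in place for every publication.

    Returns accounting: authors labelled, authors excluded (initials),
    publications excluded wholesale (more than the threshold share of
    their authors are initials).
    """
    counts = {"labelled": 0, "authors_excluded": 0, "papers_excluded": 0}
    for pub in publications:
        norms = [
            normalize_author_name(a.given_name, a.surname)
            for a in pub.authors
        ]
        n_abbr = sum(1 for n in norms if n.abbreviated)
        paper_excluded = n_abbr > abbreviated_paper_threshold * len(norms)
        if paper_excluded:
            counts["papers_excluded"] += 1
        for author, norm in zip(pub.authors, norms):
            if paper_excluded or norm.abbreviated:
                author.gender = "excluded"
                counts["authors_excluded"] += 1
                continue
            country = None
            for aff in author.affiliations:
                if aff.country and aff.country != "UNRESOLVED":
                    country = aff.country
                    break
            pa = lookup_gender(norm, country, dict_a)
            pb = lookup_gender(norm, country, dict_b)
            author.gender = reconcile(pa, pb)
            counts["labelled"] += 1
    return counts
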