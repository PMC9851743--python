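"""Brute-force oracles used by unit and acceptance tests.

Exact-rational enumerations, independent of the package's aggregation
code: author sets are re-derived from the joint flags from scratch and
all weights are Fractions, so any float drift in the implementation
would show up against these.
"""

import random
from fractions import Fraction

from gwasrep import UNRESOLVED
from gwasrep.affiliation_extraction import Affiliation
from gwasrep.catalog_io import Author, Publication


def category_authors(pub, category):
    if category == "all":
        return list(pub.authors)
    if category == "first":
        out = [a for a in pub.authors if a.joint_first]
        if pub.authors[0] not in out:
            out.insert(0, pub.authors[0])
        return out
    out = [a for a in pub.authors if a.joint_last]
    if pub.authors[-1] not in out:
        out.append(pub.authors[-1])
    return out


def brute_force_dominance(pubs, category):
    totals = {}
    for pub in pubs:
        cat = category_authors(pub, category)
        for a in cat:
            affs = a.affiliations if a.affiliations else [None]
            for aff in affs:
                inst = aff.institution if aff is not None else UNRESOLVED
                totals[inst] = totals.get(inst, Fraction(0)) + (
                    Fraction(1, len(cat)) / len(affs))
    n = len(pubs)
    return {inst: v / n for inst, v in totals.items()}


def brute_force_ubiquity(pubs, category):
    counts = {}
    for pub in pubs:
        present = set()
        for a in category_authors(pub, category):
            for aff in a.affiliations:
                present.add(aff.institution)
        for inst in present:
            counts[inst] = counts.get(inst, 0) + 1
    return {inst: Fraction(c, len(pubs)) for inst, c in counts.items()}


INSTITUTIONS = ["Inst %s" % c for c in "ABCDEFGH"]


def random_toy_corpus(seed, max_papers=20, max_authors=8, max_affs=3):
    """Small random corpus exercising joint flags, multi-affiliations
    and affiliation-less (UNRESOLVED) authors."""
    rng = random.Random(seed)
    pubs = []
    for p in range(rng.randint(1, max_papers)):
        n = rng.randint(1, max_authors)
        authors = []
        for i in range(n):
            k = rng.randint(0, max_affs)
            affs = [
                Affiliation(raw_text="", institution=rng.choice(INSTITUTIONS),
                            country="X")
                for _ in range(k)
            ]
            authors.append(Author("A", "S", i + 1, affiliations=affs))
        if n >= 3 and rng.random() < 0.3:
            authors[0].joint_first = authors[1].joint_first = True
        if n >= 3 and rng.random() < 0.3:
            authors[-1].joint_last = authors[-2].joint_last = True
        pubs.append(Publication(str(p), 2000 + p % 20, authors))
    return pubs
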