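"""Independent naive recomputation of representation tables.

Deliberately written with plain loops and the standard library only —
no code shared with the package under test — so it can serve as an
oracle for end-to-end recovery: it re-derives every representation
table straight from the files a synthetic corpus run emits.

It exploits the generator's fixed affiliation grammar
("Department, Institution, Zip City, Country") instead of gazetteer
matching, which keeps it trivially auditable.
"""

import csv
import unicodedata
import xml.etree.ElementTree as ET

NR = "NOT_REPORTED"


def _read_tsv(path):
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _norm_first(given):
    if not given:
        return "", True
    abbreviated = "." in given
    s = unicodedata.normalize("NFKD", given)
    s = "".join(c for c in s if not unicodedata.combining(c)).lower()
    tokens = [t for t in s.replace("-", " ").split() if t.isalpha()]
    if not tokens or len(tokens[0]) == 1:
        abbreviated = True
    return (tokens[0] if tokens else ""), abbreviated


def _load_gender_dict(path):
    out = {}
    rows = _read_tsv(path)
    scale = 100.0 if max(float(r["accuracy"]) for r in rows) <= 1.0 else 1.0
    for r in rows:
        out[(r["name"], r["country"])] = (
            r["label"], float(r["accuracy"]) * scale, int(r["samples"]))
    return out


def _reconcile(a, b):
    la, aa, sa = a
    lb, ab, sb = b
    if la == lb:
        return la
    if la == "unknown":
        return lb
    if lb == "unknown":
        return la
    if aa != ab:
        return la if aa > ab else lb
    if sa != sb:
        return la if sa > sb else lb
    return "unknown"


def _split_affiliation(raw):
    parts = [p.strip() for p in raw.split(",")]
    return parts[1], parts[-1]  # institution, country


def _parse_publication(el):
    """-> (pmid, year, authors) with authors as dicts."""
    authors = []
    if el.get("dialect") == "pre2014":
        block = {}
        for chunk in (el.findtext("affiliation_block") or "").split(";"):
            chunk = chunk.strip()
            if chunk:
                num, text = chunk.split(" ", 1)
                block[int(num)] = text
        for chunk in (el.findtext("author_block") or "").split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            marks = ""
            while chunk[-1] in "†*":
                marks += chunk[-1]
                chunk = chunk[:-1]
            name, nums = chunk.rsplit(" ", 1)
            given, surname = name.rsplit(" ", 1)
            affs = [block[int(n)] for n in nums.split(",")]
            authors.append({
                "ordinal": len(authors) + 1,
                "given": given, "surname": surname,
                "joint_first": "†" in marks, "joint_last": "*" in marks,
                "affiliations": affs,
            })
    else:
        for ael in el.find("authors"):
            authors.append({
                "ordinal": len(authors) + 1,
                "given": ael.findtext("given_name"),
                "surname": ael.findtext("surname"),
                "joint_first": ael.get("joint_first") == "yes",
                "joint_last": ael.get("joint_last") == "yes",
                "affiliations": [a.text for a in ael.findall("affiliation")],
            })
    return el.get("pmid"), int(el.get("year")), authors


def recompute(corpus_dir, efo_map_path, income_path):
    """Recompute {(attribute, area, category, value): (proportion, basis)}
    and ubiquity {(area, category, institution): score} from emitted files."""
    corpus_dir = str(corpus_dir)

    efo_to_areas = {}
    for r in _read_tsv(efo_map_path):
        efo_to_areas.setdefault(r["efo_code"], []).append(r["disease_area"])
    income_of = {r["country"]: r["income_group"] for r in _read_tsv(income_path)}
    dict_a = _load_gender_dict(f"{corpus_dir}/name_gender_source_a.tsv")
    dict_b = _load_gender_dict(f"{corpus_dir}/name_gender_source_b.tsv")

    # ancestry table -> entries + per-study areas
    entries = []
    study_areas = {}
    for r in _read_tsv(f"{corpus_dir}/ancestry.tsv"):
        countries = r["COUNTRY OF RECRUITMENT"].strip()
        if countries.lower() == "not reported":
            countries = NR
        else:
            countries = [c.strip() for c in countries.split(",")]
        ancestry = r["BROAD ANCESTRAL CATEGORY"].strip()
        if ancestry.lower() == "not reported":
            ancestry = NR
        entries.append({
            "study": r["STUDY ACCESSION"], "pmid": r["PUBMEDID"],
            "stage": r["STAGE"], "n": int(r["NUMBER OF INDIVIDUALS"]),
            "ancestry": ancestry, "countries": countries,
        })
        if r["STUDY ACCESSION"] not in study_areas:
            areas = set()
            for code in r["EFO CODES"].split(","):
                for a in efo_to_areas.get(code.strip(), []):
                    areas.add(a)
            if areas:
                areas.add("all_traits")
            study_areas[r["STUDY ACCESSION"]] = areas

    # publications
    root = ET.parse(f"{corpus_dir}/publications.xml").getroot()
    pubs = []
    pmid_areas = {}
    for e in entries:
        pmid_areas.setdefault(e["pmid"], set()).update(study_areas[e["study"]])
    for el in root.findall("publication"):
        pmid, year, authors = _parse_publication(el)
        # resolve attributes per author
        n_abbr = 0
        for a in authors:
            first, abbreviated = _norm_first(a["given"])
            a["abbr"] = abbreviated
            n_abbr += abbreviated
            resolved = []
            for raw in a["affiliations"]:
                inst, country = _split_affiliation(raw)
                resolved.append((inst, country, income_of[country]))
            a["resolved"] = resolved
            a["first_token"] = first
        paper_excluded = n_abbr > 0.5 * len(authors)
        for a in authors:
            if paper_excluded or a["abbr"]:
                a["gender"] = "excluded"
                continue
            pa = dict_a.get((a["first_token"], ""), ("unknown", 0.0, 0))
            pb = dict_b.get((a["first_token"], ""), ("unknown", 0.0, 0))
            a["gender"] = _reconcile(pa, pb)
        pubs.append({
            "pmid": pmid, "year": year, "authors": authors,
            "areas": pmid_areas.get(pmid, set()),
        })

    # author categories
    def members(pub, category):
        authors = pub["authors"]
        if category == "all":
            return list(authors)
        if category == "first":
            out = [a for a in authors if a["joint_first"]]
            if authors[0] not in out:
                out = [authors[0]] + out
            return out
        out = [a for a in authors if a["joint_last"]]
        if authors[-1] not in out:
            out = out + [authors[-1]]
        return out

    tables = {}
    ubiquity = {}
    all_areas = sorted({a for p in pubs for a in p["areas"]})
    for area in all_areas:
        area_pubs = [p for p in pubs if area in p["areas"]]
        for attribute in ("country", "institution", "income", "gender"):
            for category in ("all", "first", "senior"):
                maps = []
                for pub in area_pubs:
                    cat_authors = members(pub, category)
                    acc = {}
                    if attribute == "gender":
                        inc = [a for a in cat_authors
                               if a["gender"] != "excluded"]
                        if not inc:
                            continue
                        w = 1.0 / len(inc)
                        for a in inc:
                            acc[a["gender"]] = acc.get(a["gender"], 0.0) + w
                    else:
                        w = 1.0 / len(cat_authors)
                        for a in cat_authors:
                            share = w / len(a["resolved"])
                            for inst, country, inc_grp in a["resolved"]:
                                key = {"country": country,
                                       "institution": inst,
                                       "income": inc_grp}[attribute]
                                acc[key] = acc.get(key, 0.0) + share
                    maps.append(acc)
                if not maps:
                    continue
                total = {}
                for m in maps:
                    for k, v in m.items():
                        total[k] = total.get(k, 0.0) + v
                for k in total:
                    total[k] /= len(maps)
                for k, v in total.items():
                    tables[(attribute, area, category, k)] = (v, len(maps))
        # ubiquity
        for category in ("all", "first", "senior"):
            counts = {}
            for pub in area_pubs:
                present = set()
                for a in members(pub, category):
                    for inst, _c, _i in a["resolved"]:
                        present.add(inst)
                for inst in sorted(present):
                    counts[inst] = counts.get(inst, 0) + 1
            for inst, c in counts.items():
                ubiquity[(area, category, inst)] = c / len(area_pubs)

        # participant tables
        area_entries = [e for e in entries if area in study_areas[e["study"]]]

        def participant(keyfunc, attribute):
            acc, grand = {}, 0
            for e in area_entries:
                keys = keyfunc(e)
                if keys is None:
                    continue
                grand += e["n"]
                contrib = e["n"] / len(keys)
                for k in keys:
                    acc[k] = acc.get(k, 0.0) + contrib
            for k, v in acc.items():
                tables[(attribute, area, "none", k)] = (v / grand, grand)

        participant(
            lambda e: None if e["countries"] == NR else e["countries"],
            "recruitment_country")
        participant(
            lambda e: None if e["ancestry"] == NR else [e["ancestry"]],
            "ancestry")
        participant(
            lambda e: None if e["countries"] == NR
            else [income_of[c] for c in e["countries"]],
            "income")
    return tables, ubiquity


def read_representation_csv(path):
    """Parse a representation CSV into the same keyed structure."""
    out = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for r in csv.DictReader(fh):
            out[(r["attribute"], r["disease_area"], r["author_category"],
                 r["category"])] = (float(r["proportion"]), int(r["n_basis"]))
    return out


def read_ubiquity_csv(path):
    out = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for r in csv.DictReader(fh):
            out[(r["disease_area"], r["author_category"],
                 r["institution"])] = float(r["score"])
    return out
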