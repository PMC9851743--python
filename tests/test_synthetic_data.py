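import csv
import hashlib
import math
import pathlib

import pytest

from gwasrep import ConfigError, NOT_REPORTED
from gwasrep.gender_inference import (
    GenderPrediction,
    NameDictionary,
    lookup_gender,
    reconcile,
)
from gwasrep.pipeline import RunConfig, run_pipeline
from gwasrep.synthetic_data import (
    CorpusConfig,
    generate_corpus,
    generate_name_dictionary,
    load_name_roster,
)


def _hash_tree(root):
    h = hashlib.sha256()
    for p in sorted(pathlib.Path(root).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestConfigValidation:
    def test_mixture_not_summing_to_one_rejected(self):
        cfg = CorpusConfig(country_mixture={"United States": 0.6,
                                            "Japan": 0.3})
        with pytest.raises(ConfigError, match="country_mixture"):
            cfg.validate()

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError, match="not_reported_rate"):
            CorpusConfig(not_reported_rate=1.5).validate()


class TestGenerateCorpus:
    def test_same_seed_same_bytes(self, tmp_path):
        cfg = CorpusConfig(seed=5, papers_per_year=4, years=(2012, 2015))
        generate_corpus(cfg, tmp_path / "a")
        generate_corpus(cfg, tmp_path / "b")
        assert _hash_tree(tmp_path / "a") == _hash_tree(tmp_path / "b")

    def test_different_seed_different_corpus(self, tmp_path):
        generate_corpus(
            CorpusConfig(seed=5, papers_per_year=4, years=(2012, 2015)),
            tmp_path / "a")
        generate_corpus(
            CorpusConfig(seed=6, papers_per_year=4, years=(2012, 2015)),
            tmp_path / "b")
        assert _hash_tree(tmp_path / "a") != _hash_tree(tmp_path / "b")

    def test_not_reported_bookkeeping_matches_file_scan(self, tmp_path):
        cfg = CorpusConfig(seed=9, papers_per_year=20, years=(2010, 2018),
                           not_reported_rate=0.10)
        truth = generate_corpus(cfg, tmp_path / "c")
        with open(tmp_path / "c" / "ancestry.tsv", newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        nr_country = sum(
            r["COUNTRY OF RECRUITMENT"].strip().lower() == "not reported"
            for r in rows)
        nr_ancestry = sum(
            r["BROAD ANCESTRAL CATEGORY"].strip().lower() == "not reported"
            for r in rows)
        assert truth.counts["nr_country_rows"] == nr_country
        assert truth.counts["nr_ancestry_rows"] == nr_ancestry

    def test_degenerate_mixture_recovered_exactly_by_pipeline(self, tmp_path):
        """Single country, single institution, all-male roster: the
        pipeline must recover fraction 1.0 for each."""
        cfg = CorpusConfig(
            seed=3, papers_per_year=4, years=(2015, 2017),
            country_mixture={"Iceland": 1.0},
            recruitment_mixture={"Iceland": 1.0},
            ancestry_mixture={"European": 1.0},
            gender_start={"all": 0.0, "first": 0.0, "senior": 0.0},
            gender_slope_pp={"all": 0.0, "first": 0.0, "senior": 0.0},
            institutions_per_country=1,
            not_reported_rate=0.0, multi_country_rate=0.0,
            abbreviated_name_rate=0.0,
        )
        generate_corpus(cfg, tmp_path / "c")
        result = run_pipeline(RunConfig(
            ancestry_path=str(tmp_path / "c" / "ancestry.tsv"),
            publications_path=str(tmp_path / "c" / "publications.xml"),
            dict_a_path=str(tmp_path / "c" / "name_gender_source_a.tsv"),
            dict_b_path=str(tmp_path / "c" / "name_gender_source_b.tsv"),
            outdir=str(tmp_path / "out"),
        ))
        by_key = {
            (t.attribute, t.disease_area, t.author_category): t.proportions
            for t in result.tables
        }
        for key, expected in [
            (("country", "all_traits", "all"), "Iceland"),
            (("gender", "all_traits", "all"), "men"),
            (("institution", "all_traits", "all"), "deCODE genetics"),
            (("recruitment_country", "all_traits", "none"), "Iceland"),
        ]:
            props = by_key[key]
            assert set(props) == {expected}
            assert props[expected] == pytest.approx(1.0, abs=1e-9)

    def test_realized_mixture_approaches_nominal_with_size(self, tmp_path):
        """Recovered country fractions converge on nominal weights
        within 3 binomial standard errors."""
        mixture = {"United States": 0.5, "Japan": 0.3, "Sweden": 0.2}
        cfg = CorpusConfig(seed=17, papers_per_year=40, years=(2010, 2017),
                           country_mixture=mixture,
                           multi_affiliation_rate=0.0)
        truth = generate_corpus(cfg, tmp_path / "c")
        table = next(
            t for t in truth.tables
            if (t.attribute, t.disease_area, t.author_category)
            == ("country", "all_traits", "all"))
        n_authors = sum(
            len(p.authors) for p in truth.publications)
        for country, weight in mixture.items():
            se = math.sqrt(weight * (1 - weight) / n_authors)
            # per-paper weighting inflates the SE of the pooled share;
            # 3x binomial SE on authors plus slack for the design effect
            assert abs(table.proportions[country] - weight) <= max(
                6 * se, 0.02)


class TestGenerateNameDictionary:
    def test_zero_disagreement_reconcile_equals_source_a(self, tmp_path):
        roster = load_name_roster()
        names = {n: "men" for n in roster["men"][:20]}
        names.update({n: "women" for n in roster["women"][:20]})
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        generate_name_dictionary(names, seed=1, conflict_rate=0.0,
                                 unknown_rate=0.0, path_a=pa, path_b=pb)
        da = NameDictionary.from_tsv(pa, "source_a")
        db = NameDictionary.from_tsv(pb, "source_b")
        for name in names:
            a = lookup_gender(name, None, da)
            b = lookup_gender(name, None, db)
            assert reconcile(a, b) == a.label == names[name]

    def test_realized_disagreement_counts_match_file_scan(self, tmp_path):
        roster = load_name_roster()
        names = {n: "men" for n in roster["men"]}
        names.update({n: "women" for n in roster["women"]})
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        counts = generate_name_dictionary(names, seed=4, conflict_rate=0.2,
                                          unknown_rate=0.2,
                                          path_a=pa, path_b=pb)

        def rows(path):
            with open(path, newline="") as fh:
                return {r["name"]: r["label"]
                        for r in csv.DictReader(fh, delimiter="\t")}

        a, b = rows(pa), rows(pb)
        conflicts = sum(
            1 for n in a
            if "unknown" not in (a[n], b[n]) and a[n] != b[n])
        unknowns = sum(1 for n in a if "unknown" in (a[n], b[n]))
        assert counts["conflict"] == conflicts
        assert counts["unknown"] == unknowns
        assert counts["conflict"] + counts["unknown"] + counts["agree"] \
            == len(names)

    def test_empty_roster_writes_empty_dictionaries(self, tmp_path):
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        counts = generate_name_dictionary({}, seed=1, path_a=pa, path_b=pb)
        assert counts == {"agree": 0, "conflict": 0, "unknown": 0}
        assert pa.read_text().count("\n") == 1  # header only

    def test_conflicts_always_reconcile_to_truth(self, tmp_path):
        roster = load_name_roster()
        names = {n: "women" for n in roster["women"]}
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        generate_name_dictionary(names, seed=2, conflict_rate=0.5,
                                 unknown_rate=0.3, path_a=pa, path_b=pb)
        da = NameDictionary.from_tsv(pa, "source_a")
        db = NameDictionary.from_tsv(pb, "source_b")
        for name, truth in names.items():
            got = reconcile(lookup_gender(name, None, da),
                            lookup_gender(name, None, db))
            assert got == truth
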