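import pytest

from gwasrep import NOT_REPORTED, UNRESOLVED, EmptyTableError
from gwasrep.affiliation_extraction import Affiliation
from gwasrep.catalog_io import AncestryEntry, Author, Publication
from gwasrep.representation_stats import (
    IncomeTable,
    aggregate_area_proportions,
    ancestry_proportions,
    classify_income,
    dominance_scores,
    paper_attribute_proportions,
    recruitment_proportions,
    top_categories,
    ubiquity_scores,
)
from oracles import (
    brute_force_dominance,
    brute_force_ubiquity,
    random_toy_corpus,
)


def _aff(inst, country="X"):
    return Affiliation(raw_text="", institution=inst, country=country)


def _pub(author_affs, **kw):
    authors = [
        Author("A%d" % i, "S", i + 1, affiliations=[_aff(*a) for a in affs])
        for i, affs in enumerate(author_affs)
    ]
    for i in kw.get("joint_first", ()):
        authors[i].joint_first = True
    return Publication("1", 2015, authors)


class TestPaperAttributeProportions:
    def test_two_level_weighting_splits_across_affiliations(self):
        pub = _pub([[("X",)], [("X",), ("Y",)]])
        props = paper_attribute_proportions(pub, "institution")
        assert props == {"X": 0.75, "Y": 0.25}

    def test_degenerate_single_country_paper(self):
        pub = _pub([[("I", "Sweden")]] * 4)
        props = paper_attribute_proportions(pub, "country")
        assert props == {"Sweden": 1.0}

    def test_joint_first_authors_share_position_weight(self):
        pub = _pub(
            [[("I1", "United States")], [("I2", "United Kingdom")],
             [("I3", "Japan")]],
            joint_first=(0, 1),
        )
        props = paper_attribute_proportions(pub, "country", "first")
        assert props == {"United States": 0.5, "United Kingdom": 0.5}

    def test_author_without_affiliation_counts_as_unresolved(self):
        pub = _pub([[("X",)], []])
        props = paper_attribute_proportions(pub, "institution")
        assert props == {"X": 0.5, UNRESOLVED: 0.5}

    def test_gender_denominator_excludes_excluded_authors(self):
        pub = _pub([[("X",)], [("X",)], [("X",)]])
        pub.authors[0].gender = "women"
        pub.authors[1].gender = "men"
        pub.authors[2].gender = "excluded"
        props = paper_attribute_proportions(pub, "gender")
        assert props == {"women": 0.5, "men": 0.5}

    def test_all_excluded_is_an_error(self):
        pub = _pub([[("X",)]])
        pub.authors[0].gender = "excluded"
        with pytest.raises(EmptyTableError):
            paper_attribute_proportions(pub, "gender")


class TestAggregateAreaProportions:
    def test_mean_over_papers(self):
        table = aggregate_area_proportions(
            [{"X": 0.5, "Y": 0.5}, {"X": 0.2, "Y": 0.8}])
        assert table.proportions["X"] == pytest.approx(0.35, abs=1e-15)
        assert table.n_basis == 2

    def test_single_paper_is_identity(self):
        pm = {"X": 0.3, "Y": 0.7}
        table = aggregate_area_proportions([pm])
        assert table.proportions == pm

    def test_category_absent_from_all_papers_is_absent_not_crash(self):
        table = aggregate_area_proportions([{"X": 1.0}])
        assert table.proportions.get("Z", 0.0) == 0.0


class TestDominanceAndUbiquity:
    def test_dominance_matches_hand_example(self):
        pubs = [
            _pub([[("X",)], [("X",)]]),       # X fraction 1.0? no: both X
            _pub([[("X",)], [("Y",)], [("Y",)], [("Y",)], [("Y",)]]),
        ]
        scores = dominance_scores(pubs)
        assert scores["X"] == pytest.approx((1.0 + 0.2) / 2, abs=1e-15)

    def test_single_paper_single_institution_dominates_fully(self):
        assert dominance_scores([_pub([[("X",)]] * 3)]) == {"X": 1.0}

    def test_ubiquity_counts_papers_not_authors(self):
        pubs = [
            _pub([[("X",)], [("X",)], [("W",)]]),
            _pub([[("X",)]]),
        ]
        scores = ubiquity_scores(pubs)
        assert scores["X"] == 1.0
        assert scores["W"] == 0.5
        assert scores.get("Z", 0.0) == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_scores_match_exact_rational_enumeration(self, seed):
        pubs = random_toy_corpus(seed)
        for category in ("all", "first", "senior"):
            dom = dominance_scores(pubs, category)
            brute = brute_force_dominance(pubs, category)
            assert set(dom) == set(brute)
            for inst in brute:
                assert abs(dom[inst] - float(brute[inst])) <= 1e-12
            ubi = ubiquity_scores(pubs, category)
            brute_u = brute_force_ubiquity(pubs, category)
            assert set(ubi) == set(brute_u)
            for inst in brute_u:
                assert abs(ubi[inst] - float(brute_u[inst])) <= 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_positive_dominance_implies_ubiquity_floor(self, seed):
        pubs = random_toy_corpus(seed)
        dom = dominance_scores(pubs)
        ubi = ubiquity_scores(pubs)
        for inst, score in dom.items():
            if inst != UNRESOLVED and score > 0:
                assert ubi[inst] >= 1.0 / len(pubs) - 1e-15

    @pytest.mark.parametrize("seed", range(10))
    def test_dominance_fractions_conserve_mass(self, seed):
        pubs = random_toy_corpus(seed)
        assert sum(dominance_scores(pubs).values()) == pytest.approx(
            1.0, abs=1e-9)


def _entry(n, countries, ancestry="European", stage="discovery", sid="G1"):
    return AncestryEntry(sid, "1", stage, n, ancestry, countries)


class TestParticipantProportions:
    def test_equal_share_rule_for_multi_country_entries(self):
        table, _ = recruitment_proportions(
            [_entry(300, ["United Kingdom", "Japan", "Brazil"])])
        assert table.proportions == {
            "United Kingdom": pytest.approx(1 / 3),
            "Japan": pytest.approx(1 / 3),
            "Brazil": pytest.approx(1 / 3),
        }

    def test_quotient_against_total_included(self):
        table, _ = recruitment_proportions(
            [_entry(900, ["United Kingdom"]), _entry(100, ["United States"])])
        assert table.proportions == {
            "United Kingdom": 0.9, "United States": 0.1}
        assert table.n_basis == 1000

    def test_not_reported_excluded_and_counted(self):
        table, excluded = recruitment_proportions(
            [_entry(500, ["United Kingdom"]), _entry(500, NOT_REPORTED)])
        assert table.proportions == {"United Kingdom": 1.0}
        assert excluded == 500

    def test_all_not_reported_is_empty_table_error(self):
        with pytest.raises(EmptyTableError):
            recruitment_proportions([_entry(10, NOT_REPORTED)])

    def test_ancestry_quotients(self):
        entries = [
            _entry(910, ["X"], "European"),
            _entry(49, ["X"], "East Asian"),
            _entry(41, ["X"], "Other admixed ancestry"),
        ]
        table, _ = ancestry_proportions(entries)
        assert table.proportions == {
            "European": 0.91, "East Asian": 0.049,
            "Other admixed ancestry": 0.041}

    def test_discovery_and_replication_summed_per_study(self):
        entries = [
            _entry(100, ["X"], "European", "discovery"),
            _entry(100, ["X"], "European", "replication"),
        ]
        table, _ = ancestry_proportions(entries)
        assert table.n_basis == 200
        discovery_only, _ = ancestry_proportions(
            entries, stages=("discovery",))
        assert discovery_only.n_basis == 100

    @pytest.mark.parametrize("factor", [2, 10, 1000])
    def test_scale_invariance(self, factor):
        entries = [_entry(300, ["A", "B"]), _entry(700, ["C"])]
        scaled = [
            _entry(e.n_individuals * factor, e.recruitment_countries)
            for e in entries
        ]
        t1, _ = recruitment_proportions(entries)
        t2, _ = recruitment_proportions(scaled)
        for c in t1.proportions:
            assert t2.proportions[c] == pytest.approx(
                t1.proportions[c], abs=1e-12)


class TestIncome:
    def test_snapshot_lookup(self, income_table):
        assert classify_income("Sweden", income_table) == "HIC"
        assert classify_income("China", income_table) == "UMIC"
        assert classify_income("Ethiopia", income_table) == "LIC"

    def test_unresolved_propagates(self, income_table):
        assert classify_income(UNRESOLVED, income_table) == UNRESOLVED

    def test_lookup_is_a_function(self):
        table = IncomeTable({"X": "HIC"})
        assert {classify_income("X", table) for _ in range(3)} == {"HIC"}


class TestTopCategories:
    def test_ties_broken_alphabetically_after_score(self):
        props = {"B": 0.2, "A": 0.2, "C": 0.6}
        assert top_categories(props, 2) == [("C", 0.6), ("A", 0.2)]
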