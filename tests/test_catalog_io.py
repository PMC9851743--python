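import warnings

import pytest

from gwasrep import NOT_REPORTED, ALL_TRAITS, CatalogFormatError, RecordError
from gwasrep.catalog_io import (
    Author,
    Publication,
    StudyRecord,
    assign_author_positions,
    map_disease_areas,
    read_ancestry_table,
    read_publication_xml,
    write_ancestry_table,
    write_publication_xml,
)

HEADER = ("STUDY ACCESSION\tPUBMEDID\tSTAGE\tNUMBER OF INDIVIDUALS\t"
          "BROAD ANCESTRAL CATEGORY\tCOUNTRY OF RECRUITMENT")


def _write(tmp_path, rows, header=HEADER):
    path = tmp_path / "ancestry.tsv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestReadAncestryTable:
    def test_toy_file_row_and_study_counts(self, tmp_path):
        path = _write(tmp_path, [
            "GCST1\t100\tdiscovery\t500\tEuropean\tSweden",
            "GCST1\t100\treplication\t300\tEuropean\tSweden",
            "GCST2\t101\tdiscovery\t200\tEast Asian\tJapan",
        ])
        table = read_ancestry_table(path)
        assert len(table.entries) == 3
        assert len({e.study_id for e in table.entries}) == 2
        assert table.accounted()

    def test_not_reported_country_is_sentinel_not_empty(self, tmp_path):
        path = _write(tmp_path, [
            "GCST1\t100\tdiscovery\t500\tEuropean\tNot Reported",
        ])
        entry = read_ancestry_table(path).entries[0]
        assert entry.recruitment_countries == NOT_REPORTED
        assert entry.recruitment_countries != []

    def test_multi_country_field_split_on_comma(self, tmp_path):
        path = _write(tmp_path, [
            "GCST1\t100\tdiscovery\t300\tEuropean\tU.K., Japan, Brazil",
        ])
        entry = read_ancestry_table(path).entries[0]
        assert entry.recruitment_countries == ["U.K.", "Japan", "Brazil"]

    def test_missing_mandatory_column_names_it(self, tmp_path):
        bad = HEADER.replace("\tSTAGE", "")
        path = _write(tmp_path, ["GCST1\t100\t500\tEuropean\tSweden"], bad)
        with pytest.raises(CatalogFormatError, match="STAGE"):
            read_ancestry_table(path)

    def test_unparseable_sample_size_reported_not_dropped_silently(
            self, tmp_path):
        path = _write(tmp_path, [
            "GCST1\t100\tdiscovery\tn/a\tEuropean\tSweden",
            "GCST2\t101\tdiscovery\t200\tEuropean\tSweden",
        ])
        table = read_ancestry_table(path)
        assert len(table.entries) == 1
        assert [i.reason for i in table.issues] == ["unparseable_sample_size"]
        assert table.accounted()

    def test_duplicate_rows_warn_but_are_kept(self, tmp_path):
        row = "GCST1\t100\tdiscovery\t500\tEuropean\tSweden"
        path = _write(tmp_path, [row, row])
        with pytest.warns(UserWarning, match="duplicate"):
            table = read_ancestry_table(path)
        assert len(table.entries) == 2

    def test_round_trip_preserves_records(self, tmp_path, small_corpus):
        table = read_ancestry_table(small_corpus["dir"] / "ancestry.tsv")
        out = tmp_path / "again.tsv"
        write_ancestry_table(table, out)
        again = read_ancestry_table(out)
        assert again.entries == table.entries
        assert again.studies == table.studies


PUB_XML = """<?xml version='1.0' encoding='UTF-8'?>
<publications>
  <publication pmid="1" year="2016">
    <authors>
      <author joint_first="yes"><given_name>Anna</given_name>
        <surname>Smith</surname>
        <affiliation>Lund University, Malmo, Sweden</affiliation></author>
      <author joint_first="yes"><given_name>Erik</given_name>
        <surname>Olsen</surname></author>
      <author><given_name>Mei</given_name><surname>Chen</surname></author>
    </authors>
  </publication>
  <publication pmid="2" year="2010" dialect="pre2014">
    <author_block>Anna Smith 1,2†; Bob Jones 2</author_block>
    <affiliation_block>1 Univ X, Boston, United States; 2 Univ Y, Oslo, Norway</affiliation_block>
  </publication>
</publications>
"""


class TestReadPublicationXml:
    def test_order_and_ordinals_preserved(self, tmp_path):
        path = tmp_path / "pubs.xml"
        path.write_text(PUB_XML, encoding="utf-8")
        pubs = read_publication_xml(path)
        assert len(pubs) == 2
        for pub in pubs:
            assert [a.ordinal for a in pub.authors] == list(
                range(1, len(pub.authors) + 1))

    def test_joint_first_flags_on_both_marked_authors(self, tmp_path):
        path = tmp_path / "pubs.xml"
        path.write_text(PUB_XML, encoding="utf-8")
        structured, legacy = read_publication_xml(path)
        assert [a.joint_first for a in structured.authors] == [
            True, True, False]
        assert legacy.authors[0].joint_first  # the dagger glyph
        assert not legacy.authors[1].joint_first

    def test_legacy_blocks_kept_verbatim(self, tmp_path):
        path = tmp_path / "pubs.xml"
        path.write_text(PUB_XML, encoding="utf-8")
        legacy = read_publication_xml(path)[1]
        assert legacy.author_block == "Anna Smith 1,2†; Bob Jones 2"
        assert legacy.affiliation_block.startswith("1 Univ X, Boston")
        assert legacy.authors[0].superscripts == [1, 2]

    def test_zero_author_record_is_an_error(self, tmp_path):
        path = tmp_path / "pubs.xml"
        path.write_text(
            "<publications><publication pmid='9' year='2015'>"
            "<authors/></publication></publications>")
        with pytest.raises(RecordError, match="zero authors"):
            read_publication_xml(path)

    def test_malformed_xml_is_a_format_error(self, tmp_path):
        path = tmp_path / "pubs.xml"
        path.write_text("<publications><publication>")
        with pytest.raises(CatalogFormatError):
            read_publication_xml(path)

    def test_round_trip(self, tmp_path):
        path = tmp_path / "pubs.xml"
        path.write_text(PUB_XML, encoding="utf-8")
        pubs = read_publication_xml(path)
        out = tmp_path / "again.xml"
        write_publication_xml(pubs, out)
        assert read_publication_xml(out) == pubs


class TestMapDiseaseAreas:
    MAPPING = {"EFO:A": {"diabetes and CKD"},
               "EFO:B": {"diabetes and CKD", "cardiovascular diseases"}}

    def test_single_area_plus_all_traits(self):
        study = StudyRecord("GCST1", "1", 2015, {"EFO:A"})
        mapped = map_disease_areas(study, self.MAPPING)
        assert mapped.disease_areas == {"diabetes and CKD", ALL_TRAITS}

    def test_multi_area_membership_all_traits_once(self):
        study = StudyRecord("GCST1", "1", 2015, {"EFO:B"})
        mapped = map_disease_areas(study, self.MAPPING)
        assert mapped.disease_areas == {
            "diabetes and CKD", "cardiovascular diseases", ALL_TRAITS}

    def test_unmapped_study_excluded_and_logged(self):
        log = []
        study = StudyRecord("GCST1", "1", 2015, {"EFO:ZZZ"})
        mapped = map_disease_areas(study, self.MAPPING, log)
        assert mapped.disease_areas == set()
        assert log == [("GCST1", "no_efo_match")]


def _pub(n, joint_first=(), joint_last=()):
    authors = [
        Author("A%d" % i, "S%d" % i, i + 1,
               joint_first=i in joint_first, joint_last=i in joint_last)
        for i in range(n)
    ]
    return Publication("1", 2015, authors)


class TestAssignAuthorPositions:
    def test_plain_list_first_and_last(self):
        pub = _pub(3)
        pos = assign_author_positions(pub)
        assert pos["first"] == [pub.authors[0]]
        assert pos["senior"] == [pub.authors[2]]
        assert pos["all"] == pub.authors

    def test_joint_first_marks_extend_first_set(self):
        pub = _pub(4, joint_first={0, 1})
        pos = assign_author_positions(pub)
        assert pos["first"] == pub.authors[:2]

    def test_single_author_fills_all_three_roles(self):
        pub = _pub(1)
        pos = assign_author_positions(pub)
        assert pos["first"] == pos["senior"] == pos["all"] == pub.authors

    def test_first_and_senior_nonempty_subsets_of_all(self, small_corpus):
        for pub in small_corpus["truth"].publications:
            pos = assign_author_positions(pub)
            assert len(pos["first"]) >= 1 and len(pos["senior"]) >= 1
            assert set(id(a) for a in pos["first"] + pos["senior"]) <= set(
                id(a) for a in pos["all"])
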