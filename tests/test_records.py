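import textwrap

import pytest

from seqdup.records import (
    MergedGroup,
    NucleotideRecord,
    ParseError,
    ValidationError,
    expand_groups,
    read_fasta,
    read_genbank_flat,
    read_group_table,
    submitter_overlap,
    write_fasta,
)

GENBANK_MINIMAL = """\
LOCUS       TESTREC1                  12 bp    DNA     linear   PRI 01-JAN-2000
DEFINITION  Homo sapiens chromosome 5 clone, WORKING DRAFT SEQUENCE, 3
            unordered pieces.
ACCESSION   TESTREC1
VERSION     TESTREC1.2
SOURCE      Homo sapiens
  ORGANISM  Homo sapiens
            Eukaryota.
REFERENCE   1  (bases 1 to 12)
  AUTHORS   Smith,J.
  TITLE     Direct Submission
  JOURNAL   Unpublished
REFERENCE   2  (bases 1 to 12)
  AUTHORS   Smith,J., Lee,K.
  TITLE     Direct Submission
  JOURNAL   Unpublished
ORIGIN
        1 acgtacgtac gt
//
"""

GENBANK_NO_ORIGIN = """\
LOCUS       TESTREC2                  12 bp    DNA     linear   PRI 01-JAN-2000
DEFINITION  Test record without sequence.
ACCESSION   TESTREC2
VERSION     TESTREC2.1
//
"""


def test_read_fasta_parses_headers_and_uppercases(tmp_path):
    path = tmp_path / "in.fasta"
    path.write_text(">X1 organism=Homo_sapiens def=test\nacgt\n")
    (rec,) = read_fasta(path)
    assert rec.accession == "X1"
    assert rec.sequence == "ACGT"
    assert rec.organism == "Homo sapiens"
    assert rec.definition == "test"


def test_read_fasta_empty_file_gives_empty_collection(tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    assert read_fasta(path) == []


def test_read_fasta_rejects_non_iupac_character(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">X1\nACJT\n")
    with pytest.raises(ParseError, match="X1.*J"):
        read_fasta(path)


def test_fasta_round_trip_preserves_accession_and_sequence(tmp_path):
    records = [
        NucleotideRecord(accession=f"R{i}", sequence=seq, organism="Danio rerio",
                         definition="clone x")
        for i, seq in enumerate(["ACGT" * 30, "TTTTGGGG", "ACGTN"])
    ]
    path = tmp_path / "round.fasta"
    write_fasta(records, path)
    back = read_fasta(path)
    assert [(r.accession, r.sequence) for r in back] == [
        (r.accession, r.sequence) for r in records
    ]
    assert all(r.organism == "Danio rerio" for r in back)


def test_u_mapped_to_t_at_parse(tmp_path):
    path = tmp_path / "rna.fasta"
    path.write_text(">X1\nacgu\n")
    (rec,) = read_fasta(path)
    assert rec.sequence == "ACGT"


def test_read_genbank_definition_and_author_union(tmp_path):
    path = tmp_path / "rec.gb"
    path.write_text(GENBANK_MINIMAL)
    (rec,) = read_genbank_flat(path)
    assert rec.accession == "TESTREC1"
    assert rec.version == 2
    # multi-line DEFINITION joined with single spaces (terminal period is
    # stripped by the flat-file parser's convention)
    assert rec.definition == (
        "Homo sapiens chromosome 5 clone, WORKING DRAFT SEQUENCE, 3 "
        "unordered pieces"
    )
    assert rec.submitters == {"Smith,J.", "Lee,K."}
    assert rec.organism == "Homo sapiens"
    assert rec.sequence == "ACGTACGTACGT"


def test_read_genbank_missing_origin_is_parse_error(tmp_path):
    path = tmp_path / "noseq.gb"
    path.write_text(GENBANK_NO_ORIGIN)
    with pytest.raises(ParseError, match="ORIGIN|malformed"):
        read_genbank_flat(path)


def _write_group_table(tmp_path, rows):
    path = tmp_path / "groups.tsv"
    header = "group_id\texemplar_accession\tmember_accession\torganism"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


def test_read_group_table_groups_rows(tmp_path):
    path = _write_group_table(
        tmp_path,
        ["g1\tE1\tD1\tHomo sapiens", "g1\tE1\tD2\tHomo sapiens"],
    )
    (group,) = read_group_table(path)
    assert group.exemplar_accession == "E1"
    assert group.member_accessions == ("D1", "D2")
    assert group.n_records == 3


def test_read_group_table_rejects_self_merge(tmp_path):
    path = _write_group_table(tmp_path, ["g1\tE1\tE1\tHomo sapiens"])
    with pytest.raises(ValidationError):
        read_group_table(path)


def test_read_group_table_rejects_duplicate_member_rows(tmp_path):
    path = _write_group_table(
        tmp_path, ["g1\tE1\tD1\tHomo sapiens", "g1\tE1\tD1\tHomo sapiens"]
    )
    with pytest.raises(ValidationError):
        read_group_table(path)


def test_three_groups_totalling_nine_records(tmp_path):
    rows = [
        "g1\tE1\tA1\tX x",
        "g2\tE2\tB1\tX x",
        "g2\tE2\tB2\tX x",
        "g3\tE3\tC1\tX x",
        "g3\tE3\tC2\tX x",
        "g3\tE3\tC3\tX x",
    ]
    groups = read_group_table(_write_group_table(tmp_path, rows))
    assert len(groups) == 3
    assert sum(g.n_records for g in groups) == 9


def _records(*accs):
    return {
        acc: NucleotideRecord(accession=acc, sequence="ACGTACGT") for acc in accs
    }


def test_expand_groups_pair_count_is_member_total():
    groups = [
        MergedGroup("g1", "E1", ("A1", "A2"), "Homo sapiens"),
        MergedGroup("g2", "E2", ("B1",), "Bos taurus"),
    ]
    pairs = expand_groups(groups, _records("E1", "A1", "A2", "E2", "B1"))
    assert len(pairs) == 3
    assert {p.group_id for p in pairs} == {"g1", "g2"}
    assert pairs[0].organism == "Homo sapiens"


def test_expand_groups_scales_to_collection_bookkeeping():
    """1620 groups whose member counts sum to 1660 expand to 1660 pairs."""
    groups = []
    accs = []
    for i in range(1620):
        k = 2 if i < 40 else 1  # 40 groups with two members, rest with one
        members = tuple(f"D{i}_{j}" for j in range(k))
        groups.append(MergedGroup(f"g{i}", f"E{i}", members, "Xenopus laevis"))
        accs.extend([f"E{i}", *members])
    pairs = expand_groups(groups, _records(*accs))
    assert len(pairs) == 1660


def test_expand_groups_missing_accession_named_in_error():
    groups = [MergedGroup("g1", "E1", ("GHOST",), "X x")]
    with pytest.raises(ValidationError, match="GHOST"):
        expand_groups(groups, _records("E1"))


@pytest.mark.parametrize(
    "a_subs,b_subs,shared,same",
    [
        ({"Smith,J."}, {"smith, j."}, 1, True),
        ({"Smith,J."}, {"Lee,K."}, 0, False),
        (set(), {"Lee,K."}, 0, False),
        ({"Smith,J.", "Lee,K."}, {"LEE, K.", "Chen,X."}, 1, True),
    ],
)
def test_submitter_overlap_normalizes_names(a_subs, b_subs, shared, same):
    a = NucleotideRecord("A", "ACGT", submitters=frozenset(a_subs))
    b = NucleotideRecord("B", "ACGT", submitters=frozenset(b_subs))
    cmp = submitter_overlap(a, b)
    assert cmp.shared_count == shared
    assert cmp.same_submitter is same
    assert cmp.shared_count <= cmp.union_count
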