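"""Masking and SNP culling: the hand-worked fixture, accounting, formats."""

import numpy as np
import pytest

from coaldate import (
    AlignmentMatrix,
    RecombinationInterval,
    load_alignment,
    load_intervals,
    mask_and_cull,
    write_snp_matrix,
)
from coaldate.errors import AlignmentError, IntervalError, InvalidParameterError


@pytest.fixture()
def worked_alignment():
    """4 taxa x 10 columns with variant columns exactly at {2, 4, 7} (1-based)."""
    seqs = {
        "taxonA": "AACGTACGTA",
        "taxonB": "ATCGTACGTA",
        "taxonC": "AACATAGGTA",
        "taxonD": "AACGTAGGTA",
    }
    return AlignmentMatrix.from_sequences(list(seqs), list(seqs.values()))


def test_worked_fixture_masks_column_four(worked_alignment):
    """One interval (taxonA, 3, 5) removes variant column 4; {2, 7} remain."""
    snp, report = mask_and_cull(
        worked_alignment, [RecombinationInterval("taxonA", 3, 5)]
    )
    assert report.kept_coordinates == [2, 7]
    assert snp.length == 2
    assert snp.sequence("taxonA") == "AC"
    assert snp.sequence("taxonB") == "TC"
    assert report.recombination_fraction == pytest.approx(0.3)


def test_no_intervals_identical_rows_yield_zero_snps():
    aln = AlignmentMatrix.from_sequences(["a", "b"], ["ACGT", "ACGT"])
    snp, report = mask_and_cull(aln, [])
    assert snp.length == 0
    assert report.n_invariant == 4


def test_ambiguous_column_removed_even_if_variant():
    aln = AlignmentMatrix.from_sequences(["a", "b", "c"], ["ANG", "ACG", "ATG"])
    snp, report = mask_and_cull(aln, [], drop_incomplete=True)
    assert snp.length == 0
    assert report.n_incomplete == 1
    # same column kept when incomplete sites are tolerated: C vs T is variant
    snp2, _ = mask_and_cull(aln, [], drop_incomplete=False)
    assert snp2.length == 1


def test_gaps_and_lowercase_handling():
    aln = AlignmentMatrix.from_sequences(["a", "b"], ["a-cg", "atcg"])
    snp, report = mask_and_cull(aln, [])
    # column 2 has a gap (missing); lowercase a/t etc. are valid bases
    assert report.n_incomplete == 1
    assert snp.length == 0  # no variant complete column remains


def test_column_accounting_reconciles(worked_alignment):
    for intervals in ([], [RecombinationInterval("taxonA", 1, 6)]):
        _, report = mask_and_cull(worked_alignment, intervals)
        assert report.reconciles()


def test_idempotence_on_own_output(worked_alignment):
    snp, report = mask_and_cull(worked_alignment, [RecombinationInterval("taxonA", 3, 5)])
    again, report2 = mask_and_cull(snp, [])
    assert again.length == snp.length
    assert report2.kept == snp.length
    np.testing.assert_array_equal(again.data, snp.data)


def test_out_of_bounds_interval_reports_row():
    aln = AlignmentMatrix.from_sequences(["a", "b"], ["ACGT", "ACGA"])
    iv = RecombinationInterval("a", 2, 99, row=5)
    with pytest.raises(IntervalError, match="row 5"):
        mask_and_cull(aln, [iv])
    with pytest.raises(IntervalError):
        RecombinationInterval("a", 0, 3)
    with pytest.raises(IntervalError):
        RecombinationInterval("a", 5, 3)


def test_unknown_taxon_warns_and_masks_whole_columns(worked_alignment):
    with pytest.warns(UserWarning, match="not in the alignment"):
        snp, report = mask_and_cull(
            worked_alignment, [RecombinationInterval("NODE_7", 1, 10)]
        )
    assert snp.length == 0
    assert report.n_masked == 10
    with pytest.raises(IntervalError):
        mask_and_cull(
            worked_alignment,
            [RecombinationInterval("NODE_7", 1, 10)],
            on_unknown_taxon="error",
        )


def test_internal_node_interval_expanded_via_tree(worked_alignment):
    """With a tree, a node-labelled interval masks only the node's descendants."""
    tree = "((taxonA:1,taxonB:1)NODE_1:1,(taxonC:1.5,taxonD:1.5):0.5);"
    snp, report = mask_and_cull(
        worked_alignment,
        [RecombinationInterval("NODE_1", 1, 10)],
        per_taxon=True,
        tree_newick=tree,
    )
    # taxonA and taxonB are fully N-ed, so every variant column becomes incomplete
    assert snp.length == 0
    assert report.n_masked == 0


def test_per_taxon_masking_preserves_other_rows(worked_alignment):
    snp, report = mask_and_cull(
        worked_alignment,
        [RecombinationInterval("taxonA", 4, 4)],
        per_taxon=True,
    )
    # column 4 now holds an N for taxonA -> dropped as incomplete;
    # columns 2 and 7 are untouched
    assert report.kept_coordinates == [2, 7]


def test_empty_alignment_rejected():
    aln = AlignmentMatrix.from_sequences(["a", "b"], ["", ""])
    with pytest.raises(AlignmentError):
        mask_and_cull(aln, [])


class TestIO:
    def test_load_alignment_round_trip(self, tmp_path, worked_alignment):
        path = tmp_path / "aln.fasta"
        write_snp_matrix(worked_alignment, path, fmt="fasta")
        again = load_alignment(path)
        assert again.labels == worked_alignment.labels
        np.testing.assert_array_equal(again.data, worked_alignment.data)

    def test_load_alignment_ragged_names_offender(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">one\nACGT\n>two\nACG\n")
        with pytest.raises(AlignmentError, match="two"):
            load_alignment(path)

    def test_load_intervals_dialect(self, tmp_path):
        path = tmp_path / "imports.tsv"
        path.write_text("Node\tBeg\tEnd\ntaxonA\t3\t5\nNODE_2\t8\t9\n")
        intervals = load_intervals(path)
        assert [(iv.taxon, iv.begin, iv.end) for iv in intervals] == [
            ("taxonA", 3, 5),
            ("NODE_2", 8, 9),
        ]

    def test_load_intervals_empty_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "imports.tsv"
        path.write_text("Node\tBeg\tEnd\n")
        assert load_intervals(path) == []

    def test_load_intervals_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "imports.tsv"
        path.write_text("Taxon\tStart\tStop\nx\t1\t2\n")
        with pytest.raises(IntervalError):
            load_intervals(path)

    def test_fasta_output_worked_fixture(self, tmp_path, worked_alignment):
        snp, report = mask_and_cull(
            worked_alignment, [RecombinationInterval("taxonA", 3, 5)]
        )
        out = tmp_path / "snp.fasta"
        write_snp_matrix(snp, out, fmt="fasta", coordinates=report.kept_coordinates)
        text = out.read_text()
        assert text.count(">") == 4
        assert "AC" in text
        sidecar = (tmp_path / "snp.fasta.coords.tsv").read_text().splitlines()
        assert sidecar[1:] == ["1\t2", "2\t7"]

    def test_nexus_output_parses_with_correct_dimensions(self, tmp_path, worked_alignment):
        import dendropy

        snp, _ = mask_and_cull(worked_alignment, [RecombinationInterval("taxonA", 3, 5)])
        out = tmp_path / "snp.nex"
        write_snp_matrix(snp, out, fmt="nexus")
        matrix = dendropy.DnaCharacterMatrix.get(path=str(out), schema="nexus")
        assert len(matrix) == 4
        assert matrix.max_sequence_size == 2

    def test_zero_column_matrix_writes_stub_with_warning(self, tmp_path):
        aln = AlignmentMatrix.from_sequences(["a", "b"], ["ACGT", "ACGT"])
        snp, _ = mask_and_cull(aln, [])
        with pytest.warns(UserWarning, match="zero-column"):
            write_snp_matrix(snp, tmp_path / "empty.fasta", fmt="fasta")
        assert (tmp_path / "empty.fasta").read_text() == ">a\n\n>b\n\n"

    def test_unknown_format_lists_options(self, tmp_path, worked_alignment):
        with pytest.raises(InvalidParameterError, match="fasta, nexus, tsv"):
            write_snp_matrix(worked_alignment, tmp_path / "x", fmt="phylip")
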