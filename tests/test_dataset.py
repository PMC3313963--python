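import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import epicore as ec
from epicore.dataset import enumerate_windows, write_epitope_table, write_fasta
from tests.conftest import random_peptides


# ---------------------------------------------------------------------------
# table / FASTA ingest


def _write(tmp_path, text, name="epitopes.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


def test_read_epitope_table_valid_row(tmp_path):
    path = _write(
        tmp_path,
        "protein_id\tstart\tend\tpeptide\thaplotype\n"
        "PROT1\t46\t60\tERQNGVLNSWTDQDS\tI-Ag7\n",
    )
    (rec,) = ec.read_epitope_table(path)
    assert (rec.protein_id, rec.start, rec.end) == ("PROT1", 46, 60)
    assert rec.peptide == "ERQNGVLNSWTDQDS" and len(rec) == 15
    assert rec.haplotype == "I-Ag7"


def test_read_epitope_table_rejects_bad_rows_with_line_numbers(tmp_path, caplog):
    path = _write(
        tmp_path,
        "protein_id\tstart\tend\tpeptide\n"
        "P1\t46\t60\tERQNGVLNSWTDQDS\n"
        "P2\t10\t20\tSHORTPEP\n"  # span says 11 aa, peptide has 8
        "P3\t5\t2\tACDEFGHIK\n",  # malformed span
    )
    with caplog.at_level("WARNING"):
        records = ec.read_epitope_table(path)
    assert len(records) == 1
    assert "line 3" in caplog.text and "line 4" in caplog.text


def test_read_epitope_table_missing_column_raises(tmp_path):
    path = _write(tmp_path, "protein_id\tstart\tpeptide\nP1\t1\tACDEFGHIK\n")
    with pytest.raises(ValueError, match="end"):
        ec.read_epitope_table(path)


def test_read_epitope_table_empty_inputs_warn(tmp_path, caplog):
    with caplog.at_level("WARNING"):
        assert ec.read_epitope_table(_write(tmp_path, "", "a.tsv")) == []
        assert (
            ec.read_epitope_table(
                _write(tmp_path, "protein_id\tstart\tend\tpeptide\n", "b.tsv")
            )
            == []
        )


def test_fasta_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    proteins = {
        "P1": "".join(rng.choice(list(ec.AMINO_ACIDS), size=150)),
        "P2": "".join(rng.choice(list(ec.AMINO_ACIDS), size=45)),
    }
    path = tmp_path / "p.fasta"
    write_fasta(path, proteins)
    assert ec.read_fasta(path) == proteins


def test_epitope_table_round_trip(tmp_path):
    eps = [ec.EpitopeRecord("P1", 3, 13, "ACDEFGHIKLM", "HLA-DQ8")]
    path = tmp_path / "e.tsv"
    write_epitope_table(path, eps, header_lines=["provenance"])
    back = ec.read_epitope_table(path)
    assert back == eps


# ---------------------------------------------------------------------------
# negative-set construction


def test_negative_windows_exclude_fully_contained_only():
    # 20-aa protein with all-distinct windows; epitope at 5..15 contains
    # exactly the windows starting at 5, 6, 7.
    protein = "ACDEFGHIKLMNPQRSTVWY"
    epitope = ec.EpitopeRecord("P1", 5, 15, protein[4:15])
    negatives = ec.build_negative_set({"P1": protein}, [epitope])
    starts = sorted(w.start for w in negatives)
    assert starts == [1, 2, 3, 4, 8, 9, 10, 11, 12]
    assert len({w.sequence for w in negatives}) == 9


def test_epitope_covering_whole_protein_leaves_no_negatives():
    protein = "ACDEFGHIKLMNPQRSTVWY"
    epitope = ec.EpitopeRecord("P1", 1, 20, protein)
    assert ec.build_negative_set({"P1": protein}, [epitope]) == []


def test_negative_windows_deduplicate_by_sequence():
    # the same 9-mer occurs at two loci; epitope elsewhere keeps both eligible
    protein = "NGVLNSWTD" + "NGVLNSWTD" + "ACDEFGHIK"
    epitope = ec.EpitopeRecord("P1", 19, 27, "ACDEFGHIK")
    negatives = ec.build_negative_set({"P1": protein}, [epitope])
    seqs = [w.sequence for w in negatives]
    assert len(seqs) == len(set(seqs))
    assert sum(1 for s in seqs if s == "NGVLNSWTD") == 1


def test_negative_windows_skip_non_standard_residues():
    protein = "NGVLNSWTDXNGVLNSWTE"
    epitope = ec.EpitopeRecord("P1", 1, 9, "NGVLNSWTD")
    negatives = ec.build_negative_set({"P1": protein}, [epitope])
    assert sorted(w.start for w in negatives) == [11]


def test_missing_protein_accession_is_reported():
    epitope = ec.EpitopeRecord("MISSING1", 1, 9, "NGVLNSWTD")
    with pytest.raises(ValueError, match="MISSING1"):
        ec.build_negative_set({}, [epitope])


def test_window_enumeration_count():
    protein = "ACDEFGHIKLMNPQRSTVWY"
    assert len(enumerate_windows("P", protein)) == len(protein) - 8
    assert enumerate_windows("P", "ACDEFGHI") == []


def test_labeled_set_removes_negatives_identical_to_positives():
    data = ec.LabeledNonamerSet(
        positives=["NGVLNSWTD", "ACDEFGHIK"],
        negatives=["NGVLNSWTD", "KLMNPQRST", "KLMNPQRST"],
    )
    assert data.positives == ["NGVLNSWTD", "ACDEFGHIK"]
    assert data.negatives == ["KLMNPQRST"]


# ---------------------------------------------------------------------------
# hit rule and intersections


def test_contained_prediction_is_a_hit():
    e = ec.EpitopeRecord("P1", 46, 60, "ERQNGVLNSWTDQDS")
    assert ec.epitope_hit(e, [(49, 57)]) is True


def test_overlap_without_containment_is_not_a_hit():
    e = ec.EpitopeRecord("P1", 46, 60, "ERQNGVLNSWTDQDS")
    assert ec.epitope_hit(e, [(40, 48)]) is False
    assert ec.epitope_hit(e, []) is False


@given(st.lists(st.integers(min_value=1, max_value=80), max_size=8))
def test_epitope_hit_is_monotone_in_predictions(starts):
    e = ec.EpitopeRecord("P1", 30, 50, "A" * 21)
    spans = [(s, s + 8) for s in starts]
    base = ec.epitope_hit(e, spans)
    assert ec.epitope_hit(e, spans + [(31, 39)]) is True
    if base:
        assert ec.epitope_hit(e, spans + [(1, 9)]) is True


def test_shared_core_count_set_semantics():
    a = ["NGVLNSWTD", "ACDEFGHIK", "KLMNPQRST"]
    b = ["ACDEFGHIK", "KLMNPQRST", "YYYYYYYYY"]
    assert ec.shared_core_count(a, b) == 2
    assert ec.shared_core_count(a, []) == 0
    assert ec.shared_core_count(a[:2], a) == 2  # subset


def test_shared_epitope_count_uses_sequence_identity():
    a = [ec.EpitopeRecord("P1", 1, 11, "ACDEFGHIKLM")]
    b = [ec.EpitopeRecord("OTHER", 40, 50, "ACDEFGHIKLM")]
    assert ec.shared_epitope_count(a, b) == 1
    assert ec.shared_epitope_count(a, []) == 0


# ---------------------------------------------------------------------------
# frequency table


def test_frequency_table_single_core_is_one_hot():
    table = ec.position_frequency_table(["NGVLNSWTD"])
    assert table.shape == (9, 20)
    assert table.loc[1, "N"] == 1.0 and table.loc[7, "W"] == 1.0
    assert np.allclose(table.sum(axis=1), 1.0)


def test_frequency_table_splits_differing_position():
    table = ec.position_frequency_table(["NGVLNSWTD", "NGVLNSWTE"])
    assert table.loc[9, "D"] == 0.5 and table.loc[9, "E"] == 0.5
    assert table.loc[1, "N"] == 1.0


def test_frequency_table_rows_normalized_on_random_cores():
    rng = np.random.default_rng(8)
    table = ec.position_frequency_table(random_peptides(rng, 200))
    assert np.allclose(table.sum(axis=1), 1.0)


def test_frequency_table_rejects_empty_or_non_nonamer():
    with pytest.raises(ValueError):
        ec.position_frequency_table([])
    with pytest.raises(ValueError):
        ec.position_frequency_table(["SHORT"])
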