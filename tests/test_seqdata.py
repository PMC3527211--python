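"""Alignment I/O, normalization, and the pre-analysis filtering policies."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from invgen import (
    complete_deletion,
    from_sequences,
    mask_het_arms,
    read_bed,
    read_fasta_alignment,
    read_meta_tsv,
    subset,
    write_bed,
    write_fasta_alignment,
)
from invgen.seqdata import AlignmentShapeError, AlphabetError, IntervalSet

from conftest import random_alignment


def test_fasta_round_trip_preserves_records(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(">a\nACGTNACGT-\n>b\nacgtnacgtn\n>c\nAAAAAAAAAA\n")
    aln = read_fasta_alignment(path)
    assert aln.n == 3 and aln.length == 10
    assert aln.sample_ids == ["a", "b", "c"]
    # lowercase is uppercased
    assert aln.sequences[1] == "ACGTNACGTN"
    out = tmp_path / "out.fasta"
    write_fasta_alignment(aln, out)
    again = read_fasta_alignment(out)
    assert again.sequences == aln.sequences and again.sample_ids == aln.sample_ids


def test_unequal_lengths_rejected(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">a\nACGTACGTAC\n>b\nACGTACGTA\n")
    with pytest.raises(AlignmentShapeError):
        read_fasta_alignment(path)


def test_ambiguity_codes_normalized_to_n_with_warning(tmp_path, caplog):
    path = tmp_path / "amb.fasta"
    path.write_text(">a\nACRTA\n>b\nACGTA\n")
    with caplog.at_level("WARNING"):
        aln = read_fasta_alignment(path)
    assert aln.sequences[0] == "ACNTA"
    assert any("ambiguity" in r.message for r in caplog.records)


def test_truly_illegal_character_rejected():
    with pytest.raises(AlphabetError):
        from_sequences(["a"], ["ACG?A"])


def test_complete_deletion_drops_gap_and_n_columns():
    aln = from_sequences(["a", "b"], ["AC-T", "ACGT"])
    clean = complete_deletion(aln)
    assert clean.sequences == ["ACT", "ACT"]
    assert list(clean.column_map) == [0, 1, 3]
    # no gaps anywhere -> identity
    full = from_sequences(["a", "b"], ["ACGT", "ACGA"])
    assert complete_deletion(full).sequences == full.sequences


def test_complete_deletion_matches_bruteforce_and_is_idempotent(rng):
    aln = random_alignment(rng, n=5, L=60)
    clean = complete_deletion(aln)
    expected_cols = [
        c for c in range(aln.length)
        if all(seq[c] not in "N-" for seq in aln.sequences)
    ]
    assert list(clean.column_map) == expected_cols
    for seq, orig in zip(clean.sequences, aln.sequences):
        assert seq == "".join(orig[c] for c in expected_cols)
    twice = complete_deletion(clean)
    assert twice.sequences == clean.sequences


def test_subset_identity_and_selection(rng):
    aln = random_alignment(rng, n=5, L=30)
    assert subset(aln).sequences == aln.sequences
    two = subset(aln, ["s3", "s1"])
    assert two.sample_ids == ["s3", "s1"]
    assert two.sequences == [aln.sequence("s3"), aln.sequence("s1")]
    with pytest.raises(KeyError):
        subset(aln, ["nope"])


def test_subset_composition(rng):
    aln = random_alignment(rng, n=6, L=25)
    x = ["s0", "s2", "s4", "s5"]
    y = ["s2", "s5"]
    direct = subset(aln, y)
    nested = subset(subset(aln, x), y)
    assert nested.sequences == direct.sequences
    assert nested.sample_ids == direct.sample_ids


def test_subset_interval_remaps_coordinates(rng):
    aln = random_alignment(rng, n=3, L=30)
    aln.region = ("X", 100, 130)
    win = subset(aln, interval=(10, 20))
    assert win.region == ("X", 110, 120)
    assert win.sequences == [s[10:20] for s in aln.sequences]


def test_masking_more_samples_never_reveals_columns(rng):
    aln = random_alignment(rng, n=6, L=50)
    fewer = ["s0", "s1", "s2"]
    # complete deletion over more samples removes a superset of columns
    all_kept = set(complete_deletion(aln).column_map)
    fewer_kept = set(complete_deletion(subset(aln, fewer)).column_map)
    assert all_kept <= fewer_kept


@given(st.lists(st.booleans(), min_size=1, max_size=40), st.integers(1, 5))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_mask_het_arms_matches_longest_run_oracle(flags, threshold):
    df = pd.DataFrame(
        dict(
            sample="s", arm="2L", window=range(len(flags)),
            het_fraction=[0.02 if f else 0.0 for f in flags],
        )
    )
    excluded = mask_het_arms(df, run_threshold=threshold, het_fraction_cut=0.005)
    runs = "".join("1" if f else "0" for f in flags).split("0")
    longest = max(len(r) for r in runs)
    assert (("s", "2L") in excluded) == (longest >= threshold)


def test_mask_het_arms_examples():
    keep = pd.DataFrame(
        dict(sample="a", arm="X", window=range(10), het_fraction=[0.001] * 10)
    )
    assert mask_het_arms(keep) == []
    flags = [0.0] * 3 + [0.01] * 4 + [0.0] * 3
    drop = pd.DataFrame(dict(sample="a", arm="X", window=range(10), het_fraction=flags))
    assert mask_het_arms(drop, run_threshold=3) == [("a", "X")]


def test_meta_tsv_validation(tmp_path):
    good = tmp_path / "meta.tsv"
    good.write_text(
        "sample_id\tpopulation\tarm\tIn(1)Be\na\tRG\tX\tinverted\nb\tFR\tX\tstandard\n"
    )
    meta = read_meta_tsv(good)
    assert meta.loc["a", "In(1)Be"] == "inverted"
    bad = tmp_path / "bad.tsv"
    bad.write_text("sample_id\tpopulation\tarm\tInX\na\tRG\tX\tflipped\n")
    with pytest.raises(ValueError, match="arrangement"):
        read_meta_tsv(bad)


def test_bed_round_trip_and_invariants(tmp_path):
    path = tmp_path / "genes.bed"
    path.write_text("2L\t100\t200\tgeneA\n2L\t300\t450\tgeneB\n")
    ivs = read_bed(path, arm_lengths={"2L": 1000})
    assert len(ivs) == 2
    out = tmp_path / "out.bed"
    write_bed(ivs, out)
    assert out.read_text() == path.read_text()
    with pytest.raises(ValueError, match="start < end"):
        IntervalSet(pd.DataFrame(dict(arm=["X"], start=[5], end=[5])))
    with pytest.raises(ValueError, match="exceeds arm"):
        IntervalSet(
            pd.DataFrame(dict(arm=["X"], start=[5], end=[50])),
            arm_lengths={"X": 20},
        )
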