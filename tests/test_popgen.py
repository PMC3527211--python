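"""Summary statistics against hand enumeration and brute-force oracles."""
from itertools import combinations

import numpy as np
import pytest

from invgen import (
    between_group_pi,
    divergence_pair,
    from_sequences,
    hudson_fst,
    stats_suite,
    window_scan,
)
from invgen.popgen import InsufficientSampleError, tajima_d_from

from conftest import random_alignment


@pytest.fixture
def four_singletons():
    # every column carries one singleton T: S=3, all sites singletons
    return from_sequences(["a", "b", "c", "d"], ["AAA", "AAT", "ATA", "TAA"])


def test_stats_suite_hand_example(four_singletons):
    st = stats_suite(four_singletons, "complete")
    assert st.S == 3
    assert st.pi_region == pytest.approx(1.5)
    # theta_W per region = S / a_3 = 3 / (1 + 1/2 + 1/3)
    assert st.theta_w_site * st.L == pytest.approx(3 / (11 / 6), abs=1e-9)
    # frozen from an independent evaluation of Tajima's variance constants
    assert st.tajima_d == pytest.approx(-0.7544510776527732, abs=1e-9)
    # every site already a singleton -> D equals its minimum
    assert st.d_prime == pytest.approx(-1.0)


def test_monomorphic_alignment_flags_undefined():
    st = stats_suite(from_sequences(["a", "b"], ["ACGT", "ACGT"]))
    assert st.S == 0 and st.pi_region == 0
    assert st.tajima_d is None and st.d_prime is None


def test_single_sample_rejected():
    with pytest.raises(InsufficientSampleError):
        stats_suite(from_sequences(["a"], ["ACGT"]))


def test_tajima_sign_matches_pi_minus_theta(rng):
    for _ in range(20):
        aln = random_alignment(rng, n=6, L=40, alphabet="ACGT")
        st = stats_suite(aln)
        if st.S == 0:
            continue
        theta_region = st.theta_w_site * st.L
        assert np.sign(st.tajima_d) == np.sign(st.pi_region - theta_region) or (
            st.pi_region == theta_region and st.tajima_d == 0
        )


def test_pi_equals_mean_pairwise_divergence(rng):
    """pi_region must equal the average of per-pair mismatch counts."""
    for n in (4, 8):
        aln = random_alignment(rng, n=n, L=50, alphabet="ACGT")
        st = stats_suite(aln, "complete")
        pairs = [
            divergence_pair(s1, s2)[1]
            for s1, s2 in combinations(aln.sequences, 2)
        ]
        assert st.pi_region == pytest.approx(np.mean(pairs))


def test_between_group_pi_cases(rng):
    same = from_sequences(["a", "b", "c"], ["ACGT"] * 3)
    region, site = between_group_pi(same, ["a"], ["b", "c"])
    assert region == 0 and site == 0
    fixed = from_sequences(["a", "b"], ["AAAA", "TAAA"])
    region, site = between_group_pi(fixed, ["a"], ["b"])
    assert site == pytest.approx(1 / 4)
    # random 3x2 against brute-force cross-pair enumeration
    aln = random_alignment(rng, n=5, L=30, alphabet="ACGT")
    g1, g2 = ["s0", "s1", "s2"], ["s3", "s4"]
    region, _ = between_group_pi(aln, g1, g2)
    manual = np.mean(
        [
            divergence_pair(aln.sequence(i), aln.sequence(j))[1]
            for i in g1
            for j in g2
        ]
    )
    assert region == pytest.approx(manual)


def test_between_group_requires_disjoint_nonempty():
    aln = from_sequences(["a", "b"], ["AC", "AC"])
    with pytest.raises(ValueError):
        between_group_pi(aln, [], ["a"])
    with pytest.raises(ValueError):
        between_group_pi(aln, ["a"], ["a", "b"])


def test_hudson_fst_hand_enumeration():
    # one site: group1 = {A, A, T}, group2 = {T, T}
    # pi1 = 2/3, pi2 = 0, H_w = 1/3, H_b = 4/6 -> F_ST = 0.5
    aln = from_sequences(list("abcde"), ["A", "A", "T", "T", "T"])
    assert hudson_fst(aln, ["a", "b", "c"], ["d", "e"]) == pytest.approx(0.5)


def test_hudson_fst_limits(rng):
    fixed = from_sequences(list("abcd"), ["AAAA", "AAAA", "TTTT", "TTTT"])
    assert hudson_fst(fixed, ["a", "b"], ["c", "d"]) == pytest.approx(1.0)
    mono = from_sequences(list("abcd"), ["AAAA"] * 4)
    assert hudson_fst(mono, ["a", "b"], ["c", "d"]) is None
    with pytest.raises(ValueError):
        hudson_fst(fixed, ["a"], ["c", "d"])
    # bounded above by 1 whenever defined; not clamped below
    for _ in range(20):
        aln = random_alignment(rng, n=6, L=30, alphabet="ACGT")
        f = hudson_fst(aln, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        if f is not None:
            assert f <= 1.0


def test_window_scan_seg_sites_partitioning(rng):
    aln = random_alignment(rng, n=4, L=400, alphabet="ACGT")
    global_s = stats_suite(aln, "pairwise").S
    for mode, width in (("seg_sites", 25), ("fixed_bp", 60)):
        table = window_scan(aln, mode=mode, width=width)
        assert table["n_sites"].sum() == global_s
        assert list(table["start"])[0] == 0 and list(table["end"])[-1] == aln.length
        # windows are contiguous and non-overlapping
        assert all(
            table["end"].iloc[i] == table["start"].iloc[i + 1]
            for i in range(len(table) - 1)
        )
    seg = window_scan(aln, mode="seg_sites", width=25)
    assert all(seg["n_sites"].iloc[:-1] == 25)
    assert seg["n_sites"].iloc[-1] <= 25


def test_window_counts_arithmetic():
    # 6 segregating sites, width 4 -> windows of 4 and 2
    seqs = ["AAAAAAAAAA", "TTTTTTAAAA"][:]
    aln = from_sequences(["a", "b"], seqs)
    table = window_scan(aln, mode="seg_sites", width=4)
    assert list(table["n_sites"]) == [4, 2]


def test_divergence_pair_examples():
    assert divergence_pair("ACGT", "ACGT") == (4, 0, 0.0)
    s1 = "A" * 52099
    s2 = "T" * 568 + "A" * (52099 - 568)
    aligned, mism, prop = divergence_pair(s1, s2)
    assert (aligned, mism) == (52099, 568)
    assert round(prop, 4) == 0.0109
    # masked sites drop out of the aligned-base count
    masked = "N" * 7 + "ACGT"
    assert divergence_pair("A" * 7 + "ACGT", masked)[0] == 4
    with pytest.raises(ValueError):
        divergence_pair("ACG", "AC")


def test_d_prime_normalization_bounds(rng):
    for _ in range(20):
        aln = random_alignment(rng, n=8, L=60, alphabet="ACGT")
        st = stats_suite(aln)
        if st.S == 0:
            continue
        assert st.d_prime >= -1.0 - 1e-12
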