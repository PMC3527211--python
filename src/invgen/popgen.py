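"""Summary statistics and windowed scans for haplotype alignments.

Implements the region statistics used throughout the breakpoint analyses:
segregating sites S, nucleotide diversity pi (per region and per site),
Watterson's theta, Tajima's D, its rescaled form D', between-group pi,
unweighted Hudson F_ST, and fixed-bp / fixed-segregating-site window scans.

Two missing-data policies are supported.  Breakpoint-region analyses use
complete deletion (every column containing a gap or N anywhere is dropped
first); genome-scan diversity uses pairwise deletion with no sample-size
threshold, where each haplotype pair is compared over the columns at which
both carry a called base.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .seqdata import Alignment, complete_deletion, subset

_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")


class InsufficientSampleError(ValueError):
    pass


@dataclass
class SummaryStats:
    n: int
    L: int
    S: int
    pi_region: float
    pi_site: float
    theta_w_site: float
    tajima_d: float | None
    d_prime: float | None
    deletion_mode: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _valid_mask(matrix: np.ndarray) -> np.ndarray:
    """True where the character is a called base A/C/G/T."""
    return np.isin(matrix, _BASE_BYTES)


def _allele_counts(matrix: np.ndarray) -> np.ndarray:
    """(4, L) counts of A,C,G,T per column, ignoring N and gaps."""
    return np.stack([(matrix == b).sum(axis=0) for b in _BASE_BYTES])


def segregating_columns(matrix: np.ndarray) -> np.ndarray:
    """Boolean mask of columns with >= 2 observed alleles among called bases."""
    counts = _allele_counts(matrix)
    return (counts > 0).sum(axis=0) >= 2


def pairwise_diff_totals(matrix: np.ndarray) -> tuple[int, int]:
    """Sum over all unordered pairs of (mismatch count, compared-column count).

    Pairwise deletion: a column contributes to a pair only when both members
    carry a called base there.
    """
    n = matrix.shape[0]
    valid = _valid_mask(matrix)
    mism = comp = 0
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        comp += int(both.sum())
        mism += int((matrix[i][both] != matrix[j][both]).sum())
    return mism, comp


def harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def tajima_constants(n: int) -> dict[str, float]:
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_d_from(pi_region: float, S: int, n: int) -> float | None:
    """Tajima's D from the region-wide pi and S (None when S = 0)."""
    if S == 0:
        return None
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        # n = 3 degenerates: pi is a deterministic function of S there
        return None
    return (pi_region - S / k["a1"]) / math.sqrt(var)


def d_prime_from(pi_region: float, S: int, n: int) -> float | None:
    """D' = D / |D_min|, D_min evaluated at the all-singleton configuration.

    With every one of the S sites a singleton, pi would be 2S/n; D evaluated
    there is the theoretical minimum for the observed S and n.
    """
    d = tajima_d_from(pi_region, S, n)
    if d is None:
        return None
    d_min = tajima_d_from(2 * S / n, S, n)
    return d / abs(d_min)


def stats_suite(a: Alignment, deletion_mode: str = "complete") -> SummaryStats:
    """The standard per-region summary: n, L, S, pi, theta_W, Tajima's D, D'."""
    if a.n < 2:
        raise InsufficientSampleError("need >= 2 haplotypes")
    if deletion_mode not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion mode {deletion_mode!r}")
    work = complete_deletion(a) if deletion_mode == "complete" else a
    matrix = work.matrix
    if deletion_mode == "complete":
        L = work.length
    else:
        L = int((_valid_mask(matrix).sum(axis=0) >= 2).sum())
    S = int(segregating_columns(matrix).sum())
    mism, _ = pairwise_diff_totals(matrix)
    npairs = a.n * (a.n - 1) // 2
    pi_region = mism / npairs
    pi_site = pi_region / L if L else 0.0
    theta_w_site = (S / harmonic(a.n)) / L if L else 0.0
    return SummaryStats(
        n=a.n, L=L, S=S, pi_region=pi_region, pi_site=pi_site,
        theta_w_site=theta_w_site,
        tajima_d=tajima_d_from(pi_region, S, a.n),
        d_prime=d_prime_from(pi_region, S, a.n),
        deletion_mode=deletion_mode,
    )


def between_group_pi(
    a: Alignment, group1: list[str], group2: list[str],
    deletion_mode: str = "complete",
) -> tuple[float, float]:
    """Mean mismatch count over all cross-group pairs: (per region, per site).

    Per-site value is the ratio of total cross-pair mismatches to total
    cross-pair compared columns.
    """
    if not group1 or not group2:
        raise ValueError("both groups must be non-empty")
    if set(group1) & set(group2):
        raise ValueError("groups must be disjoint")
    work = subset(a, list(group1) + list(group2))
    if deletion_mode == "complete":
        work = complete_deletion(work)
    matrix = work.matrix
    valid = _valid_mask(matrix)
    n1 = len(group1)
    mism = comp = 0
    for i in range(n1):
        for j in range(n1, work.n):
            both = valid[i] & valid[j]
            comp += int(both.sum())
            mism += int((matrix[i][both] != matrix[j][both]).sum())
    npairs = n1 * len(group2)
    pi_region = mism / npairs
    pi_site = mism / comp if comp else float("nan")
    return pi_region, pi_site


def within_group_pi_site(a: Alignment, group: list[str]) -> float:
    """Per-site pi within one group (pairwise deletion, ratio of totals)."""
    work = subset(a, list(group))
    mism, comp = pairwise_diff_totals(work.matrix)
    return mism / comp if comp else float("nan")


def hudson_fst(
    a: Alignment, group1: list[str], group2: list[str]
) -> float | None:
    """Hudson's F_ST = 1 - H_w / H_b, with groups weighted equally.

    H_w is the unweighted mean of the two within-group per-site diversities
    (no sample-size weighting); H_b is the between-group per-site diversity.
    Returns None (undefined) when H_b = 0.  Negative values are reported as
    computed, not clamped.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group requires >= 2 haplotypes")
    pi1 = within_group_pi_site(a, group1)
    pi2 = within_group_pi_site(a, group2)
    _, h_b = between_group_pi(a, group1, group2, deletion_mode="pairwise")
    h_w = (pi1 + pi2) / 2.0
    if not h_b:
        return None
    return 1.0 - h_w / h_b


def divergence_pair(s1: str, s2: str) -> tuple[int, int, float | None]:
    """(aligned_bases, mismatches, proportion) for two pre-aligned sequences.

    A column is aligned when both characters are called bases (A/C/G/T);
    proportion is None when no column is aligned.
    """
    if len(s1) != len(s2):
        raise ValueError("sequences must have equal length")
    x = np.frombuffer(s1.encode(), dtype="S1")
    y = np.frombuffer(s2.encode(), dtype="S1")
    both = np.isin(x, _BASE_BYTES) & np.isin(y, _BASE_BYTES)
    aligned = int(both.sum())
    mism = int((x[both] != y[both]).sum())
    return aligned, mism, (mism / aligned if aligned else None)


def window_scan(
    a: Alignment,
    mode: str = "fixed_bp",
    width: int = 250_000,
    statistic: str = "pi",
    group1: list[str] | None = None,
    group2: list[str] | None = None,
) -> pd.DataFrame:
    """Non-overlapping window scan of pi or F_ST along the alignment.

    ``fixed_bp`` tiles the region in windows of ``width`` alignment columns
    (the last window may be short).  ``seg_sites`` closes each window after
    accumulating exactly ``width`` segregating sites, so per-window S sums to
    the whole-region S.  Columns returned: start, end, n_sites, value (with
    window bounds in reference coordinates when the alignment carries them).
    """
    if statistic not in ("pi", "fst"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "fst" and not (group1 and group2):
        raise ValueError("fst scan requires group1 and group2")
    L = a.length
    bounds: list[tuple[int, int]] = []
    if mode == "fixed_bp":
        for start in range(0, L, width):
            bounds.append((start, min(start + width, L)))
    elif mode == "seg_sites":
        seg = np.flatnonzero(segregating_columns(a.matrix))
        start = 0
        for k in range(width - 1, len(seg), width):
            end = int(seg[k]) + 1
            bounds.append((start, end))
            start = end
        if start < L and (not bounds or len(seg) % width != 0 or len(seg) == 0):
            bounds.append((start, L))
        elif start < L:
            # trailing monomorphic tail folds into the final window
            s0, _ = bounds.pop()
            bounds.append((s0, L))
    else:
        raise ValueError(f"unknown window mode {mode!r}")

    offset = a.region[1] if a.region is not None else 0
    rows = []
    for start, end in bounds:
        win = subset(a, interval=(start, end))
        n_sites = int(segregating_columns(win.matrix).sum())
        if statistic == "pi":
            mism, comp = pairwise_diff_totals(win.matrix)
            value = mism / comp if comp else float("nan")
        else:
            value = hudson_fst(win, group1, group2)
            value = float("nan") if value is None else value
        rows.append(
            dict(start=offset + start, end=offset + end, n_sites=n_sites, value=value)
        )
    return pd.DataFrame(rows, columns=["start", "end", "n_sites", "value"])
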