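"""Hypothesis tests for selection on inversions.

Two procedures: a permutation test asking whether inversion breakpoints fall
inside genic sequences less often than uniformly placed breakpoints would,
and exact binomial tests for sex-ratio segregation distortion in crosses
(K = proportion of female progeny, tested one-sided against the Mendelian
1:1 expectation), with Bonferroni correction and a conservative variant that
charges all pre-adult egg mortality to males.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .seqdata import IntervalSet


@dataclass
class PermutationResult:
    observed_overlap: int
    null_draws: np.ndarray
    p_value: float
    B: int
    seed: int | None
    tail: str


def _merged_arm_intervals(genes: IntervalSet, arm: str, flank: int, arm_len: int):
    """Sorted, merged, flank-extended gene intervals on one arm, clipped."""
    rows = genes.on_arm(arm)
    iv = sorted(
        (max(0, s - flank), min(arm_len, e + flank))
        for s, e in zip(rows["start"], rows["end"])
    )
    merged: list[list[int]] = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    starts = np.array([m[0] for m in merged], dtype=float)
    ends = np.array([m[1] for m in merged], dtype=float)
    return starts, ends


def _points_in(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of positions in half-open merged intervals."""
    if len(starts) == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(positions), dtype=bool)
    out[ok] = positions[ok] < ends[idx[ok]]
    return out


def breakpoint_gene_overlap(
    breakpoints: IntervalSet,
    genes: IntervalSet,
    arm_lengths: dict[str, int],
    flank: int = 0,
) -> int:
    """Count breakpoints (point positions) inside any flank-extended gene."""
    total = 0
    for arm in breakpoints.df["arm"].unique():
        if arm not in arm_lengths:
            raise ValueError(f"breakpoint on undeclared arm {arm!r}")
        pos = breakpoints.on_arm(arm)["start"].to_numpy(dtype=float)
        if (pos < 0).any() or (pos >= arm_lengths[arm]).any():
            raise ValueError(f"breakpoint outside arm {arm!r}")
        starts, ends = _merged_arm_intervals(genes, arm, flank, arm_lengths[arm])
        total += int(_points_in(pos, starts, ends).sum())
    return total


def breakpoint_permutation_test(
    breakpoints: IntervalSet,
    genes: IntervalSet,
    arm_lengths: dict[str, int],
    B: int = 100_000,
    seed: int | None = None,
    flank: int = 0,
    tail: str = "lower",
) -> PermutationResult:
    """Permutation test of breakpoint-gene overlap.

    Each permutation redraws every breakpoint independently and uniformly on
    its own arm.  The add-one estimator is used, so p is never zero:
    lower tail p = (1 + #{null <= observed}) / (B + 1).
    """
    if B < 1:
        raise ValueError("B >= 1 required")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    observed = breakpoint_gene_overlap(breakpoints, genes, arm_lengths, flank)
    rng = np.random.default_rng(seed)
    null = np.zeros(B, dtype=np.int64)
    for arm in breakpoints.df["arm"].unique():
        n_bp = len(breakpoints.on_arm(arm))
        starts, ends = _merged_arm_intervals(genes, arm, flank, arm_lengths[arm])
        pos = rng.uniform(0, arm_lengths[arm], size=(B, n_bp))
        null += _points_in(pos.ravel(), starts, ends).reshape(B, n_bp).sum(axis=1)
    if tail == "lower":
        p = (1 + int((null <= observed).sum())) / (B + 1)
    else:
        p = (1 + int((null >= observed).sum())) / (B + 1)
    return PermutationResult(
        observed_overlap=observed, null_draws=null, p_value=p, B=B, seed=seed,
        tail=tail,
    )


# ---------------------------------------------------------------------------
# Sex-ratio distortion

def sex_ratio_test(females: int, males: int) -> tuple[float, float]:
    """K = females / progeny and the one-sided exact binomial p-value.

    p = P(X >= females | n, 1/2): the probability under Mendelian segregation
    of a female excess at least as large as observed.
    """
    n = females + males
    if n < 1:
        raise ValueError("at least one progeny required")
    if min(females, males) < 0:
        raise ValueError("counts must be non-negative")
    k = females / n
    p = float(stats.binom.sf(females - 1, n, 0.5))
    return k, p


def conservative_egg_test(eggs: int, females: int) -> tuple[float, float]:
    """Distortion test assuming all pre-adult mortality is suffered by males.

    All eggs not yielding adult females are counted as males, so
    K = females / eggs and the exact binomial uses n = eggs.
    """
    if females > eggs:
        raise ValueError("females cannot exceed eggs")
    k = females / eggs
    p = float(stats.binom.sf(females - 1, eggs, 0.5))
    return k, p


def bonferroni_adjust(p_values, m: int) -> np.ndarray:
    """p_adj = min(1, m * p); m must cover the number of tests performed."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def cross_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-role unweighted means of F1 male count, progeny, and K.

    K is averaged across crosses (each cross one observation), not pooled
    over progeny.  ``records`` needs columns role, f1_males, females, males.
    """
    df = records.copy()
    df["progeny"] = df["females"] + df["males"]
    df["K"] = df["females"] / df["progeny"]
    out = (
        df.groupby("role")
        .agg(
            n_crosses=("K", "size"),
            mean_f1_males=("f1_males", "mean"),
            mean_progeny=("progeny", "mean"),
            mean_K=("K", "mean"),
        )
        .reset_index()
    )
    return out


def analyze_crosses(records: pd.DataFrame, bonferroni_m: int | None = None) -> pd.DataFrame:
    """Per-cross K and p, optional Bonferroni adjustment over experimental tests."""
    df = records.copy()
    ks, ps = [], []
    for _, row in df.iterrows():
        k, p = sex_ratio_test(int(row["females"]), int(row["males"]))
        ks.append(k)
        ps.append(p)
    df["K"] = ks
    df["p"] = ps
    if bonferroni_m is not None:
        # the correction covers the family of experimental tests; controls
        # are not part of the tested family
        df["p_bonferroni"] = np.nan
        exp = df["role"] == "experimental" if "role" in df.columns else df.index == df.index
        df.loc[exp, "p_bonferroni"] = bonferroni_adjust(
            df.loc[exp, "p"].to_numpy(), bonferroni_m
        )
    if "eggs" in df.columns:
        egg_k, egg_p = [], []
        for _, row in df.iterrows():
            if pd.notna(row.get("eggs")) and row["eggs"]:
                k, p = conservative_egg_test(int(row["eggs"]), int(row["females"]))
            else:
                k = p = np.nan
            egg_k.append(k)
            egg_p.append(p)
        df["K_egg"] = egg_k
        df["p_egg"] = egg_p
    return df


def read_crosses_tsv(path) -> pd.DataFrame:
    """Cross records: x_line, y_line, role, f1_males, females, males[, eggs]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"x_line", "y_line", "role", "f1_males", "females", "males"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cross table missing columns: {sorted(missing)}")
    if (df[["f1_males", "females", "males"]] < 0).any().any():
        raise ValueError("counts must be non-negative")
    if "eggs" in df.columns:
        have = df["eggs"].notna()
        if (df.loc[have, "females"] + 0 > df.loc[have, "eggs"]).any():
            raise ValueError("females + males cannot exceed eggs")
    return df


def load_inbe_crosses() -> pd.DataFrame:
    """The published In(1)Be distortion cross table.

    Female counts are reconstructed from the printed per-cross K and progeny
    totals as round(K * N); the egg-assay female count is taken from the
    paired adult cross of the same mating.
    """
    with resources.files("invgen.data").joinpath("inbe_crosses.tsv").open() as fh:
        return read_crosses_tsv(fh)
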