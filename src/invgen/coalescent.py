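"""Single-population coalescent with exponential growth and infinite-sites mutation.

Conventions follow ms: time is measured in units of 4*N0 generations, theta is
the population-scaled mutation rate per region (4*N0*mu_region), and the
growth rate alpha is in units of 1/(4*N0) generations with backward population
size N(t) = N0 * exp(-alpha * t).  With k lineages at scaled time t the total
coalescence rate is k*(k-1)*exp(alpha*t) (a per-pair rate of 2 at t = 0), so
E[T_MRCA] = 1 - 1/n and E[pi] = theta at alpha = 0.

Two code paths are provided: a per-replicate path that returns the full
genealogy and 0/1 haplotype matrix (for ms-like output and the synthetic-data
generator), and a vectorized path returning only (S, pi, T_MRCA) per replicate
(the hot loop of rejection ABC).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CoalescentConfig:
    n: int
    theta: float
    alpha: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n >= 2 required")
        if self.theta < 0 or self.alpha < 0:
            raise ValueError("theta and alpha must be non-negative")


@dataclass
class Genealogy:
    """A coalescent tree: nodes 0..n-1 are leaves, node 2n-2 is the root."""

    n: int
    node_times: np.ndarray          # (2n-1,)
    children: np.ndarray            # (2n-1, 2); -1 for leaves

    @property
    def t_mrca(self) -> float:
        return float(self.node_times[-1])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node, (2n-2,)."""
        parent_time = np.empty(2 * self.n - 2)
        for node in range(self.n, 2 * self.n - 1):
            for child in self.children[node]:
                parent_time[child] = self.node_times[node]
        return parent_time - self.node_times[: 2 * self.n - 2]

    @property
    def t_total(self) -> float:
        return float(self.branch_lengths().sum())

    def leaves_below(self, node: int) -> list[int]:
        if node < self.n:
            return [node]
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def rescale(self, t_mrca_target: float) -> "Genealogy":
        """Linearly rescale all node times so the root sits at the target depth."""
        if self.t_mrca <= 0:
            raise ValueError("cannot rescale a degenerate tree")
        factor = t_mrca_target / self.t_mrca
        return Genealogy(self.n, self.node_times * factor, self.children)


@dataclass
class CoalescentSample:
    t_mrca: float
    t_total: float
    haplotypes: np.ndarray      # (n, S) 0/1
    positions: np.ndarray       # (S,) in (0, 1)


def _waiting_time(k: int, alpha: float, t0: float, rng: np.random.Generator) -> float:
    """Time to the next coalescence from scaled time t0 with k lineages.

    Standard time-change inversion of the inhomogeneous rate k(k-1)exp(alpha t);
    evaluated with log1p so large alpha*t never overflows.
    """
    e = rng.exponential()
    rate = k * (k - 1)
    if alpha == 0.0:
        return e / rate
    return np.log1p(alpha * e * np.exp(-alpha * t0) / rate) / alpha


def sample_genealogy(n: int, alpha: float, rng: np.random.Generator) -> Genealogy:
    """Simulate one coalescent genealogy under exponential growth."""
    node_times = np.zeros(2 * n - 1)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += _waiting_time(k, alpha, t, rng)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node_times[nxt] = t
        children[nxt] = (a, b)
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Genealogy(n, node_times, children)


def drop_mutations(
    g: Genealogy, theta: float, rng: np.random.Generator
) -> CoalescentSample:
    """Infinite-sites mutation: Poisson(theta * t_total) mutations on branches.

    Each mutation lands on a branch with probability proportional to its
    length; carriers are the leaves below, so every column has between 1 and
    n-1 carriers.
    """
    lengths = g.branch_lengths()
    t_total = float(lengths.sum())
    n_mut = rng.poisson(theta * t_total) if theta > 0 and t_total > 0 else 0
    haps = np.zeros((g.n, n_mut), dtype=np.int8)
    if n_mut:
        branches = rng.choice(len(lengths), size=n_mut, p=lengths / t_total)
        for col, br in enumerate(branches):
            haps[g.leaves_below(int(br)), col] = 1
    positions = np.sort(rng.uniform(size=n_mut))
    return CoalescentSample(
        t_mrca=g.t_mrca, t_total=t_total, haplotypes=haps, positions=positions
    )


def pi_from_matrix(haps: np.ndarray) -> float:
    """Mean pairwise Hamming distance of a 0/1 haplotype matrix."""
    n = haps.shape[0]
    if haps.shape[1] == 0:
        return 0.0
    counts = haps.sum(axis=0)
    return float((counts * (n - counts)).sum()) / (n * (n - 1) / 2)


def simulate_batch(config: CoalescentConfig, reps: int) -> pd.DataFrame:
    """Replicate simulations; columns (S, pi_region, t_mrca, t_total, alpha, theta)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for _ in range(reps):
        g = sample_genealogy(config.n, config.alpha, rng)
        s = drop_mutations(g, config.theta, rng)
        rows.append(
            dict(
                S=s.haplotypes.shape[1],
                pi_region=pi_from_matrix(s.haplotypes),
                t_mrca=s.t_mrca,
                t_total=s.t_total,
                alpha=config.alpha,
                theta=config.theta,
            )
        )
    return pd.DataFrame(
        rows, columns=["S", "pi_region", "t_mrca", "t_total", "alpha", "theta"]
    )


def batch_s_pi(
    n: int,
    thetas: np.ndarray,
    alphas: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (S, pi_region, t_mrca) for R replicates with per-replicate
    (theta, alpha).

    Equivalent in distribution to sample_genealogy + drop_mutations but tracks
    only leaf counts per lineage, drawing each branch's Poisson mutation count
    at the moment the branch closes.  This is the ABC hot path.
    """
    thetas = np.asarray(thetas, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    R = len(thetas)
    leafcnt = np.ones((R, n), dtype=np.int64)
    birth = np.zeros((R, n))
    t = np.zeros(R)
    S = np.zeros(R, dtype=np.int64)
    pi_num = np.zeros(R)
    rows = np.arange(R)
    growth = alphas > 0
    for k in range(n, 1, -1):
        e = rng.exponential(size=R)
        rate = k * (k - 1)
        dt = np.empty(R)
        dt[~growth] = e[~growth] / rate
        if growth.any():
            a = alphas[growth]
            dt[growth] = np.log1p(a * e[growth] * np.exp(-a * t[growth]) / rate) / a
        t = t + dt
        i = rng.integers(0, k, size=R)
        j = rng.integers(0, k - 1, size=R)
        j = j + (j >= i)
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        for idx in (lo, hi):
            length = t - birth[rows, idx]
            cnt = leafcnt[rows, idx]
            m = rng.poisson(thetas * length)
            S += m
            pi_num += m * cnt * (n - cnt)
        leafcnt[rows, lo] += leafcnt[rows, hi]
        birth[rows, lo] = t
        move = hi < k - 1
        leafcnt[rows[move], hi[move]] = leafcnt[rows[move], k - 1]
        birth[rows[move], hi[move]] = birth[rows[move], k - 1]
    pi = pi_num / (n * (n - 1) / 2)
    return S, pi, t


def ms_like_lines(sample: CoalescentSample) -> list[str]:
    """Render one replicate in ms text form (segsites / positions / haplotypes)."""
    s = sample.haplotypes.shape[1]
    lines = ["//", f"segsites: {s}"]
    if s:
        lines.append("positions: " + " ".join(f"{p:.5f}" for p in sample.positions))
        lines.extend("".join(str(x) for x in row) for row in sample.haplotypes)
    return lines
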