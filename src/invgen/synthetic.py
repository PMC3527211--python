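"""Synthetic breakpoint-region datasets with ground truth.

The generator emulates the statistical structure the inversion analyses
assume, so every pipeline stage can be exercised with a known answer:

* African standard haplotypes from a neutral coalescent at theta_site * L;
* cosmopolitan standard haplotypes as a shallow clade hanging off one African
  haplotype, with within-clade diversity reduced to a configured fraction of
  the African level (the out-of-Africa bottleneck, reduced to the two features
  the origin classifier uses: shared recent ancestry and low diversity);
* inverted haplotypes as a clade founded on one standard haplotype (African
  or cosmopolitan, fixing the true origin), with stem mutations accumulated
  for the requested age and a within-clade genealogy rescaled so its T_MRCA
  corresponds to that age under the same calibration the age estimators use;
* exchange tracts copied from random standard haplotypes into inverted ones;
* indels (contiguous gap runs) and missing data injected last.

Mutations follow infinite sites on distinct columns, so the generated
alignments contain no recurrent mutation; alignment ambiguity is not
simulated (inputs are pre-aligned by construction).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import drop_mutations, sample_genealogy
from .seqdata import Alignment, IntervalSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    The defaults describe a moderately young African-origin inversion sampled
    at frequency 0.2 in a diverse ancestral population, with mutation/
    divergence calibration matching the age-estimation defaults
    (d = 0.06 to the sister species over t_gen = 3e7 generations, Ne = 1e6,
    10 generations per year, hence mu = 1e-9 per site per generation).
    """

    age_years: float = 5_000.0
    origin: str = "African"            # African | Cosmopolitan
    inversion: str = "In(1)Sim"
    L: int = 20_000
    d: float = 0.06
    t_gen: float = 3e7
    Ne: float = 1e6
    f: float = 0.2
    gens_per_year: float = 10.0
    theta_site_std: float = 0.008
    n_inverted: int = 8
    n_standard_african: int = 20
    n_standard_cosmopolitan: int = 10
    bottleneck_severity: float = 0.2   # cosmopolitan / African diversity ratio
    exchange_rate: float = 0.25        # per-inverted-haplotype tract probability
    exchange_mean_len: float = 3_000.0
    indel_rate: float = 2.0            # expected indel runs per haplotype
    indel_mean_len: float = 5.0
    missing_fraction: float = 0.01
    arm: str = "X"
    arm_length: int = 1_000_000
    gene_density: float = 0.3
    gene_mean_len: float = 2_000.0
    n_breakpoints: int = 16
    breakpoints_avoid_genes: bool = False
    true_k: float = 0.541
    n_experimental: int = 11
    n_control: int = 9
    mean_f1_males: float = 6.0
    mean_brood: float = 120.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age must be non-negative")
        for name in ("bottleneck_severity", "exchange_rate", "missing_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.true_k < 1):
            raise ValueError("true_k must be in (0, 1)")
        if self.origin not in ("African", "Cosmopolitan"):
            raise ValueError("origin must be African or Cosmopolitan")

    @property
    def mu_site_per_gen(self) -> float:
        return self.d / (2.0 * self.t_gen)

    @property
    def theta_site(self) -> float:
        """Per-site theta of the African standard population.

        Set to the observed nucleotide diversity of ancestral-range panels
        (pi ~ 0.008/site) rather than derived from Ne * mu: diversity-based
        and census-style effective sizes are known to disagree in this
        species, and the standards' diversity is what exchange detection and
        origin classification actually see.
        """
        return self.theta_site_std

    @property
    def theta_region_std(self) -> float:
        return self.theta_site * self.L

    @property
    def theta_hat_inverted(self) -> float:
        """4*(Ne*f)*mu_region, the inverted population's expected theta.

        Kept on the same (d, t_gen, Ne) calibration the age estimators use,
        so ages recovered from the inverted clade are commensurate with the
        ages requested of the generator.
        """
        return 4.0 * self.Ne * self.f * self.mu_site_per_gen * self.L

    @property
    def mu_region_per_year(self) -> float:
        return self.mu_site_per_gen * self.L * self.gens_per_year

    @property
    def t_mrca_target(self) -> float:
        """Inverted-clade root depth in units of 4*Ne*f generations."""
        return self.age_years * self.gens_per_year / (4.0 * self.Ne * self.f)


@dataclass
class TruthLedger:
    age_years: float
    origin: str
    inversion: str
    exchange_tracts: list[dict] = field(default_factory=list)
    true_k: float | None = None
    n_stem_mutations: int = 0
    n_clade_mutations: int = 0

    def as_dict(self) -> dict:
        return {
            "age_years": self.age_years,
            "origin": self.origin,
            "inversion": self.inversion,
            "exchange_tracts": self.exchange_tracts,
            "true_k": self.true_k,
            "n_stem_mutations": self.n_stem_mutations,
            "n_clade_mutations": self.n_clade_mutations,
        }


def _clade_matrix(n: int, theta: float, rng: np.random.Generator,
                  t_mrca: float | None = None) -> np.ndarray:
    """0/1 matrix of a coalescent clade; optionally rescaled to a fixed root depth."""
    if n == 1:
        return np.zeros((1, 0), dtype=np.int8)
    g = sample_genealogy(n, 0.0, rng)
    if t_mrca is not None:
        if t_mrca == 0.0:
            return np.zeros((n, 0), dtype=np.int8)
        g = g.rescale(t_mrca)
    return drop_mutations(g, theta, rng).haplotypes


def generate_breakpoint_region(
    config: ScenarioConfig, seed: int | None = None, max_retries: int = 20
) -> tuple[Alignment, pd.DataFrame, TruthLedger]:
    """One breakpoint-region dataset: (Alignment, metadata, TruthLedger)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    for attempt in range(max_retries):
        try:
            return _generate_region_once(config, rng)
        except _InfeasibleDraw:
            continue
    raise RuntimeError(f"could not generate a feasible region in {max_retries} tries")


class _InfeasibleDraw(Exception):
    pass


def _generate_region_once(config: ScenarioConfig, rng: np.random.Generator):
    n_af = config.n_standard_african
    n_co = config.n_standard_cosmopolitan
    n_inv = config.n_inverted
    L = config.L

    af = _clade_matrix(n_af, config.theta_region_std, rng)
    co = _clade_matrix(
        n_co, config.bottleneck_severity * config.theta_region_std, rng
    )
    n_stem = rng.poisson(config.mu_region_per_year * config.age_years)
    inv = _clade_matrix(
        n_inv, config.theta_hat_inverted, rng, t_mrca=config.t_mrca_target
    )

    blocks = [af.shape[1], co.shape[1], n_stem, inv.shape[1]]
    total = sum(blocks)
    if total > L:
        raise _InfeasibleDraw
    cols = rng.choice(L, size=total, replace=False)
    c_af, c_co, c_stem, c_inv = np.split(cols, np.cumsum(blocks)[:-1])

    ancestral = _BASES[rng.integers(0, 4, size=L)]
    derived = {}
    for c in cols:
        alts = [b for b in _BASES if b != ancestral[c]]
        derived[int(c)] = alts[rng.integers(0, 3)]

    n_total = n_af + n_co + n_inv
    mat = np.tile(ancestral, (n_total, 1))

    def paint(rows: np.ndarray, matrix01: np.ndarray, columns: np.ndarray) -> None:
        for j, c in enumerate(columns):
            carriers = rows[matrix01[:, j] == 1]
            mat[carriers, c] = derived[int(c)]

    af_rows = np.arange(n_af)
    co_rows = np.arange(n_af, n_af + n_co)
    inv_rows = np.arange(n_af + n_co, n_total)

    paint(af_rows, af, c_af)
    co_ancestor = int(rng.integers(0, n_af))
    mat[co_rows, :] = mat[co_ancestor, :]
    paint(co_rows, co, c_co)

    founder_row = (
        int(rng.choice(af_rows)) if config.origin == "African"
        else int(rng.choice(co_rows))
    )
    mat[inv_rows, :] = mat[founder_row, :]
    for c in c_stem:
        mat[inv_rows, c] = derived[int(c)]
    paint(inv_rows, inv, c_inv)

    ledger = TruthLedger(
        age_years=config.age_years,
        origin=config.origin,
        inversion=config.inversion,
        true_k=config.true_k,
        n_stem_mutations=int(n_stem),
        n_clade_mutations=int(inv.shape[1]),
    )

    sample_ids = (
        [f"AF{i:02d}" for i in range(n_af)]
        + [f"FR{i:02d}" for i in range(n_co)]
        + [f"INV{i:02d}" for i in range(n_inv)]
    )

    std_rows = np.concatenate([af_rows, co_rows])
    for r in inv_rows:
        if rng.random() < config.exchange_rate:
            donor = int(rng.choice(std_rows))
            length = max(1, int(rng.exponential(config.exchange_mean_len)))
            start = int(rng.integers(0, max(1, L - length)))
            end = min(L, start + length)
            changed = np.flatnonzero(mat[r, start:end] != mat[donor, start:end])
            mat[r, start:end] = mat[donor, start:end]
            if changed.size == 0:
                # silent exchange: the copy left the sequence unchanged, so
                # the event has no footprint in the data and no coordinates
                continue
            ledger.exchange_tracts.append(
                dict(
                    sample_id=sample_ids[r],
                    # identifiable footprint: flanking sequence identical to
                    # the founder's cannot be attributed to the exchange
                    start=start + int(changed[0]),
                    end=start + int(changed[-1]) + 1,
                    copy_start=start,
                    copy_end=end,
                    donor=sample_ids[donor],
                )
            )

    for r in range(n_total):
        for _ in range(rng.poisson(config.indel_rate)):
            length = 1 + rng.poisson(max(config.indel_mean_len - 1, 0))
            start = int(rng.integers(0, max(1, L - length)))
            mat[r, start: start + length] = b"-"
        if config.missing_fraction > 0:
            run = 100
            for _ in range(rng.poisson(config.missing_fraction * L / run)):
                start = int(rng.integers(0, max(1, L - run)))
                mat[r, start: start + run] = b"N"

    populations = (
        ["RG"] * n_af + ["FR"] * n_co
        + (["RG"] * n_inv if config.origin == "African" else ["FR"] * n_inv)
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": populations,
            "arm": config.arm,
            config.inversion: ["standard"] * (n_af + n_co) + ["inverted"] * n_inv,
        }
    ).set_index("sample_id", drop=False)

    aln = Alignment(
        sample_ids, mat, region=(config.arm, 0, L), meta=meta
    )
    return aln, meta, ledger


def generate_annotation(
    config: ScenarioConfig, seed: int | None = None
) -> tuple[IntervalSet, IntervalSet, dict[str, int]]:
    """Gene intervals at the configured genic fraction plus breakpoint points."""
    if not (0 < config.gene_density <= 1):
        raise ValueError("gene density must be in (0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arm, arm_len = config.arm, config.arm_length
    rho = config.gene_density
    genes = []
    pos = 0
    mean_gap = config.gene_mean_len * (1 - rho) / rho if rho < 1 else 0.0
    while pos < arm_len:
        pos += int(round(rng.exponential(mean_gap))) if mean_gap > 0 else 0
        length = max(50, int(round(rng.exponential(config.gene_mean_len))))
        if pos >= arm_len:
            break
        end = min(arm_len, pos + length)
        genes.append(dict(arm=arm, start=pos, end=end, name=f"gene{len(genes)}"))
        pos = end
    gene_set = IntervalSet(pd.DataFrame(genes), arm_lengths={arm: arm_len})

    starts = np.array([g["start"] for g in genes])
    ends = np.array([g["end"] for g in genes])
    bps = []
    while len(bps) < config.n_breakpoints:
        p = int(rng.integers(0, arm_len))
        if config.breakpoints_avoid_genes:
            inside = ((starts <= p) & (p < ends)).any()
            if inside:
                continue
        bps.append(p)
    bp_set = IntervalSet(
        pd.DataFrame(
            [dict(arm=arm, start=p, end=p + 1, name=f"bp{i}") for i, p in enumerate(bps)]
        ),
        arm_lengths={arm: arm_len},
    )
    return gene_set, bp_set, {arm: arm_len}


def generate_cross_counts(
    config: ScenarioConfig, seed: int | None = None
) -> pd.DataFrame:
    """Synthetic distortion-assay cross table with known true K.

    Experimental crosses transmit females at the configured true K; controls
    are Mendelian (K = 0.5).  Per cross, each F1 male sires a Poisson brood.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    specs = [("experimental", config.true_k)] * config.n_experimental + [
        ("control", 0.5)
    ] * config.n_control
    for i, (role, k) in enumerate(specs):
        f1 = max(1, int(rng.poisson(config.mean_f1_males)))
        progeny = int(rng.poisson(config.mean_brood * f1))
        progeny = max(progeny, 1)
        females = int(rng.binomial(progeny, k))
        rows.append(
            dict(
                x_line=f"X{i:02d}", y_line=f"Y{i % 5}", role=role,
                f1_males=f1, females=females, males=progeny - females,
            )
        )
    return pd.DataFrame(rows)
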