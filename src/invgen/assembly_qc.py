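"""Consensus-quality validation arithmetic and the depth-titration harness.

These are the statistics used to certify a reassembled consensus against an
independently Sanger-sequenced truth: divergence accounting (mismatches over
aligned bases), a Poisson upper confidence bound on the error count, its
Phred-quality conversion, a minimal depth/quality pileup consensus caller,
and a bootstrap that rebuilds the consensus from randomly down-sampled reads
to measure robustness to sequencing depth.

The full reassembly pipeline (read mapping, mate recruitment, de novo
assembly, consensus extraction with external tools) is out of scope here;
the simple pileup caller below exercises the statistics, not the assembler.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .popgen import divergence_pair

Q_INFINITY = "Qinf"


@dataclass
class ComparisonRecord:
    label: str
    aligned_bases: int
    mismatches: int

    @property
    def divergence(self) -> float | None:
        if self.aligned_bases == 0:
            return None
        return self.mismatches / self.aligned_bases


def compare_to_truth(consensus: str, truth: str, label: str = "") -> ComparisonRecord:
    """Column-wise comparison of two pre-aligned equal-length sequences.

    Columns where either character is not a called base (A/C/G/T) are
    excluded from the aligned-base count.
    """
    aligned, mism, _ = divergence_pair(consensus, truth)
    return ComparisonRecord(label=label, aligned_bases=aligned, mismatches=mism)


def poisson_error_upper(observed: int, confidence: float = 0.95) -> float:
    """Smallest Poisson mean lambda with P(X <= observed | lambda) = 1 - confidence.

    The exact upper confidence bound on a Poisson count; for observed = 0 this
    is -ln(1 - confidence) ~ 3 at 95%, conventionally reported as a whole
    error count after ceiling.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    return float(chi2.ppf(confidence, 2 * (observed + 1)) / 2.0)


def phred_quality(errors: float, bases: int) -> float | str:
    """Q = -10 log10(errors / bases); the Qinf sentinel when errors = 0."""
    if errors < 0 or bases <= 0:
        raise ValueError("errors must be >= 0 and bases > 0")
    if errors == 0:
        return Q_INFINITY
    return -10.0 * math.log10(errors / bases)


def pileup_consensus(
    columns, min_depth: int = 3, min_quality: float = 50.0
) -> str:
    """Majority-rule consensus from per-position base observations.

    ``columns`` iterates positions; each element is a list of (base, quality)
    observations.  A position emits the majority base only when depth >=
    ``min_depth`` and the consensus quality >= ``min_quality``; ties and
    everything below threshold emit N.  Consensus quality is the Phred sum of
    supporting qualities minus conflicting qualities (a simplification of the
    full samtools consensus model).
    """
    out = []
    for obs in columns:
        obs = [(b.upper(), q) for b, q in obs if b.upper() in "ACGT"]
        if len(obs) < min_depth:
            out.append("N")
            continue
        totals: dict[str, float] = {}
        for b, q in obs:
            totals[b] = totals.get(b, 0.0) + q
        best = max(totals.values())
        leaders = [b for b, t in totals.items() if t == best]
        if len(leaders) != 1:
            out.append("N")
            continue
        base = leaders[0]
        qual = totals[base] - sum(t for b, t in totals.items() if b != base)
        out.append(base if qual >= min_quality else "N")
    return "".join(out)


def consensus_from_reads(
    reads: pd.DataFrame, length: int, min_depth: int = 3, min_quality: float = 50.0
) -> str:
    """Pileup consensus over [0, length) from a (start, sequence, quality) table.

    ``quality`` is a per-read nominal Phred score applied to each of its
    bases.  Same calling rule as :func:`pileup_consensus`, vectorized over
    positions.
    """
    depth = np.zeros(length, dtype=np.int64)
    qsum = np.zeros((length, 4))
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
        lut[ord(chr(b).lower())] = i
    for start, seq, qual in zip(reads["start"], reads["sequence"], reads["quality"]):
        start = int(start)
        idx = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        pos = start + np.arange(len(seq))
        ok = (idx >= 0) & (pos >= 0) & (pos < length)
        np.add.at(qsum, (pos[ok], idx[ok].astype(np.int64)), float(qual))
        np.add.at(depth, pos[ok], 1)
    best = qsum.max(axis=1)
    tie = (qsum == best[:, None]).sum(axis=1) != 1
    qual = 2 * best - qsum.sum(axis=1)
    callable_ = (depth >= min_depth) & ~tie & (qual >= min_quality) & (best > 0)
    bases = np.array(list("ACGT"))
    out = np.full(length, "N", dtype="<U1")
    out[callable_] = bases[qsum.argmax(axis=1)[callable_]]
    return "".join(out)


def simulate_reads(
    truth: str,
    depth: float,
    read_length: int,
    rng: np.random.Generator,
    error_rate: float = 0.0,
    quality: float = 30.0,
) -> pd.DataFrame:
    """Uniform shotgun reads from a truth sequence (QC fixture generator)."""
    L = len(truth)
    n_reads = int(round(depth * L / read_length))
    starts = rng.integers(0, max(1, L - read_length + 1), size=n_reads)
    rows = []
    bases = "ACGT"
    for s in starts:
        frag = list(truth[s: s + read_length])
        if error_rate > 0:
            errs = rng.random(len(frag)) < error_rate
            for i in np.flatnonzero(errs):
                frag[i] = bases[(bases.index(frag[i]) + rng.integers(1, 4)) % 4]
        rows.append(dict(start=int(s), sequence="".join(frag), quality=quality))
    return pd.DataFrame(rows, columns=["start", "sequence", "quality"])


def depth_titration(
    reads: pd.DataFrame,
    truth: str,
    reference: str,
    fractions=tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    reps: int = 100,
    seed: int | None = None,
    min_depth: int = 3,
    min_quality: float = 50.0,
) -> pd.DataFrame:
    """Bootstrap consensus accuracy under read down-sampling.

    Per replicate: subsample the read set without replacement at the retained
    fraction, rebuild the consensus, and compare it to the reference.
    Divergence and coverage are normalized by the 'true' values from the
    truth-vs-reference comparison, so an unbiased caller stays at 1.  Columns:
    fraction, rep, divergence_ratio, coverage_ratio.
    """
    if len(truth) != len(reference):
        raise ValueError("truth and reference must be pre-aligned, equal length")
    rng = np.random.default_rng(seed)
    truth_rec = compare_to_truth(truth, reference, label="truth")
    true_div = truth_rec.divergence
    true_cov = truth_rec.aligned_bases
    rows = []
    n = len(reads)
    for frac in fractions:
        keep_n = int(round(frac * n))
        for rep in range(reps):
            idx = rng.choice(n, size=keep_n, replace=False)
            cons = consensus_from_reads(
                reads.iloc[idx], len(reference),
                min_depth=min_depth, min_quality=min_quality,
            )
            rec = compare_to_truth(cons, reference, label=f"f{frac}")
            div = rec.divergence
            rows.append(
                dict(
                    fraction=float(frac),
                    rep=rep,
                    divergence_ratio=(
                        np.nan if div is None or not true_div else div / true_div
                    ),
                    coverage_ratio=rec.aligned_bases / true_cov if true_cov else np.nan,
                )
            )
    return pd.DataFrame(rows)
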