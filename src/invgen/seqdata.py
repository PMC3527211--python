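"""Alignment data model, FASTA/TSV/BED I/O, and pre-analysis filtering policies.

All coordinates are 0-based half-open internally.  Sequences are stored as an
(n_samples, n_columns) byte matrix over the alphabet {A, C, G, T, N, -};
IUPAC ambiguity codes (residual heterozygosity in inbred-line assemblies) are
normalized to N on input, and lowercase is uppercased.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset(b"ACGTN-")
_BASES = frozenset(b"ACGT")
# IUPAC ambiguity codes that are mapped to N (het sites are masked, not called)
_AMBIGUOUS = b"RYSWKMBDHV"

ARRANGEMENTS = ("inverted", "standard", "unknown")


class AlignmentShapeError(ValueError):
    """Sequences in one alignment do not all have the same length."""


class AlphabetError(ValueError):
    """A sequence contains a character outside {A,C,G,T,N,-} after normalization."""


def _normalize(seq: str) -> bytes:
    """Uppercase, map IUPAC ambiguity codes to N, validate the alphabet."""
    raw = seq.upper().encode("ascii")
    arr = np.frombuffer(raw, dtype="S1").copy()
    amb = np.isin(arr, np.frombuffer(_AMBIGUOUS, dtype="S1"))
    if amb.any():
        logger.warning(
            "normalized %d IUPAC ambiguity code(s) to N", int(amb.sum())
        )
        arr[amb] = b"N"
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN-", dtype="S1"))
    if bad.any():
        offender = arr[bad][0].decode()
        raise AlphabetError(f"illegal character {offender!r} in sequence")
    return arr.tobytes()


@dataclass
class Alignment:
    """A multiple-sequence alignment of haplotypes with genomic coordinates.

    Parameters
    ----------
    sample_ids : list of str
        Unique identifiers, one per row of ``matrix``.
    matrix : ndarray of dtype S1, shape (n, L)
        Aligned sequences over {A, C, G, T, N, -}.
    region : (str, int, int), optional
        (arm, start, end) in 0-based half-open reference coordinates.
    column_map : ndarray of int, optional
        For derived alignments, the original column index of each retained
        column; identity when absent.
    meta : pandas.DataFrame, optional
        Per-sample metadata indexed by sample_id.
    """

    sample_ids: list[str]
    matrix: np.ndarray
    region: tuple[str, int, int] | None = None
    column_map: np.ndarray | None = None
    meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise AlignmentShapeError("matrix must be 2-dimensional")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentShapeError("one sample_id per sequence required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.matrix.shape[1] < 1:
            logger.warning("alignment has zero columns")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def sequences(self) -> list[str]:
        return [row.tobytes().decode() for row in self.matrix]

    def sequence(self, sample_id: str) -> str:
        return self.matrix[self._index(sample_id)].tobytes().decode()

    def _index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def arrangement(self, inversion: str) -> pd.Series:
        """Arrangement labels for ``inversion``, aligned to row order."""
        if self.meta is None or inversion not in self.meta.columns:
            raise KeyError(f"no arrangement column {inversion!r} in metadata")
        return self.meta.loc[self.sample_ids, inversion]


def from_sequences(
    sample_ids: list[str],
    sequences: list[str],
    region: tuple[str, int, int] | None = None,
    meta: pd.DataFrame | None = None,
) -> Alignment:
    """Build an Alignment from raw strings, normalizing and validating."""
    if not sequences:
        raise AlignmentShapeError("at least one sequence required")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise AlignmentShapeError(f"unequal sequence lengths: {sorted(lengths)}")
    rows = [np.frombuffer(_normalize(s), dtype="S1") for s in sequences]
    return Alignment(list(sample_ids), np.vstack(rows), region=region, meta=meta)


def read_fasta_alignment(
    path, region: tuple[str, int, int] | None = None, meta: pd.DataFrame | None = None
) -> Alignment:
    """Read a FASTA multiple alignment; record order is preserved."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    return from_sequences(
        [r.id for r in records], [str(r.seq) for r in records], region=region, meta=meta
    )


def write_fasta_alignment(a: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(a.sample_ids, a.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def complete_deletion(a: Alignment) -> Alignment:
    """Drop every column containing any gap or N in any sample.

    The returned alignment's ``column_map`` gives, for each retained column,
    its index in ``a`` (composed with any existing map on ``a``).
    """
    invalid = (a.matrix == b"-") | (a.matrix == b"N")
    keep = ~invalid.any(axis=0)
    if not keep.any():
        logger.warning("complete deletion removed every column")
    idx = np.flatnonzero(keep)
    colmap = idx if a.column_map is None else a.column_map[idx]
    return Alignment(
        list(a.sample_ids), a.matrix[:, keep], region=a.region,
        column_map=colmap, meta=a.meta,
    )


def subset(
    a: Alignment,
    samples: list[str] | None = None,
    interval: tuple[int, int] | None = None,
) -> Alignment:
    """Restrict to the requested samples (order preserved) and column range.

    ``interval`` is a half-open (start, end) range in *alignment column*
    coordinates of ``a``.
    """
    if samples is None:
        samples = list(a.sample_ids)
    rows = [a._index(s) for s in samples]
    mat = a.matrix[rows, :]
    region = a.region
    colmap = a.column_map
    if interval is not None:
        start, end = interval
        if not (0 <= start <= end <= a.length):
            raise ValueError(f"interval {interval} outside alignment of length {a.length}")
        mat = mat[:, start:end]
        colmap = (
            np.arange(start, end) if colmap is None else colmap[start:end]
        )
        if region is not None:
            arm, rstart, _ = region
            region = (arm, rstart + start, rstart + end)
    return Alignment(list(samples), mat, region=region, column_map=colmap, meta=a.meta)


def mask_het_arms(
    het_flags: pd.DataFrame,
    run_threshold: int = 3,
    het_fraction_cut: float = 0.005,
) -> list[tuple[str, str]]:
    """Flag (sample, arm) pairs showing long runs of residual heterozygosity.

    ``het_flags`` has columns (sample, arm, window, het_fraction), with
    windows tiling each arm in order (0.5 Mb windows in the intended use; a
    final partial window is allowed).  A pair is excluded when at least
    ``run_threshold`` consecutive windows exceed ``het_fraction_cut``.
    """
    excluded = []
    for (sample, arm), grp in het_flags.groupby(["sample", "arm"], sort=False):
        above = (
            grp.sort_values("window")["het_fraction"].to_numpy() > het_fraction_cut
        )
        run = best = 0
        for flag in above:
            run = run + 1 if flag else 0
            best = max(best, run)
        if best >= run_threshold:
            excluded.append((sample, arm))
    return excluded


# ---------------------------------------------------------------------------
# Metadata and intervals

def read_meta_tsv(path) -> pd.DataFrame:
    """Per-sample metadata: sample_id, population, arm, one column per inversion.

    Arrangement columns are validated against {inverted, standard, unknown}.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sample_id" not in meta.columns:
        raise ValueError("metadata requires a sample_id column")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    meta = meta.set_index("sample_id", drop=False)
    for col in meta.columns:
        if col in ("sample_id", "population", "arm"):
            continue
        bad = set(meta[col].dropna()) - set(ARRANGEMENTS)
        if bad:
            raise ValueError(f"invalid arrangement labels in {col!r}: {sorted(bad)}")
    return meta


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


@dataclass
class IntervalSet:
    """Genomic intervals (arm, start, end, name), 0-based half-open."""

    df: pd.DataFrame
    arm_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        required = ["arm", "start", "end"]
        if not all(c in self.df.columns for c in required):
            raise ValueError(f"interval table requires columns {required}")
        if "name" not in self.df.columns:
            self.df = self.df.assign(name=[f"iv{i}" for i in range(len(self.df))])
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("intervals require start < end")
        if self.arm_lengths is not None:
            for _, row in self.df.iterrows():
                limit = self.arm_lengths.get(row["arm"])
                if limit is not None and row["end"] > limit:
                    raise ValueError(
                        f"interval {row['name']} exceeds arm {row['arm']} length {limit}"
                    )

    def __len__(self) -> int:
        return len(self.df)

    def on_arm(self, arm: str) -> pd.DataFrame:
        return self.df[self.df["arm"] == arm]


def read_bed(path, arm_lengths: dict[str, int] | None = None) -> IntervalSet:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["arm", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    return IntervalSet(df.astype({"start": int, "end": int}), arm_lengths=arm_lengths)


def write_bed(ivs: IntervalSet, path) -> None:
    ivs.df[["arm", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def points_from_positions(
    positions: list[tuple[str, int]], names: list[str] | None = None,
    arm_lengths: dict[str, int] | None = None, one_based: bool = False,
) -> IntervalSet:
    """Breakpoint positions as width-1 intervals.

    ``one_based=True`` converts 1-based reference positions (as printed in
    cytological tables) to internal 0-based coordinates.
    """
    shift = 1 if one_based else 0
    rows = [
        {"arm": arm, "start": pos - shift, "end": pos - shift + 1}
        for arm, pos in positions
    ]
    df = pd.DataFrame(rows)
    if names is not None:
        df["name"] = names
    return IntervalSet(df, arm_lengths=arm_lengths)
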