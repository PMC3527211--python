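"""Detection and masking of genetic exchange between arrangements.

Gene flux (double crossover or gene conversion in inversion heterokaryotypes)
moves standard-arrangement sequence onto inverted haplotypes.  Its signature
in a breakpoint alignment is a run of shared polymorphisms: sites at which the
same minor allele segregates in both the inverted and the standard class, all
carried by the same inverted haplotype.  Isolated shared sites are expected
occasionally from recurrent mutation or lineage sorting and are not masked;
a run of ``min_run`` (default 3) consecutive shared alleles among a
haplotype's variant sites is treated as an exchange tract.

Because the true recombination breakpoints are unidentifiable between
informative sites, detected tracts extend halfway from the run's outermost
shared sites toward the nearest flanking non-shared variant site (or to the
alignment edge).  SNPs within 10 alignment columns of an indel are excluded
from the informative-site set, mirroring the flag-and-inspect rule applied to
alignments around indels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdata import Alignment

logger = logging.getLogger(__name__)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")

INDEL_PROXIMITY = 10


@dataclass
class SiteClassification:
    column: int
    inverted_counts: dict[str, int]
    standard_counts: dict[str, int]
    shared_polymorphism: bool
    indel_proximal: bool
    shared_allele: str | None = None


@dataclass
class MaskInterval:
    sample_id: str
    start: int
    end: int
    reason: str = "exchange_tract"


def _class_rows(a: Alignment, meta: pd.DataFrame, inversion: str) -> tuple[list[int], list[int]]:
    labels = meta.loc[a.sample_ids, inversion]
    inv = [i for i, s in enumerate(a.sample_ids) if labels[s] == "inverted"]
    std = [i for i, s in enumerate(a.sample_ids) if labels[s] == "standard"]
    if not inv or not std:
        raise ValueError("both inverted and standard haplotypes are required")
    return inv, std


def classify_sites(
    a: Alignment, meta: pd.DataFrame, inversion: str
) -> list[SiteClassification]:
    """Classify every polymorphic column of the alignment.

    A column is a shared polymorphism when it is biallelic among called bases
    and its minor allele is observed in at least one inverted and at least one
    standard haplotype.  ``indel_proximal`` flags SNP columns within
    10 columns of any gap character.
    """
    inv_rows, std_rows = _class_rows(a, meta, inversion)
    mat = a.matrix
    has_gap = (mat == b"-").any(axis=0)
    gap_cols = np.flatnonzero(has_gap)
    near_indel = np.zeros(a.length, dtype=bool)
    for g in gap_cols:
        near_indel[max(0, g - INDEL_PROXIMITY): g + INDEL_PROXIMITY + 1] = True

    out: list[SiteClassification] = []
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASE_BYTES])
    poly = (counts > 0).sum(axis=0) >= 2
    for col in np.flatnonzero(poly):
        column = mat[:, col]
        inv_counts = _base_counts(column[inv_rows])
        std_counts = _base_counts(column[std_rows])
        alleles = [b for b in "ACGT" if counts["ACGT".index(b), col] > 0]
        shared = False
        shared_allele = None
        if len(alleles) == 2:
            a1, a2 = alleles
            c1 = int(counts["ACGT".index(a1), col])
            c2 = int(counts["ACGT".index(a2), col])
            # minor allele; lexicographic tie-break on equal counts
            minor = a1 if (c1, a1) <= (c2, a2) else a2
            if inv_counts.get(minor, 0) >= 1 and std_counts.get(minor, 0) >= 1:
                shared = True
                shared_allele = minor
        out.append(
            SiteClassification(
                column=int(col),
                inverted_counts=inv_counts,
                standard_counts=std_counts,
                shared_polymorphism=shared,
                indel_proximal=bool(near_indel[col] and not has_gap[col]),
                shared_allele=shared_allele,
            )
        )
    return out


def _base_counts(col: np.ndarray) -> dict[str, int]:
    return {
        b.decode(): int((col == b).sum()) for b in _BASE_BYTES if (col == b).any()
    }


def detect_exchange_tracts(
    a: Alignment,
    meta: pd.DataFrame,
    inversion: str,
    min_run: int = 3,
    sites: list[SiteClassification] | None = None,
) -> list[MaskInterval]:
    """Exchange tracts on inverted haplotypes.

    For each inverted haplotype, its variant sites are the informative
    polymorphic columns (gap-free, not indel-proximal) at which it differs
    from the inverted-class majority allele.  Maximal runs of >= min_run
    consecutive variant sites at which the haplotype carries the shared minor
    allele become mask intervals, extended halfway toward the nearest
    non-shared flanking variant site.
    """
    if sites is None:
        sites = classify_sites(a, meta, inversion)
    inv_rows, _ = _class_rows(a, meta, inversion)
    mat = a.matrix
    usable = [s for s in sites if not s.indel_proximal]
    # inverted-class majority allele per usable column
    maj: dict[int, str] = {}
    for s in usable:
        if s.inverted_counts:
            maj[s.column] = max(s.inverted_counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
    masks: list[MaskInterval] = []
    for row in inv_rows:
        sample = a.sample_ids[row]
        variant: list[tuple[int, bool]] = []  # (column, carries shared minor)
        for s in usable:
            base = mat[row, s.column].decode()
            if base not in "ACGT" or s.column not in maj:
                continue
            if base != maj[s.column]:
                # shared when the allele this haplotype carries (against the
                # inverted-class majority) is also observed among standards
                carries_shared = s.standard_counts.get(base, 0) >= 1
                variant.append((s.column, carries_shared))
        masks.extend(_runs_to_masks(sample, variant, min_run, a.length))
    return masks


def _runs_to_masks(
    sample: str, variant: list[tuple[int, bool]], min_run: int, length: int
) -> list[MaskInterval]:
    out = []
    k = 0
    while k < len(variant):
        if not variant[k][1]:
            k += 1
            continue
        j = k
        while j + 1 < len(variant) and variant[j + 1][1]:
            j += 1
        if j - k + 1 >= min_run:
            first, last = variant[k][0], variant[j][0]
            left = (variant[k - 1][0] + first) // 2 + 1 if k > 0 else 0
            right = (last + variant[j + 1][0]) // 2 if j + 1 < len(variant) else length - 1
            out.append(MaskInterval(sample, int(left), int(right) + 1))
        k = j + 1
    return out


def apply_masks(
    a: Alignment,
    masks: list[MaskInterval],
    whole_haplotype_cut: float = 0.5,
    inversion: str | None = None,
) -> tuple[Alignment, pd.DataFrame]:
    """Replace masked spans with N; drop haplotypes masked beyond the cut.

    Returns the masked alignment and a per-sample report (masked fraction,
    dropped flag).  When more than half of the inverted haplotypes are
    dropped, a warning is emitted: exchange that extensive means the original
    inverted haplotype cannot be recovered, and the breakpoint should be
    excluded (as done for one extensively exchanged distal breakpoint).
    """
    mat = a.matrix.copy()
    frac = {s: 0.0 for s in a.sample_ids}
    for m in masks:
        row = a._index(m.sample_id)
        mat[row, m.start: m.end] = b"N"
    for sid in a.sample_ids:
        row = a._index(sid)
        frac[sid] = float((mat[row] == b"N").sum()) / max(a.length, 1)
    dropped = [s for s in a.sample_ids if frac[s] > whole_haplotype_cut]
    keep = [i for i, s in enumerate(a.sample_ids) if s not in dropped]
    report = pd.DataFrame(
        dict(
            sample_id=a.sample_ids,
            masked_fraction=[frac[s] for s in a.sample_ids],
            dropped=[s in dropped for s in a.sample_ids],
        )
    )
    if inversion is not None and a.meta is not None and dropped:
        labels = a.meta.loc[a.sample_ids, inversion]
        inv_ids = [s for s in a.sample_ids if labels[s] == "inverted"]
        if inv_ids and sum(s in dropped for s in inv_ids) > 0.5 * len(inv_ids):
            logger.warning(
                "more than half of inverted haplotypes dropped: exchange too "
                "extensive to recover the ancestral inverted haplotype"
            )
    out = Alignment(
        [s for s in a.sample_ids if s not in dropped],
        mat[keep, :],
        region=a.region,
        column_map=a.column_map,
        meta=a.meta,
    )
    return out, report
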