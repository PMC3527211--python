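"""Geographic-origin classification of inversions.

D. melanogaster expanded out of sub-Saharan Africa roughly 10-15 thousand
years ago through a sharp bottleneck, so cosmopolitan (e.g. French) standard
haplotypes are a low-diversity subset of African variation.  An inversion is
judged cosmopolitan in origin when, at its breakpoint regions, (i) the single
nearest-neighbor standard haplotype is French and (ii) the mean divergence of
inverted haplotypes to French standards is smaller than to African standards.
African-origin inversions are roughly equidistant from both reference groups
with an African nearest neighbor.  Breakpoint-level calls are combined by
unanimity; disagreement yields Ambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen import divergence_pair
from .seqdata import Alignment, complete_deletion, subset


@dataclass
class OriginReport:
    inversion: str
    mean_div_french: float
    mean_div_african: float
    nearest_id: str | None
    nearest_population: str | None
    nearest_divergence: float
    call: str  # African | Cosmopolitan | Ambiguous


def mean_divergence_to_group(inv: Alignment, group: Alignment) -> float:
    """Mean per-site divergence over all inverted x group haplotype pairs.

    Each comparison uses complete deletion across the combined pair set
    (per-pair proportions from divergence_pair), so missing data never
    inflates divergence.
    """
    if inv.n == 0 or group.n == 0:
        raise ValueError("both groups must be non-empty")
    merged = Alignment(
        inv.sample_ids + [f"g::{s}" for s in group.sample_ids],
        np.vstack([inv.matrix, group.matrix]),
    )
    clean = complete_deletion(merged)
    if clean.length == 0:
        raise ValueError("no comparable columns after complete deletion")
    props = []
    for i in range(inv.n):
        for j in range(inv.n, clean.n):
            _, _, p = divergence_pair(clean.sequences[i], clean.sequences[j])
            props.append(p)
    return float(np.mean(props))


def nearest_neighbor(
    inv_haplotype: str, standards: Alignment, populations: dict[str, str]
) -> tuple[list[str], list[str], float]:
    """Closest standard haplotype(s) to one inverted haplotype.

    Returns (tied sample ids, tied populations, divergence); ties are all
    reported so mixed-population ties can escalate the call to Ambiguous.
    """
    if standards.n == 0:
        raise ValueError("at least one standard haplotype required")
    divs = []
    for sid, seq in zip(standards.sample_ids, standards.sequences):
        _, _, p = divergence_pair(inv_haplotype, seq)
        divs.append(np.inf if p is None else p)
    divs = np.asarray(divs)
    best = float(divs.min())
    tied = [standards.sample_ids[i] for i in np.flatnonzero(divs == best)]
    return tied, sorted({populations[s] for s in tied}), best


def classify_breakpoint(
    inv: Alignment,
    french_std: Alignment,
    african_std: Alignment,
    inversion: str = "",
    french_label: str = "FR",
    african_label: str = "african",
) -> OriginReport:
    """Apply the two-condition rule at one breakpoint."""
    mean_fr = mean_divergence_to_group(inv, french_std)
    mean_af = mean_divergence_to_group(inv, african_std)
    pops = {s: french_label for s in french_std.sample_ids}
    pops.update({s: african_label for s in african_std.sample_ids})
    merged_std = Alignment(
        french_std.sample_ids + african_std.sample_ids,
        np.vstack([french_std.matrix, african_std.matrix]),
    )
    # nearest neighbor of the inversion: the closest standard over all
    # inverted x standard pairs
    best = (None, None, np.inf)
    ambiguous_tie = False
    for seq in inv.sequences:
        ids, tie_pops, div = nearest_neighbor(seq, merged_std, pops)
        if div < best[2]:
            best = (ids[0], tie_pops[0] if len(tie_pops) == 1 else None, div)
            ambiguous_tie = len(tie_pops) > 1
        elif div == best[2] and len(tie_pops) > 1:
            ambiguous_tie = True
    nearest_id, nearest_pop, nearest_div = best
    if ambiguous_tie or nearest_pop is None:
        call = "Ambiguous"
    elif nearest_pop == french_label and mean_fr < mean_af:
        call = "Cosmopolitan"
    else:
        call = "African"
    return OriginReport(
        inversion=inversion,
        mean_div_french=mean_fr,
        mean_div_african=mean_af,
        nearest_id=nearest_id,
        nearest_population=nearest_pop,
        nearest_divergence=float(nearest_div),
        call=call,
    )


def classify_origin(
    breakpoints: list[tuple[Alignment, Alignment, Alignment]],
    inversion: str = "",
) -> OriginReport:
    """Per-inversion call: unanimity across analyzed breakpoints, else Ambiguous.

    ``breakpoints`` is a list of (inverted, french_std, african_std)
    alignment triples, one per breakpoint region.  African standards are
    assumed to be pre-masked for cosmopolitan admixture by the caller.
    """
    if not breakpoints:
        raise ValueError("at least one breakpoint region required")
    reports = [
        classify_breakpoint(inv, fr, af, inversion=inversion)
        for inv, fr, af in breakpoints
    ]
    calls = {r.call for r in reports}
    call = calls.pop() if len(calls) == 1 else "Ambiguous"
    closest = min(reports, key=lambda r: r.nearest_divergence)
    return OriginReport(
        inversion=inversion,
        mean_div_french=float(np.mean([r.mean_div_french for r in reports])),
        mean_div_african=float(np.mean([r.mean_div_african for r in reports])),
        nearest_id=closest.nearest_id,
        nearest_population=closest.nearest_population,
        nearest_divergence=closest.nearest_divergence,
        call=call,
    )


def classify_from_metadata(
    a: Alignment, inversion: str, french_population: str = "FR"
) -> OriginReport:
    """Single-region convenience: split one alignment by metadata and classify.

    Standard haplotypes with population == ``french_population`` form the
    cosmopolitan reference; all other standard haplotypes the African one.
    """
    if a.meta is None:
        raise ValueError("alignment metadata required")
    arr = a.arrangement(inversion)
    pop = a.meta.loc[a.sample_ids, "population"]
    inv_ids = [s for s in a.sample_ids if arr[s] == "inverted"]
    fr_ids = [
        s for s in a.sample_ids
        if arr[s] == "standard" and pop[s] == french_population
    ]
    af_ids = [
        s for s in a.sample_ids
        if arr[s] == "standard" and pop[s] != french_population
    ]
    return classify_origin(
        [(subset(a, inv_ids), subset(a, fr_ids), subset(a, af_ids))],
        inversion=inversion,
    )
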