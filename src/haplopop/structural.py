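"""Coverage-window deletion detection/genotyping and the three-primer
in-silico PCR marker.

The deletion assay works on read-depth ratios: a haplotype missing the
segment halves the expected coverage there, so the window-mean depth,
normalised by the sample's genome-wide mean, sits near 1, 0.5 or 0 for
zero, one or two deleted copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

WINDOW = 800  # bp, the coverage window width used throughout

GENOTYPES = ("no-deletion", "heterozygous", "homozygous-deletion")


@dataclass
class CoverageTrack:
    """Fixed-width window coverage for one sample, grid-aligned."""

    sample: str
    chrom: str
    window: int
    starts: np.ndarray          # multiples of ``window`` (last may be partial)
    mean_depth: np.ndarray
    genome_mean: float

    @property
    def ratio(self) -> np.ndarray:
        return self.mean_depth / self.genome_mean

    def region_ratio(self, start: int, end: int) -> float:
        """Mean normalised ratio of windows overlapping [start, end)."""
        ends = np.minimum(self.starts + self.window, self.starts[-1] + self.window)
        sel = (self.starts < end) & (self.starts + self.window > start)
        if not sel.any():
            raise ValueError("region overlaps no window")
        return float(self.ratio[sel].mean())


def window_coverage(depth: np.ndarray, sample: str, chrom: str = "chr1", window: int = WINDOW) -> CoverageTrack:
    """Window a per-base depth array into fixed ``window``-bp means.

    The trailing partial window is averaged over its actual length; the
    normalising genome-wide mean is the sample's mean per-base depth.
    """
    n = len(depth)
    starts = np.arange(0, n, window)
    sums = np.add.reduceat(depth.astype(float), starts)
    lengths = np.minimum(starts + window, n) - starts
    return CoverageTrack(
        sample=sample,
        chrom=chrom,
        window=window,
        starts=starts,
        mean_depth=sums / lengths,
        genome_mean=float(depth.mean()),
    )


def genotype_deletion(region_ratio: float, het_band: tuple = (0.25, 0.75)) -> str:
    """Deletion genotype from a normalised region coverage ratio.

    Thresholds default to the midpoints between the expected copy ratios
    {1, 0.5, 0}: above 0.75 no deletion, 0.25-0.75 heterozygous, below 0.25
    homozygous deletion.
    """
    lo, hi = het_band
    if region_ratio > hi:
        return "no-deletion"
    if region_ratio >= lo:
        return "heterozygous"
    return "homozygous-deletion"


def detect_deletion_run(track: CoverageTrack, max_ratio: float = 0.75) -> tuple | None:
    """Longest contiguous run of windows with ratio < ``max_ratio``.

    Returns (start, end) in base coordinates, or None if no window is low.
    """
    low = track.ratio < max_ratio
    if not low.any():
        return None
    best = cur = None
    best_len = 0
    for i, flag in enumerate(low):
        if flag:
            cur = i if cur is None else cur
            if i - cur + 1 > best_len:
                best_len = i - cur + 1
                best = (cur, i)
        else:
            cur = None
    s, e = best
    return int(track.starts[s]), int(track.starts[e] + track.window)


def compare_groups_over_region(
    tracks: Sequence[CoverageTrack],
    region: tuple,
    groups: dict,
    group_a: str,
    group_b: str,
    welch: bool = False,
) -> dict:
    """Two-sided t test of mean region coverage ratio between two groups.

    Per-sample mean normalised ratios over ``region`` = (start, end) are
    compared with a pooled-variance Student's t test by default (Welch by
    flag).  Requires at least two samples per group.
    """
    start, end = region
    vals = {g: [] for g in (group_a, group_b)}
    for t in tracks:
        g = groups.get(t.sample)
        if g in vals:
            vals[g].append(t.region_ratio(start, end))
    a, b = np.array(vals[group_a]), np.array(vals[group_b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per group")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "mean_ratio": {group_a: float(a.mean()), group_b: float(b.mean())},
        "t": float(t_stat),
        "p": float(p),
        "n": {group_a: len(a), group_b: len(b)},
    }


# ---------------------------------------------------------------------------
# in-silico PCR

@dataclass(frozen=True)
class Primer:
    id: str
    sequence: str
    orientation: str  # intended orientation: "forward" or "reverse"

    def __post_init__(self):
        if not 15 <= len(self.sequence) <= 30:
            raise ValueError(f"primer {self.id}: length must be 15-30 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"primer {self.id}: sequence must be over ACGT")


@dataclass
class PrimerSet:
    primers: list
    max_amplicon: int

    def __post_init__(self):
        ids = [p.id for p in self.primers]
        if len(set(ids)) != len(ids):
            raise ValueError("primer ids must be unique")


@dataclass
class Amplicon:
    forward_id: str
    reverse_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _find_all(template: str, query: str) -> list:
    out, i = [], template.find(query)
    while i != -1:
        out.append(i)
        i = template.find(query, i + 1)
    return out


def insilico_pcr(template: str, primer_set: PrimerSet) -> list:
    """All feasible PCR products of the primer set on one template.

    Exact matching only, both strands searched: a product runs from the
    start of a plus-strand primer match to the end of a reverse-complement
    match of another (or the same) primer, within ``max_amplicon`` bp.
    """
    fwd_hits = {}  # primer id -> plus-strand match starts
    rev_hits = {}  # primer id -> revcomp match ends
    ambiguous = []
    for p in primer_set.primers:
        fwd_hits[p.id] = _find_all(template, p.sequence)
        rc = str(Seq(p.sequence).reverse_complement())
        rev_hits[p.id] = [i + len(rc) for i in _find_all(template, rc)]
        if len(fwd_hits[p.id]) + len(rev_hits[p.id]) > 1:
            ambiguous.append(p.id)
    products = []
    for pf in primer_set.primers:
        for pr in primer_set.primers:
            for s in fwd_hits[pf.id]:
                for e in rev_hits[pr.id]:
                    if s < e and e - s <= primer_set.max_amplicon:
                        products.append(Amplicon(pf.id, pr.id, s, e))
    if ambiguous:
        import logging

        logging.getLogger("haplopop").warning(
            "in-silico PCR: primers with multiple template matches: %s", sorted(set(ambiguous))
        )
    return products


def band_pattern(haplotype_templates: Sequence[str], primer_set: PrimerSet) -> set:
    """Diploid band pattern: union of product (primer pair, length) over
    both haplotype templates."""
    bands = set()
    for tmpl in haplotype_templates:
        for amp in insilico_pcr(tmpl, primer_set):
            bands.add((amp.forward_id, amp.reverse_id, amp.length))
    return bands


def classify_marker(bands: set, inside_primer: str = "b1", spanning_pair: tuple = ("a1", "c1")) -> str:
    """Cultivar-group call from a diploid band pattern.

    The deletion-spanning product (a1+c1, amplifiable only when the segment
    is gone) marks a deleted haplotype; the product ending at the
    inside-deletion primer (b1) marks an intact haplotype.  Only the
    spanning product -> EEMC-like (both haplotypes deleted); only the intact
    product -> LMC-like; both -> EMC-like heterozygote.
    """
    has_span = any(b[0] == spanning_pair[0] and b[1] == spanning_pair[1] for b in bands)
    has_intact = any(b[1] == inside_primer for b in bands)
    if has_span and has_intact:
        return "EMC-like"
    if has_span:
        return "EEMC-like"
    if has_intact:
        return "LMC-like"
    raise ValueError("no diagnostic band amplified")
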