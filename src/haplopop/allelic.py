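"""Allele-specific analyses: haplotype-of-origin classification from mapping
fractions, differentially-expressed-allele (DEA) calling with saturation
curves, allelic Ka/Ks (Nei-Gojobori 1986 with Jukes-Cantor correction), and
SNP density per gene feature.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .variant_impact import GeneModel, STOP_CODONS, translate_codon

# ---------------------------------------------------------------------------
# haplotype-of-origin from mapping fractions

#: fraction-of-reads-on-HY thresholds separating the three classes, taken
#: from the printed group ranges (HY-dominant accessions sit at 0.777-0.831,
#: HH-dominant ones at 1 - (0.640-0.758), admixed F1s at 0.36-0.592).
HY_DOMINANT_MIN = 0.64
HH_DOMINANT_MAX = 0.36


@dataclass
class MappingFractionRecord:
    sample: str
    n_reads_hy: int
    n_reads_hh: int

    @property
    def f_hy(self) -> float:
        total = self.n_reads_hy + self.n_reads_hh
        if total == 0:
            raise ValueError(f"{self.sample}: no mapped reads")
        return self.n_reads_hy / total


def classify_mapping_fraction(
    rec: MappingFractionRecord,
    hy_min: float = HY_DOMINANT_MIN,
    hh_max: float = HH_DOMINANT_MAX,
) -> str:
    """HY-dominant / HH-dominant / admixed from the HY mapping fraction."""
    f = rec.f_hy
    if f >= hy_min:
        return "HY-dominant"
    if f <= hh_max:
        return "HH-dominant"
    return "admixed"


# ---------------------------------------------------------------------------
# DEA calling

@dataclass
class DEACallSet:
    """Per-library DEA calls: gene, counts, p, BH q, direction."""

    library: str
    table: pd.DataFrame  # index gene; columns count_A, count_B, p, q, dea, direction

    @property
    def dea_genes(self) -> set:
        return set(self.table.index[self.table["dea"]])


def call_dea(
    counts: pd.DataFrame,
    library: str,
    alpha: float = 0.05,
    min_depth: int = 10,
) -> DEACallSet:
    """Allelic-imbalance test for one library.

    Per gene with total allele coverage >= ``min_depth``: an exact two-sided
    binomial test of theta = 0.5, Benjamini-Hochberg corrected within the
    library; a gene is a DEA iff q < alpha.  ``counts`` is the MultiIndex
    (library, allele) frame produced by the generator or read from TSV.
    """
    a = counts[(library, "count_A")].to_numpy(int)
    b = counts[(library, "count_B")].to_numpy(int)
    total = a + b
    tested = total >= min_depth
    p = np.full(len(a), np.nan)
    for i in np.flatnonzero(tested):
        p[i] = binomtest(int(a[i]), int(total[i]), 0.5, alternative="two-sided").pvalue
    q = np.full(len(a), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    dea = tested & (q < alpha)
    direction = np.where(a > b, "A", np.where(b > a, "B", "="))
    table = pd.DataFrame(
        {"count_A": a, "count_B": b, "tested": tested, "p": p, "q": q, "dea": dea, "direction": direction},
        index=counts.index,
    )
    return DEACallSet(library=library, table=table)


def call_dea_all(counts: pd.DataFrame, alpha: float = 0.05, min_depth: int = 10) -> list:
    libs = counts.columns.get_level_values("library").unique()
    return [call_dea(counts, lib, alpha=alpha, min_depth=min_depth) for lib in libs]


def dea_union(call_sets: Iterable[DEACallSet]) -> set:
    out: set = set()
    for cs in call_sets:
        out |= cs.dea_genes
    return out


def saturation_curve(
    call_sets: Sequence[DEACallSet],
    k_values: Sequence[int],
    reps: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Union DEA count versus number of libraries sampled.

    For each k, draw ``reps`` random k-subsets of the libraries and record
    the size of the union of their DEA sets; when the number of distinct
    k-subsets is at most ``reps`` all subsets are enumerated exactly instead.
    Returns per-k mean and standard deviation of the union size.
    """
    rng = np.random.default_rng(seed)
    sets = [cs.dea_genes for cs in call_sets]
    n = len(sets)
    rows = []
    for k in k_values:
        if k < 0 or k > n:
            raise ValueError(f"k={k} outside [0, {n}]")
        if k == 0:
            rows.append({"k": 0, "mean_union": 0.0, "sd_union": 0.0, "n_draws": 1})
            continue
        if math.comb(n, k) <= reps:
            sizes = [len(set().union(*(sets[i] for i in combo))) for combo in itertools.combinations(range(n), k)]
        else:
            sizes = []
            for _ in range(reps):
                pick = rng.choice(n, size=k, replace=False)
                sizes.append(len(set().union(*(sets[i] for i in pick))))
        rows.append(
            {"k": k, "mean_union": float(np.mean(sizes)), "sd_union": float(np.std(sizes)), "n_draws": len(sizes)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction

_BASES = "ACGT"


def _codon_site_counts(codon: str) -> tuple:
    """(synonymous, nonsynonymous) potential site counts of one codon.

    Per position, the synonymous fraction is the share of the three possible
    substitutions that preserve the amino acid; mutations to stop codons are
    excluded from the denominator.
    """
    syn = 0.0
    for pos in range(3):
        s = n = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if translate_codon(mut) == translate_codon(codon):
                s += 1
            else:
                n += 1
        if s + n:
            syn += s / (s + n)
    return syn, 3.0 - syn


def _codon_path_differences(c1: str, c2: str) -> tuple:
    """(syn, nonsyn) differences between two codons, averaged over all
    mutation orders; paths passing through a stop codon are excluded."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                ok = False
                break
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all paths blocked by stops: fall back to counting all orders
        for order in itertools.permutations(diff):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if translate_codon(cur) == translate_codon(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    return (
        float(np.mean([p[0] for p in paths])),
        float(np.mean([p[1] for p in paths])),
    )


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:  # correction saturates; distance not estimable
        return float("nan")
    return -0.75 * math.log(1 - 4.0 * p / 3.0) + 0.0


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def allelic_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori Ka and Ks between an in-frame allelic CDS pair.

    Potential site counts are averaged over both sequences, observed
    differences are averaged over mutation paths per codon, and both
    proportions receive the Jukes-Cantor multiple-hit correction.  The
    Ka/Ks ratio is None when Ks = 0.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS lengths differ")
    if len(cds_a) % 3:
        raise ValueError("CDS length not a multiple of three")
    syn_sites = nonsyn_sites = syn_d = nonsyn_d = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            if i + 3 == len(cds_a):  # terminal stop: not a comparable codon
                continue
            raise ValueError(f"internal stop codon at nucleotide {i + 1}")
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        syn_sites += (sa + sb) / 2
        nonsyn_sites += (na + nb) / 2
        sd, nd = _codon_path_differences(ca, cb)
        syn_d += sd
        nonsyn_d += nd
    ks = _jukes_cantor(syn_d / syn_sites) if syn_sites else 0.0
    ka = _jukes_cantor(nonsyn_d / nonsyn_sites) if nonsyn_sites else 0.0
    ratio = ka / ks if ks > 0 and not (math.isnan(ka) or math.isnan(ks)) else None
    return KaKsResult(ka, ks, ratio, syn_sites, nonsyn_sites, syn_d, nonsyn_d)


def kaks_selection_summary(results: dict, purifying_max: float = 0.1, positive_min: float = 1.0) -> dict:
    """Counts and percentages of allelic pairs under strong purifying
    (Ka/Ks < purifying_max) and possible positive (Ka/Ks > positive_min)
    selection, over all annotated genes."""
    n_total = len(results)
    ratios = {g: r.ratio for g, r in results.items() if r.ratio is not None}
    n_pur = sum(1 for v in ratios.values() if v < purifying_max)
    n_pos = sum(1 for v in ratios.values() if v > positive_min)
    from .variant_impact import DivergenceSummary

    return {
        "n_total": n_total,
        "n_purifying": n_pur,
        "n_positive": n_pos,
        "pct_purifying": DivergenceSummary.percent(n_pur, n_total),
        "pct_positive": DivergenceSummary.percent(n_pos, n_total),
    }


# ---------------------------------------------------------------------------
# SNP density per gene feature

FEATURES = ("promoter", "utr5", "exon", "intron", "utr3", "downstream2kb")


def gene_feature_intervals(model: GeneModel, flank: int = 2000) -> dict:
    """0-based half-open intervals of each feature of one gene model.

    The promoter is ``flank`` bp upstream of the TSS; downstream2kb is
    ``flank`` bp past the 3' end; UTRs are exonic sequence outside the CDS
    span, split by strand.
    """
    g0, g1 = model.span()
    cds0 = model.cds[0][0]
    cds1 = model.cds[-1][1]
    exons = model.exons
    introns = [(a_end, b_start) for (_, a_end), (b_start, _) in zip(exons, exons[1:]) if b_start > a_end]
    left_utr = [(max(s, g0), min(e, cds0)) for s, e in exons if s < cds0]
    right_utr = [(max(s, cds1), e) for s, e in exons if e > cds1]
    left_utr = [(s, e) for s, e in left_utr if e > s]
    right_utr = [(s, e) for s, e in right_utr if e > s]
    if model.strand == "+":
        promoter = [(max(0, g0 - flank), g0)]
        downstream = [(g1, g1 + flank)]
        utr5, utr3 = left_utr, right_utr
    else:
        promoter = [(g1, g1 + flank)]
        downstream = [(max(0, g0 - flank), g0)]
        utr5, utr3 = right_utr, left_utr
    return {
        "promoter": promoter,
        "utr5": utr5,
        "exon": list(exons),
        "intron": introns,
        "utr3": utr3,
        "downstream2kb": downstream,
    }


def snp_feature_density(vt, models: Sequence[GeneModel], flank: int = 2000) -> pd.DataFrame:
    """SNPs per 100 bp in each gene feature, per gene plus an aggregate row.

    density = 100 * (SNP count in the feature) / (feature length in bp).
    """
    snp_pos: dict = {}
    bial = vt.is_biallelic_snp()
    for i in np.flatnonzero(bial):
        snp_pos.setdefault(str(vt.chrom[i]), []).append(int(vt.pos[i]) - 1)
    snp_pos = {c: np.array(sorted(v)) for c, v in snp_pos.items()}
    rows = []
    totals = {f: [0, 0] for f in FEATURES}  # feature -> [snps, bp]
    for m in models:
        pos = snp_pos.get(m.chrom, np.empty(0, dtype=int))
        rec = {"gene_id": m.gene_id}
        for feat, ivs in gene_feature_intervals(m, flank).items():
            length = sum(e - s for s, e in ivs)
            count = int(sum(((pos >= s) & (pos < e)).sum() for s, e in ivs))
            rec[feat] = 100.0 * count / length if length else np.nan
            totals[feat][0] += count
            totals[feat][1] += length
        rows.append(rec)
    agg = {"gene_id": "__aggregate__"}
    for f, (c, L) in totals.items():
        agg[f] = 100.0 * c / L if L else np.nan
    rows.append(agg)
    return pd.DataFrame(rows).set_index("gene_id")
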