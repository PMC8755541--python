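"""Population-genetic statistics: nucleotide diversity, Tajima's D, the
called-site-normalised pi_n/pi_s pipeline, Weir-Cockerham F_st, LD decay and
pruning, the f3 admixture statistic, and per-sample inbreeding coefficients.

All estimators operate on called alleles only: missing genotypes are excluded
site-wise, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, VariantTable

__all__ = [
    "sitewise_pi", "windowed_pi", "tajimas_d", "pin_pis", "PinPisResult",
    "weir_cockerham_fst", "ld_decay", "half_decay", "ld_prune",
    "f3_statistic", "inbreeding_coefficient", "CalledSiteCounts",
]


# ---------------------------------------------------------------------------
# nucleotide diversity

def _allele_counts(gt: np.ndarray) -> np.ndarray:
    """Counts of alleles 0..max over called alleles; gt is (sites, samples, 2)."""
    n_sites = gt.shape[0]
    flat = gt.reshape(n_sites, -1)
    n_alleles = int(max(2, flat.max() + 1)) if flat.size else 2
    counts = np.zeros((n_sites, n_alleles), dtype=np.int64)
    for a in range(n_alleles):
        counts[:, a] = (flat == a).sum(axis=1)
    return counts


def sitewise_pi(vt: VariantTable, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-site nucleotide diversity over called alleles.

    pi_site = sum_{a<b} n_a n_b / C(n, 2), the unbiased mean pairwise
    difference among the n called alleles.  Sites with fewer than two called
    alleles are omitted.

    Returns a DataFrame with columns chrom, pos, pi, n_called_alleles.
    """
    gt = vt.genotypes if samples is None else vt.genotypes[:, vt.sample_index(samples), :]
    counts = _allele_counts(gt)
    n = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = (n.astype(float) ** 2 - (counts.astype(float) ** 2).sum(axis=1)) / (n * (n - 1))
    keep = n >= 2
    return pd.DataFrame(
        {
            "chrom": vt.chrom[keep],
            "pos": vt.pos[keep],
            "pi": het[keep],
            "n_called_alleles": n[keep],
        }
    )


def windowed_pi(
    track: pd.DataFrame,
    window: int = 100_000,
    step: int = 10_000,
    chrom_lengths: dict | None = None,
    called_site_denominator: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window pi from a sitewise track.

    The window value is (sum of site pi in the window) / window length in bp:
    monomorphic and uncalled positions contribute zero to the numerator and
    full length to the denominator.  Pass ``called_site_denominator``
    ({chrom: per-window called-site counts}) to divide by called sites
    instead.
    """
    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1
        pi = sub["pi"].to_numpy()
        length = chrom_lengths[chrom] if chrom_lengths else int(pos0.max()) + 1
        start = 0
        while start < length:
            end = min(start + window, length)
            m = (pos0 >= start) & (pos0 < end)
            denom = end - start
            if called_site_denominator is not None:
                denom = called_site_denominator[chrom][start // step]
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "pi": pi[m].sum() / denom if denom else np.nan,
                    "n_sites": int(m.sum()),
                }
            )
            start += step
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tajima's D

def tajimas_d(vt: VariantTable, samples: Sequence[str] | None = None) -> float:
    """Tajima's D over the biallelic SNPs of the table.

    D = (theta_pi - theta_W) / sqrt(e1*S + e2*S*(S-1)) with the standard
    constants a1, a2, b1, b2, c1, c2, e1, e2 computed at the mean number of
    called alleles.  Indel records are skipped.  Returns NaN when S = 0
    (undefined, explicitly not zero).
    """
    vt = vt.take_sites(vt.is_biallelic_snp())
    gt = vt.genotypes if samples is None else vt.genotypes[:, vt.sample_index(samples), :]
    counts = _allele_counts(gt)[:, :2]
    n_site = counts.sum(axis=1)
    seg = (counts > 0).all(axis=1) & (n_site >= 2)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    n = int(round(n_site[seg].mean()))
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    c = counts[seg].astype(float)
    ns = n_site[seg].astype(float)
    theta_pi = float(((ns**2 - (c**2).sum(axis=1)) / (ns * (ns - 1))).sum())
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    theta_w = S / a1
    var = e1 * S + e2 * S * (S - 1)
    return (theta_pi - theta_w) / math.sqrt(var)


# ---------------------------------------------------------------------------
# pi_n / pi_s with called-site normalisation

@dataclass
class CalledSiteCounts:
    """Numbers of confidently called positions (from all-sites genotyping,
    monomorphic positions included) — the pi_n/pi_s denominators."""

    n_called_hq_models: int
    n_called_intergenic: int

    def __post_init__(self):
        if self.n_called_hq_models < 0 or self.n_called_intergenic < 0:
            raise ValueError("called-site counts must be nonnegative")


@dataclass
class PinPisResult:
    pi_n: float
    pi_s: float | None
    ratio: float | None
    sum_diversity_nonsyn: float
    sum_diversity_intergenic: float
    denominator_nonsyn: float
    denominator_intergenic: int


def pin_pis(
    diversity_nonsyn: Iterable[float],
    diversity_intergenic: Iterable[float],
    called: CalledSiteCounts,
) -> PinPisResult:
    """The called-site-normalised pi_n/pi_s estimator.

    pi_n sums sitewise diversity at HIGH/MODERATE-impact positions inside
    high-quality gene models and divides by two-thirds of the called
    positions in those models (operationally, every third exonic position is
    taken to be synonymous).  pi_s sums diversity at intergenic positions and
    divides by the intergenic called-position count.  The ratio is undefined
    (None) when pi_s is zero or undefined.
    """
    sum_n = float(np.sum(list(diversity_nonsyn)))
    sum_s = float(np.sum(list(diversity_intergenic)))
    denom_n = called.n_called_hq_models * 2.0 / 3.0
    if denom_n == 0:
        raise ValueError("no called positions inside high-quality gene models")
    pi_n = sum_n / denom_n
    if called.n_called_intergenic == 0:
        return PinPisResult(pi_n, None, None, sum_n, sum_s, denom_n, 0)
    pi_s = sum_s / called.n_called_intergenic
    ratio = pi_n / pi_s if pi_s > 0 else None
    return PinPisResult(pi_n, pi_s, ratio, sum_n, sum_s, denom_n, called.n_called_intergenic)


def pin_pis_from_tables(
    vt: VariantTable,
    impact_calls: Sequence,
    hq_models: Sequence,
    called: CalledSiteCounts,
    samples: Sequence[str] | None = None,
) -> PinPisResult:
    """pi_n/pi_s from a variant table plus impact calls.

    The table is subset to the population's samples before diversity is
    computed.  Numerator sites for pi_n are those with HIGH or MODERATE
    impact inside high-quality models; pi_s sites are those outside any gene
    span.
    """
    sub = vt if samples is None else vt.subset_samples(list(samples))
    track = sitewise_pi(sub)
    pi_by_locus = {(c, p): v for c, p, v in zip(track["chrom"], track["pos"], track["pi"])}
    hq_ids = {m.gene_id for m in hq_models}
    spans = {}
    for m in hq_models:
        spans.setdefault(m.chrom, []).append(m.span())
    nonsyn, intergenic = [], []
    for c in impact_calls:
        v = pi_by_locus.get((c.chrom, c.pos), 0.0)
        if c.impact in ("HIGH", "MODERATE") and c.gene_id in hq_ids:
            nonsyn.append(v)
        elif c.gene_id is None and not _in_any_span(spans.get(c.chrom, ()), c.pos - 1):
            intergenic.append(v)
    return pin_pis(nonsyn, intergenic, called)


def _in_any_span(spans, pos0: int) -> bool:
    return any(s <= pos0 < e for s, e in spans)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_st

def _wc_components(vt: VariantTable, pop_indices: list) -> tuple:
    """Per-site Weir & Cockerham (1984) variance components a, b, c.

    Diploid formulation with the heterozygosity term; sites monomorphic
    across all populations (or with <2 called alleles in any population used)
    get NaN components and are skipped by callers.
    """
    r = len(pop_indices)
    n_i = np.zeros((vt.n_sites, r))      # diploid sample sizes
    p_i = np.zeros((vt.n_sites, r))      # alt-allele frequencies
    h_i = np.zeros((vt.n_sites, r))      # observed het frequencies
    for k, idx in enumerate(pop_indices):
        gt = vt.genotypes[:, idx, :]
        called = np.all(gt != MISSING, axis=2)
        nk = called.sum(axis=1).astype(float)
        alt = np.where(called, (gt > 0).sum(axis=2), 0).astype(float)
        het = np.where(called, (gt[:, :, 0] != gt[:, :, 1]), False).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i[:, k] = alt.sum(axis=1) / (2 * nk)
            h_i[:, k] = het / nk
        n_i[:, k] = nk
    ok = (n_i >= 1).all(axis=1) & (n_i.sum(axis=1) >= 2)
    n_bar = n_i.mean(axis=1)
    n_sum = n_i.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (n_sum - (n_i**2).sum(axis=1) / n_sum) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=1) / n_sum
        s2 = (n_i * (p_i - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=1) / n_sum
        a = (n_bar / nc) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    poly = ok & (p_bar > 0) & (p_bar < 1)
    return a, b, c, poly


def weir_cockerham_fst(
    vt: VariantTable,
    populations: dict,
    window: int | None = 100_000,
) -> tuple:
    """Weir & Cockerham (1984) theta, windowed and genome-wide.

    ``populations`` maps population label -> list of sample ids.  The
    "weighted" estimate is the ratio of sums, theta = sum(a)/sum(a+b+c),
    computed over polymorphic sites — per window of ``window`` bp and
    genome-wide.  Returns ``(window_frame, genome_theta)``; pass
    ``window=None`` to skip windowing.
    """
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    pop_indices = [vt.sample_index(ids) for ids in populations.values()]
    a, b, c, poly = _wc_components(vt, pop_indices)
    denom = a + b + c
    use = poly & np.isfinite(denom) & (denom != 0)
    genome_theta = float(a[use].sum() / denom[use].sum()) if use.any() else float("nan")
    if window is None:
        return None, genome_theta
    rows = []
    for chrom in pd.unique(vt.chrom):
        on = (vt.chrom == chrom) & use
        if not on.any():
            continue
        w = (vt.pos[on] - 1) // window
        df = pd.DataFrame({"w": w, "a": a[on], "d": denom[on]})
        g = df.groupby("w").sum()
        for wi, row in g.iterrows():
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(wi) * window,
                    "end": (int(wi) + 1) * window,
                    "theta": row["a"] / row["d"] if row["d"] else np.nan,
                    "n_sites": int((df["w"] == wi).sum()),
                }
            )
    return pd.DataFrame(rows), genome_theta


# ---------------------------------------------------------------------------
# linkage disequilibrium

def _pairwise_r2(dos: np.ndarray, pos: np.ndarray, max_dist: int):
    """r^2 (squared dosage correlation) for all site pairs within max_dist."""
    n_sites = dos.shape[0]
    out_d, out_r2 = [], []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            d = int(pos[j] - pos[i])
            if d <= 0 or d > max_dist:
                if d > max_dist:
                    break
                continue
            both = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
            x, y = dos[i][both], dos[j][both]
            if len(x) < 2 or x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            out_d.append(d)
            out_r2.append(r * r)
    return np.array(out_d), np.array(out_r2)


def pairwise_r2(vt: VariantTable, samples: Sequence[str] | None = None, max_dist: int = 500_000):
    """(distance, r^2) arrays for all within-chromosome site pairs inside
    ``max_dist``; r^2 is the squared correlation of genotype dosages."""
    dos = vt.dosage(samples)
    dists, r2s = [], []
    for c in pd.unique(vt.chrom):
        on = vt.chrom == c
        d, r2 = _pairwise_r2(dos[on], vt.pos[on], max_dist)
        dists.append(d)
        r2s.append(r2)
    return (np.concatenate(dists) if dists else np.empty(0),
            np.concatenate(r2s) if r2s else np.empty(0))


@dataclass
class LDDecayCurve:
    distance: np.ndarray
    r2: np.ndarray
    beta0: float
    beta1: float

    def fitted_at(self, d) -> np.ndarray:
        return self.beta0 + self.beta1 * np.log10(d)


def ld_decay(
    vt: VariantTable,
    samples: Sequence[str] | None = None,
    max_dist: int = 500_000,
    r2_min: float = 0.01,
    min_minor_count: int = 4,
) -> LDDecayCurve:
    """LD decay: r^2 versus distance within ``max_dist``, fitted linearly on
    log10(distance).

    Sites must be biallelic SNPs with minor allele count strictly greater
    than ``min_minor_count``; only pairs with r^2 > ``r2_min`` enter the
    curve, matching the reporting convention of the decay analysis.
    """
    vt = vt.take_sites(vt.is_biallelic_snp())
    dos = vt.dosage(samples)
    alt = np.nansum(dos, axis=1)
    n2 = 2 * (~np.isnan(dos)).sum(axis=1)
    minor = np.minimum(alt, n2 - alt)
    vt2_idx = minor > min_minor_count
    dos = dos[vt2_idx]
    pos = vt.pos[vt2_idx]
    chrom = vt.chrom[vt2_idx]
    dists, r2s = [], []
    for c in pd.unique(chrom):
        on = chrom == c
        d, r2 = _pairwise_r2(dos[on], pos[on], max_dist)
        dists.append(d)
        r2s.append(r2)
    d = np.concatenate(dists) if dists else np.empty(0)
    r2 = np.concatenate(r2s) if r2s else np.empty(0)
    keep = r2 > r2_min
    d, r2 = d[keep], r2[keep]
    if len(d) < 2:
        raise ValueError("too few informative pairs for a decay fit")
    X = np.log10(d)
    beta1, beta0 = np.polyfit(X, r2, 1)
    return LDDecayCurve(distance=d, r2=r2, beta0=float(beta0), beta1=float(beta1))


def half_decay(curve: LDDecayCurve) -> float | None:
    """Distance where the fitted line drops to half its initial value.

    The initial value r0 is the fitted value at the smallest observed
    distance; the half-decay point solves beta0 + beta1*log10(d) = r0/2.
    None when the fit does not decay (beta1 >= 0).
    """
    if curve.beta1 >= 0:
        return None
    r0 = float(curve.fitted_at(curve.distance.min()))
    return float(10 ** ((0.5 * r0 - curve.beta0) / curve.beta1))


def ld_prune(
    vt: VariantTable,
    samples: Sequence[str] | None = None,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.1,
) -> VariantTable:
    """LD pruning over sliding windows of ``window`` SNPs advancing by
    ``step`` SNPs: of any pair with r^2 > ``r2_max``, remove the SNP with the
    lower minor-allele frequency (tie: the larger coordinate).
    """
    snp = vt.take_sites(vt.is_biallelic_snp())
    dos = snp.dosage(samples)
    alt = np.nansum(dos, axis=1)
    n2 = 2 * (~np.isnan(dos)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(alt, n2 - alt) / n2
    removed = np.zeros(snp.n_sites, dtype=bool)
    start = 0
    while True:
        idx = [i for i in range(start, min(start + window, snp.n_sites)) if not removed[i]]
        for ii, i in enumerate(idx):
            if removed[i]:
                continue
            for j in idx[ii + 1 :]:
                if removed[i] or removed[j]:
                    continue
                both = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
                x, y = dos[i][both], dos[j][both]
                if len(x) < 2 or x.std() == 0 or y.std() == 0:
                    continue
                r2 = np.corrcoef(x, y)[0, 1] ** 2
                if r2 > r2_max:
                    if maf[i] < maf[j]:
                        removed[i] = True
                    elif maf[j] < maf[i]:
                        removed[j] = True
                    else:  # tie: drop the larger coordinate
                        removed[j if snp.pos[j] > snp.pos[i] else i] = True
        if start + window >= snp.n_sites:
            break
        start += step
    return snp.take_sites(~removed)


# ---------------------------------------------------------------------------
# f3 admixture statistic

def f3_statistic(
    vt: VariantTable,
    target: Sequence[str],
    source_a: Sequence[str],
    source_b: Sequence[str],
    block_size: int = 5_000,
    correction: bool = True,
) -> dict:
    """f3(target; A, B) with block-jackknife standard error.

    Per usable site, f3 = (c-a)(c-b) minus (when ``correction`` is on) the
    finite-sample heterozygosity correction h_c/n_c for the target, where
    h_c = n_c c (1-c)/(n_c - 1) and n_c is the number of called target
    alleles.  A Z score below about -3 signals admixture of the target
    between sources related to A and B.
    """
    vt = vt.take_sites(vt.is_biallelic_snp())
    freqs, ns = [], []
    for ids in (target, source_a, source_b):
        gt = vt.genotypes[:, vt.sample_index(list(ids)), :]
        called = gt != MISSING
        n = called.sum(axis=(1, 2)).astype(float)
        alt = (gt > 0).sum(axis=(1, 2)).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs.append(alt / n)
        ns.append(n)
    c, a, b = freqs
    n_c = ns[0]
    use = np.isfinite(c) & np.isfinite(a) & np.isfinite(b) & (n_c >= 2)
    c, a, b, n_c = c[use], a[use], b[use], n_c[use]
    terms = (c - a) * (c - b)
    if correction:
        h_c = n_c * c * (1 - c) / (n_c - 1)
        terms = terms - h_c / n_c
    m = len(terms)
    if m == 0:
        raise ValueError("no usable sites for f3")
    f3 = float(terms.mean())
    n_blocks = max(1, m // block_size)
    if n_blocks < 2:
        return {"f3": f3, "se": None, "z": None, "n_sites": m, "n_blocks": n_blocks}
    blocks = np.array_split(terms, n_blocks)
    loo = np.array([(terms.sum() - blk.sum()) / (m - len(blk)) for blk in blocks])
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    z = f3 / se if se > 0 else float("nan")
    return {"f3": f3, "se": se, "z": float(z), "n_sites": m, "n_blocks": n_blocks}


# ---------------------------------------------------------------------------
# inbreeding coefficient

def inbreeding_coefficient(vt: VariantTable, sample: str) -> float:
    """Method-of-moments F from the deficit of heterozygosity.

    F = (O_hom - E_hom) / (L - E_hom) with E_hom = sum over the sample's
    called sites of 1 - 2 p q n/(n-1), p the sample-frequency of the
    alternate allele and n the called allele count at the site; L is the
    number of sites where the sample is called.  Negative values indicate
    excess heterozygosity (e.g. F1 hybrids of diverged parents).
    """
    vt = vt.take_sites(vt.is_biallelic_snp())
    j = vt.sample_index([sample])[0]
    gt = vt.genotypes
    called_all = gt != MISSING
    n = called_all.sum(axis=(1, 2)).astype(float)
    alt = (gt > 0).sum(axis=(1, 2)).astype(float)
    sample_called = np.all(gt[:, j, :] != MISSING, axis=1)
    use = sample_called & (n > 1)
    p = alt[use] / n[use]
    q = 1 - p
    e_hom = float((1 - 2 * p * q * n[use] / (n[use] - 1)).sum())
    o_hom = float((gt[use, j, 0] == gt[use, j, 1]).sum())
    L = int(use.sum())
    if L == 0 or L == e_hom:
        return float("nan")
    return (o_hom - e_hom) / (L - e_hom)
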