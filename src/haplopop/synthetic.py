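"""Synthetic-data generators with ground truth.

Every input the pipeline consumes can be generated here: a two-population
Balding-Nichols genotype panel with admixed F1s and within-population
inbreeding, Mendelian pedigree genotypes, a two-haplotype annotated genome
carrying a planted multi-kb deletion, allele-specific expression count
matrices, and per-base coverage tracks.  All generators are fully
deterministic under a fixed seed; sub-streams are derived from the master
seed through fixed spawn keys so each generator's output is independently
reproducible.

Default parameters follow the study system the package models: two diverged
wild source populations (drift parameter F = 0.15), 20 diploids per
population with an 8-sample F1 cultivar group, haplotype divergence around
2.3 differences per 100 bp, and a planted deletion of 3,781 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, VariantTable
from .variant_impact import GeneModel

BASES = np.array(list("ACGT"))


def _rng(seed: int, key: int) -> np.random.Generator:
    """Deterministic sub-stream ``key`` of the master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class SimulationParams:
    """Parameters of the two-population genotype simulation.

    divergence_F is the Balding-Nichols drift parameter of each source
    population relative to the shared ancestor; inbreeding_F_within is the
    probability that an individual's second allele copies its first
    (expected heterozygosity deficit = F_within).
    """

    seed: int
    n_sites: int = 10_000
    n_per_population: tuple = (20, 20)
    n_admixed: int = 8
    divergence_F: float = 0.15
    ancestral_freq_range: tuple = (0.05, 0.95)
    inbreeding_F_within: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.divergence_F < 1:
            raise ValueError("divergence_F must be in (0, 1)")
        for f in self.inbreeding_F_within:
            if not 0 <= f < 1:
                raise ValueError("inbreeding_F_within must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generators; unused fields stay None."""

    seed: int
    ancestral_freq: np.ndarray | None = None
    population_freqs: np.ndarray | None = None      # (n_pops, n_sites)
    sample_population: dict | None = None           # sample -> label
    haplotype_origin: dict | None = None            # sample -> (popA, popB) per haplotype
    relationship_degrees: pd.DataFrame | None = None
    deletion_interval: tuple | None = None          # (chrom, start0, end0) on the reference
    deletion_carrier_haplotype: str | None = None
    dea_genes: dict | None = None                   # gene -> true allelic ratio theta
    gene_models: list | None = None
    malformed_genes: list | None = None


def _draw_diploids(q: np.ndarray, n: int, f_within: float, rng) -> np.ndarray:
    """(n_sites, n, 2) genotypes at per-site alt frequency q with inbreeding."""
    n_sites = len(q)
    a1 = rng.random((n_sites, n)) < q[:, None]
    copy = rng.random((n_sites, n)) < f_within
    a2_draw = rng.random((n_sites, n)) < q[:, None]
    a2 = np.where(copy, a1, a2_draw)
    return np.stack([a1, a2], axis=2).astype(np.int16)


def simulate_two_population_genotypes(params: SimulationParams):
    """Balding-Nichols two-population panel with F1 admixed samples.

    Per site an ancestral frequency p is drawn uniformly from
    ``ancestral_freq_range``; each source population's frequency comes from a
    Beta with mean p and variance p(1-p)F.  Diploid genotypes are drawn with
    within-population inbreeding; each admixed sample receives one haplotype
    drawn from each source population's frequency.

    Returns ``(VariantTable, SyntheticTruth)``.
    """
    rng = _rng(params.seed, 1)
    lo, hi = params.ancestral_freq_range
    F = params.divergence_F
    p = rng.uniform(lo, hi, params.n_sites)
    shape = (1 - F) / F
    n_resampled = 0
    qs = []
    for _ in range(2):
        q = rng.beta(p * shape, (1 - p) * shape)
        bad = (q <= 0) | (q >= 1)
        n_resampled += int(bad.sum())
        while bad.any():
            q[bad] = rng.beta(p[bad] * shape, (1 - p[bad]) * shape)
            bad = (q <= 0) | (q >= 1)
        qs.append(q)
    if n_resampled > 0.5 * params.n_sites:
        raise RuntimeError(f"degenerate frequencies resampled at {n_resampled} draws (>50% of sites)")
    q1, q2 = qs
    blocks, names, pops, origins = [], [], {}, {}
    for k, (q, n) in enumerate(zip(qs, params.n_per_population)):
        blocks.append(_draw_diploids(q, n, params.inbreeding_F_within[k], rng))
        for i in range(n):
            s = f"P{k + 1}_{i:03d}"
            names.append(s)
            pops[s] = f"pop{k + 1}"
            origins[s] = (f"pop{k + 1}", f"pop{k + 1}")
    if params.n_admixed:
        hapA = rng.random((params.n_sites, params.n_admixed)) < q1[:, None]
        hapB = rng.random((params.n_sites, params.n_admixed)) < q2[:, None]
        blocks.append(np.stack([hapA, hapB], axis=2).astype(np.int16))
        for i in range(params.n_admixed):
            s = f"F1_{i:03d}"
            names.append(s)
            pops[s] = "admixed"
            origins[s] = ("pop1", "pop2")
    gt = np.concatenate(blocks, axis=1)
    refs, alts = _random_snp_alleles(params.n_sites, rng)
    vt = VariantTable(
        chrom=np.array(["chr1"] * params.n_sites, dtype=object),
        pos=np.arange(1, params.n_sites + 1, dtype=np.int64) * 100,
        ref=refs,
        alt=alts,
        annotations=_passing_annotations(params.n_sites, rng),
        genotypes=gt,
        samples=names,
    )
    truth = SyntheticTruth(
        seed=params.seed,
        ancestral_freq=p,
        population_freqs=np.vstack([q1, q2]),
        sample_population=pops,
        haplotype_origin=origins,
    )
    return vt, truth


def _random_snp_alleles(n: int, rng):
    ref_idx = rng.integers(0, 4, n)
    shift = rng.integers(1, 4, n)
    alt_idx = (ref_idx + shift) % 4
    return list(BASES[ref_idx]), [[b] for b in BASES[alt_idx]]


def _passing_annotations(n: int, rng) -> dict:
    """Site annotations drawn well inside the hard-filter pass bands."""
    return {
        "QD": rng.uniform(20, 35, n),
        "FS": rng.uniform(0, 5, n),
        "MQ": rng.uniform(55, 60, n),
        "SOR": rng.uniform(0.5, 2.0, n),
        "DP": rng.uniform(800, 1500, n),
        "MQRankSum": rng.normal(0, 1, n),
        "ReadPosRankSum": rng.normal(0, 1, n),
    }


# ---------------------------------------------------------------------------
# pedigree

def pedigree_kinship(samples: list, pedigree: list) -> pd.DataFrame:
    """Expected kinship coefficients from a pedigree by the standard
    recursion; clones (single-parent entries) are treated as genetic copies.

    ``pedigree`` lists (child, parentA, parentB) with parentB None for a
    clone; parents must precede children.  Founders are all samples never
    appearing as a child.
    """
    parents = {c: (a, b) for c, a, b in pedigree}
    order = [s for s in samples if s not in parents] + [c for c, _, _ in pedigree]
    phi = {}

    def get(x, y):
        return phi[(x, y)] if (x, y) in phi else phi.get((y, x), 0.0)

    for i, s in enumerate(order):
        if s not in parents:
            phi[(s, s)] = 0.5
            continue
        pa, pb = parents[s]
        if pb is None:  # clone
            phi[(s, s)] = get(pa, pa)
            for t in order[:i]:
                phi[(s, t)] = get(pa, t) if t != pa else get(pa, pa)
        else:
            for p in (pa, pb):
                if p not in order[:i]:
                    raise ValueError(f"parent {p!r} of {s!r} not defined before child")
            phi[(s, s)] = 0.5 * (1 + get(pa, pb))
            for t in order[:i]:
                phi[(s, t)] = 0.5 * (get(pa, t) + get(pb, t))
    rows = []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            rows.append({"sample_i": a, "sample_j": b, "phi_expected": get(a, b)})
    return pd.DataFrame(rows)


def _degree_from_phi(phi: float) -> str:
    from .kinship import classify_relationship

    return classify_relationship(phi)


def simulate_pedigree_genotypes(founders: VariantTable, pedigree: list, seed: int):
    """Extend a founder panel by Mendelian sampling along a pedigree.

    Each child receives one uniformly chosen allele per parent per site; a
    single-parent entry copies the parent's genotypes (a clone).  Truth
    records the expected kinship and relationship degree for every pair.
    """
    rng = _rng(seed, 2)
    gt = {s: founders.genotypes[:, i, :].copy() for i, s in enumerate(founders.samples)}
    for child, pa, pb in pedigree:
        if pa not in gt or (pb is not None and pb not in gt):
            raise ValueError(f"pedigree parent of {child!r} absent from panel")
        if pb is None:
            gt[child] = gt[pa].copy()
        else:
            n_sites = founders.n_sites
            pick_a = rng.integers(0, 2, n_sites)
            pick_b = rng.integers(0, 2, n_sites)
            gt[child] = np.stack(
                [gt[pa][np.arange(n_sites), pick_a], gt[pb][np.arange(n_sites), pick_b]], axis=1
            )
    names = list(gt)
    out = VariantTable(
        chrom=founders.chrom.copy(),
        pos=founders.pos.copy(),
        ref=list(founders.ref),
        alt=list(founders.alt),
        annotations={k: v.copy() for k, v in founders.annotations.items()},
        genotypes=np.stack([gt[s] for s in names], axis=1),
        samples=names,
    )
    deg = pedigree_kinship(names, pedigree)
    deg["degree"] = [_degree_from_phi(p) for p in deg["phi_expected"]]
    truth = SyntheticTruth(seed=seed, relationship_degrees=deg)
    return out, truth


# ---------------------------------------------------------------------------
# genome + annotation + deletion

STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(length: int, rng) -> str:
    """ATG + random non-stop codons + stop; length divisible by 3, >= 9."""
    n_mid = length // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_mid + 1:
        c = "".join(rng.choice(BASES, 3))
        if c not in STOPS:
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


def generate_genome_with_annotation(
    n_genes: int = 40,
    mean_gene_length: int = 900,
    deletion_length: int = 3781,
    snp_rate: float = 0.02,
    indel_rate: float = 0.003,
    malformed_fraction: float = 0.0,
    intergenic_length: int = 6000,
    seed: int = 0,
    deletion_after_gene: int | None = None,
):
    """Two divergent haplotype sequences plus a GFF3-style annotation.

    The reference haplotype ("HH") is built as alternating intergenic
    spacers and genes; the second haplotype ("HY") differs by SNPs and short
    indels at a combined density of about 2.3 per 100 bp by default and
    carries a deletion of ``deletion_length`` bp planted in the intergenic
    region downstream of a designated gene.  A ``malformed_fraction`` of the
    gene models is deliberately broken (non-ATG start or CDS length not
    divisible by three) to exercise the high-quality model filter.

    Returns ``(genomes, models, truth)`` where ``genomes`` maps haplotype
    name ("HH", "HY") to {chrom: sequence}; coordinates (models, truth
    deletion interval) refer to the reference haplotype HH.
    """
    rng = _rng(seed, 3)
    if deletion_after_gene is None:
        deletion_after_gene = n_genes // 2
    chrom = "chr1"
    parts = []
    models: list = []
    malformed: list = []
    pos = 0

    def spacer(extra: int = 0):
        nonlocal pos
        L = intergenic_length + extra + int(rng.integers(0, 1000))
        parts.append("".join(rng.choice(BASES, L)))
        pos += L

    spacer()
    deletion_interval = None
    for g in range(n_genes):
        L = max(9, 3 * int(rng.normal(mean_gene_length, mean_gene_length / 5) // 3))
        cds = _random_cds(L, rng)
        broken = rng.random() < malformed_fraction
        if broken:
            if rng.random() < 0.5:
                cds = "GTG" + cds[3:]           # non-ATG start
                reason = "non-ATG start"
            else:
                cds = cds + "A"                 # length not divisible by three
                reason = "length not divisible by three"
            malformed.append((f"gene{g:04d}", reason))
        start = pos
        strand = "+" if rng.random() < 0.7 else "-"
        seq = cds
        if strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            seq = "".join(comp[b] for b in reversed(cds))
        parts.append(seq)
        pos += len(seq)
        end = pos
        tss = start if strand == "+" else end - 1
        models.append(
            GeneModel(
                gene_id=f"gene{g:04d}",
                chrom=chrom,
                strand=strand,
                exons=[(start, end)],
                cds=[(start, end)],
                tss=tss,
            )
        )
        if g == deletion_after_gene:
            gap = 500 + int(rng.integers(0, 200))
            parts.append("".join(rng.choice(BASES, gap)))
            pos += gap
            deletion_interval = (chrom, pos, pos + deletion_length)
            parts.append("".join(rng.choice(BASES, deletion_length)))
            pos += deletion_length
            spacer()
        else:
            spacer()
    reference = "".join(parts)
    if deletion_interval is None:
        raise ValueError(f"deletion_after_gene={deletion_after_gene} outside gene range")
    hy = _mutate_haplotype(reference, models, deletion_interval, snp_rate, indel_rate, rng)
    genomes = {"HH": {chrom: reference}, "HY": {chrom: hy}}
    truth = SyntheticTruth(
        seed=seed,
        deletion_interval=deletion_interval,
        deletion_carrier_haplotype="HY",
        gene_models=models,
        malformed_genes=malformed,
    )
    return genomes, models, truth


def _mutate_haplotype(reference, models, deletion_interval, snp_rate, indel_rate, rng):
    """Apply SNPs/short indels outside CDS plus the deletion.

    Edits are applied right to left so every edit's coordinate is valid on
    the reference at apply time; a 1 kb buffer around the deletion is kept
    mutation-free so primer sites and product arithmetic stay exact.
    """
    protected = np.zeros(len(reference), dtype=bool)
    for m in models:
        for s, e in m.cds:
            protected[s:e] = True
    _, dstart, dend = deletion_interval
    protected[max(0, dstart - 1000) : min(len(reference), dend + 1000)] = True
    seq = list(reference)
    edits = [(dstart, "deletion")]
    for i in np.flatnonzero(~protected):
        u = rng.random()
        if u < snp_rate:
            edits.append((i, "snp"))
        elif u < snp_rate + indel_rate:
            edits.append((i, "indel"))
    for i, kind in sorted(edits, reverse=True):
        if kind == "deletion":
            del seq[dstart:dend]
        elif kind == "snp":
            seq[i] = BASES[(int(np.flatnonzero(BASES == seq[i])[0]) + int(rng.integers(1, 4))) % 4]
        elif rng.random() < 0.5:
            k = int(rng.integers(1, 4))
            if not protected[i : i + k].any():
                del seq[i : i + k]
        else:
            seq.insert(i, "".join(rng.choice(BASES, int(rng.integers(1, 4)))))
    return "".join(seq)


def design_deletion_primers(reference: str, deletion_interval: tuple, primer_len: int = 20):
    """Three-primer set bracketing the planted deletion (labels a1/b1/c1).

    a1: forward, upstream of the deletion; b1: reverse, inside the deletion
    (its site is lost on the deleted haplotype); c1: reverse, downstream.
    Returns a :class:`haplopop.structural.PrimerSet` with a maximum amplicon
    length between the deleted and non-deleted a1+c1 product sizes, so band
    patterns separate the three diploid configurations.
    """
    from Bio.Seq import Seq

    from .structural import Primer, PrimerSet

    _, dstart, dend = deletion_interval
    a1_start = dstart - 400
    b1_end = dstart + 320
    c1_end = dend + 320
    a1 = reference[a1_start : a1_start + primer_len]
    b1 = str(Seq(reference[b1_end - primer_len : b1_end]).reverse_complement())
    c1 = str(Seq(reference[c1_end - primer_len : c1_end]).reverse_complement())
    deleted_product = (c1_end - a1_start) - (dend - dstart)
    non_deleted_ab = b1_end - a1_start
    max_amp = max(deleted_product, non_deleted_ab) + 200
    return PrimerSet(
        primers=[Primer("a1", a1, "forward"), Primer("b1", b1, "reverse"), Primer("c1", c1, "reverse")],
        max_amplicon=max_amp,
    )


# ---------------------------------------------------------------------------
# allele-specific expression counts

def simulate_allelic_counts(
    genes: list,
    n_libraries: int = 39,
    mean_depth: float = 100.0,
    dea_fraction: float = 0.3,
    theta_dea: float = 0.8,
    seed: int = 0,
):
    """Allele count matrices for ``n_libraries`` expression libraries.

    Non-DEA genes draw the first-allele count Binomial(depth, 0.5); genes in
    the true DEA set use Binomial(depth, theta_dea); per-gene, per-library
    depths are Poisson(mean_depth).  Returns ``(counts, truth)`` with
    ``counts`` a DataFrame indexed by gene with columns
    (library, allele) -> count.
    """
    rng = _rng(seed, 4)
    n_dea = int(round(dea_fraction * len(genes)))
    dea_idx = rng.choice(len(genes), size=n_dea, replace=False) if n_dea else np.array([], dtype=int)
    theta = np.full(len(genes), 0.5)
    theta[dea_idx] = theta_dea
    data = {}
    for lib in range(n_libraries):
        depth = rng.poisson(mean_depth, len(genes))
        a = rng.binomial(depth, theta)
        data[(f"lib{lib:02d}", "count_A")] = a
        data[(f"lib{lib:02d}", "count_B")] = depth - a
    counts = pd.DataFrame(data, index=list(genes))
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["library", "allele"])
    truth = SyntheticTruth(seed=seed, dea_genes={genes[i]: theta_dea for i in dea_idx})
    return counts, truth


# ---------------------------------------------------------------------------
# coverage

def simulate_coverage(
    chrom_length: int,
    deletion_interval: tuple,
    sample_genotypes: dict,
    mean_depth: float = 30.0,
    seed: int = 0,
    chrom: str = "chr1",
) -> dict:
    """Per-base Poisson coverage with the deletion's copy-loss imprinted.

    ``sample_genotypes`` maps sample -> number of deleted copies g in
    {0, 1, 2}; inside the deletion the Poisson rate is scaled by (2 - g)/2.
    Returns {sample: depth array of length chrom_length}.
    """
    rng = _rng(seed, 5)
    _, dstart, dend = deletion_interval
    out = {}
    for sample, g in sample_genotypes.items():
        lam = np.full(chrom_length, float(mean_depth))
        lam[dstart:dend] *= (2 - g) / 2.0
        out[sample] = rng.poisson(lam)
    return out


def coverage_to_bed(depth: np.ndarray, chrom: str = "chr1") -> pd.DataFrame:
    """Run-length encode a per-base depth array as a BED-like frame."""
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(depth)]])
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "depth": depth[starts]}
    )
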