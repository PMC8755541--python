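"""Variant effect classification against gene models, high-quality model
filtering, and haplotype divergence / mutational-load summaries.

The effect classifier is deliberately minimal: it covers exactly the impact
classes the downstream diversity analysis consumes (HIGH / MODERATE / LOW /
MODIFIER) with one transcript per gene and no regulatory-region logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io_formats import MISSING, VariantTable

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)

#: severity order, most severe first
IMPACT_ORDER = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_SEVERITY = {c: i for i, c in enumerate(IMPACT_ORDER)}


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop."""
    return "*" if codon in STOP_CODONS else CODON_TABLE[codon]


@dataclass
class GeneModel:
    """A single-transcript gene model; intervals 0-based half-open, sorted."""

    gene_id: str
    chrom: str
    strand: str
    exons: list  # [(start, end)]
    cds: list    # [(start, end)]
    tss: int     # 0-based position of transcription start

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for ivs in (self.exons, self.cds):
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c < b:
                    raise ValueError(f"{self.gene_id}: overlapping intervals")

    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_sequence(self, genome: dict) -> str:
        """Spliced CDS in translation orientation."""
        seq = "".join(genome[self.chrom][s:e] for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_offset(self, pos0: int) -> int | None:
        """Offset of genomic position within the spliced, oriented CDS, or None."""
        off = 0
        for s, e in self.cds:
            if s <= pos0 < e:
                fwd = off + (pos0 - s)
                return fwd if self.strand == "+" else self.cds_length - 1 - fwd
            off += e - s
        return None

    def in_exon(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)


@dataclass
class ImpactCall:
    chrom: str
    pos: int          # 1-based
    ref: str
    alt: str
    gene_id: str | None
    impact: str
    codon_change: tuple | None = None  # (ref_codon, alt_codon) for coding SNPs

    @property
    def severity(self) -> int:
        return _SEVERITY[self.impact]


def filter_high_quality_models(models: Sequence[GeneModel], genome: dict):
    """Split models into (kept, rejected) under the high-quality criteria:
    the CDS must start with ATG (strand-aware) and its total length must be
    divisible by three.

    Returns ``(kept, rejected)`` with ``rejected`` a list of
    ``(model, reason)`` pairs.
    """
    absent = sorted({m.chrom for m in models} - set(genome))
    if absent:
        raise ValueError(f"model chromosomes absent from genome: {absent}")
    kept, rejected = [], []
    for m in models:
        cds = m.cds_sequence(genome)
        if len(cds) % 3 != 0:
            rejected.append((m, "length not divisible by three"))
        elif not cds.startswith("ATG"):
            rejected.append((m, "non-ATG start"))
        else:
            kept.append(m)
    return kept, rejected


def _classify_against_model(pos0: int, ref: str, alt: str, model: GeneModel, genome: dict) -> ImpactCall:
    is_snp = len(ref) == 1 and len(alt) == 1
    mk = lambda impact, codon_change=None: ImpactCall(
        model.chrom, pos0 + 1, ref, alt, model.gene_id, impact, codon_change
    )
    off = model.cds_offset(pos0) if is_snp else None
    if is_snp:
        if off is None:
            return mk("MODIFIER")  # intron or UTR
        cds = model.cds_sequence(genome)
        base = ref if model.strand == "+" else str(Seq(ref).complement())
        alt_base = alt if model.strand == "+" else str(Seq(alt).complement())
        if cds[off] != base:
            # reference mismatch against supplied genome; classify from genome base
            base = cds[off]
        ci = off // 3
        ref_codon = cds[ci * 3 : ci * 3 + 3]
        alt_codon = ref_codon[: off % 3] + alt_base + ref_codon[off % 3 + 1 :]
        if len(ref_codon) < 3:
            return mk("MODIFIER")
        aa_ref, aa_alt = translate_codon(ref_codon), translate_codon(alt_codon)
        codons = (ref_codon, alt_codon)
        if aa_ref == aa_alt:
            return mk("LOW", codons)
        if aa_alt == "*" or aa_ref == "*":
            return mk("HIGH", codons)  # stop gained / lost
        return mk("MODERATE", codons)
    # indel: affected span on the reference
    span_end = pos0 + max(len(ref), 1)
    overlaps_cds = any(s < span_end and pos0 < e for s, e in model.cds)
    if overlaps_cds:
        shift = abs(len(alt) - len(ref))
        return mk("MODERATE" if shift % 3 == 0 else "HIGH")
    # an indel truncating an exon boundary is treated as HIGH
    for s, e in model.exons:
        if pos0 < s < span_end or pos0 < e < span_end:
            return mk("HIGH")
    return mk("MODIFIER")


def classify_variant_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    models: Sequence[GeneModel],
    genome: dict,
    all_calls: bool = False,
):
    """Classify one variant (1-based ``pos``) against gene models.

    When a variant overlaps several genes it is classified against each and
    the most severe call is returned; pass ``all_calls=True`` to receive the
    full list (most severe first).
    """
    pos0 = pos - 1
    calls = []
    for m in models:
        if m.chrom != chrom:
            continue
        g0, g1 = m.span()
        if g0 <= pos0 < g1 or (g0 < pos0 + len(ref) and pos0 < g1):
            calls.append(_classify_against_model(pos0, ref, alt, m, genome))
    if not calls:
        calls = [ImpactCall(chrom, pos, ref, alt, None, "MODIFIER")]
    calls.sort(key=lambda c: c.severity)
    return calls if all_calls else calls[0]


def classify_table(vt: VariantTable, models: Sequence[GeneModel], genome: dict) -> list:
    """ImpactCall per record of a VariantTable (first ALT allele)."""
    return [
        classify_variant_effect(str(vt.chrom[i]), int(vt.pos[i]), vt.ref[i], vt.alt[i][0], models, genome)
        for i in range(vt.n_sites)
    ]


@dataclass
class DivergenceSummary:
    """Counts and one-decimal percentages summarising haplotype divergence."""

    n_genes_total: int
    n_genes_with_variant: int
    n_genes_with_aa_change: int
    n_nonsyn_snps_total: int
    n_nonsense_snps: int
    n_genes_with_nonsense: int

    @staticmethod
    def percent(num: int, den: int):
        """round(100*num/den, 1); None (undefined) when the denominator is 0."""
        if den == 0:
            return None
        return round(100.0 * num / den, 1)

    @property
    def pct_genes_with_variant(self):
        return self.percent(self.n_genes_with_variant, self.n_genes_total)

    @property
    def pct_genes_with_aa_change(self):
        """Share of variant-bearing genes holding an amino-acid change."""
        return self.percent(self.n_genes_with_aa_change, self.n_genes_with_variant)

    @property
    def pct_nonsense_of_nonsyn(self):
        return self.percent(self.n_nonsense_snps, self.n_nonsyn_snps_total)

    @property
    def pct_genes_with_nonsense(self):
        return self.percent(self.n_genes_with_nonsense, self.n_genes_total)

    def as_dict(self) -> dict:
        return {
            "n_genes_total": self.n_genes_total,
            "n_genes_with_variant": self.n_genes_with_variant,
            "n_genes_with_aa_change": self.n_genes_with_aa_change,
            "n_nonsyn_snps_total": self.n_nonsyn_snps_total,
            "n_nonsense_snps": self.n_nonsense_snps,
            "n_genes_with_nonsense": self.n_genes_with_nonsense,
            "pct_genes_with_variant": self.pct_genes_with_variant,
            "pct_genes_with_aa_change": self.pct_genes_with_aa_change,
            "pct_nonsense_of_nonsyn": self.pct_nonsense_of_nonsyn,
            "pct_genes_with_nonsense": self.pct_genes_with_nonsense,
        }


def summarize_haplotype_divergence(
    impact_calls: Iterable[ImpactCall],
    models: Sequence[GeneModel],
    stop_gain_only: bool = False,
) -> DivergenceSummary:
    """Aggregate impact calls into a divergence summary against one
    haplotype's annotation.

    ``stop_gain_only`` restricts the "nonsense-affected" gene count to genes
    with a stop-gain SNP; the default also counts frameshift (HIGH indel)
    genes as nonsense-affected.
    """
    genes_with_variant, genes_aa, genes_nonsense = set(), set(), set()
    n_nonsyn = n_nonsense = 0
    for c in impact_calls:
        if c.gene_id is None:
            continue
        genes_with_variant.add(c.gene_id)
        if c.impact in ("HIGH", "MODERATE"):
            genes_aa.add(c.gene_id)
            n_nonsyn += 1
        if c.impact == "HIGH":
            n_nonsense += 1
            is_stop_gain = c.codon_change is not None and translate_codon(c.codon_change[1]) == "*"
            if is_stop_gain or not stop_gain_only:
                genes_nonsense.add(c.gene_id)
    return DivergenceSummary(
        n_genes_total=len(models),
        n_genes_with_variant=len(genes_with_variant),
        n_genes_with_aa_change=len(genes_aa),
        n_nonsyn_snps_total=n_nonsyn,
        n_nonsense_snps=n_nonsense,
        n_genes_with_nonsense=len(genes_nonsense),
    )


def count_impact_per_individual(vt: VariantTable, impact_calls: Sequence[ImpactCall]) -> pd.DataFrame:
    """Per-sample counts of sites, by impact class, where the sample carries
    at least one alternate allele.
    """
    if len(impact_calls) != vt.n_sites:
        raise ValueError("one impact call per site required")
    carries = np.any(vt.genotypes > 0, axis=2)  # sites x samples
    rows = {}
    classes = np.array([c.impact for c in impact_calls])
    for cls in IMPACT_ORDER:
        mask = classes == cls
        rows[cls] = carries[mask].sum(axis=0)
    return pd.DataFrame(rows, index=vt.samples)


def compare_load_between_groups(counts: pd.DataFrame, groups: dict, impact: str = "HIGH") -> dict:
    """Group means plus one-way ANOVA and Tukey HSD on per-individual counts.

    ``groups`` maps sample id -> group label.  Returns group means, the ANOVA
    F and p, and the Tukey HSD table.
    """
    from scipy.stats import f_oneway
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    lab = pd.Series({s: groups[s] for s in counts.index})
    by_group = [counts.loc[lab.index[lab == g], impact].to_numpy(float) for g in sorted(set(lab))]
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    f, p = f_oneway(*by_group)
    if np.isnan(f):  # zero variance everywhere: identical groups
        f, p = 0.0, 1.0
    tukey = pairwise_tukeyhsd(counts[impact].to_numpy(float), lab.to_numpy())
    means = {g: float(np.mean(v)) for g, v in zip(sorted(set(lab)), by_group)}
    return {"group_means": means, "anova_F": float(f), "anova_p": float(p), "tukey": tukey}
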