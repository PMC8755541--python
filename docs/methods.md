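# Methods

`haplopop` models the population genomics of a highly heterozygous, clonally
propagated fruit crop whose cultivated gene pool derives from two diverged
wild source populations, with admixed F1-like cultivars between them. This
note records the statistical models, the defaults and why they were chosen,
what the synthetic generators do and do not emulate, and the numerical
corner-case decisions.

## Diversity statistics

**Sitewise π** is the unbiased mean pairwise difference among called
alleles, π = Σ_{a<b} n_a n_b / C(n,2); missing genotypes are excluded
site-wise, never imputed, and a site needs at least two called alleles to
receive a value. **Windowed π** divides the summed site values by the full
window length (100 kb windows, 10 kb step by default), so monomorphic and
uncalled positions count as zero diversity over full length — the
convention of the windowed-diversity tools this mirrors; a called-site
denominator is available by argument for panels with heavy missingness.

**Tajima's D** uses the standard constants a1, a2, b1, b2, c1, c2, e1, e2
evaluated at the mean called-allele count over segregating sites, with
D = (θ_π − θ_W)/√(e1·S + e2·S(S−1)). S = 0 yields NaN (undefined), never 0.
Indel records are skipped; π and D are SNP statistics here.

**π_n/π_s** follows a called-site-normalised design: π_n sums sitewise
diversity at HIGH/MODERATE-impact positions inside high-quality gene models
and divides by two-thirds of the number of confidently called positions in
those models — the operational assumption being that every third exonic
position is synonymous — while π_s sums diversity at intergenic positions
(gene spans excluded exactly, no buffer; a buffer is configurable) divided
by the intergenic called-position count. The called-position counts must
come from all-sites genotyping (monomorphic positions included); they are a
model input here, not something a variant-only VCF can supply. The ratio is
undefined (None) when π_s is zero or its denominator empty.

**Weir–Cockerham F_st** computes the 1984 per-site variance components a
(among populations), b (among individuals within populations) and c (within
individuals), with the "weighted" estimate the ratio of sums
θ = Σa / Σ(a+b+c) per 100 kb window and genome-wide — the same quantity the
commonly used VCF tools label "weighted". Sites monomorphic across all
populations are skipped.

**LD decay** computes r² as the squared correlation of genotype dosages
(unphased) for all pairs within 500 kb, keeps sites with minor allele count
strictly greater than 4 and pairs with r² > 0.01, and fits
r² = β0 + β1·log10(d). The decay's "initial value" is the fitted value at
the smallest observed distance; the half-decay distance solves the fitted
line for half that value and is undefined when β1 ≥ 0. **LD pruning** runs
50-SNP windows advanced by 10 SNPs, removing the lower-MAF member of any
pair with r² > 0.1 (ties remove the larger coordinate).

**f3(C; A, B)** is the mean over sites of (c−a)(c−b) minus, by default, the
finite-sample heterozygosity correction h_c/n_c for the target, with a
block-jackknife standard error over contiguous blocks of 5,000 SNPs and
Z = f3/SE; Z below about −3 is an admixture signal. The correction is
toggleable because the uncorrected form has the exact identity f3 = 0 when
the target's frequencies coincide with a source's.

**The inbreeding coefficient** is the method-of-moments
F = (O_hom − E_hom)/(L − E_hom) with E_hom = Σ 1 − 2pq·n/(n−1) over the
sample's called sites. F1 hybrids of diverged parents come out negative
(excess heterozygosity), which is the diagnostic the admixture analysis
relies on.

## Kinship and cultivation history

The kinship estimator is the KING-robust within-pair form,
φ = (N_AaAa − 2·N_AA,aa)/(2·min(N_Aa^i, N_Aa^j)) + 1/2 −
(N_Aa^i + N_Aa^j)/(4·min(N_Aa^i, N_Aa^j)),
chosen over the between-family estimator because its min-heterozygosity
denominator makes it insensitive to sample composition and population
structure — essential when wild panels and admixed cultivars are pooled.
Degrees use cutoffs at 2^−(d+3/2): duplicate above 0.3536, then first,
second, third degree down to 0.0442, else unrelated. IBS0/1/2 site
fractions are reported alongside φ as a summary of identity-by-state
sharing; no HMM segment-based IBD is attempted. The cultivation-history
graph links each sample to its highest-φ positive partner (ties broken by
sample-id order); samples with no positive partner are isolated.

## Variant impact and divergence summaries

The effect classifier is a minimal re-implementation restricted to the
classes the diversity analysis consumes: coding SNPs are classified by
translating the affected codon (strand-aware, standard genetic code) into
LOW (synonymous), MODERATE (missense) or HIGH (stop gained/lost); CDS
indels are MODERATE when in-frame and HIGH otherwise, with exon-boundary
truncations folded into HIGH; everything else is MODIFIER. One transcript
per gene, no canonical-transcript or regulatory logic. A variant spanning
several genes is classified against each and reported at the most severe
class (HIGH > MODERATE > LOW > MODIFIER).

High-quality gene models must start with ATG in their own orientation and
have CDS length divisible by three; rejects carry their reason. Divergence
summaries report counts with percentages at one-decimal rounding
(round(100·num/den, 1)); a zero denominator yields an undefined percentage,
not 0. Genes counted as "nonsense-affected" include both stop-gain and
frameshift carriers by default, with a flag to restrict to stop-gains.
Per-individual mutational-load counts (sites where the sample carries at
least one alternate allele, by class) are compared between groups with
one-way ANOVA plus Tukey HSD.

## Allele-specific expression

The DEA (differentially expressed alleles) test is an exact two-sided
binomial test of allelic ratio 0.5 per gene and library, gated at total
allele coverage ≥ 10, Benjamini–Hochberg corrected within each library,
called at q < 0.05; all three knobs are configurable. This is the simplest
defensible allele-balance test; it ignores overdispersion between
libraries, so its q-values are anti-conservative for genes with strong
biological replicate variance — acceptable here because calls are made
within libraries and aggregated as unions. Saturation curves draw random
k-subsets of libraries (500 replicates by default) and report the mean
union size; when C(n,k) ≤ replicates the subsets are enumerated
exhaustively, making the toy cases exact.

Allelic Ka/Ks is Nei–Gojobori (1986): potential synonymous/nonsynonymous
site counts averaged over both sequences with stop-codon mutations excluded
from the denominators, observed differences averaged over mutation paths
per codon (paths through stops excluded, re-admitted only if every path is
blocked), and Jukes–Cantor correction of both proportions. Proportions at
or above 3/4 saturate the correction and return NaN. NG86 was chosen over
likelihood methods for closed-form auditability — every value is checkable
by per-codon path enumeration.

Gene-feature SNP density is 100·(SNPs in feature)/(feature bp) for
promoter (2 kb upstream of the TSS — mirroring the symmetric 2 kb
downstream feature), 5′ UTR, exon, intron, 3′ UTR and 2 kb downstream.

## Deletion marker

Coverage is windowed in fixed 800 bp windows, normalised by the sample's
genome-wide mean depth. With g deleted copies the expected region ratio is
(2−g)/2, so genotype thresholds sit at the midpoints 0.25 and 0.75 between
the expected ratios {1, 0.5, 0}; both are configurable. Group comparisons
use a pooled-variance two-sided t test by default (Welch by flag). The
in-silico PCR engine does exact matching only (no mismatches or degenerate
bases), searches both strands, and reports all products within the
amplicon-length cap, flagging primers with multiple template hits. The
three-primer design (forward upstream; reverse inside the deletion; reverse
downstream) classifies diploid band patterns: spanning product only →
both haplotypes deleted; inside product only → both intact; both bands →
heterozygote.

## Demography adjustment

Ne trajectories are consumed as (time, Ne) tables — the package does not
fit sequential coalescent models. Generation-time rescaling multiplies the
time axis (the factor-3 correction for a highly selfing population is the
motivating case) and composes multiplicatively. "Matched" trajectories are
formalised as uniform agreement of log Ne into the past: both trajectories
are resampled onto a common log-spaced grid (with the original breakpoints
retained so constructed step pairs are recovered exactly), interpolated as
step functions because coalescent outputs are piecewise constant, and the
split time is the most recent grid time from which |Δ ln Ne| ≤ tol into the
past, with tol defaulting to 0.1. The original procedure was a manual
read-off; this formalisation, including the default tolerance, is the
package's own design.

## Synthetic data

The generators exist so every pipeline stage can be tested against known
truth. The genotype panel is Balding–Nichols: per site an ancestral
frequency p ~ Uniform(0.05, 0.95), population frequencies Beta-distributed
with mean p and variance p(1−p)F, diploids drawn with within-population
inbreeding implemented as probability-F of copying the first allele
(E[het deficit] = F). Defaults are the study conditions the package
models: two source populations at F = 0.15, 20 diploids each, 8 admixed
samples receiving one haplotype per source. Balding–Nichols was chosen over
forward simulation for controllable F_st, O(sites) cost and analytic
expectations. Pedigree genotypes are Mendelian draws over the founder
panel, with expected kinship computed by the standard pedigree recursion
(clones treated as genetic copies). The two-haplotype genome generator
plants SNPs/short indels at ~2.3 events per 100 bp (the heterozygosity
scale of the system) outside CDS, plus a 3,781 bp deletion in an intergenic
region, with a 1 kb mutation-free buffer so primer arithmetic is exact.
Expression counts are Binomial(depth, θ) with θ = 0.5 for non-DEA genes and
0.8 by default for the true DEA set; coverage is per-base Poisson with the
deletion's copy loss imprinted on the rate.

What the generators do **not** emulate: linkage disequilibrium beyond
pedigree sharing (sites are independent, so LD-decay distances on synthetic
panels are not meaningful), sequencing error and mapping bias, overdispersed
expression counts, repeat content, and real site-annotation distributions
(generated annotations sit inside the hard-filter pass bands). Passing
tests therefore demonstrate estimator correctness and calibration under the
stated models, not robustness to real-data artefacts.

All randomness flows through one seeded generator per run, with sub-streams
derived by fixed spawn keys so each generator's output is independently
reproducible; identical seeds give byte-identical output files.

## Problem sizes

The test suite and the acceptance script run simulations at 10k independent
sites with 20+20 diploids (parameter recovery), a 10-founder pedigree at
10k sites (kinship), 600 genes × 10 libraries at depth 100 (DEA), and a
~160 kb annotated genome at depth 20 (deletion marker) — sizes at which the
binomial/CLT error bounds on every checked quantity are an order of
magnitude below the acceptance tolerances.

## Known limitations

Hard-filter grammar covers the `ann < x || ann > y` subset only. The VCF
writer emits the supported field subset (CHROM/POS/REF/ALT, the seven site
annotations, GT). The missingness filter is strictly "greater than", per
its defining description. The phasing/population filter expressions are
applied to SNPs and indels jointly before biallelic selection (filter
first, select second). π_s takes intergenic positions with no buffer around
genes; a buffer is configurable but off by default. The DEA saturation
total depends on whether the union or a joint model defines the headline
count; both union and per-library summaries are exposed.
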