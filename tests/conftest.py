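import numpy as np
import pytest

from haplopop.io_formats import MISSING, VariantTable


def make_table(genotype_rows, pos=None, annotations=None, sample_prefix="s"):
    """Build a small VariantTable from nested genotype lists.

    ``genotype_rows`` is [site][sample] -> (a, b) allele-index pairs, with
    None meaning a fully missing genotype.
    """
    n_sites = len(genotype_rows)
    n_samples = len(genotype_rows[0]) if n_sites else 0
    gt = np.full((n_sites, n_samples, 2), MISSING, dtype=np.int16)
    for i, row in enumerate(genotype_rows):
        for j, g in enumerate(row):
            if g is not None:
                gt[i, j] = g
    ann = {k: np.asarray(v, dtype=float) for k, v in (annotations or {}).items()}
    return VariantTable(
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n_sites + 1) * 10, dtype=np.int64),
        ref=["A"] * n_sites,
        alt=[["T"]] * n_sites,
        annotations=ann,
        genotypes=gt,
        samples=[f"{sample_prefix}{j}" for j in range(n_samples)],
    )


@pytest.fixture(scope="session")
def two_pop_panel():
    """A mid-size Balding-Nichols panel shared across statistic tests."""
    from haplopop.synthetic import SimulationParams, simulate_two_population_genotypes

    params = SimulationParams(seed=1234, n_sites=10_000)
    vt, truth = simulate_two_population_genotypes(params)
    pops = {
        "pop1": [s for s in vt.samples if s.startswith("P1")],
        "pop2": [s for s in vt.samples if s.startswith("P2")],
    }
    f1 = [s for s in vt.samples if s.startswith("F1")]
    return vt, truth, pops, f1


@pytest.fixture(scope="session")
def annotated_genome():
    """Two-haplotype genome with annotation and a planted 3,781 bp deletion."""
    from haplopop.synthetic import generate_genome_with_annotation

    genomes, models, truth = generate_genome_with_annotation(n_genes=20, seed=5)
    return genomes, models, truth
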