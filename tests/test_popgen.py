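"""Unit and oracle tests for the population-genetic statistics.

The oracles here are deliberately naive: explicit pair enumeration for pi,
direct transcription of the 1984 variance-component formulas for F_st,
explicit constant evaluation for Tajima's D, and covariance sums for r^2.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from haplopop.io_formats import MISSING
from haplopop.popgen import (
    CalledSiteCounts,
    f3_statistic,
    half_decay,
    inbreeding_coefficient,
    ld_decay,
    ld_prune,
    pin_pis,
    sitewise_pi,
    tajimas_d,
    weir_cockerham_fst,
    windowed_pi,
    LDDecayCurve,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# oracles

def pi_oracle(alleles):
    """Mean pairwise difference by enumerating every haplotype pair."""
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def tajima_oracle(allele_counts, n):
    """Direct evaluation of the 1989 constants for biallelic count data."""
    S = len(allele_counts)
    theta_pi = sum(2 * i * (n - i) / (n * (n - 1)) for i, _ in allele_counts)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (theta_pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def wc_theta_oracle(genotype_lists):
    """Ratio-of-sums Weir-Cockerham theta, transcribed per site in scalars.

    ``genotype_lists`` is [site][population][individual] -> (a, b).
    """
    num = den = 0.0
    for site in genotype_lists:
        r = len(site)
        n_i = [len(pop) for pop in site]
        p_i = [sum(int(a > 0) + int(b > 0) for a, b in pop) / (2 * len(pop)) for pop in site]
        h_i = [sum(int(a != b) for a, b in pop) / len(pop) for pop in site]
        n_bar = sum(n_i) / r
        n_sum = sum(n_i)
        p_bar = sum(n * p for n, p in zip(n_i, p_i)) / n_sum
        if p_bar in (0.0, 1.0):
            continue
        nc = (n_sum - sum(n**2 for n in n_i) / n_sum) / (r - 1)
        s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
        h_bar = sum(n * h for n, h in zip(n_i, h_i)) / n_sum
        a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        num += a
        den += a + b + c
    return num / den


def r2_oracle(x, y):
    """Squared correlation from explicit covariance sums."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov**2 / (vx * vy)


# ---------------------------------------------------------------------------
# sitewise / windowed pi

class TestSitewisePi:
    def test_opposite_homozygotes(self):
        track = sitewise_pi(make_table([[(0, 0), (1, 1)]]))
        assert track["pi"].iloc[0] == pytest.approx(pi_oracle([0, 0, 1, 1]))  # 4/6

    def test_monomorphic_site_zero(self):
        track = sitewise_pi(make_table([[(0, 0), (0, 0)]]))
        assert track["pi"].iloc[0] == 0.0

    def test_het_with_missing_partner(self):
        track = sitewise_pi(make_table([[(0, 1), None]]))
        assert track["pi"].iloc[0] == 1.0
        assert track["n_called_alleles"].iloc[0] == 2

    def test_single_called_allele_omitted(self):
        vt = make_table([[None, None]])
        assert len(sitewise_pi(vt)) == 0

    def test_random_instances_match_pair_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_samples = rng.integers(2, 11)
            rows = [[tuple(rng.integers(0, 2, 2)) for _ in range(n_samples)]]
            track = sitewise_pi(make_table(rows))
            alleles = [a for g in rows[0] for a in g]
            if len(set(alleles)) > 1:
                assert track["pi"].iloc[0] == pytest.approx(pi_oracle(alleles), abs=1e-9)

    def test_windowed_pi_divides_by_window_length(self):
        track = pd.DataFrame({"chrom": ["chr1"], "pos": [5], "pi": [2.0 / 3.0], "n_called_alleles": [4]})
        win = windowed_pi(track, window=10, step=10, chrom_lengths={"chr1": 10})
        assert win["pi"].iloc[0] == pytest.approx(0.06667, abs=1e-5)

    def test_empty_window_zero_and_step_overlap(self):
        track = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [5, 95], "pi": [0.5, 0.5], "n_called_alleles": [4, 4]})
        win = windowed_pi(track, window=100, step=50, chrom_lengths={"chr1": 200})
        assert win["pi"].iloc[0] == pytest.approx(1.0 / 100)
        assert win.loc[win["start"] == 50, "pi"].iloc[0] == pytest.approx(0.5 / 100)  # shared site
        assert win.loc[win["start"] == 150, "pi"].iloc[0] == 0.0


# ---------------------------------------------------------------------------
# Tajima's D

class TestTajimasD:
    def test_four_haplotype_example(self):
        # allele counts (1,3), (2,2), (1,3): theta_pi = 1.6667, theta_W = 1.6364
        rows = [
            [(1, 0), (0, 0)],
            [(1, 1), (0, 0)],
            [(0, 1), (0, 0)],
        ]
        d = tajimas_d(make_table(rows))
        assert d == pytest.approx(0.168, abs=5e-4)
        assert d == pytest.approx(tajima_oracle([(1, 3), (2, 2), (1, 3)], 4), abs=1e-9)

    def test_no_segregating_sites_undefined(self):
        assert math.isnan(tajimas_d(make_table([[(0, 0), (0, 0)]])))

    def test_random_instances_match_constant_evaluation(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n_dip = int(rng.integers(2, 11))
            n_sites = int(rng.integers(1, 8))
            rows, counts = [], []
            for _ in range(n_sites):
                while True:
                    g = rng.integers(0, 2, (n_dip, 2))
                    if 0 < g.sum() < 2 * n_dip:
                        break
                rows.append([tuple(x) for x in g])
                counts.append((int(g.sum()), 2 * n_dip - int(g.sum())))
            assert tajimas_d(make_table(rows)) == pytest.approx(
                tajima_oracle(counts, 2 * n_dip), abs=1e-9
            )


# ---------------------------------------------------------------------------
# pi_n / pi_s

class TestPinPis:
    def test_hand_computed_toy(self):
        res = pin_pis([0.5, 0.5], [2.0], CalledSiteCounts(300, 1000))
        assert res.pi_n == pytest.approx(0.005)
        assert res.pi_s == pytest.approx(0.002)
        assert res.ratio == pytest.approx(2.5)

    def test_no_variants(self):
        res = pin_pis([], [], CalledSiteCounts(300, 1000))
        assert res.pi_n == 0.0 and res.pi_s == 0.0 and res.ratio is None

    def test_zero_intergenic_positions_undefined(self):
        res = pin_pis([0.5], [0.5], CalledSiteCounts(300, 0))
        assert res.pi_s is None and res.ratio is None

    def test_monotone_in_numerator(self):
        called = CalledSiteCounts(300, 1000)
        lo = pin_pis([0.1], [1.0], called)
        hi = pin_pis([0.1, 0.4], [1.0], called)
        assert hi.pi_n > lo.pi_n and hi.ratio > lo.ratio


# ---------------------------------------------------------------------------
# Weir-Cockerham F_st

class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        rows = [[(0, 0)] * 5 + [(1, 1)] * 5]
        vt = make_table(rows)
        pops = {"a": vt.samples[:5], "b": vt.samples[5:]}
        _, theta = weir_cockerham_fst(vt, pops, window=None)
        assert theta == pytest.approx(1.0)

    def test_identical_populations_small_negative(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 2, (50, 6, 2))
        rows = [[tuple(g[i, j]) for j in range(6)] + [tuple(g[i, j]) for j in range(6)] for i in range(50)]
        vt = make_table(rows)
        pops = {"a": vt.samples[:6], "b": vt.samples[6:]}
        _, theta = weir_cockerham_fst(vt, pops, window=None)
        assert theta <= 0 and abs(theta) < 0.2

    def test_random_instances_match_component_transcription(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            r = int(rng.integers(2, 4))
            sizes = [int(rng.integers(2, 8)) for _ in range(r)]
            n_sites = int(rng.integers(1, 6))
            site_lists, rows = [], []
            for _ in range(n_sites):
                while True:
                    pops = [[tuple(rng.integers(0, 2, 2)) for _ in range(s)] for s in sizes]
                    flat = [a for pop in pops for g in pop for a in g]
                    if 0 < sum(flat) < len(flat):
                        break
                site_lists.append(pops)
                rows.append([g for pop in pops for g in pop])
            vt = make_table(rows)
            names, k = {}, 0
            for pi, s in enumerate(sizes):
                names[f"p{pi}"] = vt.samples[k : k + s]
                k += s
            _, theta = weir_cockerham_fst(vt, names, window=None)
            assert theta == pytest.approx(wc_theta_oracle(site_lists), abs=1e-9)

    def test_balding_nichols_recovery(self, two_pop_panel):
        vt, truth, pops, _ = two_pop_panel
        _, theta = weir_cockerham_fst(vt, pops, window=None)
        assert abs(theta - 0.15) <= 0.02

    def test_windows_aligned_to_grid(self, two_pop_panel):
        vt, _, pops, _ = two_pop_panel
        windows, _ = weir_cockerham_fst(vt, pops, window=100_000)
        assert (windows["start"] % 100_000 == 0).all()
        assert windows["theta"].between(-1, 1).all()


# ---------------------------------------------------------------------------
# LD

class TestLD:
    def _panel(self, seed=0, n_sites=30, n_samples=40):
        rng = np.random.default_rng(seed)
        rows = [[tuple(rng.integers(0, 2, 2)) for _ in range(n_samples)] for _ in range(n_sites)]
        return make_table(rows, pos=np.arange(1, n_sites + 1) * 50)

    def test_identical_sites_r2_one(self):
        rng = np.random.default_rng(1)
        row = [tuple(rng.integers(0, 2, 2)) for _ in range(30)]
        vt = make_table([row, row, row], pos=[10, 20, 40])
        curve = ld_decay(vt, max_dist=1000, r2_min=0.0)
        assert curve.r2.max() == pytest.approx(1.0)

    def test_r2_matches_covariance_sums(self):
        vt = self._panel(seed=8)
        curve = ld_decay(vt, max_dist=10_000, r2_min=-1)
        dos = vt.dosage()
        # recompute one specific pair with the naive oracle
        i, j = 0, 1
        expected = r2_oracle(list(dos[i]), list(dos[j]))
        d = int(vt.pos[j] - vt.pos[i])
        got = curve.r2[curve.distance == d]
        assert any(abs(g - expected) < 1e-9 for g in got)

    def test_half_decay_closed_form(self):
        curve = LDDecayCurve(distance=np.array([10, 100]), r2=np.array([0.5, 0.4]), beta0=0.6, beta1=-0.1)
        # r0 = 0.6 - 0.1*log10(10) = 0.5; solve 0.6 - 0.1 x = 0.25 -> x = 3.5
        assert half_decay(curve) == pytest.approx(10**3.5)

    def test_no_decay_undefined(self):
        curve = LDDecayCurve(distance=np.array([10, 100]), r2=np.array([0.1, 0.2]), beta0=0.1, beta1=0.05)
        assert half_decay(curve) is None

    def test_minor_count_gate(self):
        # singleton-ish sites (minor count <= 4) must be excluded entirely
        rows = [[(1, 0)] + [(0, 0)] * 19, [(1, 0)] + [(0, 0)] * 19]
        vt = make_table(rows, pos=[10, 20])
        with pytest.raises(ValueError, match="too few"):
            ld_decay(vt)


class TestLDPrune:
    def test_independent_sites_untouched(self):
        rng = np.random.default_rng(2)
        rows = [[tuple(rng.integers(0, 2, 2)) for _ in range(40)] for _ in range(12)]
        vt = make_table(rows)
        assert ld_prune(vt, r2_max=0.99).n_sites == 12

    def test_duplicated_site_loses_one_copy(self):
        rng = np.random.default_rng(3)
        row = [tuple(rng.integers(0, 2, 2)) for _ in range(40)]
        other = [[tuple(rng.integers(0, 2, 2)) for _ in range(40)] for _ in range(3)]
        vt = make_table([row, row] + other)
        pruned = ld_prune(vt)
        assert pruned.n_sites == 4
        assert 10 in pruned.pos  # smaller coordinate survives the tie-break

    def test_three_perfectly_correlated_leave_one(self):
        rng = np.random.default_rng(4)
        row = [tuple(rng.integers(0, 2, 2)) for _ in range(40)]
        vt = make_table([row, row, row])
        assert ld_prune(vt).n_sites == 1


# ---------------------------------------------------------------------------
# f3

class TestF3:
    def test_target_equals_source_no_correction(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 2, (500, 5, 2))
        rows = [
            [tuple(g[i, j]) for j in range(5)] * 2 + [tuple(rng.integers(0, 2, 2)) for _ in range(5)]
            for i in range(500)
        ]
        vt = make_table(rows)
        c, a, b = vt.samples[:5], vt.samples[5:10], vt.samples[10:]
        res = f3_statistic(vt, c, a, b, block_size=100, correction=False)
        assert res["f3"] == pytest.approx(0.0, abs=1e-12)

    def test_admixed_target_strongly_negative(self, two_pop_panel):
        vt, _, pops, f1 = two_pop_panel
        res = f3_statistic(vt, f1, pops["pop1"], pops["pop2"], block_size=1000)
        assert res["f3"] < 0 and res["z"] < -3

    def test_unadmixed_target_nonnegative(self, two_pop_panel):
        vt, _, pops, _ = two_pop_panel
        res = f3_statistic(vt, pops["pop1"][:10], pops["pop1"][10:], pops["pop2"], block_size=1000)
        assert res["f3"] >= 0

    def test_too_few_blocks_se_undefined(self):
        rng = np.random.default_rng(7)
        rows = [[tuple(rng.integers(0, 2, 2)) for _ in range(9)] for _ in range(50)]
        vt = make_table(rows)
        res = f3_statistic(vt, vt.samples[:3], vt.samples[3:6], vt.samples[6:], block_size=5000)
        assert res["se"] is None and res["z"] is None


# ---------------------------------------------------------------------------
# inbreeding

class TestInbreeding:
    def test_all_homozygous_is_one(self):
        rng = np.random.default_rng(8)
        rows = []
        for _ in range(200):
            g = [(int(x), int(x)) for x in rng.integers(0, 2, 10)]
            if len({a for p in g for a in p}) > 1:
                rows.append(g)
        vt = make_table(rows)
        assert inbreeding_coefficient(vt, "s0") == pytest.approx(1.0)

    def test_f1_hybrid_negative(self, two_pop_panel):
        vt, _, _, f1 = two_pop_panel
        assert inbreeding_coefficient(vt, f1[0]) < 0

    def test_random_mating_near_zero(self):
        rng = np.random.default_rng(9)
        rows = [[tuple(rng.integers(0, 2, 2)) for _ in range(30)] for _ in range(3000)]
        vt = make_table(rows)
        assert abs(inbreeding_coefficient(vt, "s0")) < 0.1
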