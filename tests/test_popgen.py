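"""Weir-Cockerham F_ST, Tajima's D, and percentile enrichment, checked
against independent brute-force oracles."""

import math

import numpy as np
import pytest

from supergene.popgen import (
    WindowStat,
    fst_window,
    percentile_rank,
    tajima_constants,
    tajimas_d,
    tajimas_d_window,
    weir_cockerham_components,
)
from supergene.variants import Window, make_windows

from conftest import random_genotype_matrix


def wc_site_oracle(d1, d2):
    """Scalar Weir & Cockerham (1984) components for one site, written
    directly from the estimator's definitions (r = 2 populations)."""
    d1 = [x for x in d1 if x >= 0]
    d2 = [x for x in d2 if x >= 0]
    r = 2
    n = [len(d1), len(d2)]
    p = [sum(d) / (2 * len(d)) for d in (d1, d2)]
    h = [sum(1 for x in d if x == 1) / len(d) for d in (d1, d2)]
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
    if pbar in (0.0, 1.0):
        return 0.0, 0.0, 0.0
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def _single_window(g):
    return [Window(str(g.chrom[0]), 1, int(g.pos.max()) + 1, g.n_sites)]


class TestWeirCockerhamFst:
    def test_matches_scalar_oracle_on_random_instances(self, rng):
        """Windowed ratio-of-sums equals an independently coded per-site
        variance-components oracle on 100 random two-population matrices."""
        for _ in range(100):
            g = random_genotype_matrix(
                rng, n_ind=rng.integers(6, 14), n_sites=rng.integers(5, 25),
                missing_rate=float(rng.choice([0.0, 0.15])),
            )
            half = g.n_individuals // 2
            pop1, pop2 = g.ids[:half], g.ids[half:]
            got = fst_window(g, pop1, pop2, _single_window(g))[0]
            num = den = 0.0
            for j in range(g.n_sites):
                d1 = g.dosage[:half, j].tolist()
                d2 = g.dosage[half:, j].tolist()
                if sum(1 for x in d1 if x >= 0) < 2 or sum(1 for x in d2 if x >= 0) < 2:
                    continue
                a, b, c = wc_site_oracle(d1, d2)
                num += a
                den += a + b + c
            if den == 0:
                assert not got.defined
            else:
                assert got.defined
                assert got.value == pytest.approx(num / den, abs=1e-12)

    def test_fixed_difference_gives_fst_one(self):
        g = random_genotype_matrix(np.random.default_rng(0), n_ind=10, n_sites=1)
        g.dosage[:5, 0] = 0
        g.dosage[5:, 0] = 2
        got = fst_window(g, g.ids[:5], g.ids[5:], _single_window(g))[0]
        assert got.value == pytest.approx(1.0)

    def test_identical_populations_give_nonpositive_fst(self, rng):
        g = random_genotype_matrix(rng, n_ind=6, n_sites=30)
        g.dosage[3:] = g.dosage[:3]  # second population is a copy
        got = fst_window(g, g.ids[:3], g.ids[3:], _single_window(g))[0]
        assert got.value <= 0

    def test_allele_label_swap_invariance(self, rng):
        g = random_genotype_matrix(rng, n_ind=10, n_sites=20)
        flipped = random_genotype_matrix(rng, n_ind=10, n_sites=20)
        flipped.dosage = (2 - g.dosage).astype(np.int8)
        flipped.pos = g.pos
        w = _single_window(g)
        a = fst_window(g, g.ids[:5], g.ids[5:], w)[0].value
        b = fst_window(flipped, g.ids[:5], g.ids[5:], w)[0].value
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_window_flagged_not_zero(self, rng):
        g = random_genotype_matrix(rng, n_ind=8, n_sites=5)
        w = [Window("chr1", 500_000, 510_000, 0)]
        got = fst_window(g, g.ids[:4], g.ids[4:], w)[0]
        assert not got.defined and math.isnan(got.value)


class TestTajimasD:
    def test_a1_constant_matches_direct_summation(self):
        assert tajima_constants(10).a1 == pytest.approx(
            sum(1 / i for i in range(1, 10)), abs=1e-12
        )
        assert tajima_constants(10).a1 == pytest.approx(2.828968, abs=1e-6)

    def test_statistic_matches_textbook_formula_on_random_instances(self, rng):
        """D recomputed from scratch (constants by direct summation, pi by
        pairwise difference counting over haplotypes) on 100 instances."""
        for _ in range(100):
            n_ind = int(rng.integers(3, 9))
            n_sites = int(rng.integers(2, 15))
            g = random_genotype_matrix(rng, n_ind=n_ind, n_sites=n_sites, phased=True)
            got = tajimas_d_window(g, g.ids, _single_window(g))[0]
            haps = g.haplotypes.reshape(2 * n_ind, n_sites)
            n = 2 * n_ind
            seg = [j for j in range(n_sites) if 0 < haps[:, j].sum() < n]
            S = len(seg)
            if S == 0:
                assert not got.defined
                continue
            # pi: mean pairwise differences over all haplotype pairs
            tot = 0
            for i in range(n):
                for k in range(i + 1, n):
                    tot += sum(haps[i, j] != haps[k, j] for j in seg)
            pi = tot / (n * (n - 1) / 2)
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1, e2 = c1 / a1, c2 / (a1**2 + a2)
            expect = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
            assert got.value == pytest.approx(expect, abs=1e-9)

    def test_singleton_only_window_is_negative(self):
        n_ind, S = 5, 5  # n = 10 haplotypes, 5 singleton sites
        haps = np.zeros((n_ind, 2, S), dtype=np.int8)
        for j in range(S):
            haps[j % n_ind, 0, j] = 1
        g = random_genotype_matrix(np.random.default_rng(1), n_ind=n_ind, n_sites=S,
                                   phased=True)
        g.haplotypes = haps
        g.dosage = haps.sum(axis=1).astype(np.int8)
        got = tajimas_d_window(g, g.ids, _single_window(g))[0]
        assert got.value < 0

    def test_zero_segregating_sites_undefined(self, rng):
        g = random_genotype_matrix(rng, n_ind=5, n_sites=3, phased=True)
        g.haplotypes[:] = 0
        g.dosage[:] = 0
        got = tajimas_d_window(g, g.ids, _single_window(g))[0]
        assert not got.defined

    def test_site_permutation_invariance(self, rng):
        g = random_genotype_matrix(rng, n_ind=6, n_sites=12, phased=True)
        perm = rng.permutation(g.n_sites)
        g2 = g.take_sites(np.sort(perm))  # site order within window irrelevant
        a = tajimas_d_window(g, g.ids, _single_window(g))[0].value
        b = tajimas_d_window(g2, g.ids, _single_window(g2))[0].value
        assert a == pytest.approx(b, abs=1e-12)

    def test_requires_four_haplotypes(self, rng):
        g = random_genotype_matrix(rng, n_ind=4, n_sites=5)
        with pytest.raises(ValueError):
            tajimas_d_window(g, g.ids[:1], _single_window(g))


class TestPercentileRank:
    @staticmethod
    def _windows(values):
        return [
            WindowStat("chr1", 1 + i * 10, 10 + i * 10, 1, float(v))
            for i, v in enumerate(values)
        ]

    def test_focal_near_top(self):
        ws = self._windows(range(1, 101))
        ws.append(WindowStat("chr1", 5001, 5010, 1, 99.5))
        assert percentile_rank(ws, ("chr1", 5001, 5010)) == pytest.approx(99.0)

    def test_focal_below_genome_minimum_is_zero(self):
        ws = self._windows([5, 6, 7])
        ws.append(WindowStat("chr1", 9001, 9010, 1, 1.0))
        assert percentile_rank(ws, ("chr1", 9001, 9010)) == 0.0

    def test_ties_follow_strictly_below_rule_vs_sort_oracle(self, rng):
        for _ in range(50):
            vals = rng.integers(0, 10, size=30).astype(float)
            ws = self._windows(vals)
            focal = ("chr1", ws[4].start, ws[4].end)
            got = percentile_rank(ws, focal)
            background = [v for i, v in enumerate(vals) if i != 4]
            expect = 100.0 * sum(v < vals[4] for v in background) / len(background)
            assert got == pytest.approx(expect)

    def test_no_focal_window_errors(self):
        with pytest.raises(ValueError):
            percentile_rank(self._windows([1, 2]), ("chr9", 1, 10))
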