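"""Allelic association, BH q-values, genome-vs-locus PCA, heterozygote
calling, and the cross-species shared-SNP report."""

import math

import numpy as np
import pandas as pd
import pytest

from supergene.assoc import (
    PcaResult,
    bh_qvalues,
    call_locus_genotypes,
    gwas,
    pca,
    score_associated,
    shared_snps,
)
from supergene.variants import GenotypeMatrix, SampleTable

from conftest import random_genotype_matrix


def _matrix(dosage):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_ind, n_sites = dosage.shape
    return GenotypeMatrix(
        ids=[f"i{k}" for k in range(n_ind)],
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1) * 100,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosage=dosage,
    )


def _samples(morphs, species="sp1"):
    return SampleTable.from_records(
        [
            {"sample": f"i{k}", "species": species, "morph": m}
            for k, m in enumerate(morphs)
        ]
    )


def bh_oracle(p):
    """Independent step-up implementation of Benjamini-Hochberg."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    p = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = comb(r1, x) * comb(r2, c1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            p += px
    return p


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = bh_qvalues([0.005, 0.01, 0.03, 0.04])
        assert q == pytest.approx([0.02, 0.02, 0.04, 0.04], abs=1e-12)

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert bh_qvalues(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_q_at_least_p_and_monotone(self, rng):
        p = np.sort(rng.random(25))
        q = bh_qvalues(p)
        assert (q >= p - 1e-15).all()
        assert (np.diff(q) >= -1e-15).all()


class TestGwas:
    def test_perfectly_associated_site_matches_fisher_oracle(self):
        d = np.array([[2]] * 10 + [[0]] * 10)
        g = _matrix(d)
        st = _samples(["mA"] * 10 + ["mB"] * 10)
        out = gwas(g, st)
        # allelic table [20, 0; 0, 20]
        expect = fisher_2x2_oracle(20, 0, 0, 20)
        assert out.loc[0, "method"] == "fisher"
        assert out.loc[0, "p"] == pytest.approx(expect, rel=1e-9)
        assert bool(out.loc[0, "associated_q0.01"])

    def test_fisher_path_matches_enumeration_oracle_on_random_tables(self, rng):
        from scipy import stats

        for _ in range(100):
            tab = rng.integers(0, 8, size=(2, 2))
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                continue
            got = stats.fisher_exact(tab)[1]
            expect = fisher_2x2_oracle(tab[0, 0], tab[0, 1], tab[1, 0], tab[1, 1])
            assert got == pytest.approx(expect, rel=1e-9, abs=1e-12)

    def test_identical_allele_frequencies_give_p_one(self):
        d = np.array([[1]] * 4 + [[1]] * 4)
        g = _matrix(d)
        st = _samples(["mA"] * 4 + ["mB"] * 4)
        out = gwas(g, st)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_single_phenotype_class_errors(self):
        g = _matrix(np.array([[0], [1], [2], [0]]))
        with pytest.raises(ValueError):
            gwas(g, _samples(["mA"] * 4))

    def test_high_missingness_sites_excluded(self, rng):
        d = rng.integers(0, 3, size=(10, 3)).astype(np.int8)
        d[:5, 1] = -1  # 50% missing
        g = _matrix(d)
        st = _samples(["mA"] * 5 + ["mB"] * 5)
        out = gwas(g, st, max_missing=0.2)
        assert 1 not in set(out["site"])


class TestPca:
    def test_heterozygote_intermediate_on_pc1(self, rng):
        # two homozygote clusters at a differentiated site set + one het
        n_sites = 30
        d = np.zeros((11, n_sites), dtype=np.int8)
        d[5:10] = 2
        d[10] = 1  # heterozygous at every differentiated site
        noise = rng.integers(0, 2, size=d.shape).astype(np.int8)
        g = _matrix(np.clip(d + (noise == 1), 0, 2))
        res = pca(g, g.ids)
        pc1 = res.scores[:, 0]
        lo, hi = pc1[:5].mean(), pc1[5:10].mean()
        lo, hi = min(lo, hi), max(lo, hi)
        assert lo < pc1[10] < hi

    def test_identical_rows_error(self):
        g = _matrix(np.ones((5, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            pca(g, g.ids)

    def test_scores_match_svd_oracle_up_to_sign(self, rng):
        g = random_genotype_matrix(rng, n_ind=15, n_sites=25)
        res = pca(g, g.ids, n_components=3)
        x = g.dosage.astype(float)
        x = x[:, x.std(axis=0) > 0]
        x = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        expect = u[:, :3] * s[:3]
        for k in range(res.scores.shape[1]):
            assert min(
                np.abs(res.scores[:, k] - expect[:, k]).max(),
                np.abs(res.scores[:, k] + expect[:, k]).max(),
            ) < 1e-8

    def test_explained_variance_fractions_sum_below_one(self, rng):
        g = random_genotype_matrix(rng, n_ind=10, n_sites=30)
        res = pca(g, g.ids, n_components=4)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-12


class TestLocusGenotypeCalls:
    def test_separable_clusters(self):
        res = PcaResult(
            ids=[f"i{k}" for k in range(6)],
            scores=np.array([[-5.0], [-5.0], [0.0], [0.0], [5.0], [5.0]]),
            explained_variance_ratio=np.array([1.0]),
            site_index=np.arange(1),
        )
        calls = call_locus_genotypes(res)
        assert list(calls) == [
            "hom_ref_morph", "hom_ref_morph", "het", "het",
            "hom_alt_morph", "hom_alt_morph",
        ]

    def test_constant_scores_error(self):
        res = PcaResult(
            ids=["a", "b", "c"],
            scores=np.zeros((3, 1)),
            explained_variance_ratio=np.array([0.0]),
            site_index=np.arange(1),
        )
        with pytest.raises(ValueError):
            call_locus_genotypes(res)


class TestSharedSnps:
    @staticmethod
    def _assoc(positions, chrom="chr1"):
        return pd.DataFrame(
            {
                "chrom": [chrom] * len(positions),
                "pos": positions,
                "associated": [True] * len(positions),
            }
        )

    def test_intersection_counts(self):
        rep = shared_snps(
            {"sp1": self._assoc([100, 200, 300]), "sp2": self._assoc([200, 400])},
            {("sp1", "sp2"): 0.1},
        )
        assert rep.pair_counts[("sp1", "sp2")] == 1
        assert rep.associated_sites["sp1"] & rep.associated_sites["sp2"] == {
            ("chr1", 200)
        }

    def test_disjoint_sets_share_nothing(self):
        rep = shared_snps(
            {"sp1": self._assoc([1, 2]), "sp2": self._assoc([3, 4])},
            {("sp1", "sp2"): 0.1},
        )
        assert rep.total_shared == 0

    def test_proximity_correlation_sign(self):
        # closest pair shares most: positive rho against proximity
        per = {
            "a": self._assoc(list(range(100, 200))),
            "b": self._assoc(list(range(100, 180))),
            "c": self._assoc(list(range(160, 260))),
        }
        dist = {("a", "b"): 0.1, ("a", "c"): 0.5, ("b", "c"): 0.5}
        rep = shared_snps(per, dist)
        assert rep.pair_counts[("a", "b")] == 80
        assert rep.spearman_rho > 0

    def test_score_associated_rule(self):
        t = pd.DataFrame(
            {"q": [0.01, 0.2, 0.01], "max_freq_diff": [0.9, 0.9, 0.1]}
        )
        out = score_associated(t, min_freq_diff=0.5, max_q=0.05)
        assert out["associated"].tolist() == [True, False, False]
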