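"""Pairwise linkage disequilibrium over a region, with the Haploview-style
D' / LOD colour classification.

Haplotype frequencies for a pair of biallelic sites come directly from
phased haplotypes when available, otherwise from the standard two-locus EM
over double-heterozygote ambiguity.  LOD is the base-10 multinomial
likelihood ratio of the fitted haplotype frequencies against linkage
equilibrium at the same allele frequencies, the statistic Haploview colours
its heat maps by:

* white:    D' < 1 and LOD < 2 (weak, unsupported LD)
* blue:     D' = 1 and LOD < 2 (complete but unsupported LD)
* pink_red: LOD >= 2           (strongly supported LD)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .variants import MISSING, GenotypeMatrix

DPRIME_ONE_TOL = 1e-9

COLOR_WHITE = "white"
COLOR_BLUE = "blue"
COLOR_PINK_RED = "pink_red"


@dataclass(frozen=True)
class LDPair:
    """LD summary for one pair of sites (indices refer to the thinned site
    list of the matrix that produced them)."""

    i: int
    j: int
    D: float
    Dprime: float
    r2: float
    LOD: float
    color_class: str
    defined: bool = True


def classify_ld(dprime: float, lod: float) -> str:
    """Map (D', LOD) to the standard heat-map colour class."""
    if not (math.isfinite(dprime) and math.isfinite(lod)):
        raise ValueError("D' and LOD must be finite")
    if lod >= 2:
        return COLOR_PINK_RED
    if abs(abs(dprime) - 1.0) < DPRIME_ONE_TOL:
        return COLOR_BLUE
    return COLOR_WHITE


def _d_stats(pAB: float, pA: float, pB: float) -> tuple[float, float, float]:
    """(D, D', r2) from haplotype frequency pAB and allele frequencies."""
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else D / dmax
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom == 0 else D * D / denom
    return D, dprime, r2


def haplotype_freqs_phased(hap_i: np.ndarray, hap_j: np.ndarray) -> np.ndarray:
    """2x2 haplotype frequency table [[p00,p01],[p10,p11]] from phased alleles.

    ``hap_i``/``hap_j`` are flat arrays of 0/1 alleles per haplotype (missing
    ``-1`` haplotypes are dropped pairwise).
    """
    ok = (hap_i >= 0) & (hap_j >= 0)
    a, b = hap_i[ok], hap_j[ok]
    tab = np.zeros((2, 2))
    for x in (0, 1):
        for y in (0, 1):
            tab[x, y] = np.sum((a == x) & (b == y))
    tot = tab.sum()
    if tot == 0:
        raise ValueError("no jointly called haplotypes")
    return tab / tot


def em_haplotype_freqs(
    dos_i: np.ndarray,
    dos_j: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> np.ndarray:
    """Two-locus EM haplotype frequencies [[p00,p01],[p10,p11]] from unphased
    dosages (missing dropped pairwise).

    Only the double-heterozygote class is phase-ambiguous; all other genotype
    combinations contribute fixed haplotype counts.
    """
    ok = (dos_i != MISSING) & (dos_j != MISSING)
    di, dj = dos_i[ok].astype(int), dos_j[ok].astype(int)
    n = di.size
    if n == 0:
        raise ValueError("no jointly called individuals")
    # fixed haplotype counts from unambiguous genotype pairs
    counts = np.zeros((2, 2))
    n_dh = 0
    for gi, gj in zip(di, dj):
        if gi == 1 and gj == 1:
            n_dh += 1
            continue
        # each individual contributes two haplotypes; for het at one site the
        # two haplotypes carry allele 0 and 1 at that site respectively
        ai = (0, 0) if gi == 0 else (1, 1) if gi == 2 else (0, 1)
        aj = (0, 0) if gj == 0 else (1, 1) if gj == 2 else (0, 1)
        if gi == 1:
            counts[ai[0], aj[0]] += 1
            counts[ai[1], aj[1] if gj == 1 else aj[0]] += 1
        elif gj == 1:
            counts[ai[0], aj[0]] += 1
            counts[ai[0], aj[1]] += 1
        else:
            counts[ai[0], aj[0]] += 2
    total = 2.0 * n
    p = np.full((2, 2), 0.25)
    for _ in range(max_iter):
        # E step: split double hets between the two phasings
        cis = p[0, 0] * p[1, 1]
        trans = p[0, 1] * p[1, 0]
        denom = cis + trans
        f_cis = 0.5 if denom == 0 else cis / denom
        new = counts.copy()
        new[0, 0] += n_dh * f_cis
        new[1, 1] += n_dh * f_cis
        new[0, 1] += n_dh * (1 - f_cis)
        new[1, 0] += n_dh * (1 - f_cis)
        new /= total
        if np.abs(new - p).max() < tol:
            p = new
            break
        p = new
    return p


def _loglik_ratio_log10(
    freqs: np.ndarray, dos_i: np.ndarray, dos_j: np.ndarray, phased_counts=None
) -> float:
    """Base-10 log likelihood ratio of ``freqs`` vs linkage equilibrium."""
    pA = freqs[1, 0] + freqs[1, 1]
    pB = freqs[0, 1] + freqs[1, 1]
    eq = np.outer([1 - pA, pA], [1 - pB, pB])

    def safe_log10(x):
        return math.log10(max(x, 1e-300))

    if phased_counts is not None:
        lod = 0.0
        for x in (0, 1):
            for y in (0, 1):
                if phased_counts[x, y] > 0:
                    lod += phased_counts[x, y] * (
                        safe_log10(freqs[x, y]) - safe_log10(eq[x, y])
                    )
        return lod

    # genotype-level likelihood (sums over double-het phasings)
    ok = (dos_i != MISSING) & (dos_j != MISSING)
    di, dj = dos_i[ok].astype(int), dos_j[ok].astype(int)

    def geno_prob(p, gi, gj):
        hap_opts = {
            0: [(0,)],
            2: [(1,)],
            1: [(0, 1)],
        }
        # genotype probability: sum over ordered haplotype pairs consistent
        # with (gi, gj)
        total = 0.0
        for a0 in (0, 1):
            for b0 in (0, 1):
                for a1 in (0, 1):
                    for b1 in (0, 1):
                        if a0 + a1 == gi and b0 + b1 == gj:
                            total += p[a0, b0] * p[a1, b1]
        return total

    lod = 0.0
    from collections import Counter

    for (gi, gj), cnt in Counter(zip(di, dj)).items():
        lod += cnt * (
            safe_log10(geno_prob(freqs, gi, gj)) - safe_log10(geno_prob(eq, gi, gj))
        )
    return lod


def ld_pair(
    g: GenotypeMatrix, idx_i: int, idx_j: int, individuals=None
) -> LDPair:
    """Full LD summary for one site pair (uses phase when available)."""
    ind = (
        np.arange(g.n_individuals)
        if individuals is None
        else g.individual_index(individuals)
    )
    if g.is_phased:
        hi = g.haplotypes[ind, :, idx_i].reshape(-1)
        hj = g.haplotypes[ind, :, idx_j].reshape(-1)
        ok = (hi >= 0) & (hj >= 0)
        counts = np.zeros((2, 2))
        for x in (0, 1):
            for y in (0, 1):
                counts[x, y] = np.sum((hi[ok] == x) & (hj[ok] == y))
        freqs = counts / counts.sum()
        lod_counts = counts
        dos_i = dos_j = None
    else:
        dos_i = g.dosage[ind, idx_i]
        dos_j = g.dosage[ind, idx_j]
        freqs = em_haplotype_freqs(dos_i, dos_j)
        lod_counts = None
    pA = freqs[1, 0] + freqs[1, 1]
    pB = freqs[0, 1] + freqs[1, 1]
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDPair(idx_i, idx_j, math.nan, math.nan, math.nan, math.nan, COLOR_WHITE, False)
    D, dprime, r2 = _d_stats(freqs[1, 1], pA, pB)
    lod = _loglik_ratio_log10(freqs, dos_i, dos_j, phased_counts=lod_counts)
    return LDPair(idx_i, idx_j, D, dprime, r2, lod, classify_ld(dprime, lod))


@dataclass
class LDMatrix:
    """Symmetric LD summaries over a thinned site list."""

    site_index: np.ndarray  # indices into the source GenotypeMatrix
    pos: np.ndarray
    dprime: np.ndarray
    r2: np.ndarray
    lod: np.ndarray
    color: np.ndarray  # object array of colour-class labels ('' undefined)

    @property
    def n_sites(self) -> int:
        return len(self.site_index)


def ld_matrix(
    g: GenotypeMatrix,
    individuals=None,
    region: tuple[str, int, int] | None = None,
    thin_to: int = 1000,
    min_genotyping: float = 0.75,
    min_maf: float = 0.001,
    seed: int = 0,
) -> LDMatrix:
    """All-pairs LD over a region after genotyping-rate/MAF filters and a
    seeded uniform thinning to at most ``thin_to`` sites."""
    ind = (
        np.arange(g.n_individuals)
        if individuals is None
        else g.individual_index(individuals)
    )
    sub = g.take_individuals([g.ids[i] for i in ind]) if individuals is not None else g
    mask = np.ones(sub.n_sites, dtype=bool)
    if region is not None:
        mask &= sub.site_mask_region(*region)
    called_frac = 1.0 - sub.site_missingness()
    mask &= called_frac >= min_genotyping
    alt, tot = sub.alt_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(af, 1 - af)
    mask &= maf >= min_maf
    sites = np.nonzero(mask)[0]
    if sites.size == 0:
        raise ValueError("no sites left in region after filters")
    if sites.size > thin_to:
        rng = np.random.default_rng(seed)
        sites = np.sort(rng.choice(sites, size=thin_to, replace=False))
    k = sites.size
    if sub.is_phased:
        dprime, r2, lod, color = _ld_all_pairs_phased(sub, sites)
    else:
        dprime = np.full((k, k), np.nan)
        r2 = np.full((k, k), np.nan)
        lod = np.full((k, k), np.nan)
        color = np.full((k, k), "", dtype=object)
        for a in range(k):
            for b in range(a + 1, k):
                pair = ld_pair(sub, int(sites[a]), int(sites[b]))
                if not pair.defined:
                    continue
                dprime[a, b] = dprime[b, a] = pair.Dprime
                r2[a, b] = r2[b, a] = pair.r2
                lod[a, b] = lod[b, a] = pair.LOD
                color[a, b] = color[b, a] = pair.color_class
    return LDMatrix(
        site_index=sites,
        pos=sub.pos[sites],
        dprime=dprime,
        r2=r2,
        lod=lod,
        color=color,
    )


def _ld_all_pairs_phased(g: GenotypeMatrix, sites: np.ndarray):
    """All-pairs D'/r2/LOD from phased haplotypes via count matrices
    (identical results to :func:`ld_pair`, vectorised)."""
    H = g.haplotypes[:, :, sites].reshape(-1, sites.size)
    V = (H == 1).astype(np.float64)
    U = (H == 0).astype(np.float64)
    n11 = V.T @ V
    n10 = V.T @ U
    n01 = U.T @ V
    n00 = U.T @ U
    tot = n11 + n10 + n01 + n00
    with np.errstate(invalid="ignore", divide="ignore"):
        p11, p10, p01, p00 = n11 / tot, n10 / tot, n01 / tot, n00 / tot
        pA = p11 + p10
        pB = p11 + p01
        D = p11 - pA * pB
        dmax = np.where(
            D > 0,
            np.minimum(pA * (1 - pB), (1 - pA) * pB),
            np.minimum(pA * pB, (1 - pA) * (1 - pB)),
        )
        dprime = np.where(dmax > 0, D / dmax, 0.0)
        denom = pA * (1 - pA) * pB * (1 - pB)
        r2 = np.where(denom > 0, D * D / denom, 0.0)

        def term(n_ab, p_ab, eq_ab):
            with np.errstate(invalid="ignore", divide="ignore"):
                t = n_ab * (np.log10(np.maximum(p_ab, 1e-300))
                            - np.log10(np.maximum(eq_ab, 1e-300)))
            return np.where(n_ab > 0, t, 0.0)

        lod = (
            term(n11, p11, pA * pB)
            + term(n10, p10, pA * (1 - pB))
            + term(n01, p01, (1 - pA) * pB)
            + term(n00, p00, (1 - pA) * (1 - pB))
        )
    defined = (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1) & (tot > 0)
    np.fill_diagonal(defined, False)
    dprime = np.where(defined, dprime, np.nan)
    r2 = np.where(defined, r2, np.nan)
    lod = np.where(defined, lod, np.nan)
    color = np.full(dprime.shape, "", dtype=object)
    blue = defined & (lod < 2) & (np.abs(np.abs(dprime) - 1.0) < DPRIME_ONE_TOL)
    white = defined & (lod < 2) & ~blue
    pink = defined & (lod >= 2)
    color[white] = COLOR_WHITE
    color[blue] = COLOR_BLUE
    color[pink] = COLOR_PINK_RED
    return dprime, r2, lod, color


def mean_abs_dprime(ldm: LDMatrix, site_subset: np.ndarray | None = None) -> float:
    """Mean |D'| over defined pairs, optionally restricted to a boolean
    subset of the thinned sites (both ends inside the subset)."""
    d = ldm.dprime
    if site_subset is not None:
        d = d[np.ix_(site_subset, site_subset)]
    vals = np.abs(d[np.triu_indices(d.shape[0], k=1)])
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else math.nan
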