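"""Windowed population-genetic statistics: Weir-Cockerham F_ST, Tajima's D,
and genome-wide percentile enrichment of a focal region.

F_ST follows the Weir & Cockerham (1984) variance-components estimator for
two populations of diploids, combined per window as the ratio of summed
components sum(a) / sum(a+b+c) (the "weighted" windowed convention of
VCFtools).  Tajima's D uses the standard normalisation constants, with pi
computed from allele counts (phase-free) with the unbiased n/(n-1)
correction.  Missing genotypes are excluded site-wise, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .variants import MISSING, GenotypeMatrix, Window


@dataclass(frozen=True)
class WindowStat:
    """A per-window statistic value; ``defined`` is False when no usable
    sites fell in the window (such windows are excluded from genome-wide
    distributions rather than scored 0)."""

    chrom: str
    start: int
    end: int
    n_used: int
    value: float
    defined: bool = True


@dataclass(frozen=True)
class FstComponents:
    """Per-site Weir-Cockerham variance components: ``a`` among populations,
    ``b`` among individuals within populations, ``c`` within individuals."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray


def weir_cockerham_components(
    g: GenotypeMatrix, pop1, pop2, min_called: int = 2
) -> tuple[FstComponents, np.ndarray]:
    """Per-site W&C (1984) components for two diploid populations.

    Returns the components and a boolean mask of usable sites: sites where
    both populations have >= ``min_called`` called individuals and that are
    polymorphic across the pooled sample.  Monomorphic sites get zero
    components and are masked out (they contribute nothing to window sums).
    """
    i1 = g.individual_index(pop1)
    i2 = g.individual_index(pop2)
    r = 2
    n_i, p_i, h_i = [], [], []
    for idx in (i1, i2):
        d = g.dosage[idx]
        called = d != MISSING
        n = called.sum(axis=0).astype(float)  # individuals called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, d, 0).sum(axis=0) / (2 * np.maximum(n, 1))
            h = (d == 1).sum(axis=0) / np.maximum(n, 1)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.stack(n_i)
    p_i = np.stack(p_i)
    h_i = np.stack(h_i)

    usable = (n_i >= min_called).all(axis=0)
    nbar = n_i.mean(axis=0)
    sum_n = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (sum_n - (n_i**2).sum(axis=0) / sum_n) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / sum_n
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / sum_n

        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2

    poly = (pbar > 0) & (pbar < 1)
    usable &= poly & (nbar > 1)
    zero = ~usable
    for arr in (a, b, c):
        arr[zero] = 0.0
        np.nan_to_num(arr, copy=False)
    return FstComponents(a=a, b=b, c=c), usable


def fst_sites(g: GenotypeMatrix, pop1, pop2) -> np.ndarray:
    """Per-site W&C F_ST = a / (a+b+c); NaN at unusable sites."""
    comp, usable = weir_cockerham_components(g, pop1, pop2)
    denom = comp.a + comp.b + comp.c
    out = np.full(g.n_sites, np.nan)
    ok = usable & (denom != 0)
    out[ok] = comp.a[ok] / denom[ok]
    return out


def fst_window(
    g: GenotypeMatrix, pop1, pop2, windows: list[Window]
) -> list[WindowStat]:
    """Windowed weighted F_ST: sum(a) / sum(a+b+c) over usable sites per window."""
    comp, usable = weir_cockerham_components(g, pop1, pop2)
    denom = comp.a + comp.b + comp.c
    out = []
    for w in windows:
        m = g.site_mask_region(w.chrom, w.start, w.end) & usable
        n_used = int(m.sum())
        tot = denom[m].sum()
        if n_used == 0 or tot == 0:
            out.append(WindowStat(w.chrom, w.start, w.end, n_used, math.nan, False))
        else:
            out.append(
                WindowStat(w.chrom, w.start, w.end, n_used, float(comp.a[m].sum() / tot))
            )
    return out


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass(frozen=True)
class TajimaConstants:
    """The standard normalisation constants for a sample of ``n`` haplotypes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 4:
        raise ValueError("Tajima's D requires >= 4 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(n: int, S: int, pi: float) -> float:
    """Tajima's D from haplotype count, segregating sites, and mean pairwise
    differences; NaN when S == 0 (undefined)."""
    if S == 0:
        return math.nan
    k = tajima_constants(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    return (pi - S / k.a1) / math.sqrt(var)


def pairwise_diversity_counts(alt: np.ndarray, n: int) -> np.ndarray:
    """Unbiased per-site mean pairwise difference 2*j*(n-j)/(n*(n-1))."""
    j = alt.astype(float)
    return 2.0 * j * (n - j) / (n * (n - 1))


def tajimas_d_window(
    g: GenotypeMatrix, individuals, windows: list[Window]
) -> list[WindowStat]:
    """Windowed Tajima's D over the given individuals (2 haplotypes each).

    Sites with any missing call among the chosen individuals are excluded so
    that a single haplotype count applies to the whole window.
    """
    idx = g.individual_index(individuals)
    n = 2 * len(idx)
    if n < 4:
        raise ValueError("need >= 4 haplotypes (2 individuals)")
    d = g.dosage[idx]
    fully_called = (d != MISSING).all(axis=0)
    alt = np.where(d != MISSING, d, 0).sum(axis=0)
    seg = fully_called & (alt > 0) & (alt < n)
    pi_site = pairwise_diversity_counts(alt, n)
    out = []
    for w in windows:
        m = g.site_mask_region(w.chrom, w.start, w.end) & seg
        S = int(m.sum())
        if S == 0:
            out.append(WindowStat(w.chrom, w.start, w.end, 0, math.nan, False))
        else:
            pi = float(pi_site[m].sum())
            out.append(WindowStat(w.chrom, w.start, w.end, S, tajimas_d(n, S, pi)))
    return out


# ---------------------------------------------------------------------------
# Percentile enrichment


def percentile_rank(
    stat_windows: list[WindowStat], focal_interval: tuple[str, int, int]
) -> float:
    """Percentile rank of the maximum focal-window value in the genome-wide
    window distribution.

    The rank is the fraction of defined background windows strictly below
    the focal maximum, x100.  Focal windows are those overlapping the
    1-based inclusive ``(chrom, start, end)`` interval; the background
    distribution is every other defined window.
    """
    chrom, start, end = focal_interval

    def overlaps(w):
        return w.chrom == chrom and w.start <= end and w.end >= start

    defined = [w for w in stat_windows if w.defined]
    focal = [w for w in defined if overlaps(w)]
    if not focal:
        raise ValueError("no defined focal windows overlap the interval")
    background = [w.value for w in defined if not overlaps(w)]
    if not background:
        raise ValueError("no defined background windows outside the interval")
    focal_max = max(w.value for w in focal)
    values = np.array(background)
    return float(100.0 * np.mean(values < focal_max))


def window_stats_to_frame(stats: list[WindowStat]):
    """Long-format table (chrom, start, end, n_used, value, defined)."""
    import dataclasses

    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(s) for s in stats])
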