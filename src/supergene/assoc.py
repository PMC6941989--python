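"""Genotype-phenotype association, local-vs-genome-wide PCA, heterozygote
calling, and the cross-species shared-SNP comparison.

The association test is a per-site allelic contingency test (chi-square on
the 2 x K allele-count table, Fisher's exact test as a fallback for sparse
2 x 2 tables) with Benjamini-Hochberg q-values.  Population structure is not
modelled in the test itself; instead the contrast between genome-wide and
locus-restricted PCA exposes it, which is also how heterozygous supergene
carriers are identified (they fall between the homozygote clusters on PC1 of
the locus PCA).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .variants import LOCUS_GENOTYPE_CLASSES, MISSING, GenotypeMatrix, SampleTable


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def allele_count_table(dosage_col: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """2 x K table of (ref, alt) allele counts per phenotype class."""
    labels = np.unique(classes)
    tab = np.zeros((2, len(labels)), dtype=np.int64)
    for k, lab in enumerate(labels):
        d = dosage_col[classes == lab]
        d = d[d != MISSING]
        tab[1, k] = d.sum()
        tab[0, k] = 2 * d.size - d.sum()
    return tab


def gwas(
    g: GenotypeMatrix,
    samples: SampleTable,
    phenotype_partition: dict[str, str] | None = None,
    max_missing: float = 0.20,
    q_cutoffs: tuple[float, float] = (0.01, 0.001),
) -> pd.DataFrame:
    """Per-site allelic association between genotype and morph phenotype.

    Parameters
    ----------
    phenotype_partition:
        Optional mapping individual -> phenotype class; defaults to the
        sample table's morph column, restricted to the matrix individuals.

    Returns a table with chrom, pos, site index, test statistic, p, BH q,
    the maximum between-class allele-frequency difference, and associated
    flags at the two configured q cutoffs.
    """
    pheno = phenotype_partition or {
        s: m for s, m in samples.morph_of().items() if s in set(g.ids)
    }
    ind = [s for s in g.ids if s in pheno]
    classes = np.array([pheno[s] for s in ind])
    uniq, counts = np.unique(classes, return_counts=True)
    # classes represented by a single individual carry no testable contrast
    keep_classes = set(uniq[counts >= 2])
    if len(keep_classes) < 2:
        raise ValueError("need >= 2 phenotype classes with >= 2 individuals each")
    keep = np.array([c in keep_classes for c in classes])
    ind = [s for s, k in zip(ind, keep) if k]
    classes = classes[keep]
    idx = g.individual_index(ind)
    d = g.dosage[idx]

    miss = (d == MISSING).mean(axis=0)
    tested = np.nonzero(miss <= max_missing)[0]
    rows = []
    for j in tested:
        tab = allele_count_table(d[:, j], classes)
        tab = tab[:, tab.sum(axis=0) > 0]
        if tab.shape[1] < 2 or (tab.sum(axis=1) == 0).any():
            continue  # monomorphic or single-class after missingness
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = tab[1] / tab.sum(axis=0)
        max_freq_diff = float(freqs.max() - freqs.min())
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        # exact test for sparse 2x2 tables (observed or expected cells < 5)
        if tab.shape == (2, 2) and ((expected < 5).any() or (tab < 5).any()):
            stat, p = stats.fisher_exact(tab)
            method = "fisher"
        else:
            stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
            method = "chi2"
        rows.append(
            dict(
                site=int(j),
                chrom=str(g.chrom[j]),
                pos=int(g.pos[j]),
                stat=float(stat),
                p=float(p),
                max_freq_diff=max_freq_diff,
                method=method,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["site", "chrom", "pos", "stat", "p", "max_freq_diff", "method"],
    )
    if len(out):
        out["q"] = bh_qvalues(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    for cutoff in q_cutoffs:
        out[f"associated_q{cutoff:g}"] = out["q"] < cutoff
    return out


@dataclass
class PcaResult:
    """PCA of the mean-centred (and mean-imputed) dosage matrix."""

    ids: list[str]
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    site_index: np.ndarray
    site_set: str = "genome"


def pca(
    g: GenotypeMatrix,
    individuals=None,
    site_mask: np.ndarray | None = None,
    site_set: str = "genome",
    max_site_missing: float = 0.10,
    n_components: int = 2,
) -> PcaResult:
    """PCA of individuals on dosages over a site set (genome-wide or locus).

    Sites above the missingness cutoff are dropped; remaining missing
    dosages are mean-imputed per site before centring.
    """
    ind = list(g.ids) if individuals is None else list(individuals)
    if len(ind) < 3:
        raise ValueError("need >= 3 individuals for PCA")
    idx = g.individual_index(ind)
    d = g.dosage[idx].astype(float)
    keep = np.ones(g.n_sites, dtype=bool) if site_mask is None else site_mask.copy()
    miss = (d == MISSING).mean(axis=0)
    keep &= miss <= max_site_missing
    d = d[:, keep]
    d[d == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = col_mean[inds[1]]
    poly = np.nanstd(d, axis=0) > 0
    d = d[:, poly]
    if d.shape[1] < 2:
        raise ValueError("fewer than 2 polymorphic sites after filtering")
    model = PCA(n_components=min(n_components, len(ind) - 1, d.shape[1]))
    scores = model.fit_transform(d - d.mean(axis=0))
    if not np.any(model.explained_variance_ > 0):
        raise ValueError("zero-variance matrix")
    site_index = np.nonzero(keep)[0][poly]
    return PcaResult(
        ids=ind,
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        site_index=site_index,
        site_set=site_set,
    )


def call_locus_genotypes(pca_locus: PcaResult, k: int = 3, seed: int = 0) -> pd.Series:
    """Cluster PC1 scores into ``k`` ordered classes; with k=3 the middle
    class is labelled heterozygous (hom_ref_morph / het / hom_alt_morph)."""
    if len(pca_locus.ids) < k:
        raise ValueError(f"need >= {k} individuals")
    x = pca_locus.scores[:, 0].reshape(-1, 1)
    if np.ptp(x) == 0:
        raise ValueError("constant PC1 scores")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    order = np.argsort(km.cluster_centers_[:, 0])
    rank_of = {int(c): r for r, c in enumerate(order)}
    if k == 3:
        names = LOCUS_GENOTYPE_CLASSES
    else:
        names = tuple(f"class{r}" for r in range(k))
    calls = [names[rank_of[int(c)]] for c in km.labels_]
    return pd.Series(calls, index=pca_locus.ids, name="locus_genotype")


@dataclass
class SharedSnpReport:
    """Cross-species comparison of wing-pattern-associated SNP positions."""

    associated_sites: dict[str, set]
    pair_counts: dict[tuple[str, str], int]
    pair_distances: dict[tuple[str, str], float]
    spearman_rho: float
    spearman_p: float

    @property
    def total_shared(self) -> int:
        return sum(self.pair_counts.values())


def score_associated(
    assoc_table: pd.DataFrame,
    min_freq_diff: float = 0.5,
    max_q: float = 0.05,
) -> pd.DataFrame:
    """Declared surrogate for manual association scoring: a site is
    associated when BH q < ``max_q`` and the maximum allele-frequency
    difference between morph classes is >= ``min_freq_diff``."""
    t = assoc_table.copy()
    t["associated"] = (t["q"] < max_q) & (t["max_freq_diff"] >= min_freq_diff)
    return t


def shared_snps(
    per_species_assoc: dict[str, pd.DataFrame],
    species_distances: dict[tuple[str, str], float],
    match_alleles: bool = False,
) -> SharedSnpReport:
    """Pairwise intersections of associated SNPs across species, and the
    Spearman correlation between shared counts and phylogenetic proximity.

    Associated tables must carry chrom/pos on the same reference; a chrom
    name mismatch across species raises.  Proximity is the negative of the
    supplied pairwise distance, so a positive rho means closer species pairs
    share more associated SNPs.
    """
    keys: dict[str, set] = {}
    chrom_sets = {}
    for sp, t in per_species_assoc.items():
        sub = t[t["associated"]] if "associated" in t.columns else t
        cols = ["chrom", "pos"] + (["alt"] if match_alleles and "alt" in t else [])
        keys[sp] = set(map(tuple, sub[cols].itertuples(index=False)))
        chrom_sets[sp] = set(t["chrom"].unique())
    all_chroms = set().union(*chrom_sets.values()) if chrom_sets else set()
    for sp, cs in chrom_sets.items():
        if cs and not cs <= all_chroms:
            raise ValueError("chromosome name mismatch across species tables")

    species = sorted(keys)
    pair_counts, pair_dist = {}, {}
    for a, b in itertools.combinations(species, 2):
        pair = (a, b)
        pair_counts[pair] = len(keys[a] & keys[b])
        d = species_distances.get(pair, species_distances.get((b, a)))
        if d is None:
            raise KeyError(f"no distance for species pair {pair}")
        pair_dist[pair] = float(d)
    counts = np.array([pair_counts[p] for p in pair_counts])
    prox = np.array([-pair_dist[p] for p in pair_counts])
    if len(counts) >= 3 and np.ptp(counts) > 0 and np.ptp(prox) > 0:
        rho, pval = stats.spearmanr(counts, prox)
    else:
        rho, pval = 0.0, 1.0
    return SharedSnpReport(
        associated_sites=keys,
        pair_counts=pair_counts,
        pair_distances=pair_dist,
        spearman_rho=float(rho),
        spearman_p=float(pval),
    )
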