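"""Allelic genealogies from SNP data and the genealogical signatures that
separate the four supergene-sharing scenarios.

Trees are neighbour-joining on normalised Hamming (p-) distances, which is
sufficient to expose the distance-visible signatures of the four hypotheses:
clustering of locus haplotypes by species versus by phenotype, elongation of
the locus genealogy relative to the genome-wide genealogy, nesting of one
species' haplotypes inside another's, and (together with Tajima's D
enrichment and trans-species SNP sharing) the allelic-turnover syndrome.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .variants import MISSING, GenotypeMatrix

SCENARIOS = ("introgression", "ils", "turnover", "independent")
UNCERTAIN = "mixed/uncertain"


@dataclass
class LabeledTree:
    """An unrooted NJ tree whose tips carry species and morph labels."""

    tree: TreeNode
    species: dict[str, str]
    morph: dict[str, str]
    star_degenerate: bool = False

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def write_newick(self, path_or_buf) -> None:
        self.tree.write(path_or_buf, format="newick")


def p_distance_matrix(
    calls: np.ndarray, ids: list[str]
) -> DistanceMatrix:
    """Normalised Hamming distance over non-missing shared sites.

    ``calls`` is (n_tips, n_sites) of 0/1 alleles (haplotypes) or dosages
    scaled to [0, 2]; missing entries are ``-1`` and excluded pairwise.
    """
    X = np.asarray(calls, dtype=float)
    X[X == MISSING] = np.nan
    n = X.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1 :])
        shared = ~np.isnan(diff)
        with np.errstate(invalid="ignore"):
            d = np.where(
                shared.sum(axis=1) > 0,
                np.nansum(diff, axis=1) / np.maximum(shared.sum(axis=1), 1),
                0.0,
            )
        dm[i, i + 1 :] = d
        dm[i + 1 :, i] = d
    return DistanceMatrix(dm, ids)


def distance_tree(
    calls: np.ndarray,
    ids: list[str],
    species: dict[str, str],
    morph: dict[str, str],
) -> LabeledTree:
    """Neighbour-joining tree on p-distances with deterministic tip order.

    All-identical tips produce a flagged star-like degenerate tree rather
    than an error.  Negative NJ branch lengths are clamped to zero.
    """
    if len(ids) < 4:
        raise ValueError("need >= 4 tips")
    order = np.argsort(ids)
    ids_sorted = [ids[i] for i in order]
    dm = p_distance_matrix(np.asarray(calls)[order], ids_sorted)
    star = bool(np.allclose(dm.data, 0.0))
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return LabeledTree(tree=tree, species=dict(species), morph=dict(morph), star_degenerate=star)


def read_newick_tree(
    source, species: dict[str, str], morph: dict[str, str]
) -> LabeledTree:
    if isinstance(source, str) and source.strip().startswith("("):
        tree = TreeNode.read(io.StringIO(source), format="newick")
    else:
        tree = TreeNode.read(str(source), format="newick")
    return LabeledTree(tree=tree, species=dict(species), morph=dict(morph))


# ---------------------------------------------------------------------------
# Clustering mode


def _clade_sets(tree: TreeNode) -> set[frozenset]:
    """Tip-name sets of every clade under an arbitrary rooting, plus their
    complements — i.e. both sides of every edge (unrooted bipartitions)."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            s = frozenset([node.name])
        else:
            s = frozenset(t.name for t in node.tips())
        out.add(s)
        out.add(all_tips - s)
    out.add(all_tips)
    return out


def _is_monophyletic(
    group: frozenset, clades: set[frozenset], tolerance: float = 0.0
) -> bool:
    """Exact monophyly, or — with ``tolerance`` > 0 — existence of a
    bipartition side covering >= (1-tolerance) of the group with foreign-tip
    contamination <= tolerance.  The tolerant form absorbs the stray tips
    that finite-sample NJ trees inevitably misplace when species splits are
    on the order of the coalescent timescale."""
    if len(group) <= 1 or group in clades:
        return True
    if tolerance <= 0:
        return False
    need = (1.0 - tolerance) * len(group)
    for x in clades:
        inter = len(group & x)
        if inter >= need and (len(x) - inter) <= tolerance * len(x):
            return True
    return False


def _smallest_containing_clade(group: frozenset, clades: set[frozenset]) -> frozenset:
    candidates = [x for x in clades if group <= x]
    if not candidates:
        return group
    # deterministic tie-break: size, then lexicographic tip names
    return min(candidates, key=lambda x: (len(x), tuple(sorted(x))))


@dataclass
class ClusteringResult:
    mode: str  # by_species | by_phenotype | mixed
    support: float  # fraction of label groups satisfying monophyly
    nesting_events: list[tuple[str, str]] = field(default_factory=list)  # (nested, host)
    # small cross-species clades of retained ancestral alleles whose removal
    # restores species monophyly (trans-species polymorphism at young
    # timescales); lists of tip names
    retained_clades: list[list[str]] = field(default_factory=list)


def clustering_mode(
    ltree: LabeledTree,
    exclude_tips: set[str] | frozenset = frozenset(),
    tolerance: float = 0.0,
    morph_tree: LabeledTree | None = None,
) -> ClusteringResult:
    """Classify a locus genealogy as clustering by species, by phenotype, or
    mixed.

    Species monophyly is tested first (the turnover / independent-origin
    signature) on *all* tips — a species label is valid for every haplotype.
    A species whose haplotypes are interrupted only by a second,
    itself-monophyletic species counts as monophyletic with a recorded
    nesting event (retention of ancestral variation at young timescales).
    If species fail, morph-class monophyly across species (the introgression
    / ILS signature) is tested with the tips in ``exclude_tips`` removed —
    these are the haplotypes of called locus heterozygotes, whose morph
    label does not identify the haplotype's own allele class.  When a
    dedicated ``morph_tree`` is supplied (built from phenotype-informative
    locus homozygotes), the morph test runs on it instead, decoupling the
    two tests' sampling needs: the species test wants a random haplotype
    sample, the morph test wants every morph's alleles represented.

    The result is invariant to re-rooting: tests use unrooted bipartitions.
    """
    all_tips = [t.name for t in ltree.tree.tips()]
    missing = [t for t in all_tips if t not in ltree.species or t not in ltree.morph]
    if missing:
        raise ValueError(f"tips missing labels: {missing[:3]}")
    clades = _clade_sets(ltree.tree)

    by_sp: dict[str, set] = {}
    for t in all_tips:
        by_sp.setdefault(ltree.species[t], set()).add(t)

    # -- phenotype test first: trans-species allele clades are the specific
    # signature of introgression / ILS.  It only wins when morph classes are
    # genuinely shared across species (most morph groups span >= 2 species),
    # which species-private allele sets never satisfy.
    if morph_tree is not None:
        morph_source = morph_tree
        morph_tips = [t.name for t in morph_tree.tree.tips()]
        morph_clades = _clade_sets(morph_tree.tree)
    else:
        morph_source = ltree
        morph_tips = [t for t in all_tips if t not in exclude_tips]
        morph_clades = (
            _clade_sets(ltree.tree.shear(morph_tips)) if exclude_tips else clades
        )
    by_morph: dict[str, set] = {}
    for t in morph_tips:
        by_morph.setdefault(morph_source.morph[t], set()).add(t)
    if not by_morph:
        raise ValueError("no tips left for the morph test after exclusions")
    morph_groups = {k: frozenset(v) for k, v in by_morph.items()}
    morph_mono = {
        k: _is_monophyletic(g, morph_clades, tolerance) for k, g in morph_groups.items()
    }
    morph_support = sum(morph_mono.values()) / len(morph_mono)
    # species span of each morph counted over ALL main-tree tips
    # (heterozygote carriers included): a shared allele is shared even
    # where its homozygotes are too rare to appear in the pruned tip sample
    span_of: dict[str, set] = {}
    for t in all_tips:
        span_of.setdefault(ltree.morph[t], set()).add(ltree.species[t])
    for t in morph_tips:
        span_of.setdefault(morph_source.morph[t], set()).add(morph_source.species[t])
    spanning = sum(
        1 for k in morph_groups if len(span_of.get(k, set())) >= 2
    )
    # at least two morph classes must each span species: one shared
    # background class plus species-private alleles is not allele sharing
    cross_species_morphs = (
        len(morph_groups) >= 2
        and spanning >= 2
        and spanning * 2 >= len(morph_groups)
    )
    if all(morph_mono.values()) and cross_species_morphs:
        return ClusteringResult("by_phenotype", morph_support, [])

    sp_groups = {k: frozenset(v) for k, v in by_sp.items()}
    mono = {k: _is_monophyletic(g, clades, tolerance) for k, g in sp_groups.items()}
    nesting: list[tuple[str, str]] = []
    for k, ok in list(mono.items()):
        if ok:
            continue
        # retention exception: the interrupting tips come from at most two
        # other species (haplotypes nested inside / interdigitated with
        # close relatives — ancestral variation retained at young
        # timescales).  A species interleaved with most of the tree never
        # passes, which keeps trans-species (ILS-like) clustering out.
        host = _smallest_containing_clade(sp_groups[k], clades)
        partners = sorted({ltree.species[t] for t in host - sp_groups[k]})
        if 1 <= len(partners) <= 2:
            joint = frozenset().union(sp_groups[k], *(sp_groups[p] for p in partners))
            if len(joint) < len(all_tips) and _is_monophyletic(
                joint, clades, tolerance
            ):
                nesting.extend((p, k) for p in partners)
                mono[k] = True
    sp_support = sum(mono.values()) / len(mono)
    if all(mono.values()):
        return ClusteringResult("by_species", sp_support, nesting)

    # retained ancestral lineage: a single small cross-species clade whose
    # removal restores species monophyly everywhere — the trans-species
    # polymorphism a turnover history leaves at young timescales.  ILS-like
    # clustering cannot pass here: its cross-species clades each hold about
    # half the tree.
    retained = _retained_lineage_rescue(ltree, clades, sp_groups, tolerance)
    if retained is not None:
        return ClusteringResult(
            "by_species", 1.0, nesting, [sorted(c) for c in retained]
        )
    return ClusteringResult("mixed", max(sp_support, morph_support), nesting)


def _retained_lineage_rescue(
    ltree: LabeledTree,
    clades: set[frozenset],
    sp_groups: dict[str, frozenset],
    tolerance: float,
    max_clade_fraction: float = 0.2,
    max_total_fraction: float = 0.35,
) -> list[frozenset] | None:
    """Up to two disjoint small cross-species clades whose removal makes
    every species monophyletic, or None.  Size caps keep ILS-like
    clustering (whose cross-species clades each hold about half the tips)
    from ever passing."""
    all_tips = frozenset(t.name for t in ltree.tree.tips())
    n = len(all_tips)
    failing = frozenset().union(
        *(
            grp
            for grp in sp_groups.values()
            if not _is_monophyletic(grp, clades, tolerance)
        )
    )
    candidates = sorted(
        (
            x
            for x in clades
            if 2 <= len(x) <= max_clade_fraction * n
            and len({ltree.species[t] for t in x}) >= 2
            and x & failing
        ),
        key=lambda c: (len(c), tuple(sorted(c))),
    )[:10]  # smallest candidates only; bounds the shear-and-retest work

    def species_sorted_without(removed: frozenset) -> bool:
        remaining = sorted(all_tips - removed)
        if len(remaining) < 4:
            return False
        sub_clades = _clade_sets(ltree.tree.shear(remaining))
        return all(
            _is_monophyletic(grp - removed, sub_clades, tolerance)
            for grp in sp_groups.values()
            if len(grp - removed) > 0
        )

    for x in candidates:
        if species_sorted_without(x):
            return [x]
    for i, x1 in enumerate(candidates):
        for x2 in candidates[i + 1 :]:
            if x1 & x2 or len(x1) + len(x2) > max_total_fraction * n:
                continue
            if species_sorted_without(x1 | x2):
                return [x1, x2]
    return None


# ---------------------------------------------------------------------------
# Branch-length signatures


def _terminal_fraction(tree: TreeNode) -> tuple[float, float]:
    term = [t.length or 0.0 for t in tree.tips()]
    total = sum(n.length or 0.0 for n in tree.traverse(include_self=False))
    if total == 0:
        raise ValueError("zero total tree length")
    return float(np.mean(term)), float(total)


def elongation_ratio(locus_tree: LabeledTree, genome_tree: LabeledTree) -> float:
    """Ratio of (mean terminal branch / total length) at the locus versus
    genome-wide; > 1 indicates relative terminal elongation at the locus."""
    lt, lt_tot = _terminal_fraction(locus_tree.tree)
    gt, gt_tot = _terminal_fraction(genome_tree.tree)
    return (lt / lt_tot) / (gt / gt_tot)


def _mean_between_within(dm: DistanceMatrix, groups: dict[str, str]) -> tuple[float, float]:
    """(mean between-group, mean within-group) distances over tip pairs."""
    ids = dm.ids
    between, within = [], []
    for i, j in itertools.combinations(range(len(ids)), 2):
        if groups.get(ids[i]) is None or groups.get(ids[j]) is None:
            continue
        (between if groups[ids[i]] != groups[ids[j]] else within).append(dm[i, j])
    return (
        float(np.mean(between)) if between else math.nan,
        float(np.mean(within)) if within else 0.0,
    )


@dataclass
class GenealogySignature:
    """Evidence extracted from the locus and genome genealogies."""

    clustering: ClusteringResult
    elongation_ratio: float
    between_phenotype_divergence: float  # net (da) locus divergence between morph classes
    species_depth: float  # max net between-species genome divergence
    locus_star_degenerate: bool = False


def genealogy_signature(
    locus_tree: LabeledTree,
    genome_tree: LabeledTree,
    locus_dm: DistanceMatrix,
    genome_dm: DistanceMatrix,
    het_tips: set[str] | frozenset = frozenset(),
    elongation_locus_tree: LabeledTree | None = None,
    elongation_genome_tree: LabeledTree | None = None,
    monophyly_tolerance: float = 0.0,
    morph_tree: LabeledTree | None = None,
) -> GenealogySignature:
    """Assemble the discriminator's genealogical evidence.

    Net divergences subtract mean within-group diversity from mean
    between-group distance (d_a = d_xy - (pi_x + pi_y)/2 in spirit), putting
    the locus morph-class divergence and the genome species depth on the
    same scale.

    When allele-representative trees (one haplotype per species x morph,
    the tips the hypothesis genealogies are drawn with) are supplied, the
    elongation ratio is computed on them: with one tip per allele,
    within-species allelic divergence maintained by balancing selection
    loads onto terminal branches, which is the predicted elongation
    signature; on dense per-haplotype trees it would load onto internal
    branches instead.
    """
    clus = clustering_mode(
        locus_tree,
        exclude_tips=het_tips,
        tolerance=monophyly_tolerance,
        morph_tree=morph_tree,
    )

    morph_labels = {
        t: locus_tree.morph[t]
        for t in locus_tree.tip_names
        if t not in het_tips
    }
    b, w = _mean_between_within(locus_dm, morph_labels)
    between_phen = b - w if math.isfinite(b) else math.nan

    sp_labels = {t: genome_tree.species[t] for t in genome_tree.tip_names}
    depth = -math.inf
    species = sorted(set(sp_labels.values()))
    for s1, s2 in itertools.combinations(species, 2):
        sub = {t: g for t, g in sp_labels.items() if g in (s1, s2)}
        b2, w2 = _mean_between_within(genome_dm, sub)
        if math.isfinite(b2):
            depth = max(depth, b2 - w2)
    e_lt = elongation_locus_tree if elongation_locus_tree is not None else locus_tree
    e_gt = elongation_genome_tree if elongation_genome_tree is not None else genome_tree
    try:
        elong = elongation_ratio(e_lt, e_gt)
    except ValueError:  # degenerate zero-length tree: no elongation evidence
        elong = math.nan
    return GenealogySignature(
        clustering=clus,
        elongation_ratio=elong,
        between_phenotype_divergence=between_phen,
        species_depth=float(depth),
        locus_star_degenerate=locus_tree.star_degenerate,
    )


# ---------------------------------------------------------------------------
# Scenario discriminator


@dataclass(frozen=True)
class DiscriminatorThresholds:
    """Decision thresholds for the scenario call.

    The turnover decision is a weighted majority over three
    balancing-selection signatures.  Trans-species sharing that tracks
    phylogenetic proximity carries double weight because it is the
    signature specific to turnover of an ancestral polymorphism — genealogy
    elongation and Tajima's D enrichment also arise under any young
    balanced polymorphism, including independently evolved ones.  With the
    default weights (2 + 1 + 1, score >= 3) the sharing signature plus at
    least one other is required.  ``elongation_min`` (r*) and
    ``tajima_percentile_min`` (P*) are calibrated so that neutral
    simulations rarely fire them."""

    elongation_min: float = 1.2  # r*
    tajima_percentile_min: float = 90.0  # P*
    sharing_rho_min: float = 0.3
    min_shared_snps: int = 12
    # pervasive trans-species sharing fires the vote even when the rank
    # correlation over the handful of species pairs is noisy: sustained
    # turnover of an ancestral polymorphism leaves shared associated SNPs
    # in essentially every pair, independent origin in essentially none
    strong_shared_snps: int = 20
    depth_factor: float = 1.0  # introgression if between-phenotype div < factor x depth
    weight_elongation: int = 1
    weight_percentile: int = 1
    weight_sharing: int = 2
    turnover_score_min: int = 3


@dataclass
class ScenarioCall:
    label: str
    evidence: dict


def discriminate(
    signature: GenealogySignature,
    tajima_percentiles: dict[str, float] | float,
    shared_report=None,
    thresholds: DiscriminatorThresholds = DiscriminatorThresholds(),
) -> ScenarioCall:
    """Decision tree over the four supergene-sharing scenarios.

    * by_phenotype clustering: alleles are shared across species —
      introgression when the between-phenotype locus divergence is shallow
      relative to the species-split depth, ILS when it is deep.
    * by_species clustering: alleles are species-specific — turnover when a
      weighted majority of the balancing-selection signatures fire
      (genealogy elongation, locus Tajima's D percentile, trans-species
      sharing tracking phylogenetic proximity), otherwise independent
      origin.
    * anything else: "mixed/uncertain", with the evidence vector returned
      rather than silently coerced.
    """
    if isinstance(tajima_percentiles, dict):
        perc_values = [v for v in tajima_percentiles.values() if math.isfinite(v)]
        percentile = float(np.median(perc_values)) if perc_values else math.nan
    else:
        percentile = float(tajima_percentiles)

    rho = getattr(shared_report, "spearman_rho", math.nan)
    total_shared = getattr(shared_report, "total_shared", 0)

    votes = {
        "elongated_genealogy": bool(
            math.isfinite(signature.elongation_ratio)
            and signature.elongation_ratio > thresholds.elongation_min
        ),
        "elevated_tajima_percentile": bool(
            math.isfinite(percentile) and percentile >= thresholds.tajima_percentile_min
        ),
        "sharing_tracks_proximity": bool(
            total_shared >= thresholds.min_shared_snps
            and (
                (math.isfinite(rho) and rho > thresholds.sharing_rho_min)
                or total_shared >= thresholds.strong_shared_snps
            )
        ),
    }
    evidence = {
        "clustering_mode": signature.clustering.mode,
        "clustering_support": signature.clustering.support,
        "nesting_events": list(signature.clustering.nesting_events),
        "retained_ancestral_clades": [
            list(c) for c in signature.clustering.retained_clades
        ],
        "elongation_ratio": signature.elongation_ratio,
        "tajima_percentile": percentile,
        "between_phenotype_divergence": signature.between_phenotype_divergence,
        "species_depth": signature.species_depth,
        "sharing_rho": float(rho) if math.isfinite(rho) else None,
        "total_shared_snps": int(total_shared),
        "turnover_votes": votes,
        "thresholds": {
            "elongation_min": thresholds.elongation_min,
            "tajima_percentile_min": thresholds.tajima_percentile_min,
            "sharing_rho_min": thresholds.sharing_rho_min,
            "min_shared_snps": thresholds.min_shared_snps,
            "strong_shared_snps": thresholds.strong_shared_snps,
            "depth_factor": thresholds.depth_factor,
        },
    }

    mode = signature.clustering.mode
    if mode == "by_phenotype":
        div = signature.between_phenotype_divergence
        if not (math.isfinite(div) and math.isfinite(signature.species_depth)):
            return ScenarioCall(UNCERTAIN, evidence)
        label = (
            "introgression"
            if div < thresholds.depth_factor * signature.species_depth
            else "ils"
        )
        return ScenarioCall(label, evidence)
    if mode == "by_species":
        score = (
            thresholds.weight_elongation * votes["elongated_genealogy"]
            + thresholds.weight_percentile * votes["elevated_tajima_percentile"]
            + thresholds.weight_sharing * votes["sharing_tracks_proximity"]
        )
        evidence["turnover_score"] = score
        label = "turnover" if score >= thresholds.turnover_score_min else "independent"
        return ScenarioCall(label, evidence)
    return ScenarioCall(UNCERTAIN, evidence)
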