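"""NJ genealogies, clustering-mode classification, elongation, and the
scenario discriminator's decision rule."""

import numpy as np
import pytest

from supergene import trees
from supergene.trees import (
    ClusteringResult,
    DiscriminatorThresholds,
    GenealogySignature,
    clustering_mode,
    discriminate,
    distance_tree,
    elongation_ratio,
    read_newick_tree,
)


def random_additive_distances(rng, n_tips):
    """Random additive (tree) metric: distances induced by a random binary
    tree with random positive branch lengths — built without NJ."""
    nodes = {i: [i] for i in range(n_tips)}  # node -> tip list
    dist = np.zeros((n_tips, n_tips))
    depth = {i: 0.0 for i in range(n_tips)}  # tip -> distance to current node root
    tip_depth = [dict({i: 0.0}) for i in range(n_tips)]
    groups = [[i] for i in range(n_tips)]
    to_root = [{i: 0.0} for i in range(n_tips)]  # per group: tip -> dist to group root
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        bi, bj = rng.uniform(0.1, 2.0, size=2)
        gi, gj = groups[i], groups[j]
        for a in gi:
            for b in gj:
                dist[a, b] = dist[b, a] = to_root[i][a] + bi + to_root[j][b] + bj
        merged = {a: d + bi for a, d in to_root[i].items()}
        merged.update({b: d + bj for b, d in to_root[j].items()})
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [gi + gj]
        to_root = [t for k, t in enumerate(to_root) if k not in (i, j)] + [merged]
    return dist


class TestDistanceTree:
    def test_nj_reproduces_additive_matrices_exactly(self, rng):
        """On an additive matrix NJ is exact: the tree's induced path
        distances equal the input distances (100 random instances)."""
        for _ in range(100):
            n = int(rng.integers(4, 9))
            dm = random_additive_distances(rng, n)
            from skbio import DistanceMatrix
            from skbio.tree import nj

            ids = [f"t{i}" for i in range(n)]
            tree = nj(DistanceMatrix(dm, ids))
            tips = {t.name: t for t in tree.tips()}
            for a in range(n):
                for b in range(a + 1, n):
                    got = tips[f"t{a}"].distance(tips[f"t{b}"])
                    assert got == pytest.approx(dm[a, b], abs=1e-9)

    def test_identical_tips_make_zero_length_cherry(self):
        calls = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 0, 1, 0]], dtype=float
        )
        ids = ["a1", "a2", "b1", "c1"]
        lt = distance_tree(calls, ids, dict.fromkeys(ids, "s"), dict.fromkeys(ids, "m"))
        tips = {t.name: t for t in lt.tree.tips()}
        assert tips["a1"].distance(tips["a2"]) == pytest.approx(0.0, abs=1e-12)

    def test_distances_invariant_to_site_order(self, rng):
        calls = rng.integers(0, 2, size=(5, 30)).astype(float)
        perm = rng.permutation(30)
        ids = [f"t{i}" for i in range(5)]
        a = trees.p_distance_matrix(calls.copy(), ids)
        b = trees.p_distance_matrix(calls[:, perm], ids)
        assert np.allclose(a.data, b.data)

    def test_all_identical_tips_flagged_star_degenerate(self):
        calls = np.zeros((4, 10), dtype=float)
        ids = ["a", "b", "c", "d"]
        lt = distance_tree(calls, ids, dict.fromkeys(ids, "s"), dict.fromkeys(ids, "m"))
        assert lt.star_degenerate

    def test_fewer_than_four_tips_rejected(self):
        with pytest.raises(ValueError):
            distance_tree(np.zeros((3, 5)), ["a", "b", "c"], {}, {})


def _labeled(newick, species, morph):
    return read_newick_tree(newick, species, morph)


class TestClusteringMode:
    def test_species_monophyly(self):
        lt = _labeled(
            "((a1:1,a2:1):1,(b1:1,b2:1):1);",
            {"a1": "a", "a2": "a", "b1": "b", "b2": "b"},
            {"a1": "m1", "a2": "m2", "b1": "m1", "b2": "m2"},
        )
        assert clustering_mode(lt).mode == "by_species"

    def test_phenotype_monophyly_across_species(self):
        lt = _labeled(
            "((ar:1,br:1):1,(ab:1,bb:1):1);",
            {"ar": "a", "br": "b", "ab": "a", "bb": "b"},
            {"ar": "red", "br": "red", "ab": "blue", "bb": "blue"},
        )
        res = clustering_mode(lt)
        assert res.mode == "by_phenotype"

    def test_fully_nested_species_is_by_species_unrooted(self):
        # a clean nested clade violates only rooted monophyly; on the
        # unrooted tree both species still correspond to bipartitions
        lt = _labeled(
            "((a1:1,(b1:1,b2:1):1):1,(a2:1,a3:1):1);",
            {"a1": "a", "a2": "a", "a3": "a", "b1": "b", "b2": "b"},
            dict.fromkeys(["a1", "a2", "a3", "b1", "b2"], "m"),
        )
        assert clustering_mode(lt).mode == "by_species"

    def test_interdigitated_species_recorded_as_nesting_exception(self):
        # species a's haplotypes interrupted by (only) species b: by_species
        # with the retention/nesting event recorded, not a broken clustering
        sp = {"a1": "a", "a2": "a", "b1": "b", "b2": "b", "c1": "c", "c2": "c"}
        lt = _labeled(
            "(((a1:1,(b1:1,b2:1):1):1,a2:1):1,(c1:1,c2:1):1);",
            sp,
            dict.fromkeys(sp, "m"),
        )
        res = clustering_mode(lt)
        assert res.mode == "by_species"
        # on the unrooted tree the interrupting partner is b (equivalently,
        # a joint clade with c): exactly one retention event on host a
        assert len(res.nesting_events) == 1
        assert res.nesting_events[0][1] == "a"

    def test_rerooting_invariance(self):
        sp = {"a1": "a", "a2": "a", "b1": "b", "b2": "b", "c1": "c", "c2": "c"}
        mo = dict.fromkeys(sp, "m")
        lt = _labeled("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(c1:1,c2:1):1);", sp, mo)
        base = clustering_mode(lt).mode
        for tip in ("a1", "b2", "c1"):
            rerooted = lt.tree.root_at(lt.tree.find(tip).parent)
            lt2 = trees.LabeledTree(tree=rerooted, species=sp, morph=mo)
            assert clustering_mode(lt2).mode == base

    def test_retained_ancestral_clade_rescued_and_recorded(self):
        # a small cross-species clade of retained ancestral alleles breaks
        # naive monophyly for two species; removing it restores by_species
        sp = {
            "a1": "a", "a2": "a", "a3": "a", "aR": "a",
            "b1": "b", "b2": "b", "b3": "b", "bR": "b",
            "c1": "c", "c2": "c", "c3": "c",
        }
        mo = {t: f"m_{s}" for t, s in sp.items()}  # species-private morphs
        # the retained a/b clade sits deep inside species c's clade, so no
        # pairwise nesting exception applies
        lt = _labeled(
            "(((a1:1,(a2:1,a3:1):1):1,(b1:1,(b2:1,b3:1):1):1):1,"
            "(c1:1,(c2:1,(c3:1,(aR:1,bR:1):5):1):1):1);",
            sp,
            mo,
        )
        res = clustering_mode(lt, tolerance=0.0)
        assert res.mode == "by_species"
        assert res.retained_clades == [["aR", "bR"]]

    def test_ils_like_interleaving_stays_unresolved(self):
        # every species split across two deep allele clades: no small-clade
        # removal can restore species monophyly
        sp = {}
        mo = {}
        parts = []
        for allele, morph in (("R", "red"), ("B", "blue")):
            tips = []
            for s in "abcd":
                for i in (1, 2, 3):
                    name = f"{s}{allele}{i}"
                    sp[name] = s
                    mo[name] = "m"  # uninformative morphs: phenotype test moot
                    tips.append(f"{name}:1")
            parts.append("(" + ",".join(tips) + "):5")
        lt = _labeled("(" + ",".join(parts) + ");", sp, mo)
        assert clustering_mode(lt, tolerance=0.1).mode == "mixed"

    def test_dedicated_morph_tree_drives_phenotype_test(self):
        # main tree has no informative morph tips (all excluded as hets);
        # the supplied homozygote tree carries the phenotype signal
        sp = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        main = _labeled(
            "((a1:1,b1:1):1,(a2:1,b2:1):1);", sp, dict.fromkeys(sp, "m0")
        )
        msp = {"aR": "a", "bR": "b", "aW": "a", "bW": "b"}
        morph_tree = _labeled(
            "((aR:1,bR:1):3,(aW:1,bW:1):3);",
            msp,
            {"aR": "red", "bR": "red", "aW": "white", "bW": "white"},
        )
        res = clustering_mode(main, morph_tree=morph_tree)
        assert res.mode == "by_phenotype"

    def test_missing_labels_rejected(self):
        lt = _labeled(
            "((a1:1,a2:1):1,(b1:1,b2:1):1);",
            {"a1": "a", "a2": "a", "b1": "b", "b2": "b"},
            {"a1": "m"},
        )
        with pytest.raises(ValueError, match="labels"):
            clustering_mode(lt)


class TestElongation:
    def test_identical_trees_give_one(self):
        sp = dict.fromkeys(["a", "b", "c", "d"], "s")
        mo = dict.fromkeys(sp, "m")
        lt = _labeled("((a:1,b:1):0.5,(c:1,d:1):0.5);", sp, mo)
        assert elongation_ratio(lt, lt) == pytest.approx(1.0)

    def test_doubled_terminal_branches_closed_form(self):
        sp = dict.fromkeys(["a", "b", "c", "d"], "s")
        mo = dict.fromkeys(sp, "m")
        genome = _labeled("((a:1,b:1):0.5,(c:1,d:1):0.5);", sp, mo)
        locus = _labeled("((a:2,b:2):0.5,(c:2,d:2):0.5);", sp, mo)
        # genome: mean terminal 1, total 5; locus: mean terminal 2, total 9
        assert elongation_ratio(locus, genome) == pytest.approx((2 / 9) / (1 / 5))

    def test_zero_total_length_errors(self):
        sp = dict.fromkeys(["a", "b", "c", "d"], "s")
        lt = _labeled("((a:0,b:0):0,(c:0,d:0):0);", sp, dict.fromkeys(sp, "m"))
        with pytest.raises(ValueError):
            elongation_ratio(lt, lt)


def _signature(mode, elong, bpd=0.01, depth=0.05, support=1.0):
    return GenealogySignature(
        clustering=ClusteringResult(mode, support, []),
        elongation_ratio=elong,
        between_phenotype_divergence=bpd,
        species_depth=depth,
    )


class _Shared:
    def __init__(self, rho, total):
        self.spearman_rho = rho
        self.total_shared = total


class TestDiscriminator:
    def test_by_phenotype_shallow_divergence_is_introgression(self):
        call = discriminate(_signature("by_phenotype", 1.0, bpd=0.01, depth=0.05),
                            50.0, _Shared(0.0, 0))
        assert call.label == "introgression"

    def test_by_phenotype_deep_divergence_is_ils(self):
        call = discriminate(_signature("by_phenotype", 1.0, bpd=0.2, depth=0.05),
                            50.0, _Shared(0.0, 0))
        assert call.label == "ils"

    def test_turnover_syndrome(self):
        call = discriminate(
            _signature("by_species", 1.6), {"A": 99.0, "B": 97.0},
            _Shared(0.8, 30),
        )
        assert call.label == "turnover"
        assert call.evidence["turnover_votes"]["sharing_tracks_proximity"]

    def test_no_balancing_signatures_is_independent(self):
        call = discriminate(_signature("by_species", 1.0), 50.0, _Shared(0.0, 0))
        assert call.label == "independent"

    def test_sharing_signature_required_by_default_weights(self):
        # elongation + percentile alone score 2 < 3: not called turnover
        call = discriminate(_signature("by_species", 1.6), 99.0, _Shared(0.0, 0))
        assert call.label == "independent"

    def test_mixed_clustering_returns_uncertain_with_evidence(self):
        call = discriminate(_signature("mixed", 1.0), 50.0, _Shared(0.0, 0))
        assert call.label == "mixed/uncertain"
        assert call.evidence["clustering_mode"] == "mixed"
        assert "turnover_votes" in call.evidence

    def test_custom_thresholds_respected(self):
        th = DiscriminatorThresholds(weight_sharing=0, turnover_score_min=2)
        call = discriminate(_signature("by_species", 1.6), 99.0, _Shared(0.0, 0), th)
        assert call.label == "turnover"
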