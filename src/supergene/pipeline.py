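"""End-to-end orchestration: simulate (or ingest a VCF + sample table),
filter and window the variants, compute the per-species differentiation /
diversity / LD / association signatures around the supergene locus, scan for
conversion tracts, build locus and genome genealogies, and discriminate the
four evolutionary scenarios.

Every stochastic stage receives a sub-seed derived from the master seed via
a fixed counter, so adding a stage never perturbs earlier stages and
identical configurations reproduce byte-identical summary JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import assoc as assoc_mod
from . import geneconv as geneconv_mod
from . import popgen, trees
from . import ld as ld_mod
from .simdata import SimResult, scenario_preset, simulate
from .trees import DiscriminatorThresholds, ScenarioCall
from .variants import (
    GenotypeMatrix,
    SampleTable,
    drop_sparse_windows,
    filter_site_missingness,
    make_windows,
    read_sample_table,
    read_vcf,
)


@dataclass
class RunConfig:
    """Configuration for one full pipeline run.

    Exactly one input mode: ``preset`` (simulate) or ``vcf``+``samples``
    (ingest); the latter requires ``locus_region``.
    """

    preset: str | None = None
    vcf: str | None = None
    samples: str | None = None
    locus_region: tuple[str, int, int] | None = None
    seed: int = 0
    out_dir: str | None = None
    window_size: int = 10_000
    sparse_quantile: float = 0.10
    max_missing_sites: float = 0.25
    gwas_max_missing: float = 0.20
    pca_max_missing: float = 0.10
    assoc_min_freq_diff: float = 0.5
    assoc_max_q: float = 0.05
    ld_thin_to: int = 400
    ld_min_genotyping: float = 0.75
    ld_min_maf: float = 0.001
    ld_flank_bp: int = 100_000
    geneconv_permutations: int = 2000
    geneconv_alpha: float = 0.05
    geneconv_haps_per_class: int = 3
    tips_per_species: int = 10
    min_per_morph: int = 4
    monophyly_tolerance: float = 0.25
    thresholds: DiscriminatorThresholds = field(default_factory=DiscriminatorThresholds)
    run_ld: bool = True
    run_geneconv: bool = True
    preset_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if (self.preset is None) == (self.vcf is None):
            raise ValueError("exactly one input mode: preset or vcf")
        if self.vcf is not None and (self.samples is None or self.locus_region is None):
            raise ValueError("vcf mode needs --samples and --locus region")


def _stage_seed(master: int, counter: int) -> int:
    return (master * 1_000_003 + counter) % (2**31)


def _round(x, nd=8):
    if isinstance(x, float):
        return None if not math.isfinite(x) else round(x, nd)
    return x


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and optionally writes) the
    summary report bundle."""
    config.validate()
    stage = "input"
    try:
        sim_result: SimResult | None = None
        if config.preset is not None:
            cfg = scenario_preset(
                config.preset, seed=_stage_seed(config.seed, 0), **config.preset_overrides
            )
            sim_result = simulate(cfg)
            g = sim_result.genotypes
            samples = sim_result.samples
            locus_region = sim_result.locus_region
        else:
            g = read_vcf(config.vcf)
            samples = read_sample_table(config.samples)
            locus_region = tuple(config.locus_region)
        samples.validate_against(g)

        stage = "filter"
        g = filter_site_missingness(g, config.max_missing_sites)

        stage = "windows"
        windows_all = make_windows(g, config.window_size)
        windows = drop_sparse_windows(windows_all, config.sparse_quantile)

        species_report: dict[str, dict] = {}
        per_species_assoc = {}
        tajima_percentiles: dict[str, float] = {}
        het_individuals: dict[str, list[str]] = {}

        for sp in samples.species:
            stage = f"species:{sp}"
            inds = samples.individuals(species=sp)
            rep: dict = {"n_individuals": len(inds)}
            morph_counts = (
                samples.table[samples.table["species"] == sp]["morph"]
                .value_counts()
                .to_dict()
            )
            rep["morphs"] = morph_counts
            usable_morphs = [m for m, c in morph_counts.items() if c >= config.min_per_morph]
            polymorphic = len(usable_morphs) >= 2

            tw = popgen.tajimas_d_window(g, inds, windows)
            try:
                perc = popgen.percentile_rank(tw, locus_region)
            except ValueError:
                perc = math.nan
            tajima_percentiles[sp] = perc
            defined = [w.value for w in tw if w.defined]
            rep["tajima"] = {
                "locus_percentile": _round(perc),
                "genome_mean": _round(float(np.mean(defined))) if defined else None,
                "n_windows": len(defined),
            }

            if polymorphic:
                top2 = sorted(usable_morphs, key=lambda m: -morph_counts[m])[:2]
                pop1 = samples.individuals(species=sp, morph=top2[0])
                pop2 = samples.individuals(species=sp, morph=top2[1])
                fw = popgen.fst_window(g, pop1, pop2, windows)
                try:
                    fperc = popgen.percentile_rank(fw, locus_region)
                except ValueError:
                    fperc = math.nan
                locus_vals = [
                    w.value
                    for w in fw
                    if w.defined
                    and w.chrom == locus_region[0]
                    and w.start <= locus_region[2]
                    and w.end >= locus_region[1]
                ]
                rep["fst"] = {
                    "morph_pair": top2,
                    "locus_percentile": _round(fperc),
                    "locus_max": _round(max(locus_vals)) if locus_vals else None,
                }

                stage = f"gwas:{sp}"
                at = assoc_mod.gwas(
                    g.take_individuals(inds), samples, max_missing=config.gwas_max_missing
                )
                at = assoc_mod.score_associated(
                    at, config.assoc_min_freq_diff, config.assoc_max_q
                )
                in_locus = (
                    (at["chrom"] == locus_region[0])
                    & (at["pos"] >= locus_region[1])
                    & (at["pos"] <= locus_region[2])
                )
                per_species_assoc[sp] = at[in_locus].reset_index(drop=True)
                rep["gwas"] = {
                    "n_tested": int(len(at)),
                    "n_associated_locus": int(at[in_locus]["associated"].sum()),
                }

                stage = f"pca:{sp}"
                locus_mask = g.site_mask_region(*locus_region)
                try:
                    p_locus = assoc_mod.pca(
                        g,
                        inds,
                        site_mask=locus_mask,
                        site_set="locus",
                        max_site_missing=config.pca_max_missing,
                    )
                    calls = assoc_mod.call_locus_genotypes(
                        p_locus, seed=_stage_seed(config.seed, 3)
                    )
                    het_individuals[sp] = list(calls[calls == "het"].index)
                    rep["locus_genotypes"] = calls.value_counts().to_dict()
                except ValueError as e:
                    rep["locus_genotypes"] = {"error": str(e)}
                    het_individuals[sp] = []

                if config.run_ld:
                    stage = f"ld:{sp}"
                    chrom, lo, hi = locus_region
                    flank_lo = max(1, lo - config.ld_flank_bp)
                    flank_hi = hi + config.ld_flank_bp
                    try:
                        ldm = ld_mod.ld_matrix(
                            g,
                            inds,
                            region=(chrom, flank_lo, flank_hi),
                            thin_to=config.ld_thin_to,
                            min_genotyping=config.ld_min_genotyping,
                            min_maf=config.ld_min_maf,
                            seed=_stage_seed(config.seed, 4),
                        )
                        in_loc = (ldm.pos >= lo) & (ldm.pos <= hi)
                        rep["ld"] = {
                            "mean_abs_dprime_locus": _round(
                                ld_mod.mean_abs_dprime(ldm, in_loc)
                            ),
                            "mean_abs_dprime_flank": _round(
                                ld_mod.mean_abs_dprime(ldm, ~in_loc)
                            ),
                            "n_sites": int(ldm.n_sites),
                        }
                    except ValueError as e:
                        rep["ld"] = {"error": str(e)}

                if config.run_geneconv and het_individuals.get(sp) is not None:
                    stage = f"geneconv:{sp}"
                    rep["geneconv"] = _geneconv_stage(g, sp, samples, locus_region, config)
            else:
                het_individuals[sp] = []
            species_report[sp] = rep

        stage = "trees"
        tree_bundle = _tree_stage(g, samples, locus_region, het_individuals, config)

        stage = "shared_snps"
        if len(per_species_assoc) >= 2:
            shared = assoc_mod.shared_snps(
                per_species_assoc, tree_bundle["species_distances"]
            )
            shared_summary = {
                "pair_counts": {f"{a}|{b}": c for (a, b), c in shared.pair_counts.items()},
                "spearman_rho": _round(shared.spearman_rho),
                "total_shared": shared.total_shared,
            }
        else:
            shared = None
            shared_summary = None

        stage = "discriminate"
        call = trees.discriminate(
            tree_bundle["signature"],
            tajima_percentiles,
            shared,
            thresholds=config.thresholds,
        )

        summary = {
            "input": {
                "mode": "simulate" if config.preset else "vcf",
                "preset": config.preset,
                "seed": config.seed,
                "n_individuals": g.n_individuals,
                "n_sites": g.n_sites,
                "locus_region": list(locus_region),
            },
            "windows": {"n_total": len(windows_all), "n_kept": len(windows)},
            "species": species_report,
            "shared_snps": shared_summary,
            "scenario_call": {
                "label": call.label,
                "evidence": _jsonable(call.evidence),
            },
        }
        if sim_result is not None:
            summary["truth"] = {
                "scenario": sim_result.true_scenario,
                "n_allele_classes_created": sim_result.n_allele_classes_created,
            }
        if config.out_dir:
            _write_bundle(summary, config, g)
        return summary
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - name the failing stage
        raise PipelineError(stage, e) from e


def _geneconv_stage(g, sp, samples, locus_region, config) -> dict:
    """Conversion-tract scan between called locus homozygote haplotypes."""
    if not g.is_phased:
        return {"skipped": "unphased input"}
    inds = samples.individuals(species=sp)
    locus_mask = g.site_mask_region(*locus_region)
    try:
        p_locus = assoc_mod.pca(
            g, inds, site_mask=locus_mask, site_set="locus",
            max_site_missing=config.pca_max_missing,
        )
        calls = assoc_mod.call_locus_genotypes(p_locus, seed=_stage_seed(config.seed, 5))
    except ValueError as e:
        return {"skipped": str(e)}
    rng = np.random.default_rng(_stage_seed(config.seed, 6))
    hap_rows, labels, hap_ids = [], [], []
    idx_of = {s: i for i, s in enumerate(g.ids)}
    cols = np.nonzero(locus_mask)[0]
    for cls in ("hom_ref_morph", "hom_alt_morph"):
        members = [s for s in calls.index if calls[s] == cls]
        if len(members) > config.geneconv_haps_per_class:
            members = list(rng.choice(members, config.geneconv_haps_per_class, replace=False))
        for m in members:
            hap_rows.append(g.haplotypes[idx_of[m], 0, :][cols])
            labels.append(cls)
            hap_ids.append(f"{m}_h0")
    if len(set(labels)) < 2:
        return {"skipped": "fewer than 2 called homozygote classes"}
    tracts = geneconv_mod.detect_tracts(
        np.array(hap_rows),
        g.pos[cols],
        labels,
        hap_ids=hap_ids,
        n_permutations=config.geneconv_permutations,
        alpha=config.geneconv_alpha,
        seed=_stage_seed(config.seed, 7),
    )
    return {
        "n_significant_tracts": len(tracts),
        "tracts": [
            {
                "pair": [t.hap_a, t.hap_b],
                "start_pos": t.start_pos,
                "end_pos": t.end_pos,
                "p_corrected": _round(t.p_corrected),
            }
            for t in tracts[:20]
        ],
    }


def _tree_stage(g, samples, locus_region, het_individuals, config) -> dict:
    """Locus and genome NJ genealogies on a per-species haplotype subsample,
    plus the genealogical evidence for the discriminator."""
    rng = np.random.default_rng(_stage_seed(config.seed, 8))
    species_of = samples.species_of()
    morph_of = samples.morph_of()
    chosen: list[str] = []
    for sp in samples.species:
        inds = samples.individuals(species=sp)
        if len(inds) > config.tips_per_species:
            inds = sorted(rng.choice(inds, config.tips_per_species, replace=False))
        chosen.extend(inds)
    idx = g.individual_index(chosen)
    locus_mask = g.site_mask_region(*locus_region)
    tip_ids, tip_species, tip_morph, rows_locus, rows_genome = [], {}, {}, [], []
    het_tips: set[str] = set()
    hets_all = {i for v in het_individuals.values() for i in v}
    for k, ind in zip(idx, chosen):
        if g.is_phased:
            for hpl in (0, 1):
                name = f"{ind}_h{hpl}"
                tip_ids.append(name)
                tip_species[name] = species_of[ind]
                tip_morph[name] = morph_of[ind]
                rows_locus.append(g.haplotypes[k, hpl, locus_mask])
                rows_genome.append(g.haplotypes[k, hpl, :])
                if ind in hets_all:
                    het_tips.add(name)
        else:
            tip_ids.append(ind)
            tip_species[ind] = species_of[ind]
            tip_morph[ind] = morph_of[ind]
            d = g.dosage[k].astype(float) / 2.0
            d[g.dosage[k] < 0] = -1
            rows_locus.append(d[locus_mask])
            rows_genome.append(d)
            if ind in hets_all:
                het_tips.add(ind)
    locus_calls = np.array(rows_locus, dtype=float)
    genome_calls = np.array(rows_genome, dtype=float)
    order = np.argsort(tip_ids)
    ids_sorted = [tip_ids[i] for i in order]
    locus_dm = trees.p_distance_matrix(locus_calls[order], ids_sorted)
    genome_dm = trees.p_distance_matrix(genome_calls[order], ids_sorted)
    locus_tree = trees.distance_tree(locus_calls, tip_ids, tip_species, tip_morph)
    genome_tree = trees.distance_tree(genome_calls, tip_ids, tip_species, tip_morph)
    elong = _representative_trees(g, samples, locus_mask, het_individuals, config)
    morph_tree = _morph_test_tree(
        g, samples, locus_mask, het_individuals, config, rng
    )
    signature = trees.genealogy_signature(
        locus_tree,
        genome_tree,
        locus_dm,
        genome_dm,
        het_tips=frozenset(het_tips),
        elongation_locus_tree=elong[0] if elong else None,
        elongation_genome_tree=elong[1] if elong else None,
        monophyly_tolerance=config.monophyly_tolerance,
        morph_tree=morph_tree,
    )
    # mean between-species genome distances, for the sharing-vs-proximity test
    species_distances = {}
    sp_list = samples.species
    import itertools as it

    for a, b in it.combinations(sorted(sp_list), 2):
        ia = [i for i, t in enumerate(ids_sorted) if tip_species[t] == a]
        ib = [i for i, t in enumerate(ids_sorted) if tip_species[t] == b]
        species_distances[(a, b)] = float(np.mean(genome_dm.data[np.ix_(ia, ib)]))
    return {
        "locus_tree": locus_tree,
        "genome_tree": genome_tree,
        "signature": signature,
        "species_distances": species_distances,
    }


def _representative_trees(g, samples, locus_mask, het_individuals, config):
    """Allele-representative locus and genome trees: one haplotype per
    (species, morph), taken from a called locus homozygote where possible.

    These are the trees the elongation statistic is computed on — one tip
    per allele, as in the hypothesis genealogies; the per-haplotype trees
    keep serving the clustering tests.
    """
    idx_all = {s: i for i, s in enumerate(g.ids)}

    def _locus_row(ind):
        k = idx_all[ind]
        if g.is_phased:
            return g.haplotypes[k, 0, locus_mask].astype(float)
        d = g.dosage[k].astype(float) / 2.0
        d[g.dosage[k] < 0] = -1
        return d[locus_mask]

    reps: list[tuple[str, str, str]] = []  # (individual, species, morph)
    for sp in samples.species:
        morph_counts = (
            samples.table[samples.table["species"] == sp]["morph"].value_counts()
        )
        usable = [m for m, c in morph_counts.items() if c >= config.min_per_morph]
        if not usable:
            usable = [morph_counts.idxmax()]
        hets = set(het_individuals.get(sp, []))
        cand_reps = []
        for morph in sorted(usable):
            cands = sorted(samples.individuals(species=sp, morph=morph))
            nonhet = [c for c in cands if c not in hets]
            cand_reps.append(((nonhet or cands)[0], sp, morph))
        if len(cand_reps) > 2:
            # keep the deepest allele pair: the species' two most divergent
            # morph representatives at the locus
            rows = [_locus_row(r[0]) for r in cand_reps]
            best, pair = -1.0, (0, 1)
            for a in range(len(rows)):
                for b in range(a + 1, len(rows)):
                    ok = (rows[a] >= 0) & (rows[b] >= 0)
                    d = float(np.abs(rows[a] - rows[b])[ok].mean()) if ok.any() else 0.0
                    if d > best:
                        best, pair = d, (a, b)
            cand_reps = [cand_reps[pair[0]], cand_reps[pair[1]]]
        reps.extend(cand_reps)
    if len(reps) < 4:
        return None
    ids, sp_map, mo_map, rows_l, rows_g = [], {}, {}, [], []
    idx_of = {s: i for i, s in enumerate(g.ids)}
    for ind, sp, morph in reps:
        k = idx_of[ind]
        name = f"{ind}_rep"
        ids.append(name)
        sp_map[name], mo_map[name] = sp, morph
        if g.is_phased:
            rows_l.append(g.haplotypes[k, 0, locus_mask].astype(float))
            rows_g.append(g.haplotypes[k, 0, :].astype(float))
        else:
            d = g.dosage[k].astype(float) / 2.0
            d[g.dosage[k] < 0] = -1
            rows_l.append(d[locus_mask])
            rows_g.append(d)
    try:
        lt = trees.distance_tree(np.array(rows_l), ids, sp_map, mo_map)
        gt = trees.distance_tree(np.array(rows_g), ids, sp_map, mo_map)
    except ValueError:
        return None
    return lt, gt


def _morph_test_tree(g, samples, locus_mask, het_individuals, config, rng):
    """Locus tree of phenotype-informative haplotypes for the morph
    monophyly test: up to two called locus homozygotes per (species, morph),
    one haplotype each, so every morph's alleles are represented regardless
    of its homozygote frequency in the random tip sample."""
    idx_of = {s: i for i, s in enumerate(g.ids)}
    ids, sp_map, mo_map, rows = [], {}, {}, []
    for sp in samples.species:
        counts = (
            samples.table[samples.table["species"] == sp]["morph"].value_counts()
        )
        hets = set(het_individuals.get(sp, []))
        for morph in sorted(m for m, c in counts.items() if c >= config.min_per_morph):
            cands = sorted(samples.individuals(species=sp, morph=morph))
            pool = [c for c in cands if c not in hets] or cands
            k = min(2, len(pool))
            for ind in rng.choice(pool, k, replace=False):
                name = f"{ind}_m"
                ids.append(name)
                sp_map[name], mo_map[name] = sp, morph
                kx = idx_of[ind]
                if g.is_phased:
                    rows.append(g.haplotypes[kx, 0, locus_mask].astype(float))
                else:
                    d = g.dosage[kx].astype(float) / 2.0
                    d[g.dosage[kx] < 0] = -1
                    rows.append(d[locus_mask])
    if len(ids) < 4:
        return None
    try:
        return trees.distance_tree(np.array(rows), ids, sp_map, mo_map)
    except ValueError:
        return None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_bundle(summary: dict, config: RunConfig, g: GenotypeMatrix) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    payload = json.dumps(_jsonable(summary), indent=1, sort_keys=True)
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        fh.write(payload)
    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "config": _jsonable(cfg_dict),
        "config_sha256": hashlib.sha256(
            json.dumps(_jsonable(cfg_dict), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": _versions(),
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _versions() -> dict:
    import importlib.metadata as im

    out = {}
    for pkg in ("supergene", "numpy", "scipy", "pandas", "scikit-learn", "scikit-bio"):
        try:
            out[pkg] = im.version(pkg)
        except im.PackageNotFoundError:  # pragma: no cover
            out[pkg] = "unknown"
    return out
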