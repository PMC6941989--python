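"""Forward-time Wright-Fisher simulation of multiple diverging species that
carry a mimicry supergene under negative frequency-dependent selection
(NFDS), with presets generating data under the four classical hypotheses for
a shared mimicry locus: introgression, incomplete lineage sorting (ILS),
allelic turnover, and independent origin.

Model summary
-------------
Each species is a Wright-Fisher population of ``N`` diploids over a fixed
lattice of candidate SNP sites on one chromosome.  A designated locus
interval hosts discrete mimicry *allele classes*; an individual's expressed
morph is a deterministic function of its two classes and a dominance rule
(by default the more recently derived class is dominant, as is typical for
mimicry supergene alleles).  Fitness is ``w = 1 - s * f`` where ``f`` is the
current within-species frequency of the individual's expressed morph, so
``s = 0`` recovers neutrality and ``s > 0`` is NFDS.  Offspring parents are
sampled by fitness-weighted multinomial draws; gametes recombine with a
Poisson number of crossovers, gene-conversion tracts copy the homolog over
geometric-length tracts, and neutral mutations flip single sites.
Crossovers falling inside the locus of a class heterokaryotype are
suppressed (the recombination-suppression that defines a supergene), while
gene conversion is not — conversion is the force that erodes trans-species
variation between supergene alleles.

At a species split the population is copied instantaneously into the
daughter populations.  Migration replaces a binomial number of recipient
haplotypes with random donor haplotypes during a configured generation
interval.  New allele classes arise by per-haplotype innovation events
(rate ``mu_allele``) carrying a few class-defining locus mutations, or by
scripted ``forced_innovations`` used by the scenario presets.

The ancestral population is initialised at neutral mutation-drift
equilibrium by drawing each site's allele count from the stationary 1/i
frequency spectrum, so short forward runs start from (approximately)
stationary neutral diversity.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .variants import GenotypeMatrix, SampleTable, write_sample_table, write_vcf

PRESETS = ("neutral", "introgression", "ils", "turnover", "independent")


class SimulationError(RuntimeError):
    """Raised for inviable simulation states (e.g. zero-fitness populations)."""


@dataclass
class SimConfig:
    """Parameters for one forward simulation.

    Rates are per generation: ``mu_neutral`` per site per haplotype,
    ``mu_allele`` per haplotype, ``crossover_rate``/``gc_rate`` expected
    events per transmitted gamete, ``gc_tract_mean`` mean conversion-tract
    length in bp.  ``species_tree`` is an ultrametric newick string with
    branch lengths in generations.  ``locus_interval`` is the [start, end)
    site-index interval hosting the mimicry locus; the preset constructors
    lay out the genome (``n_sites`` candidate sites over ``genome_length``
    bp, with ``locus_n_sites`` of them packed into ``locus_region_bp``) and
    derive it.
    """

    n_diploids_per_species: int = 100
    species_tree: str = "((A:90,B:90):150,(C:160,D:160):80);"
    n_sites: int = 3600
    genome_length: int = 2_400_000
    locus_region_bp: tuple[int, int] = (1_200_001, 1_260_000)
    locus_n_sites: int = 300
    mu_neutral: float = 5e-5
    mu_allele: float = 0.0
    s: float = 0.0
    crossover_rate: float = 1.0
    gc_rate: float = 0.3
    gc_tract_mean: float = 500.0
    migration: list = field(default_factory=list)  # (donor, recipient, rate, (g0, g1))
    dominance: str = "derived_dominant"  # or "ancestral_dominant"
    seed: int = 0
    scenario_preset: str | None = None
    # generator structure
    ancestral_generations: int = 40
    n_ancestral_classes: int = 1
    ancestral_marker_sites: int = 0
    innovation_marker_sites: int = 0
    innovation_in_leaves_only: bool = False
    innovation_start_generation: int = 0
    forced_innovations: list = field(default_factory=list)  # (gen, pop, freq, n_markers)
    suppress_locus_recombination: bool = True
    log_interval: int = 20
    chrom: str = "chr1"

    def validate(self) -> None:
        for name in ("mu_neutral", "mu_allele"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if not 0 <= self.s <= 1:
            raise ValueError("s must be in [0, 1]")
        for name in ("crossover_rate", "gc_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gc_tract_mean < 1:
            raise ValueError("gc_tract_mean must be >= 1")
        if self.n_diploids_per_species < 2:
            raise ValueError("need >= 2 diploids per species")
        lo, hi = self.locus_region_bp
        if not (1 <= lo <= hi <= self.genome_length):
            raise ValueError("locus_region_bp outside genome")
        if not 0 < self.locus_n_sites <= self.n_sites:
            raise ValueError("locus_n_sites outside [1, n_sites]")
        for d, r, m, (g0, g1) in self.migration:
            if not 0 <= m <= 1:
                raise ValueError("migration rate must be in [0, 1]")
            if g1 < g0:
                raise ValueError("migration interval reversed")
        if self.dominance not in ("derived_dominant", "ancestral_dominant"):
            raise ValueError("dominance must be derived_dominant or ancestral_dominant")


@dataclass
class SimResult:
    """Simulation output: phased genotypes at segregating sites, sample
    table, the truth record, and per-epoch allele-class frequency logs."""

    genotypes: GenotypeMatrix
    samples: SampleTable
    true_scenario: str
    true_allele_class: np.ndarray  # (n_individuals, 2) class ids per haplotype
    generation_log: list
    locus_region: tuple[str, int, int]
    n_allele_classes_created: int
    config: SimConfig

    @property
    def locus_site_mask(self) -> np.ndarray:
        c, lo, hi = self.locus_region
        return self.genotypes.site_mask_region(c, lo, hi)


# ---------------------------------------------------------------------------
# Genome layout & species tree


@dataclass
class _Layout:
    pos: np.ndarray  # 1-based bp positions, strictly increasing
    locus_start: int  # site-index interval [start, end)
    locus_end: int
    locus_mid: int


def genome_layout(cfg: SimConfig) -> _Layout:
    """Deterministic candidate-site positions: background sites evenly spaced
    outside the locus region, ``locus_n_sites`` evenly spaced inside it."""
    lo, hi = cfg.locus_region_bp
    n_back = cfg.n_sites - cfg.locus_n_sites
    left_len = lo - 1
    right_len = cfg.genome_length - hi
    n_left = int(round(n_back * left_len / (left_len + right_len))) if n_back else 0
    n_right = n_back - n_left
    parts = []
    if n_left:
        parts.append(np.linspace(1, lo - 1, n_left))
    parts.append(np.linspace(lo, hi, cfg.locus_n_sites))
    if n_right:
        parts.append(np.linspace(hi + 1, cfg.genome_length, n_right))
    pos = np.unique(np.round(np.concatenate(parts)).astype(np.int64))
    if pos.size != cfg.n_sites:  # collisions from rounding: respace minimally
        pos = np.unique(
            np.round(np.linspace(1, cfg.genome_length, cfg.n_sites)).astype(np.int64)
        )
    start = int(np.searchsorted(pos, lo, side="left"))
    end = int(np.searchsorted(pos, hi, side="right"))
    return _Layout(pos=pos, locus_start=start, locus_end=end, locus_mid=(start + end) // 2)


@dataclass
class _Schedule:
    total_generations: int
    root_name: str
    leaves: list[str]
    splits: dict[int, list[tuple[str, list[str]]]]  # gen -> [(pop, children)]


def parse_species_tree(cfg: SimConfig) -> _Schedule:
    tree = TreeNode.read(io.StringIO(cfg.species_tree), format="newick")
    if not tree.children:  # single-population tree, e.g. "A;"
        name = tree.name or "A"
        return _Schedule(
            total_generations=cfg.ancestral_generations,
            root_name=name,
            leaves=[name],
            splits={},
        )
    tips = list(tree.tips())

    def name_of(node) -> str:
        if node.is_tip():
            return node.name
        return "+".join(sorted(t.name for t in node.tips()))

    def age_of(node) -> float:
        if node.is_tip():
            return 0.0
        ages = {
            node.distance(t) for t in node.tips()
        }
        if max(ages) - min(ages) > 1e-6:
            raise ValueError("species tree must be ultrametric in generations")
        return float(max(ages))

    root_age = age_of(tree)
    total = cfg.ancestral_generations + int(round(root_age))
    splits: dict[int, list] = {}
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            continue
        gen = total - int(round(age_of(node)))
        if gen < 0:
            raise ValueError("negative split time; increase ancestral_generations")
        splits.setdefault(gen, []).append(
            (name_of(node), [name_of(ch) for ch in node.children])
        )
    return _Schedule(
        total_generations=total,
        root_name=name_of(tree),
        leaves=sorted(t.name for t in tips),
        splits=splits,
    )


# ---------------------------------------------------------------------------
# Core update


def _phenotypes(classes: np.ndarray, dominance: str) -> np.ndarray:
    """Expressed morph per individual from its two allele classes: the
    dominance rule picks which class a heterozygote expresses."""
    c = classes.reshape(-1, 2)
    if dominance == "derived_dominant":
        return c.max(axis=1)
    return c.min(axis=1)


class _SimState:
    def __init__(self, cfg: SimConfig, layout: _Layout):
        self.cfg = cfg
        self.layout = layout
        self.next_class_id = cfg.n_ancestral_classes
        self.n_innovations = 0

    def new_class(self) -> int:
        self.next_class_id += 1
        self.n_innovations += 1
        return self.next_class_id - 1


def _init_ancestral(rng, cfg: SimConfig, layout: _Layout):
    two_n = 2 * cfg.n_diploids_per_species
    S = cfg.n_sites
    haps = np.zeros((two_n, S), dtype=np.int8)
    theta = 4 * cfg.n_diploids_per_species * cfg.mu_neutral
    i = np.arange(1, two_n)
    harm = np.cumsum(1.0 / i)
    p_seg = min(1.0, theta * harm[-1])
    seg = np.nonzero(rng.random(S) < p_seg)[0]
    cdf = harm / harm[-1]
    counts = 1 + np.searchsorted(cdf, rng.random(seg.size), side="left")
    for site, k in zip(seg, counts):
        rows = rng.choice(two_n, size=min(int(k), two_n - 1), replace=False)
        haps[rows, site] = 1

    classes = np.zeros(two_n, dtype=np.int32)
    K = cfg.n_ancestral_classes
    if K > 1:
        classes = rng.permutation(np.arange(two_n) % K).astype(np.int32)
        if cfg.ancestral_marker_sites:
            locus_cols = np.arange(layout.locus_start, layout.locus_end)
            need = cfg.ancestral_marker_sites * (K - 1)
            marker_cols = rng.choice(locus_cols, size=min(need, locus_cols.size), replace=False)
            per = np.array_split(marker_cols, K - 1)
            for k in range(1, K):
                cols = per[k - 1]
                haps[:, cols] = 0
                haps[np.ix_(classes == k, cols)] = 1
    return haps, classes


def _evolve_one_generation(rng, haps, classes, cfg, layout, state, allow_innovation):
    two_n, S = haps.shape
    N = two_n // 2
    ph = _phenotypes(classes, cfg.dominance)
    uniq, inv, cnt = np.unique(ph, return_inverse=True, return_counts=True)
    w = 1.0 - cfg.s * (cnt / N)[inv]
    w = np.clip(w, 0.0, None)
    if not np.any(w > 0):
        raise SimulationError("population extinct: all individuals have zero fitness")
    parents = rng.choice(N, size=two_n, p=w / w.sum())
    which = rng.integers(0, 2, size=two_n)
    idx_a = 2 * parents + which
    idx_b = 2 * parents + 1 - which
    child = haps[idx_a].copy()
    child_classes = classes[idx_a].copy()

    ev_rows, ev_cols = [], []
    n_x = rng.poisson(cfg.crossover_rate, two_n)
    xr = np.repeat(np.arange(two_n), n_x)
    if xr.size:
        bp = rng.integers(1, cfg.genome_length + 1, size=xr.size)
        col = np.searchsorted(layout.pos, bp, side="right")
        if cfg.suppress_locus_recombination:
            in_locus = (col > layout.locus_start) & (col < layout.locus_end)
            hetero = classes[idx_a[xr]] != classes[idx_b[xr]]
            keep = ~(in_locus & hetero)
            xr, col = xr[keep], col[keep]
        ev_rows.append(xr)
        ev_cols.append(col)
    n_g = rng.poisson(cfg.gc_rate, two_n)
    gr = np.repeat(np.arange(two_n), n_g)
    if gr.size:
        start_bp = rng.integers(1, cfg.genome_length + 1, size=gr.size)
        length = rng.geometric(1.0 / cfg.gc_tract_mean, size=gr.size)
        c0 = np.searchsorted(layout.pos, start_bp, side="left")
        c1 = np.searchsorted(layout.pos, start_bp + length, side="left")
        covers = c1 > c0
        gr, c0, c1 = gr[covers], c0[covers], c1[covers]
        ev_rows += [gr, gr]
        ev_cols += [c0, c1]

    if ev_rows and sum(a.size for a in ev_rows):
        er = np.concatenate(ev_rows)
        ec = np.concatenate(ev_cols)
        sub = np.unique(er)
        remap = np.zeros(two_n, dtype=np.intp)
        remap[sub] = np.arange(sub.size)
        par = np.zeros((sub.size, S + 1), dtype=np.int16)
        np.add.at(par, (remap[er], ec), 1)
        parity = np.logical_xor.accumulate((par & 1).astype(bool), axis=1)[:, :S]
        other = haps[idx_b[sub]]
        block = child[sub]
        block[parity] = other[parity]
        child[sub] = block
        flip_mid = parity[:, layout.locus_mid]
        rows_mid = sub[flip_mid]
        child_classes[rows_mid] = classes[idx_b[rows_mid]]

    n_mut = rng.poisson(cfg.mu_neutral * two_n * S)
    if n_mut:
        r = rng.integers(0, two_n, n_mut)
        c = rng.integers(0, S, n_mut)
        child[r, c] ^= 1

    if allow_innovation and cfg.mu_allele > 0:
        innovators = np.nonzero(rng.random(two_n) < cfg.mu_allele)[0]
        for i in innovators:
            child_classes[i] = state.new_class()
            if cfg.innovation_marker_sites:
                cols = rng.choice(
                    np.arange(layout.locus_start, layout.locus_end),
                    size=cfg.innovation_marker_sites,
                    replace=False,
                )
                child[i, cols] ^= 1
    return child, child_classes


def _apply_forced_innovation(rng, haps, classes, cfg, layout, state, freq, n_markers):
    two_n = haps.shape[0]
    k = max(1, int(round(freq * two_n)))
    source = int(rng.integers(0, two_n))
    targets = rng.choice(two_n, size=k, replace=False)
    new_id = state.new_class()
    haps[targets] = haps[source]
    classes[targets] = new_id
    if n_markers:
        cols = rng.choice(
            np.arange(layout.locus_start, layout.locus_end), size=n_markers, replace=False
        )
        block = haps[targets]
        block[:, cols] = 1 - haps[source, cols]
        haps[targets] = block


# ---------------------------------------------------------------------------
# Driver


def simulate(config: SimConfig) -> SimResult:
    """Run the forward simulation described by ``config``.

    Identical configs (including seed) give identical outputs end to end:
    every stochastic draw is routed through one ``numpy`` Generator.
    """
    config.validate()
    layout = genome_layout(config)
    sched = parse_species_tree(config)
    rng = np.random.default_rng(config.seed)
    state = _SimState(config, layout)

    haps, classes = _init_ancestral(rng, config, layout)
    pops: dict[str, tuple[np.ndarray, np.ndarray]] = {sched.root_name: (haps, classes)}
    forced = sorted(config.forced_innovations, key=lambda t: t[0])
    genlog: list = []

    for gen in range(sched.total_generations):
        for pop_name, children in sched.splits.get(gen, []):
            h, c = pops.pop(pop_name)
            for i, ch_name in enumerate(children):
                pops[ch_name] = (h if i == len(children) - 1 else h.copy(),
                                 c if i == len(children) - 1 else c.copy())
        for g_f, pop_name, freq, n_markers in forced:
            if g_f == gen:
                if pop_name not in pops:
                    raise ValueError(f"forced innovation in inactive population {pop_name}")
                h, c = pops[pop_name]
                _apply_forced_innovation(rng, h, c, config, layout, state, freq, n_markers)
        for donor, recip, rate, (g0, g1) in config.migration:
            if g0 <= gen < g1 and donor in pops and recip in pops:
                hd, cd = pops[donor]
                hr, cr = pops[recip]
                n_mig = rng.binomial(hr.shape[0], rate)
                if n_mig:
                    slots = rng.choice(hr.shape[0], size=n_mig, replace=False)
                    src = rng.integers(0, hd.shape[0], size=n_mig)
                    hr[slots] = hd[src]
                    cr[slots] = cd[src]
        for name in list(pops):
            h, c = pops[name]
            allow = (not config.innovation_in_leaves_only or name in sched.leaves) and (
                gen >= config.innovation_start_generation
            )
            pops[name] = _evolve_one_generation(rng, h, c, config, layout, state, allow)
        if config.log_interval and gen % config.log_interval == 0:
            entry = {"generation": gen}
            for name, (h, c) in pops.items():
                uniq, cnt = np.unique(c, return_counts=True)
                entry[name] = {int(u): float(k / c.size) for u, k in zip(uniq, cnt)}
            genlog.append(entry)

    return _package_result(config, layout, sched, pops, genlog, state)


def _package_result(cfg, layout, sched, pops, genlog, state) -> SimResult:
    N = cfg.n_diploids_per_species
    leaves = [name for name in sched.leaves if name in pops] or list(pops)
    ids, species_col, hap_blocks, class_rows = [], [], [], []
    for sp in leaves:
        h, c = pops[sp]
        hap_blocks.append(h.reshape(N, 2, cfg.n_sites))
        class_rows.append(c.reshape(N, 2))
        ids.extend(f"{sp}_{i:03d}" for i in range(N))
        species_col.extend([sp] * N)
    H = np.concatenate(hap_blocks, axis=0)
    C = np.concatenate(class_rows, axis=0)

    tot = H.sum(axis=(0, 1))
    n_haps = H.shape[0] * 2
    seg = (tot > 0) & (tot < n_haps)
    H = H[:, :, seg]
    pos = layout.pos[seg]
    n_sites = int(seg.sum())

    g = GenotypeMatrix(
        ids=ids,
        chrom=np.array([cfg.chrom] * n_sites, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosage=H.sum(axis=1, dtype=np.int8),
        haplotypes=H,
    )
    morph = [f"m{p}" for p in _phenotypes(C.reshape(-1), cfg.dominance)]
    samples = SampleTable.from_records(
        {"sample": i, "species": s, "morph": m}
        for i, s, m in zip(ids, species_col, morph)
    )
    lo, hi = cfg.locus_region_bp
    return SimResult(
        genotypes=g,
        samples=samples,
        true_scenario=cfg.scenario_preset or "custom",
        true_allele_class=C,
        generation_log=genlog,
        locus_region=(cfg.chrom, lo, hi),
        n_allele_classes_created=cfg.n_ancestral_classes + state.n_innovations,
        config=cfg,
    )


def write_outputs(result: SimResult, out_prefix) -> dict[str, str]:
    """Write <prefix>.vcf (phased GT), <prefix>.samples.tsv and
    <prefix>.truth.json; returns the paths written."""
    prefix = str(out_prefix)
    paths = {
        "vcf": prefix + ".vcf",
        "samples": prefix + ".samples.tsv",
        "truth": prefix + ".truth.json",
    }
    write_vcf(result.genotypes, paths["vcf"])
    write_sample_table(result.samples, paths["samples"])
    truth = {
        "scenario": result.true_scenario,
        "locus_region": list(result.locus_region),
        "n_allele_classes_created": result.n_allele_classes_created,
        "allele_classes": {
            ind: [int(a), int(b)]
            for ind, (a, b) in zip(result.genotypes.ids, result.true_allele_class)
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Scenario presets


def scenario_preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """A fully-populated :class:`SimConfig` for one of the four supergene
    evolution scenarios, or the neutral control, on the default 4-species
    tree ((A,B),(C,D)) with staggered splits (A-B 90, C-D 160, root 240
    generations before sampling).

    * ``neutral``: s = 0 control; the locus is a single ordinary 10 kb
      window, statistically exchangeable with any background window.
    * ``ils``: a deeply diverged ancestral balanced polymorphism (two marked
      allele classes) retained by NFDS in all four descendants.
    * ``turnover``: the ILS start plus ongoing allele-class innovation, so
      extant classes are young, species-private descendants of the
      ancestral alleles.
    * ``independent``: no ancestral polymorphism; each species gains its own
      mimicry allele after its origin.
    * ``introgression``: the mimicry allele arises in species A after the
      A-B split and crosses into B by a brief pulse of migration.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    base: dict = dict(seed=seed, scenario_preset=name)
    # The four scenario presets share a deeper tree (splits at 240 / 400 /
    # 560 generations before sampling, total 600 generations) so that
    # species-level divergence dominates coalescent noise at the locus.
    deep_tree = "((A:240,B:240):320,(C:400,D:400):160);"
    if name == "neutral":
        base.update(
            n_diploids_per_species=200,
            s=0.0,
            n_ancestral_classes=2,
            locus_region_bp=(1_200_001, 1_210_000),
            locus_n_sites=15,
            suppress_locus_recombination=False,
        )
    elif name == "ils":
        base.update(
            species_tree=deep_tree,
            s=0.4,
            n_ancestral_classes=2,
            ancestral_marker_sites=25,
        )
    elif name == "turnover":
        base.update(
            species_tree=deep_tree,
            s=0.4,
            n_ancestral_classes=2,
            ancestral_marker_sites=16,
            mu_allele=1e-3,
            innovation_marker_sites=3,
            gc_rate=2.0,
        )
    elif name == "independent":
        base.update(
            species_tree=deep_tree,
            s=0.4,
            n_ancestral_classes=1,
            forced_innovations=[
                (420, "A", 0.08, 3),
                (420, "B", 0.08, 3),
                (420, "C", 0.08, 3),
                (420, "D", 0.08, 3),
            ],
        )
    elif name == "introgression":
        base.update(
            species_tree=deep_tree,
            s=0.4,
            n_ancestral_classes=1,
            forced_innovations=[(450, "A", 0.08, 8)],
            migration=[("A", "B", 0.01, (460, 475))],
        )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# Constructed conversion panels (for tract-detection validation)


def simulate_conversion_panel(
    seed: int,
    n_per_class: int = 5,
    n_columns: int = 90,
    class_divergence: float = 0.7,
    within_noise: float = 0.02,
    tract_columns: int = 24,
    region_bp: tuple[int, int] = (1_000_001, 1_090_000),
):
    """Two diverged supergene haplotype classes with one planted conversion
    event: a single recipient haplotype of class B carries class-A sequence
    over a contiguous tract of ``tract_columns`` class-diagnostic columns.

    Returns ``(haplotypes, positions, class_labels, hap_ids, truth)`` where
    ``truth`` is the (start, end) inclusive column span of the planted tract
    in alignment coordinates.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    diag = rng.random(n_columns) < class_divergence  # columns where classes differ
    consA = np.zeros(n_columns, dtype=np.int8)
    consB = diag.astype(np.int8)
    haps = np.empty((n, n_columns), dtype=np.int8)
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    for i in range(n):
        base = consA if labels[i] == "A" else consB
        noise = rng.random(n_columns) < within_noise
        haps[i] = base ^ noise.astype(np.int8)
    # plant the tract on the first B haplotype: a run of tract_columns
    # diagnostic columns copied from class A
    diag_cols = np.nonzero(diag)[0]
    if diag_cols.size < tract_columns:
        raise ValueError("not enough diagnostic columns for requested tract")
    first = int(rng.integers(0, diag_cols.size - tract_columns + 1))
    c_start = int(diag_cols[first])
    c_end = int(diag_cols[first + tract_columns - 1])
    recipient = n_per_class  # first B haplotype
    haps[recipient, c_start : c_end + 1] = consA[c_start : c_end + 1]
    positions = np.linspace(region_bp[0], region_bp[1], n_columns).astype(np.int64)
    hap_ids = [f"{lab}{i % n_per_class}" for i, lab in enumerate(labels)]
    return haps, positions, labels, hap_ids, (c_start, c_end)
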