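# Methods

`supergene` implements, as one validated chain, the comparative
population-genetic analysis used to ask whether several related species
share a mimicry supergene and, if so, by what history: introgressive
hybridization, retention of an ancestral balanced polymorphism (incomplete
lineage sorting, ILS), allelic turnover under multiallelic balancing
selection, or independent co-option of the same locus.  Because the real
study system (female-polymorphic *Papilio* swallowtails and the autosomal
locus *doublesex*) requires ~10^2 whole-genome resequencing datasets, the
package pairs every estimator with a forward simulator that generates data
under each hypothesis at desk scale, so the whole chain is validated by
parameter and scenario recovery rather than by re-analysis of the original
data.

## Statistics

**Windowed F_ST.** Weir & Cockerham's (1984) two-population
variance-components estimator, computed per biallelic site
(components `a`, `b`, `c`) and combined per window as the ratio of sums
`sum(a) / sum(a+b+c)` — the "weighted" convention of VCFtools' windowed
output.  Sites monomorphic across the pooled sample contribute nothing;
windows with no usable site are flagged undefined and excluded, never
scored 0.  Negative window values are reported as computed, since
downstream use is percentile ranking, not effect-size interpretation.
Missing genotypes are excluded site-wise, never imputed.

**Windowed Tajima's D.** The standard normalisation
`D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1))` with constants from direct
summation, `pi` from allele counts with the unbiased `n/(n-1)` correction
(phase-free).  Sites with any missing call among the chosen individuals are
excluded from the window so that a single haplotype count `n` applies.
Windows with `S = 0` are undefined and excluded from the genome
distribution.

**Windows.** Non-overlapping 10 kb tiles anchored at position 1 of each
chromosome (the anchoring convention is a declared choice).  Before
percentile analysis, windows in the bottom decile of the per-window variant
count are removed: the cutoff is the linear-interpolated quantile and ties
at the cutoff are all removed (an all-tied distribution removes everything,
with a warning).

**Percentile enrichment.** The rank of the maximum focal-window value among
all other defined windows, using a strictly-below rule; focal windows are
excluded from the background distribution.  Under neutrality a
single-window focal region is then exactly uniform, which is what the
calibration test checks.

**Linkage disequilibrium.** For a site pair, haplotype frequencies come
from phased data directly or from the standard two-locus EM over
double-heterozygote ambiguity; `D' = D / D_max` with the usual sign-dependent
`D_max`, `r2 = D^2 / (pA pa pB pb)`, and LOD is the base-10 multinomial
likelihood ratio of the fitted haplotype frequencies against linkage
equilibrium — the statistic behind the classic heat-map colour scheme
(white: D' < 1, LOD < 2; blue: D' = 1, LOD < 2; pink/red: LOD >= 2; D'
compared to 1 at tolerance 1e-9).  Site thinning to a target count is a
seeded uniform subsample.  For phased input the all-pairs matrix is
computed from haplotype count matrices; this path is tested to equal the
per-pair computation exactly.

**Association.** A per-site allelic contingency test (chi-square on the
2 x K allele-count table; Fisher's exact test when a 2 x 2 table has any
observed or expected cell below 5) with Benjamini-Hochberg q-values over
all tested sites.  A linear mixed model is deliberately not used:
population structure is instead exposed through the genome-wide versus
locus-restricted PCA contrast, which is also how supergene heterozygotes
are identified (1-D k-means, k = 3, on locus PC1; the middle class is
heterozygous).  For the trans-species comparison, a site is scored
"associated" when q < 0.05 and the largest between-morph allele-frequency
difference is at least 0.5.  The 0.5 default replaces a manual scoring
step with a reproducible rule; it is set below the often-suggested 0.8
because with a fully dominant allele at balanced frequency the expected
morph contrast of a perfectly linked variant is only about 2/3 —
a 0.8 cutoff would score zero sites by construction — while neutral sites
at these sample sizes scatter well below 0.5.  Both thresholds are
configurable.

**Shared-SNP report.** Associated sites are intersected across species by
exact reference position (optionally position + allele), and the Spearman
correlation between pairwise shared counts and phylogenetic proximity
(negative genome-tree distance) quantifies whether sharing tracks
relatedness — the signature separating retained ancestral variation from
recurrent origin.

**Conversion tracts.** Between-class haplotype pairs are scanned over the
alignment's polymorphic columns with score +1 per match and
-penalty per mismatch (default penalty `m/(1-m)` for pair mismatch
fraction `m`, making a random column score zero in expectation); the
maximal segment is found by a linear max-subarray scan, significance by
permutation of column order (default 10,000 permutations, add-one
estimator), Bonferroni-corrected across pairs, alpha 0.05.  A silent-site
mask can exclude annotated exon intervals.  This is the inner-fragment
spirit of Sawyer's test; the exact scoring constants of the original
software are not reproduced.

**Genealogies.** Neighbour-joining on normalised Hamming (p-) distances
over non-missing shared sites, with deterministic tie-breaking by sorted
tip label and negative NJ branch lengths clamped to zero.  Distance trees
stand in for likelihood trees because every signature used downstream
(clustering mode, nesting, branch-length contrast) is distance-visible.

## The scenario discriminator

Evidence is assembled from four sources: the locus genealogy's clustering
mode, the elongation of the locus genealogy relative to the genome
genealogy, the per-species locus Tajima's D percentile, and the
shared-SNP-versus-proximity correlation.

**Clustering mode** is decided on unrooted bipartitions, so it is invariant
to rooting.  The phenotype test runs first: if every morph class is
monophyletic and morph classes genuinely span species (at least two morph
groups — and at least half of them — contain tips of two or more species,
so one shared background class plus species-private alleles does not
qualify), the locus clusters `by_phenotype` — the allele-sharing
signature.  Haplotypes of called locus
heterozygotes are excluded from this test only, because an individual's
morph does not identify which allele each of its haplotypes carries;
species labels are valid for every tip, so the species test uses all tips.
The morph test runs on a dedicated tree of called locus homozygotes (two
per species x morph) when the pipeline can build one: with a dominant
allele at balanced frequency, homozygous carriers are only ~6-9% of
individuals, so a random tip sample often contains none and the phenotype
test would silently lose its informative tips.

Otherwise each species is tested for monophyly with three desk-scale
allowances: (i) a stray-tip tolerance (default 0.25: a bipartition side
covering at least 75% of the species with at most 25% foreign tips
suffices), absorbing the lineage-sorting noise that finite-sample NJ trees
carry when species splits are of the same order as the coalescent
timescale; (ii) a retention exception — a species whose haplotypes are
interrupted by tips of at most two other species, jointly monophyletic
with them (and jointly a proper subset of the tree), passes with the
nesting events recorded (the analogue of one species' haplotypes
appearing inside another's at young timescales); and (iii) a
retained-lineage rescue — if removing at most two disjoint small
cross-species clades (each at most 20% of tips, together at most 35%)
restores species monophyly everywhere, the mode is `by_species` with the
retained clades recorded.  The removed clades are exactly the
trans-species polymorphism a turnover history predicts at young
timescales.  A species interleaved with most of the tree never passes,
and ILS-like clustering cannot slip through the rescue because its
cross-species allele clades each hold about half of the tree.

**Elongation** is the ratio of (mean terminal branch / total tree length)
between the locus and genome trees, computed on allele-representative
trees: one haplotype per species x morph, taken from a called locus
homozygote, reduced to the species' two most divergent representatives
when there are more than two morphs.  With one tip per allele, the
within-species allelic divergence maintained by balancing selection loads
onto terminal branches — the predicted elongation — whereas on dense
per-haplotype trees the same divergence loads onto internal branches and
the ratio is uninformative.  The deepest-pair reduction matters under
turnover, where sibling classes are near-identical and would otherwise
produce zero-length terminals.

**Decision rule.**  `by_phenotype` clustering splits on the depth of the
between-phenotype locus divergence (net of within-class diversity, i.e.
d_a) against the species-split depth (maximum net between-species
genome divergence): shallow means the shared allele is younger than the
species — introgression; deep means it predates them — ILS.
`by_species` clustering splits turnover from independent origin by a
weighted vote over three balancing-selection signatures: genealogy
elongation > r* (default 1.2), median per-species locus Tajima percentile
>= P* (default 90), and trans-species sharing.  The sharing vote requires
at least `min_shared_snps` (default 12) shared associated SNPs overall and
fires when sharing either tracks phylogenetic proximity (Spearman
rho > 0.3 over the species pairs) or is pervasive
(total >= `strong_shared_snps`, default 20): sustained turnover of an
ancestral polymorphism leaves shared associated SNPs in essentially every
species pair, independent origin in essentially none, while the rank
correlation over a handful of pairs is noisy at these replicate sizes.
The sharing signature carries double weight and is effectively required:
elongation and Tajima enrichment also arise under young, independently
evolved balanced polymorphisms, whereas substantial trans-species sharing
does not.
r* and P* are set so the neutral control rarely fires them (a neutral
locus percentile is uniform, so P* = 90 fires 10% of the time by
construction).  Contradictory evidence returns `mixed/uncertain` with the
full evidence vector; the label is never silently coerced.

## The simulator

Each species is a Wright-Fisher population of N diploids over a fixed
lattice of candidate SNP sites (default 3,600 sites on a 2.4 Mb
chromosome; enough for >= 200 10 kb windows).  The locus interval hosts
discrete allele classes; a dominance ranking (default: derived over
ancestral, the usual situation for mimicry supergene alleles) maps an
individual's two classes to its expressed morph, and fitness is
`w = 1 - s f(morph)` — negative frequency-dependent selection on the
expressed phenotype, the standard model for supergene balancing selection.
Gametes recombine (Poisson crossovers, default 1 per gamete per
generation), undergo gene conversion (geometric tracts, mean 500 bp, within
the 0.1-2 kb range typical of conversion events), and mutate (per-site
flips).  Crossovers inside the locus of a class heterokaryotype are
suppressed — the recombination suppression that defines a supergene —
while gene conversion is not, making conversion the force that erodes
trans-species variation between alleles.  Species splits copy the
population instantaneously; migration replaces a binomial number of
recipient haplotypes with donor haplotypes during a configured interval.
New allele classes arise by per-haplotype innovation carrying a few
class-defining regulatory mutations, or by scripted events the presets use
to place an allele's origin at a definite time and frequency.

The ancestral population is initialised at neutral equilibrium by drawing
each site's derived count from the stationary 1/i spectrum (segregating
with probability theta x a_{2N-1}), so short forward runs start from
approximately stationary diversity; the neutral-calibration test verifies
that windowed Tajima's D stays centred near zero downstream of this
choice.  Mutation and selection parameters are scaled up and population
sizes scaled down relative to nature, as is standard for forward
simulation at desk scale; all signatures used downstream depend on ratios
(split depth to coalescent time, allelic divergence to species divergence)
that the presets control directly.

### Scenario presets

All four scenario presets share a 4-species tree ((A,B),(C,D)) with splits
240 / 400 / 560 generations before sampling, N = 100 diploids per species,
mu = 5e-5 per site, and a 60 kb locus carrying 300 candidate sites; the
neutral control uses N = 200, a short tree (90 / 160 / 240), and a locus
that is a single ordinary 10 kb window, so its percentile rank has an
exactly uniform null.

* **ils** — two ancestral classes marked by 25 class-specific locus sites,
  maintained by NFDS (s = 0.4) in all four descendants.  Class divergence
  far exceeds species depth, so locus haplotypes cluster by phenotype with
  deep between-phenotype branches.
* **turnover** — two marked ancestral classes (16 sites) plus ongoing
  innovation (mu_allele = 1e-3 per haplotype, 3 class-defining sites per
  new allele) and elevated gene conversion.  Derived-dominant NFDS lets
  new alleles invade while older alleles, expressed only in homozygotes,
  drift out: extant classes are young, largely species-private descendants
  of the ancestral alleles.  Classes shared by close species pairs persist
  long enough to leave proximity-graded trans-species polymorphism.
* **independent** — no ancestral polymorphism; each species gains its own
  allele (3 marker sites, initial frequency 0.08) at a scripted time after
  its origin.  Balancing signatures appear, but sharing does not.
* **introgression** — one species evolves the allele after the youngest
  split; a brief migration pulse (0.5% per generation for 10 generations)
  carries it into the sister species, where NFDS establishes it.  The
  genome-wide migrant fraction stays small and decays by recombination,
  while the locus shows a young allele shared across the pair.

Preset parameters were chosen so that each preset robustly *generates its
defining regime* (allelic sorting completed or not, allele age relative to
split depth, presence of migration) — that is the generator's contract —
with rates inside biologically sensible scaled ranges.

### What the generator does and does not emulate

It emulates: multi-species diploid genotype matrices with a supergene
window under NFDS, neutral background variation at mutation-drift
equilibrium, staggered species-tree structure, recombination suppression
across the locus in heterokaryotypes, gene conversion, migration, and
allele-class innovation with dominance.  It does not emulate sequence-level
realism (codon structure, indels), sex linkage, inversion breakpoints,
population growth or bottlenecks, geographic structure within species, or
genotyping error and missingness (real-data paths for missing calls exist
and are unit-tested, but the simulator emits complete, phased calls).
Passing tests therefore demonstrate that the estimators and the decision
rule are correct and well-calibrated on data generated by this model —
not that the thresholds transfer unchanged to real resequencing data,
where sample sizes, divergence scales and ascertainment differ.

## Numerical choices and degenerate inputs

* Internal coordinates are 0-based half-open; all file interfaces (VCF,
  BED, window tables) are 1-based inclusive.
* VCF round-trips (write, then read with cyvcf2) are bit-exact on calls,
  positions and phase, and the file-input pipeline path is tested to equal
  the in-memory path end to end.
* Undefined statistics (zero usable sites, S = 0, monomorphic LD pairs,
  zero-variance PCA input) are flagged or raised explicitly, never coerced
  to 0.
* Identical tips give zero-length cherries; an all-identical alignment
  yields a flagged star-degenerate tree; NJ's occasional negative branch
  lengths are clamped to zero.
* Permutation p-values use the add-one estimator, so a reported p is never
  exactly 0 and corrected p >= raw p always holds.
* Every stochastic stage draws from a generator seeded by the master seed
  through a fixed counter; identical configuration gives byte-identical
  summary JSON.

## Problem sizes

Replicate counts used in the validation suite (100 neutral replicates for
calibration; 50 turnover and 25-per-scenario replicates for signature
generation and recovery; 50 planted conversion panels) were chosen as the
smallest sets at which the binomial uncertainty of the reported rates is
comfortably inside the margins being tested.  `scripts/acceptance.py`
recomputes the same quantities at reduced replicate counts (20 neutral, 15
turnover, 8 per scenario, 30 conversion panels), trading tighter rate
estimates for a quick single-command reproduction; its per-rate
uncertainty is correspondingly wider.

## Known limitations

* The discriminator's thresholds are calibrated against this generator's
  neutral control; real applications should recalibrate r* and P* with
  simulations matched to their own sample sizes and divergence scales.
* Desk-scale species splits are of the same order as the coalescent
  timescale, so locus genealogies carry substantial lineage-sorting noise;
  the monophyly tolerance absorbs it, at the cost of some sensitivity to
  genuinely marginal trans-species structure.
* The unphased LD path estimates haplotype frequencies by EM and is exact
  only in the no-double-heterozygote limit.
* `mixed/uncertain` is a first-class outcome: a fraction of scenario
  replicates is left uncalled rather than forced into a label, which is
  why the recovery criterion is a rate, not a guarantee.
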