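"""Genotype matrices, sample tables, genomic windows, and the filtering rules
applied before every downstream statistic.

The central container is :class:`GenotypeMatrix`: individuals x biallelic SNP
sites, stored as alternate-allele dosages (0/1/2, -1 for missing) with an
optional phased haplotype representation.  Internally coordinates are 0-based
half-open; every file interface (VCF, BED, window tables) uses the standard
1-based inclusive convention of those formats.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

LOCUS_GENOTYPE_CLASSES = ("hom_ref_morph", "het", "hom_alt_morph")


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-SNP matrix of alt-allele dosages.

    Parameters
    ----------
    ids:
        Individual identifiers, unique, one per matrix row.
    chrom, pos, ref, alt:
        Per-site arrays; ``pos`` is 1-based and strictly increasing within
        each chromosome.
    dosage:
        ``(n_individuals, n_sites)`` int8 array of alt-allele dosages in
        {0, 1, 2}, with ``-1`` for missing calls.
    haplotypes:
        Optional ``(n_individuals, 2, n_sites)`` int8 array of phased alleles
        in {0, 1} (``-1`` missing).  When present, dosage must equal the
        haplotype sum at every called site.
    """

    ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual ids must be unique")
        if self.dosage.shape != (len(self.ids), len(self.pos)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.pos)} sites"
            )
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            h = self.haplotypes
            if h.shape != (len(self.ids), 2, len(self.pos)):
                raise ValueError("haplotype array shape mismatch")
            called = (h >= 0).all(axis=1)
            s = h.sum(axis=1)
            if not np.array_equal(s[called], self.dosage[called]):
                raise ValueError("dosage does not equal haplotype sum where phased")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def individual_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown individual id {e.args[0]!r}") from None

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        return GenotypeMatrix(
            ids=list(self.ids),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=np.asarray(self.ref)[index],
            alt=np.asarray(self.alt)[index],
            dosage=self.dosage[:, index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, index],
        )

    def take_individuals(self, ids) -> "GenotypeMatrix":
        idx = self.individual_index(ids)
        return GenotypeMatrix(
            ids=[self.ids[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
        )

    def site_mask_region(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites in a 1-based inclusive [start, end] region."""
        return (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)

    def site_missingness(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        return (self.dosage == MISSING).mean(axis=0)

    def alt_counts(self, individual_index=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) over a subset."""
        d = self.dosage if individual_index is None else self.dosage[individual_index]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)


@dataclass(frozen=True)
class Window:
    """A genomic window with 1-based inclusive ends."""

    chrom: str
    start: int
    end: int
    n_variants: int = 0

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleTable:
    """Mapping of individuals to species and morph phenotype labels."""

    table: pd.DataFrame

    REQUIRED = ("sample", "species", "morph")

    def __post_init__(self) -> None:
        for c in self.REQUIRED:
            if c not in self.table.columns:
                raise ValueError(f"sample table missing column {c!r}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in sample table")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "SampleTable":
        return cls(pd.DataFrame(records, columns=list(cls.REQUIRED)))

    def species_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample"], self.table["species"]))

    def morph_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample"], self.table["morph"]))

    def individuals(self, species: str | None = None, morph: str | None = None) -> list[str]:
        t = self.table
        if species is not None:
            t = t[t["species"] == species]
        if morph is not None:
            t = t[t["morph"] == morph]
        return list(t["sample"])

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.table["species"]))

    def validate_against(self, g: GenotypeMatrix) -> None:
        missing = set(g.ids) - set(self.table["sample"])
        if missing:
            raise ValueError(f"{len(missing)} genotype-matrix individuals absent from sample table")


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path, region: tuple[str, int, int] | str | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCFv4.x file into a :class:`GenotypeMatrix`.

    Multiallelic records and indels are skipped (a count is logged).  If all
    genotypes in the file are phased the haplotype representation is kept.

    Parameters
    ----------
    region:
        Optional ``(chrom, start, end)`` 1-based inclusive interval or a
        ``"chrom:start-end"`` string; sites outside it are dropped.  An empty
        result is returned (not an error) when nothing overlaps.
    """
    from cyvcf2 import VCF

    if isinstance(region, str):
        c, span = region.split(":")
        s, e = span.split("-")
        region = (c, int(s), int(e))

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    dos_rows, hap_rows = [], []
    n_skipped = 0
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        if region is not None and not (
            v.CHROM == region[0] and region[1] <= v.POS <= region[2]
        ):
            continue
        gts = v.genotypes  # list of [allele0, allele1, phased]
        d = np.empty(len(ids), dtype=np.int8)
        h = np.empty((len(ids), 2), dtype=np.int8)
        for i, (a0, a1, *ph) in enumerate(gts):
            if a0 < 0 or a1 < 0:
                d[i] = MISSING
                h[i] = MISSING
            else:
                d[i] = a0 + a1
                h[i] = (a0, a1)
                if not (ph and ph[0]):
                    all_phased = False
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        dos_rows.append(d)
        hap_rows.append(h)
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/indel records", n_skipped)
    n_sites = len(poss)
    dosage = (
        np.stack(dos_rows, axis=1) if n_sites else np.zeros((len(ids), 0), dtype=np.int8)
    )
    haplotypes = None
    if all_phased:
        haplotypes = (
            np.stack(hap_rows, axis=2)
            if n_sites
            else np.zeros((len(ids), 2, 0), dtype=np.int8)
        )
    return GenotypeMatrix(
        ids=ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=dosage,
        haplotypes=haplotypes,
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as VCFv4.2 with GT-only FORMAT.

    Phased matrices are written with ``|`` separators, unphased with ``/``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=supergene\n")
        for c in dict.fromkeys(g.chrom):
            maxpos = int(g.pos[g.chrom == c].max()) if g.n_sites else 1
            fh.write(f"##contig=<ID={c},length={maxpos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.ids) + "\n")
        sep = "|" if g.is_phased else "/"
        for j in range(g.n_sites):
            fields = [
                str(g.chrom[j]),
                str(int(g.pos[j])),
                ".",
                str(g.ref[j]),
                str(g.alt[j]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            if g.is_phased:
                col = g.haplotypes[:, :, j]
                gts = [
                    ".|." if a0 < 0 else f"{a0}{sep}{a1}" for a0, a1 in col
                ]
            else:
                d = g.dosage[:, j]
                gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
                gts = ["./." if x < 0 else gt_of[int(x)] for x in d]
            fh.write("\t".join(fields) + "\t" + "\t".join(gts) + "\n")


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_table(samples: SampleTable, path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and windowing


def filter_site_missingness(g: GenotypeMatrix, max_missing_fraction: float) -> GenotypeMatrix:
    """Retain sites whose missing-call fraction is <= ``max_missing_fraction``."""
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    keep = g.site_missingness() <= max_missing_fraction
    return g.take_sites(keep)


def make_windows(g: GenotypeMatrix, size: int = 10_000) -> list[Window]:
    """Tile each chromosome with non-overlapping windows anchored at position 1.

    Windows run from the first tile through the tile containing the last site
    on each chromosome; ``n_variants`` counts matrix sites per window.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    out: list[Window] = []
    for c in dict.fromkeys(g.chrom):
        p = g.pos[g.chrom == c]
        if p.size == 0:
            continue
        n_tiles = int((p.max() - 1) // size) + 1
        counts = np.bincount((p - 1) // size, minlength=n_tiles)
        for t in range(n_tiles):
            out.append(Window(str(c), t * size + 1, (t + 1) * size, int(counts[t])))
    return out


def drop_sparse_windows(windows: list[Window], quantile: float = 0.10) -> list[Window]:
    """Remove windows whose variant count falls at or below a quantile cutoff.

    The cutoff is the linear-interpolated ``quantile`` of the per-window
    ``n_variants`` distribution; every window with count <= cutoff is removed
    (ties at the threshold all go).  Mirrors the bottom-10% rule used before
    interpreting windowed F_ST / Tajima's D distributions.
    """
    if not windows:
        raise ValueError("empty window list")
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    counts = np.array([w.n_variants for w in windows], dtype=float)
    cutoff = float(np.quantile(counts, quantile))
    kept = [w for w in windows if w.n_variants > cutoff]
    if not kept:
        warnings.warn(
            "drop_sparse_windows removed every window (tied variant counts)",
            stacklevel=2,
        )
    return kept


def windows_to_bed(windows: list[Window], path) -> None:
    """Export windows as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\t{w.n_variants}\n")
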