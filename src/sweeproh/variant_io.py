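"""VCF input/output and site filtering.

The central container is :class:`GenotypeMatrix`: biallelic SNP sites by
samples, with genotypes coded as hom-ref (0), het (1), hom-alt (2) or
missing (-1), held per chromosome as numpy arrays. Everything downstream
(the sweep scan and the ROH caller) operates on this matrix.

Site filtering mirrors the standard WGS post-calling step: a site is
dropped when its minor allele frequency, computed over non-missing
alleles, falls below ``maf_min`` (strictly less than), or when its
missing-call proportion exceeds ``max_missing`` (strictly greater than).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING: int = -1
"""Genotype code for a missing call."""


@dataclass
class ChromosomeSites:
    """SNP sites of one chromosome: positions (1-based, strictly increasing),
    alleles and the sites-by-samples genotype code array."""

    positions: np.ndarray          # int64, shape (S,)
    ref: np.ndarray                # str, shape (S,)
    alt: np.ndarray                # str, shape (S,)
    genotypes: np.ndarray          # int8, shape (S, N), values {0,1,2,-1}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.genotypes.shape[0] != self.positions.size:
            raise ValueError("genotypes and positions disagree on site count")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a fixed, ordered sample set.

    ``chroms`` preserves contig order; sample order is identical across
    chromosomes.
    """

    samples: list[str]
    chroms: dict[str, ChromosomeSites] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return sum(c.n_sites for c in self.chroms.values())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chroms={
                name: ChromosomeSites(
                    c.positions.copy(), c.ref.copy(), c.alt.copy(), c.genotypes.copy()
                )
                for name, c in self.chroms.items()
            },
            chrom_lengths=dict(self.chrom_lengths),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.samples != other.samples or set(self.chroms) != set(other.chroms):
            return False
        for name, c in self.chroms.items():
            o = other.chroms[name]
            if not (
                np.array_equal(c.positions, o.positions)
                and np.array_equal(c.genotypes, o.genotypes)
                and list(c.ref) == list(o.ref)
                and list(c.alt) == list(o.alt)
            ):
                return False
        return True


@dataclass(frozen=True)
class SiteFilterParams:
    """Thresholds for site-level filtering.

    ``maf_min`` removes sites with minor allele frequency strictly below the
    threshold; ``max_missing`` removes sites with missing proportion strictly
    above it (a 95% call-rate rule corresponds to ``max_missing=0.05``).
    """

    maf_min: float = 0.05
    max_missing: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")


def _normalize_chrom(name: str, strip_chr: bool) -> str:
    if strip_chr and name.lower().startswith("chr"):
        return name[3:]
    return name


def read_vcf(path: str, strip_chr_prefix: bool = False) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNP records (indels, MNPs) are skipped and
    counted in a log message. Contig order follows record order in the file.
    Contig lengths are taken from ``##contig`` header lines when present.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    per_chrom: dict[str, list] = {}
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        chrom = _normalize_chrom(v.CHROM, strip_chr_prefix)
        rec = per_chrom.setdefault(chrom, [[], [], [], []])
        rec[0].append(v.POS)
        rec[1].append(v.REF)
        rec[2].append(v.ALT[0])
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types, dtype=np.int8)
        codes = np.where(gt == 3, 2, np.where(gt == 2, MISSING, gt)).astype(np.int8)
        rec[3].append(codes)
    if skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", skipped)
    chroms = {}
    lengths = {}
    try:
        for name, ln in zip(vcf.seqnames, vcf.seqlens):
            lengths[_normalize_chrom(name, strip_chr_prefix)] = int(ln)
    except AttributeError:  # header without contig lengths
        pass
    for name, (pos, ref, alt, rows) in per_chrom.items():
        chroms[name] = ChromosomeSites(
            np.asarray(pos, dtype=np.int64),
            np.asarray(ref, dtype=object),
            np.asarray(alt, dtype=object),
            np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8),
        )
    lengths = {k: v for k, v in lengths.items() if k in chroms} or {
        k: int(c.positions[-1]) for k, c in chroms.items() if c.n_sites
    }
    return GenotypeMatrix(samples=samples, chroms=chroms, chrom_lengths=lengths)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write the matrix as a minimal VCF 4.2 (GT field only, one ALT per record).

    The writer is deterministic: identical matrices yield byte-identical files.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrix.chroms:
            length = matrix.chrom_lengths.get(chrom)
            if length is not None:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for chrom, c in matrix.chroms.items():
            for i in range(c.n_sites):
                gts = "\t".join(_GT_STRINGS[int(g)] for g in c.genotypes[i])
                fh.write(
                    f"{chrom}\t{int(c.positions[i])}\t.\t{c.ref[i]}\t{c.alt[i]}"
                    f"\t.\t.\t.\tGT\t{gts}\n"
                )


def site_maf(genotype_rows: np.ndarray) -> np.ndarray:
    """Minor allele frequency per site from coded genotypes, excluding
    missing alleles from the denominator. Sites with no calls get MAF 0."""
    g = np.asarray(genotype_rows)
    called = g != MISSING
    alt_alleles = np.where(called, g, 0).sum(axis=-1)
    total_alleles = 2 * called.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total_alleles > 0, alt_alleles / np.maximum(total_alleles, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def filter_sites(matrix: GenotypeMatrix, params: SiteFilterParams | None = None) -> GenotypeMatrix:
    """Apply MAF and missingness filters; order of retained sites is preserved.

    Idempotent: a second application removes nothing further.
    """
    params = params or SiteFilterParams()
    out_chroms: dict[str, ChromosomeSites] = {}
    n_in = n_out = 0
    for name, c in matrix.chroms.items():
        if c.n_sites == 0:
            out_chroms[name] = c
            continue
        maf = site_maf(c.genotypes)
        miss = (c.genotypes == MISSING).mean(axis=1)
        keep = (maf >= params.maf_min) & (miss <= params.max_missing)
        n_in += c.n_sites
        n_out += int(keep.sum())
        out_chroms[name] = ChromosomeSites(
            c.positions[keep], c.ref[keep], c.alt[keep], c.genotypes[keep]
        )
    if n_out == 0 and n_in > 0:
        logger.warning("filter_sites: all %d sites removed", n_in)
    else:
        logger.info("filter_sites: retained %d of %d sites", n_out, n_in)
    return GenotypeMatrix(
        samples=list(matrix.samples),
        chroms=out_chroms,
        chrom_lengths=dict(matrix.chrom_lengths),
    )
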