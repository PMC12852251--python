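"""Seed-controlled synthetic diploid genomes with planted selection signals.

The generator exists so that every downstream stage — the composite-µ sweep
scan, the windowed ROH caller, conserved-ROH incidence mapping and interval
annotation — can be verified against known ground truth without external
data.

Model
-----
Each chromosome carries a pool of ``P`` founder haplotypes. SNP positions
follow a Poisson process at ``snp_density`` per bp. Derived-allele counts
over the founder pool are drawn from the discretized neutral site-frequency
spectrum (probability of count ``i`` proportional to ``1/i``), so the folded
minor-allele spectrum of the background is approximately proportional to
``1/f``. Each individual's two haplotypes are founder mosaics: the copied
founder switches at Poisson breakpoints, giving background linkage
disequilibrium that decays with distance while keeping every allele drawn
from the founder pool.

Three local signals can be planted on top of the neutral background:

* sweeps (:func:`plant_sweep`) — diversity reduction by site thinning, an
  excess of singletons (site-frequency-spectrum skew), and flank-wise
  haplotype homogenization that maximizes within-flank r²;
* shared autozygosity (:func:`plant_autozygosity`) — a tract over which a
  chosen subset of carriers becomes fully homozygous, creating known
  per-SNP ROH incidence;
* missing genotype calls, i.i.d. per call, applied after planting so that
  planted tracts still exercise the ROH caller's missing-call tolerance.

Exported genotypes are diploid and unphased; haplotypes survive only inside
the in-memory :class:`TruthRecord`.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .variant_io import MISSING, ChromosomeSites, GenotypeMatrix, write_vcf

logger = logging.getLogger(__name__)

# fixed tags for per-chromosome random substreams
_STREAM_BACKGROUND = 0
_STREAM_SWEEP = 1
_STREAM_TRACT = 2
_STREAM_MISSING = 3


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep: position, footprint and signal strengths.

    ``diversity_reduction`` is the fraction of footprint SNPs *retained*
    (1.0 leaves diversity untouched); ``sfs_skew`` is the fraction of
    surviving footprint SNPs rewritten to minor-allele-count 1; ``ld_block``
    replaces each flank's haplotypes with at most two distinct patterns so
    within-flank pairwise r² is maximal.
    """

    chromosome: str
    center: int
    footprint: int                  # half-width in bp
    diversity_reduction: float = 0.2
    sfs_skew: float = 0.5
    ld_block: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.diversity_reduction <= 1.0:
            raise ValueError("diversity_reduction must be in (0, 1]")
        if not 0.0 <= self.sfs_skew <= 1.0:
            raise ValueError("sfs_skew must be in [0, 1]")
        if self.footprint <= 0:
            raise ValueError("footprint must be positive")


@dataclass(frozen=True)
class AutozygositySpec:
    """A shared autozygous tract carried by a subset of individuals."""

    chromosome: str
    start: int
    end: int
    carrier_individuals: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; see module docstring for the model."""

    seed: int = 0
    n_individuals: int = 20
    chromosomes: tuple[tuple[str, int], ...] = (("1", 1_000_000),)
    snp_density: float = 2e-3
    founder_haplotypes: int = 20
    sweep_specs: tuple[SweepSpec, ...] = ()
    autozygosity_specs: tuple[AutozygositySpec, ...] = ()
    missing_rate: float = 0.0
    mosaic_block_bp: float = 100_000.0   # mean founder-switch spacing

    def __post_init__(self) -> None:
        if self.founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        for _, length in self.chromosomes:
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")
        lengths = dict(self.chromosomes)
        for s in self.sweep_specs:
            if s.chromosome not in lengths or not 1 <= s.center <= lengths[s.chromosome]:
                raise ValueError(f"sweep center outside chromosome {s.chromosome}")
        for a in self.autozygosity_specs:
            if a.chromosome not in lengths or a.end > lengths[a.chromosome]:
                raise ValueError(f"autozygous tract outside chromosome {a.chromosome}")


@dataclass
class TruthRecord:
    """Ground truth of one simulation: planted intervals, per-chromosome SNP
    counts, and (in memory only) the founder haplotype pools."""

    sweep_intervals: list[dict] = field(default_factory=list)
    autozygous_intervals: list[dict] = field(default_factory=list)
    snp_counts: dict[str, int] = field(default_factory=dict)
    founder_pools: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "sweep_intervals": self.sweep_intervals,
            "autozygous_intervals": self.autozygous_intervals,
            "snp_counts": self.snp_counts,
        }


def _rng(seed: int, chrom: str, stream: int) -> np.random.Generator:
    """Deterministic per-chromosome, per-purpose substream (stable under
    chromosome subsetting: keyed by chromosome name, not index)."""
    return np.random.default_rng([seed, zlib.crc32(chrom.encode()), stream])


def neutral_sfs_probs(n_haplotypes: int) -> np.ndarray:
    """P(derived count = i) ∝ 1/i for i in 1..n-1 (discretized neutral SFS)."""
    i = np.arange(1, n_haplotypes)
    w = 1.0 / i
    return w / w.sum()


def folded_sfs_probs(n_haplotypes: int) -> np.ndarray:
    """Expected folded minor-count probabilities implied by the 1/i draw;
    index m runs over 1..floor(n/2)."""
    p = neutral_sfs_probs(n_haplotypes)
    n = n_haplotypes
    out = np.zeros(n // 2)
    for i in range(1, n):
        m = min(i, n - i)
        out[m - 1] += p[i - 1]
    return out


def _simulate_chromosome(
    chrom: str, length: int, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (positions, founder_pool P×S, haplotype_pair 2×N×S of alleles)."""
    rng = _rng(config.seed, chrom, _STREAM_BACKGROUND)
    P = config.founder_haplotypes
    n_snps = rng.poisson(config.snp_density * length)
    positions = np.unique(rng.integers(1, length + 1, size=n_snps))
    S = positions.size
    if S == 0:
        logger.warning("degenerate chromosome %s: zero SNPs simulated", chrom)
        empty = np.empty((0,), dtype=np.int64)
        return empty, np.empty((P, 0), np.int8), np.empty((2, config.n_individuals, 0), np.int8)

    counts = rng.choice(np.arange(1, P), size=S, p=neutral_sfs_probs(P))
    pool = np.zeros((P, S), dtype=np.int8)
    for s in range(S):
        carriers = rng.choice(P, size=counts[s], replace=False)
        pool[carriers, s] = 1

    # founder mosaics: switch copied founder at Poisson breakpoints
    n_hap = 2 * config.n_individuals
    hap = np.zeros((n_hap, S), dtype=np.int8)
    switch_p = np.empty(S)
    switch_p[0] = 1.0
    if S > 1:
        gaps = np.diff(positions).astype(float)
        switch_p[1:] = 1.0 - np.exp(-gaps / config.mosaic_block_bp)
    site_idx = np.arange(S)
    for h in range(n_hap):
        switches = rng.random(S) < switch_p        # switch_p[0] == 1
        switch_at = np.flatnonzero(switches)
        donors = rng.integers(0, P, size=switch_at.size)
        governing = np.searchsorted(switch_at, site_idx, side="right") - 1
        hap[h] = pool[donors[governing], site_idx]
    haplotypes = hap.reshape(config.n_individuals, 2, S).transpose(1, 0, 2)
    return positions.astype(np.int64), pool, haplotypes


def _genotypes_from_haplotypes(haplotypes: np.ndarray) -> np.ndarray:
    """(2, N, S) allele array -> (S, N) genotype codes 0/1/2."""
    return (haplotypes[0] + haplotypes[1]).T.astype(np.int8)


def plant_sweep(matrix: GenotypeMatrix, spec: SweepSpec, seed: int = 0) -> GenotypeMatrix:
    """Plant a sweep footprint on a genotype matrix (returns a new matrix).

    Within ``[center - footprint, center + footprint]``: footprint SNPs are
    retained independently with probability ``diversity_reduction``; if
    ``ld_block``, every individual's dosages over each flank (left and right
    of the center) are rewritten from at most two flank haplotypes, making
    within-flank pairwise r² maximal; finally a ``sfs_skew`` fraction of
    surviving footprint SNPs is rewritten to minor-allele-count 1 (one
    heterozygote, all other individuals homozygous reference).
    """
    out = matrix.copy()
    c = out.chroms.get(spec.chromosome)
    if c is None:
        raise ValueError(f"no such chromosome: {spec.chromosome}")
    rng = _rng(seed, spec.chromosome, _STREAM_SWEEP)
    lo, hi = spec.center - spec.footprint, spec.center + spec.footprint
    in_fp = (c.positions >= lo) & (c.positions <= hi)
    if not in_fp.any():
        warnings.warn(f"sweep footprint on {spec.chromosome} contains no SNPs; no-op")
        return out

    keep = np.ones(c.n_sites, dtype=bool)
    if spec.diversity_reduction < 1.0:
        fp_idx = np.flatnonzero(in_fp)
        keep[fp_idx] = rng.random(fp_idx.size) < spec.diversity_reduction
    positions = c.positions[keep]
    genotypes = c.genotypes[keep].copy()
    in_fp = (positions >= lo) & (positions <= hi)

    n = genotypes.shape[1]
    if spec.ld_block and n >= 2:
        for flank in ((positions >= lo) & (positions < spec.center),
                      (positions >= spec.center) & (positions <= hi)):
            idx = np.flatnonzero(flank)
            if idx.size == 0:
                continue
            # two flank haplotypes; per-individual dose of haplotype B is
            # constant across the flank -> identical dosage columns, r² = 1
            seg = np.array([site for site in idx
                            if len(np.unique(genotypes[site][genotypes[site] != MISSING])) > 1])
            dose = rng.integers(0, 3, size=n).astype(np.int8)
            if len(np.unique(dose)) < 2:
                dose[0] = (dose[0] + 1) % 3
            for site in (seg if seg.size else idx):
                genotypes[site] = dose

    if spec.sfs_skew > 0:
        fp_idx = np.flatnonzero(in_fp)
        n_skew = int(round(spec.sfs_skew * fp_idx.size))
        chosen = rng.choice(fp_idx, size=n_skew, replace=False) if n_skew else []
        for site in chosen:
            row = np.zeros(n, dtype=np.int8)
            row[rng.integers(0, n)] = 1
            genotypes[site] = row

    out.chroms[spec.chromosome] = ChromosomeSites(
        positions, c.ref[keep], c.alt[keep], genotypes
    )
    return out


def plant_autozygosity(
    matrix: GenotypeMatrix, spec: AutozygositySpec, seed: int = 0
) -> GenotypeMatrix:
    """Force each carrier homozygous over the tract (returns a new matrix).

    Heterozygous carrier calls inside ``[start, end]`` are rewritten to one
    of the two homozygous states, emulating replacement of one haplotype by
    a copy of the other; homozygous calls are untouched, non-carriers are
    untouched. An empty carrier list or a tract containing no SNPs is a
    warned no-op.
    """
    out = matrix.copy()
    if not spec.carrier_individuals:
        warnings.warn("plant_autozygosity: empty carrier list; no-op")
        return out
    c = out.chroms.get(spec.chromosome)
    if c is None:
        raise ValueError(f"no such chromosome: {spec.chromosome}")
    unknown = set(spec.carrier_individuals) - set(matrix.samples)
    if unknown:
        raise ValueError(f"unknown carriers: {sorted(unknown)}")
    in_tract = np.flatnonzero((c.positions >= spec.start) & (c.positions <= spec.end))
    if in_tract.size == 0:
        warnings.warn(
            f"autozygous tract {spec.chromosome}:{spec.start}-{spec.end} contains no SNPs; no-op"
        )
        return out
    rng = _rng(seed, spec.chromosome, _STREAM_TRACT)
    for sample in spec.carrier_individuals:
        j = matrix.samples.index(sample)
        col = c.genotypes[in_tract, j]
        het = col == 1
        # which haplotype gets duplicated decides each het site's fate
        col[het] = rng.choice([0, 2], size=int(het.sum())).astype(np.int8)
        c.genotypes[in_tract, j] = col
    return out


def simulate_population(config: SimConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate genotypes with planted sweeps and autozygous tracts.

    Stage order: neutral background → sweeps → autozygous tracts → missing
    calls. Identical configs (including seed) give identical output.
    """
    samples = [f"ind{i:03d}" for i in range(config.n_individuals)]
    truth = TruthRecord()
    chroms: dict[str, ChromosomeSites] = {}
    lengths: dict[str, int] = {}
    for chrom, length in config.chromosomes:
        positions, pool, haplotypes = _simulate_chromosome(chrom, length, config)
        truth.snp_counts[chrom] = int(positions.size)
        truth.founder_pools[chrom] = pool
        ref = np.full(positions.size, "A", dtype=object)
        alt = np.full(positions.size, "G", dtype=object)
        chroms[chrom] = ChromosomeSites(
            positions, ref, alt, _genotypes_from_haplotypes(haplotypes)
        )
        lengths[chrom] = length
    matrix = GenotypeMatrix(samples=samples, chroms=chroms, chrom_lengths=lengths)

    for spec in config.sweep_specs:
        matrix = plant_sweep(matrix, spec, seed=config.seed)
        truth.sweep_intervals.append(
            {
                "chromosome": spec.chromosome,
                "start": spec.center - spec.footprint,
                "end": spec.center + spec.footprint,
                "center": spec.center,
            }
        )
    for spec in config.autozygosity_specs:
        matrix = plant_autozygosity(matrix, spec, seed=config.seed)
        truth.autozygous_intervals.append(
            {
                "chromosome": spec.chromosome,
                "start": spec.start,
                "end": spec.end,
                "carriers": list(spec.carrier_individuals),
            }
        )

    if config.missing_rate > 0:
        for chrom, c in matrix.chroms.items():
            rng = _rng(config.seed, chrom, _STREAM_MISSING)
            mask = rng.random(c.genotypes.shape) < config.missing_rate
            c.genotypes[mask] = MISSING
    return matrix, truth


# ---------------------------------------------------------------------------
# fixture bundle: VCF + toy GTF + QTL table + truth JSON

_TOY_TRAITS = [
    ("Milk yield", "milk"),
    ("Somatic cell score", "health"),
    ("Carcass weight", "meat and carcass"),
    ("Body weight gain", "production"),
    ("Calving ease", "reproduction"),
    ("Coat color", "exterior"),
]


def write_fixture_bundle(
    matrix: GenotypeMatrix,
    truth: TruthRecord,
    out_dir: str,
    genes_per_chrom: int = 8,
    qtls_per_chrom: int = 6,
    seed: int = 0,
) -> dict[str, str]:
    """Write a VCF, toy GTF, QTL interval table and truth JSON to ``out_dir``.

    The GTF tiles each chromosome with ``gene`` features carrying stable
    ``gene_id`` attributes; every fourth gene lacks ``gene_name`` so that
    downstream annotation classifies it as novel. The QTL table mimics a
    livestock QTL-database export (tab-separated, 1-based inclusive) and
    includes one deliberately duplicated QTL identifier per chromosome to
    exercise downstream deduplication.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "gtf": os.path.join(out_dir, "genes.gtf"),
        "qtl": os.path.join(out_dir, "qtl.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_vcf(matrix, paths["vcf"])

    gene_serial = 0
    with open(paths["gtf"], "w") as fh:
        for chrom in matrix.chroms:
            length = matrix.chrom_lengths.get(chrom, int(matrix.chroms[chrom].positions[-1]))
            step = max(length // (genes_per_chrom + 1), 1)
            for g in range(genes_per_chrom):
                start = g * step + 1
                end = min(start + int(step * 0.8), length)
                gene_serial += 1
                gene_id = f"SYNGENE{gene_serial:05d}"
                attrs = f'gene_id "{gene_id}"; gene_biotype "protein_coding";'
                if gene_serial % 4 != 0:
                    attrs += f' gene_name "GN{gene_serial:03d}";'
                fh.write(
                    f"{chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
                )

    rng = np.random.default_rng([seed, 97])
    with open(paths["qtl"], "w") as fh:
        fh.write("chrom\tstart\tend\tqtl_id\ttrait_name\ttrait_class\n")
        serial = 0
        for chrom in matrix.chroms:
            length = matrix.chrom_lengths.get(chrom, int(matrix.chroms[chrom].positions[-1]))
            step = max(length // (qtls_per_chrom + 1), 1)
            for q in range(qtls_per_chrom):
                serial += 1
                start = q * step + 1
                end = min(start + int(step * 1.2), length)
                trait, klass = _TOY_TRAITS[serial % len(_TOY_TRAITS)]
                # duplicate the first QTL id of each chromosome once
                qid = f"QTL{serial - (1 if q == 1 else 0):05d}"
                fh.write(f"{chrom}\t{start}\t{end}\t{qid}\t{trait}\t{klass}\n")

    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
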