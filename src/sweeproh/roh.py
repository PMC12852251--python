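"""Runs of homozygosity: windowed calling, F_ROH, and conserved-ROH mapping.

Calling procedure (per sample, per chromosome), in the style of window-based
ROH scanners tuned for short-read WGS data:

1. every window of ``window_snps`` consecutive sites is *homozygous* when it
   holds at most ``window_het_max`` heterozygous and ``window_missing_max``
   missing calls for the sample;
2. each SNP's hit proportion is the fraction of windows covering it that are
   homozygous (SNPs near chromosome ends are covered by fewer windows; the
   covering-window count is the denominator);
3. SNPs with hit proportion >= ``hit_proportion_min`` form maximal
   consecutive runs;
4. runs split wherever the bp gap between adjacent run SNPs exceeds
   ``max_gap_kb``;
5. a run is reported iff its bp length (last - first + 1) >=
   ``min_length_kb``, it holds >= ``min_snps`` SNPs, and its kb-per-SNP
   ratio does not exceed ``density_kb_per_snp_max``.

The genomic inbreeding coefficient F_ROH is the summed segment length over
the autosomal length covered by the analyzed SNPs (``L_AUTO``, default
2,489,385.779 kb — the autosomal span of a 95-animal cattle WGS panel on
ARS-UCD1.3).

Conserved ROH are found from per-SNP incidence: for each analyzed SNP, the
number of individuals carrying it inside at least one ROH. SNPs whose
incidence reaches ``ceil(threshold_prop * N)`` are retained and maximal
runs of consecutive retained SNPs become conserved regions; the individual
segments overlapping a region's retained SNPs are recovered as its
contributing segments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .variant_io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: autosomal genome length (kb) covered by the SNPs of the motivating
#: 95-animal cattle WGS panel; override for other datasets.
DEFAULT_L_AUTO_KB = 2_489_385.779


@dataclass(frozen=True)
class RohParams:
    """WGS-tuned calling parameters (see module docstring for semantics)."""

    window_snps: int = 50
    window_het_max: int = 2
    window_missing_max: int = 10
    hit_proportion_min: float = 0.025
    min_length_kb: float = 500.0
    min_snps: int = 50
    max_gap_kb: float = 1000.0
    density_kb_per_snp_max: float = 500.0

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_snps < 1:
            raise ValueError("window_snps and min_snps must be positive")
        if not 0.0 < self.hit_proportion_min <= 1.0:
            raise ValueError("hit_proportion_min must be in (0, 1]")
        for name in ("min_length_kb", "max_gap_kb", "density_kb_per_snp_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_het_max < 0 or self.window_missing_max < 0:
            raise ValueError("window tolerances must be non-negative")


#: comparator parameter set in the style of array-era defaults, used for the
#: parameterization-concordance check against the WGS-tuned set above.
ARRAY_DEFAULT_PARAMS = RohParams(
    window_snps=50,
    window_het_max=1,
    window_missing_max=5,
    hit_proportion_min=0.05,
    min_length_kb=1000.0,
    min_snps=100,
    max_gap_kb=1000.0,
    density_kb_per_snp_max=50.0,
)


@dataclass(frozen=True)
class RohSegment:
    sample: str
    chromosome: str
    start: int
    end: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0


@dataclass(frozen=True)
class FrohResult:
    sample: str
    total_roh_kb: float
    froh: float
    l_auto_kb: float


@dataclass
class IncidenceTrack:
    """Per-chromosome SNP positions with ROH incidence counts."""

    n_individuals: int
    chroms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    # chrom -> (positions int64, incidence int64)


@dataclass
class ConservedRegion:
    chromosome: str
    start: int
    end: int
    n_snps: int
    min_incidence: int
    contributing_segments: list[RohSegment] = field(default_factory=list)
    population_label: str = ""

    @property
    def length_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0


def _runs_from_mask(mask: np.ndarray):
    """Yield (start_idx, end_idx) of maximal True runs (end inclusive)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, ends):
        yield int(idx[a]), int(idx[b])


def call_roh(
    matrix: GenotypeMatrix, sample: str, params: RohParams | None = None
) -> list[RohSegment]:
    """Call ROH segments for one sample across all chromosomes."""
    params = params or RohParams()
    j = matrix.samples.index(sample)
    w = params.window_snps
    segments: list[RohSegment] = []
    for chrom, c in matrix.chroms.items():
        s = c.n_sites
        if s < w:
            logger.info("call_roh: chromosome %s has %d < %d SNPs; skipped", chrom, s, w)
            continue
        col = c.genotypes[:, j]
        het = (col == 1).astype(np.int64)
        miss = (col == -1).astype(np.int64)
        # sliding-window counts via cumulative sums
        chet = np.concatenate(([0], np.cumsum(het)))
        cmiss = np.concatenate(([0], np.cumsum(miss)))
        n_win = s - w + 1
        win_het = chet[w:] - chet[:-w]
        win_miss = cmiss[w:] - cmiss[:-w]
        hom_win = (
            (win_het <= params.window_het_max) & (win_miss <= params.window_missing_max)
        ).astype(np.int64)
        # windows covering SNP i: indices max(0, i-w+1) .. min(i, n_win-1)
        chom = np.concatenate(([0], np.cumsum(hom_win)))
        i = np.arange(s)
        lo = np.maximum(0, i - w + 1)
        hi = np.minimum(i, n_win - 1)
        covering = (hi - lo + 1).astype(np.float64)
        hits = (chom[hi + 1] - chom[lo]).astype(np.float64)
        hit_prop = hits / covering
        retained = hit_prop >= params.hit_proportion_min

        pos = c.positions
        max_gap_bp = params.max_gap_kb * 1000.0
        for a, b in _runs_from_mask(retained):
            run = np.arange(a, b + 1)
            gaps = np.diff(pos[run]).astype(float)
            split_after = np.flatnonzero(gaps > max_gap_bp)
            piece_starts = np.concatenate(([0], split_after + 1))
            piece_ends = np.concatenate((split_after, [run.size - 1]))
            for pa, pb in zip(piece_starts, piece_ends):
                first, last = int(pos[run[pa]]), int(pos[run[pb]])
                n_snps = int(pb - pa + 1)
                length_kb = (last - first + 1) / 1000.0
                if (
                    length_kb >= params.min_length_kb
                    and n_snps >= params.min_snps
                    and length_kb / n_snps <= params.density_kb_per_snp_max
                ):
                    segments.append(RohSegment(sample, chrom, first, last, n_snps))
    return segments


def call_roh_all(
    matrix: GenotypeMatrix, params: RohParams | None = None
) -> dict[str, list[RohSegment]]:
    """Call ROH for every sample; returns sample -> sorted segment list."""
    return {s: call_roh(matrix, s, params) for s in matrix.samples}


def froh(
    segments: list[RohSegment], l_auto_kb: float = DEFAULT_L_AUTO_KB, sample: str = ""
) -> FrohResult:
    """F_ROH = total ROH length / autosomal length covered by analyzed SNPs."""
    if l_auto_kb <= 0:
        raise ValueError("l_auto_kb must be positive")
    if segments and not sample:
        sample = segments[0].sample
    total = float(sum(s.length_kb for s in segments))
    return FrohResult(sample=sample, total_roh_kb=total, froh=total / l_auto_kb,
                      l_auto_kb=l_auto_kb)


def froh_concordance(
    froh_a: dict[str, float] | list[float], froh_b: dict[str, float] | list[float]
) -> tuple[float, float]:
    """(Spearman rho, Pearson r) between two per-sample F_ROH vectors.

    Inputs may be dicts keyed by sample (matched by key) or aligned lists.
    Returns (nan, nan) when either vector has zero variance.
    """
    if isinstance(froh_a, dict):
        if set(froh_a) != set(froh_b):
            raise ValueError("sample sets differ")
        keys = sorted(froh_a)
        a = np.array([froh_a[k] for k in keys], dtype=float)
        b = np.array([froh_b[k] for k in keys], dtype=float)
    else:
        a, b = np.asarray(froh_a, float), np.asarray(froh_b, float)
        if a.size != b.size:
            raise ValueError("vectors differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(a) == 0 or np.std(b) == 0:
        logger.warning("froh_concordance: zero variance; correlation undefined")
        return (float("nan"), float("nan"))
    rho = stats.spearmanr(a, b).statistic
    r = stats.pearsonr(a, b).statistic
    return (float(rho), float(r))


def snp_incidence(
    all_segments: dict[str, list[RohSegment]], matrix: GenotypeMatrix
) -> IncidenceTrack:
    """Per-SNP count of individuals carrying the SNP inside >= 1 ROH.

    Computed on the matrix's (filtered) site list; an individual counts at
    most once per SNP however many of its segments cover it.
    """
    track = IncidenceTrack(n_individuals=len(all_segments))
    for chrom, c in matrix.chroms.items():
        pos = c.positions
        inc = np.zeros(pos.size, dtype=np.int64)
        for sample, segs in all_segments.items():
            covered = np.zeros(pos.size, dtype=bool)
            for seg in segs:
                if seg.chromosome != chrom:
                    continue
                a = np.searchsorted(pos, seg.start, side="left")
                b = np.searchsorted(pos, seg.end, side="right")
                covered[a:b] = True
            inc += covered
        track.chroms[chrom] = (pos.copy(), inc)
    return track


def conserved_regions(
    track: IncidenceTrack,
    n_individuals: int,
    threshold_prop: float,
    all_segments: dict[str, list[RohSegment]] | None = None,
    population_label: str = "",
) -> list[ConservedRegion]:
    """Merge runs of high-incidence SNPs into conserved-ROH regions.

    The incidence cutoff is ``ceil(threshold_prop * n_individuals)`` ("at
    least this many carriers"); retained SNPs that are consecutive on the
    chromosome's analyzed-site list (no intervening non-retained SNP) merge
    into one region. When ``all_segments`` is given, each region collects
    the individual segments overlapping >= 1 of its retained SNPs, over
    which summary statistics can be computed downstream.
    """
    if not 0.0 < threshold_prop <= 1.0:
        raise ValueError("threshold_prop must be in (0, 1]")
    cutoff = math.ceil(threshold_prop * n_individuals)
    regions: list[ConservedRegion] = []
    for chrom, (pos, inc) in track.chroms.items():
        retained = inc >= cutoff
        for a, b in _runs_from_mask(retained):
            region = ConservedRegion(
                chromosome=chrom,
                start=int(pos[a]),
                end=int(pos[b]),
                n_snps=int(b - a + 1),
                min_incidence=int(inc[a : b + 1].min()),
                population_label=population_label,
            )
            if all_segments is not None:
                retained_pos = pos[a : b + 1][retained[a : b + 1]]
                for segs in all_segments.values():
                    for seg in segs:
                        if seg.chromosome != chrom:
                            continue
                        k = np.searchsorted(retained_pos, seg.start, side="left")
                        if k < retained_pos.size and retained_pos[k] <= seg.end:
                            region.contributing_segments.append(seg)
            regions.append(region)
    return regions


def segment_summary(segments: list[RohSegment]) -> dict[str, float]:
    """Count, mean and SD (ddof=1) of segment lengths in kb."""
    lengths = np.array([s.length_kb for s in segments], dtype=float)
    if lengths.size == 0:
        return {"count": 0, "mean_kb": float("nan"), "sd_kb": float("nan")}
    sd = float(np.std(lengths, ddof=1)) if lengths.size > 1 else 0.0
    return {"count": int(lengths.size), "mean_kb": float(lengths.mean()), "sd_kb": sd}


def write_segments(all_segments: dict[str, list[RohSegment]], path: str) -> None:
    """Tab-separated segment table (sample, chrom, start, end, n_snps, length_kb)."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_snps\tlength_kb\n")
        for sample in all_segments:
            for s in all_segments[sample]:
                fh.write(
                    f"{s.sample}\t{s.chromosome}\t{s.start}\t{s.end}\t{s.n_snps}\t{s.length_kb:.3f}\n"
                )


def write_froh(results: list[FrohResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttotal_roh_kb\tfroh\n")
        for r in results:
            fh.write(f"{r.sample}\t{r.total_roh_kb:.3f}\t{r.froh:.6g}\n")
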