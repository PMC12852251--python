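"""Two-step percentile selection of sweep candidate regions.

Raw µ scores are winnowed per autosome in two stages: stage 1 keeps the top
``top_fraction`` of windows (default 1%), stage 2 applies a stringent
``inner_percentile`` cutoff (default 99.99) *within* the stage-1 subset of
the same chromosome. Both stages use the nearest-rank (ceiling) empirical
quantile and keep ties at the cutoff, so results are reproducible across
platforms with no interpolation rule. Retained windows overlapping in bp
are optionally merged into candidate regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np

from .mu_scan import MuWindow

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepFilterParams:
    top_fraction: float = 0.01
    inner_percentile: float = 99.99
    merge_overlapping: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0.0 < self.inner_percentile <= 100.0:
            raise ValueError("inner_percentile must be in (0, 100]")


@dataclass(frozen=True)
class CandidateRegion:
    chromosome: str
    start: int
    end: int
    peak_mu: float
    population_label: str = ""


def _top_fraction_cutoff(values: np.ndarray, fraction: float) -> float:
    """Value of the k-th largest score with k = ceil(fraction * n)."""
    k = max(ceil(fraction * values.size), 1)
    return float(np.sort(values)[-k])


def _nearest_rank_cutoff(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank (ceiling) percentile on the empirical distribution."""
    rank = max(ceil(percentile / 100.0 * values.size), 1)
    return float(np.sort(values)[rank - 1])


def stage1_windows(
    windows: list[MuWindow], params: SweepFilterParams | None = None
) -> list[MuWindow]:
    """Per-chromosome top-fraction selection (ties at the cutoff kept)."""
    params = params or SweepFilterParams()
    by_chrom: dict[str, list[MuWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chromosome, []).append(w)
    kept: list[MuWindow] = []
    for chrom, ws in by_chrom.items():
        mu = np.array([w.mu for w in ws])
        cutoff = _top_fraction_cutoff(mu, params.top_fraction)
        kept.extend(w for w in ws if w.mu >= cutoff)
    return kept


def merge_windows(
    windows: list[MuWindow], population_label: str = ""
) -> list[CandidateRegion]:
    """Merge bp-overlapping windows (per chromosome) into regions; the
    region's peak µ is the maximum over its merged windows."""
    by_chrom: dict[str, list[MuWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chromosome, []).append(w)
    regions: list[CandidateRegion] = []
    for chrom, ws in by_chrom.items():
        ws = sorted(ws, key=lambda w: (w.start, w.end))
        cur_start, cur_end, cur_peak = ws[0].start, ws[0].end, ws[0].mu
        for w in ws[1:]:
            if w.start <= cur_end:  # 1-based inclusive overlap
                cur_end = max(cur_end, w.end)
                cur_peak = max(cur_peak, w.mu)
            else:
                regions.append(CandidateRegion(chrom, cur_start, cur_end, cur_peak, population_label))
                cur_start, cur_end, cur_peak = w.start, w.end, w.mu
        regions.append(CandidateRegion(chrom, cur_start, cur_end, cur_peak, population_label))
    return regions


def two_step_filter(
    windows: list[MuWindow],
    params: SweepFilterParams | None = None,
    population_label: str = "",
) -> list[CandidateRegion]:
    """Apply both percentile stages, then merge retained windows into regions.

    Each stage operates per chromosome; the inner percentile is computed
    within the chromosome's stage-1 subset. With ``merge_overlapping=False``
    every retained window becomes its own single-window region.
    """
    params = params or SweepFilterParams()
    if not windows:
        return []
    s1 = stage1_windows(windows, params)
    by_chrom: dict[str, list[MuWindow]] = {}
    for w in s1:
        by_chrom.setdefault(w.chromosome, []).append(w)
    s2: list[MuWindow] = []
    for chrom, ws in by_chrom.items():
        mu = np.array([w.mu for w in ws])
        cutoff = _nearest_rank_cutoff(mu, params.inner_percentile)
        s2.extend(w for w in ws if w.mu >= cutoff)
    logger.info(
        "two_step_filter: %d windows -> %d (stage 1) -> %d (stage 2)",
        len(windows), len(s1), len(s2),
    )
    if params.merge_overlapping:
        return merge_windows(s2, population_label)
    return [
        CandidateRegion(w.chromosome, w.start, w.end, w.mu, population_label) for w in s2
    ]


def write_regions_bed(regions, path: str) -> None:
    """Write regions as BED (0-based half-open) with the peak µ (or the
    region's score attribute) in column 4."""
    with open(path, "w") as fh:
        for r in regions:
            score = getattr(r, "peak_mu", getattr(r, "min_incidence", "."))
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{score}\n")
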