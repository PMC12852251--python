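"""Composite µ-statistic sweep scan.

Positive selection driving a haplotype toward fixation leaves three local
footprints: reduced genetic diversity, a site-frequency spectrum skewed
toward rare variants, and elevated linkage disequilibrium on either side of
the swept site with reduced association across it. The scan slides a
window of ``W`` consecutive SNPs along each chromosome (stride one SNP)
and scores each window by the product of three non-negative factors:

* ``mu_var`` — window bp span divided by chromosome length: a fixed number
  of SNPs spanning more sequence means locally reduced diversity;
* ``mu_sfs`` — fraction of window sites whose folded minor-allele count
  (over non-missing alleles) is at most ``sfs_class_k``;
* ``mu_ld`` — mean pairwise genotype-dosage r² within the two half-windows,
  divided by the mean r² of cross-half pairs.

The composite ``mu = mu_var * mu_sfs * mu_ld``; higher values mean stronger
sweep evidence. Exact numerical agreement with any particular sweep-scan
tool is not attempted; the factors realize the same three signals on
unphased genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .variant_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MuParams:
    """Scan parameters.

    ``window_snps`` must be even (the window splits into equal halves at the
    SNP index); ``min_segregating`` is the minimum number of segregating
    sites required in each half-window for the LD factor to be defined —
    windows failing it are skipped, not scored.
    """

    window_snps: int = 50
    sfs_class_k: int = 1
    ld_epsilon: float = 1e-9
    min_segregating: int = 2

    def __post_init__(self) -> None:
        if self.window_snps < 4 or self.window_snps % 2:
            raise ValueError("window_snps must be even and >= 4")
        if self.sfs_class_k < 1:
            raise ValueError("sfs_class_k must be >= 1")
        if self.ld_epsilon <= 0:
            raise ValueError("ld_epsilon must be positive")


@dataclass(frozen=True)
class MuWindow:
    """One scored scan window (coordinates are first/last SNP bp)."""

    chromosome: str
    start: int
    end: int
    center: float
    mu_var: float
    mu_sfs: float
    mu_ld: float
    mu: float


def compute_mu_var(window_positions: np.ndarray, chrom_length: int) -> float:
    """Diversity factor: bp span of the window over the chromosome length."""
    pos = np.asarray(window_positions)
    if pos.size < 2:
        raise ValueError("need at least 2 positions")
    if pos[-1] > chrom_length:
        raise ValueError("positions exceed chromosome length")
    span = int(pos[-1]) - int(pos[0])
    if span == 0:
        raise ValueError("all window positions identical")
    return span / chrom_length


def folded_minor_counts(genotype_rows: np.ndarray) -> np.ndarray:
    """Folded minor-allele count per site over non-missing alleles."""
    g = np.asarray(genotype_rows)
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=-1)
    total = 2 * called.sum(axis=-1)
    return np.minimum(alt, total - alt)


def compute_mu_sfs(window_genotypes: np.ndarray, params: MuParams | None = None) -> float:
    """SFS factor: fraction of window sites with minor count <= sfs_class_k."""
    params = params or MuParams()
    counts = folded_minor_counts(window_genotypes)
    low = (counts <= params.sfs_class_k) & ((window_genotypes != MISSING).any(axis=-1))
    return float(low.sum()) / window_genotypes.shape[0]


def _pairwise_r2(window_genotypes: np.ndarray) -> np.ndarray:
    """Pairwise-complete r² matrix between the sites of a window.

    Missing calls are handled by pairwise deletion; pairs where either site
    has zero variance over the jointly called samples get NaN.
    """
    g = np.asarray(window_genotypes, dtype=np.float64)
    valid = (window_genotypes != MISSING).astype(np.float64)
    x = np.where(valid > 0, g, 0.0)
    n = valid @ valid.T
    sx = x @ valid.T
    sxx = (x * x) @ valid.T
    sxy = x @ x.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        denom = varx * varx.T
        r2 = np.where(denom > 0, cov**2 / np.where(denom > 0, denom, 1.0), np.nan)
    r2[n < 2] = np.nan
    return r2


def _mean_offdiag(block: np.ndarray) -> float:
    """Mean of finite off-diagonal entries of a symmetric block (NaN if none)."""
    m = block.copy().astype(float)
    if m.shape[0] == m.shape[1]:
        np.fill_diagonal(m, np.nan)
    finite = np.isfinite(m)
    if not finite.any():
        return float("nan")
    return float(m[finite].mean())


def compute_mu_ld(window_genotypes: np.ndarray, params: MuParams | None = None) -> float:
    """LD factor: mean within-half r² over mean cross-half r².

    r² is computed only between *informative* sites: segregating in-sample
    with folded minor count above ``sfs_class_k``. Pairwise r² estimated
    from rare variants is dominated by sampling noise, and a sweep's
    rare-allele excess would otherwise leak into the LD contrast; applying
    a frequency floor before LD estimation is the standard remedy.

    Raises ``ValueError`` when a half-window has fewer than
    ``min_segregating`` informative sites (caller skips such windows).
    """
    params = params or MuParams()
    w = window_genotypes.shape[0]
    half = w // 2
    called = window_genotypes != MISSING
    seg = np.array(
        [len(np.unique(row[c])) > 1 for row, c in zip(window_genotypes, called)]
    )
    informative = seg & (folded_minor_counts(window_genotypes) > params.sfs_class_k)
    left = np.flatnonzero(informative[:half])
    right = np.flatnonzero(informative[half:]) + half
    if left.size < params.min_segregating or right.size < params.min_segregating:
        raise ValueError("too few informative sites in a half-window")
    use = np.concatenate([left, right])
    r2_full = _pairwise_r2(window_genotypes[use])
    nl = left.size
    r_left = _mean_offdiag(r2_full[:nl, :nl])
    r_right = _mean_offdiag(r2_full[nl:, nl:])
    r_cross = _mean_offdiag(r2_full[:nl, nl:])
    if not (np.isfinite(r_left) and np.isfinite(r_right)):
        raise ValueError("no informative pairs within a half-window")
    if not np.isfinite(r_cross):
        r_cross = 0.0
    return ((r_left + r_right) / 2.0) / (r_cross + params.ld_epsilon)


def mu_scan(
    matrix: GenotypeMatrix,
    chrom_lengths: dict[str, int] | None = None,
    params: MuParams | None = None,
) -> list[MuWindow]:
    """Slide a W-SNP window along every chromosome and score each position.

    Chromosomes with fewer than ``window_snps`` SNPs yield no windows
    (logged); windows whose LD factor is undefined are skipped (logged).
    """
    params = params or MuParams()
    lengths = chrom_lengths or matrix.chrom_lengths
    w = params.window_snps
    out: list[MuWindow] = []
    for chrom, c in matrix.chroms.items():
        s = c.n_sites
        if s < w:
            logger.info("mu_scan: chromosome %s has %d < %d SNPs; no windows", chrom, s, w)
            continue
        length = lengths.get(chrom)
        if length is None:
            length = int(c.positions[-1])
        skipped = 0
        for i in range(s - w + 1):
            pos = c.positions[i : i + w]
            gw = c.genotypes[i : i + w]
            try:
                m_ld = compute_mu_ld(gw, params)
            except ValueError:
                skipped += 1
                continue
            m_var = compute_mu_var(pos, length)
            m_sfs = compute_mu_sfs(gw, params)
            start, end = int(pos[0]), int(pos[-1])
            out.append(
                MuWindow(
                    chromosome=chrom,
                    start=start,
                    end=end,
                    center=(start + end) / 2.0,
                    mu_var=m_var,
                    mu_sfs=m_sfs,
                    mu_ld=m_ld,
                    mu=m_var * m_sfs * m_ld,
                )
            )
        if skipped:
            logger.info("mu_scan: %s: skipped %d windows failing the LD precondition", chrom, skipped)
    return out


def write_mu_report(windows: list[MuWindow], path: str) -> None:
    """Tab-separated scan report (one row per window)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcenter\tmu_var\tmu_sfs\tmu_ld\tmu\n")
        for w in windows:
            fh.write(
                f"{w.chromosome}\t{w.start}\t{w.end}\t{w.center:.1f}\t"
                f"{w.mu_var:.6g}\t{w.mu_sfs:.6g}\t{w.mu_ld:.6g}\t{w.mu:.6g}\n"
            )


def read_mu_report(path: str) -> list[MuWindow]:
    """Read a scan report written by :func:`write_mu_report`."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, start, end, center, m_var, m_sfs, m_ld, mu = line.rstrip("\n").split("\t")
            out.append(
                MuWindow(chrom, int(start), int(end), float(center),
                         float(m_var), float(m_sfs), float(m_ld), float(mu))
            )
    return out
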