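"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive each algorithm from its definition with plain
loops; they stay deliberately independent of the vectorized implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import sweeproh as sp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_matrix(positions, genotype_rows, samples=None, chrom="1", chrom_length=None):
    """Build a one-chromosome GenotypeMatrix from plain lists."""
    g = np.asarray(genotype_rows, dtype=np.int8)
    if samples is None:
        samples = [f"s{i}" for i in range(g.shape[1])]
    pos = np.asarray(positions, dtype=np.int64)
    return sp.GenotypeMatrix(
        samples=list(samples),
        chroms={
            chrom: sp.ChromosomeSites(
                pos,
                np.full(pos.size, "A", dtype=object),
                np.full(pos.size, "G", dtype=object),
                g,
            )
        },
        chrom_lengths={chrom: int(chrom_length or (pos[-1] if pos.size else 0))},
    )


def brute_force_roh(positions, genotype_col, params: sp.RohParams):
    """Exhaustive re-derivation of the windowed ROH procedure.

    Returns (start_bp, end_bp, n_snps) tuples for one sample's chromosome.
    """
    pos = list(positions)
    col = list(genotype_col)
    s, w = len(pos), params.window_snps
    if s < w:
        return []
    n_win = s - w + 1
    hom = []
    for i in range(n_win):
        win = col[i : i + w]
        hom.append(
            sum(1 for g in win if g == 1) <= params.window_het_max
            and sum(1 for g in win if g == -1) <= params.window_missing_max
        )
    retained = []
    for snp in range(s):
        covering = [i for i in range(n_win) if i <= snp <= i + w - 1]
        hits = sum(1 for i in covering if hom[i])
        retained.append(hits / len(covering) >= params.hit_proportion_min)
    runs, cur = [], []
    for snp in range(s):
        if retained[snp]:
            cur.append(snp)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    pieces = []
    for run in runs:
        piece = [run[0]]
        for snp in run[1:]:
            if pos[snp] - pos[piece[-1]] > params.max_gap_kb * 1000:
                pieces.append(piece)
                piece = [snp]
            else:
                piece.append(snp)
        pieces.append(piece)
    out = []
    for piece in pieces:
        first, last = pos[piece[0]], pos[piece[-1]]
        n = len(piece)
        length_kb = (last - first + 1) / 1000.0
        if (
            length_kb >= params.min_length_kb
            and n >= params.min_snps
            and length_kb / n <= params.density_kb_per_snp_max
        ):
            out.append((int(first), int(last), n))
    return out


def sort_slice_two_step(mu_values, top_fraction, inner_percentile):
    """Sort-based oracle for the two-step percentile filter on one
    chromosome's scores; returns the retained index set."""
    import math

    n = len(mu_values)
    order = sorted(range(n), key=lambda i: mu_values[i])
    k = max(math.ceil(top_fraction * n), 1)
    cutoff1 = mu_values[order[n - k]]
    stage1 = [i for i in range(n) if mu_values[i] >= cutoff1]
    vals1 = sorted(mu_values[i] for i in stage1)
    rank = max(math.ceil(inner_percentile / 100.0 * len(vals1)), 1)
    cutoff2 = vals1[rank - 1]
    return {i for i in stage1 if mu_values[i] >= cutoff2}


def brute_force_r2(col_a, col_b):
    """r² between two dosage columns over jointly called samples; None when
    either column is constant on that subset."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    ok = (np.asarray(col_a) != sp.MISSING) & (np.asarray(col_b) != sp.MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1] ** 2)


@pytest.fixture(scope="session")
def planted_bundle(tmp_path_factory):
    """One simulated two-chromosome population with a sweep, a shared
    autozygous tract, and its on-disk fixture bundle."""
    cfg = sp.SimConfig(
        seed=11,
        n_individuals=12,
        chromosomes=(("1", 1_000_000), ("2", 900_000)),
        snp_density=1e-3,
        sweep_specs=(sp.SweepSpec("1", 500_000, 100_000),),
        autozygosity_specs=(
            sp.AutozygositySpec(
                "2", 100_000, 700_000, tuple(f"ind{i:03d}" for i in range(7))
            ),
        ),
        missing_rate=0.02,
    )
    matrix, truth = sp.simulate_population(cfg)
    out = tmp_path_factory.mktemp("bundle")
    paths = sp.write_fixture_bundle(matrix, truth, str(out), seed=cfg.seed)
    return {"config": cfg, "matrix": matrix, "truth": truth, "paths": paths}
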