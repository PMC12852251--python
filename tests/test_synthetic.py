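"""Generator: determinism, planted-signal guarantees, neutral SFS shape."""

import numpy as np
import pytest
from scipy import stats

import sweeproh as sp
from sweeproh.synthetic import folded_sfs_probs


def small_config(**kw):
    base = dict(
        seed=1,
        n_individuals=8,
        chromosomes=(("1", 500_000),),
        snp_density=1e-3,
        missing_rate=0.0,
    )
    base.update(kw)
    return sp.SimConfig(**base)


def test_identical_seed_gives_byte_identical_vcf(tmp_path):
    cfg = small_config(missing_rate=0.05)
    for name in ("a.vcf", "b.vcf"):
        matrix, _ = sp.simulate_population(cfg)
        sp.write_vcf(matrix, str(tmp_path / name))
    assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()


def test_snp_count_within_poisson_band():
    cfg = small_config(seed=7, chromosomes=(("1", 1_000_000),), snp_density=1e-3)
    _, truth = sp.simulate_population(cfg)
    expectation = 1000
    lo = stats.poisson.ppf(0.005, expectation)
    hi = stats.poisson.ppf(0.995, expectation)
    assert lo <= truth.snp_counts["1"] <= hi


def test_zero_missing_rate_leaves_no_missing_calls():
    matrix, _ = sp.simulate_population(small_config())
    for c in matrix.chroms.values():
        assert not (c.genotypes == sp.MISSING).any()


def test_missing_calls_appear_at_roughly_requested_rate():
    matrix, _ = sp.simulate_population(small_config(missing_rate=0.1))
    g = matrix.chroms["1"].genotypes
    rate = (g == sp.MISSING).mean()
    assert 0.05 < rate < 0.15


def test_positions_strictly_increasing_and_genotypes_valid():
    matrix, _ = sp.simulate_population(small_config(missing_rate=0.03))
    c = matrix.chroms["1"]
    assert np.all(np.diff(c.positions) > 0)
    assert set(np.unique(c.genotypes)) <= {-1, 0, 1, 2}


def test_planted_tract_has_no_carrier_hets():
    carriers = ("ind000", "ind002", "ind005")
    cfg = small_config(
        autozygosity_specs=(sp.AutozygositySpec("1", 100_000, 400_000, carriers),),
    )
    matrix, _ = sp.simulate_population(cfg)
    c = matrix.chroms["1"]
    in_tract = (c.positions >= 100_000) & (c.positions <= 400_000)
    assert in_tract.sum() > 50
    for s in carriers:
        col = c.genotypes[in_tract, matrix.samples.index(s)]
        assert not (col == 1).any()
    # a non-carrier keeps heterozygous sites in the tract
    other = c.genotypes[in_tract, matrix.samples.index("ind001")]
    assert (other == 1).any()


def test_empty_carrier_list_is_warned_noop():
    matrix, _ = sp.simulate_population(small_config())
    spec = sp.AutozygositySpec("1", 100_000, 400_000, ())
    with pytest.warns(UserWarning, match="empty carrier"):
        out = sp.plant_autozygosity(matrix, spec)
    assert out == matrix


def test_tract_without_snps_is_warned_noop():
    matrix, _ = sp.simulate_population(small_config())
    pos = matrix.chroms["1"].positions
    gaps = np.diff(pos)
    i = int(np.argmax(gaps))
    start, end = int(pos[i]) + 1, int(pos[i + 1]) - 1
    assert end > start
    spec = sp.AutozygositySpec("1", start, end, ("ind000",))
    with pytest.warns(UserWarning, match="no SNPs"):
        out = sp.plant_autozygosity(matrix, spec)
    assert out == matrix


def test_sweep_thinning_within_binomial_band():
    cfg = small_config(seed=3, chromosomes=(("1", 2_000_000),))
    matrix, _ = sp.simulate_population(cfg)
    spec = sp.SweepSpec("1", 1_000_000, 250_000, diversity_reduction=0.2,
                        sfs_skew=0.0, ld_block=False)
    pos = matrix.chroms["1"].positions
    before = int(((pos >= 750_000) & (pos <= 1_250_000)).sum())
    out = sp.plant_sweep(matrix, spec, seed=cfg.seed)
    pos2 = out.chroms["1"].positions
    after = int(((pos2 >= 750_000) & (pos2 <= 1_250_000)).sum())
    lo = stats.binom.ppf(0.005, before, 0.2)
    hi = stats.binom.ppf(0.995, before, 0.2)
    assert lo <= after <= hi
    # sites outside the footprint are untouched
    assert np.array_equal(pos[pos < 750_000], pos2[pos2 < 750_000])


def test_ld_block_makes_within_flank_r2_one():
    from conftest import brute_force_r2

    cfg = small_config(seed=4, n_individuals=10)
    matrix, _ = sp.simulate_population(cfg)
    spec = sp.SweepSpec("1", 250_000, 100_000, diversity_reduction=1.0,
                        sfs_skew=0.0, ld_block=True)
    out = sp.plant_sweep(matrix, spec, seed=cfg.seed)
    c = out.chroms["1"]
    for lo, hi in ((150_000, 249_999), (250_000, 350_000)):
        idx = np.flatnonzero((c.positions >= lo) & (c.positions <= hi))
        seg = [i for i in idx if len(np.unique(c.genotypes[i])) > 1]
        assert len(seg) >= 2
        r2s = [
            brute_force_r2(c.genotypes[a], c.genotypes[b])
            for a in seg
            for b in seg
            if a < b
        ]
        assert all(r2 == pytest.approx(1.0) for r2 in r2s if r2 is not None)


def test_identity_sweep_leaves_matrix_unchanged():
    matrix, _ = sp.simulate_population(small_config())
    spec = sp.SweepSpec("1", 250_000, 100_000, diversity_reduction=1.0,
                        sfs_skew=0.0, ld_block=False)
    assert sp.plant_sweep(matrix, spec) == matrix


def test_sfs_skew_rewrites_sites_to_singletons():
    cfg = small_config(seed=9, n_individuals=10)
    matrix, _ = sp.simulate_population(cfg)
    spec = sp.SweepSpec("1", 250_000, 100_000, diversity_reduction=1.0,
                        sfs_skew=1.0, ld_block=False)
    out = sp.plant_sweep(matrix, spec, seed=cfg.seed)
    c = out.chroms["1"]
    in_fp = (c.positions >= 150_000) & (c.positions <= 350_000)
    from sweeproh.mu_scan import folded_minor_counts

    counts = folded_minor_counts(c.genotypes[in_fp])
    assert (counts == 1).all()


def test_background_folded_sfs_matches_neutral_expectation():
    """Chi-square goodness of fit of founder-pool folded counts against the
    folded 1/i spectrum, >= 10,000 background SNPs, alpha = 0.001."""
    cfg = sp.SimConfig(
        seed=5, n_individuals=4, chromosomes=(("1", 6_000_000),),
        snp_density=2e-3, founder_haplotypes=20,
    )
    _, truth = sp.simulate_population(cfg)
    pool = truth.founder_pools["1"]
    assert pool.shape[1] >= 10_000
    p = cfg.founder_haplotypes
    folded = np.minimum(pool.sum(axis=0), p - pool.sum(axis=0))
    observed = np.bincount(folded, minlength=p // 2 + 1)[1:]
    expected = folded_sfs_probs(p) * folded.size
    result = stats.chisquare(observed, expected)
    assert result.pvalue > 0.001


def test_fixture_bundle_roundtrip_and_contents(planted_bundle):
    matrix = planted_bundle["matrix"]
    paths = planted_bundle["paths"]
    assert sp.read_vcf(paths["vcf"]) == matrix
    genes = sp.read_gtf(paths["gtf"])
    assert any(g.gene_name is None for g in genes)
    assert any(g.gene_name is not None for g in genes)
    qtls = sp.read_qtl_table(paths["qtl"])
    ids = [q.qtl_id for q in qtls]
    assert len(ids) > len(set(ids))  # duplicated id present for dedup tests


def test_degenerate_chromosome_warns_and_yields_empty():
    cfg = sp.SimConfig(
        seed=2, n_individuals=4, chromosomes=(("1", 100),), snp_density=1e-6
    )
    matrix, truth = sp.simulate_population(cfg)
    assert truth.snp_counts["1"] == 0
    assert matrix.chroms["1"].n_sites == 0
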