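import numpy as np
import pytest

from crocokin import (SimConfig, run_simulation, king_robust, site_filter,
                      pcair_partition, pcrelate, KIN_DEG3_THRESHOLD)
from conftest import kinship_chain


# ---------------------------------------------------------------------------
# site_filter

def test_duplicated_site_pruned_to_one():
    rng = np.random.default_rng(0)
    col = rng.binomial(2, 0.4, size=100).astype(float)
    other = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
    G = np.column_stack([col, other[:, 0], col, other[:, 1:]])
    keep = site_filter(G, maf_min=0.0, ld_r2=0.1, window=10)
    assert (0 in keep) != (2 in keep)


def test_independent_sites_mostly_retained():
    # 200 individuals x 200 independent MAF-0.3 sites: pruning at r2=0.1
    # should keep nearly everything
    rng = np.random.default_rng(1)
    G = rng.binomial(2, 0.3, size=(200, 200)).astype(float)
    keep = site_filter(G, maf_min=0.0, ld_r2=0.1, window=200)
    assert keep.size >= 0.95 * 200


def test_lower_mac_member_dropped():
    rng = np.random.default_rng(2)
    a = rng.binomial(2, 0.5, size=300).astype(float)
    b = a.copy()
    b[:60] = rng.binomial(2, 0.5, size=60)  # correlated, fewer minor alleles?
    # force MACs: make a clearly higher-MAC by flipping b toward 0
    b[b == 2] = np.where(rng.random((b == 2).sum()) < 0.3, 0, 2)
    G = np.column_stack([a, b])
    r = np.corrcoef(a, b)[0, 1]
    if r ** 2 > 0.1:
        keep = site_filter(G, maf_min=0.0, ld_r2=0.1, window=5)
        assert keep.size == 1
        mac = [min(v.sum(), 2 * len(v) - v.sum()) for v in (a, b)]
        assert keep[0] == int(np.argmax(mac))


def test_all_sites_removed_raises():
    G = np.zeros((10, 3))
    with pytest.raises(ValueError):
        site_filter(G, maf_min=0.05, ld_r2=0.1, window=3)


# ---------------------------------------------------------------------------
# KING-robust

def test_king_duplicate_individuals_phi_half():
    rng = np.random.default_rng(3)
    g = rng.binomial(2, 0.4, size=500).astype(float)
    assert (g == 1).any()
    G = np.vstack([g, g, rng.binomial(2, 0.4, size=500)])
    phi = king_robust(G)
    assert phi[0, 1] == pytest.approx(0.5)


def test_king_matches_hand_formula_on_small_fixture():
    G = np.array([
        [0, 1, 2, 1, 0, 1],
        [1, 1, 0, 0, 2, 1],
        [2, 0, 0, 1, 1, 1],
        [0, 2, 1, 1, 0, 0],
    ], dtype=float)
    phi = king_robust(G)
    for i in range(4):
        for j in range(i + 1, 4):
            het_het = int(np.sum((G[i] == 1) & (G[j] == 1)))
            opp = int(np.sum(((G[i] == 0) & (G[j] == 2))
                             | ((G[i] == 2) & (G[j] == 0))))
            het_i = int(np.sum(G[i] == 1))
            het_j = int(np.sum(G[j] == 1))
            want = (het_het - 2 * opp) / (het_i + het_j)
            assert phi[i, j] == pytest.approx(want)
            assert phi[j, i] == pytest.approx(want)


def test_king_pairwise_complete_missing_handling():
    G = np.array([[1, 1, np.nan, 0], [1, np.nan, 1, 2]], dtype=float)
    phi = king_robust(G)
    # jointly observed sites: 0 and 3 -> het_het=1, opp=1, het_i=1, het_j=1
    assert phi[0, 1] == pytest.approx((1 - 2) / 2)


def test_king_requires_two_individuals():
    with pytest.raises(ValueError):
        king_robust(np.ones((1, 5)))


# ---------------------------------------------------------------------------
# PC-AiR partition

def test_partition_all_unrelated_when_phi_below_threshold():
    rng = np.random.default_rng(4)
    G = rng.binomial(2, 0.5, size=(30, 400)).astype(float)
    kin = np.full((30, 30), 0.001)
    np.fill_diagonal(kin, 0.5)
    part = pcair_partition(G, kin, n_pcs=2)
    assert part.related.size == 0
    assert part.unrelated.size == 30


def test_partition_moves_planted_trio_to_related():
    rng = np.random.default_rng(5)
    n = 24
    G = rng.binomial(2, 0.5, size=(n, 400)).astype(float)
    kin = np.zeros((n, n))
    np.fill_diagonal(kin, 0.5)
    for a, b in ((0, 1), (0, 2), (1, 2)):
        kin[a, b] = kin[b, a] = 0.25
    part = pcair_partition(G, kin, n_pcs=2)
    assert np.isin([0, 1, 2], part.related).sum() >= 2
    assert part.unrelated.size + part.related.size == n
    # unrelated set contains no pair above the threshold
    sub = kin[np.ix_(part.unrelated, part.unrelated)]
    np.fill_diagonal(sub, 0.0)
    assert sub.max() <= KIN_DEG3_THRESHOLD


def test_partition_errors_when_unrelated_set_too_small():
    rng = np.random.default_rng(6)
    G = rng.binomial(2, 0.5, size=(6, 50)).astype(float)
    kin = np.full((6, 6), 0.3)
    with pytest.raises(ValueError):
        pcair_partition(G, kin, n_pcs=5)


# ---------------------------------------------------------------------------
# PC-Relate

def test_pcrelate_duplicate_individuals():
    # a duplicated pair estimates phi = (1 + F)/2 with F the individual's
    # chance homozygosity excess, so tolerances reflect the finite panel
    rng = np.random.default_rng(7)
    p = rng.uniform(0.1, 0.9, size=4000)
    G = rng.binomial(2, p, size=(100, 4000)).astype(float)
    G[1] = G[0]
    pcs = np.zeros((100, 1))  # intercept-only model: pooled frequencies
    out = pcrelate(G, pcs, training=np.arange(2, 100))
    row = out[(out.id_a == 0) & (out.id_b == 1)].iloc[0]
    assert row.phi == pytest.approx(0.5, abs=0.06)
    assert row.k2 == pytest.approx(1.0, abs=0.15)
    assert row.k0 == pytest.approx(0.0, abs=0.02)


def test_pcrelate_unrelated_pairs_centered():
    rng = np.random.default_rng(8)
    p = rng.uniform(0.1, 0.9, size=1000)
    G = rng.binomial(2, p, size=(50, 1000)).astype(float)
    pcs = np.zeros((50, 1))
    out = pcrelate(G, pcs, training=np.arange(50))
    # phi is relative to the pooled sample, giving the usual ~ -1/n shift
    assert abs(out.phi.mean()) < 0.02
    assert out.k0.mean() == pytest.approx(1.0, abs=0.05)
    assert abs(out.k2.mean()) < 0.02


def test_pcrelate_empty_training_raises():
    G = np.ones((4, 10))
    with pytest.raises(ValueError):
        pcrelate(G, np.zeros((4, 1)), training=np.array([], dtype=int))


def test_pcrelate_pop_calibration_panmictic(panmictic_triples):
    """Mean phi over true parent-offspring pairs ~1/4 and mean k0 over
    unrelated pairs ~1 in a panmictic simulated population."""
    tr = panmictic_triples
    pops = tr[tr.label == "POP"]
    assert len(pops) >= 50
    assert pops.phi.mean() == pytest.approx(0.25, abs=0.03)
    unrel = tr[tr.label == "U"]
    assert unrel.k0.mean() == pytest.approx(1.0, abs=0.05)


def test_pcrelate_second_degree_phi_not_deflated(panmictic_triples):
    deg2 = panmictic_triples[panmictic_triples.label == "DEG2"]
    assert len(deg2) >= 50
    assert deg2.phi.mean() >= 0.125 - 0.02


def test_moment_consistency(panmictic_triples):
    """phi ~ k2/2 + k1/4 holds in the median over well-estimated pairs."""
    tr = panmictic_triples
    k1 = 1.0 - tr.k0 - tr.k2
    gap = (tr.phi - (tr.k2 / 2 + k1 / 4)).abs()
    assert gap.median() < 0.02


def test_structure_robustness_two_demes():
    """PC adjustment removes the structure-induced distortion: among
    pairs without tracked kinship, PC-Relate phi within demes sits closer
    to zero than KING-robust phi between demes."""
    cfg = SimConfig(carrying_capacity=100, migration_rate=0.0001,
                    clutch_lambda=None, n_generations=100, pedigree_window=80,
                    n_founder_sites=3000, genome_length=100_000_000, seed=17)
    ped, pop = run_simulation(cfg)
    triples, Gf, part = kinship_chain(ped, pop, 60, seed=17, n_subpops=2)
    king = king_robust(Gf)
    # deme labels aligned with the sorted-id order used in kinship_chain
    from crocokin import sample_individuals
    rng = np.random.default_rng(17)
    sample = sample_individuals(pop, min(60, int(pop.census(2).min())), rng)
    order = np.argsort(sample.ids, kind="stable")
    sub = sample.subpop[order]
    iu, ju = np.triu_indices(len(sub), 1)
    unrel = triples.label.to_numpy() == "U"
    within = (sub[iu] == sub[ju]) & unrel
    between = (sub[iu] != sub[ju]) & unrel
    pc_within = np.abs(triples.phi.to_numpy()[within].mean())
    king_between = np.abs(king[iu, ju][between].mean())
    assert pc_within < king_between


def test_pcrelate_deterministic(panmictic_run):
    cfg, ped, pop = panmictic_run
    t1, _, _ = kinship_chain(ped, pop, 80, seed=99)
    t2, _, _ = kinship_chain(ped, pop, 80, seed=99)
    assert np.array_equal(t1.phi.to_numpy(), t2.phi.to_numpy())
    assert np.array_equal(t1.k0.to_numpy(), t2.k0.to_numpy())
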