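import numpy as np
import pytest

from crocokin import (SimConfig, run_simulation, sample_individuals,
                      enumerate_kin, site_filter, king_robust,
                      pcair_partition, pcrelate)


def kinship_chain(pedigree, pop, n_sample, seed, n_pcs=2, ld_window=10,
                  n_subpops=1):
    """Shared helper: sample a finished run and estimate (phi,k0,k2)+truth."""
    rng = np.random.default_rng(seed)
    n = min(n_sample, int(pop.census(n_subpops).min()))
    sample = sample_individuals(pop, n, rng)
    order = np.argsort(sample.ids, kind="stable")
    ids = sample.ids[order]
    G = sample.genotypes[order].astype(float)
    truth = enumerate_kin(pedigree, ids)
    keep = site_filter(G, maf_min=0.05, ld_r2=0.1, window=ld_window)
    Gf = G[:, keep]
    part = pcair_partition(Gf, king_robust(Gf), n_pcs=n_pcs)
    triples = pcrelate(Gf, part.pcs, part.unrelated, ids=ids)
    triples["label"] = truth["label"].to_numpy()
    triples["subtype"] = truth["subtype"].to_numpy()
    return triples, Gf, part


@pytest.fixture(scope="session")
def panmictic_run():
    """Single panmictic deme, single-offspring reproduction: the cleanest
    setting for checking PC-Relate calibration against pedigree truth."""
    cfg = SimConfig(carrying_capacity=250, n_subpops=1, migration_rate=0.0,
                    clutch_lambda=None, n_generations=150, pedigree_window=100,
                    n_founder_sites=4000, genome_length=100_000_000, seed=73)
    pedigree, pop = run_simulation(cfg)
    return cfg, pedigree, pop


@pytest.fixture(scope="session")
def panmictic_triples(panmictic_run):
    cfg, pedigree, pop = panmictic_run
    triples, Gf, part = kinship_chain(pedigree, pop, 200, seed=73)
    return triples
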