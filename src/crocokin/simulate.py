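"""Forward-time non-Wright-Fisher simulator with pedigree tracking.

Simulates a small number of subpopulations (demes) of a long-lived,
age-structured species linked by per-individual migration, with overlapping
generations, clutch reproduction, and density-dependent survival.  The model
follows the standard non-WF recipe: each time step (one year) runs

    reproduction -> migration -> density-dependent survival -> aging

Each mature female (age >= ``female_maturity``) mates with one uniformly
chosen mature male (age >= ``male_maturity``) from her own deme and produces
either one offspring (no-clutch scenario) or a Poisson(``clutch_lambda``)
clutch.  Every individual then switches deme independently with probability
``migration_rate``, and survives the year with probability
``min(1, K / N_deme)`` where ``N_deme`` counts the deme census including
newborns.  This survival rule is the only density regulation and produces
the characteristic age structure of a crocodilian population: mostly
juveniles, with the oldest animals in the 50-80 year range at carrying
capacity 1500 under single-offspring reproduction.

Genetics are finite-sites bi-allelic loci on one linear chromosome:
recombination as Poisson(r*L) crossovers with uniform breakpoints, mutation
as Poisson(mu*L) new (infinite-sites style) polymorphisms per gamete.
Standing variation can be seeded directly into the founders by drawing site
frequencies from the neutral 1/x frequency spectrum, with between-deme
divergence drawn from a Balding-Nichols model at the island-model
migration-drift equilibrium; this replaces a multi-thousand-generation
burn-in at reduced scale (see docs/methods.md).

A pedigree (id, mother, father, birth generation, natal deme, sex) is
recorded for all births in the final ``pedigree_window`` generations;
individuals alive when the window opens are recorded as founders with
untracked parents (-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Population",
    "SampleSet",
    "ExtinctionError",
    "run_simulation",
    "sample_individuals",
]

UNTRACKED = -1


class ExtinctionError(RuntimeError):
    """A subpopulation lost all individuals during the simulation."""

    def __init__(self, subpop: int, generation: int):
        self.subpop = subpop
        self.generation = generation
        super().__init__(
            f"subpopulation {subpop} went extinct at generation {generation}"
        )


@dataclass
class SimConfig:
    """All demographic and genetic parameters of a simulation run.

    Defaults are the full-scale study profile: two demes of carrying
    capacity 1500, mutation 3.5e-9 /bp/gen, crossover 1e-8 /bp/gen,
    female maturity 15 y, male maturity 16 y, 6000 generations with the
    last 100 pedigree-tracked.  ``clutch_lambda=None`` selects the
    single-offspring (no-clutch) scenario.
    """

    carrying_capacity: int = 1500
    migration_rate: float = 0.001
    n_subpops: int = 2
    mutation_rate: float = 3.5e-9
    recomb_rate: float = 1e-8
    genome_length: int = 100_000_000
    clutch_lambda: Optional[float] = 15.0
    female_maturity: int = 15
    male_maturity: int = 16
    n_generations: int = 6000
    pedigree_window: int = 100
    seed: int = 0
    # Chromosome count: equal-length chromosomes assort freely, with
    # Poisson(r * chrom_length) crossovers within each (the saltwater
    # crocodile karyotype is 2n = 34, i.e. 17 pairs).
    n_chromosomes: int = 17
    # "island": migrants pick a uniform other deme; "stepping_stone":
    # migrants move to an adjacent deme on a 1-D chain.
    migration_topology: str = "island"
    # Standing-variation initialisation (desk-scale burn-in replacement):
    # number of segregating sites seeded into the founders from the neutral
    # SFS; 0 starts from a monomorphic genome (mutation-only).
    n_founder_sites: int = 0
    # Between-deme divergence of founder allele frequencies; None derives
    # the island-model equilibrium value from K and m (see methods note).
    founder_fst: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.mutation_rate < 0 or self.recomb_rate < 0:
            raise ValueError("mutation_rate and recomb_rate must be >= 0")
        if self.carrying_capacity < 2:
            raise ValueError("carrying_capacity must be >= 2")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.clutch_lambda is not None and self.clutch_lambda <= 0:
            raise ValueError("clutch_lambda must be > 0 when present")
        if self.pedigree_window > self.n_generations:
            raise ValueError("pedigree_window must be <= n_generations")
        if self.n_founder_sites < 0:
            raise ValueError("n_founder_sites must be >= 0")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.migration_topology not in ("island", "stepping_stone"):
            raise ValueError("migration_topology must be 'island' or "
                             "'stepping_stone'")

    @property
    def chrom_length(self) -> int:
        return max(1, self.genome_length // self.n_chromosomes)


@dataclass
class Population:
    """Living population state (structure-of-arrays over individuals)."""

    ids: np.ndarray          # int64, unique
    sex: np.ndarray          # int8, 0 = female, 1 = male
    age: np.ndarray          # int32, years
    subpop: np.ndarray       # int8
    mother: np.ndarray       # int64, UNTRACKED for founders
    father: np.ndarray       # int64
    haplotypes: np.ndarray   # uint8, (n, 2, n_sites)
    positions: np.ndarray    # int64, bp positions of segregating sites

    @property
    def size(self) -> int:
        return self.ids.shape[0]

    def census(self, n_subpops: int) -> np.ndarray:
        return np.bincount(self.subpop, minlength=n_subpops)


@dataclass
class SampleSet:
    """Sampled individuals with 0/1/2 genotypes at polymorphic sites."""

    genotypes: np.ndarray    # uint8, (n_individuals, n_sites)
    ids: np.ndarray          # int64
    subpop: np.ndarray       # int8
    positions: np.ndarray    # int64, bp


def neutral_sfs_frequencies(n_sites: int, n_chrom: int, rng: np.random.Generator) -> np.ndarray:
    """Draw derived-allele frequencies from the neutral SFS (P(x) ~ 1/x).

    Frequencies are drawn on the grid {1/n_chrom, ..., (n_chrom-1)/n_chrom}
    with weights proportional to 1/i, the standard equilibrium frequency
    spectrum of neutral segregating sites.
    """
    counts = np.arange(1, n_chrom)
    w = 1.0 / counts
    probs = w / w.sum()
    return rng.choice(counts, size=n_sites, p=probs) / float(n_chrom)


def island_equilibrium_fst(carrying_capacity: int, migration_rate: float,
                           generation_time: float = 20.0) -> float:
    """Island-model equilibrium differentiation F ~ 1/(1 + 4*N*m_g).

    ``migration_rate`` is per individual per year; with a generation time of
    roughly 20 years the per-generation migrant fraction is min(1, 20*m).
    Used only to seed founder divergence at reduced scale.
    """
    m_gen = min(1.0, migration_rate * generation_time)
    return 1.0 / (1.0 + 4.0 * carrying_capacity * m_gen)


def _founder_haplotypes(config: SimConfig, n_per_subpop: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Seed founder haplotypes from the SFS with Balding-Nichols divergence."""
    s = config.n_founder_sites
    n_total = n_per_subpop * config.n_subpops
    if s == 0:
        return (np.zeros((n_total, 2, 0), dtype=np.uint8),
                np.empty(0, dtype=np.int64))
    n_chrom = 2 * n_total
    p_anc = neutral_sfs_frequencies(s, n_chrom, rng)
    if config.n_subpops > 1:
        fst = (config.founder_fst if config.founder_fst is not None
               else island_equilibrium_fst(config.carrying_capacity,
                                           config.migration_rate))
    else:
        fst = 0.0
    haps = np.empty((n_total, 2, s), dtype=np.uint8)
    for d in range(config.n_subpops):
        if fst > 0:
            a = p_anc * (1.0 - fst) / fst
            b = (1.0 - p_anc) * (1.0 - fst) / fst
            p_deme = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
        else:
            p_deme = p_anc
        lo, hi = d * n_per_subpop, (d + 1) * n_per_subpop
        haps[lo:hi] = rng.random((n_per_subpop, 2, s)) < p_deme
    positions = np.sort(rng.choice(config.genome_length, size=s, replace=False))
    return haps, positions


class _Pedigree:
    """Accumulates pedigree rows as flat arrays."""

    def __init__(self) -> None:
        self._chunks: list[tuple[np.ndarray, ...]] = []

    def add(self, ids, mother, father, birth_gen, subpop, sex) -> None:
        self._chunks.append((
            np.asarray(ids, dtype=np.int64),
            np.asarray(mother, dtype=np.int64),
            np.asarray(father, dtype=np.int64),
            np.broadcast_to(np.asarray(birth_gen, dtype=np.int64), np.shape(ids)).copy(),
            np.asarray(subpop, dtype=np.int64),
            np.asarray(sex, dtype=np.int64),
        ))

    def to_frame(self) -> pd.DataFrame:
        if not self._chunks:
            cols = {k: np.empty(0, dtype=np.int64)
                    for k in ("id", "mother_id", "father_id", "birth_gen", "subpop")}
            cols["sex"] = np.empty(0, dtype=object)
            return pd.DataFrame(cols)
        arrs = [np.concatenate([c[i] for c in self._chunks]) for i in range(6)]
        return pd.DataFrame({
            "id": arrs[0], "mother_id": arrs[1], "father_id": arrs[2],
            "birth_gen": arrs[3], "subpop": arrs[4],
            "sex": np.where(arrs[5] == 0, "F", "M"),
        })


def _site_chrom(positions: np.ndarray, config: SimConfig) -> np.ndarray:
    return np.minimum(positions // config.chrom_length,
                      config.n_chromosomes - 1).astype(np.int64)


def _make_gametes(haps: np.ndarray, parent_idx: np.ndarray, positions: np.ndarray,
                  site_chrom: np.ndarray, config: SimConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """One gamete per entry of ``parent_idx``.

    Chromosomes assort freely (independent start-haplotype coin per
    chromosome) and each chromosome recombines with Poisson(r * chrom
    length) crossovers at uniform breakpoints.
    """
    n = parent_idx.shape[0]
    nc = config.n_chromosomes
    clen = config.chrom_length
    h = haps[parent_idx]                                    # (n, 2, S)
    coin = rng.integers(0, 2, size=(n, nc), dtype=np.uint8)
    if positions.size == 0:
        return h[:, 0, :]
    mask = coin[np.arange(n)[:, None], site_chrom[None, :]]  # (n, S)
    mean_co = config.recomb_rate * clen
    if mean_co > 0:
        n_co = rng.poisson(mean_co, size=(n, nc))
        gi, ci = np.nonzero(n_co)
        chrom_sites = [np.nonzero(site_chrom == c)[0] for c in range(nc)]
        for g, c in zip(gi, ci):
            sel = chrom_sites[c]
            breaks = rng.integers(c * clen, (c + 1) * clen, size=n_co[g, c])
            if sel.size == 0:
                continue
            parity = (positions[sel][None, :] >= breaks[:, None]).sum(axis=0) & 1
            mask[g, sel] ^= parity.astype(np.uint8)
    return np.where(mask.astype(bool), h[:, 1, :], h[:, 0, :])


def run_simulation(config: SimConfig) -> tuple[pd.DataFrame, Population]:
    """Run the simulator and return (pedigree table, final living population).

    The pedigree covers births in the final ``pedigree_window`` generations
    plus untracked-founder rows for individuals alive when the window opens.
    Output is bit-identical for a fixed config (single seeded RNG threaded
    through reproduction -> migration -> survival in that order).
    """
    rng = np.random.default_rng(config.seed)
    K, nd = config.carrying_capacity, config.n_subpops
    L, mu, r = config.genome_length, config.mutation_rate, config.recomb_rate
    n0 = K * nd

    haps, positions = _founder_haplotypes(config, K, rng)
    site_chrom = _site_chrom(positions, config)
    n_sites = positions.size

    ids = np.arange(n0, dtype=np.int64)
    next_id = n0
    sex = rng.integers(0, 2, size=n0).astype(np.int8)
    # Rough stable age profile; demographic burn-in reshapes it.
    age = np.minimum(rng.geometric(0.1, size=n0) - 1, 60).astype(np.int32)
    subpop = np.repeat(np.arange(nd, dtype=np.int8), K)
    mother = np.full(n0, UNTRACKED, dtype=np.int64)
    father = np.full(n0, UNTRACKED, dtype=np.int64)

    pedigree = _Pedigree()
    window_start = config.n_generations - config.pedigree_window

    for gen in range(config.n_generations):
        if gen == window_start:
            pedigree.add(ids, mother, father, gen - age, subpop, sex)

        # --- reproduction -------------------------------------------------
        mat_f = (sex == 0) & (age >= config.female_maturity)
        mat_m = (sex == 1) & (age >= config.male_maturity)
        moms_idx: list[np.ndarray] = []
        dads_idx: list[np.ndarray] = []
        for d in range(nd):
            fi = np.nonzero(mat_f & (subpop == d))[0]
            mi = np.nonzero(mat_m & (subpop == d))[0]
            if fi.size == 0 or mi.size == 0:
                continue
            mates = mi[rng.integers(0, mi.size, size=fi.size)]
            if config.clutch_lambda is None:
                n_off = np.ones(fi.size, dtype=np.int64)
            else:
                n_off = rng.poisson(config.clutch_lambda, size=fi.size)
            moms_idx.append(np.repeat(fi, n_off))
            dads_idx.append(np.repeat(mates, n_off))
        if moms_idx:
            mom = np.concatenate(moms_idx)
            dad = np.concatenate(dads_idx)
            nb = mom.shape[0]
        else:
            mom = dad = np.empty(0, dtype=np.int64)
            nb = 0

        if nb:
            gam_m = _make_gametes(haps, mom, positions, site_chrom, config, rng)
            gam_f = _make_gametes(haps, dad, positions, site_chrom, config, rng)
            child_haps = np.stack([gam_m, gam_f], axis=1)
            # de novo mutations: new infinite-sites columns, one carrier each
            if mu * L > 0:
                n_mut = rng.poisson(mu * L, size=2 * nb)
                total = int(n_mut.sum())
                if total:
                    new_pos = rng.integers(0, L, size=total).astype(np.int64)
                    block = np.zeros((nb, 2, total), dtype=np.uint8)
                    carrier = np.repeat(np.arange(2 * nb), n_mut)
                    block[carrier // 2, carrier % 2, np.arange(total)] = 1
                    child_haps = np.concatenate([child_haps, block], axis=2)
                    haps = np.concatenate(
                        [haps, np.zeros((haps.shape[0], 2, total), dtype=np.uint8)],
                        axis=2)
                    positions = np.concatenate([positions, new_pos])
                    site_chrom = np.concatenate(
                        [site_chrom, _site_chrom(new_pos, config)])
                    n_sites += total

            child_ids = np.arange(next_id, next_id + nb, dtype=np.int64)
            next_id += nb
            child_sex = rng.integers(0, 2, size=nb).astype(np.int8)
            child_sub = subpop[mom].copy()
            mom_ids, dad_ids = ids[mom], ids[dad]
            if gen >= window_start:
                pedigree.add(child_ids, mom_ids, dad_ids, gen,
                             child_sub, child_sex)
            ids = np.concatenate([ids, child_ids])
            sex = np.concatenate([sex, child_sex])
            age = np.concatenate([age, np.zeros(nb, dtype=np.int32)])
            subpop = np.concatenate([subpop, child_sub])
            mother = np.concatenate([mother, mom_ids])
            father = np.concatenate([father, dad_ids])
            haps = np.concatenate([haps, child_haps], axis=0)

        # --- migration ----------------------------------------------------
        if nd > 1 and config.migration_rate > 0:
            mig = rng.random(ids.shape[0]) < config.migration_rate
            if mig.any():
                subpop = subpop.copy()
                if config.migration_topology == "island":
                    shift = rng.integers(1, nd, size=int(mig.sum()))
                    subpop[mig] = ((subpop[mig].astype(np.int64) + shift)
                                   % nd).astype(np.int8)
                else:  # stepping stone: step to an adjacent deme, clipped
                    step = rng.choice([-1, 1], size=int(mig.sum()))
                    dest = np.clip(subpop[mig].astype(np.int64) + step, 0, nd - 1)
                    subpop[mig] = dest.astype(np.int8)

        # --- density-dependent survival ------------------------------------
        census = np.bincount(subpop, minlength=nd)
        s_prob = np.minimum(1.0, K / np.maximum(census, 1))
        alive = rng.random(ids.shape[0]) < s_prob[subpop]
        ids, sex, age, subpop = ids[alive], sex[alive], age[alive], subpop[alive]
        mother, father = mother[alive], father[alive]
        haps = haps[alive]
        census = np.bincount(subpop, minlength=nd)
        if (census == 0).any():
            raise ExtinctionError(int(np.argmin(census)), gen)

        # --- aging ----------------------------------------------------------
        age = age + 1

        # periodic compaction: drop lost / fixed sites
        if n_sites and (gen % 25 == 24 or gen == config.n_generations - 1):
            counts = haps.sum(axis=(0, 1))
            keep = (counts > 0) & (counts < 2 * ids.shape[0])
            if not keep.all():
                haps = np.ascontiguousarray(haps[:, :, keep])
                positions = positions[keep]
                site_chrom = site_chrom[keep]
                n_sites = positions.size

    # final compaction (only currently polymorphic sites, position order)
    if n_sites:
        counts = haps.sum(axis=(0, 1))
        keep = np.nonzero((counts > 0) & (counts < 2 * ids.shape[0]))[0]
        order = keep[np.argsort(positions[keep], kind="stable")]
        haps = np.ascontiguousarray(haps[:, :, order])
        positions = positions[order]

    pop = Population(ids=ids, sex=sex, age=age, subpop=subpop,
                     mother=mother, father=father,
                     haplotypes=haps, positions=positions)
    return pedigree.to_frame(), pop


def sample_individuals(population: Population, n_per_subpop: int,
                       rng: np.random.Generator) -> SampleSet:
    """Uniform sample without replacement from each deme's final-generation
    living individuals; genotypes emitted at currently polymorphic sites."""
    if n_per_subpop < 0:
        raise ValueError("n_per_subpop must be >= 0")
    subpops = np.unique(population.subpop)
    chosen: list[np.ndarray] = []
    for d in subpops:
        idx = np.nonzero(population.subpop == d)[0]
        if idx.size < n_per_subpop:
            raise ValueError(
                f"requested {n_per_subpop} individuals from subpopulation {d} "
                f"but only {idx.size} are alive")
        sel = rng.choice(idx, size=n_per_subpop, replace=False)
        chosen.append(np.sort(sel))
    sel = np.concatenate(chosen) if chosen else np.empty(0, dtype=np.int64)
    geno = population.haplotypes[sel].sum(axis=1).astype(np.uint8)
    if geno.size:
        poly = (geno.sum(axis=0) > 0) & (geno.sum(axis=0) < 2 * sel.size)
        geno = geno[:, poly]
        positions = population.positions[poly]
    else:
        positions = population.positions[:0]
    return SampleSet(genotypes=geno, ids=population.ids[sel],
                     subpop=population.subpop[sel], positions=positions)
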