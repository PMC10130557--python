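"""Read-count cluster QC, four-way genotype scoring, and SNP/individual
filter cascades for reduced-representation (DArT-style) genotyping.

Two-row count data report, per locus and individual, the number of
sequence tags supporting the reference and alternate alleles.  Genotypes
are scored to four categories: AB (both alleles observed), AA/A0 (only the
reference observed — a true homozygote or a heterozygote with a null
allele), BB/B0 (only the alternate), and 00 (double null, no reads).  A0
and AA are intentionally indistinguishable from counts.

``pilot_qc_and_score`` implements the pilot-marker QC: drop loci whose
likely heterozygotes (minor-allele proportion >= 5%) have median total
read depth < 15; drop loci whose heterozygote allele-balance ratio falls
outside [0.33, 0.67]; flag excess-allele (polyploidy/contamination) loci
and individuals; score everything four-way; drop individuals that are
lower-tail outliers on (het loci - null loci); and apply a call-based MAF
filter (default 2%).  Outlier rules replace the original visual
inspection with a deterministic median - 3*MAD cut.

``main_filter_cascade`` implements the SNP/individual cascade used on the
full dataset: reproducibility, call rate, minor allele count, mean
coverage, one SNP per fragment, Hardy-Weinberg across sampling
populations, individual missingness and heterozygosity, and duplicate
resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["ReadCountMatrix", "FilterReport", "FourWay",
           "pilot_qc_and_score", "main_filter_cascade",
           "generate_readcount_fixture", "calls_to_genotypes", "hwe_test"]


class FourWay:
    """Integer codes for the four-way genotype calls."""
    AB = 0
    AA_A0 = 1
    BB_B0 = 2
    NULL00 = 3
    NAMES = {0: "AB", 1: "AA_A0", 2: "BB_B0", 3: "NULL00"}


@dataclass
class ReadCountMatrix:
    """Per-locus, per-individual reference/alternate tag counts."""

    ref: np.ndarray                       # (n_loci, n_ind) int
    alt: np.ndarray                       # (n_loci, n_ind) int
    locus_ids: np.ndarray
    individual_ids: np.ndarray
    fragments: Optional[np.ndarray] = None       # per-locus fragment/clone id
    pops: Optional[np.ndarray] = None            # per-individual labels
    repro_scores: Optional[np.ndarray] = None    # per-locus reproducibility
    extra_counts: Optional[np.ndarray] = None    # reads from 3rd+ alleles

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref and alt count matrices must share a shape")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def n_loci(self) -> int:
        return self.ref.shape[0]

    @property
    def n_ind(self) -> int:
        return self.ref.shape[1]


@dataclass
class FilterReport:
    """Ordered record of filter steps and surviving ids."""

    steps: list[dict] = field(default_factory=list)
    surviving_loci: Optional[np.ndarray] = None
    surviving_individuals: Optional[np.ndarray] = None

    def add(self, step: str, axis: str, removed_ids, threshold) -> None:
        removed_ids = list(np.asarray(removed_ids).tolist())
        self.steps.append({"step": step, "axis": axis,
                           "n_removed": len(removed_ids),
                           "removed": removed_ids, "threshold": threshold})
        log.info("QC step %-28s removed %4d %s (threshold=%s)",
                 step, len(removed_ids), axis, threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{k: s[k] for k in
                              ("step", "axis", "n_removed", "threshold")}
                             for s in self.steps])

    def to_json(self, path=None) -> str:
        import json
        payload = json.dumps({
            "steps": [{**s, "threshold": str(s["threshold"])}
                      for s in self.steps],
            "surviving_loci": _id_list(self.surviving_loci),
            "surviving_individuals": _id_list(self.surviving_individuals),
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _id_list(ids):
    return [] if ids is None else [str(x) for x in np.asarray(ids).tolist()]


def _lower_tail_outliers(x: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return x < med - n_mad * np.maximum(mad, 1e-12)


def _upper_tail_outliers(x: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return x > med + n_mad * np.maximum(mad, 1e-12)


def score_four_way(ref: np.ndarray, alt: np.ndarray,
                   het_min_prop: float = 0.05) -> np.ndarray:
    """Score every (locus, individual) to a FourWay call (total scoring)."""
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_prop = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
        ref_prop = np.where(total > 0, ref / np.maximum(total, 1), 0.0)
    calls = np.full(ref.shape, FourWay.NULL00, dtype=np.int8)
    has = total > 0
    both = has & (alt_prop >= het_min_prop) & (ref_prop >= het_min_prop)
    calls[both] = FourWay.AB
    calls[has & (alt_prop < het_min_prop)] = FourWay.AA_A0
    calls[has & (ref_prop < het_min_prop)] = FourWay.BB_B0
    return calls


def calls_to_genotypes(calls: np.ndarray) -> np.ndarray:
    """FourWay calls to 0/1/2/NaN dosage (individuals x loci)."""
    g = np.full(calls.shape, np.nan)
    g[calls == FourWay.AA_A0] = 0.0
    g[calls == FourWay.AB] = 1.0
    g[calls == FourWay.BB_B0] = 2.0
    return g.T


def pilot_qc_and_score(counts: ReadCountMatrix,
                       het_depth_min: float = 15.0,
                       balance_range: tuple[float, float] = (0.33, 0.67),
                       het_min_prop: float = 0.05,
                       maf_min: float = 0.02,
                       excess_allele_floor: int = 3,
                       excess_allele_frac: float = 0.25,
                       ) -> tuple[np.ndarray, np.ndarray, FilterReport]:
    """Pilot cluster QC and four-way scoring.

    Returns (calls for surviving loci x individuals, locus keep-indices are
    recorded in the report, FilterReport).  Calls use FourWay codes.
    """
    if counts.n_loci == 0 or counts.n_ind == 0:
        raise ValueError("empty read-count matrix")
    report = FilterReport()
    ref, alt = counts.ref.astype(np.int64), counts.alt.astype(np.int64)
    locus_ids = np.asarray(counts.locus_ids)
    ind_ids = np.asarray(counts.individual_ids)
    locus_keep = np.ones(counts.n_loci, dtype=bool)

    # (1) likely-heterozygote median depth
    total = ref + alt
    minor = np.minimum(ref, alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_prop = np.where(total > 0, minor / np.maximum(total, 1), 0.0)
    het_like = (total > 0) & (minor_prop >= het_min_prop)
    med_depth = np.array([
        np.median(total[i, het_like[i]]) if het_like[i].any() else 0.0
        for i in range(counts.n_loci)])
    drop = med_depth < het_depth_min
    report.add("het_median_depth", "loci", locus_ids[drop], het_depth_min)
    locus_keep &= ~drop

    # (2) heterozygote allele-balance ratio of median counts
    lo, hi = balance_range
    med_ref = np.array([np.median(ref[i, het_like[i]])
                        if het_like[i].any() else np.nan
                        for i in range(counts.n_loci)])
    med_alt = np.array([np.median(alt[i, het_like[i]])
                        if het_like[i].any() else np.nan
                        for i in range(counts.n_loci)])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = med_ref / (med_ref + med_alt)
    drop = locus_keep & ((ratio < lo) | (ratio > hi))
    report.add("het_allele_balance", "loci", locus_ids[drop], balance_range)
    locus_keep &= ~drop

    # (3) excess-allele (polyploidy / contamination) flags
    if counts.extra_counts is not None:
        excess = counts.extra_counts >= excess_allele_floor
        frac_by_locus = excess.mean(axis=1)
        frac_by_ind = excess.mean(axis=0)
        drop = locus_keep & (frac_by_locus > excess_allele_frac)
        report.add("excess_alleles", "loci", locus_ids[drop],
                   excess_allele_frac)
        locus_keep &= ~drop
        flagged_ind = frac_by_ind > excess_allele_frac
        report.add("excess_alleles_flag", "individuals",
                   ind_ids[flagged_ind], excess_allele_frac)
    else:
        report.add("excess_alleles", "loci", [], "skipped: no 3rd-allele counts")

    # (4) four-way scoring on surviving loci
    calls = score_four_way(ref[locus_keep], alt[locus_keep], het_min_prop)

    # (5) composite het - null lower-tail individual outliers
    het_n = (calls == FourWay.AB).sum(axis=0)
    null_n = (calls == FourWay.NULL00).sum(axis=0)
    composite = het_n - null_n
    bad_ind = _lower_tail_outliers(composite.astype(float))
    report.add("composite_het_minus_null", "individuals",
               ind_ids[bad_ind], "median - 3*MAD")
    calls = calls[:, ~bad_ind]

    # (6) MAF from calls
    n_a = 2 * (calls == FourWay.AA_A0).sum(axis=1) + (calls == FourWay.AB).sum(axis=1)
    n_b = 2 * (calls == FourWay.BB_B0).sum(axis=1) + (calls == FourWay.AB).sum(axis=1)
    tot = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, n_a / np.maximum(tot, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    drop_local = maf < maf_min
    kept_ids = locus_ids[locus_keep]
    report.add("maf", "loci", kept_ids[drop_local], maf_min)
    calls = calls[~drop_local]
    kept_ids = kept_ids[~drop_local]

    report.surviving_loci = kept_ids
    report.surviving_individuals = ind_ids[~bad_ind]
    return calls, kept_ids, report


def hwe_test(genotypes: np.ndarray, method: str = "chisq") -> float:
    """Hardy-Weinberg test p-value for one locus (0/1/2 dosages, NaN ok).

    ``chisq`` is the 1-df goodness-of-fit test; ``exact`` is the standard
    conditional exact test enumerating heterozygote counts.
    """
    g = genotypes[~np.isnan(genotypes)]
    n = g.size
    if n == 0:
        return 1.0
    n_aa = int((g == 0).sum()); n_ab = int((g == 1).sum()); n_bb = int((g == 2).sum())
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    if method == "chisq":
        p = n_a / (2.0 * n)
        exp = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
        obs = np.array([n_aa, n_ab, n_bb], dtype=float)
        chi2 = float((((obs - exp) ** 2) / np.maximum(exp, 1e-12)).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        # conditional distribution of the heterozygote count (Levene/Haldane)
        rare = min(n_a, n_b)
        hets = np.arange(rare % 2, rare + 1, 2)
        from scipy.special import gammaln
        ll = (hets * np.log(2) + gammaln(n + 1)
              - gammaln((n_a - hets) / 2 + 1) - gammaln(hets + 1)
              - gammaln((n_b - hets) / 2 + 1)
              - (gammaln(2 * n + 1) - gammaln(n_a + 1) - gammaln(n_b + 1)))
        pr = np.exp(ll - ll.max())
        pr /= pr.sum()
        obs_p = pr[hets == n_ab][0] if (n_ab in hets) else 0.0
        return float(pr[pr <= obs_p + 1e-12].sum())
    raise ValueError(f"unknown HWE method {method!r}")


def main_filter_cascade(G, locus_ids=None, individual_ids=None,
                        pops=None, fragments=None, positions=None,
                        coverage=None, repro_scores=None,
                        call_rate_min: float = 0.3, mac_min: int = 5,
                        coverage_range: tuple[float, float] = (10.0, 200.0),
                        hwe_p: float = 1e-3, hwe_min_pops: int = 3,
                        hwe_method: str = "chisq",
                        het_max: float = 0.36,
                        dup_identity: float = 0.95,
                        remove_low_het: bool = False,
                        ) -> tuple[np.ndarray, FilterReport]:
    """SNP/individual filter cascade on a 0/1/2/NaN genotype matrix
    (individuals x loci).  Returns (filtered matrix, FilterReport).

    Low-heterozygosity individuals are flagged but removed only when
    ``remove_low_het`` is set (the original decision used external
    metadata judgement).
    """
    G = np.asarray(G, dtype=float)
    n_ind0, n_loc0 = G.shape
    locus_ids = (np.asarray(locus_ids) if locus_ids is not None
                 else np.arange(n_loc0))
    individual_ids = (np.asarray(individual_ids) if individual_ids is not None
                      else np.arange(n_ind0))
    report = FilterReport()
    loc_keep = np.ones(n_loc0, dtype=bool)
    ind_keep = np.ones(n_ind0, dtype=bool)

    def _lmask():
        return np.nonzero(loc_keep)[0]

    # reproducibility
    if repro_scores is not None:
        bad = _lower_tail_outliers(np.asarray(repro_scores, dtype=float))
        report.add("reproducibility", "loci", locus_ids[bad], "median - 3*MAD")
        loc_keep &= ~bad
    else:
        report.add("reproducibility", "loci", [], "skipped: no scores")

    # call rate
    cr = 1.0 - np.isnan(G).mean(axis=0)
    bad = loc_keep & (cr < call_rate_min)
    report.add("call_rate", "loci", locus_ids[bad], call_rate_min)
    loc_keep &= ~bad

    # minor allele count
    _, mac = _maf_mac(G)
    bad = loc_keep & (mac < mac_min)
    report.add("mac", "loci", locus_ids[bad], mac_min)
    loc_keep &= ~bad

    # coverage window
    if coverage is not None:
        cov = np.asarray(coverage, dtype=float)
        bad = loc_keep & ((cov < coverage_range[0]) | (cov > coverage_range[1]))
        report.add("coverage", "loci", locus_ids[bad], coverage_range)
        loc_keep &= ~bad
    else:
        report.add("coverage", "loci", [], "skipped: no counts")

    # one SNP per fragment: keep max MAC, ties -> lower position/index
    if fragments is not None:
        frag = np.asarray(fragments)
        pos = (np.asarray(positions) if positions is not None
               else np.arange(n_loc0))
        drop_ids = []
        for f in pd.unique(frag[loc_keep]):
            members = np.nonzero(loc_keep & (frag == f))[0]
            if members.size <= 1:
                continue
            order = sorted(members, key=lambda j: (-mac[j], pos[j]))
            for j in order[1:]:
                loc_keep[j] = False
                drop_ids.append(locus_ids[j])
        report.add("one_snp_per_fragment", "loci", drop_ids, "max MAC")
    else:
        report.add("one_snp_per_fragment", "loci", [], "skipped: no fragments")

    # HWE across sampling populations
    if hwe_p is not None:
        if pops is None:
            raise ValueError("population labels required for the HWE filter")
        pops = np.asarray(pops)
        drop_ids = []
        for j in _lmask():
            n_viol = 0
            for pop in pd.unique(pops):
                pv = hwe_test(G[(pops == pop) & ind_keep, j], hwe_method)
                n_viol += pv < hwe_p
            if n_viol >= hwe_min_pops:
                loc_keep[j] = False
                drop_ids.append(locus_ids[j])
        report.add("hwe", "loci", drop_ids, f"p<{hwe_p} in >={hwe_min_pops} pops")

    Gs = G[:, loc_keep]

    # individual missingness outliers (upper tail)
    miss = np.isnan(Gs).mean(axis=1)
    bad = ind_keep & _upper_tail_outliers(miss)
    report.add("individual_missingness", "individuals",
               individual_ids[bad], "median + 3*MAD")
    ind_keep &= ~bad

    # individual heterozygosity: remove high outliers, flag low
    obs = ~np.isnan(Gs)
    het = np.where(obs.sum(axis=1) > 0,
                   (Gs == 1).sum(axis=1) / np.maximum(obs.sum(axis=1), 1), 0.0)
    bad = ind_keep & (het > het_max)
    report.add("individual_heterozygosity_high", "individuals",
               individual_ids[bad], het_max)
    ind_keep &= ~bad
    low = ind_keep & _lower_tail_outliers(het)
    if remove_low_het:
        report.add("individual_heterozygosity_low", "individuals",
                   individual_ids[low], "median - 3*MAD")
        ind_keep &= ~low
    else:
        report.add("individual_heterozygosity_low_flag", "individuals", [],
                   f"flagged only: {individual_ids[low].tolist()}")

    # duplicate resolution: identity over jointly observed sites
    act = np.nonzero(ind_keep)[0]
    Ga = Gs[act]
    obs = ~np.isnan(Ga)
    drop_ids = []
    if act.size > 1 and Gs.shape[1] > 0:
        eq_counts = np.zeros((act.size, act.size))
        joint = obs.astype(float) @ obs.astype(float).T
        for g in (0.0, 1.0, 2.0):
            ind = ((Ga == g) & obs).astype(float)
            eq_counts += ind @ ind.T
        with np.errstate(invalid="ignore", divide="ignore"):
            identity = np.where(joint > 0, eq_counts / np.maximum(joint, 1), 0.0)
        np.fill_diagonal(identity, 0.0)
        miss_a = np.isnan(Ga).mean(axis=1)
        order = np.argsort(miss_a, kind="stable")  # keep least-missing first
        kept_local = np.ones(act.size, dtype=bool)
        for i in order:
            if not kept_local[i]:
                continue
            dups = np.nonzero((identity[i] >= dup_identity) & kept_local)[0]
            for j in dups:
                if j != i:
                    kept_local[j] = False
                    drop_ids.append(individual_ids[act[j]])
        ind_keep[act[~kept_local]] = False
    report.add("duplicates", "individuals", drop_ids, dup_identity)

    out = G[np.ix_(ind_keep, loc_keep)]
    report.surviving_loci = locus_ids[loc_keep]
    report.surviving_individuals = individual_ids[ind_keep]
    return out, report


def _maf_mac(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    obs = ~np.isnan(G)
    n_obs = obs.sum(axis=0)
    alt = np.nansum(G, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, alt / np.maximum(2.0 * n_obs, 1), 0.0)
    return np.minimum(p, 1 - p), np.minimum(alt, 2 * n_obs - alt)


def generate_readcount_fixture(n_ind: int = 200, n_loci: int = 1000,
                               planted_defects: dict[str, int] | None = None,
                               seed: int = 0, n_pops: int = 4,
                               mean_depth: float = 40.0,
                               ) -> tuple[ReadCountMatrix, dict[str, np.ndarray]]:
    """Synthetic two-row count matrix with optional planted QC violations.

    ``planted_defects`` maps defect class to a count; supported classes:
    ``low_depth`` and ``imbalance`` loci (caught by the pilot QC),
    ``hwe`` loci (heterozygote excess in every population, caught by the
    cascade HWE filter), ``excess_null`` individuals (high null rates,
    caught by the composite het-null outlier step) and ``duplicate``
    individuals (caught by duplicate resolution).  Returns the matrix and
    a truth dict of planted ids per class.
    """
    planted = dict(planted_defects or {})
    rng = np.random.default_rng(seed)
    pops = np.repeat(np.arange(n_pops), int(np.ceil(n_ind / n_pops)))[:n_ind]
    # skewed MAF spectrum (mean H_E ~ 0.29, as in reduced-representation
    # panels after MAF filtering), random reference orientation
    p_anc = 0.08 + 0.42 * rng.beta(0.8, 2.2, size=n_loci)
    flip = rng.random(n_loci) < 0.5
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)
    p_pop = np.clip(p_anc[None, :] +
                    rng.normal(0, 0.05, size=(n_pops, n_loci)), 0.02, 0.98)

    geno = np.empty((n_loci, n_ind), dtype=np.int8)
    for k in range(n_pops):
        sel = pops == k
        geno[:, sel] = rng.binomial(
            2, p_pop[k][:, None], size=(n_loci, int(sel.sum()))).astype(np.int8)

    truth: dict[str, np.ndarray] = {}
    locus_ids = np.array([f"L{i:05d}" for i in range(n_loci)])
    ind_ids = np.array([f"I{i:04d}" for i in range(n_ind)])
    avail = rng.permutation(n_loci)
    cursor = 0

    def take_loci(k):
        nonlocal cursor
        sel = avail[cursor:cursor + k]
        cursor += k
        return np.sort(sel)

    low_depth = take_loci(planted.get("low_depth", 0))
    imbalance = take_loci(planted.get("imbalance", 0))
    hwe_loci = take_loci(planted.get("hwe", 0))
    truth["low_depth"] = locus_ids[low_depth]
    truth["imbalance"] = locus_ids[imbalance]
    truth["hwe"] = locus_ids[hwe_loci]
    geno[hwe_loci, :] = 1                       # universal heterozygosity

    n_dup = planted.get("duplicate", 0)
    n_null = planted.get("excess_null", 0)
    ind_perm = rng.permutation(n_ind)
    null_inds = np.sort(ind_perm[:n_null])
    dup_targets = ind_perm[n_null:n_null + n_dup]     # copied over these
    dup_sources = ind_perm[n_null + n_dup:n_null + 2 * n_dup]
    geno[:, dup_targets] = geno[:, dup_sources]
    truth["excess_null"] = ind_ids[null_inds]
    truth["duplicate"] = ind_ids[np.sort(dup_targets)]

    depth_mean = np.full(n_loci, mean_depth)
    depth_mean[low_depth] = 8.0
    nb_n = 5.0
    depth = rng.negative_binomial(
        nb_n, nb_n / (nb_n + depth_mean)[:, None], size=(n_loci, n_ind))

    balance = np.full(n_loci, 0.5)
    balance[imbalance] = 0.82

    ref = np.zeros((n_loci, n_ind), dtype=np.int64)
    alt = np.zeros_like(ref)
    het = geno == 1
    ref[het] = rng.binomial(depth[het], np.broadcast_to(
        balance[:, None], depth.shape)[het])
    alt[het] = depth[het] - ref[het]
    hom0 = geno == 0
    err = rng.binomial(depth[hom0], 0.005)
    ref[hom0] = depth[hom0] - err
    alt[hom0] = err
    hom2 = geno == 2
    err = rng.binomial(depth[hom2], 0.005)
    alt[hom2] = depth[hom2] - err
    ref[hom2] = err

    # background dropout plus planted excess-null individuals
    null_rate = np.full(n_ind, 0.02)
    null_rate[null_inds] = 0.45
    null_mask = rng.random((n_loci, n_ind)) < null_rate[None, :]
    ref[null_mask] = 0
    alt[null_mask] = 0

    frag = np.array([f"F{i:05d}" for i in range(n_loci)])
    return (ReadCountMatrix(ref=ref, alt=alt, locus_ids=locus_ids,
                            individual_ids=ind_ids, fragments=frag,
                            pops=pops.astype(str)),
            truth)
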