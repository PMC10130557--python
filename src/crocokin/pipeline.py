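"""End-to-end workflows: the simulation study and the empirical pipeline.

The simulation study calibrates kin classification for datasets with a few
thousand SNPs: a grid of six scenarios (clutch Poisson(15) vs single
offspring, crossed with migration 1%, 0.1%, 0.01%) is simulated with
pedigree tracking, kinship statistics are estimated with the PC-AiR +
PC-Relate chain, pairs are classified by the Euclidean-center rule, the
Manichaikul criteria and a linear SVM trained on the designated training
replicates, and performance is scored on the held-out replicates against
pedigree truth.

The empirical pipeline runs the same estimation chain on real genotypes:
QC cascade, diversity and pairwise F_ST with the Mantel
isolation-by-distance test against coastal distance, kinship estimation
and classification, and a kin-pair report with pairwise distances
(straight-line within a region, along-coast between regions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .simulate import SimConfig, run_simulation, sample_individuals
from .pedigree import enumerate_kin, kin_census
from .kinship import site_filter, king_robust, pcair_partition, pcrelate
from .classify import (classify_euclidean, classify_manichaikul, train_svm,
                       SvmModel, evaluate)
from .dartqc import main_filter_cascade
from .popgen import (diversity_table, pairwise_fst, mantel_test,
                     coastal_distance, haversine_km, _project_along)

log = logging.getLogger(__name__)

__all__ = ["ScenarioGrid", "StudyResult", "run_simulation_study",
           "run_replicate", "EmpiricalResult", "run_empirical", "count_pairs"]

METHODS = ("svm", "euclidean", "manichaikul")


def count_pairs(n: int) -> int:
    """Number of unordered pairs among n individuals, n(n-1)/2."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * (n - 1) // 2


@dataclass
class ScenarioGrid:
    """Scenario grid and profile for the simulation study.

    The default is the desk-scale profile (K=250 per deme, 10 replicates
    per scenario with 3 for SVM training, 250 sampled per deme, 10 Mb
    genome with SFS-seeded founders); ``full_scale()`` restores the
    original profile (K=1500, 6000 generations, 50 replicates, 5 training).
    """

    migration_rates: tuple = (0.01, 0.001, 0.0001)
    clutch_lambdas: tuple = (15.0, None)
    n_replicates: int = 10
    train_replicates: int = 3
    n_sample_per_subpop: int = 250
    carrying_capacity: int = 250
    genome_length: int = 100_000_000
    n_founder_sites: int = 20_000
    n_generations: int = 150
    pedigree_window: int = 100
    maf_min: float = 0.05
    ld_r2: float = 0.1
    ld_window: int = 10
    n_pcs: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.train_replicates < self.n_replicates:
            raise ValueError("train_replicates must be < n_replicates")

    @classmethod
    def full_scale(cls, seed: int = 1) -> "ScenarioGrid":
        return cls(n_replicates=50, train_replicates=5,
                   carrying_capacity=1500, genome_length=100_000_000,
                   n_founder_sites=0, n_generations=6000,
                   ld_window=3000, seed=seed)

    def sim_config(self, clutch, m, seed: int) -> SimConfig:
        return SimConfig(carrying_capacity=self.carrying_capacity,
                         migration_rate=m, clutch_lambda=clutch,
                         genome_length=self.genome_length,
                         n_founder_sites=self.n_founder_sites,
                         n_generations=self.n_generations,
                         pedigree_window=self.pedigree_window,
                         seed=seed)

    def scenarios(self):
        for clutch in self.clutch_lambdas:
            for m in self.migration_rates:
                name = f"{'clutch' if clutch else 'noclutch'}_m{m:g}"
                yield name, clutch, m

    def config_hash(self) -> str:
        return hashlib.md5(json.dumps(asdict(self), sort_keys=True,
                                      default=str).encode()).hexdigest()[:12]


def _rep_seed(master: int, scen_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence([master, scen_idx, rep])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_replicate(config: SimConfig, n_sample_per_subpop: int,
                  maf_min: float = 0.05, ld_r2: float = 0.1,
                  ld_window: int = 100, n_pcs: int = 2,
                  clamp_sample: bool = True) -> pd.DataFrame:
    """One replicate: simulate, sample, estimate kinship, attach truth.

    Returns one row per unordered sampled pair with columns id_a, id_b,
    phi, k0, k2, n_sites, label (pedigree truth).  ``clamp_sample`` lowers
    the per-deme sample size to the final census when the census dips
    below the request (logged), which at desk scale happens routinely.
    """
    pedigree, pop = run_simulation(config)
    rng = np.random.default_rng(config.seed + 977)
    n_req = n_sample_per_subpop
    census = pop.census(config.n_subpops)
    if clamp_sample and census.min() < n_req:
        n_req = int(census.min())
        log.info("sample size clamped to %d (census %s)", n_req, census)
    sample = sample_individuals(pop, n_req, rng)
    order = np.argsort(sample.ids, kind="stable")
    ids = sample.ids[order]
    G = sample.genotypes[order].astype(float)

    truth = enumerate_kin(pedigree, ids)
    keep = site_filter(G, maf_min=maf_min, ld_r2=ld_r2, window=ld_window)
    Gf = G[:, keep]
    kin = king_robust(Gf)
    part = pcair_partition(Gf, kin, n_pcs=n_pcs)
    triples = pcrelate(Gf, part.pcs, part.unrelated, ids=ids)
    if not (triples["id_a"].to_numpy() == truth["id_a"].to_numpy()).all():
        raise AssertionError("pair enumeration mismatch between kinship "
                             "and truth tables")
    triples["label"] = truth["label"].to_numpy()
    return triples


@dataclass
class StudyResult:
    replicate_metrics: pd.DataFrame   # scenario, clutch, m, replicate, method, f1
    summary: dict
    svm: SvmModel
    kin_counts: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def run_simulation_study(grid: ScenarioGrid,
                         out_dir: Optional[str] = None) -> StudyResult:
    """Run the scenario grid end to end and score the three classifiers.

    The SVM is trained once on the first ``train_replicates`` replicates
    of every scenario and evaluated, like the other two methods, only on
    the held-out replicates.  FSP is excluded from macro averaging in the
    no-clutch scenarios, where true full siblings are vanishingly rare.
    Failed replicates are logged and skipped; their count is reported.
    """
    train_X, train_y = [], []
    test_store = []      # (scenario, clutch, m, rep, X float32, labels)
    kin_rows = []
    n_failed = 0
    for scen_idx, (name, clutch, m) in enumerate(grid.scenarios()):
        for rep in range(grid.n_replicates):
            cfg = grid.sim_config(clutch, m, _rep_seed(grid.seed, scen_idx, rep))
            try:
                tr = run_replicate(cfg, grid.n_sample_per_subpop,
                                   maf_min=grid.maf_min, ld_r2=grid.ld_r2,
                                   ld_window=grid.ld_window, n_pcs=grid.n_pcs)
            except Exception:
                log.exception("replicate failed: %s rep %d", name, rep)
                n_failed += 1
                continue
            X = tr[["phi", "k0", "k2"]].to_numpy(dtype=np.float32)
            y = tr["label"].to_numpy()
            counts = kin_census(tr)
            counts.update(scenario=name, clutch=bool(clutch), m=m,
                          replicate=rep)
            kin_rows.append(counts)
            if rep < grid.train_replicates:
                train_X.append(X)
                train_y.append(y)
            else:
                test_store.append((name, clutch, m, rep, X, y))
            log.info("replicate done: %s rep %d (%d pairs)", name, rep, len(tr))

    if not train_X or not test_store:
        raise RuntimeError("simulation study produced no usable replicates")
    svm = train_svm(np.concatenate(train_X), np.concatenate(train_y),
                    seed=grid.seed % (2 ** 31),
                    training_meta={"scenarios": [s for s, *_ in
                                                 [(n, c, m) for n, c, m in
                                                  grid.scenarios()]],
                                   "train_replicates": grid.train_replicates,
                                   "config_hash": grid.config_hash()})

    rows = []
    pop_conf = {"TP": 0, "FP": 0}
    for name, clutch, m, rep, X, y in test_store:
        preds = {"euclidean": classify_euclidean(X),
                 "manichaikul": classify_manichaikul(X),
                 "svm": svm.predict(X)}
        present = [c for c in ("POP", "FSP", "DEG2", "U") if c in set(y)]
        classes = [c for c in present if clutch or c != "FSP"]
        for method, p in preds.items():
            mt = evaluate(p, y, classes=classes)
            rows.append(dict(scenario=name, clutch=bool(clutch), m=m,
                             replicate=rep, method=method,
                             f1_macro=mt.f1_macro,
                             precision_macro=mt.precision_macro,
                             recall_macro=mt.recall_macro, n_pairs=len(y)))
        if clutch:
            is_pop_pred = preds["svm"] == "POP"
            pop_conf["TP"] += int((is_pop_pred & (y == "POP")).sum())
            pop_conf["FP"] += int((is_pop_pred & (y != "POP")).sum())

    metrics = pd.DataFrame(rows)
    f1 = metrics.groupby("method")["f1_macro"].mean()
    denom = pop_conf["TP"] + pop_conf["FP"]
    pop_fdr = 100.0 * pop_conf["FP"] / denom if denom else float("nan")
    summary = {
        "f1_macro": {meth: float(f1[meth]) for meth in METHODS},
        "per_scenario_f1": {
            meth: metrics[metrics.method == meth]
            .groupby("scenario")["f1_macro"].mean().to_dict()
            for meth in METHODS},
        "pop_fdr_svm_clutch_pct": float(pop_fdr),
        "n_failed_replicates": n_failed,
        "n_test_replicates": len(test_store),
    }
    prov = {"config_hash": grid.config_hash(), "seed": grid.seed,
            "version": __version__}
    result = StudyResult(replicate_metrics=metrics, summary=summary, svm=svm,
                         kin_counts=pd.DataFrame(kin_rows), provenance=prov)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.assign(**prov).to_csv(out / "replicate_metrics.tsv",
                                      sep="\t", index=False)
        result.kin_counts.to_csv(out / "kin_counts.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump({"summary": summary, "provenance": prov}, fh, indent=2)
        import joblib
        joblib.dump(svm, out / "svm_model.joblib")
    return result


@dataclass
class EmpiricalResult:
    diversity: pd.DataFrame
    fst: object
    mantel: Optional[tuple]
    kin_pairs: pd.DataFrame          # one row per classified kin pair
    triples: pd.DataFrame
    qc_report: object
    frac_kin_within_threshold: float
    provenance: dict = field(default_factory=dict)


def run_empirical(G, ids, groups, coords=None, coastline=None,
                  svm_model: Optional[SvmModel] = None,
                  run_qc: bool = True, qc_kwargs: Optional[dict] = None,
                  maf_min: float = 0.05, ld_r2: float = 0.1,
                  ld_window: int = 3000, n_pcs: int = 10,
                  n_boot_fst: int = 1000, n_perm_mantel: int = 999,
                  dist_threshold_km: float = 50.0,
                  seed: int = 0) -> EmpiricalResult:
    """Empirical-style pipeline: QC, popgen summaries, kinship, kin report.

    ``coords`` is an (n, 2) lon/lat array aligned to ``ids`` (rows of NaN
    are excluded from distance summaries, warned).  Kin labels come from
    the Manichaikul criteria and, when ``svm_model`` is given, the SVM
    (which then drives the kin-pair report, mirroring the all-scenario
    classifier choice).
    """
    G = np.asarray(G, dtype=float)
    ids = np.asarray(ids)
    groups = np.asarray(groups)
    coords = None if coords is None else np.asarray(coords, dtype=float)

    qc_report = None
    if run_qc:
        kw = dict(qc_kwargs or {})
        kw.setdefault("pops", groups)
        Gq, qc_report = main_filter_cascade(G, locus_ids=np.arange(G.shape[1]),
                                            individual_ids=ids, **kw)
        ind_mask = np.isin(ids, qc_report.surviving_individuals)
        loc_idx = np.asarray(qc_report.surviving_loci)
        G = G[np.ix_(ind_mask, loc_idx)]
        ids, groups = ids[ind_mask], groups[ind_mask]
        coords = coords[ind_mask] if coords is not None else None

    diversity = diversity_table(G, groups, seed=seed)
    fst = pairwise_fst(G, groups, n_boot=n_boot_fst, seed=seed)

    mantel = None
    if coastline is not None and coords is not None:
        labels = list(fst.theta.index)
        if len(labels) >= 4:
            cent = np.array([np.nanmean(coords[groups == lab], axis=0)
                             for lab in labels])
            d_geo = coastal_distance(coastline, cent, cent, mode="coastal")
            mantel = mantel_test(fst.linearized.to_numpy(), d_geo,
                                 n_perm=n_perm_mantel, seed=seed)
        else:
            log.warning("fewer than 4 groups: Mantel test skipped")

    order = np.argsort(ids, kind="stable")
    G, ids, groups = G[order], ids[order], groups[order]
    coords = coords[order] if coords is not None else None
    keep = site_filter(G, maf_min=maf_min, ld_r2=ld_r2, window=ld_window)
    Gf = G[:, keep]
    kin = king_robust(Gf)
    part = pcair_partition(Gf, kin, n_pcs=n_pcs)
    triples = pcrelate(Gf, part.pcs, part.unrelated, ids=ids)
    triples["label_manichaikul"] = classify_manichaikul(triples)
    triples["label_euclidean"] = classify_euclidean(triples)
    report_col = "label_manichaikul"
    if svm_model is not None:
        triples["label_svm"] = svm_model.predict(triples)
        report_col = "label_svm"

    kin_pairs = triples[triples[report_col] != "U"].copy()
    frac = float("nan")
    if len(kin_pairs) and coords is not None:
        pos = pd.DataFrame({"group": groups,
                            "lon": coords[:, 0], "lat": coords[:, 1]},
                           index=pd.Index(ids))
        a = pos.loc[kin_pairs["id_a"]]
        b = pos.loc[kin_pairs["id_b"]]
        has_xy = (~a[["lon", "lat"]].isna().any(axis=1).to_numpy()
                  & ~b[["lon", "lat"]].isna().any(axis=1).to_numpy())
        if not has_xy.all():
            log.warning("%d kin pairs lack coordinates; excluded from "
                        "distance summaries", int((~has_xy).sum()))
        same = (a["group"].to_numpy() == b["group"].to_numpy())
        dist = np.full(len(kin_pairs), np.nan)
        sw = same & has_xy
        dist[sw] = haversine_km(a["lon"].to_numpy()[sw], a["lat"].to_numpy()[sw],
                                b["lon"].to_numpy()[sw], b["lat"].to_numpy()[sw])
        bw = (~same) & has_xy
        if bw.any() and coastline is not None:
            sa = _project_along(coastline,
                                np.column_stack([a["lon"].to_numpy()[bw],
                                                 a["lat"].to_numpy()[bw]]))
            sb = _project_along(coastline,
                                np.column_stack([b["lon"].to_numpy()[bw],
                                                 b["lat"].to_numpy()[bw]]))
            dist[bw] = np.abs(sa - sb)
        elif bw.any():
            dist[bw] = haversine_km(a["lon"].to_numpy()[bw], a["lat"].to_numpy()[bw],
                                    b["lon"].to_numpy()[bw], b["lat"].to_numpy()[bw])
        kin_pairs["distance_km"] = dist
        kin_pairs["same_group"] = same
        ok = np.isfinite(dist)
        if ok.any():
            frac = float((dist[ok] <= dist_threshold_km).mean())
    elif len(kin_pairs) == 0:
        log.info("no kin pairs classified; distance summary omitted")

    prov = {"seed": seed, "version": __version__,
            "n_individuals": int(len(ids)), "n_sites": int(Gf.shape[1])}
    return EmpiricalResult(diversity=diversity, fst=fst, mantel=mantel,
                           kin_pairs=kin_pairs, triples=triples,
                           qc_report=qc_report,
                           frac_kin_within_threshold=frac, provenance=prov)
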