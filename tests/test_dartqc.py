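import numpy as np
import pytest

from crocokin import (ReadCountMatrix, FourWay, pilot_qc_and_score,
                      main_filter_cascade, generate_readcount_fixture,
                      calls_to_genotypes, hwe_test)
from crocokin.dartqc import score_four_way


# ---------------------------------------------------------------------------
# four-way scoring

@pytest.mark.parametrize("ref,alt,want", [
    (30, 10, FourWay.AB),       # alt proportion 0.25 >= 0.05
    (39, 1, FourWay.AA_A0),     # alt proportion 0.025 < 0.05
    (1, 39, FourWay.BB_B0),
    (0, 0, FourWay.NULL00),
    (19, 1, FourWay.AB),        # alt proportion exactly 0.05
])
def test_four_way_threshold_arithmetic(ref, alt, want):
    calls = score_four_way(np.array([[ref]]), np.array([[alt]]))
    assert calls[0, 0] == want


def test_four_way_scoring_is_total():
    rng = np.random.default_rng(0)
    ref = rng.integers(0, 50, size=(30, 20))
    alt = rng.integers(0, 50, size=(30, 20))
    calls = score_four_way(ref, alt)
    assert np.isin(calls, [FourWay.AB, FourWay.AA_A0, FourWay.BB_B0,
                           FourWay.NULL00]).all()


def test_calls_to_genotypes_mapping():
    calls = np.array([[FourWay.AB, FourWay.AA_A0],
                      [FourWay.BB_B0, FourWay.NULL00]], dtype=np.int8)
    G = calls_to_genotypes(calls)     # individuals x loci
    assert G.shape == (2, 2)
    assert G[0, 0] == 1 and G[0, 1] == 2
    assert G[1, 0] == 0 and np.isnan(G[1, 1])


# ---------------------------------------------------------------------------
# pilot QC

def test_zero_count_locus_removed_at_depth_step():
    counts, _ = generate_readcount_fixture(n_ind=60, n_loci=40, seed=1)
    counts.ref[3, :] = 0
    counts.alt[3, :] = 0
    calls, kept, report = pilot_qc_and_score(counts)
    assert counts.locus_ids[3] not in kept
    step = report.steps[0]
    assert step["step"] == "het_median_depth"
    assert counts.locus_ids[3] in step["removed"]


def test_pilot_qc_removes_exactly_planted_depth_and_balance_defects():
    counts, truth = generate_readcount_fixture(
        n_ind=150, n_loci=400, seed=2,
        planted_defects={"low_depth": 20, "imbalance": 10})
    calls, kept, report = pilot_qc_and_score(counts)
    removed_depth = set(report.steps[0]["removed"])
    removed_bal = set(report.steps[1]["removed"])
    assert removed_depth == set(truth["low_depth"])
    assert removed_bal == set(truth["imbalance"])


def test_pilot_flags_excess_null_individuals():
    counts, truth = generate_readcount_fixture(
        n_ind=150, n_loci=300, seed=3, planted_defects={"excess_null": 5})
    calls, kept, report = pilot_qc_and_score(counts)
    step = [s for s in report.steps if s["step"] == "composite_het_minus_null"][0]
    assert set(truth["excess_null"]) <= set(step["removed"])


def test_pilot_empty_matrix_raises():
    with pytest.raises(ValueError):
        pilot_qc_and_score(ReadCountMatrix(
            ref=np.empty((0, 0), dtype=int), alt=np.empty((0, 0), dtype=int),
            locus_ids=np.array([]), individual_ids=np.array([])))


# ---------------------------------------------------------------------------
# HWE test

def test_hwe_conforming_locus_not_rejected():
    rng = np.random.default_rng(4)
    g = rng.binomial(2, 0.4, size=200).astype(float)
    assert hwe_test(g, "chisq") > 1e-3
    assert hwe_test(g, "exact") > 1e-3


def test_hwe_all_heterozygote_locus_rejected():
    g = np.ones(100)
    assert hwe_test(g, "chisq") < 1e-6
    assert hwe_test(g, "exact") < 1e-6


def test_hwe_exact_matches_chisq_order_of_magnitude():
    rng = np.random.default_rng(5)
    g = np.concatenate([np.zeros(40), np.ones(10), 2 * np.ones(40)])
    p_chi, p_ex = hwe_test(g, "chisq"), hwe_test(g, "exact")
    assert p_chi < 0.001 and p_ex < 0.001


# ---------------------------------------------------------------------------
# main cascade

def _genotypes(n=120, m=60, seed=6, n_pops=4):
    counts, _ = generate_readcount_fixture(n_ind=n, n_loci=m, seed=seed,
                                           n_pops=n_pops)
    calls = score_four_way(counts.ref, counts.alt)
    return calls_to_genotypes(calls), counts


def test_low_call_rate_snp_removed():
    G, counts = _genotypes()
    G[: int(0.8 * G.shape[0]), 5] = np.nan   # typed in ~20% of individuals
    out, report = main_filter_cascade(G, pops=counts.pops)
    step = [s for s in report.steps if s["step"] == "call_rate"][0]
    assert 5 in step["removed"]


def test_duplicate_resolution_keeps_less_missing_member():
    G, counts = _genotypes()
    G[11] = G[10]
    G[11, :1] = np.nan           # the copy is (slightly) more missing
    out, report = main_filter_cascade(G, pops=counts.pops, het_max=1.0)
    step = [s for s in report.steps if s["step"] == "duplicates"][0]
    assert 11 in step["removed"] and 10 not in step["removed"]


def test_one_snp_per_fragment_keeps_highest_mac():
    G, counts = _genotypes()
    frag = np.array([f"F{i // 2}" for i in range(G.shape[1])])
    out, report = main_filter_cascade(G, pops=counts.pops, fragments=frag)
    kept = set(report.surviving_loci)
    for f in set(frag):
        members = [j for j in range(G.shape[1]) if frag[j] == f]
        assert len(kept & set(members)) <= 1


def test_hwe_violating_loci_removed_in_enough_populations():
    G, counts = _genotypes()
    G[:, 7] = 1.0                 # heterozygous everywhere: out of HWE in all pops
    out, report = main_filter_cascade(G, pops=counts.pops)
    step = [s for s in report.steps if s["step"] == "hwe"][0]
    assert 7 in step["removed"]


def test_missing_pops_with_hwe_enabled_raises():
    G, _ = _genotypes()
    with pytest.raises(ValueError):
        main_filter_cascade(G, pops=None)


def test_filter_report_conserves_counts():
    counts, truth = generate_readcount_fixture(
        n_ind=150, n_loci=300, seed=7,
        planted_defects={"hwe": 8, "duplicate": 4})
    calls = score_four_way(counts.ref, counts.alt)
    G = calls_to_genotypes(calls)
    out, report = main_filter_cascade(G, locus_ids=counts.locus_ids,
                                      individual_ids=counts.individual_ids,
                                      pops=counts.pops)
    for axis, n_in, n_out in (("loci", G.shape[1], out.shape[1]),
                              ("individuals", G.shape[0], out.shape[0])):
        removed = sum(s["n_removed"] for s in report.steps
                      if s["axis"] == axis and "flag" not in s["step"])
        assert n_in - removed == n_out


def test_locus_filters_invariant_to_individual_order():
    counts, _ = generate_readcount_fixture(n_ind=100, n_loci=120, seed=8)
    calls = score_four_way(counts.ref, counts.alt)
    G = calls_to_genotypes(calls)
    out1, rep1 = main_filter_cascade(G, pops=counts.pops)
    perm = np.random.default_rng(0).permutation(G.shape[0])
    out2, rep2 = main_filter_cascade(G[perm], pops=counts.pops[perm])
    assert set(rep1.surviving_loci) == set(rep2.surviving_loci)


def test_cascade_recovers_planted_defects():
    counts, truth = generate_readcount_fixture(
        n_ind=200, n_loci=1000, seed=9,
        planted_defects={"low_depth": 20, "imbalance": 10, "hwe": 10,
                         "excess_null": 5, "duplicate": 5})
    calls, kept, pilot = pilot_qc_and_score(counts)
    G = calls_to_genotypes(calls)
    keep_mask = np.isin(counts.locus_ids, kept)
    pop_kept = counts.pops[np.isin(counts.individual_ids,
                                   pilot.surviving_individuals)]
    out, report = main_filter_cascade(
        G, locus_ids=kept,
        individual_ids=pilot.surviving_individuals, pops=pop_kept)
    removed_loci = set()
    removed_inds = set()
    for s in pilot.steps + report.steps:
        if "flag" in s["step"]:
            continue
        (removed_loci if s["axis"] == "loci" else removed_inds).update(
            map(str, s["removed"]))
    planted_loci = set(map(str, truth["low_depth"])) \
        | set(map(str, truth["imbalance"])) | set(map(str, truth["hwe"]))
    planted_inds = set(map(str, truth["excess_null"])) \
        | set(map(str, truth["duplicate"]))
    recall = (len(planted_loci & removed_loci) + len(planted_inds & removed_inds)) \
        / (len(planted_loci) + len(planted_inds))
    assert recall >= 0.9


def test_fixture_deterministic():
    a, _ = generate_readcount_fixture(n_ind=30, n_loci=40, seed=11)
    b, _ = generate_readcount_fixture(n_ind=30, n_loci=40, seed=11)
    assert np.array_equal(a.ref, b.ref) and np.array_equal(a.alt, b.alt)
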