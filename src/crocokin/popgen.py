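"""Per-group diversity indices, Weir-Cockerham F_ST with bootstrap
significance, coastal-distance computation, and the Mantel
isolation-by-distance test.

Diversity per group: observed heterozygosity H_O (mean fraction of
heterozygous calls), unbiased expected heterozygosity uH_E
(2p(1-p) * 2n/(2n-1) per locus, averaged), allelic richness A_r by
hypergeometric rarefaction to the smallest group's allele count, and
F_IS = 1 - H_O/uH_E aggregated over loci, with locus-bootstrap confidence
intervals.

Pairwise differentiation uses the Weir & Cockerham (1984) theta
variance-components estimator aggregated over loci as a ratio of sums,
with one-sided locus-bootstrap p-values (fraction of resampled theta <= 0,
add-one smoothed) and Benjamini-Hochberg FDR control across pairs.
Slatkin's linearization theta/(1-theta) feeds the Mantel test against
along-coast geographic distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = ["diversity_table", "weir_cockerham_theta", "pairwise_fst",
           "slatkin_linearized", "coastal_distance", "haversine_km",
           "mantel_test", "FstResult"]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# diversity

def _uhe_per_locus(G: np.ndarray) -> np.ndarray:
    """Unbiased expected heterozygosity 2p(1-p)*2n/(2n-1) per locus."""
    obs = ~np.isnan(G)
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(G, axis=0) / (2.0 * np.maximum(n, 1))
        uhe = 2.0 * p * (1.0 - p) * (2.0 * n) / np.maximum(2.0 * n - 1.0, 1.0)
    return np.where(n > 0, uhe, np.nan)


def _rarefied_richness(G: np.ndarray, g: int) -> np.ndarray:
    """Expected allele count per locus in a random draw of g allele copies."""
    obs = ~np.isnan(G)
    n2 = 2.0 * obs.sum(axis=0)
    alt = np.nansum(G, axis=0)
    counts = np.stack([n2 - alt, alt])           # ref copies, alt copies
    with np.errstate(invalid="ignore"):
        ar = np.zeros(G.shape[1])
        for a in counts:
            # P(allele present in draw) = 1 - C(n2-a, g)/C(n2, g)
            with np.errstate(divide="ignore", invalid="ignore"):
                from scipy.special import gammaln
                logc = (gammaln(n2 - a + 1) - gammaln(g + 1)
                        - gammaln(n2 - a - g + 1)
                        - (gammaln(n2 + 1) - gammaln(g + 1) - gammaln(n2 - g + 1)))
            pr_absent = np.where(n2 - a >= g, np.exp(logc), 0.0)
            ar += np.where(a > 0, 1.0 - pr_absent, 0.0)
    return np.where(n2 >= g, ar, np.nan)


def diversity_table(G, groups, n_boot: int = 200, seed: int = 0,
                    ci: float = 0.95) -> pd.DataFrame:
    """Diversity indices per group; rows indexed by group label.

    Columns: N, M0 (monomorphic loci), maf_lt_1pct, Ar, Ho, uHe, Fis and
    the bootstrap CI bounds for Fis.  Fis is reported as NaN when uHe is 0
    (all loci monomorphic in the group).
    """
    G = np.asarray(G, dtype=float)
    groups = np.asarray(groups)
    if G.shape[0] == 0 or groups.size != G.shape[0]:
        raise ValueError("need one group label per individual, n >= 1")
    labels = pd.unique(groups)
    sizes = {lab: int((groups == lab).sum()) for lab in labels}
    g_rare = 2 * min(sizes.values())
    rng = np.random.default_rng(seed)
    rows = {}
    alpha = (1.0 - ci) / 2.0
    for lab in labels:
        Gg = G[groups == lab]
        obs = ~np.isnan(Gg)
        n_loci = Gg.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(Gg, axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))
        mono = int(((p == 0) | (p == 1)).sum())
        maf = np.minimum(p, 1 - p)
        ho_loc = np.where(obs.sum(axis=0) > 0,
                          (Gg == 1).sum(axis=0) / np.maximum(obs.sum(axis=0), 1),
                          np.nan)
        uhe_loc = _uhe_per_locus(Gg)
        ar = np.nanmean(_rarefied_richness(Gg, g_rare))
        ho, uhe = float(np.nanmean(ho_loc)), float(np.nanmean(uhe_loc))
        fis = 1.0 - ho / uhe if uhe > 0 else np.nan
        # locus bootstrap for Fis CI
        if uhe > 0 and n_boot > 0:
            idx = rng.integers(0, n_loci, size=(n_boot, n_loci))
            ho_b = np.nanmean(ho_loc[idx], axis=1)
            uhe_b = np.nanmean(uhe_loc[idx], axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                fis_b = 1.0 - ho_b / uhe_b
            lo_ci, hi_ci = np.nanquantile(fis_b, [alpha, 1 - alpha])
        else:
            lo_ci = hi_ci = np.nan
        rows[lab] = dict(N=sizes[lab], M0=mono,
                         maf_lt_1pct=int((maf < 0.01).sum()),
                         Ar=float(ar), Ho=ho, uHe=uhe, Fis=fis,
                         Fis_ci_lo=float(lo_ci), Fis_ci_hi=float(hi_ci))
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Weir-Cockerham theta

def _wc_components(G_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components a, b, c.

    ``G_list`` holds one (n_i x m) genotype matrix per population; alleles
    are bi-allelic dosages with NaN missing.
    """
    r = len(G_list)
    m = G_list[0].shape[1]
    n_i = np.stack([(~np.isnan(Gi)).sum(axis=0).astype(float) for Gi in G_list])
    p_i = np.stack([
        np.where(n > 0, np.nansum(Gi, axis=0) / (2 * np.maximum(n, 1)), 0.0)
        for Gi, n in zip(G_list, n_i)])
    h_i = np.stack([
        np.where(n > 0, (Gi == 1).sum(axis=0) / np.maximum(n, 1), 0.0)
        for Gi, n in zip(G_list, n_i)])

    n_bar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n_i ** 2).sum(axis=0) / (r * n_bar)) / (r - 1.0)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (p_bar * (1 - p_bar)
                                       - (r - 1.0) / r * s2
                                       - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2.0
    valid = (n_i > 0).all(axis=0) & (n_bar > 1)
    return (np.where(valid, a, np.nan), np.where(valid, b, np.nan),
            np.where(valid, c, np.nan))


def weir_cockerham_theta(G_list: list[np.ndarray]) -> float:
    """Multi-locus theta as the ratio of summed components sum(a)/sum(a+b+c)."""
    a, b, c = _wc_components(G_list)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if den == 0 or not np.isfinite(den):
        return np.nan
    return float(num / den)


def slatkin_linearized(theta) -> np.ndarray:
    """Slatkin's linearization theta/(1-theta); monotone for theta < 1."""
    theta = np.asarray(theta, dtype=float)
    return theta / (1.0 - theta)


@dataclass
class FstResult:
    theta: pd.DataFrame        # symmetric, zero diagonal
    p_values: pd.DataFrame
    significant: pd.DataFrame  # after BH FDR
    linearized: pd.DataFrame


def pairwise_fst(G, groups, n_boot: int = 1000, seed: int = 0,
                 fdr: float = 0.05) -> FstResult:
    """Pairwise Weir-Cockerham theta between groups with locus-bootstrap
    one-sided p-values and Benjamini-Hochberg adjustment across pairs."""
    G = np.asarray(G, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 individuals")
    k = len(labels)
    rng = np.random.default_rng(seed)
    theta = np.zeros((k, k))
    pval = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            Gi, Gj = G[groups == labels[i]], G[groups == labels[j]]
            a, b, c = _wc_components([Gi, Gj])
            ok = np.isfinite(a + b + c)
            a, b, c = a[ok], b[ok], c[ok]
            if a.size == 0:
                log.warning("no informative loci for pair (%s, %s)",
                            labels[i], labels[j])
                theta[i, j] = theta[j, i] = np.nan
                continue
            den = (a + b + c).sum()
            t = a.sum() / den if den != 0 else np.nan
            theta[i, j] = theta[j, i] = t
            if n_boot:
                idx = rng.integers(0, a.size, size=(n_boot, a.size))
                num_b = a[idx].sum(axis=1)
                den_b = (a + b + c)[idx].sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    t_b = np.where(den_b != 0, num_b / den_b, 0.0)
                p = (1.0 + (t_b <= 0).sum()) / (1.0 + n_boot)
                pval[i, j] = pval[j, i] = p
    iu = np.triu_indices(k, 1)
    finite = np.isfinite(theta[iu])
    sig = np.zeros((k, k), dtype=bool)
    if finite.any():
        rej = multipletests(pval[iu][finite], alpha=fdr, method="fdr_bh")[0]
        flat = np.zeros(iu[0].size, dtype=bool)
        flat[finite] = rej
        sig[iu] = flat
        sig |= sig.T
    as_df = lambda M: pd.DataFrame(M, index=labels, columns=labels)
    return FstResult(theta=as_df(theta), p_values=as_df(pval),
                     significant=as_df(sig),
                     linearized=as_df(slatkin_linearized(theta)))


# ---------------------------------------------------------------------------
# geographic distance

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (spherical Earth, R = 6371 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, map(np.asarray, (lon1, lat1, lon2, lat2)))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _project_along(polyline: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Along-polyline arc position (km) of each point's nearest projection.

    The perpendicular foot is computed in a local equirectangular frame
    (longitude scaled by cos(mean latitude)); segment arc lengths use the
    haversine formula.  Adequate at the scale of a coastline in degrees.
    """
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
        raise ValueError("polyline must be an ordered (n>=2, 2) lon/lat array")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lat0 = np.radians(poly[:, 1].mean())
    scale = np.cos(lat0)
    P = np.column_stack([poly[:, 0] * scale, poly[:, 1]])
    X = np.column_stack([pts[:, 0] * scale, pts[:, 1]])
    seg_len = haversine_km(poly[:-1, 0], poly[:-1, 1], poly[1:, 0], poly[1:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    A, B = P[:-1], P[1:]
    AB = B - A
    denom = (AB ** 2).sum(axis=1)
    out = np.empty(X.shape[0])
    for i, x in enumerate(X):
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom > 0, ((x - A) * AB).sum(axis=1) / np.maximum(denom, 1e-300), 0.0)
        t = np.clip(t, 0.0, 1.0)
        foot = A + t[:, None] * AB
        d2 = ((x - foot) ** 2).sum(axis=1)
        s = int(np.argmin(d2))
        out[i] = cum[s] + t[s] * seg_len[s]
    return out


def coastal_distance(polyline, points_a, points_b,
                     mode: str = "coastal") -> np.ndarray:
    """Pairwise distance (km) between two point sets (lon/lat, degrees).

    ``coastal``: each point is projected to its nearest position on the
    polyline and the distance is the difference in along-coast arc length.
    ``within-group``: plain great-circle point-to-point distance (the
    convention for pairs inside one region).
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if mode == "within-group":
        return haversine_km(a[:, None, 0], a[:, None, 1],
                            b[None, :, 0], b[None, :, 1])
    if mode != "coastal":
        raise ValueError("mode must be 'coastal' or 'within-group'")
    sa = _project_along(polyline, a)
    sb = _project_along(polyline, b)
    return np.abs(sa[:, None] - sb[None, :])


# ---------------------------------------------------------------------------
# Mantel test

def mantel_test(d_gen, d_geo, n_perm: int = 999,
                seed: int = 0) -> tuple[float, float]:
    """Standard Mantel test: Pearson r of lower-triangle distances; p by
    joint row/column permutation of one matrix, add-one smoothed."""
    A = np.asarray(d_gen, dtype=float)
    B = np.asarray(d_geo, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = A.shape[0]
    if n < 4:
        raise ValueError("need at least 4 items for a Mantel test")
    if not (np.allclose(A, A.T, equal_nan=True) and np.allclose(B, B.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")
    il = np.tril_indices(n, -1)
    x, y = A[il], B[il]
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = A[np.ix_(perm, perm)][il]
        if float(stats.pearsonr(xp, y)[0]) >= r_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return r_obs, p
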