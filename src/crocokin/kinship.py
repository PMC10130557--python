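"""Structure-robust kinship estimation from SNP genotypes.

The estimation chain mirrors the standard workflow for relatedness
inference in structured populations:

1. ``site_filter`` — greedy windowed LD pruning (squared Pearson
   correlation of genotype dosages) followed by a MAF filter.
2. ``king_robust`` — the KING-robust pairwise kinship moment estimator,
   robust to allele-frequency misspecification but not to structure.
3. ``pcair_partition`` — a kinship-greedy partition of the sample into a
   mutually-unrelated set and a related set, with principal components
   computed on the unrelated set and related individuals projected onto
   them (the PC-AiR idea, without the divergence-weighting machinery).
4. ``pcrelate`` — PC-Relate moment estimators of the kinship coefficient
   phi and the IBD-sharing probabilities k0 and k2, using
   individual-specific allele frequencies predicted from the PCs by
   linear regression on the unrelated (training) set.

PC-Relate estimators (Conomos et al.'s moment estimators, restated here
because they are fixed in code):  with individual-specific alternate-allele
frequency ``p_is`` (half the regression-predicted genotype mean, clamped
away from 0 and 1) and ``q = 1 - p``:

    phi_ij = sum_s (g_is - 2 p_is)(g_js - 2 p_js)
             / (4 sum_s sqrt(p_is q_is p_js q_js))

    k2_ij  = sum_s h_is h_js / sum_s p_is q_is p_js q_js,
             h = p^2, -pq, q^2 for g = 0, 1, 2

    k0_ij  = (#opposite homozygotes) / sum_s (p_is^2 q_js^2 + q_is^2 p_js^2)

The opposite-homozygote ratio is used for k0 across all pairs: it is the
direct moment estimator (a parent-offspring pair cannot produce opposite
homozygotes, so its k0 stays near zero even when phi is attenuated by
residual relatedness in the training set), and for unrelated pairs its
expectation is 1.

Sites where either member of a pair has an individual-specific MAF below
``indiv_maf_min`` are excluded for that pair.  Missing genotypes are
handled pairwise-complete in KING and the PC-Relate sums, and mean-imputed
for the PCA / regression steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["site_filter", "king_robust", "pcair_partition", "pcrelate",
           "PcairResult", "KIN_DEG3_THRESHOLD"]

#: 3rd-degree kinship boundary 2^(-11/2), the default PC-AiR relatedness cut
KIN_DEG3_THRESHOLD = 2.0 ** (-11.0 / 2.0)


def _as_float_matrix(G) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (individuals x sites)")
    return G


def _maf_and_mac(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    obs = ~np.isnan(G)
    n_obs = obs.sum(axis=0)
    alt = np.nansum(G, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
    maf = np.minimum(p, 1.0 - p)
    mac = np.minimum(alt, 2.0 * n_obs - alt)
    return maf, mac


def site_filter(G, maf_min: float = 0.05, ld_r2: float = 0.1,
                window: int = 3000) -> np.ndarray:
    """LD prune then MAF filter; returns indices of retained sites, in order.

    Greedy windowed pruning: sites are scanned left to right; when a site's
    squared genotype correlation with a retained site less than ``window``
    positions back exceeds ``ld_r2``, the member of the pair with the lower
    minor-allele count is dropped (ties drop the higher index).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    G = _as_float_matrix(G)
    n, m = G.shape
    maf, mac = _maf_and_mac(G)

    # standardize columns (mean-impute missing) for correlation products
    mu = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    Z = np.where(np.isnan(G), mu[None, :], G) - mu[None, :]
    sd = np.sqrt((Z ** 2).sum(axis=0))
    nonconst = sd > 0
    Z = np.divide(Z, np.where(sd > 0, sd, 1.0)[None, :])

    kept: list[int] = []
    removed = np.zeros(m, dtype=bool)
    for j in range(m):
        if not nonconst[j]:
            kept.append(j)  # monomorphic sites carry no LD; MAF step handles
            continue
        while True:
            cand = []
            for k in reversed(kept):          # kept is increasing
                if j - k >= window:
                    break
                if nonconst[k]:
                    cand.append(k)
            if not cand:
                break
            r = Z[:, cand].T @ Z[:, j]
            bad = np.nonzero(r ** 2 > ld_r2)[0]
            if bad.size == 0:
                break
            k = cand[bad[0]]
            # keep the higher minor-allele-count member; ties keep lower index
            if mac[j] > mac[k]:
                kept.remove(k)
                removed[k] = True
                continue
            removed[j] = True
            break
        if not removed[j]:
            kept.append(j)

    keep_idx = np.array([j for j in kept if maf[j] >= maf_min], dtype=np.int64)
    if keep_idx.size == 0:
        raise ValueError("all sites removed by LD/MAF filtering")
    return keep_idx


def king_robust(G) -> np.ndarray:
    """KING-robust pairwise kinship matrix.

    phi_ij = (N_het,het - 2 N_opp-hom) / (N_het,i + N_het,j), counted over
    sites observed in both individuals.  Pairs with no jointly observed
    heterozygous sites get NaN (warned).
    """
    G = _as_float_matrix(G)
    if G.shape[0] < 2:
        raise ValueError("need at least two individuals")
    M = (~np.isnan(G)).astype(np.float64)
    Gz = np.where(np.isnan(G), -1.0, G)
    H = (Gz == 1).astype(np.float64)
    A = (Gz == 0).astype(np.float64)
    B = (Gz == 2).astype(np.float64)
    n_hh = H @ H.T
    n_opp = A @ B.T + B @ A.T
    denom = H @ M.T + M @ H.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hh - 2.0 * n_opp) / denom
    if np.isnan(phi[np.triu_indices_from(phi, 1)]).any():
        log.warning("KING-robust: pairs with no jointly observed "
                    "heterozygous sites produced missing estimates")
    np.fill_diagonal(phi, 0.5)
    return phi


@dataclass
class PcairResult:
    unrelated: np.ndarray   # indices of the mutually unrelated set
    related: np.ndarray     # indices of the related set
    pcs: np.ndarray         # (n, n_pcs), all individuals


def pcair_partition(G, kin: np.ndarray, n_pcs: int = 10,
                    kin_threshold: float = KIN_DEG3_THRESHOLD,
                    div_threshold: float | None = None) -> PcairResult:
    """Greedy unrelated/related partition plus ancestry PCs.

    Individuals with the most partners above ``kin_threshold`` are moved
    to the related set (ties: larger summed kinship, then lower index)
    until no pair inside the unrelated set exceeds the threshold.  PCs come
    from the eigendecomposition of the standardized genotype covariance of
    the unrelated set; related individuals are projected.
    ``div_threshold`` is accepted for interface compatibility and unused
    (no divergence weighting).
    """
    G = _as_float_matrix(G)
    n = G.shape[0]
    kin = np.asarray(kin, dtype=float)
    above = (np.nan_to_num(kin, nan=0.0) > kin_threshold)
    np.fill_diagonal(above, False)
    active = np.ones(n, dtype=bool)
    related: list[int] = []
    deg = above.sum(axis=1).astype(np.int64)
    tot = np.where(above, np.nan_to_num(kin, nan=0.0), 0.0).sum(axis=1)
    while True:
        deg_active = np.where(active, deg, -1)
        dmax = deg_active.max()
        if dmax <= 0:
            break
        cand = np.nonzero(deg_active == dmax)[0]
        if cand.size > 1:
            best = cand[np.argmax(tot[cand])]
            ties = cand[tot[cand] == tot[best]]
            best = int(ties.min())
        else:
            best = int(cand[0])
        active[best] = False
        related.append(best)
        nbrs = np.nonzero(above[best] & active)[0]
        deg[nbrs] -= 1
        tot[nbrs] -= kin[best, nbrs]
        deg[best] = 0
    unrel = np.nonzero(active)[0]
    if unrel.size < n_pcs:
        raise ValueError(
            f"unrelated set ({unrel.size}) smaller than requested PCs ({n_pcs})")

    mu = np.nanmean(G[unrel], axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    p = np.clip(mu / 2.0, 1e-12, 1 - 1e-12)
    sd = np.sqrt(2.0 * p * (1.0 - p))
    Z = (np.where(np.isnan(G), mu[None, :], G) - mu[None, :]) / sd[None, :]
    # drop (near-)monomorphic-in-training columns
    ok = np.nanstd(G[unrel], axis=0) > 0
    Zu = Z[unrel][:, ok]
    U, S, Vt = np.linalg.svd(Zu, full_matrices=False)
    V = Vt[:n_pcs].T
    denom = np.where(S[:n_pcs] > 0, S[:n_pcs], 1.0)
    pcs = (Z[:, ok] @ V) / denom[None, :] * np.sqrt(unrel.size)
    # sign convention: largest-|loading| coordinate positive
    for c in range(pcs.shape[1]):
        j = np.argmax(np.abs(pcs[unrel, c]))
        if pcs[unrel[j], c] < 0:
            pcs[:, c] = -pcs[:, c]
    return PcairResult(unrelated=unrel, related=np.array(related, dtype=np.int64),
                       pcs=pcs)


def pcrelate(G, pcs: np.ndarray, training: np.ndarray,
             indiv_maf_min: float = 0.01,
             ids=None) -> pd.DataFrame:
    """PC-Relate (phi, k0, k2) for all unordered pairs.

    ``training`` indexes the (unrelated) individuals used to fit the
    per-site linear regression of genotype on PCs; predictions give
    individual-specific allele frequencies for everyone.  Returns a frame
    with columns id_a, id_b, phi, k0, k2, n_sites.
    """
    G = _as_float_matrix(G)
    n, m = G.shape
    training = np.asarray(training, dtype=np.int64)
    if training.size == 0:
        raise ValueError("training set is empty")
    X = np.column_stack([np.ones(n), np.asarray(pcs, dtype=float)])
    Xt = X[training]
    Gt = G[training]
    col_mu = np.nanmean(Gt, axis=0)
    col_mu = np.where(np.isnan(col_mu), 0.0, col_mu)
    Gt_fill = np.where(np.isnan(Gt), col_mu[None, :], Gt)
    beta, *_ = np.linalg.lstsq(Xt, Gt_fill, rcond=None)
    mu_hat = X @ beta                       # predicted genotype mean, (n, m)
    eps = 1e-6
    n_clamped = int(((mu_hat < 2 * eps) | (mu_hat > 2 - 2 * eps)).sum())
    if n_clamped:
        log.info("pcrelate: clamped %d predicted frequencies into (0,1)",
                 n_clamped)
    mu_hat = np.clip(mu_hat, 2 * eps, 2.0 - 2 * eps)
    p = mu_hat / 2.0
    q = 1.0 - p

    obs = ~np.isnan(G)
    mask = obs & (np.minimum(p, q) >= indiv_maf_min)
    W = mask.astype(np.float64)

    Gz = np.where(obs, G, 0.0)
    R = (Gz - mu_hat) * W                    # residuals, masked
    V = (p * q) * W                          # variance terms, masked
    SqV = np.sqrt(p * q) * W

    num_phi = R @ R.T
    den_phi = 4.0 * (SqV @ SqV.T)

    h = np.where(Gz == 0, p ** 2, np.where(Gz == 1, -p * q, q ** 2)) * W
    num_k2 = h @ h.T
    den_k2 = V @ V.T

    hom_ref = ((Gz == 0) & mask).astype(np.float64)
    hom_alt = ((Gz == 2) & mask).astype(np.float64)
    ibs0 = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    e0 = (p ** 2) * W
    e2 = (q ** 2) * W
    den_k0 = e0 @ e2.T + e2 @ e0.T

    n_sites = W @ W.T

    with np.errstate(invalid="ignore", divide="ignore"):
        phi = num_phi / den_phi
        k2 = num_k2 / den_k2
        k0 = ibs0 / den_k0

    iu, ju = np.triu_indices(n, k=1)
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    return pd.DataFrame({
        "id_a": ids[iu], "id_b": ids[ju],
        "phi": phi[iu, ju], "k0": k0[iu, ju], "k2": k2[iu, ju],
        "n_sites": n_sites[iu, ju].astype(np.int64),
    })
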