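"""Ground-truth kin classes from a pedigree table.

Labels every unordered pair of sampled individuals with exactly one of
POP (parent-offspring), FSP (full siblings), DEG2 (second degree, with the
subtype recording whether the link is a half-sibling pair HSP, a
grandparent-grandchild pair GGP, or a full-thiatic pair FTP: aunt/uncle to
niece/nephew through a full sibling of a parent), or U (everything else,
including pairs whose ancestry is not tracked in the pedigree window).
Pairs matching several definitions take the closest degree, with fixed
precedence POP > FSP > HSP > GGP > FTP.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

__all__ = ["KinLabel", "enumerate_kin", "kin_census", "KIN_LABELS"]


class KinLabel(str, Enum):
    POP = "POP"
    FSP = "FSP"
    DEG2 = "DEG2"
    U = "U"


KIN_LABELS = [k.value for k in KinLabel]

_UNKNOWN = -1


def _parent_arrays(pedigree: pd.DataFrame, ids: np.ndarray):
    """Return (mother, father) arrays aligned to ``ids``; unknown -> -1."""
    idx = pd.Index(pedigree["id"])
    if not idx.is_unique:
        raise ValueError("pedigree ids are not unique")
    loc = idx.get_indexer(ids)
    if (loc < 0).any():
        missing = ids[loc < 0][:5]
        raise KeyError(f"ids not in pedigree: {missing.tolist()}")
    mo = pedigree["mother_id"].to_numpy()[loc]
    fa = pedigree["father_id"].to_numpy()[loc]
    return mo, fa


def enumerate_kin(pedigree: pd.DataFrame, sampled_ids) -> pd.DataFrame:
    """Label all unordered pairs of ``sampled_ids``.

    Returns a frame with columns (id_a, id_b, label, subtype), one row per
    unordered pair with id_a < id_b.  ``subtype`` is "HSP"/"GGP"/"FTP" for
    DEG2 rows and "" otherwise.  Raises ``KeyError`` for ids missing from
    the pedigree.
    """
    ids = np.asarray(sampled_ids, dtype=np.int64)
    n = ids.size
    mo, fa = _parent_arrays(pedigree, ids)

    # parent lookup over the whole pedigree for grandparent / avuncular walks
    all_ids = pedigree["id"].to_numpy()
    all_mo = pedigree["mother_id"].to_numpy()
    all_fa = pedigree["father_id"].to_numpy()
    idx = pd.Index(all_ids)

    def parents_of(id_arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Parents of arbitrary ids; unknown ids or parents -> -1."""
        loc = idx.get_indexer(id_arr)
        pm = np.where(loc >= 0, all_mo[np.maximum(loc, 0)], _UNKNOWN)
        pf = np.where(loc >= 0, all_fa[np.maximum(loc, 0)], _UNKNOWN)
        return pm, pf

    # grandparents of each sampled individual, via mother and via father
    gmm, gmf = parents_of(mo)   # maternal grandmother / grandfather
    gfm, gff = parents_of(fa)   # paternal grandmother / grandfather
    grand = np.stack([gmm, gmf, gfm, gff], axis=1)           # (n, 4)
    parents = np.stack([mo, fa], axis=1)                      # (n, 2)
    # parents' parents, for the full-sib-of-parent (FTP) test: (n, 2, 2)
    par_par = np.stack([np.stack([gmm, gmf], axis=1),
                        np.stack([gfm, gff], axis=1)], axis=1)

    # POP: one is a recorded parent of the other
    pop = (parents[:, None, :] == ids[None, :, None]).any(axis=2)
    pop |= pop.T

    known_both = (mo != _UNKNOWN) & (fa != _UNKNOWN)
    same_mo = (mo[:, None] == mo[None, :]) & (mo != _UNKNOWN)[:, None]
    same_fa = (fa[:, None] == fa[None, :]) & (fa != _UNKNOWN)[:, None]
    fsp = same_mo & same_fa & known_both[:, None] & known_both[None, :]
    hsp = (same_mo ^ same_fa)

    # GGP: one is a grandparent of the other
    ggp = (grand[:, None, :] == ids[None, :, None]).any(axis=2)
    ggp |= ggp.T

    # FTP: a parent of one is a full sibling of the other
    # parent p of a is full sib of b  <=>  parents(p) == parents(b), all known
    ftp = np.zeros((n, n), dtype=bool)
    for side in range(2):  # via mother, via father
        pp = par_par[:, side, :]                       # (n, 2) parents of parent
        ok = (pp != _UNKNOWN).all(axis=1)
        m = ((pp[:, None, 0] == mo[None, :]) & (pp[:, None, 1] == fa[None, :])
             & ok[:, None] & known_both[None, :])
        # exclude the parent being b itself (that is POP/handled earlier)
        m &= parents[:, side][:, None] != ids[None, :]
        ftp |= m
    ftp |= ftp.T

    iu, ju = np.triu_indices(n, k=1)
    label = np.full(iu.size, "U", dtype=object)
    subtype = np.full(iu.size, "", dtype=object)
    for mask, lab, sub in ((ftp, "DEG2", "FTP"), (ggp, "DEG2", "GGP"),
                           (hsp, "DEG2", "HSP"), (fsp, "FSP", ""),
                           (pop, "POP", "")):
        sel = mask[iu, ju]
        label[sel] = lab
        subtype[sel] = sub
    subtype[label != "DEG2"] = ""

    a, b = ids[iu], ids[ju]
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    return pd.DataFrame({"id_a": a2, "id_b": b2, "label": label,
                         "subtype": subtype})


def kin_census(truth: pd.DataFrame) -> dict[str, int]:
    """Counts per kin label (POP/FSP/DEG2/U), summing to the pair count."""
    counts = {k: 0 for k in KIN_LABELS}
    counts.update(truth["label"].value_counts().to_dict())
    return counts
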