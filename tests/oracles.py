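"""Independent brute-force oracles used by the test suite.

These deliberately use plain dict/loop implementations, separate from the
vectorised package code they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def random_pedigree(n: int, seed: int, n_founders: int = 12) -> pd.DataFrame:
    """Random multi-generation pedigree with n individuals.

    Founders have unknown parents (-1); later individuals draw a mother
    and father uniformly from earlier females/males (falling back to
    unknown when none exist), which produces plenty of overlapping kin
    relations including inbred loops.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sexes = []
    for i in range(n):
        sex = int(rng.integers(0, 2))
        sexes.append(sex)
        if i < n_founders:
            mo = fa = -1
        else:
            females = [j for j in range(i) if sexes[j] == 0]
            males = [j for j in range(i) if sexes[j] == 1]
            mo = int(rng.choice(females)) if females else -1
            fa = int(rng.choice(males)) if males else -1
        rows.append((i, mo, fa, i, 0, "F" if sex == 0 else "M"))
    return pd.DataFrame(rows, columns=["id", "mother_id", "father_id",
                                       "birth_gen", "subpop", "sex"])


def walker_kin_labels(pedigree: pd.DataFrame, ids) -> dict:
    """Exhaustive relationship walker: label every unordered pair.

    Walks parent maps directly per the definitions (POP parent link, FSP
    both parents shared, HSP exactly one, GGP grandparent link, FTP full
    sibling of a parent), resolving multi-path pairs by closest degree
    with precedence POP > FSP > HSP > GGP > FTP; unknown ancestry -> U.
    """
    par = {int(r.id): (int(r.mother_id), int(r.father_id))
           for r in pedigree.itertuples()}

    def parents(x):
        return [p for p in par.get(x, (-1, -1)) if p != -1]

    def full_sibs(x, y):
        if x == y:
            return False
        mx, fx = par.get(x, (-1, -1))
        my, fy = par.get(y, (-1, -1))
        return mx != -1 and fx != -1 and mx == my and fx == fy

    def half_sibs(x, y):
        mx, fx = par.get(x, (-1, -1))
        my, fy = par.get(y, (-1, -1))
        shared = int(mx != -1 and mx == my) + int(fx != -1 and fx == fy)
        return shared == 1

    def grandparents(x):
        out = []
        for p in parents(x):
            out.extend(parents(p))
        return out

    labels = {}
    ids = list(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if b in parents(a) or a in parents(b):
                lab = ("POP", "")
            elif full_sibs(a, b):
                lab = ("FSP", "")
            elif half_sibs(a, b):
                lab = ("DEG2", "HSP")
            elif b in grandparents(a) or a in grandparents(b):
                lab = ("DEG2", "GGP")
            elif any(full_sibs(p, b) for p in parents(a)) or \
                    any(full_sibs(p, a) for p in parents(b)):
                lab = ("DEG2", "FTP")
            else:
                lab = ("U", "")
            labels[(min(a, b), max(a, b))] = lab
    return labels


def wc_theta_brute(G_list) -> float:
    """Scalar per-locus Weir & Cockerham (1984) theta, ratio of sums.

    Independent re-derivation from the published a, b, c components with
    explicit per-locus loops.
    """
    r = len(G_list)
    m = G_list[0].shape[1]
    num = den = 0.0
    for loc in range(m):
        ns, ps, hs = [], [], []
        for Gi in G_list:
            g = Gi[:, loc]
            g = g[~np.isnan(g)]
            if g.size == 0:
                break
            ns.append(g.size)
            ps.append(g.sum() / (2 * g.size))
            hs.append(float((g == 1).mean()))
        else:
            nbar = sum(ns) / r
            if nbar <= 1:
                continue
            nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
            pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den if den else float("nan")
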