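"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's fast code paths: exhaustive
enumeration for gene dropping, direct likelihood optimisation for the
ordinal model, and hand-rolled normal equations for OLS.
"""

import numpy as np
from scipy import optimize

from idload.pedigree import UNKNOWN


def enumerate_gene_drop(ped):
    """Exact autozygosity and Kalinowski probabilities by enumerating every
    Mendelian transmission pattern (feasible for <= ~16 meioses).

    Returns ``(fk, autozygosity)`` arrays over the pedigree.
    """
    meioses = [(x, slot)
               for x in range(ped.n)
               for slot, p in ((0, ped.sire[x]), (1, ped.dam[x]))
               if p != UNKNOWN]
    m = len(meioses)
    if m > 16:
        raise ValueError("pedigree too large for exhaustive enumeration")
    fk = np.zeros(ped.n)
    auto_p = np.zeros(ped.n)
    lab = np.zeros((ped.n, 2), dtype=int)
    flg = np.zeros((ped.n, 2), dtype=bool)
    for mask in range(2 ** m):
        choice = {meioses[i]: (mask >> i) & 1 for i in range(m)}
        next_label = 0
        for x in range(ped.n):
            for slot, p in ((0, ped.sire[x]), (1, ped.dam[x])):
                if p == UNKNOWN:
                    lab[x, slot] = next_label
                    flg[x, slot] = False
                    next_label += 1
                else:
                    c = choice[(x, slot)]
                    lab[x, slot] = lab[p, c]
                    flg[x, slot] = flg[p, c]
            if ped.sire[x] != UNKNOWN and ped.dam[x] != UNKNOWN \
                    and lab[x, 0] == lab[x, 1]:
                auto_p[x] += 1
                if flg[x, 0] or flg[x, 1]:
                    fk[x] += 1
                flg[x, 0] = True
                flg[x, 1] = True
    return fk / 2 ** m, auto_p / 2 ** m


def ols_normal_equations(y, f):
    """Slope/intercept/SE/t of simple OLS straight from the normal equations."""
    y = np.asarray(y, float)
    f = np.asarray(f, float)
    n = len(y)
    sxx = np.sum((f - f.mean()) ** 2)
    sxy = np.sum((f - f.mean()) * (y - y.mean()))
    b = sxy / sxx
    a = y.mean() - b * f.mean()
    resid = y - a - b * f
    s2 = np.sum(resid ** 2) / (n - 2)
    se = np.sqrt(s2 / sxx)
    return {"slope": b, "intercept": a, "se": se, "t": b / se}


def ordinal_direct_fit(y, f, k, n_starts=8, seed=0):
    """Proportional-odds ML by direct NLL minimisation from multiple starts.

    ``y`` holds categories 0..k-1.  Returns (params, nll) of the best fit.
    """
    from idload.regression import ordinal_nll

    rng = np.random.default_rng(seed)
    best = None
    freq = np.bincount(y, minlength=k) / len(y)
    cum = np.cumsum(freq)[:-1]
    z0 = np.log(cum / (1 - cum))
    for s in range(n_starts):
        start = np.concatenate([[0.0], z0])
        if s > 0:
            start = start + rng.normal(0, 0.5, size=start.size)
            start[1:] = np.sort(start[1:])
        res = optimize.minimize(ordinal_nll, start, args=(y, f, k),
                                method="Nelder-Mead",
                                options={"maxiter": 5000, "xatol": 1e-10,
                                         "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return best.x, best.fun
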