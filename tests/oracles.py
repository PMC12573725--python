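"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exact rational
arithmetic where feasible) and shares no code path with the package.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, gammaln


# ---------------------------------------------------------------------------
# CpG islands


def island_windows_naive(seq: str, window: int = 200):
    """All qualifying 200-bp substrings by direct counting."""
    out = []
    for i in range(0, len(seq) - window + 1):
        sub = seq[i:i + window]
        if "N" in sub:
            continue
        nc, ng = sub.count("C"), sub.count("G")
        ncg = sum(1 for j in range(window - 1) if sub[j:j + 2] == "CG")
        if nc == 0 or ng == 0:
            continue
        gc = Fraction(nc + ng, window)
        oe = Fraction(ncg * window, nc * ng)
        if gc > Fraction(1, 2) and oe > Fraction(3, 5):
            out.append((i, i + window))
    return out


def islands_naive(seq: str, window: int = 200, min_length: int = 200):
    """Merge qualifying windows and re-check each merged interval."""
    wins = island_windows_naive(seq, window)
    merged = []
    for s, e in wins:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    def qualifies(s, e):
        sub = seq[s:e]
        nc, ng = sub.count("C"), sub.count("G")
        ncg = sum(1 for j in range(len(sub) - 1) if sub[j:j + 2] == "CG")
        L = e - s
        if nc == 0 or ng == 0 or "N" in sub:
            return False
        return (Fraction(nc + ng, L) > Fraction(1, 2)
                and Fraction(ncg * L, nc * ng) > Fraction(3, 5))

    keep = []
    for s, e in merged:
        # same trimming discipline, written naively: strip non-C/G ends,
        # then shrink from the start until the whole interval qualifies
        while e - s > min_length:
            if seq[s] not in "CG":
                s += 1
            elif seq[e - 1] not in "CG":
                e -= 1
            elif qualifies(s, e):
                keep.append((s, e))
                break
            else:
                s += 1
    return keep


# ---------------------------------------------------------------------------
# feature track


def per_base_labels(chrom_size, promoters, repeats, cds, introns):
    """Priority labelling base by base."""
    labels = ["intergenic"] * chrom_size
    for name, ivs in (("intron", introns), ("CDS", cds), ("repeat", repeats),
                      ("promoter", promoters)):
        for s, e in ivs:
            for i in range(s, e):
                labels[i] = name
    return labels


# ---------------------------------------------------------------------------
# population genetics (exact rational arithmetic)


def hudson_fst_exact(haps_a, haps_b):
    """Ratio-of-averages Hudson F_ST on lists of 0/1 haplotype tuples."""
    haps_a = [tuple(int(x) for x in h) for h in haps_a]
    haps_b = [tuple(int(x) for x in h) for h in haps_b]
    na, nb = len(haps_a), len(haps_b)
    S = len(haps_a[0])
    pw_sum = Fraction(0)
    pb_sum = Fraction(0)
    for s in range(S):
        ca = sum(h[s] for h in haps_a)
        cb = sum(h[s] for h in haps_b)
        pa, pb = Fraction(ca, na), Fraction(cb, nb)
        hw_a = 2 * pa * (1 - pa) * Fraction(na, na - 1)
        hw_b = 2 * pb * (1 - pb) * Fraction(nb, nb - 1)
        pw_sum += Fraction(hw_a + hw_b, 2)
        pb_sum += pa * (1 - pb) + pb * (1 - pa)
    if pb_sum == 0:
        return None
    return 1 - pw_sum / pb_sum


def dxy_exact(haps_a, haps_b, L):
    """Mean between-population pairwise difference per site, by direct
    haplotype-pair comparison."""
    haps_a = [tuple(int(x) for x in h) for h in haps_a]
    haps_b = [tuple(int(x) for x in h) for h in haps_b]
    total = 0
    npairs = 0
    for ha in haps_a:
        for hb in haps_b:
            total += sum(1 for x, y in zip(ha, hb) if x != y)
            npairs += 1
    return Fraction(total, npairs * L)


def pi_total_exact(haps):
    """Mean pairwise differences across all haplotype pairs (total)."""
    n = len(haps)
    total = sum(sum(1 for x, y in zip(a, b) if x != y)
                for a, b in combinations(haps, 2))
    return Fraction(total, n * (n - 1) // 2)


def tajimas_d_exact(haps):
    n = len(haps)
    S = sum(1 for s in range(len(haps[0]))
            if 0 < sum(h[s] for h in haps) < n)
    if S == 0:
        return None
    pi = float(pi_total_exact(haps))
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_dstar_exact(haps):
    n = len(haps)
    S = 0
    eta_s = 0
    for s in range(len(haps[0])):
        c = sum(h[s] for h in haps)
        if 0 < c < n:
            S += 1
            if c == 1 or c == n - 1:
                eta_s += 1
    if S == 0:
        return None
    an = sum(1 / i for i in range(1, n))
    bn = sum(1 / i ** 2 for i in range(1, n))
    an1 = an + 1 / n
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1 / n)
    nr = n / (n - 1)
    v = (nr ** 2 * bn + an ** 2 * dn - 2 * n * an * (an + 1) / (n - 1) ** 2) \
        / (an ** 2 + bn)
    u = nr * (an - nr) - v
    return (nr * S - an * eta_s) / np.sqrt(u * S + v * S * S)


def hd_exact(haps):
    haps = [tuple(int(x) for x in h) for h in haps]
    n = len(haps)
    counts = {}
    for h in haps:
        counts[tuple(h)] = counts.get(tuple(h), 0) + 1
    s = sum(Fraction(c, n) ** 2 for c in counts.values())
    return Fraction(n, n - 1) * (1 - s)


# ---------------------------------------------------------------------------
# beta-binomial maximum likelihood (numeric optimisation)


def betabinom_ml_wald(m, n, X, col):
    """Exact beta-binomial ML with logit-linked mean; Wald z for column
    `col` from the numerical observed information."""
    m = np.asarray(m, float)
    n = np.asarray(n, float)
    X = np.asarray(X, float)
    k = X.shape[1]

    def nll(theta):
        beta, logit_rho = theta[:k], theta[k]
        rho = 1 / (1 + np.exp(-np.clip(logit_rho, -30, 30))) * 0.98 + 1e-4
        mu = 1 / (1 + np.exp(-(X @ beta)))
        mu = np.clip(mu, 1e-6, 1 - 1e-6)
        conc = (1 - rho) / rho
        a, b = mu * conc, (1 - mu) * conc
        ll = (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
              + betaln(m + a, n - m + b) - betaln(a, b))
        return -np.sum(ll)

    p0 = np.clip(m.sum() / n.sum(), 0.05, 0.95)
    x0 = np.zeros(k + 1)
    x0[0] = np.log(p0 / (1 - p0))
    x0[k] = -3.0
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    theta = res.x
    # numerical Hessian for the beta block
    h = 1e-4
    H = np.zeros((k + 1, k + 1))
    for i in range(k + 1):
        for j in range(i, k + 1):
            ei = np.zeros(k + 1); ei[i] = h
            ej = np.zeros(k + 1); ej[j] = h
            H[i, j] = H[j, i] = (nll(theta + ei + ej) - nll(theta + ei - ej)
                                 - nll(theta - ei + ej) + nll(theta - ei - ej)) / (4 * h * h)
    try:
        covm = np.linalg.inv(H)
        se = np.sqrt(max(covm[col, col], 1e-12))
    except np.linalg.LinAlgError:
        return np.nan
    return theta[col] / se


# ---------------------------------------------------------------------------
# redundancy analysis (direct, on the centered matrix)


def rda_direct(Y, X):
    """Classical RDA: eigenvalues of the fitted part of the centered
    response regressed on the design. Returns (eigenvalues, R^2)."""
    Y = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    B, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    fitted = Xc @ B
    sv = np.linalg.svd(fitted, compute_uv=False)
    eig = sv ** 2
    eig = eig[eig > 1e-10]
    total = np.sum(Y ** 2)
    return eig, float(eig.sum() / total)


# ---------------------------------------------------------------------------
# exhaustive 1-D 2-means


def two_means_exhaustive(x):
    """Optimal 2-partition of scalars by trying every subset split that is
    an interval in sorted order (the optimum is always such a cut)."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    best = None
    for k in range(1, n):
        left, right = xs[:k], xs[k:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if best is None or sse < best[0] - 1e-15:
            best = (sse, k)
    k = best[1]
    states_sorted = np.array([0.0] * k + [1.0] * (n - k))
    states = np.empty(n)
    states[order] = states_sorted
    return states


def bh_adjust_naive(p):
    """Benjamini-Hochberg step-up by the textbook recipe."""
    p = np.asarray(p, float)
    mtests = len(p)
    order = np.argsort(p)
    q = np.empty(mtests)
    prev = 1.0
    for rank in range(mtests, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * mtests / rank)
        q[i] = val
        prev = val
    return q


def binom_tail_two_sided(k, n, p0):
    """Two-sided exact binomial p by summing all outcomes with probability
    <= that of the observed count (the scipy/R convention)."""
    from math import comb

    def pmf(x):
        return comb(n, x) * p0 ** x * (1 - p0) ** (n - x)

    pk = pmf(k)
    return min(1.0, sum(pmf(x) for x in range(n + 1) if pmf(x) <= pk * (1 + 1e-9)))
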