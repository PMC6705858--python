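"""Independent oracles for the dip statistic.

Two routes that share no code with the implementation:

* :func:`dip_exhaustive` — brute-force enumeration over candidate modal
  points; for each, the one-sided errors are taken from an exhaustive scan
  over all candidate chords of the ECDF band targets, and the mode-crossing
  constraint from the closed-form roots of every (left bound, right bound)
  pair of linear-in-e constraints.
* :func:`dip_lp` — linear program over unimodal CDFs: variables are the CDF
  values at the data points (plus the left limit at the mode), constraints
  encode the sup-norm band, monotonicity, convexity below and concavity
  above the mode; minimised for every mode placement.
"""

import numpy as np
from scipy.optimize import linprog


def _targets(values):
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    x, counts = np.unique(v, return_counts=True)
    cum = np.cumsum(counts) / n
    upper = np.concatenate(([0.0], cum[:-1]))
    return x, upper, cum


def dip_exhaustive(values) -> float:
    x, upper, lower = _targets(values)
    m = x.size
    if m == 1:
        return 0.0

    def gcm_value(js, j, U):
        best = np.inf
        for a in js:
            if a > j:
                continue
            for b in js:
                if b < j:
                    continue
                if a == b:
                    val = U[a]
                else:
                    val = U[a] + (U[b] - U[a]) * (x[j] - x[a]) / (x[b] - x[a])
                best = min(best, val)
        return best

    best_e = np.inf
    for k in range(m):
        # decoupled one-sided errors via exhaustive chord search
        le = 0.0
        js = list(range(k + 1))
        for j in range(k):
            le = max(le, lower[j] - gcm_value(js, j, upper))
        re = 0.0
        js = list(range(k, m))
        for j in range(k + 1, m):
            # least concave majorant of the lower targets = -GCM of negated
        # (evaluated via the same chord enumeration)
            best = np.inf
            for a in js:
                if a > j:
                    continue
                for b in js:
                    if b < j:
                        continue
                    if a == b:
                        val = -lower[a]
                    else:
                        val = -lower[a] + (lower[a] - lower[b]) * (x[j] - x[a]) / (
                            x[b] - x[a]
                        )
                    best = min(best, val)
            re = max(re, -best - upper[j])
        base = 0.5 * max(le, re)
        # mode-crossing link: lower bounds on the left limit (A - B e) vs
        # upper bounds on the mode value (A' + B' e)
        lbs = [(upper[k], 1.0)]
        for j in range(k):
            lbs.append((lower[j], 1.0))
            for i in range(j):
                r = (x[k] - x[j]) / (x[j] - x[i])
                lbs.append((lower[j] * (1 + r) - upper[i] * r, 1 + 2 * r))
        ubs = [(lower[k], 1.0)]
        for j in range(k + 1, m):
            ubs.append((upper[j], 1.0))
            for i in range(j + 1, m):
                s = (x[j] - x[k]) / (x[i] - x[j])
                ubs.append((upper[j] * (1 + s) - lower[i] * s, 1 + 2 * s))
        link = 0.0
        for A, B in lbs:
            for A2, B2 in ubs:
                link = max(link, (A - A2) / (B + B2))
        best_e = min(best_e, max(base, link))
    return best_e


def dip_lp(values) -> float:
    x, upper, lower = _targets(values)
    m = x.size
    if m == 1:
        return 0.0
    best = np.inf
    for k in range(m):
        nv = m + 2  # g_0..g_{m-1}, g_mode_left_limit, e
        KM, E = m, m + 1
        A_ub, b_ub = [], []

        def le(coefs, rhs):
            row = [0.0] * nv
            for idx, c in coefs:
                row[idx] += c
            A_ub.append(row)
            b_ub.append(rhs)

        for j in range(m):
            centre_lo = lower[j] if j != k else lower[k]
            centre_hi = upper[j] if j != k else lower[k]
            le([(j, -1.0), (E, -1.0)], -centre_lo)  # g_j >= centre_lo - e
            le([(j, 1.0), (E, -1.0)], centre_hi)  # g_j <= centre_hi + e
        le([(KM, -1.0), (E, -1.0)], -upper[k])
        le([(KM, 1.0), (E, -1.0)], upper[k])
        chain = []
        for j in range(m):
            if j == k:
                chain.extend([KM, j])
            else:
                chain.append(j)
        for a, b in zip(chain[:-1], chain[1:]):
            le([(a, 1.0), (b, -1.0)], 0.0)  # monotone
        pts = [(x[j], j) for j in range(k)] + [(x[k], KM)]
        for (x0, i0), (x1, i1), (x2, i2) in zip(pts[:-2], pts[1:-1], pts[2:]):
            # convex: slope(x0,x1) <= slope(x1,x2)
            le(
                [
                    (i0, -1.0 / (x1 - x0)),
                    (i1, 1.0 / (x1 - x0) + 1.0 / (x2 - x1)),
                    (i2, -1.0 / (x2 - x1)),
                ],
                0.0,
            )
        pts = [(x[j], j) for j in range(k, m)]
        for (x0, i0), (x1, i1), (x2, i2) in zip(pts[:-2], pts[1:-1], pts[2:]):
            # concave: slope(x0,x1) >= slope(x1,x2)
            le(
                [
                    (i0, 1.0 / (x1 - x0)),
                    (i1, -1.0 / (x1 - x0) - 1.0 / (x2 - x1)),
                    (i2, 1.0 / (x2 - x1)),
                ],
                0.0,
            )
        c = [0.0] * nv
        c[E] = 1.0
        res = linprog(
            c,
            A_ub=np.array(A_ub),
            b_ub=np.array(b_ub),
            bounds=[(0.0, 1.0)] * m + [(0.0, 1.0), (0.0, 1.0)],
            method="highs",
        )
        assert res.success, res.message
        best = min(best, res.fun)
    return best
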