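"""Hartigan & Hartigan dip statistic and Monte Carlo dip test.

The dip of an empirical CDF F_n is the smallest sup-norm distance between
F_n and any unimodal CDF — convex below its mode, concave above, monotone,
with at most one jump (at the mode).  We minimise over candidate modal
points.  Placing the mode at the j-th distinct value splits the problem
into a convex band-approximation to the ECDF step corners on the left and
a concave one on the right:

* at a distinct value with cumulative fractions c_prev (just below the
  step) and c (at it), a CDF G within sup-distance e and continuous there
  must satisfy ``c - e <= G(x) <= c_prev + e``;
* a convex function threading those bands exists iff the greatest convex
  minorant (GCM) of the upper targets clears every lower target, so the
  one-sided error is half the largest gap ``lower - GCM(upper)``; the
  concave side is the mirror image via the least concave majorant;
* the two branches must also meet: the convex branch's left limit at the
  mode may not exceed the concave branch's value there.  Convexity forces
  chord slopes to keep growing, so pairs of (upper, lower) targets left of
  the mode extrapolate to a lower bound on the left limit, and mirrored
  pairs bound the right value from above.  Each such bound is linear in e,
  making the smallest e reconciling them the root of a piecewise-linear
  equation, found exactly by an active-constraint (Newton) iteration.

The dip is ``min over modes of max(left error, right error, link root)``.
Tests verify this against an exhaustive search over candidate modal chords
and against a linear-programming formulation over unimodal CDFs.

For a sample with at least two distinct values the dip is at least 1/(2n);
a single repeated value has dip 0 (its ECDF is itself unimodal).
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import InsufficientDataError

try:  # optional JIT; the pure-Python path computes identical values
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is present in normal installs
    HAVE_NUMBA = False

    def _njit(**kwargs):
        def wrap(f):
            return f

        return wrap


@_njit(cache=False)
def _left_errors(x, upper, lower):
    """Decoupled one-sided error for every candidate mode, left branch.

    ``err[k]`` is half the largest gap between the lower targets and the
    greatest convex minorant of the upper targets over points j < k.  The
    hull is maintained incrementally; when a new point pops hull vertices,
    gaps under the fresh chord are rescanned.
    """
    m = x.shape[0]
    err = np.zeros(m)
    hull = np.empty(m, dtype=np.int64)
    seg_max = np.empty(m)  # max gap within the segment ending at hull[t]
    pref = np.empty(m)  # prefix max of seg_max up to t
    hull[0] = 0
    seg_max[0] = lower[0] - upper[0]
    pref[0] = seg_max[0]
    top = 0
    for k in range(1, m):
        while top >= 1:
            i = hull[top - 1]
            j = hull[top]
            # keep j only if strictly below the chord i -> k
            if (upper[j] - upper[i]) * (x[k] - x[i]) < (upper[k] - upper[i]) * (
                x[j] - x[i]
            ):
                break
            top -= 1
        v = hull[top]
        g = 0.0
        dx = x[k] - x[v]
        for j in range(v + 1, k):
            hv = upper[v] + (upper[k] - upper[v]) * (x[j] - x[v]) / dx
            d = lower[j] - hv
            if d > g:
                g = d
        e = g
        if pref[top] > e:
            e = pref[top]
        if e < 0.0:
            e = 0.0
        err[k] = 0.5 * e
        own = lower[k] - upper[k]
        if own > g:
            g = own
        top += 1
        hull[top] = k
        seg_max[top] = g
        pref[top] = pref[top - 1] if pref[top - 1] > g else g
    return err


@_njit(cache=False)
def _left_limit_min(x, upper, lower, k, e):
    """Greatest lower bound on the convex branch's left limit at mode k.

    Returns ``(value, A, B)`` with value = A - B*e for the active linear
    constraint: the mode band itself, monotonicity from each lower target,
    or a chord through an (upper_i, lower_j) pair extrapolated to x[k].
    The steepest chord into each lower target is found by a tangent query
    (binary search) on the incrementally maintained lower hull of the
    upper targets; slope-to-query is unimodal along a convex chain.
    """
    bA, bB = upper[k], 1.0
    best = bA - bB * e
    hull = np.empty(k + 1, dtype=np.int64)
    top = -1
    for j in range(k):
        A, B = lower[j], 1.0
        if top >= 0:
            yq = lower[j] - 2.0 * e  # slope_ij = (yq - upper_i)/(x_j - x_i)
            lo, hi = 0, top
            while lo < hi:
                mid = (lo + hi) // 2
                i1 = hull[mid]
                i2 = hull[mid + 1]
                f1 = (yq - upper[i1]) / (x[j] - x[i1])
                f2 = (yq - upper[i2]) / (x[j] - x[i2])
                if f2 >= f1:
                    lo = mid + 1
                else:
                    hi = mid
            i = hull[lo]
            s = (yq - upper[i]) / (x[j] - x[i])
            if s > 0.0:
                r = (x[k] - x[j]) / (x[j] - x[i])
                A = lower[j] * (1.0 + r) - upper[i] * r
                B = 1.0 + 2.0 * r
        val = A - B * e
        if val > best:
            best, bA, bB = val, A, B
        while top >= 1:
            a = hull[top - 1]
            b = hull[top]
            if (upper[b] - upper[a]) * (x[j] - x[a]) < (upper[j] - upper[a]) * (
                x[b] - x[a]
            ):
                break
            top -= 1
        top += 1
        hull[top] = j
    return best, bA, bB


@_njit(cache=False)
def _dip_core(x, upper, lower):
    m = x.shape[0]
    xr = np.ascontiguousarray(-x[::-1])
    ur = np.ascontiguousarray(-lower[::-1])
    lr = np.ascontiguousarray(-upper[::-1])
    left = _left_errors(x, upper, lower)
    right = _left_errors(xr, ur, lr)[::-1]
    base = np.maximum(left, right)
    order = np.argsort(base)
    best = 1.0e308
    for oi in range(m):
        k = order[oi]
        if base[k] >= best:
            break
        e = base[k]
        # raise e until the two branches can meet at the mode
        for _ in range(200):
            gv, gA, gB = _left_limit_min(x, upper, lower, k, e)
            # the concave branch's max value at the mode is the mirror query
            mv, mA, mB = _left_limit_min(xr, ur, lr, m - 1 - k, e)
            rv, rA, rB = -mv, -mA, mB
            if gv <= rv + 1e-14 * (1.0 + abs(gv)):
                break
            enew = (gA - rA) / (gB + rB)
            if enew <= e:
                break
            e = enew
        if e < best:
            best = e
    return best


def _dip_from_sorted_unique(x, cum):
    m = x.shape[0]
    if m == 1:
        return 0.0
    upper = np.empty(m)
    upper[0] = 0.0
    upper[1:] = cum[:-1]
    return float(_dip_core(x, upper, cum))


def dip_statistic(values) -> float:
    """Dip statistic of a univariate sample (n >= 4)."""
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n < 4:
        raise InsufficientDataError("dip statistic needs n >= 4")
    if not np.all(np.isfinite(v)):
        raise ValueError("sample contains non-finite values")
    x, counts = np.unique(v, return_counts=True)
    cum = np.cumsum(counts) / n
    return _dip_from_sorted_unique(x, cum)


def dip_test(values, B: int = 2000, seed=None, rng=None):
    """Monte Carlo dip test of unimodality.

    The null reference is the uniform distribution (the asymptotically
    least-favourable unimodal law): ``B`` uniform samples of the same size
    are drawn and ``p = (1 + #{dip_b >= dip_obs}) / (B + 1)``.

    Returns ``(dip, p)``.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    d = dip_statistic(v)
    if B < 100:
        warnings.warn(f"B={B} null replicates is small; p-value will be coarse")
    if rng is None:
        rng = np.random.default_rng(seed)
    null = rng.random((B, n))
    null.sort(axis=1)
    frac = np.arange(1, n + 1) / n
    ge = 0
    for b in range(B):
        if _dip_from_sorted_unique(null[b], frac) >= d:
            ge += 1
    return d, float((1 + ge) / (B + 1))
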