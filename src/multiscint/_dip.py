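"""Hartigan & Hartigan dip statistic of unimodality.

The dip of an empirical CDF F_n is the smallest sup-norm distance from F_n to
the class of unimodal distribution functions (convex below the mode, concave
above it).  It is computed with the classic iterative greatest-convex-minorant
/ least-concave-majorant algorithm: the candidate modal interval is shrunk
until the deviation of F_n from the best unimodal envelope inside the interval
no longer grows.  For n points the statistic is bounded below by 1/(2n), the
value attained by perfectly "unimodal" samples such as equally spaced points.

P-values are calibrated against the uniform null distribution -- the
least-favorable unimodal case -- by seeded bootstrap.  A cache of null
critical values, keyed by (sample size, significance), serves the clustering
module's split decisions without re-simulating for every cluster.

The core loop is accelerated with numba when available and falls back to pure
Python otherwise.
"""

from __future__ import annotations

import numpy as np


def _dip_sorted_py(x):
    """Dip statistic of an ascending-sorted 1-D array (pure kernel)."""
    n = x.shape[0]
    if n < 2 or x[n - 1] == x[0]:
        return 0.0

    low = 0
    high = n - 1
    dip = 1.0  # count units; yields the universal floor 1/(2n)

    mn = np.empty(n, dtype=np.int64)
    mj = np.empty(n, dtype=np.int64)
    gcm = np.empty(n + 1, dtype=np.int64)
    lcm = np.empty(n + 1, dtype=np.int64)

    # indices over which combination is necessary for the convex minorant
    mn[0] = 0
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or ((x[j] - x[mnj]) * (mnj - mnmnj)
                            < (x[mnj] - x[mnmnj]) * (j - mnj)):
                break
            mn[j] = mnmnj

    # ... and for the concave majorant
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or ((x[k] - x[mjk]) * (mjk - mjmjk)
                                < (x[mjk] - x[mjmjk]) * (k - mjk)):
                break
            mj[k] = mjmjk

    while True:
        # change points of the GCM from high to low
        gcm[0] = high
        i = 0
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = i
        ix = i - 1

        # change points of the LCM from low to high
        lcm[0] = low
        i = 0
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = i
        iv = 1

        # largest distance between GCM and LCM on [low, high] (count units)
        d = 0.0
        if l_gcm != 1 or l_lcm != 1:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = ((lcmiv - gcmi1 + 1)
                          - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1)
                          / (x[gcmix] - x[gcmi1]))
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = ((x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1)
                          / (x[lcmiv] - x[lcmiv1])
                          - (gcmix - lcmiv1 - 1))
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # dip inside the convex minorant part
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # dip inside the concave majorant part
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * C - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew

        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _dip_sorted = njit(cache=False)(_dip_sorted_py)
except Exception:  # pragma: no cover
    _dip_sorted = _dip_sorted_py


def dip_statistic(sample) -> float:
    """Dip statistic of a 1-D sample (any order; constant samples give 0)."""
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    if x.size < 2:
        return 0.0
    return float(_dip_sorted(x))


def _null_dips(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    u = np.sort(rng.random((n_boot, n)), axis=1)
    return np.array([_dip_sorted(row) for row in u])


def dip_pvalue(dip: float, n: int, n_boot: int = 1000,
               seed: int = 0) -> float:
    """Bootstrap p-value of an observed dip against the uniform null."""
    rng = np.random.default_rng(seed)
    null = _null_dips(n, n_boot, rng)
    return float((1 + np.count_nonzero(null >= dip)) / (n_boot + 1))


def dip_test(sample, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and uniform-null bootstrap p-value.

    Samples with fewer than 4 points are declared unimodal by decision
    (dip as computed, p = 1): the dip carries no modality information there.
    """
    x = np.asarray(sample, dtype=float).ravel()
    d = dip_statistic(x)
    if x.size < 4 or d == 0.0:
        return d, 1.0
    return d, dip_pvalue(d, x.size, n_boot=n_boot, seed=seed)


# -------------------------------------------------- cached critical values
_CRIT_CACHE: dict[tuple[int, float, int, int], float] = {}
_GRID = np.array([8, 16, 32, 64, 128, 256, 512, 1024, 2048, 4096,
                  8192, 16384, 32768, 65536])


def critical_value(n: int, alpha: float = 0.001, n_boot: int = 2000,
                   seed: int = 0) -> float:
    """Null critical dip value c(n, alpha): reject unimodality if dip > c.

    Values are simulated once per grid sample size (geometric grid) under the
    uniform null with a fixed seed and interpolated in sqrt(n) * dip, which is
    asymptotically sample-size free.
    """
    if n < 4:
        return np.inf
    n_lo = int(_GRID[np.searchsorted(_GRID, n, side="right") - 1]) \
        if n >= _GRID[0] else int(_GRID[0])
    n_hi = int(_GRID[min(np.searchsorted(_GRID, n, side="left"),
                         len(_GRID) - 1)])

    def grid_crit(m: int) -> float:
        key = (m, alpha, n_boot, seed)
        if key not in _CRIT_CACHE:
            rng = np.random.default_rng(np.random.SeedSequence([seed, m]))
            null = _null_dips(m, n_boot, rng)
            _CRIT_CACHE[key] = float(np.quantile(null, 1.0 - alpha))
        return _CRIT_CACHE[key]

    s_lo = np.sqrt(n_lo) * grid_crit(n_lo)
    if n_hi == n_lo:
        return s_lo / np.sqrt(n)
    s_hi = np.sqrt(n_hi) * grid_crit(n_hi)
    t = (np.log(n) - np.log(n_lo)) / (np.log(n_hi) - np.log(n_lo))
    return ((1 - t) * s_lo + t * s_hi) / np.sqrt(n)
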