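"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a method unrelated to the package's
implementation path: the dip by direct optimization over unimodal CDFs, the
Fowlkes-Mallows index by enumerating all point pairs, and the permuted image
accuracy by exhaustive permutation search.
"""

from itertools import combinations, permutations

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(sample, n_grid: int = 33) -> float:
    """Dip as the minimal sup-distance to a unimodal CDF, by LP.

    A unimodal CDF is convex below its mode and concave above it, and may
    jump only at the mode.  For a fixed mode position the minimal band
    half-width eps enclosing the empirical CDF is a linear program in the
    CDF values at the sample points plus the pre/post-jump values at the
    mode; scanning modes over every sample point and a grid inside every gap
    gives an upper bound that converges to the dip as the grid refines.
    """
    x = np.sort(np.asarray(sample, float))
    n = x.size
    span = x[-1] - x[0]
    modes = list(x) + [x[0] - 0.1 * span - 1e-9, x[-1] + 0.1 * span + 1e-9]
    for a, b in zip(x[:-1], x[1:]):
        if b > a:
            modes.extend(np.linspace(a, b, n_grid)[1:-1])
    best = np.inf
    for m in modes:
        k = int(np.searchsorted(x, m, side="left"))
        k_le = int(np.searchsorted(x, m, side="right"))
        nv = n + 3
        iw, iv, ie = n, n + 1, n + 2
        c = np.zeros(nv)
        c[ie] = 1.0
        A, b_ub = [], []

        def box(col, lo_val, hi_val):
            row = np.zeros(nv); row[col] = -1.0; row[ie] = -1.0
            A.append(row); b_ub.append(-lo_val)
            row = np.zeros(nv); row[col] = 1.0; row[ie] = -1.0
            A.append(row); b_ub.append(hi_val)

        for i in range(1, n + 1):
            box(i - 1, i / n, (i - 1) / n)
        box(iw, k / n, k / n)                       # F just below the mode
        box(iv, k_le / n, k / n)                    # F at/after the mode
        chain_left = list(range(k)) + [iw]
        chain_right = [iv] + list(range(k_le, n))
        for a_, b_ in zip(chain_left[:-1] + [iw], chain_left[1:] + [iv]):
            row = np.zeros(nv); row[a_] = 1.0; row[b_] = -1.0
            A.append(row); b_ub.append(0.0)
        for a_, b_ in zip(chain_right[:-1], chain_right[1:]):
            row = np.zeros(nv); row[a_] = 1.0; row[b_] = -1.0
            A.append(row); b_ub.append(0.0)
        xs_left = list(x[:k]) + [m]
        xs_right = [m] + list(x[k_le:])

        def curvature(cols, xs, sign):
            for i in range(len(cols) - 2):
                h1, h2 = xs[i + 1] - xs[i], xs[i + 2] - xs[i + 1]
                if h1 <= 0 or h2 <= 0:
                    continue
                row = np.zeros(nv)
                row[cols[i]] += -sign / h1
                row[cols[i + 1]] += sign / h1 + sign / h2
                row[cols[i + 2]] += -sign / h2
                A.append(row); b_ub.append(0.0)

        curvature(chain_left, xs_left, +1.0)
        curvature(chain_right, xs_right, -1.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b_ub),
                      bounds=[(0.0, 1.0)] * nv, method="highs")
        if res.success:
            best = min(best, res.fun)
    return best


def fm_bruteforce(labels_a, labels_b) -> float:
    """Fowlkes-Mallows by enumerating every point pair."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    tp = fp = fn = 0
    for i, j in combinations(range(a.size), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        tp += sa and sb
        fn += sa and not sb
        fp += sb and not sa
    if tp == 0:
        return 0.0
    return float(np.sqrt(tp / (tp + fp) * tp / (tp + fn)))


def image_accuracy_bruteforce(truth, predicted) -> float:
    """Permuted pixel accuracy by exhaustive search over label permutations."""
    t = np.asarray(truth).ravel()
    p = np.asarray(predicted).ravel()
    t_labels = np.unique(t)
    p_labels = np.unique(p)
    k = max(len(t_labels), len(p_labels))
    best = 0
    for perm in permutations(range(k), len(p_labels)):
        mapping = dict(zip(p_labels, (t_labels[i] if i < len(t_labels)
                                      else -999 for i in perm)))
        best = max(best, int(np.sum([mapping[v] == tv
                                     for v, tv in zip(p, t)])))
    return best / t.size
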