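"""Brute-force oracles, independent of the LP engine under test.

The flux polytope P = {v : S v = 0, lb <= v <= ub} is bounded, so a linear
objective attains its optimum at a vertex; vertices are enumerated by fixing
subsets of variables at a bound and solving the resulting square system.
The weighted absolute-value objective is linear within each sign orthant,
so its minimum is found by enumerating orthant-restricted vertices.
Exponential, but exact — for fixtures of <= 8 reactions only.
"""

import itertools
import math

import numpy as np

_TOL = 1e-9


def polytope_vertices(S, lb, ub):
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    k = n - rank
    verts = []
    for idx in itertools.combinations(range(n), k):
        for sides in itertools.product((0, 1), repeat=k):
            rows = np.zeros((k, n))
            rhs = np.zeros(k)
            skip = False
            for t, (j, s) in enumerate(zip(idx, sides)):
                bound = lb[j] if s == 0 else ub[j]
                if not math.isfinite(bound):
                    skip = True
                    break
                rows[t, j] = 1.0
                rhs[t] = bound
            if skip:
                continue
            M = np.vstack([S, rows])
            r = np.concatenate([np.zeros(m), rhs])
            if np.linalg.matrix_rank(M) < n:
                continue
            v, *_ = np.linalg.lstsq(M, r, rcond=None)
            if np.max(np.abs(M @ v - r)) > 1e-7:
                continue
            if np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7):
                verts.append(np.clip(v, lb, ub))
    return verts


def oracle_max_flux(S, lb, ub, j):
    """Exact max of v_j over the polytope; None if infeasible."""
    verts = polytope_vertices(S, lb, ub)
    if not verts:
        return None
    return max(v[j] for v in verts)


def oracle_min_weighted_abs(S, lb, ub, w):
    """Exact min of sum_j w_j |v_j| over the polytope; None if infeasible."""
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(lb)
    best = None
    for signs in itertools.product((-1.0, 1.0), repeat=n):
        s = np.array(signs)
        l2 = np.where(s > 0, np.maximum(lb, 0.0), lb)
        u2 = np.where(s > 0, ub, np.minimum(ub, 0.0))
        if np.any(l2 > u2 + _TOL):
            continue
        for v in polytope_vertices(S, l2, u2):
            val = float(np.sum(w * np.abs(v)))
            if best is None or val < best:
                best = val
    return best
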