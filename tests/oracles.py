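"""Independent brute-force recomputations used as test oracles.

Everything here is deliberately naive (plain loops, textbook formulas,
alternative algorithms) and shares no code with the package implementations
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import Delaunay


# ---------------------------------------------------------------- germination

def oracle_gp(trials):
    germinated = 0
    sown = 0
    for t in trials:
        germinated += sum(t.daily_counts)
        sown += t.n_sown
    return germinated / sown


def oracle_gr_mean(trials):
    vals = []
    for t in trials:
        acc = 0.0
        for day, count in enumerate(t.daily_counts, start=1):
            acc += count / day
        vals.append(acc / t.n_sown)
    return sum(vals) / len(vals)


def oracle_niche(gps_by_temp):
    gmax = max(gps_by_temp.values())
    if gmax == 0:
        return None, None, None
    occ = {t: g / gmax for t, g in gps_by_temp.items()}
    total = sum(occ.values())
    prop = {t: o / total for t, o in occ.items()}
    btn = sum(occ.values()) / len(occ)
    return occ, prop, btn


def oracle_ratio_response(a, b):
    return None if a + b == 0 else (a - b) / (a + b)


def oracle_cwm(counts, trait_values):
    pairs = [(n, trait_values[sp]) for sp, n in counts.items()
             if n > 0 and trait_values.get(sp) is not None]
    denom = sum(n for n, _ in pairs)
    if denom == 0:
        return None
    return sum(n * v for n, v in pairs) / denom


# ---------------------------------------------------------------- geometry

def oracle_hull_volume(points):
    """Hull volume as the sum of Delaunay simplex volumes (det formula)."""
    points = np.asarray(points, dtype=float)
    m = points.shape[1]
    tri = Delaunay(points)
    vol = 0.0
    for simplex in tri.simplices:
        verts = points[simplex]
        mat = verts[1:] - verts[0]
        vol += abs(np.linalg.det(mat)) / math.factorial(m)
    return vol


def oracle_hull_vertices(points, tol=1e-9):
    """Hull vertex detection by LP: point i is interior iff it is a convex
    combination of the others."""
    points = np.asarray(points, dtype=float)
    n, m = points.shape
    vertices = []
    for i in range(n):
        others = np.delete(points, i, axis=0)
        # find lambda >= 0, sum lambda = 1, others' lambda = points[i]
        a_eq = np.vstack([others.T, np.ones(n - 1)])
        b_eq = np.concatenate([points[i], [1.0]])
        res = linprog(np.zeros(n - 1), A_eq=a_eq, b_eq=b_eq,
                      bounds=[(0, None)] * (n - 1), method="highs")
        if not res.success:
            vertices.append(i)
    return np.array(vertices, dtype=int)


def oracle_prim_mst_edges(dist):
    """O(S^2) Prim's algorithm; returns MST edges as (i, j) pairs."""
    n = dist.shape[0]
    in_tree = [0]
    edges = []
    best = {j: (dist[0, j], 0) for j in range(1, n)}
    while len(in_tree) < n:
        j = min(best, key=lambda k: best[k][0])
        d, i = best.pop(j)
        edges.append((i, j))
        in_tree.append(j)
        for k in list(best):
            if dist[j, k] < best[k][0]:
                best[k] = (dist[j, k], j)
    return edges


def oracle_feve(points, weights):
    points = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    s = len(points)
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    edges = oracle_prim_mst_edges(dist)
    ew = [dist[i, j] / (w[i] + w[j]) for i, j in edges]
    total = sum(ew)
    pew = [e / total for e in ew] if total > 0 else [1.0 / (s - 1)] * (s - 1)
    thr = 1.0 / (s - 1)
    return (sum(min(p, thr) for p in pew) - thr) / (1.0 - thr)


def oracle_fdiv(points, weights):
    points = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    verts = oracle_hull_vertices(points)
    g = points[verts].mean(axis=0)
    dg = np.sqrt(((points - g) ** 2).sum(-1))
    dbar = dg.mean()
    delta_d = float((w * (dg - dbar)).sum())
    delta_abs = float((w * np.abs(dg - dbar)).sum())
    if delta_abs + dbar == 0:
        return 1.0
    return (delta_d + dbar) / (delta_abs + dbar)


# ---------------------------------------------------------------- inference

def oracle_lmm_loglik(y, x, blocks, sigma_b2, sigma_e2):
    """Direct multivariate-normal log-likelihood with explicit covariance."""
    n = len(y)
    z = np.zeros((n, len(set(blocks))))
    labels = {b: i for i, b in enumerate(dict.fromkeys(blocks))}
    for i, b in enumerate(blocks):
        z[i, labels[b]] = 1.0
    v = sigma_e2 * np.eye(n) + sigma_b2 * (z @ z.T)
    vinv = np.linalg.inv(v)
    beta = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y)
    r = y - x @ beta
    sign, logdet = np.linalg.slogdet(v)
    return -0.5 * (n * math.log(2 * math.pi) + logdet + r @ vinv @ r)
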