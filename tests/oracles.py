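"""Independent reference implementations used only to check the package.

Each oracle computes its quantity by a different route than the library:
integer-arithmetic and brute-force enumeration for the discrete tests,
a Lance-Williams recursion for Ward.D2 linkage heights, and dense surface
sampling (with an independent point-to-triangle routine) for envelope
distances.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# hypergeometric upper tail
# ---------------------------------------------------------------------------

def hypergeom_tail_fraction(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k), X ~ Hypergeom(N, K, n), by exact rational arithmetic."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(max(k, 0), min(K, n) + 1):
        acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return float(min(acc, Fraction(1)))


def hypergeom_tail_enumeration(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by enumerating every size-n draw from a universe of N
    items whose first K are cluster members."""
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for i in draw if i < K) >= k:
            hits += 1
    return hits / total if total else 1.0


# ---------------------------------------------------------------------------
# Ward.D2 agglomeration via the Lance-Williams recursion
# ---------------------------------------------------------------------------

def ward_d2_heights(x: np.ndarray) -> list[float]:
    """Merge heights of Ward.D2 clustering on Euclidean distances.

    Naive agglomeration: start from the pairwise Euclidean distance matrix,
    repeatedly merge the closest pair and update distances with

        d(i∪j, k) = sqrt(((n_i + n_k) d_ik^2 + (n_j + n_k) d_jk^2
                          - n_k d_ij^2) / (n_i + n_j + n_k)).
    """
    n = x.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {
        (i, j): float(np.linalg.norm(x[i] - x[j]))
        for i in range(n) for j in range(i + 1, n)
    }
    heights = []
    next_id = n
    for _ in range(n - 1):
        (i, j), dij = min(d.items(), key=lambda kv: kv[1])
        heights.append(dij)
        ni, nj = len(clusters[i]), len(clusters[j])
        merged = clusters.pop(i) + clusters.pop(j)
        new_d = {}
        for k in clusters:
            nk = len(clusters[k])
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            new_d[(k, next_id)] = math.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
        d = {
            (a, b): v for (a, b), v in d.items()
            if i not in (a, b) and j not in (a, b)
        }
        d.update(new_d)
        clusters[next_id] = merged
        next_id += 1
    return heights


# ---------------------------------------------------------------------------
# Mann-Whitney U two-sided p by full permutation enumeration
# ---------------------------------------------------------------------------

def mannwhitney_exact_p(x, y) -> float:
    """Two-sided exact p: 2 * min(P(U <= u), P(U >= u)) over all
    reassignments of the pooled sample, capped at 1."""
    x = list(x)
    y = list(y)
    pooled = x + y
    m = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) \
            + 0.5 * sum(1 for a in xs for b in ys if a == b)

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), m):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.asarray(us)
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# envelope distance by dense surface sampling
# ---------------------------------------------------------------------------

def _fibonacci_dirs(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def ellipsoid_surface_distance_oracle(axes, point, n_samples: int = 1_000_000) -> float:
    """Min distance from a point (ellipsoid frame) to the surface via
    >= 1e6 quasi-uniform samples, refined by golden-section-free local
    search on the two best parameter neighborhoods."""
    axes = np.asarray(axes, float)
    point = np.asarray(point, float)
    dirs = _fibonacci_dirs(n_samples)
    surf = dirs / np.sqrt(np.sum((dirs / axes) ** 2, axis=1))[:, None]
    d2 = np.sum((surf - point) ** 2, axis=1)
    best = np.argmin(d2)
    # local refinement: dense re-sampling of directions around the best one
    u0 = dirs[best]
    d_best = math.sqrt(d2[best])
    for shrink in (1e-2, 1e-3, 1e-4):
        jitter = _fibonacci_dirs(4000) * shrink
        cand = u0[None, :] + jitter
        cand /= np.linalg.norm(cand, axis=1)[:, None]
        s = cand / np.sqrt(np.sum((cand / axes) ** 2, axis=1))[:, None]
        dd = np.sqrt(np.sum((s - point) ** 2, axis=1))
        j = np.argmin(dd)
        if dd[j] < d_best:
            d_best = float(dd[j])
            u0 = cand[j]
    return d_best


def _point_triangle_distance(p, a, b, c) -> float:
    """Exact distance from point p to triangle (a, b, c); independent
    implementation (barycentric clamping)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(p - a))
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(p - b))
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return float(np.linalg.norm(p - (a + v * ab)))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(p - c))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return float(np.linalg.norm(p - (a + w * ac)))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(np.linalg.norm(p - (b + w * (c - b))))
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    return float(np.linalg.norm(p - (a + v * ab + w * ac)))


def mesh_surface_distance_oracle(mesh, point, n_samples: int = 1_000_000,
                                 seed: int = 0) -> float:
    """Min distance from a point to a triangulated surface via dense random
    surface sampling, refined by exact point-to-triangle distance on the
    faces nearest the best samples."""
    import trimesh

    point = np.asarray(point, float)
    samples, face_idx = trimesh.sample.sample_surface(mesh, n_samples, seed=seed)
    d = np.linalg.norm(samples - point, axis=1)
    near = np.argsort(d)[:400]
    faces = np.unique(face_idx[near])
    tri = mesh.triangles[faces]
    return min(
        _point_triangle_distance(point, t[0], t[1], t[2]) for t in tri
    )
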