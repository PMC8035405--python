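"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations — plain Python loops, recompute-from-
scratch at every step — kept separate from the package so they share no
code path with what they check.
"""

from __future__ import annotations

import numpy as np


def ward_cost(points_a: np.ndarray, points_b: np.ndarray) -> float:
    na, nb = len(points_a), len(points_b)
    mu_a = points_a.mean(axis=0)
    mu_b = points_b.mean(axis=0)
    d2 = float(np.sum((mu_a - mu_b) ** 2))
    return na * nb / (na + nb) * d2


def naive_ward_merges(coords: np.ndarray) -> list[tuple[int, int, float, int]]:
    """O(N^3) greedy Ward agglomeration: recompute every pair cost at every
    step; ties broken toward the lexicographically smallest (a, b) pair of
    creation-order cluster ids. Returns (a, b, cost, new_size) per merge."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        means = {k: coords[v].mean(axis=0) for k, v in clusters.items()}
        sizes = {k: len(v) for k, v in clusters.items()}
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                d = means[a] - means[b]
                c = sizes[a] * sizes[b] / (sizes[a] + sizes[b]) * float(d @ d)
                key = (c, a, b)
                if best is None or key < best:
                    best = key
        c, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, c, len(clusters[next_id])))
        next_id += 1
    return merges


def naive_cmi(coords: np.ndarray, labels: np.ndarray) -> float:
    """CMI from scratch: naive Ward merges, explicit membership at every k,
    full Gini recomputation, trapezoid rule."""
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    n = len(coords)
    p = np.mean(labels == 0)
    g_total = 1 - p**2 - (1 - p) ** 2
    merges = naive_ward_merges(coords)

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    ys = [0.0]
    for a, b, _, _ in merges:
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
        impurity = 0.0
        for members in clusters.values():
            pc = np.mean(labels[members] == 0)
            impurity += len(members) / n * (1 - pc**2 - (1 - pc) ** 2)
        ys.append(impurity / g_total)
    xs = np.arange(n) / (n - 1)
    return float(np.trapezoid(ys, xs))


def naive_otsu_index(counts: np.ndarray, centers: np.ndarray) -> int:
    """Exhaustive search over all split points of a histogram for the one
    maximizing between-class variance; ties toward the lower index."""
    total = counts.sum()
    best_idx, best_var = 0, -1.0
    for t in range(len(counts) - 1):
        w0 = counts[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_idx = var, t
    return best_idx


def sobel_response_direct(slice2d: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct 3×3 convolution with edge replication, nested loops."""
    h, w = slice2d.shape
    padded = np.pad(slice2d, 1, mode="edge")
    out = np.zeros_like(slice2d, dtype=float)
    flipped = kernel[::-1, ::-1]  # convolution, not correlation
    for i in range(h):
        for j in range(w):
            out[i, j] = float(np.sum(padded[i : i + 3, j : j + 3] * flipped))
    return out


def box_surface_closed_form(a: int, b: int, c: int, voxel: tuple[float, float, float]) -> float:
    """Closed-form exposed-face area of an a×b×c-voxel box."""
    dz, dy, dx = voxel
    return 2 * (b * c * dy * dx + a * c * dz * dx + a * b * dz * dy)
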