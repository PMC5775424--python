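"""Independent brute-force reference implementations used only by tests.

These deliberately recompute everything from first principles — naive
threshold scans, greedy Ward merges that re-evaluate the objective at
every step, direct formula evaluation — so they share no code path with
the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_otsu(pixels: np.ndarray) -> int:
    """Exhaustive between-class-variance scan over every integer cut."""
    flat = np.asarray(pixels).ravel().astype(float)
    best_t, best_v = None, -1.0
    for t in range(int(flat.min()), int(flat.max())):
        bg = flat[flat <= t]
        fg = flat[flat > t]
        if bg.size == 0 or fg.size == 0:
            continue
        w0, w1 = bg.size / flat.size, fg.size / flat.size
        v = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def ward_partitions(coords: np.ndarray) -> dict[int, set[frozenset]]:
    """Greedy Ward agglomeration re-evaluating the ESS increase per pair.

    Returns, for every cluster count m = N..1, the partition as a set
    of frozensets of pixel indices.  Tie-break: lowest (i, j) pair.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    out = {n: set(clusters)}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca = coords[list(clusters[a])]
            cb = coords[list(clusters[b])]
            na, nb = len(ca), len(cb)
            delta = (na * nb / (na + nb)) * float(
                np.sum((ca.mean(axis=0) - cb.mean(axis=0)) ** 2))
            key = (delta, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
        out[len(clusters)] = set(clusters)
    return out


def direct_gli(partition: set[frozenset], colors: np.ndarray) -> float:
    """Eq-by-eq evaluation: weighted average of 1 − (Y²+R²)/(Y+R)²."""
    n = sum(len(c) for c in partition)
    total = 0.0
    for c in partition:
        idx = list(c)
        y = int(np.sum(colors[idx] == 0))
        r = int(np.sum(colors[idx] == 1))
        imp = 1 - (y**2 + r**2) / (y + r) ** 2
        total += (y + r) / n * imp
    return total


def brute_force_cmi(coords: np.ndarray, colors: np.ndarray) -> dict:
    """Full clustering → impurity-curve → index chain, all by brute force."""
    n = len(coords)
    parts = ward_partitions(coords)
    gli = {m: direct_gli(parts[m], colors) for m in range(1, n + 1)}
    exact = (2 / np.log2(n + 1)) * sum(
        np.log2((m + 1) / m) * gli[m] for m in range(1, n + 1))
    n_prime = int(np.floor(np.log2(n)))
    approx = (2 / (n_prime + 1)) * sum(gli[2**j] for j in range(n_prime + 1))
    return {"partitions": parts, "gli": gli, "cmi_exact": float(exact),
            "cmi_approx": float(approx), "n_prime": n_prime}
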