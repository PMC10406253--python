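"""Independent brute-force oracles used to pin down expected values."""

from __future__ import annotations

import numpy as np


def bruteforce_density_clusters(mask, eps, v_min):
    """O(n^2) reference implementation of the core/border cluster rules.

    Returns a set of ``(frozenset(voxels), frozenset(core))`` pairs so the
    partition can be compared up to cluster relabeling.
    """
    pts = [tuple(p) for p in np.argwhere(np.asarray(mask, dtype=bool))]

    def dist(a, b):
        return ((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2) ** 0.5

    core = [
        p
        for p in pts
        if sum(1 for q in pts if q != p and dist(p, q) <= eps) > v_min
    ]
    core_set = set(core)

    # Union-find over core points within eps of each other.
    parent = {p: p for p in core}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, p in enumerate(core):
        for q in core[i + 1 :]:
            if dist(p, q) <= eps:
                union(p, q)

    clusters: dict = {}
    for p in core:
        clusters.setdefault(find(p), {"voxels": set(), "core": set()})
        clusters[find(p)]["voxels"].add(p)
        clusters[find(p)]["core"].add(p)

    for p in pts:
        if p in core_set:
            continue
        candidates = [q for q in core if dist(p, q) <= eps]
        if not candidates:
            continue
        nearest = min(candidates, key=lambda q: (dist(p, q), q))
        clusters[find(nearest)]["voxels"].add(p)

    return {
        (frozenset(c["voxels"]), frozenset(c["core"]))
        for c in clusters.values()
    }


def dice(a, b) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def random_mask(rng, shape, density=None):
    density = density if density is not None else rng.uniform(0.1, 0.6)
    return rng.random(shape) < density
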