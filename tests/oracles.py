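"""Independent brute-force reference implementations used only by tests.

Everything here is written from the published definitions by direct
enumeration, deliberately avoiding the package's own code paths, so that
agreement is an informative check rather than a tautology.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np


# -- beta diversity ---------------------------------------------------------


def link_set(plant_ids, bird_ids, weights) -> set[tuple[str, str]]:
    out = set()
    for i, p in enumerate(plant_ids):
        for j, b in enumerate(bird_ids):
            if weights[i][j] > 0:
                out.add((p, b))
    return out


def sorensen(A: set, B: set) -> float:
    a = b = c = 0
    for x in A:
        if x in B:
            a += 1
        else:
            b += 1
    for x in B:
        if x not in A:
            c += 1
    return (b + c) / (2 * a + b + c)


def species_beta_bf(net_a, net_b) -> float:
    A = {("plant", p) for p in net_a.plant_ids} | {("bird", q) for q in net_a.bird_ids}
    B = {("plant", p) for p in net_b.plant_ids} | {("bird", q) for q in net_b.bird_ids}
    return sorensen(A, B)


def interaction_beta_bf(net_a, net_b) -> float:
    return sorensen(
        link_set(net_a.plant_ids, net_a.bird_ids, net_a.weights),
        link_set(net_b.plant_ids, net_b.bird_ids, net_b.weights),
    )


def rewiring_beta_bf(net_a, net_b):
    shared_p = [p for p in net_a.plant_ids if p in net_b.plant_ids]
    shared_b = [q for q in net_a.bird_ids if q in net_b.bird_ids]
    if not shared_p or not shared_b:
        return None
    sub_a = {
        (p, q)
        for (p, q) in link_set(net_a.plant_ids, net_a.bird_ids, net_a.weights)
        if p in shared_p and q in shared_b
    }
    sub_b = {
        (p, q)
        for (p, q) in link_set(net_b.plant_ids, net_b.bird_ids, net_b.weights)
        if p in shared_p and q in shared_b
    }
    if not sub_a and not sub_b:
        return None
    return sorensen(sub_a, sub_b)


# -- weighted NODF ----------------------------------------------------------


def wnodf_bf(w: np.ndarray) -> float:
    """Literal transcription of the published quantitative NODF procedure:
    rank rows/columns by decreasing fill (weighted totals break ties), pairs
    with strictly decreasing fill contribute the percentage of the sparser
    member's positive cells that are strictly exceeded by the denser member.
    """

    def axis_pairs(mat):
        fill = [sum(1 for v in row if v > 0) for row in mat]
        tot = [sum(row) for row in mat]
        order = sorted(range(len(mat)), key=lambda i: (-fill[i], -tot[i]))
        contribs = []
        for ii, jj in combinations(range(len(order)), 2):
            i, j = order[ii], order[jj]
            if fill[i] <= fill[j] or fill[i] == 0 or fill[j] == 0:
                contribs.append(0.0)
                continue
            k = sum(1 for a, b in zip(mat[i], mat[j]) if b > 0 and a > b)
            contribs.append(100.0 * k / fill[j])
        return contribs

    rows = axis_pairs([list(r) for r in w])
    cols = axis_pairs([list(r) for r in w.T])
    return sum(rows + cols) / (len(rows) + len(cols))


# -- bipartite modularity ---------------------------------------------------


def barber_q_bf(w: np.ndarray, g_plants, g_birds) -> float:
    F = float(np.sum(w))
    r = [float(sum(row)) for row in w]
    c = [float(sum(col)) for col in w.T]
    q = 0.0
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            if g_plants[i] == g_birds[j]:
                q += w[i][j] - r[i] * c[j] / F
    return q / F


def _set_partitions(items: list):
    """All set partitions (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1 :]
        yield [[first]] + part


def max_barber_q_bf(w: np.ndarray) -> float:
    """Exact maximum Barber Q.

    Modules are induced by the plant-side partition: given it, every bird
    independently joins the module maximizing its contribution (or sits
    alone, contributing zero), so enumerating plant partitions suffices.
    """
    F = float(np.sum(w))
    r = np.sum(w, axis=1)
    c = np.sum(w, axis=0)
    best = 0.0
    for part in _set_partitions(list(range(w.shape[0]))):
        q = 0.0
        for j in range(w.shape[1]):
            contrib = 0.0
            for module in part:
                val = sum(w[i][j] for i in module) - sum(r[i] for i in module) * c[j] / F
                contrib = max(contrib, val)
            q += contrib
        best = max(best, q / F)
    return best


# -- random networks --------------------------------------------------------


def random_weight_matrix(rng: np.random.Generator, max_dim: int = 6) -> np.ndarray:
    """Random nonnegative matrix with no all-zero rows/columns."""
    while True:
        nr = int(rng.integers(2, max_dim + 1))
        nc = int(rng.integers(2, max_dim + 1))
        w = rng.integers(0, 4, (nr, nc)) * np.round(rng.random((nr, nc)) * 5, 2)
        if w.sum() > 0 and (w.sum(1) > 0).all() and (w.sum(0) > 0).all():
            return w
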