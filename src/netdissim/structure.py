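"""Weighted structure metrics of bipartite networks and their PCA composite.

Five network-level descriptors are computed per local network:

* weighted connectance — Shannon-entropy ("effective partners") weighted
  linkage density divided by total species count;
* wNODF — weighted nestedness by overlap and decreasing fill, 0–100;
* interaction evenness — Shannon evenness of the cell weights;
* mean PDI — interaction-total-weighted mean of species-level Paired
  Difference Index (specialization), both guilds pooled;
* modularity — Barber's bipartite modularity Q maximized by a weighted
  label-propagation-plus-agglomeration search (DIRTLPAwb+-style).

The composite structural dissimilarity z-scores the metric columns, runs a
PCA and takes Euclidean distances between the retained component scores.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix, _as_matrix, _pca_scores
from .netio import InteractionMatrix

__all__ = [
    "StructuralProfile",
    "ModulePartition",
    "weighted_connectance",
    "wnodf",
    "interaction_evenness",
    "pdi",
    "mean_pdi",
    "barber_modularity",
    "dirtlpawb_modularity",
    "structural_profile",
    "profiles_frame",
    "structural_dissimilarity",
    "write_module_assignments",
]

METRIC_COLUMNS = (
    "weighted_connectance",
    "wnodf",
    "interaction_evenness",
    "mean_pdi",
    "modularity_q",
)


@dataclass(frozen=True)
class StructuralProfile:
    network_id: str
    weighted_connectance: float
    wnodf: float
    interaction_evenness: float
    mean_pdi: float
    modularity_q: float


@dataclass(frozen=True)
class ModulePartition:
    """Module assignment over guild-tagged nodes plus its Barber Q."""

    node_labels: tuple[str, ...]
    module_assignment: dict[str, int]
    q: float


def weighted_connectance(net: InteractionMatrix, base: float = 2.0) -> float:
    """Weighted linkage density over species count (Bersier convention).

    LDw = 1/2 [ sum_i (r_i/F) b^{H_i} + sum_j (c_j/F) b^{H_j} ] with H the
    base-``base`` Shannon entropy of each row/column weight distribution and
    r_i, c_j the marginal totals; returns LDw / (n_plants + n_birds).
    """
    w = net.weights
    F = w.sum()
    if F <= 0:
        raise ValueError("total weight must be positive")
    log = np.log2 if base == 2.0 else (lambda x: np.log(x) / np.log(base))
    r = w.sum(axis=1)
    c = w.sum(axis=0)

    def eff(margin: np.ndarray, axis_weights: np.ndarray) -> float:
        total = 0.0
        for k, m in enumerate(margin):
            if m <= 0:
                continue
            p = axis_weights[k] / m
            p = p[p > 0]
            H = float(-(p * log(p)).sum())
            total += (m / F) * base**H
        return total

    ldw = 0.5 * (eff(r, w) + eff(c, w.T))
    return ldw / (net.n_plants + net.n_birds)


def wnodf(net: InteractionMatrix) -> float:
    """Weighted NODF on the raw weight matrix, scaled 0-100.

    Reference-implementation semantics (as used for quantitative bipartite
    webs): rows/columns are ranked by decreasing fill, ties broken by
    decreasing weighted total; an unordered pair contributes only when the
    fill strictly decreases from the better-ranked member, and then equals
    100 x (#cells where the lower-fill member is positive but strictly
    smaller) / (its fill).  The statistic averages over all row pairs plus
    all column pairs.
    """
    w = net.weights
    if w.shape[0] < 2 or w.shape[1] < 2:
        raise ValueError("wNODF needs at least 2 rows and 2 columns")

    def pair_sum(mat: np.ndarray) -> tuple[float, int]:
        fills = (mat > 0).sum(axis=1)
        m = mat.shape[0]
        acc = 0.0
        count = 0
        for i in range(m):
            for j in range(i + 1, m):
                count += 1
                if fills[i] == fills[j] or fills[i] == 0 or fills[j] == 0:
                    continue
                top, bot = (i, j) if fills[i] > fills[j] else (j, i)
                mask = mat[bot] > 0
                k = int(np.count_nonzero(mat[top][mask] > mat[bot][mask]))
                acc += 100.0 * k / fills[bot]
        return acc, count

    rows_sum, rows_n = pair_sum(w)
    cols_sum, cols_n = pair_sum(w.T)
    return (rows_sum + cols_sum) / (rows_n + cols_n)


def interaction_evenness(net: InteractionMatrix) -> float:
    """Shannon evenness of cell weights: H / ln(n_plants * n_birds)."""
    w = net.weights
    F = w.sum()
    if F <= 0:
        raise ValueError("total weight must be positive")
    denom = np.log(net.n_plants * net.n_birds)
    if denom == 0:  # single-cell network
        return 0.0
    p = w[w > 0] / F
    return float(-(p * np.log(p)).sum() / denom)


def pdi(flows: Sequence[float], n_potential_partners: int | None = None) -> float:
    """Paired Difference Index of one species' flow vector, in [0, 1].

    Flows are max-normalized so the strongest partner has P1 = 1; zeros pad
    up to the number of potential partners.  PDI = sum(P1 - Pi)/(H - 1) for
    i = 2..H.  1 = perfect specialist, 0 = uniform generalist.
    """
    f = np.asarray(flows, dtype=float)
    if n_potential_partners is None:
        n_potential_partners = f.size
    H = int(n_potential_partners)
    if H < 2:
        raise ValueError("PDI undefined for fewer than 2 potential partners")
    if f.max(initial=0.0) <= 0:
        raise ValueError("PDI needs at least one positive flow")
    if f.size < H:
        f = np.concatenate([f, np.zeros(H - f.size)])
    p = np.sort(f / f.max())[::-1]
    return float((p[0] - p[1:]).sum() / (H - 1))


def mean_pdi(net: InteractionMatrix) -> float:
    """Interaction-total-weighted mean PDI over all species of both guilds.

    A species' potential partners are all members of the opposite guild in
    its network.  Guilds with a single member are skipped with a warning
    (their species' PDI is undefined).
    """
    vals: list[float] = []
    wts: list[float] = []
    if net.n_birds >= 2:
        for i in range(net.n_plants):
            row = net.weights[i]
            if row.max() > 0:
                vals.append(pdi(row, net.n_birds))
                wts.append(row.sum())
    else:
        warnings.warn(f"{net.network_id}: single bird, plant PDIs undefined", stacklevel=2)
    if net.n_plants >= 2:
        for j in range(net.n_birds):
            col = net.weights[:, j]
            if col.max() > 0:
                vals.append(pdi(col, net.n_plants))
                wts.append(col.sum())
    else:
        warnings.warn(f"{net.network_id}: single plant, bird PDIs undefined", stacklevel=2)
    if not vals:
        raise ValueError(f"{net.network_id}: no species with defined PDI")
    return float(np.average(vals, weights=wts))


def _tag_nodes(net: InteractionMatrix) -> tuple[str, ...]:
    return tuple(f"P::{p}" for p in net.plant_ids) + tuple(
        f"B::{b}" for b in net.bird_ids
    )


def barber_modularity(net: InteractionMatrix, partition: ModulePartition | Mapping[str, int]) -> float:
    """Barber's bipartite modularity Q of a given module assignment.

    Q = (1/F) sum_ij [w_ij - r_i c_j / F] 1{g(plant_i) = g(bird_j)}.
    """
    assignment = (
        partition.module_assignment if isinstance(partition, ModulePartition) else dict(partition)
    )
    nodes = _tag_nodes(net)
    missing = [n for n in nodes if n not in assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:3]}")
    g_p = np.array([assignment[f"P::{p}"] for p in net.plant_ids])
    g_b = np.array([assignment[f"B::{b}"] for b in net.bird_ids])
    w = net.weights
    F = w.sum()
    r = w.sum(axis=1)
    c = w.sum(axis=0)
    same = g_p[:, None] == g_b[None, :]
    return float(((w - np.outer(r, c) / F) * same).sum() / F)


def _q_from_arrays(w: np.ndarray, g_p: np.ndarray, g_b: np.ndarray) -> float:
    F = w.sum()
    B = w - np.outer(w.sum(axis=1), w.sum(axis=0)) / F
    return float((B * (g_p[:, None] == g_b[None, :])).sum() / F)


def dirtlpawb_modularity(
    net: InteractionMatrix, seed: int = 0, restarts: int = 40
) -> ModulePartition:
    """Maximize weighted Barber Q by seeded label propagation plus module
    agglomeration, keeping the best of ``restarts`` initializations.

    Each node starts in its own module; nodes are repeatedly moved to the
    module with the largest Q gain (ties broken toward the lowest module
    index) until no move improves Q, after which pairwise module merges with
    positive gain are applied and propagation resumes.
    """
    rng = np.random.default_rng(seed)
    w = net.weights
    np_, nb = w.shape
    F = w.sum()
    B = w - np.outer(w.sum(axis=1), w.sum(axis=0)) / F  # modularity matrix

    def q_of(g_p: np.ndarray, g_b: np.ndarray) -> float:
        return float((B * (g_p[:, None] == g_b[None, :])).sum() / F)

    best_q = -np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    n_nodes = np_ + nb
    for restart in range(max(1, restarts)):
        if restart == 0:
            g_p = np.arange(np_)
            g_b = np_ + np.arange(nb)
        else:  # random coarse initializations diversify the search
            k0 = int(rng.integers(2, n_nodes + 1))
            g_p = rng.integers(0, k0, np_)
            g_b = rng.integers(0, k0, nb)
        improved = True
        while improved:
            improved = False
            # local moves (including splitting off into a fresh module)
            moved = True
            while moved:
                moved = False
                order = rng.permutation(n_nodes)
                for node in order:
                    labels = np.unique(np.concatenate([g_p, g_b]))
                    fresh = labels.max() + 1
                    if node < np_:
                        # plant: gain of joining module m = sum_j B[node, j] 1{g_b[j]=m}
                        gains = np.array([B[node][g_b == m].sum() for m in labels])
                        current = B[node][g_b == g_p[node]].sum()
                        k = int(np.argmax(gains))
                        target, gain = labels[k], gains[k]
                        if gain < 0.0:  # a lone plant contributes zero
                            target, gain = fresh, 0.0
                        if gain > current + 1e-13 and target != g_p[node]:
                            g_p[node] = target
                            moved = True
                    else:
                        j = node - np_
                        gains = np.array([B[:, j][g_p == m].sum() for m in labels])
                        current = B[:, j][g_p == g_b[j]].sum()
                        k = int(np.argmax(gains))
                        target, gain = labels[k], gains[k]
                        if gain < 0.0:  # a lone bird contributes zero
                            target, gain = fresh, 0.0
                        if gain > current + 1e-13 and target != g_b[j]:
                            g_b[j] = target
                            moved = True
            # agglomeration: merge the module pair with the best positive gain
            merged = True
            while merged:
                merged = False
                labels = np.unique(np.concatenate([g_p, g_b]))
                base_q = q_of(g_p, g_b)
                best_gain, best_pair = 1e-13, None
                for a_i in range(len(labels)):
                    for b_i in range(a_i + 1, len(labels)):
                        a, b = labels[a_i], labels[b_i]
                        pa, ba = g_p == a, g_b == a
                        pb, bb = g_p == b, g_b == b
                        gain = (B[np.ix_(pa, bb)].sum() + B[np.ix_(pb, ba)].sum()) / F
                        if gain > best_gain:
                            best_gain, best_pair = gain, (a, b)
                if best_pair is not None:
                    a, b = best_pair
                    g_p[g_p == b] = a
                    g_b[g_b == b] = a
                    merged = True
                    improved = True
        q = q_of(g_p, g_b)
        if q > best_q:
            best_q, best = q, (g_p.copy(), g_b.copy())
    assert best is not None
    g_p, g_b = best
    # relabel modules consecutively in order of first appearance
    remap: dict[int, int] = {}
    for lab in np.concatenate([g_p, g_b]):
        if lab not in remap:
            remap[int(lab)] = len(remap)
    nodes = _tag_nodes(net)
    assignment = {
        **{f"P::{p}": remap[int(g_p[i])] for i, p in enumerate(net.plant_ids)},
        **{f"B::{b}": remap[int(g_b[j])] for j, b in enumerate(net.bird_ids)},
    }
    return ModulePartition(node_labels=nodes, module_assignment=assignment, q=best_q)


def structural_profile(net: InteractionMatrix, seed: int = 0, restarts: int = 40) -> StructuralProfile:
    """All five structure metrics for one network (modularity seeded)."""
    return StructuralProfile(
        network_id=net.network_id,
        weighted_connectance=weighted_connectance(net),
        wnodf=wnodf(net),
        interaction_evenness=interaction_evenness(net),
        mean_pdi=mean_pdi(net),
        modularity_q=dirtlpawb_modularity(net, seed=seed, restarts=restarts).q,
    )


def profiles_frame(profiles: Sequence[StructuralProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [{**{"network_id": p.network_id}, **{m: getattr(p, m) for m in METRIC_COLUMNS}} for p in profiles]
    ).set_index("network_id")


def structural_dissimilarity(
    profiles: Sequence[StructuralProfile] | pd.DataFrame,
    variance_target: float = 0.85,
    n_components: int | None = None,
) -> DistanceMatrix:
    """PCA-composite structural dissimilarity between network profiles."""
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_frame(profiles)
    if len(frame) < 3:
        raise ValueError("need at least 3 profiles")
    cols = frame[list(METRIC_COLUMNS)]
    if (cols.std(ddof=1) == 0).all():  # identical profiles: zero dissimilarity
        n = len(frame)
        return _as_matrix([str(i) for i in frame.index], np.zeros((n, n)), "quantitative")
    scores = _pca_scores(cols, variance_target, n_components)
    diff = scores[:, None, :] - scores[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    return _as_matrix([str(i) for i in frame.index], values, "quantitative")


def write_module_assignments(
    partitions: Mapping[str, ModulePartition], path
) -> pd.DataFrame:
    """TSV of module memberships: network_id, guild, species_id, module, q."""
    rows = []
    for net_id, part in partitions.items():
        for node, module in part.module_assignment.items():
            guild, species = node.split("::", 1)
            rows.append(
                {
                    "network_id": net_id,
                    "guild": {"P": "plant", "B": "bird"}[guild],
                    "species_id": species,
                    "module": module,
                    "q": part.q,
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame
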