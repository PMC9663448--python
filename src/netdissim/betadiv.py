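"""Whittaker/Sorensen-family beta diversity of paired bipartite networks.

Three facets of pairwise network dissimilarity:

* ``beta_s``  -- turnover of species composition (both guilds pooled,
  guild-tagged so a plant and a bird sharing a name never collide);
* ``beta_wn`` -- dissimilarity of the binarized whole-network link sets;
* ``beta_os`` -- rewiring: ``beta_wn`` restricted to the subwebs induced by
  the plants and birds shared by both networks.  Undefined when either guild
  shares no species or both subwebs are linkless.

All three use the Sorensen form (b + c) / (2a + b + c) on sets, where a is
the count of shared elements and b, c the counts unique to each side.  Link
sets are binarized even for quantitative networks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix
from .netio import InteractionMatrix

__all__ = [
    "BetaPartition",
    "sorensen_dissimilarity",
    "species_beta",
    "interaction_beta",
    "rewiring_beta",
    "beta_partition",
    "pairwise_beta",
    "pair_table",
    "shared_pairs_subset",
]


def sorensen_dissimilarity(set_a: Iterable, set_b: Iterable) -> float:
    """(b + c) / (2a + b + c); undefined (ValueError) when both sets empty."""
    A, B = set(set_a), set(set_b)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    denom = 2 * a + b + c
    if denom == 0:
        raise ValueError("Sorensen dissimilarity undefined for two empty sets")
    return (b + c) / denom


def species_beta(net_a: InteractionMatrix, net_b: InteractionMatrix) -> float:
    return sorensen_dissimilarity(net_a.species(), net_b.species())


def interaction_beta(net_a: InteractionMatrix, net_b: InteractionMatrix) -> float:
    return sorensen_dissimilarity(net_a.links(), net_b.links())


def _shared_subweb_links(
    net: InteractionMatrix, plants: set[str], birds: set[str]
) -> set[tuple[str, str]]:
    return {(p, b) for (p, b) in net.links() if p in plants and b in birds}


def rewiring_beta(net_a: InteractionMatrix, net_b: InteractionMatrix) -> float | None:
    """Sorensen dissimilarity of the shared-species subweb link sets.

    Returns None (undefined) when the networks share no plants or no birds,
    or when both subwebs are linkless.
    """
    plants = set(net_a.plant_ids) & set(net_b.plant_ids)
    birds = set(net_a.bird_ids) & set(net_b.bird_ids)
    if not plants or not birds:
        return None
    links_a = _shared_subweb_links(net_a, plants, birds)
    links_b = _shared_subweb_links(net_b, plants, birds)
    if not links_a and not links_b:
        return None
    return sorensen_dissimilarity(links_a, links_b)


@dataclass(frozen=True)
class BetaPartition:
    """Full pairwise beta decomposition for one network pair."""

    id_a: str
    id_b: str
    beta_s: float
    beta_wn: float
    beta_os: float | None
    shared_links: int
    unique_links_a: int
    unique_links_b: int
    shared_species: int
    shared_plants: int
    shared_birds: int

    @property
    def beta_st(self) -> float | None:
        """Species-turnover component beta_wn - beta_os (unused by the models)."""
        if self.beta_os is None:
            return None
        return self.beta_wn - self.beta_os


def beta_partition(net_a: InteractionMatrix, net_b: InteractionMatrix) -> BetaPartition:
    links_a, links_b = net_a.links(), net_b.links()
    return BetaPartition(
        id_a=net_a.network_id,
        id_b=net_b.network_id,
        beta_s=species_beta(net_a, net_b),
        beta_wn=interaction_beta(net_a, net_b),
        beta_os=rewiring_beta(net_a, net_b),
        shared_links=len(links_a & links_b),
        unique_links_a=len(links_a - links_b),
        unique_links_b=len(links_b - links_a),
        shared_species=len(net_a.species() & net_b.species()),
        shared_plants=len(set(net_a.plant_ids) & set(net_b.plant_ids)),
        shared_birds=len(set(net_a.bird_ids) & set(net_b.bird_ids)),
    )


def pairwise_beta(
    nets: Sequence[InteractionMatrix],
    which: Literal["species", "interaction"] = "interaction",
) -> DistanceMatrix:
    """Symmetric dissimilarity matrix over all network pairs."""
    if len(nets) < 2:
        raise ValueError("need at least two networks")
    ids = [n.network_id for n in nets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate network ids")
    fn = {"species": species_beta, "interaction": interaction_beta}[which]
    n = len(nets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(nets[i], nets[j])
    return DistanceMatrix(labels=tuple(ids), values=values, kind="quantitative")


def pair_table(nets: Sequence[InteractionMatrix]) -> pd.DataFrame:
    """Long-format table of the full beta decomposition for every pair."""
    rows = []
    for i in range(len(nets)):
        for j in range(i + 1, len(nets)):
            p = beta_partition(nets[i], nets[j])
            rows.append(
                {
                    "id_a": p.id_a,
                    "id_b": p.id_b,
                    "beta_s": p.beta_s,
                    "beta_wn": p.beta_wn,
                    "beta_os": math.nan if p.beta_os is None else p.beta_os,
                    "shared_links": p.shared_links,
                    "unique_links_a": p.unique_links_a,
                    "unique_links_b": p.unique_links_b,
                    "shared_species": p.shared_species,
                    "shared_plants": p.shared_plants,
                    "shared_birds": p.shared_birds,
                }
            )
    return pd.DataFrame(rows)


def shared_pairs_subset(
    nets: Sequence[InteractionMatrix],
    predictors: dict[str, DistanceMatrix] | None = None,
) -> pd.DataFrame:
    """Pairs with defined rewiring (shared plants and birds, subweb links).

    Each row carries beta_os plus, when ``predictors`` is given, the same
    pairwise predictor distances used by the matrix models.
    """
    rows = []
    by_id = {n.network_id: n for n in nets}
    for i, na in enumerate(nets):
        for nb in nets[i + 1 :]:
            b_os = rewiring_beta(na, nb)
            if b_os is None:
                continue
            row = {"id_a": na.network_id, "id_b": nb.network_id, "beta_os": b_os}
            if predictors:
                for name, dm in predictors.items():
                    row[name] = dm.value(na.network_id, nb.network_id)
            rows.append(row)
    if not rows:
        import warnings

        warnings.warn("no network pairs with defined rewiring", stacklevel=2)
        cols = ["id_a", "id_b", "beta_os"] + (list(predictors) if predictors else [])
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
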