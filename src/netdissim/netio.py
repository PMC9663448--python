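"""Domain types and file I/O for weighted bipartite interaction networks.

A local network is a labeled plants x birds matrix of nonnegative interaction
frequencies (e.g. fruit-feeding event counts).  Site metadata carries the
covariates used to build predictor distance matrices: coordinates, elevation,
ecoregion/biome membership, human footprint, and sampling effort/method
descriptors.  Ecoregions are regional ecosystem units nested within biomes, so
a valid metadata table maps every ecoregion to exactly one biome.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InteractionMatrix",
    "ValidationReport",
    "NetworkParseError",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "drop_zero_margins",
    "validate_network",
    "read_metadata",
    "validate_metadata",
    "ratio_of_interactions",
    "write_validation_reports",
    "METADATA_FIELDS",
]


class NetworkParseError(ValueError):
    """A network file could not be parsed into a weight matrix."""


class NetworkValidationError(ValueError):
    """A network or metadata table violates a structural invariant."""


@dataclass(frozen=True)
class InteractionMatrix:
    """One local weighted bipartite network (plants on rows, birds on columns)."""

    network_id: str
    plant_ids: tuple[str, ...]
    bird_ids: tuple[str, ...]
    weights: np.ndarray  # shape (n_plants, n_birds), float, >= 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "plant_ids", tuple(str(p) for p in self.plant_ids))
        object.__setattr__(self, "bird_ids", tuple(str(b) for b in self.bird_ids))
        if w.ndim != 2:
            raise NetworkValidationError(f"{self.network_id}: weights must be 2-D")
        if w.shape != (len(self.plant_ids), len(self.bird_ids)):
            raise NetworkValidationError(
                f"{self.network_id}: weight shape {w.shape} does not match labels"
            )
        if not np.all(np.isfinite(w)):
            raise NetworkValidationError(f"{self.network_id}: non-finite weight")
        if np.any(w < 0):
            raise NetworkValidationError(f"{self.network_id}: negative weight")
        if len(set(self.plant_ids)) != len(self.plant_ids):
            raise NetworkValidationError(f"{self.network_id}: duplicate plant id")
        if len(set(self.bird_ids)) != len(self.bird_ids):
            raise NetworkValidationError(f"{self.network_id}: duplicate bird id")
        if w.size == 0 or not np.any(w > 0):
            raise NetworkValidationError(f"{self.network_id}: no positive interaction")

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_birds(self) -> int:
        return len(self.bird_ids)

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.weights > 0))

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def links(self) -> frozenset[tuple[str, str]]:
        """Binarized link set {(plant_id, bird_id)} over positive cells."""
        if "_links" not in self.__dict__:
            rows, cols = np.nonzero(self.weights > 0)
            self.__dict__["_links"] = frozenset(
                (self.plant_ids[i], self.bird_ids[j]) for i, j in zip(rows, cols)
            )
        return self.__dict__["_links"]

    def species(self) -> frozenset[str]:
        """Guild-tagged species set (a plant and a bird never collide by name)."""
        if "_species" not in self.__dict__:
            self.__dict__["_species"] = frozenset(
                f"P::{p}" for p in self.plant_ids
            ) | frozenset(f"B::{b}" for b in self.bird_ids)
        return self.__dict__["_species"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(self.plant_ids), columns=list(self.bird_ids)
        )


@dataclass(frozen=True)
class ValidationReport:
    network_id: str
    passed: bool
    reasons: tuple[str, ...]
    n_plants: int
    n_birds: int
    n_links: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "reasons", tuple(self.reasons))
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be false iff reasons nonempty")


METADATA_FIELDS: tuple[str, ...] = (
    "network_id",
    "study_id",
    "latitude",
    "longitude",
    "elevation",
    "ecoregion_id",
    "biome_id",
    "human_footprint",
    "sampling_hours",
    "sampling_months",
    "sampling_year_mean",
    "sampling_intensity",
    "method_design",
    "method_focus",
    "method_frequency_type",
    "method_coverage",
)

_NUMERIC_METADATA = (
    "latitude",
    "longitude",
    "elevation",
    "human_footprint",
    "sampling_hours",
    "sampling_months",
    "sampling_year_mean",
    "sampling_intensity",
)

# Sampling covariates may be missing at read time; networks missing one are
# only excluded from models that use it.
_OPTIONAL_METADATA = (
    "sampling_hours",
    "sampling_months",
    "sampling_year_mean",
    "sampling_intensity",
    "method_design",
    "method_focus",
    "method_frequency_type",
    "method_coverage",
)


def read_network(
    path: str | Path, dialect: str = "csv", network_id: str | None = None
) -> InteractionMatrix:
    """Read a weighted adjacency matrix (row 1 = bird ids, column 1 = plant ids)."""
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    body = raw.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = next(zip(*np.nonzero(body.isna().to_numpy())))
        raise NetworkParseError(
            f"{path.name}: non-numeric cell at plant {raw.index[bad[0]]!r}, "
            f"bird {raw.columns[bad[1]]!r}"
        )
    return InteractionMatrix(
        network_id=network_id or path.stem,
        plant_ids=tuple(str(i) for i in body.index),
        bird_ids=tuple(str(c) for c in body.columns),
        weights=body.to_numpy(dtype=float),
    )


def write_network(net: InteractionMatrix, path: str | Path, dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    net.to_frame().to_csv(path, sep=sep)


def drop_zero_margins(net: InteractionMatrix) -> InteractionMatrix:
    """Remove all-zero rows and columns.  Idempotent; never alters kept weights."""
    keep_rows = np.flatnonzero(net.weights.sum(axis=1) > 0)
    keep_cols = np.flatnonzero(net.weights.sum(axis=0) > 0)
    if keep_rows.size == 0 or keep_cols.size == 0:
        raise NetworkValidationError(f"{net.network_id}: empty network after cleaning")
    if keep_rows.size == net.n_plants and keep_cols.size == net.n_birds:
        return net
    return InteractionMatrix(
        network_id=net.network_id,
        plant_ids=tuple(net.plant_ids[i] for i in keep_rows),
        bird_ids=tuple(net.bird_ids[j] for j in keep_cols),
        weights=net.weights[np.ix_(keep_rows, keep_cols)],
    )


def validate_network(
    net: InteractionMatrix,
    min_species_per_guild: int = 3,
    min_total_species: int = 0,
) -> ValidationReport:
    """Inclusion check: each guild needs >= min_species_per_guild species and
    total species strictly greater than min_total_species (small-network
    sensitivity threshold)."""
    reasons: list[str] = []
    if net.n_plants < min_species_per_guild:
        reasons.append(
            f"plant guild has {net.n_plants} species (< {min_species_per_guild})"
        )
    if net.n_birds < min_species_per_guild:
        reasons.append(
            f"bird guild has {net.n_birds} species (< {min_species_per_guild})"
        )
    total = net.n_plants + net.n_birds
    if total <= min_total_species:
        reasons.append(f"total species {total} <= {min_total_species}")
    return ValidationReport(
        network_id=net.network_id,
        passed=not reasons,
        reasons=tuple(reasons),
        n_plants=net.n_plants,
        n_birds=net.n_birds,
        n_links=net.n_links,
    )


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check metadata invariants; returns the (typed) table."""
    missing = [
        c for c in METADATA_FIELDS if c not in meta.columns and c not in _OPTIONAL_METADATA
    ]
    if missing:
        raise NetworkValidationError(f"metadata missing required columns: {missing}")
    meta = meta.copy()
    for col in _NUMERIC_METADATA:
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col], errors="raise")
    if meta["network_id"].duplicated().any():
        dup = meta.loc[meta["network_id"].duplicated(), "network_id"].iloc[0]
        raise NetworkValidationError(f"duplicate network_id {dup!r}")
    bad_lat = meta.loc[(meta["latitude"] < -90) | (meta["latitude"] > 90)]
    if len(bad_lat):
        raise NetworkValidationError(
            f"latitude out of range for networks {list(bad_lat['network_id'])}"
        )
    bad_lon = meta.loc[(meta["longitude"] < -180) | (meta["longitude"] > 180)]
    if len(bad_lon):
        raise NetworkValidationError(
            f"longitude out of range for networks {list(bad_lon['network_id'])}"
        )
    # nesting: each ecoregion belongs to exactly one biome
    biomes_per_eco = meta.groupby("ecoregion_id")["biome_id"].nunique()
    offenders = biomes_per_eco[biomes_per_eco > 1]
    if len(offenders):
        eco = offenders.index[0]
        rows = meta.loc[meta["ecoregion_id"] == eco, ["network_id", "ecoregion_id", "biome_id"]]
        raise NetworkValidationError(
            f"ecoregion {eco!r} mapped to multiple biomes:\n{rows.to_string(index=False)}"
        )
    return meta.reset_index(drop=True)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path))


class UndefinedRatio(ValueError):
    """No regional catalog pairs exist among the network's species."""


def ratio_of_interactions(
    net: InteractionMatrix, regional_catalog: Iterable[tuple[str, str]]
) -> float:
    """Sampling-completeness proxy: observed links over the regionally known
    possible links among the species present in the network (links binarized)."""
    plants, birds = set(net.plant_ids), set(net.bird_ids)
    catalog_here = {
        (p, b) for p, b in regional_catalog if p in plants and b in birds
    }
    if not catalog_here:
        raise UndefinedRatio(
            f"{net.network_id}: no catalog pairs among the network's species"
        )
    return len(net.links()) / len(catalog_here)


def write_validation_reports(
    reports: Sequence[ValidationReport], tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "network_id": [r.network_id for r in reports],
            "passed": [r.passed for r in reports],
            "reasons": ["; ".join(r.reasons) for r in reports],
            "n_plants": [r.n_plants for r in reports],
            "n_birds": [r.n_birds for r in reports],
            "n_links": [r.n_links for r in reports],
        }
    )
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(frame.to_dict("records"), indent=1))
    return frame
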