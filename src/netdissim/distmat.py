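"""Predictor distance matrices over local networks.

The pipeline's universal currency is a labeled symmetric dissimilarity matrix
with zero diagonal.  Predictors come in two kinds: ``binary`` boundary
indicators (0 = same ecoregion/biome, 1 = distinct) and ``quantitative``
distances (environment, human footprint, space, elevation, sampling effort
and methods).  Quantitative boundary matrices replace the 0/1 indicator with
the environmental dissimilarity between the regions the networks occupy.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import haversine_distances

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "EARTH_RADIUS_KM",
    "binary_membership_distance",
    "environmental_distance",
    "expand_to_networks",
    "absolute_difference_distance",
    "haversine_distance",
    "gower_mixed_distance",
    "pcoa",
    "methods_distance",
    "vectorize_lower_triangle",
    "devectorize_lower_triangle",
    "pair_index",
    "build_predictor_matrices",
]

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.0088

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric pairwise dissimilarity with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: Literal["binary", "quantitative"] = "quantitative"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distance")
        if np.any(v < 0):
            raise ValueError("negative distance")
        if np.max(np.abs(v - v.T), initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        if self.kind == "binary" and not np.all(np.isin(v, (0.0, 1.0))):
            raise ValueError("binary matrix must contain only 0 and 1")

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def reindex(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=tuple(labels), values=self.values[np.ix_(idx, idx)], kind=self.kind
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "quantitative") -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            labels=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
            kind=kind,  # type: ignore[arg-type]
        )


def _as_matrix(labels: Sequence[str], values: np.ndarray, kind: str) -> DistanceMatrix:
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=tuple(labels), values=values, kind=kind)  # type: ignore[arg-type]


def binary_membership_distance(memberships: Mapping[str, str]) -> DistanceMatrix:
    """0 within the same region, 1 across regions."""
    labels = list(memberships)
    regions = [memberships[l] for l in labels]
    if any(r is None or (isinstance(r, float) and np.isnan(r)) for r in regions):
        raise ValueError("missing region label")
    arr = np.array(regions, dtype=object)
    values = (arr[:, None] != arr[None, :]).astype(float)
    return _as_matrix(labels, values, "binary")


def _pca_scores(
    table: pd.DataFrame, variance_target: float, n_components: int | None
) -> np.ndarray:
    """z-score columns, drop constants with a warning, PCA, retain scores."""
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns constant")
    if not keep.all():
        warnings.warn(
            f"dropping constant columns: {list(table.columns[~keep])}", stacklevel=3
        )
        X, sd = X[:, keep], sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    max_comp = min(Z.shape[0] - 1, Z.shape[1])
    if n_components is not None:
        if n_components > max_comp:
            raise ValueError(
                f"requested {n_components} components but at most {max_comp} available"
            )
        k = n_components
        pca = PCA(n_components=max_comp).fit(Z)
    else:
        pca = PCA(n_components=max_comp).fit(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        k = min(k, max_comp)
    return pca.transform(Z)[:, :k]


def environmental_distance(
    env: pd.DataFrame,
    variance_target: float = 0.85,
    n_components: int | None = None,
    region_col: str = "region_id",
) -> DistanceMatrix:
    """Region-level environmental dissimilarity: z-score, PCA, Euclidean on
    the retained component scores."""
    env = env.set_index(region_col) if region_col in env.columns else env
    if env.index.duplicated().any():
        raise ValueError("duplicate region rows")
    if env.isna().any().any():
        raise ValueError("missing environmental values")
    scores = _pca_scores(env, variance_target, n_components)
    diff = scores[:, None, :] - scores[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    return _as_matrix([str(i) for i in env.index], values, "quantitative")


def expand_to_networks(
    region_dist: DistanceMatrix, memberships: Mapping[str, str]
) -> DistanceMatrix:
    """Lift a region-level matrix to networks via region membership."""
    labels = list(memberships)
    try:
        idx = np.array([region_dist.labels.index(memberships[l]) for l in labels])
    except ValueError as exc:
        raise ValueError(f"region missing from region-level matrix: {exc}") from exc
    values = region_dist.values[np.ix_(idx, idx)].copy()
    return _as_matrix(labels, values, region_dist.kind)


def absolute_difference_distance(values: Mapping[str, float]) -> DistanceMatrix:
    """|v_i - v_j| (the 1-D Euclidean distance used for footprint, elevation
    and the scalar sampling metrics).  Networks with missing values are
    excluded with a warning."""
    items = [(k, v) for k, v in values.items() if v is not None and np.isfinite(v)]
    dropped = [k for k in values if k not in dict(items)]
    if dropped:
        warnings.warn(f"excluding networks with missing values: {dropped}", stacklevel=2)
    if not items:
        raise ValueError("no networks with values")
    labels = [k for k, _ in items]
    arr = np.array([v for _, v in items], dtype=float)
    return _as_matrix(labels, np.abs(arr[:, None] - arr[None, :]), "quantitative")


def haversine_distance(coords: Mapping[str, tuple[float, float]]) -> DistanceMatrix:
    """Great-circle distance in km between network sites (lat, lon degrees)."""
    labels = list(coords)
    latlon = np.array([coords[l] for l in labels], dtype=float)
    if latlon.ndim != 2 or latlon.shape[1] != 2 or not np.all(np.isfinite(latlon)):
        raise ValueError("invalid coordinates")
    if np.any(np.abs(latlon[:, 0]) > 90) or np.any(np.abs(latlon[:, 1]) > 180):
        raise ValueError("coordinates out of range")
    values = haversine_distances(np.radians(latlon)) * EARTH_RADIUS_KM
    return _as_matrix(labels, values, "quantitative")


def gower_mixed_distance(table: pd.DataFrame) -> DistanceMatrix:
    """Gower dissimilarity over mixed columns: categorical columns contribute
    a 0/1 mismatch, numeric columns |diff|/range; unweighted mean across
    variables.  Constant numeric columns are dropped with a warning."""
    if table.shape[1] == 0:
        raise ValueError("no columns")
    n = len(table)
    parts: list[np.ndarray] = []
    for col in table.columns:
        s = table[col]
        if pd.api.types.is_numeric_dtype(s):
            arr = s.to_numpy(dtype=float)
            rng = np.ptp(arr)
            if rng == 0:
                warnings.warn(f"dropping constant column {col!r}", stacklevel=2)
                continue
            parts.append(np.abs(arr[:, None] - arr[None, :]) / rng)
        else:
            arr = s.astype(str).to_numpy()
            parts.append((arr[:, None] != arr[None, :]).astype(float))
    if not parts:
        raise ValueError("all columns dropped")
    values = np.mean(parts, axis=0)
    return _as_matrix([str(i) for i in table.index], values, "quantitative")


def pcoa(dist: DistanceMatrix, n_axes: int) -> pd.DataFrame:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    first ``n_axes`` coordinate columns ordered by decreasing eigenvalue.
    Negative eigenvalues (non-Euclidean input) are discarded; their share of
    total absolute inertia is logged.
    """
    D2 = dist.values**2
    n = dist.n
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval[0]) if n else 0.0)
    pos = eigval > tol
    neg_share = float(np.abs(eigval[eigval < -tol]).sum() / max(np.abs(eigval).sum(), 1e-300))
    if neg_share > 0:
        logger.info("pcoa: discarding negative eigenvalues (%.2f%% of inertia)", 100 * neg_share)
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        raise ValueError(f"requested {n_axes} axes but only {n_pos} positive eigenvalues")
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    return pd.DataFrame(
        coords, index=list(dist.labels), columns=[f"axis_{i+1}" for i in range(n_axes)]
    )


def methods_distance(methods: pd.DataFrame, n_axes: int = 4) -> DistanceMatrix:
    """Composite sampling-methods distance: Gower on the method descriptors,
    principal coordinates, Euclidean on the retained axes."""
    gower = gower_mixed_distance(methods)
    D2 = gower.values**2
    n = gower.n
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    eigval = np.linalg.eigvalsh((G + G.T) / 2.0)
    n_pos = int((eigval > max(1e-10, 1e-10 * abs(eigval[-1]))).sum())
    use_axes = min(n_axes, max(n_pos, 1))
    if n_pos == 0:
        # all rows identical: zero distances
        return _as_matrix(list(gower.labels), np.zeros((n, n)), "quantitative")
    coords = pcoa(gower, use_axes).to_numpy()
    diff = coords[:, None, :] - coords[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    return _as_matrix(list(gower.labels), values, "quantitative")


def pair_index(labels: Sequence[str]) -> list[tuple[str, str]]:
    """Fixed row-major pair order over the given label order."""
    labels = list(labels)
    return [
        (labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))
    ]


def vectorize_lower_triangle(
    dist: DistanceMatrix, label_order: Sequence[str] | None = None
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Condense a distance matrix to its n(n-1)/2 pair values plus pair index.

    The order is row-major over ``label_order`` (default: sorted labels) so
    that vectors from different matrices align row-by-row.
    """
    order = sorted(dist.labels) if label_order is None else list(label_order)
    if set(order) != set(dist.labels):
        raise ValueError("label mismatch between matrix and requested order")
    mat = dist.reindex(order).values
    iu = np.triu_indices(len(order), k=1)
    return mat[iu], pair_index(order)


def devectorize_lower_triangle(
    vec: np.ndarray, labels: Sequence[str], kind: str = "quantitative"
) -> DistanceMatrix:
    n = len(labels)
    values = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    values[iu] = vec
    values = values + values.T
    return DistanceMatrix(labels=tuple(labels), values=values, kind=kind)  # type: ignore[arg-type]


METHOD_COLUMNS = ("method_design", "method_focus", "method_frequency_type", "method_coverage")
SCALAR_SAMPLING = {
    "hours": "sampling_hours",
    "months": "sampling_months",
    "years": "sampling_year_mean",
    "intensity": "sampling_intensity",
}


def build_predictor_matrices(
    metadata: pd.DataFrame,
    include: Sequence[str] = (
        "ecoregion",
        "biome",
        "footprint",
        "spatial",
        "elevation",
        "hours",
        "months",
        "years",
        "intensity",
        "methods",
    ),
    env_tables: Mapping[str, pd.DataFrame] | None = None,
    methods_axes: int = 4,
) -> dict[str, DistanceMatrix]:
    """Build the standard predictor set from a site-metadata table.

    ``ecoregion``/``biome`` are binary boundary indicators; with an entry in
    ``env_tables`` (keyed by the same name) the quantitative environmental
    version is produced instead under the name ``ecoregion_env``/``biome_env``.
    """
    meta = metadata.set_index("network_id", drop=False)
    ids = list(meta.index)
    out: dict[str, DistanceMatrix] = {}
    for name in include:
        if name in ("ecoregion", "biome"):
            memberships = dict(meta[f"{name}_id"])
            out[name] = binary_membership_distance(memberships)
            if env_tables and name in env_tables:
                region_dm = environmental_distance(env_tables[name])
                out[f"{name}_env"] = expand_to_networks(region_dm, memberships)
        elif name == "footprint":
            out[name] = absolute_difference_distance(dict(meta["human_footprint"]))
        elif name == "spatial":
            out[name] = haversine_distance(
                {i: (meta.at[i, "latitude"], meta.at[i, "longitude"]) for i in ids}
            )
        elif name == "elevation":
            out[name] = absolute_difference_distance(dict(meta["elevation"]))
        elif name in SCALAR_SAMPLING:
            out[name] = absolute_difference_distance(dict(meta[SCALAR_SAMPLING[name]]))
        elif name == "methods":
            out[name] = methods_distance(meta[list(METHOD_COLUMNS)], n_axes=methods_axes)
        else:
            raise ValueError(f"unknown predictor recipe {name!r}")
    return out
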