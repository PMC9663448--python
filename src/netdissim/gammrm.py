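"""GAM-based multiple regression on distance matrices (MRM).

The response and every predictor are pairwise distance matrices over the same
set of local networks.  Their lower triangles are vectorized in a fixed pair
order and an additive Gaussian model is fitted:

    y_pair = a + sum_k b_k * I_k(pair) + sum_m f_m(x_m(pair)) + e

where I_k are 0/1 indicators derived from binary boundary matrices (coded 1
for "same region", so a negative b_k means lower dissimilarity within a
region) and f_m are penalized thin-plate-type regression splines of the
quantitative distances.  Smoothing parameters are chosen by restricted
maximum likelihood (REML).

Because the n(n-1)/2 pairwise distances that involve one network are not
independent, hypothesis tests use a permutation null: the rows and columns of
the response matrix are shuffled simultaneously by a random relabeling of
networks, the model is refitted, and the observed |t| (parametric terms) or
F (smooth terms) is compared against the permutation distribution.  The
p-value convention includes the observed statistic, p = (1 + #{exceed}) /
(n_perm + 1).

Deviance partitioning refits reduced models with the smoothing parameters
frozen at their full-model values and decomposes explained deviance into
unique and shared components by inclusion-exclusion.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .distmat import DistanceMatrix, vectorize_lower_triangle

__all__ = [
    "ModelSpec",
    "TermResult",
    "GammrmResult",
    "DeviancePartition",
    "AdditiveDesign",
    "AdditiveFit",
    "tprs_basis",
    "fit_additive_model",
    "gam_mrm",
    "deviance_partition",
    "jackknife_by_study",
]


# ---------------------------------------------------------------------------
# spline basis


def tprs_basis(x: np.ndarray, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Low-rank 1-D thin-plate-type regression spline basis.

    Radial cubic basis |x - knot|^3 at ``k`` quantile knots with the
    polynomial null space absorbed: the two null-space constraints are
    removed by a QR reparameterization, leaving k-2 penalized columns plus
    one unpenalized linear column (the constant belongs to the model
    intercept).  Returns (columns, penalty) where ``penalty`` acts on the
    first k-2 columns and is zero on the linear one.  Columns are centered
    for identifiability with the intercept.
    """
    x = np.asarray(x, dtype=float)
    rng_x = np.ptp(x)
    if rng_x == 0:
        raise ValueError("constant covariate has no spline basis")
    xs = (x - x.min()) / rng_x
    uniq = np.unique(xs)
    k_eff = min(k, uniq.size)
    if k_eff < 4:
        # too few distinct values for a spline: linear term only
        lin = xs - xs.mean()
        return lin[:, None], np.zeros((1, 1))
    knots = np.quantile(uniq, np.linspace(0.0, 1.0, k_eff))
    knots = np.unique(knots)
    m = knots.size
    E = np.abs(knots[:, None] - knots[None, :]) ** 3
    T = np.column_stack([np.ones(m), knots])
    Q, _ = np.linalg.qr(T, mode="complete")
    Z = Q[:, 2:]
    S = Z.T @ E @ Z
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    if evals.sum() < 0:  # sign convention of the radial kernel
        S = -S
        evals, evecs = np.linalg.eigh(S)
    evals = np.clip(evals, 0.0, None)
    S = (evecs * evals) @ evecs.T
    R = np.abs(xs[:, None] - knots[None, :]) ** 3
    Xpen = R @ Z
    lin = xs - xs.mean()
    cols = np.column_stack([Xpen - Xpen.mean(axis=0), lin])
    penalty = np.zeros((cols.shape[1], cols.shape[1]))
    penalty[: m - 2, : m - 2] = S / np.linalg.norm(S) if np.linalg.norm(S) > 0 else S
    return cols, penalty


# ---------------------------------------------------------------------------
# design and fitting


@dataclass(frozen=True)
class ModelSpec:
    """Model description for one response distance matrix."""

    response: str
    parametric_terms: tuple[str, ...] = ()
    smooth_terms: tuple[str, ...] = ()
    basis_dim: int = 10
    smoothing_method: str = "REML"
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "parametric_terms", tuple(self.parametric_terms))
        object.__setattr__(self, "smooth_terms", tuple(self.smooth_terms))
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")
        if self.smoothing_method != "REML":
            raise ValueError("only REML smoothing selection is implemented")


@dataclass
class _Term:
    name: str
    kind: str  # "parametric" | "smooth"
    sl: slice
    penalty: np.ndarray | None = None  # block-local, smooth terms only
    rank: int = 0


class AdditiveDesign:
    """Fixed design for a penalized additive fit, reusable across responses.

    Columns: intercept, one 0/1 column per parametric term, then the spline
    block of each smooth term.  Precomputes X'X so that repeated fits against
    permuted responses cost only a p x p factorization per REML step.
    """

    def __init__(
        self,
        parametric: Mapping[str, np.ndarray],
        smooth: Mapping[str, np.ndarray],
        basis_dim: int = 10,
        n_obs: int | None = None,
    ) -> None:
        n = n_obs
        cols: list[np.ndarray] = []
        self.terms: list[_Term] = []
        cols.append(None)  # placeholder for intercept
        p = 1
        for name, v in parametric.items():
            v = np.asarray(v, dtype=float)
            n = v.size if n is None else n
            cols.append(v[:, None])
            self.terms.append(_Term(name=name, kind="parametric", sl=slice(p, p + 1)))
            p += 1
        for name, v in smooth.items():
            v = np.asarray(v, dtype=float)
            n = v.size if n is None else n
            basis, penalty = tprs_basis(v, k=basis_dim)
            cols.append(basis)
            rank = int(np.linalg.matrix_rank(penalty)) if penalty.any() else 0
            self.terms.append(
                _Term(
                    name=name,
                    kind="smooth",
                    sl=slice(p, p + basis.shape[1]),
                    penalty=penalty,
                    rank=rank,
                )
            )
            p += basis.shape[1]
        if n is None:
            raise ValueError("model needs at least one term or an explicit n_obs")
        cols[0] = np.ones((n, 1))
        self.X = np.hstack(cols)
        self.n, self.p = self.X.shape
        self.XtX = self.X.T @ self.X
        self.smooth_terms = [t for t in self.terms if t.kind == "smooth"]
        # full-size penalty per smooth
        self._S_full: list[np.ndarray] = []
        for t in self.smooth_terms:
            S = np.zeros((self.p, self.p))
            S[t.sl, t.sl] = t.penalty
            self._S_full.append(S)
        # number of unpenalized coefficients (REML degrees-of-freedom offset)
        self.null_dim = self.p - sum(t.rank for t in self.smooth_terms)
        # tiny data-scaled ridge guards against exact collinearity between
        # near-duplicate predictors (e.g. study-level covariates)
        self._ridge = 1e-9 * float(np.trace(self.XtX)) / self.p

    # -- REML machinery ----------------------------------------------------

    def _assemble(self, lam: np.ndarray) -> np.ndarray:
        A = self.XtX + self._ridge * np.eye(self.p)
        for lj, S in zip(lam, self._S_full):
            A += lj * S
        return A

    def _reml_value_grad(
        self, rho: np.ndarray, Xty: np.ndarray, yty: float
    ) -> tuple[float, np.ndarray]:
        lam = np.exp(rho)
        A = self._assemble(lam)
        cho = linalg.cho_factor(A, lower=True)
        beta = linalg.cho_solve(cho, Xty)
        rss = yty - 2 * beta @ Xty + beta @ (self.XtX @ beta)
        rss = max(rss, 1e-300)
        pen = np.array([beta @ (S @ beta) for S in self._S_full])
        Dp = rss + float(lam @ pen)
        nm = self.n - self.null_dim
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        ranks = np.array([t.rank for t in self.smooth_terms], dtype=float)
        value = nm * np.log(Dp) + logdet - float(ranks @ rho)
        Ainv = linalg.cho_solve(cho, np.eye(self.p))
        grad = np.empty_like(rho)
        for j, (lj, S) in enumerate(zip(lam, self._S_full)):
            grad[j] = nm * lj * pen[j] / Dp + lj * np.trace(Ainv @ S) - ranks[j]
        return value, grad

    def fit(
        self,
        y: np.ndarray,
        lambdas: np.ndarray | None = None,
        rho0: np.ndarray | None = None,
    ) -> "AdditiveFit":
        """Penalized fit; REML-selects smoothing unless ``lambdas`` is given."""
        y = np.asarray(y, dtype=float)
        if y.size != self.n:
            raise ValueError("response length does not match design")
        Xty = self.X.T @ y
        yty = float(y @ y)
        m = len(self.smooth_terms)
        if lambdas is not None:
            lam = np.asarray(lambdas, dtype=float)
        elif m == 0:
            lam = np.empty(0)
        else:
            x0 = np.zeros(m) if rho0 is None else np.asarray(rho0, dtype=float)
            res = optimize.minimize(
                self._reml_value_grad,
                x0,
                args=(Xty, yty),
                jac=True,
                method="L-BFGS-B",
                bounds=[(-15.0, 18.0)] * m,
            )
            lam = np.exp(res.x)
        A = self._assemble(lam)
        cho = linalg.cho_factor(A, lower=True)
        beta = linalg.cho_solve(cho, Xty)
        Ainv = linalg.cho_solve(cho, np.eye(self.p))
        edf_cols = np.einsum("ij,ji->i", Ainv, self.XtX)
        edf_total = float(edf_cols.sum())
        rss = float(yty - 2 * beta @ Xty + beta @ (self.XtX @ beta))
        rss = max(rss, 0.0)
        ybar_ss = yty - self.n * (y.mean() ** 2)
        sigma2 = rss / max(self.n - edf_total, 1e-9)
        Vb = Ainv * sigma2
        return AdditiveFit(
            design=self,
            beta=beta,
            cov=Vb,
            lambdas=lam,
            edf_cols=edf_cols,
            edf_total=edf_total,
            rss=rss,
            null_ss=float(max(ybar_ss, 1e-300)),
            sigma2=sigma2,
        )


@dataclass
class AdditiveFit:
    """One penalized additive fit with Wald-type term statistics."""

    design: AdditiveDesign
    beta: np.ndarray
    cov: np.ndarray
    lambdas: np.ndarray
    edf_cols: np.ndarray
    edf_total: float
    rss: float
    null_ss: float
    sigma2: float

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.rss / self.null_ss

    def intercept(self) -> tuple[float, float]:
        est = float(self.beta[0])
        se = float(np.sqrt(max(self.cov[0, 0], 1e-300)))
        return est, est / se

    def parametric_stats(self) -> dict[str, tuple[float, float]]:
        """name -> (estimate, t)."""
        out = {}
        for t in self.design.terms:
            if t.kind != "parametric":
                continue
            i = t.sl.start
            est = float(self.beta[i])
            se = float(np.sqrt(max(self.cov[i, i], 1e-300)))
            out[t.name] = (est, est / se)
        return out

    def smooth_stats(self) -> dict[str, tuple[float, float]]:
        """name -> (edf, F); Wald-type F on the smooth coefficient block."""
        out = {}
        for t in self.design.terms:
            if t.kind != "smooth":
                continue
            b = self.beta[t.sl]
            V = self.cov[t.sl, t.sl]
            edf = float(self.edf_cols[t.sl].sum())
            Vinv = np.linalg.pinv((V + V.T) / 2.0, rcond=1e-10)
            F = float(b @ Vinv @ b) / max(edf, 1e-9)
            out[t.name] = (edf, F)
        return out


def fit_additive_model(
    design: pd.DataFrame,
    response: np.ndarray,
    spec: ModelSpec,
    lambdas: np.ndarray | None = None,
) -> AdditiveFit:
    """Fit the additive model to an explicit pair-level predictor table.

    ``design`` columns named in ``spec.parametric_terms`` enter linearly
    (0/1 indicators); columns in ``spec.smooth_terms`` get spline smooths.
    """
    if design.isna().any().any() or np.isnan(response).any():
        raise ValueError("missing values in design or response")
    parametric = {t: design[t].to_numpy(float) for t in spec.parametric_terms}
    smooth = {t: design[t].to_numpy(float) for t in spec.smooth_terms}
    ad = AdditiveDesign(parametric, smooth, basis_dim=spec.basis_dim)
    return ad.fit(np.asarray(response, float), lambdas=lambdas)


# ---------------------------------------------------------------------------
# the matrix-level model


@dataclass(frozen=True)
class TermResult:
    name: str
    kind: str  # "parametric" | "smooth"
    estimate: float | None  # parametric only
    t: float | None
    edf: float | None  # smooth only
    F: float | None
    p_perm: float | None


@dataclass(frozen=True)
class GammrmResult:
    response: str
    intercept_estimate: float
    intercept_t: float
    intercept_p_perm: float | None
    terms: tuple[TermResult, ...]
    deviance_explained: float
    n_pairs: int
    n_perm: int
    seed: int
    lambdas: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        """Table-style summary: term, estimate/EDF, t/F, permutation P."""
        rows = [
            {
                "term": "Intercept",
                "kind": "parametric",
                "estimate_or_edf": self.intercept_estimate,
                "t_or_F": self.intercept_t,
                "p_perm": self.intercept_p_perm,
            }
        ]
        for tr in self.terms:
            rows.append(
                {
                    "term": tr.name if tr.kind == "parametric" else f"s({tr.name})",
                    "kind": tr.kind,
                    "estimate_or_edf": tr.estimate if tr.kind == "parametric" else tr.edf,
                    "t_or_F": tr.t if tr.kind == "parametric" else tr.F,
                    "p_perm": tr.p_perm,
                }
            )
        return pd.DataFrame(rows)

    def term(self, name: str) -> TermResult:
        for tr in self.terms:
            if tr.name == name:
                return tr
        raise KeyError(name)


def _aligned_vectors(
    data: Mapping[str, DistanceMatrix], names: Sequence[str]
) -> tuple[list[str], dict[str, np.ndarray]]:
    label_sets = {frozenset(data[n].labels) for n in names}
    if len(label_sets) != 1:
        raise ValueError("distance matrices are not aligned on one label set")
    order = sorted(next(iter(label_sets)))
    vecs = {n: vectorize_lower_triangle(data[n], order)[0] for n in names}
    return order, vecs


def _prepare(
    data: Mapping[str, DistanceMatrix], spec: ModelSpec
) -> tuple[list[str], AdditiveDesign, np.ndarray, ModelSpec]:
    names = [spec.response, *spec.parametric_terms, *spec.smooth_terms]
    for n in names:
        if n not in data:
            raise KeyError(f"distance matrix {n!r} not provided")
    order, vecs = _aligned_vectors(data, names)
    if len(order) < 4:
        raise ValueError("need at least 4 networks for permutation inference")
    parametric: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for t in spec.parametric_terms:
        if data[t].kind != "binary":
            raise ValueError(f"parametric term {t!r} must be a binary matrix")
        ind = 1.0 - vecs[t]  # 1 = same region, distinct = reference level
        if np.ptp(ind) == 0:
            dropped.append(t)
            continue
        parametric[t] = ind
    smooth: dict[str, np.ndarray] = {}
    for t in spec.smooth_terms:
        if np.ptp(vecs[t]) == 0:
            dropped.append(t)
            continue
        smooth[t] = vecs[t]
    if dropped:
        warnings.warn(f"dropping constant terms: {dropped}", stacklevel=3)
        spec = ModelSpec(
            response=spec.response,
            parametric_terms=tuple(t for t in spec.parametric_terms if t not in dropped),
            smooth_terms=tuple(t for t in spec.smooth_terms if t not in dropped),
            basis_dim=spec.basis_dim,
            smoothing_method=spec.smoothing_method,
            n_perm=spec.n_perm,
            seed=spec.seed,
        )
    design = AdditiveDesign(
        parametric, smooth, basis_dim=spec.basis_dim,
        n_obs=vecs[spec.response].size,
    )
    return order, design, vecs[spec.response], spec


def _permuted_response(mat: np.ndarray, iu: tuple, perm: np.ndarray) -> np.ndarray:
    return mat[np.ix_(perm, perm)][iu]


def gam_mrm(
    data: Mapping[str, DistanceMatrix],
    spec: ModelSpec,
    fast_perm: bool = False,
    threads: int = 1,
) -> GammrmResult:
    """Fit the GAM-MRM and test each term against a permutation null.

    Each permutation relabels the networks of the response matrix (rows and
    columns shuffled simultaneously) and refits the model.  By default the
    smoothing parameters are re-estimated by REML on every refit;
    ``fast_perm=True`` freezes them at the observed-fit values.  All
    permutations are drawn up front from one seeded generator, so results
    are invariant to ``threads``.
    """
    order, design, y, spec = _prepare(data, spec)
    obs = design.fit(y)
    obs_param = obs.parametric_stats()
    obs_smooth = obs.smooth_stats()
    _, t0 = obs.intercept()

    param_names = list(obs_param)
    smooth_names = list(obs_smooth)
    exceed_param = {n: 0 for n in param_names}
    exceed_smooth = {n: 0 for n in smooth_names}
    exceed_int = 0
    rng = np.random.default_rng(spec.seed)
    rho0 = np.log(obs.lambdas) if obs.lambdas.size else None
    n = len(order)
    perms = [rng.permutation(n) for _ in range(spec.n_perm)]
    resp_mat = data[spec.response].reindex(order).values
    iu = np.triu_indices(n, k=1)

    def one_perm(perm: np.ndarray) -> tuple[dict, dict, float]:
        y_perm = _permuted_response(resp_mat, iu, perm)
        fit = design.fit(
            y_perm,
            lambdas=obs.lambdas if fast_perm else None,
            rho0=rho0,
        )
        return fit.parametric_stats(), fit.smooth_stats(), fit.intercept()[1]

    if threads > 1 and perms:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=threads) as ex:
            results = list(ex.map(one_perm, perms))
    else:
        results = [one_perm(p) for p in perms]
    for stats_p, stats_s, t_int in results:
        for name in param_names:
            if abs(stats_p[name][1]) >= abs(obs_param[name][1]) - 1e-12:
                exceed_param[name] += 1
        for name in smooth_names:
            if stats_s[name][1] >= obs_smooth[name][1] - 1e-12:
                exceed_smooth[name] += 1
        if abs(t_int) >= abs(t0) - 1e-12:
            exceed_int += 1

    def pval(count: int) -> float | None:
        if spec.n_perm == 0:
            return None
        return (1 + count) / (spec.n_perm + 1)

    terms: list[TermResult] = []
    for name in param_names:
        est, t = obs_param[name]
        terms.append(
            TermResult(
                name=name, kind="parametric", estimate=est, t=t,
                edf=None, F=None, p_perm=pval(exceed_param[name]),
            )
        )
    for name in smooth_names:
        edf, F = obs_smooth[name]
        terms.append(
            TermResult(
                name=name, kind="smooth", estimate=None, t=None,
                edf=edf, F=F, p_perm=pval(exceed_smooth[name]),
            )
        )
    est0, t0v = obs.intercept()
    return GammrmResult(
        response=spec.response,
        intercept_estimate=est0,
        intercept_t=t0v,
        intercept_p_perm=pval(exceed_int),
        terms=tuple(terms),
        deviance_explained=obs.deviance_explained,
        n_pairs=design.n,
        n_perm=spec.n_perm,
        seed=spec.seed,
        lambdas=tuple(float(l) for l in obs.lambdas),
    )


# ---------------------------------------------------------------------------
# deviance partitioning


@dataclass(frozen=True)
class DeviancePartition:
    """Signed Venn decomposition of explained deviance.

    ``components`` maps each nonempty subset of the variables of interest to
    the deviance fraction exclusively shared by that subset (fractions of
    total response deviance).  Negative components are retained and flagged.
    """

    variables_of_interest: tuple[str, ...]
    components: dict[frozenset[str], float]
    full_deviance_explained: float
    attributable: float  # full minus model-without-all-variables-of-interest
    residual: float
    negative_components: tuple[frozenset[str], ...]

    def component(self, *names: str) -> float:
        return self.components[frozenset(names)]


def deviance_partition(
    data: Mapping[str, DistanceMatrix],
    spec: ModelSpec,
    variables_of_interest: Sequence[str],
    max_variables: int = 5,
) -> DeviancePartition:
    """Unique/shared explained-deviance components for the named terms.

    Every reduced model (each subset of the variables of interest removed)
    is refitted with the smoothing parameters of the remaining smooths frozen
    at their full-model values; components follow by inclusion-exclusion.
    """
    voi = tuple(variables_of_interest)
    all_terms = set(spec.parametric_terms) | set(spec.smooth_terms)
    unknown = [v for v in voi if v not in all_terms]
    if unknown:
        raise ValueError(f"variables of interest not in the model: {unknown}")
    if len(voi) > max_variables:
        raise ValueError(f"more than {max_variables} variables of interest")

    order, design, y, spec = _prepare(data, spec)
    voi = tuple(v for v in voi if v in set(spec.parametric_terms) | set(spec.smooth_terms))
    full = design.fit(y)
    lam_by_name = dict(zip([t.name for t in design.smooth_terms], full.lambdas))

    def reduced_dev(removed: frozenset[str]) -> float:
        p_terms = tuple(t for t in spec.parametric_terms if t not in removed)
        s_terms = tuple(t for t in spec.smooth_terms if t not in removed)
        sub_spec = ModelSpec(
            response=spec.response, parametric_terms=p_terms, smooth_terms=s_terms,
            basis_dim=spec.basis_dim, n_perm=0, seed=spec.seed,
        )
        _, sub_design, sub_y, sub_spec = _prepare(data, sub_spec)
        lam = np.array([lam_by_name[t.name] for t in sub_design.smooth_terms])
        return sub_design.fit(sub_y, lambdas=lam).deviance_explained

    dev: dict[frozenset[str], float] = {frozenset(): full.deviance_explained}
    for r in range(1, len(voi) + 1):
        for combo in itertools.combinations(voi, r):
            dev[frozenset(combo)] = reduced_dev(frozenset(combo))

    full_dev = dev[frozenset()]
    voi_set = frozenset(voi)

    def lost(S: frozenset[str]) -> float:
        return full_dev - dev[S]

    # h(U) = total deviance attributable to the variables in U
    # (= lost(all) - lost(all minus U)); Moebius inversion gives the
    # exclusive component of every subset.
    def h(U: frozenset[str]) -> float:
        return lost(voi_set) - lost(voi_set - U)

    components: dict[frozenset[str], float] = {}
    for r in range(1, len(voi) + 1):
        for combo in itertools.combinations(voi, r):
            T = frozenset(combo)
            c = 0.0
            for rr in range(len(T) + 1):
                for sub in itertools.combinations(sorted(T), rr):
                    U = frozenset(sub)
                    c += (-1) ** (len(T) - len(U)) * h(U)
            components[T] = c
    negatives = tuple(k for k, v in components.items() if v < 0)
    return DeviancePartition(
        variables_of_interest=voi,
        components=components,
        full_deviance_explained=full_dev,
        attributable=lost(voi_set),
        residual=1.0 - full_dev,
        negative_components=negatives,
    )


# ---------------------------------------------------------------------------
# jackknife over studies


def jackknife_by_study(
    nets: Sequence,
    metadata: pd.DataFrame,
    build_data: Callable[[Sequence, pd.DataFrame], Mapping[str, DistanceMatrix]],
    spec: ModelSpec,
) -> pd.DataFrame:
    """Leave-one-study-out sensitivity of every term's t or F statistic.

    ``build_data`` rebuilds the named distance matrices from a reduced
    network list and metadata table, so every matrix reflects the retained
    networks only.  Rows where the reduced dataset has fewer than 4 networks
    are flagged as skipped.
    """
    rows = []
    studies = list(pd.unique(metadata["study_id"]))
    for study in studies:
        keep_meta = metadata.loc[metadata["study_id"] != study].reset_index(drop=True)
        keep_ids = set(keep_meta["network_id"])
        keep_nets = [n for n in nets if n.network_id in keep_ids]
        row: dict[str, object] = {
            "study_id": study,
            "n_networks_dropped": len(nets) - len(keep_nets),
            "skipped": False,
        }
        if len(keep_nets) < 4:
            row["skipped"] = True
            rows.append(row)
            continue
        data = build_data(keep_nets, keep_meta)
        sub_spec = ModelSpec(
            response=spec.response,
            parametric_terms=spec.parametric_terms,
            smooth_terms=spec.smooth_terms,
            basis_dim=spec.basis_dim,
            n_perm=0,
            seed=spec.seed,
        )
        res = gam_mrm(data, sub_spec)
        for tr in res.terms:
            if tr.kind == "parametric":
                row[f"t_{tr.name}"] = tr.t
            else:
                row[f"F_{tr.name}"] = tr.F
        row["deviance_explained"] = res.deviance_explained
        rows.append(row)
    return pd.DataFrame(rows)
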