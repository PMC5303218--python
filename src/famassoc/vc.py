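"""Variance-components linear mixed model: ML fitting, LRT and heritability.

The association of a predictor ``p`` with a quantitative response ``r`` in a
sample of related individuals is modelled as

    r_i = mu + beta * p_i + sum_j psi_j C_ij + g_i + e_i

where ``g`` is an additive polygenic effect with covariance
``sigma2_a * 2*Phi`` (``2*Phi`` the expected or realized relatedness matrix)
and ``e`` is i.i.d. environmental noise with variance ``sigma2_e``, so the
response covariance is ``omega = 2*Phi*sigma2_a + I*sigma2_e``. Significance
is a likelihood-ratio test of the alternative model against the null with
``beta = 0``; narrow-sense heritability is ``sigma2_a / (sigma2_a +
sigma2_e)`` from the covariates-only model.

Fitting uses a one-time symmetric eigendecomposition of the relatedness
subset: rotating response and design by the eigenvectors diagonalizes
``omega``, after which the likelihood is profiled over the heritability
ratio ``h = sigma2_a / (sigma2_a + sigma2_e)`` on [0, 1] with closed-form
GLS fixed effects and total variance at each ``h``. The decomposition is
cached per missingness pattern, so predictors sharing a pattern reuse both
the rotation and the null fit.
"""
from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as la
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

from .phenotype import PhenotypeTable
from .relatedness import RelatednessMatrix

__all__ = [
    "ModelSpec",
    "VCFit",
    "AssociationResult",
    "MissingnessCluster",
    "AssocOptions",
    "CollinearityError",
    "loglikelihood",
    "fit_ml",
    "lrt_association",
    "heritability",
    "cluster_by_missingness",
    "run_association_scan",
]

_LOG2PI = math.log(2.0 * math.pi)
_LRT_CLAMP = 1e-8
_IDENTITY_TOL = 1e-12


class CollinearityError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the offending column."""


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A single response ~ predictor + covariates model on a fixed sample.

    ``individuals`` is the missingness intersection: every listed individual
    has a non-missing response, predictor (if any) and all covariates.
    ``X`` is the design matrix with columns intercept, predictor (if any),
    then covariates, matching ``column_names``.
    """

    response: str
    predictor: str | None
    covariates: tuple[str, ...]
    individuals: list[str]
    y: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    column_names: tuple[str, ...] = ()

    @classmethod
    def from_tables(
        cls,
        response: str,
        responses: PhenotypeTable,
        rel: RelatednessMatrix,
        predictor: str | None = None,
        predictors: PhenotypeTable | None = None,
        covariates: PhenotypeTable | None = None,
    ) -> "ModelSpec":
        """Build a spec by intersecting non-missing individuals across inputs."""
        ids = [i for i in rel.ids if i in responses.data.index]
        if predictor is not None:
            if predictors is None:
                raise ValueError("predictor named but no predictor table given")
            ids = [i for i in ids if i in predictors.data.index]
        if covariates is not None:
            ids = [i for i in ids if i in covariates.data.index]
        y_all = responses.aligned(ids)[response].to_numpy()
        mask = ~np.isnan(y_all)
        cols = []
        names = ["(intercept)"]
        if predictor is not None:
            p_all = predictors.aligned(ids)[predictor].to_numpy()
            mask &= ~np.isnan(p_all)
            cols.append(p_all)
            names.append(predictor)
        cov_names: tuple[str, ...] = ()
        if covariates is not None:
            C = covariates.aligned(ids)
            cov_names = tuple(C.columns)
            mask &= C.notna().all(axis=1).to_numpy()
            for c in C.columns:
                cols.append(C[c].to_numpy())
                names.append(c)
        keep = np.flatnonzero(mask)
        X = np.column_stack(
            [np.ones(keep.size)] + [c[keep] for c in cols]
        )
        return cls(
            response=response,
            predictor=predictor,
            covariates=cov_names,
            individuals=[ids[k] for k in keep],
            y=y_all[keep],
            X=X,
            column_names=tuple(names),
        )

    def drop_predictor(self) -> "ModelSpec":
        """The nested null spec (no predictor) on the *same* individuals."""
        if self.predictor is None:
            return self
        keep = [0] + list(range(2, self.X.shape[1]))
        return replace(
            self,
            predictor=None,
            X=self.X[:, keep],
            column_names=(self.column_names[0],) + self.column_names[2:],
        )

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class VCFit:
    """A fitted variance-components model."""

    mu: float
    beta: float | None
    psi: np.ndarray
    sigma2_a: float
    sigma2_e: float
    loglik: float
    n: int
    converged: bool
    decomposition_used: str
    h: float
    h2_identifiable: bool
    se: np.ndarray
    column_names: tuple[str, ...]
    individuals: list[str]
    spec: ModelSpec = field(repr=False)

    @property
    def h2(self) -> float | None:
        """sigma2_a / (sigma2_a + sigma2_e), or None when unidentifiable."""
        return self.h if self.h2_identifiable else None

    @property
    def coef(self) -> np.ndarray:
        parts = [self.mu]
        if self.beta is not None:
            parts.append(self.beta)
        return np.concatenate([parts, self.psi])


@dataclass
class AssociationResult:
    """One predictor-response association test."""

    response: str
    predictor: str
    n: int
    beta: float | None = None
    se_beta: float | None = None
    lrt: float | None = None
    p: float | None = None
    df: int = 1
    h2_null: float | None = None
    empirical_p: float | None = None
    n_permutations: int | None = None
    family_diag: "object | None" = None
    chrom: str | None = None
    position: int | None = None
    flags: tuple[str, ...] = ()
    skip_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skip_reason is not None


@dataclass
class MissingnessCluster:
    """Predictors sharing a missingness pattern (null model fitted once)."""

    mask_key: bytes
    mask: np.ndarray
    predictor_ids: list[str]
    cached_null: VCFit | None = None


@dataclass
class AssocOptions:
    """Options for :func:`run_association_scan`."""

    min_n: int = 20
    family_diagnostics: bool = True
    use_missingness_clustering: bool = True
    permutation: "object | None" = None  # permutation.PermutationPlan
    grid_points: int = 21
    xatol: float = 1e-10


# --------------------------------------------------------------------------
# dense likelihood (Cholesky -> LU -> QR cascade)
# --------------------------------------------------------------------------

def _dense_loglik(resid: np.ndarray, omega: np.ndarray) -> tuple[float, str]:
    """Gaussian log density of residuals under covariance ``omega``.

    Solved by Cholesky when ``omega`` is positive definite, by LU when it is
    merely invertible, and by rank-revealing QR (pseudo-determinant and
    minimum-norm solve) when it is singular.
    """
    n = resid.size
    try:
        c, low = la.cho_factor(omega, lower=True, check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        quad = float(resid @ la.cho_solve((c, low), resid, check_finite=False))
        return -0.5 * (n * _LOG2PI + logdet + quad), "cholesky"
    except la.LinAlgError:
        pass
    lu, piv = la.lu_factor(omega, check_finite=False)
    diag = np.diag(lu)
    if np.all(np.abs(diag) > 1e-12 * max(1.0, np.abs(diag).max())):
        logdet = float(np.sum(np.log(np.abs(diag))))
        quad = float(resid @ la.lu_solve((lu, piv), resid, check_finite=False))
        return -0.5 * (n * _LOG2PI + logdet + quad), "lu"
    # singular: rank-revealing QR, pseudo-determinant + minimum-norm solve
    q, r, piv = la.qr(omega, pivoting=True)
    rdiag = np.abs(np.diag(r))
    tol = rdiag.max() * n * np.finfo(float).eps if rdiag.size else 0.0
    rank = int(np.sum(rdiag > tol))
    if rank == 0:
        raise np.linalg.LinAlgError("covariance matrix is zero")
    sol, *_ = np.linalg.lstsq(omega, resid, rcond=None)
    check = omega @ sol - resid
    if float(np.abs(check).max()) > 1e-6 * max(1.0, float(np.abs(resid).max())):
        raise np.linalg.LinAlgError(
            "covariance singular and residual outside its range "
            "(no decomposition applies)"
        )
    logdet = float(np.sum(np.log(rdiag[:rank])))
    quad = float(resid @ sol)
    return -0.5 * (rank * _LOG2PI + logdet + quad), "qr"


def loglikelihood(
    spec: ModelSpec,
    theta: dict,
    rel: RelatednessMatrix,
) -> float:
    """Log-likelihood of ``spec`` at explicit parameter values.

    ``theta`` holds ``mu``, ``sigma2_a``, ``sigma2_e`` and optionally
    ``beta`` and ``psi`` (sequence of covariate effects).
    """
    s2a = float(theta["sigma2_a"])
    s2e = float(theta["sigma2_e"])
    if s2a < 0 or s2e < 0:
        raise ValueError("variance components must be non-negative")
    if s2a == 0 and s2e == 0:
        raise ValueError("degenerate covariance: sigma2_a = sigma2_e = 0")
    coef = [float(theta["mu"])]
    if spec.predictor is not None:
        coef.append(float(theta["beta"]))
    coef.extend(np.atleast_1d(theta.get("psi", ())).astype(float))
    coef = np.asarray(coef)
    if coef.size != spec.X.shape[1]:
        raise ValueError(
            f"theta has {coef.size} fixed effects, design has {spec.X.shape[1]}"
        )
    K = rel.subset(spec.individuals).values
    omega = s2a * K + s2e * np.eye(spec.n)
    resid = spec.y - spec.X @ coef
    ll, _method = _dense_loglik(resid, omega)
    return ll


# --------------------------------------------------------------------------
# profile-likelihood ML fit
# --------------------------------------------------------------------------

@dataclass
class EigenDecomp:
    """Cached symmetric eigendecomposition of a relatedness subset."""

    d: np.ndarray
    U: np.ndarray | None  # None when the subset is the identity
    is_identity: bool

    @classmethod
    def of(cls, K: np.ndarray) -> "EigenDecomp":
        n = K.shape[0]
        if np.abs(K - np.eye(n)).max() <= _IDENTITY_TOL:
            return cls(d=np.ones(n), U=None, is_identity=True)
        d, U = np.linalg.eigh(K)
        d[(d < 0) & (d > -1e-10)] = 0.0
        return cls(d=d, U=U, is_identity=False)

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return a if self.U is None else self.U.T @ a


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    _q, r, piv = la.qr(X, mode="economic", pivoting=True)
    rdiag = np.abs(np.diag(r))
    tol = rdiag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(rdiag > tol))
    if rank < X.shape[1]:
        # name the first column redundant given the ones before it
        bad_idx = X.shape[1] - 1
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad_idx = j
                break
        bad = names[bad_idx] if names else f"column {bad_idx}"
        raise CollinearityError(
            f"design matrix is rank deficient: column {bad!r} is collinear "
            "(constant or a combination of other columns)"
        )


def _gls_at_h(
    h: float, d: np.ndarray, y_rot: np.ndarray, X_rot: np.ndarray
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Profile negative log-likelihood at heritability ratio ``h``.

    Returns (negloglik, coef, sigma2_total, XtX_weighted).
    """
    n = y_rot.size
    w = h * d + (1.0 - h)
    if w.min() <= 1e-12:
        return np.inf, np.empty(0), np.nan, np.empty((0, 0))
    sw = 1.0 / np.sqrt(w)
    Xw = X_rot * sw[:, None]
    yw = y_rot * sw
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    try:
        coef = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    rss = float(resid @ resid)
    if rss <= 0:
        return np.inf, coef, 0.0, XtX
    sigma2 = rss / n
    ll = -0.5 * (n * _LOG2PI + n * math.log(sigma2) + float(np.log(w).sum()) + n)
    return -ll, coef, sigma2, XtX


def _profile_grad(
    h: float, d: np.ndarray, y_rot: np.ndarray, X_rot: np.ndarray
) -> float:
    """d(negative profile log-likelihood)/dh (envelope theorem: the GLS
    coefficients are stationary, so only the weights vary)."""
    n = y_rot.size
    _nll, coef, sigma2, _ = _gls_at_h(h, d, y_rot, X_rot)
    w = h * d + (1.0 - h)
    r = y_rot - X_rot @ coef
    rss = n * sigma2
    rss_grad = -float(np.sum(r * r * (d - 1.0) / w**2))
    return 0.5 * (float(np.sum((d - 1.0) / w)) + n * rss_grad / rss)


def _fit_profile(
    spec: ModelSpec,
    decomp: EigenDecomp,
    grid_points: int = 21,
    xatol: float = 1e-10,
) -> VCFit:
    if spec.n < 3:
        raise ValueError(f"need at least 3 individuals, have {spec.n}")
    _check_rank(spec.X, spec.column_names)
    y_rot = decomp.rotate(spec.y)
    X_rot = decomp.rotate(spec.X)

    if decomp.is_identity:
        # omega = (s2a + s2e) * I: h is unidentifiable, likelihood flat in h.
        h_hat = 0.0
        nll, coef, sigma2, XtX = _gls_at_h(0.0, decomp.d, y_rot, X_rot)
        converged = True
        identifiable = False
    else:
        d = decomp.d
        # keep the covariance invertible at h = 1 when 2*Phi is singular
        h_max = 1.0 if d.min() > 1e-12 else 1.0 - 1e-8
        grid = np.concatenate([np.linspace(0.0, 1.0, grid_points - 1), [h_max]])
        grid = np.unique(np.clip(grid, 0.0, h_max))
        vals = np.array([_gls_at_h(g, d, y_rot, X_rot)[0] for g in grid])
        best = int(np.argmin(vals))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, grid.size - 1)]
        glo = _profile_grad(lo, d, y_rot, X_rot)
        ghi = _profile_grad(hi, d, y_rot, X_rot)
        converged = True
        if glo >= 0.0 and ghi >= 0.0:
            h_hat = float(lo)
        elif glo <= 0.0 and ghi <= 0.0:
            h_hat = float(hi)
        elif glo < 0.0 < ghi:
            h_hat = float(
                brentq(
                    _profile_grad, lo, hi, args=(d, y_rot, X_rot), xtol=1e-12
                )
            )
        else:
            res = minimize_scalar(
                lambda g: _gls_at_h(g, d, y_rot, X_rot)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": xatol},
            )
            h_hat = float(res.x)
            converged = bool(getattr(res, "success", True))
        nll, coef, sigma2, XtX = _gls_at_h(h_hat, d, y_rot, X_rot)
        if vals[best] < nll:  # guard: never fall below the grid optimum
            h_hat = float(grid[best])
            nll, coef, sigma2, XtX = _gls_at_h(h_hat, d, y_rot, X_rot)
        identifiable = True

    if not np.isfinite(nll):
        raise np.linalg.LinAlgError(
            "profile likelihood not finite at the optimum (degenerate covariance)"
        )
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    has_pred = spec.predictor is not None
    psi_start = 2 if has_pred else 1
    return VCFit(
        mu=float(coef[0]),
        beta=float(coef[1]) if has_pred else None,
        psi=coef[psi_start:].copy(),
        sigma2_a=h_hat * sigma2,
        sigma2_e=(1.0 - h_hat) * sigma2,
        loglik=-nll,
        n=spec.n,
        converged=converged,
        decomposition_used="eigen",
        h=h_hat,
        h2_identifiable=identifiable,
        se=se,
        column_names=spec.column_names,
        individuals=spec.individuals,
        spec=spec,
    )


def fit_ml(
    spec: ModelSpec,
    rel: RelatednessMatrix,
    options: AssocOptions | None = None,
    decomp: EigenDecomp | None = None,
) -> VCFit:
    """Maximum-likelihood fit of the variance-components model.

    ``decomp`` allows reusing a cached eigendecomposition of the relatedness
    subset for ``spec.individuals`` (the caller is responsible for the
    correspondence).
    """
    options = options or AssocOptions()
    if decomp is None:
        K = rel.subset(spec.individuals).values
        decomp = EigenDecomp.of(K)
    return _fit_profile(
        spec, decomp, grid_points=options.grid_points, xatol=options.xatol
    )


def _clamp_lrt(lrt: float) -> float:
    if lrt < -_LRT_CLAMP:
        raise AssertionError(
            f"negative likelihood-ratio statistic {lrt:.3e}: alternative "
            "does not nest the null (internal consistency failure)"
        )
    return max(lrt, 0.0)


def lrt_association(null_fit: VCFit, alt_fit: VCFit) -> tuple[float, float]:
    """Likelihood-ratio test of the predictor effect (chi-square, 1 df)."""
    if null_fit.individuals != alt_fit.individuals:
        raise ValueError("null and alternative fits use different individuals")
    if alt_fit.beta is None or null_fit.beta is not None:
        raise ValueError("expected alt fit with predictor and null fit without")
    lrt = _clamp_lrt(2.0 * (alt_fit.loglik - null_fit.loglik))
    return lrt, float(chi2.sf(lrt, 1))


def heritability(
    spec: ModelSpec,
    rel: RelatednessMatrix,
    options: AssocOptions | None = None,
    decomp: EigenDecomp | None = None,
) -> tuple[float | None, float, float]:
    """Narrow-sense heritability of the response with a boundary LRT.

    Fits the covariates-only model, compares against the ``sigma2_a = 0``
    constrained fit, and returns ``(h2, lrt, p)`` with the p-value from the
    50:50 mixture of a point mass at zero and chi-square(1) appropriate for
    a variance component tested on its boundary. When every pair in the
    sample is unrelated, h2 is unidentifiable and ``(None, 0.0, 1.0)`` is
    returned.
    """
    if spec.predictor is not None:
        spec = spec.drop_predictor()
    fit = fit_ml(spec, rel, options=options, decomp=decomp)
    if not fit.h2_identifiable:
        return None, 0.0, 1.0
    if decomp is None:
        decomp = EigenDecomp.of(rel.subset(spec.individuals).values)
    y_rot = decomp.rotate(spec.y)
    X_rot = decomp.rotate(spec.X)
    nll0, *_ = _gls_at_h(0.0, decomp.d, y_rot, X_rot)
    lrt = _clamp_lrt(2.0 * (fit.loglik - (-nll0)))
    p = 0.5 * float(chi2.sf(lrt, 1))
    if lrt == 0.0:
        p = 0.5
    return fit.h, lrt, p


# --------------------------------------------------------------------------
# missingness clustering and the pairwise scan
# --------------------------------------------------------------------------

def cluster_by_missingness(
    predictor_values: pd.DataFrame, response_mask: np.ndarray
) -> list[MissingnessCluster]:
    """Group predictors by the combined (predictor | response) missingness.

    ``predictor_values`` must be aligned to the same individual ordering as
    ``response_mask`` (True = usable individual). Within a cluster the null
    model is fitted once and reused for every member predictor; results are
    identical to per-predictor computation because the same decomposition
    and arithmetic path is taken either way.
    """
    response_mask = np.asarray(response_mask, dtype=bool)
    valid = predictor_values.notna().to_numpy() & response_mask[:, None]
    clusters: dict[bytes, MissingnessCluster] = {}
    for k, name in enumerate(predictor_values.columns):
        mask = valid[:, k]
        key = np.packbits(mask).tobytes()
        cl = clusters.get(key)
        if cl is None:
            clusters[key] = MissingnessCluster(
                mask_key=key, mask=mask, predictor_ids=[name]
            )
        else:
            cl.predictor_ids.append(name)
    return list(clusters.values())


def _spec_from_arrays(
    response: str,
    predictor: str | None,
    covariate_names: tuple[str, ...],
    ids: list[str],
    y: np.ndarray,
    x: np.ndarray | None,
    C: np.ndarray | None,
) -> ModelSpec:
    cols = [np.ones(y.size)]
    names = ["(intercept)"]
    if x is not None:
        cols.append(x)
        names.append(predictor)
    if C is not None and C.shape[1]:
        cols.append(C)
        names.extend(covariate_names)
    return ModelSpec(
        response=response,
        predictor=predictor,
        covariates=covariate_names,
        individuals=ids,
        y=y,
        X=np.column_stack(cols),
        column_names=tuple(names),
    )


def pair_seed(master_seed: int, response: str, predictor: str) -> np.random.SeedSequence:
    """A per-(response, predictor) seed sequence independent of scan order."""
    return np.random.SeedSequence(
        entropy=int(master_seed) % (2**31),
        spawn_key=(
            zlib.crc32(response.encode()),
            zlib.crc32(predictor.encode()),
        ),
    )


def run_association_scan(
    responses: PhenotypeTable,
    predictors: PhenotypeTable,
    rel: RelatednessMatrix,
    covariates: PhenotypeTable | None = None,
    options: AssocOptions | None = None,
) -> list[AssociationResult]:
    """Exact pairwise association tests for every (response, predictor).

    Results are ordered response-major, predictors in input order. Pairs
    with fewer than ``options.min_n`` usable individuals, or a predictor
    collinear with the covariates, are returned flagged as skipped rather
    than raising.
    """
    options = options or AssocOptions()
    if not responses.variables or not predictors.variables:
        raise ValueError("need at least one response and one predictor")
    universe = [
        i
        for i in rel.ids
        if i in responses.data.index
        and i in predictors.data.index
        and (covariates is None or i in covariates.data.index)
    ]
    R = responses.aligned(universe)
    P = predictors.aligned(universe)
    C = covariates.aligned(universe) if covariates is not None else None
    cov_names = tuple(C.columns) if C is not None else ()
    cov_valid = (
        C.notna().all(axis=1).to_numpy() if C is not None else np.ones(len(universe), bool)
    )
    Cv = C.to_numpy() if C is not None else None
    Pv = P.to_numpy()
    pred_col = {name: k for k, name in enumerate(P.columns)}
    universe_arr = np.array(universe, dtype=object)
    fid_by_id = (
        dict(zip(rel.ids, rel.fids)) if rel.fids is not None else None
    )
    families = (
        np.array([fid_by_id[i] for i in universe], dtype=object)
        if fid_by_id is not None
        else None
    )
    decomp_cache: dict[bytes, tuple[np.ndarray, EigenDecomp]] = {}

    def get_decomp(mask: np.ndarray) -> tuple[np.ndarray, EigenDecomp]:
        key = np.packbits(mask).tobytes()
        hit = decomp_cache.get(key)
        if hit is None:
            idx = np.flatnonzero(mask)
            K = rel.values[np.ix_(rel.indices(universe_arr[idx]), rel.indices(universe_arr[idx]))]
            hit = (idx, EigenDecomp.of(K))
            decomp_cache[key] = hit
        return hit

    if options.family_diagnostics and rel.source == "pedigree":
        from .postprocess import family_contributions
    else:
        family_contributions = None

    plan = options.permutation
    if plan is not None and plan.scheme == "within_family" and families is None:
        warnings.warn(
            "within-family permutation requires family labels; "
            "falling back to global permutation",
            stacklevel=2,
        )
        plan = replace(plan, scheme="global")

    results: list[AssociationResult] = []
    for resp in R.columns:
        y_all = R[resp].to_numpy()
        base = ~np.isnan(y_all) & cov_valid
        if options.use_missingness_clustering:
            clusters = cluster_by_missingness(P, base)
        else:
            clusters = []
            valid = P.notna().to_numpy() & base[:, None]
            for k, name in enumerate(P.columns):
                clusters.append(
                    MissingnessCluster(
                        mask_key=np.packbits(valid[:, k]).tobytes(),
                        mask=valid[:, k],
                        predictor_ids=[name],
                    )
                )
        by_pred: dict[str, AssociationResult] = {}
        for cluster in clusters:
            n_cluster = int(cluster.mask.sum())
            if n_cluster < max(options.min_n, 3):
                for pred in cluster.predictor_ids:
                    by_pred[pred] = AssociationResult(
                        response=resp,
                        predictor=pred,
                        n=n_cluster,
                        skip_reason=f"n={n_cluster} below minimum {options.min_n}",
                    )
                continue
            idx, decomp = get_decomp(cluster.mask)
            ids = list(universe_arr[idx])
            y = y_all[idx]
            Csub = Cv[idx] if Cv is not None else None
            null_spec = _spec_from_arrays(resp, None, cov_names, ids, y, None, Csub)
            try:
                null_fit = _fit_profile(
                    null_spec, decomp, options.grid_points, options.xatol
                )
            except CollinearityError as exc:
                for pred in cluster.predictor_ids:
                    by_pred[pred] = AssociationResult(
                        response=resp, predictor=pred, n=n_cluster,
                        skip_reason=str(exc),
                    )
                continue
            cluster.cached_null = null_fit
            for pred in cluster.predictor_ids:
                x = Pv[idx, pred_col[pred]]
                alt_spec = _spec_from_arrays(
                    resp, pred, cov_names, ids, y, x, Csub
                )
                try:
                    alt_fit = _fit_profile(
                        alt_spec, decomp, options.grid_points, options.xatol
                    )
                except CollinearityError as exc:
                    by_pred[pred] = AssociationResult(
                        response=resp, predictor=pred, n=n_cluster,
                        skip_reason=str(exc),
                    )
                    continue
                lrt, p = lrt_association(null_fit, alt_fit)
                result = AssociationResult(
                    response=resp,
                    predictor=pred,
                    n=n_cluster,
                    beta=alt_fit.beta,
                    se_beta=float(alt_fit.se[1]),
                    lrt=lrt,
                    p=p,
                    h2_null=null_fit.h2,
                )
                pos = predictors.position_of(pred)
                if pos is not None:
                    result.chrom, result.position = pos
                if not null_fit.h2_identifiable:
                    result.flags += ("h2_unidentifiable",)
                if family_contributions is not None:
                    result.family_diag = family_contributions(
                        null_fit, alt_fit, rel
                    )
                if plan is not None:
                    from .permutation import adaptive_empirical_p

                    rng = np.random.default_rng(
                        pair_seed(plan.seed, resp, pred)
                    )
                    evaluator = _make_permutation_evaluator(
                        resp, pred, cov_names, base, y_all, Cv,
                        cluster.mask, null_fit, get_decomp, universe_arr,
                        options,
                    )
                    emp_p, n_done, _stopped = adaptive_empirical_p(
                        evaluator,
                        lrt,
                        plan,
                        values=Pv[:, pred_col[pred]],
                        families=families if plan.scheme == "within_family" else None,
                        rng=rng,
                    )
                    result.empirical_p = emp_p
                    result.n_permutations = n_done
                by_pred[pred] = result
        results.extend(by_pred[pred] for pred in P.columns)
    return results


def _make_permutation_evaluator(
    resp, pred, cov_names, base, y_all, Cv, orig_mask, null_fit, get_decomp,
    universe_arr, options,
):
    """Evaluator mapping a permuted predictor vector (over the scan universe)
    to its LRT statistic; recomputes the missingness intersection per
    permutation, reusing the cached decomposition and null fit when the
    pattern is unchanged."""

    def evaluate(perm_values: np.ndarray) -> float:
        mask = base & ~np.isnan(perm_values)
        idx, decomp = get_decomp(mask)
        ids = list(universe_arr[idx])
        y = y_all[idx]
        Csub = Cv[idx] if Cv is not None else None
        if np.array_equal(mask, orig_mask):
            nf = null_fit
        else:
            null_spec = _spec_from_arrays(resp, None, cov_names, ids, y, None, Csub)
            nf = _fit_profile(null_spec, decomp, options.grid_points, options.xatol)
        alt_spec = _spec_from_arrays(
            resp, pred, cov_names, ids, y, perm_values[idx], Csub
        )
        alt = _fit_profile(alt_spec, decomp, options.grid_points, options.xatol)
        return _clamp_lrt(2.0 * (alt.loglik - nf.loglik))

    return evaluate
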