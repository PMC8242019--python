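"""Per-SNV association with pulmonary traits.

Fits a null model per trait and stratum — fixed effects for the top five
principal components, ancestry-group dummies and log sampling weight, plus
random effects with kinship, household and block-group covariance kernels —
then Wald-tests each instrument dosage against the fitted working covariance.

Gaussian traits use REML; binary traits use penalized quasi-likelihood (PQL)
on the logit scale, so estimates feed Mendelian randomization as log-odds per
effect-allele copy. Without cluster kernels both paths collapse to ordinary
OLS / logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .errors import ConvergenceError, DegenerateInputError, NumericalError, ValidationError
from .instrument_catalog import InstrumentSet
from .synthetic_cohort import ClusterMatrices

DEFAULT_COVARIATES: tuple[str, ...] = ("pc1", "pc2", "pc3", "pc4", "pc5")

_PQL_MAX_ITER = 50
_PQL_TOL = 1e-6


@dataclass
class NullModelFit:
    trait: str
    family: str
    beta: pd.Series
    variance_components: dict[str, float]
    converged: bool
    boundary_components: list[str] = field(default_factory=list)
    n: int = 0
    # internal state reused by test_variant
    X: np.ndarray | None = None
    y: np.ndarray | None = None
    columns: list[str] = field(default_factory=list)
    kernels: dict[str, np.ndarray] | None = None
    working_weights: np.ndarray | None = None  # binomial PQL weights at convergence
    residual_variance: float = 1.0


@dataclass
class AssociationResult:
    rsid: str
    trait: str
    stratum: str
    beta_gy: float
    se_gy: float
    n_analyzed: int
    p: float
    status: str = "ok"


def build_design(
    cohort: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept, numeric covariates, ancestry dummies,
    log sampling weight (covariates only if the columns exist)."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    for c in covariates:
        if c in cohort.columns:
            cols[c] = cohort[c].to_numpy(dtype=float)
    if "ancestry_group" in cohort.columns:
        dummies = pd.get_dummies(cohort["ancestry_group"], prefix="ancestry", drop_first=True)
        for c in dummies.columns:
            cols[c] = dummies[c].to_numpy(dtype=float)
    if "sampling_weight" in cohort.columns:
        cols["log_sampling_weight"] = np.log(cohort["sampling_weight"].to_numpy(dtype=float))
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())


def _check_design(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise NumericalError(
            f"rank-deficient design ({rank} < {X.shape[1]}); columns: {columns}"
        )


def _reml_nll(
    variances: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    base: np.ndarray,
    kernels: list[np.ndarray],
    free_residual: bool,
) -> float:
    """-2/2 * restricted log-likelihood (up to a constant)."""
    if free_residual:
        v0, comps = variances[0], variances[1:]
        V = v0 * base
    else:
        comps = variances
        V = base.copy()
    for s, K in zip(comps, kernels):
        V = V + s * K
    try:
        c, low = cho_factor(V, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vi_y = cho_solve((c, low), y, check_finite=False)
    vi_x = cho_solve((c, low), X, check_finite=False)
    xtvix = X.T @ vi_x
    sign, logdet_x = np.linalg.slogdet(xtvix)
    if sign <= 0:
        return np.inf
    xtviy = X.T @ vi_y
    try:
        beta = np.linalg.solve(xtvix, xtviy)
    except np.linalg.LinAlgError:
        return np.inf
    quad = float(y @ vi_y - xtviy @ beta)
    return 0.5 * (logdet_v + logdet_x + quad)


def _solve_gls(V: np.ndarray, y: np.ndarray, X: np.ndarray):
    c, low = cho_factor(V, check_finite=False)
    vi_y = cho_solve((c, low), y, check_finite=False)
    vi_x = cho_solve((c, low), X, check_finite=False)
    xtvix = X.T @ vi_x
    beta = np.linalg.solve(xtvix, X.T @ vi_y)
    cov_beta = np.linalg.inv(xtvix)
    return beta, cov_beta, (c, low)


def _assemble_v(
    base: np.ndarray, comps: Mapping[str, float], kernels: Mapping[str, np.ndarray]
) -> np.ndarray:
    V = base.copy()
    for name, K in kernels.items():
        V = V + comps.get(name, 0.0) * K
    return V


def _fit_gaussian_reml(
    y: np.ndarray, X: np.ndarray, kernels: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, dict[str, float], float, list[str]]:
    n = len(y)
    var_y = float(np.var(y))
    names = list(kernels.keys())
    klist = [kernels[k] for k in names]
    x0 = np.array([0.5 * var_y] + [0.1 * var_y] * len(names))
    bounds = [(1e-8 * var_y, None)] + [(0.0, None)] * len(names)
    base = np.eye(n)
    res = minimize(
        _reml_nll,
        x0,
        args=(y, X, base, klist, True),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 200},
    )
    if not res.success and not np.isfinite(res.fun):
        raise ConvergenceError(f"REML failed: {res.message}")
    est = res.x.copy()
    # project near-zero components onto the boundary so that the no-clustering
    # case is *exactly* ordinary least squares
    boundary = []
    for i, name in enumerate(names, start=1):
        if est[i] < 1e-7 * var_y:
            est[i] = 0.0
            boundary.append(name)
    comps = {"residual": float(est[0])}
    comps.update({name: float(est[i + 1]) for i, name in enumerate(names)})
    V = est[0] * base
    for i, K in enumerate(klist):
        V = V + est[i + 1] * K
    beta, cov_beta, _ = _solve_gls(V, y, X)
    return beta, cov_beta, comps, float(est[0]), boundary


def _fit_binomial_pql(
    y: np.ndarray, X: np.ndarray, kernels: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, dict[str, float], np.ndarray, list[str]]:
    n = len(y)
    names = list(kernels.keys())
    klist = [kernels[k] for k in names]
    beta = _fit_logistic(y, X)[0]
    eta = X @ beta
    comps = np.full(len(names), 0.1)
    boundary: list[str] = []
    for _ in range(_PQL_MAX_ITER):
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-6, None)
        z = eta + (y - mu) / w
        base = np.diag(1.0 / w)
        if names:
            res = minimize(
                _reml_nll,
                comps,
                args=(z, X, base, klist, False),
                method="L-BFGS-B",
                bounds=[(0.0, None)] * len(names),
                options={"maxiter": 100},
            )
            comps = res.x.copy()
            boundary = [names[i] for i in range(len(names)) if comps[i] < 1e-7]
            comps[comps < 1e-7] = 0.0
        V = base.copy()
        G = np.zeros((n, n))
        for s, K in zip(comps, klist):
            V = V + s * K
            G = G + s * K
        beta_new, cov_beta, cfac = _solve_gls(V, z, X)
        u = G @ cho_solve(cfac, z - X @ beta_new, check_finite=False)
        eta_new = X @ beta_new + u
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = eta_new
        if delta < _PQL_TOL:
            break
    else:
        raise ConvergenceError(
            f"PQL did not converge in {_PQL_MAX_ITER} iterations (last delta={delta:.3g})"
        )
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-6, None)
    comp_dict = {name: float(s) for name, s in zip(names, comps)}
    return beta, cov_beta, comp_dict, w, boundary


def _fit_logistic(y: np.ndarray, X: np.ndarray, max_iter: int = 50):
    """Plain IRLS logistic regression; returns (beta, cov_beta)."""
    beta = np.zeros(X.shape[1])
    p_bar = np.clip(y.mean(), 1e-10, 1 - 1e-10)
    beta[0] = np.log(p_bar / (1 - p_bar))  # column 0 is the intercept
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        xtwx = X.T @ WX
        try:
            beta_new = np.linalg.solve(xtwx, WX.T @ z)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("singular information matrix in logistic fit") from exc
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov


def fit_null_model(
    cohort: pd.DataFrame,
    trait: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    cluster_matrices: ClusterMatrices | Mapping[str, np.ndarray] | None = None,
    family: str = "binomial",
    fixed_variance_components: Mapping[str, float] | None = None,
) -> NullModelFit:
    """Fit the covariate-only (null) model for one trait.

    ``cluster_matrices`` may be None for the unclustered (plain regression)
    path, or kernels aligned row-for-row with ``cohort``.
    ``fixed_variance_components`` pins the cluster variances instead of
    estimating them (all-zero pins make the gaussian path exactly OLS).
    """
    if family not in ("gaussian", "binomial"):
        raise ValidationError(f"unknown family {family!r}")
    y = cohort[trait].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError(f"trait {trait} contains missing values; subset first")
    if np.var(y) == 0:
        raise DegenerateInputError(f"trait {trait} is constant in this stratum")
    X, columns = build_design(cohort, covariates)
    _check_design(X, columns)

    kernels: dict[str, np.ndarray] | None = None
    if cluster_matrices is not None:
        raw = (
            cluster_matrices.as_dict()
            if isinstance(cluster_matrices, ClusterMatrices)
            else dict(cluster_matrices)
        )
        kernels = {}
        for name, K in raw.items():
            K = np.asarray(K, dtype=float)
            if K.shape != (len(y), len(y)):
                raise ValidationError(
                    f"kernel {name} has shape {K.shape}, expected {(len(y), len(y))}"
                )
            kernels[name] = K

    weights = None
    residual = 1.0
    boundary: list[str] = []
    if kernels:
        if fixed_variance_components is not None:
            # gaussian: pins are relative to unit residual variance, which is
            # then profiled out; binomial (PQL): pins are absolute variances
            comps = {k: float(fixed_variance_components.get(k, 0.0)) for k in kernels}
            boundary = [k for k, v in comps.items() if v == 0.0]
            if family == "gaussian":
                V0 = _assemble_v(np.eye(len(y)), comps, kernels)
                beta, cov_raw, cfac = _solve_gls(V0, y, X)
                r = y - X @ beta
                residual = float(
                    r @ cho_solve(cfac, r, check_finite=False) / (len(y) - X.shape[1])
                )
                cov_beta = residual * cov_raw
                comps["residual"] = residual
            else:
                fake_null = NullModelFit(
                    trait=trait, family=family, beta=pd.Series(np.zeros(X.shape[1] - 1)),
                    variance_components=comps, converged=True, n=len(y),
                    X=X[:, :-1], y=y, kernels=kernels,
                )
                beta, cov_beta = _pql_fixed_components(y, X, fake_null)
                mu = expit(X @ beta)
                weights = np.clip(mu * (1 - mu), 1e-6, None)
        elif family == "gaussian":
            beta, cov_beta, comps, residual, boundary = _fit_gaussian_reml(y, X, kernels)
        else:
            beta, cov_beta, comps, weights, boundary = _fit_binomial_pql(y, X, kernels)
    else:
        if family == "gaussian":
            beta, resid, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            dof = len(y) - X.shape[1]
            residual = float(r @ r / dof)
            cov_beta = residual * np.linalg.inv(X.T @ X)
            comps = {"residual": residual}
        else:
            beta, cov_beta = _fit_logistic(y, X)
            comps = {}
    return NullModelFit(
        trait=trait,
        family=family,
        beta=pd.Series(beta, index=columns),
        variance_components=comps,
        converged=True,
        boundary_components=boundary,
        n=len(y),
        X=X,
        y=y,
        columns=columns,
        kernels=kernels,
        working_weights=weights,
        residual_variance=residual,
    )


def test_variant(
    null: NullModelFit, dosages: np.ndarray, rsid: str = "variant", stratum: str = "all"
) -> AssociationResult:
    """Wald test of a dosage added to the null model's design.

    Variance components are held at their null-model estimates; fixed effects
    (including the dosage coefficient) are re-estimated.
    """
    g = np.asarray(dosages, dtype=float)
    if len(g) != null.n:
        raise ValidationError(f"dosage length {len(g)} != model n {null.n}")
    if np.var(g) == 0:
        raise DegenerateInputError(f"{rsid}: monomorphic dosage in this stratum")
    X = np.column_stack([null.X, g])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise NumericalError(f"{rsid}: dosage is collinear with the null-model design")
    y = null.y
    if null.kernels:
        if null.family == "gaussian":
            V = _assemble_v(
                null.residual_variance * np.eye(null.n),
                null.variance_components,
                null.kernels,
            )
            beta, cov_beta, _ = _solve_gls(V, y, X)
        else:
            beta, cov_beta = _pql_fixed_components(y, X, null)
    else:
        if null.family == "gaussian":
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            resid = float(r @ r / (len(y) - X.shape[1]))
            cov_beta = resid * np.linalg.inv(X.T @ X)
        else:
            beta, cov_beta = _fit_logistic(y, X)
    b = float(beta[-1])
    se = float(np.sqrt(cov_beta[-1, -1]))
    p = float(2.0 * norm.sf(abs(b) / se)) if se > 0 else np.nan
    return AssociationResult(
        rsid=rsid,
        trait=null.trait,
        stratum=stratum,
        beta_gy=b,
        se_gy=se,
        n_analyzed=null.n,
        p=p,
    )


test_variant.__test__ = False  # not a pytest case despite the conventional name


def _pql_fixed_components(y: np.ndarray, X: np.ndarray, null: NullModelFit):
    """PQL IRLS with variance components frozen at the null-model estimates."""
    n = len(y)
    G = np.zeros((n, n))
    for name, K in null.kernels.items():
        G = G + null.variance_components.get(name, 0.0) * K
    beta = np.append(null.beta.to_numpy(), 0.0)
    eta = X @ beta
    for _ in range(_PQL_MAX_ITER):
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-6, None)
        z = eta + (y - mu) / w
        V = np.diag(1.0 / w) + G
        beta_new, cov_beta, cfac = _solve_gls(V, z, X)
        u = G @ cho_solve(cfac, z - X @ beta_new, check_finite=False)
        eta = X @ beta_new + u
        if np.max(np.abs(beta_new - beta)) < _PQL_TOL:
            beta = beta_new
            break
        beta = beta_new
    else:
        raise ConvergenceError("variant-test PQL did not converge")
    return beta, cov_beta


def association_scan(
    cohort: pd.DataFrame,
    instruments: InstrumentSet,
    traits: Mapping[str, tuple[str, str]],
    strata: Mapping[str, np.ndarray] | None = None,
    cluster_matrices: ClusterMatrices | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """One association row per variant x trait x stratum.

    ``traits`` maps trait name -> (cohort column, family). ``strata`` maps
    stratum name -> boolean mask over ``cohort`` rows (None = single stratum
    spanning the cohort). Failed fits yield error-coded rows, never silent
    drops.
    """
    if strata is None:
        strata = {"all": np.ones(len(cohort), dtype=bool)}
    dosage_cols = [f"dosage_{v.rsid}" for v in instruments.variants]
    missing = [c for c in dosage_cols if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort lacks dosage column(s): {', '.join(missing)}")

    rows = []
    for stratum_name, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        for trait_name, (column, family) in traits.items():
            sub_mask = mask & cohort[column].notna().to_numpy()
            sub = cohort.loc[sub_mask]
            kernels = None
            if cluster_matrices is not None:
                idx = np.flatnonzero(sub_mask)
                kernels = {
                    name: K[np.ix_(idx, idx)]
                    for name, K in cluster_matrices.as_dict().items()
                }
            try:
                null = fit_null_model(
                    sub.assign(**{column: sub[column].astype(float)}),
                    column,
                    covariates=covariates,
                    cluster_matrices=kernels,
                    family=family,
                )
            except Exception as exc:  # error-coded rows, one per variant
                for v in instruments.variants:
                    rows.append(
                        AssociationResult(
                            rsid=v.rsid,
                            trait=trait_name,
                            stratum=stratum_name,
                            beta_gy=np.nan,
                            se_gy=np.nan,
                            n_analyzed=int(sub_mask.sum()),
                            p=np.nan,
                            status=f"null_fit_error:{type(exc).__name__}",
                        )
                    )
                continue
            for v, col in zip(instruments.variants, dosage_cols):
                try:
                    res = test_variant(
                        null, sub[col].to_numpy(dtype=float), rsid=v.rsid, stratum=stratum_name
                    )
                    res.trait = trait_name
                    rows.append(res)
                except Exception as exc:
                    rows.append(
                        AssociationResult(
                            rsid=v.rsid,
                            trait=trait_name,
                            stratum=stratum_name,
                            beta_gy=np.nan,
                            se_gy=np.nan,
                            n_analyzed=null.n,
                            p=np.nan,
                            status=f"variant_test_error:{type(exc).__name__}",
                        )
                    )
    return pd.DataFrame(
        [
            {
                "rsid": r.rsid,
                "trait": r.trait,
                "stratum": r.stratum,
                "beta_gy": r.beta_gy,
                "se_gy": r.se_gy,
                "n": r.n_analyzed,
                "p": r.p,
                "status": r.status,
            }
            for r in rows
        ]
    )
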