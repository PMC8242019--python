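"""Two-sample Mendelian randomization with correlated instruments.

Combines literature SNV -> metabolite weights with cohort SNV -> trait
estimates. Because the instrument variants are in linkage disequilibrium, the
inverse-variance weighted estimator is run on principal components of a
weighted summary matrix rather than on the raw variants: the J x J matrix

    Psi_kl = beta_x[k] * beta_x[l] * rho_kl / (se_y[k] * se_y[l])

is eigen-decomposed, the leading components retained up to a cumulative
variance threshold, and generalized IVW performed in the reduced space with
outcome covariance Sigma_kl = se_y[k] * se_y[l] * rho_kl. This keeps type-I
error controlled in the presence of LD while discarding near-redundant
instrument directions.

Exposure-side standard errors are ignored in the point estimator (the
standard no-measurement-error convention for two-sample IVW).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import NumericalError, ValidationError
from .instrument_catalog import InstrumentSet, LdMatrix, METABOLITES

Z95 = 1.96  #: CI multiplier, fixed; intervals are reported as exp(theta +/- 1.96 se)

DEFAULT_VARIANCE_THRESHOLD = 0.99


@dataclass
class MrEstimate:
    """Causal estimate per metabolite x trait x stratum.

    ``theta`` is the effect per percentage point of the metabolite, on the
    log-odds scale for binary traits (trait units for continuous ones);
    ``or_point``/``ci95`` are its exponentiated presentation.
    """

    metabolite: str
    trait: str
    stratum: str
    theta: float
    se_theta: float
    k_components: int
    status: str = "ok"

    @property
    def or_point(self) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(self.theta))

    @property
    def ci95(self) -> tuple[float, float]:
        with np.errstate(over="ignore"):
            return (
                float(np.exp(self.theta - Z95 * self.se_theta)),
                float(np.exp(self.theta + Z95 * self.se_theta)),
            )

    @property
    def p(self) -> float:
        if self.se_theta <= 0:
            return float("nan")
        return float(2.0 * norm.sf(abs(self.theta) / self.se_theta))


def _as_rho(rho: LdMatrix | np.ndarray, j: int) -> np.ndarray:
    r = rho.r if isinstance(rho, LdMatrix) else np.asarray(rho, dtype=float)
    if r.shape != (j, j):
        raise ValidationError(f"LD matrix shape {r.shape} does not match J={j}")
    return r


def psi_matrix(beta_x: np.ndarray, se_y: np.ndarray, rho: LdMatrix | np.ndarray) -> np.ndarray:
    """Weighted summary matrix whose principal components form the instrument."""
    beta_x = np.asarray(beta_x, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    if beta_x.shape != se_y.shape:
        raise ValidationError("beta_x and se_y must have the same length")
    if np.any(se_y <= 0):
        raise ValidationError("se_y must be positive elementwise")
    r = _as_rho(rho, len(beta_x))
    w = beta_x / se_y
    return np.outer(w, w) * r


def select_components(
    psi: np.ndarray, variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD
) -> tuple[np.ndarray, pd.DataFrame]:
    """Retained eigenvectors of Psi plus an eigenvalue report.

    Keeps the smallest k whose cumulative eigenvalue share reaches the
    threshold. Eigenvector signs follow a deterministic convention (largest
    magnitude element made positive) so repeated runs are byte-identical.
    """
    psi = np.asarray(psi, dtype=float)
    if not np.all(np.isfinite(psi)):
        raise ValidationError("psi contains non-finite entries")
    if not np.allclose(psi, psi.T, atol=1e-10):
        raise ValidationError("psi must be symmetric")
    if not 0 < variance_threshold <= 1:
        raise ValidationError("variance threshold must be in (0, 1]")
    evals, evecs = np.linalg.eigh(psi)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = float(np.sum(np.abs(evals)))
    if total == 0:
        raise ValidationError("psi has no variation to decompose")
    share = np.cumsum(np.abs(evals)) / total
    k = int(np.searchsorted(share, variance_threshold - 1e-12) + 1)
    k = min(k, len(evals))
    W = evecs[:, :k].copy()
    for col in range(k):
        pivot = np.argmax(np.abs(W[:, col]))
        if W[pivot, col] < 0:
            W[:, col] = -W[:, col]
    report = pd.DataFrame(
        {
            "eigenvalue": evals,
            "share": np.abs(evals) / total,
            "cumulative_share": share,
            "retained": [i < k for i in range(len(evals))],
        }
    )
    return W, report


def gls_ivw_oracle(
    beta_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    rho: LdMatrix | np.ndarray,
) -> tuple[float, float]:
    """Full-rank generalized IVW: theta = (bx' S^-1 bx)^-1 bx' S^-1 by.

    Reference implementation used to validate the principal-components path;
    requires Sigma nonsingular.
    """
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    r = _as_rho(rho, len(beta_x))
    sigma = np.outer(se_y, se_y) * r
    try:
        si_bx = np.linalg.solve(sigma, beta_x)
        si_by = np.linalg.solve(sigma, beta_y)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("Sigma is singular; use the PCA path") from exc
    denom = float(beta_x @ si_bx)
    if denom <= 0:
        raise NumericalError("non-positive precision for theta (weak/degenerate instrument)")
    theta = float(beta_x @ si_by) / denom
    return theta, float(np.sqrt(1.0 / denom))


def pca_ivw(
    beta_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    rho: LdMatrix | np.ndarray,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    metabolite: str = "",
    trait: str = "",
    stratum: str = "",
) -> MrEstimate:
    """Principal-components IVW causal estimate for one metabolite and trait."""
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    if not (len(beta_x) == len(beta_y) == len(se_y)):
        raise ValidationError("beta_x, beta_y, se_y must have equal length")
    r = _as_rho(rho, len(beta_x))

    psi = psi_matrix(beta_x, se_y, r)
    W, _ = select_components(psi, variance_threshold)
    bx = W.T @ beta_x
    by = W.T @ beta_y
    sigma = np.outer(se_y, se_y) * r
    omega = W.T @ sigma @ W
    try:
        oi_bx = np.linalg.solve(omega, bx)
        oi_by = np.linalg.solve(omega, by)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "projected outcome covariance is singular; lower the variance threshold"
        ) from exc
    denom = float(bx @ oi_bx)
    if denom <= 0 or not np.isfinite(denom):
        raise NumericalError("non-positive instrument precision after projection")
    theta = float(bx @ oi_by) / denom
    se = float(np.sqrt(1.0 / denom))
    return MrEstimate(
        metabolite=metabolite,
        trait=trait,
        stratum=stratum,
        theta=theta,
        se_theta=se,
        k_components=W.shape[1],
    )


def mr_table(
    associations: pd.DataFrame,
    instruments: InstrumentSet,
    rho: LdMatrix | np.ndarray,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    metabolites: Sequence[str] = METABOLITES,
) -> pd.DataFrame:
    """One MR estimate per metabolite x trait x stratum.

    ``associations`` is the association-scan table (columns rsid, trait,
    stratum, beta_gy, se_gy, status). Cells whose association rows are
    error-coded or incomplete propagate an error status instead of being
    dropped.
    """
    required = {"rsid", "trait", "stratum", "beta_gy", "se_gy", "status"}
    missing = required - set(associations.columns)
    if missing:
        raise ValidationError(f"association table missing column(s): {sorted(missing)}")
    rsids = instruments.rsids
    rows = []
    for (stratum, trait), cell in associations.groupby(["stratum", "trait"], sort=False):
        cell = cell.set_index("rsid")
        complete = all(r in cell.index for r in rsids)
        clean = complete and (cell.loc[rsids, "status"] == "ok").all()
        for met in metabolites:
            if not clean:
                bad = (
                    "incomplete_associations"
                    if not complete
                    else ";".join(sorted(set(cell["status"]) - {"ok"}))
                )
                rows.append(
                    {
                        "stratum": stratum,
                        "trait": trait,
                        "metabolite": met,
                        "theta": np.nan,
                        "se_theta": np.nan,
                        "or": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                        "k_components": 0,
                        "status": bad,
                    }
                )
                continue
            beta_y = cell.loc[rsids, "beta_gy"].to_numpy(dtype=float)
            se_y = cell.loc[rsids, "se_gy"].to_numpy(dtype=float)
            try:
                est = pca_ivw(
                    instruments.beta_vector(met),
                    beta_y,
                    se_y,
                    rho,
                    variance_threshold,
                    metabolite=met,
                    trait=trait,
                    stratum=stratum,
                )
                lo, hi = est.ci95
                rows.append(
                    {
                        "stratum": stratum,
                        "trait": trait,
                        "metabolite": met,
                        "theta": est.theta,
                        "se_theta": est.se_theta,
                        "or": est.or_point,
                        "ci_low": lo,
                        "ci_high": hi,
                        "p": est.p,
                        "k_components": est.k_components,
                        "status": "ok",
                    }
                )
            except Exception as exc:
                rows.append(
                    {
                        "stratum": stratum,
                        "trait": trait,
                        "metabolite": met,
                        "theta": np.nan,
                        "se_theta": np.nan,
                        "or": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                        "k_components": 0,
                        "status": f"mr_error:{type(exc).__name__}",
                    }
                )
    return pd.DataFrame(rows)


def harmonization_flip(
    beta_x: np.ndarray, beta_y: np.ndarray, rho: np.ndarray, index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip one variant's allele coding in summary space (testing helper)."""
    bx = np.asarray(beta_x, dtype=float).copy()
    by = np.asarray(beta_y, dtype=float).copy()
    r = np.asarray(rho, dtype=float).copy()
    bx[index] *= -1
    by[index] *= -1
    r[index, :] *= -1
    r[:, index] *= -1
    r[index, index] = 1.0
    return bx, by, r
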