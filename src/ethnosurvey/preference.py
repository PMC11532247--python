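"""Binary logistic model of herbal-versus-allopathy preference.

The outcome is coded 1 for respondents who prefer herbal (plant-based)
treatment and 0 for those who prefer allopathy.  With covariates x the
model is the standard binary logit,

    log(p / (1 - p)) = beta0 + beta' x,

fitted by maximum likelihood via iteratively reweighted least squares
(IRLS, i.e. Fisher scoring) with a step-halving line search so the
log-likelihood never decreases between iterations.  Standard errors come
from the inverse Fisher information at the optimum, Wald z statistics
are estimate/SE, two-sided p-values from the standard normal, and odds
ratios are exp(estimate).

Before fitting, covariates are screened for multicollinearity with
variance inflation factors: VIF_j = 1 / (1 - R^2_j) from the ordinary
least-squares regression of covariate j on all the others (with
intercept).  Covariates whose VIF exceeds the threshold (default 5) are
removed one at a time, largest first, recomputing after each removal.
Exactly collinear covariates show an infinite VIF and are excluded the
same way.

Complete or quasi-complete separation makes the MLE diverge; the fitter
raises :class:`~ethnosurvey.exceptions.SeparationError` rather than
returning silently enormous coefficients.

A ``log1p`` transform of right-skewed continuous covariates (incomes,
family size) is available via :func:`log1p_transform` but is off by
default; the binary outcome itself is never transformed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, FormatError, SeparationError, SingularMatrixError

logger = logging.getLogger(__name__)

__all__ = [
    "PreferenceRecord",
    "LogitFit",
    "vif_values",
    "vif_screen",
    "ks_statistic",
    "fit_logit",
    "wald_z",
    "odds_ratio",
    "significance_stars",
    "log1p_transform",
    "read_preference_records",
]

#: Coefficient sup-norm beyond which the fit is treated as separated.
_SEPARATION_NORM = 1e3


@dataclass(frozen=True)
class PreferenceRecord:
    """One respondent: binary preference outcome plus named covariates."""

    respondent_id: str
    outcome: int
    covariates: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise DomainError(f"outcome must be 0 or 1, got {self.outcome!r}")


def records_to_frame(records: Sequence[PreferenceRecord]) -> tuple[pd.DataFrame, pd.Series]:
    """Covariate matrix and outcome vector from a record collection."""
    names = list(records[0].covariates)
    for record in records:
        if list(record.covariates) != names:
            raise DomainError("covariate names must be consistent across records")
    x = pd.DataFrame([dict(r.covariates) for r in records], columns=names, dtype=float)
    y = pd.Series([r.outcome for r in records], dtype=float, name="outcome")
    return x, y


def _as_design(data, outcome: str | None = None) -> tuple[pd.DataFrame, pd.Series | None]:
    """Accept either PreferenceRecord sequences or a DataFrame."""
    if isinstance(data, pd.DataFrame):
        if outcome is not None:
            y = data[outcome].astype(float)
            x = data.drop(columns=[outcome]).astype(float)
        else:
            y = None
            x = data.astype(float)
        return x, y
    x, y = records_to_frame(list(data))
    return x, y


# ---------------------------------------------------------------------------
# Multicollinearity screening
# ---------------------------------------------------------------------------

def _single_vif(x: np.ndarray, j: int) -> float:
    """VIF of column j from OLS of x_j on the remaining columns + intercept."""
    target = x[:, j]
    others = np.delete(x, j, axis=1)
    design = np.column_stack([np.ones(len(target)), others])
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    residual = target - design @ beta
    sst = float(np.sum((target - target.mean()) ** 2))
    if sst <= 0:
        return math.inf  # constant column: perfectly explained by the intercept
    r_squared = 1.0 - float(residual @ residual) / sst
    if r_squared >= 1.0 - 1e-12:
        return math.inf
    return 1.0 / (1.0 - r_squared)


def vif_values(data, outcome: str | None = None) -> dict[str, float]:
    """Variance inflation factor for every covariate (no exclusion)."""
    x, _ = _as_design(data, outcome)
    if x.shape[1] < 2:
        raise DomainError("VIF needs at least two covariates")
    matrix = x.to_numpy(dtype=float)
    return {name: _single_vif(matrix, j) for j, name in enumerate(x.columns)}


def vif_screen(
    data,
    threshold: float = 5.0,
    outcome: str | None = None,
) -> tuple[list[str], dict[str, float]]:
    """Iteratively exclude covariates with VIF above the threshold.

    Removal is one at a time from the largest VIF, recomputing after each
    removal.  Returns (kept covariate names in original order, excluded
    name -> VIF at the time of removal).  Exactly collinear covariates
    surface as infinite VIFs and are excluded first.
    """
    x, _ = _as_design(data, outcome)
    if x.shape[1] < 2:
        raise DomainError("VIF screening needs at least two covariates")
    if len(x) <= x.shape[1]:
        raise DomainError("need more records than covariates for VIF screening")
    kept = list(x.columns)
    excluded: dict[str, float] = {}
    while len(kept) >= 2:
        vifs = {name: _single_vif(x[kept].to_numpy(dtype=float), j)
                for j, name in enumerate(kept)}
        worst = max(kept, key=lambda name: vifs[name])
        if vifs[worst] <= threshold:
            break
        excluded[worst] = vifs[worst]
        kept.remove(worst)
        logger.info("excluded %s (VIF=%.3f)", worst, vifs[worst])
    return kept, excluded


# ---------------------------------------------------------------------------
# Distributional check
# ---------------------------------------------------------------------------

def ks_statistic(sample: Sequence[float], reference) -> float:
    """Kolmogorov-Smirnov D between a sample and a continuous reference CDF.

    ``reference`` is a callable CDF (e.g. ``scipy.stats.norm(m, s).cdf``).
    Returns the sup-distance between the empirical CDF and the reference,
    evaluated at the sample's step points.
    """
    sample = np.asarray(list(sample), dtype=float)
    if sample.size == 0:
        raise DomainError("KS statistic requires a nonempty sample")
    cdf = reference.cdf if hasattr(reference, "cdf") else reference
    return float(stats.ks_1samp(sample, cdf).statistic)


# ---------------------------------------------------------------------------
# Logistic regression by IRLS
# ---------------------------------------------------------------------------

@dataclass
class LogitFit:
    """Fitted binary logit: estimates and Wald-type report columns.

    The odds ratio column is exp(estimate) exactly, and z = estimate/SE
    wherever SE > 0; both are pure functions of the estimate columns.
    """

    params: dict[str, float]
    bse: dict[str, float]
    zvalues: dict[str, float]
    pvalues: dict[str, float]
    odds_ratios: dict[str, float]
    n_obs: int
    n_iter: int
    converged: bool
    llf: float
    llf_path: list[float] = field(default_factory=list)
    excluded: dict[str, float] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        """Report table: estimate, SE, z, p, significance star, odds ratio."""
        names = list(self.params)
        return pd.DataFrame(
            {
                "term": names,
                "estimate": [self.params[n] for n in names],
                "std_error": [self.bse[n] for n in names],
                "z_value": [self.zvalues[n] for n in names],
                "p_value": [self.pvalues[n] for n in names],
                "signif": [significance_stars(self.pvalues[n]) for n in names],
                "odds_ratio": [self.odds_ratios[n] for n in names],
            }
        )


def wald_z(estimate: float, se: float) -> float:
    """Wald statistic, estimate / SE."""
    if se <= 0:
        raise DomainError(f"standard error must be positive, got {se!r}")
    return estimate / se


def odds_ratio(estimate: float) -> float:
    """Odds ratio for a logit coefficient: exp(estimate)."""
    if not math.isfinite(estimate):
        raise DomainError("estimate must be finite")
    return math.exp(estimate)


def significance_stars(p: float) -> str:
    """Conventional significance codes: *** 0.001, ** 0.01, * 0.05, . 0.1."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logit(
    data,
    outcome: str | None = None,
    *,
    covariates: Sequence[str] | None = None,
    max_iterations: int = 50,
    tolerance: float = 1e-8,
    add_intercept: bool = True,
) -> LogitFit:
    """Maximum-likelihood binary logit via IRLS with step halving.

    ``data`` is either a sequence of :class:`PreferenceRecord` or a
    DataFrame (then ``outcome`` names the 0/1 column).  Convergence is
    declared when the largest absolute coefficient change falls below
    ``tolerance``.
    """
    x_frame, y_series = _as_design(data, outcome)
    if y_series is None:
        raise DomainError("an outcome column is required")
    if covariates is not None:
        x_frame = x_frame[list(covariates)]
    y = y_series.to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise SeparationError(
            "outcome is single-class; both preference classes are required"
        )
    names = (["intercept"] if add_intercept else []) + list(x_frame.columns)
    x = x_frame.to_numpy(dtype=float)
    if add_intercept:
        x = np.column_stack([np.ones(len(y)), x])
    n_obs, n_params = x.shape
    if n_obs <= n_params:
        raise DomainError("need more observations than parameters")

    beta = np.zeros(n_params)
    llf = _log_likelihood(y, x @ beta)
    llf_path = [llf]
    converged = False
    iteration = 0
    for iteration in range(1, max_iterations + 1):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        weights = mu * (1.0 - mu)
        score = x.T @ (y - mu)
        info = (x * weights[:, None]).T @ x
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            # Separation drives the IRLS weights to zero, which also makes
            # the information singular; tell that apart from collinearity.
            if np.all(np.abs(y - mu) < 1e-3):
                raise SeparationError(
                    "fitted probabilities reached 0/1 for every observation "
                    "(complete or quasi-complete separation)"
                ) from None
            raise SingularMatrixError(
                "singular Fisher information; offending covariate: "
                f"{_name_null_direction(info, names)!r}"
            ) from None
        # Step-halving line search: never accept a log-likelihood decrease.
        step = 1.0
        for _ in range(30):
            candidate = beta + step * delta
            new_llf = _log_likelihood(y, x @ candidate)
            if new_llf >= llf - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        llf = _log_likelihood(y, x @ beta)
        llf_path.append(llf)
        if np.max(np.abs(beta)) > _SEPARATION_NORM:
            raise SeparationError(
                "coefficients diverging (complete or quasi-complete separation)"
            )
        if np.max(np.abs(step * delta)) < tolerance:
            converged = True
            break
    if not converged and np.max(np.abs(beta)) > 50 and np.max(np.abs(score)) > 1e-4:
        raise SeparationError(
            "IRLS failed to converge with large coefficients; the data are "
            "likely separated"
        )

    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    weights = mu * (1.0 - mu)
    info = (x * weights[:, None]).T @ x
    try:
        covariance = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise SingularMatrixError(
            "singular Fisher information at the optimum; offending covariate: "
            f"{_name_null_direction(info, names)!r}"
        ) from None
    se = np.sqrt(np.diag(covariance))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LogitFit(
        params=dict(zip(names, beta.tolist())),
        bse=dict(zip(names, se.tolist())),
        zvalues=dict(zip(names, z.tolist())),
        pvalues=dict(zip(names, p.tolist())),
        odds_ratios={name: math.exp(b) for name, b in zip(names, beta.tolist())},
        n_obs=n_obs,
        n_iter=iteration,
        converged=converged,
        llf=llf,
        llf_path=llf_path,
    )


def _name_null_direction(info: np.ndarray, names: Sequence[str]) -> str:
    """Covariate loading heaviest on the information matrix's null space."""
    _, _, vt = np.linalg.svd(info)
    return names[int(np.argmax(np.abs(vt[-1])))]


def log1p_transform(frame: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    """Return a copy with log1p applied to the named (nonnegative) columns."""
    out = frame.copy()
    for column in columns:
        if (out[column] < 0).any():
            raise DomainError(f"column {column!r} has negative values; log1p undefined")
        out[column] = np.log1p(out[column])
    return out


def read_preference_records(
    path: str | Path, outcome: str = "prefers_herbal", respondent: str = "respondent"
) -> list[PreferenceRecord]:
    """Read a respondent covariate table; all non-id columns become covariates."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"preference file {path} is empty") from exc
    if outcome not in frame.columns:
        raise FormatError(f"outcome column {outcome!r} missing from {path}")
    covariate_names = [c for c in frame.columns if c not in (outcome, respondent)]
    records = []
    for i, row in frame.iterrows():
        rid = str(row[respondent]) if respondent in frame.columns else f"R{i:04d}"
        records.append(
            PreferenceRecord(
                respondent_id=rid,
                outcome=int(row[outcome]),
                covariates={name: float(row[name]) for name in covariate_names},
            )
        )
    return records
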