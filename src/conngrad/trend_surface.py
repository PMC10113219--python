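"""Trend surface modeling (TSM) of connectivity gradients.

A subject's gradient map is summarized by regressing its per-voxel
values on polynomial functions of the voxel coordinates: monomials
``x^p, y^p, z^p`` for powers 1..degree (no cross terms), so a degree-3
model has 9 coefficients. Fitting uses Bayesian linear regression with
an isotropic zero-mean Gaussian prior on the coefficients; the prior
precision (alpha) and noise precision (beta) are set by evidence
(type-II maximum likelihood) optimization. The polynomial degree is
chosen by a scree analysis of mean variance explained across degrees,
and subjects with outlying coefficients (beyond 3 SD) are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TSMBasis",
    "TSMFit",
    "ScreeResult",
    "build_basis",
    "fit_tsm",
    "fit_tsm_map",
    "select_degree_scree",
    "detect_outlier_subjects",
]

_AXES = ("x", "y", "z")


@dataclass
class TSMBasis:
    """Spatial polynomial basis on standardized voxel coordinates.

    ``columns`` holds the zero-meaned monomials in order
    x1, y1, z1, x2, y2, z2, ... (3 * degree columns, no intercept);
    ``center``/``scale`` record the per-axis standardization.
    """

    degree: int
    columns: np.ndarray
    names: list[str]
    center: np.ndarray
    scale: np.ndarray
    column_means: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


@dataclass
class TSMFit:
    """Fitted trend-surface coefficients for one gradient map."""

    beta: np.ndarray
    intercept: float
    degree: int
    variance_explained: float  # percent of map variance, in [0, 100]
    log_evidence: float
    alpha: float  # prior precision at convergence
    noise_precision: float
    n_iter: int
    converged: bool
    subject_id: str | None = None

    def predict(self, basis: TSMBasis) -> np.ndarray:
        return self.intercept + basis.columns @ self.beta


@dataclass
class ScreeResult:
    """Scree table of mean variance explained per degree, with the elbow."""

    chosen_degree: int
    table: pd.DataFrame


def build_basis(coords: np.ndarray, degree: int) -> TSMBasis:
    """Build the per-axis polynomial basis for a voxel coordinate set.

    Coordinates are z-scored per axis before raising to powers (keeps
    cubic terms well conditioned); each monomial column is then
    de-meaned so the intercept can be handled separately.
    """
    if not 1 <= int(degree) <= 5:
        raise ValueError("degree must be in 1..5")
    degree = int(degree)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must have shape (n_voxels, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if coords.shape[0] < 3 * degree + 1:
        raise ValueError(
            f"need at least {3 * degree + 1} voxels for a degree-{degree} basis"
        )
    center = coords.mean(axis=0)
    scale = coords.std(axis=0)
    if np.any(scale == 0.0):
        bad = [_AXES[i] for i in np.flatnonzero(scale == 0.0)]
        raise ValueError(f"degenerate axis (zero variance): {', '.join(bad)}")
    Z = (coords - center) / scale

    cols, names = [], []
    for p in range(1, degree + 1):
        for ax in range(3):
            cols.append(Z[:, ax] ** p)
            names.append(f"{_AXES[ax]}{p}")
    X = np.column_stack(cols)
    col_means = X.mean(axis=0)
    return TSMBasis(
        degree=degree,
        columns=X - col_means,
        names=names,
        center=center,
        scale=scale,
        column_means=col_means,
    )


def fit_tsm(
    basis: TSMBasis,
    mode_values: np.ndarray,
    subject_id: str | None = None,
    prior_precision: float | None = None,
    max_iter: int = 200,
    rtol: float = 1e-6,
) -> TSMFit:
    """Fit trend-surface coefficients by evidence-optimized Bayesian regression.

    The model is ``y = intercept + X b + e`` with ``b ~ N(0, alpha^-1 I)``
    and ``e ~ N(0, beta^-1)``. Alpha and beta are iterated to their
    type-II maximum-likelihood values (MacKay fixed-point updates) until
    the relative change falls below ``rtol`` or ``max_iter`` sweeps; the
    posterior mean of ``b`` is returned together with the percent
    variance explained and the log marginal likelihood.

    Passing ``prior_precision`` pins alpha (a value near zero recovers
    ordinary least squares).
    """
    y = np.asarray(mode_values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("mode values must be finite")
    X = basis.columns
    n, m = X.shape
    if y.shape != (n,):
        raise ValueError("mode values must match the basis voxel count")

    intercept = float(y.mean())
    t = y - intercept
    sst = float(t @ t)
    # constant map up to rounding of the mean: a few ulps per element
    if sst <= n * (8.0 * np.finfo(float).eps * max(1.0, abs(intercept))) ** 2:
        return TSMFit(
            beta=np.zeros(m),
            intercept=intercept,
            degree=basis.degree,
            variance_explained=0.0,
            log_evidence=np.nan,
            alpha=np.inf,
            noise_precision=np.inf,
            n_iter=0,
            converged=True,
            subject_id=subject_id,
        )

    # eigendecomposition of X'X makes each fixed-point sweep O(m)
    XtX = X.T @ X
    Xt_t = X.T @ t
    lam, Q = np.linalg.eigh(XtX)
    lam = np.clip(lam, 0.0, None)
    proj = Q.T @ Xt_t

    alpha = 1.0 if prior_precision is None else max(prior_precision, 1e-12)
    beta = 1.0 / np.var(t)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = beta * lam + alpha
        w = beta * Q @ (proj / denom)
        resid = t - X @ w
        sse = float(resid @ resid)
        gamma = float(np.sum(beta * lam / denom))
        beta_new = (n - gamma) / sse if sse > 0 else np.inf
        if prior_precision is None:
            ww = float(w @ w)
            alpha_new = gamma / ww if ww > 0 else 1e12
        else:
            alpha_new = alpha
        if not (np.isfinite(alpha_new) and np.isfinite(beta_new)):
            raise FloatingPointError(
                "evidence optimization diverged "
                f"(iteration {it}: alpha={alpha_new}, beta={beta_new}, sse={sse})"
            )
        if (
            abs(alpha_new - alpha) <= rtol * abs(alpha)
            and abs(beta_new - beta) <= rtol * abs(beta)
        ):
            alpha, beta = alpha_new, beta_new
            converged = True
            break
        alpha, beta = alpha_new, beta_new
    if not converged:
        warnings.warn(
            f"evidence optimization did not converge in {max_iter} iterations",
            stacklevel=2,
        )

    denom = beta * lam + alpha
    w = beta * Q @ (proj / denom)
    resid = t - X @ w
    sse = float(resid @ resid)
    ve = 100.0 * (1.0 - sse / sst)

    log_ev = 0.5 * (
        m * np.log(alpha)
        + n * np.log(beta)
        - beta * sse
        - alpha * float(w @ w)
        - float(np.sum(np.log(denom)))
        - n * np.log(2.0 * np.pi)
    )
    return TSMFit(
        beta=w,
        intercept=intercept,
        degree=basis.degree,
        variance_explained=float(np.clip(ve, 0.0, 100.0)),
        log_evidence=log_ev,
        alpha=alpha,
        noise_precision=beta,
        n_iter=it,
        converged=converged,
        subject_id=subject_id,
    )


def fit_tsm_map(
    coords: np.ndarray,
    mode_values: np.ndarray,
    degree: int = 3,
    **kwargs,
) -> TSMFit:
    """Convenience wrapper: build the basis for ``coords`` and fit."""
    return fit_tsm(build_basis(coords, degree), mode_values, **kwargs)


def select_degree_scree(
    fits_by_degree: dict[int, list[TSMFit]],
    flat_tol: float = 0.5,
    gain_floor: float = 0.1,
) -> ScreeResult:
    """Choose the polynomial degree at the elbow of the scree curve.

    The scree curve is the mean variance explained per degree. The elbow
    is the interior degree after which the marginal gain collapses by
    the largest factor: with per-degree gains ``g_d``, it maximizes
    ``g_d / max(g_{d+1}, gain_floor)`` over interior degrees whose own
    gain exceeds ``gain_floor`` (percentage points). Curves whose total
    range is below ``flat_tol`` percentage points carry no degree signal
    and fall back to the lowest degree (ties break low as well).
    """
    if not fits_by_degree:
        raise ValueError("no fits supplied")
    degrees = sorted(fits_by_degree)
    n_subjects = {len(fits_by_degree[d]) for d in degrees}
    if len(n_subjects) != 1:
        raise ValueError("each degree must be fitted on the same subject set")
    mean_ve = np.array(
        [np.mean([f.variance_explained for f in fits_by_degree[d]]) for d in degrees]
    )
    table = pd.DataFrame({"degree": degrees, "mean_variance_explained": mean_ve})

    if np.any(np.diff(mean_ve) < -1e-9):
        warnings.warn(
            "scree curve is not non-decreasing in degree", stacklevel=2
        )

    if len(degrees) < 3 or (mean_ve.max() - mean_ve[0]) < flat_tol:
        return ScreeResult(chosen_degree=degrees[0], table=table)

    gains = np.diff(mean_ve)  # gains[i] = gain of degrees[i + 1] over degrees[i]
    ratios = np.full(len(degrees), -np.inf)
    for i in range(len(gains) - 1):  # interior degrees only
        if gains[i] > gain_floor:
            ratios[i + 1] = gains[i] / max(gains[i + 1], gain_floor)
    if np.all(np.isinf(ratios)):
        return ScreeResult(chosen_degree=degrees[0], table=table)
    best = int(np.argmax(np.round(ratios, 9)))  # argmax ties break low
    return ScreeResult(chosen_degree=degrees[best], table=table)


def detect_outlier_subjects(
    fits: list[TSMFit], n_sd: float = 3.0
) -> pd.DataFrame:
    """Flag subjects with any coefficient beyond ``n_sd`` SD of the mean.

    A single pass over all subjects: per-coefficient mean and sample SD
    are computed once, and a subject is flagged iff any coefficient lies
    strictly beyond mean +/- n_sd * SD. Coefficients with zero variance
    are skipped with a warning.
    """
    if len(fits) < 3:
        raise ValueError("outlier detection requires at least 3 subjects")
    betas = np.vstack([f.beta for f in fits])
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    usable = sd > 0.0
    if not usable.all():
        warnings.warn(
            f"skipping {int((~usable).sum())} zero-variance coefficient(s)",
            stacklevel=2,
        )
    dev = np.zeros_like(betas)
    dev[:, usable] = np.abs(betas[:, usable] - mean[usable]) / sd[usable]
    flagged = (dev > n_sd).any(axis=1)
    return pd.DataFrame(
        {
            "subject_id": [
                f.subject_id if f.subject_id is not None else str(i)
                for i, f in enumerate(fits)
            ],
            "outlier": flagged,
            "max_abs_z": dev.max(axis=1),
        }
    )
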