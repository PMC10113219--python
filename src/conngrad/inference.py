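"""Group and association inference on trend-surface coefficients.

Covers the statistical layer of the gradient analysis: an omnibus
likelihood-ratio test of group differences in the TSM coefficients
(logistic regression with age/gender covariates), multiple linear
regressions of symptom/trait scores on the coefficients, post-hoc
partial correlations, Bonferroni correction, and motion/age
contamination checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestResult",
    "AssociationResult",
    "MotionQCResult",
    "bonferroni_alpha",
    "omnibus_group_lrt",
    "association_glm",
    "partial_correlations",
    "contamination_checks",
    "motion_qc",
    "framewise_displacement",
]


@dataclass
class GroupTestResult:
    """Omnibus likelihood-ratio test of group on TSM coefficients."""

    chi2: float
    df: int
    p: float
    accuracy: float  # percent correctly classified, in-sample, threshold 0.5
    n_per_group: dict[str, int]
    alpha_used: float
    separation_suspected: bool = False

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_used


@dataclass
class AssociationResult:
    """Overall F-test of a linear outcome model on TSM coefficients."""

    F: float
    df_model: int
    df_error: int
    p: float
    r_squared: float
    outcome_name: str
    alpha_used: float
    n_used: int
    n_dropped: int
    partials: pd.DataFrame | None = None

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_used


@dataclass
class MotionQCResult:
    keep: bool
    reasons: list[str]
    mean_fd: float
    spike_fraction: float
    max_fd: float


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Bonferroni-corrected per-test significance level."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def _design(*blocks: np.ndarray) -> np.ndarray:
    cols = [np.asarray(b, dtype=float) for b in blocks if b is not None]
    cols = [c[:, None] if c.ndim == 1 else c for c in cols]
    return np.hstack(cols)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        dropped = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"rank-deficient design; collinear columns: {dropped}")


def _as_binary_group(group) -> tuple[np.ndarray, dict[str, int]]:
    g = pd.Series(group).reset_index(drop=True)
    levels = sorted(g.unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    y = (g == levels[1]).to_numpy(dtype=float)
    counts = {str(lv): int((g == lv).sum()) for lv in levels}
    return y, counts


def omnibus_group_lrt(
    tsm_coeffs: np.ndarray | pd.DataFrame,
    group,
    covariates: np.ndarray | pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Omnibus group test: likelihood ratio of nested logistic regressions.

    Group membership is regressed on the covariates alone (reduced
    model) and on covariates plus all TSM coefficients (full model);
    ``chi2 = 2 (LL_full - LL_reduced)`` is referred to a chi-square law
    with df = number of coefficients. Classification accuracy is the
    in-sample fraction correctly classified by the full model at a
    probability threshold of 0.5.
    """
    X_coef = np.asarray(tsm_coeffs, dtype=float)
    if X_coef.ndim == 1:
        X_coef = X_coef[:, None]
    if not np.all(np.isfinite(X_coef)):
        raise ValueError("TSM coefficients must be finite")
    y, counts = _as_binary_group(group)
    n = len(y)
    if X_coef.shape[0] != n:
        raise ValueError("coefficients and group labels have mismatched lengths")
    df = X_coef.shape[1]
    if n <= df + (0 if covariates is None else np.atleast_2d(covariates).shape[-1]) + 2:
        raise ValueError("too few subjects for the omnibus model")

    X_red = sm.add_constant(
        _design(covariates) if covariates is not None else np.empty((n, 0)),
        has_constant="add",
    )
    X_full = sm.add_constant(
        _design(covariates, X_coef) if covariates is not None else X_coef,
        has_constant="add",
    )

    def _fit(X, label):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(
                disp=0, method="lbfgs", maxiter=1000, pgtol=1e-10, factr=10.0
            )
        if not np.isfinite(res.llf):
            raise FloatingPointError(
                f"perfect separation or non-finite likelihood in the {label} fit"
            )
        return res

    res_red = _fit(X_red, "reduced")
    res_full = _fit(X_full, "full")

    chi2 = max(2.0 * (res_full.llf - res_red.llf), 0.0)
    p = float(sps.chi2.sf(chi2, df))
    pred = (res_full.predict(X_full) >= 0.5).astype(float)
    accuracy = 100.0 * float(np.mean(pred == y))
    separation = bool(
        accuracy == 100.0 and np.max(np.abs(X_full @ res_full.params)) > 30.0
    )
    if separation:
        logger.warning("omnibus LRT: perfect in-sample separation suspected")
    return GroupTestResult(
        chi2=float(chi2),
        df=df,
        p=p,
        accuracy=accuracy,
        n_per_group=counts,
        alpha_used=alpha,
        separation_suspected=separation,
    )


def association_glm(
    tsm_coeffs: np.ndarray | pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    outcome_name: str = "outcome",
    alpha: float = 0.05,
) -> AssociationResult:
    """Multiple linear regression of an outcome on the TSM coefficients.

    Reports the overall F-test of the full model (all predictors versus
    intercept-only), R-squared and p. Rows with a missing outcome are
    dropped and logged.
    """
    coef_names = (
        list(tsm_coeffs.columns)
        if isinstance(tsm_coeffs, pd.DataFrame)
        else [f"b{j}" for j in range(np.atleast_2d(np.asarray(tsm_coeffs)).shape[-1])]
    )
    X_coef = np.asarray(tsm_coeffs, dtype=float)
    if X_coef.ndim == 1:
        X_coef = X_coef[:, None]
    y = np.asarray(outcome, dtype=float)
    keep = np.isfinite(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropping %d rows with missing outcome", outcome_name, n_dropped)
    cov = None if covariates is None else np.asarray(_design(covariates))
    X = _design(cov[keep] if cov is not None else None, X_coef[keep])
    y = y[keep]
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few complete rows for the association model")

    cov_names = [f"cov{j}" for j in range(X.shape[1] - X_coef.shape[1])]
    _check_rank(sm.add_constant(X), ["const", *cov_names, *coef_names])
    res = sm.OLS(y, sm.add_constant(X)).fit()
    return AssociationResult(
        F=float(res.fvalue),
        df_model=int(res.df_model),
        df_error=int(res.df_resid),
        p=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        outcome_name=outcome_name,
        alpha_used=alpha,
        n_used=int(len(y)),
        n_dropped=n_dropped,
    )


def partial_correlations(
    tsm_coeffs: np.ndarray | pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-coefficient partial correlation with the outcome.

    For each coefficient j, both the coefficient and the outcome are
    residualized on the covariates (age, gender, ...) and all *other*
    coefficients; the partial correlation is the Pearson correlation of
    the two residual vectors, with a two-sided p-value from the t
    transform on ``n - n_controls - 2`` degrees of freedom.
    """
    names = (
        list(tsm_coeffs.columns)
        if isinstance(tsm_coeffs, pd.DataFrame)
        else None
    )
    X_coef = np.asarray(tsm_coeffs, dtype=float)
    if X_coef.ndim == 1:
        X_coef = X_coef[:, None]
    m = X_coef.shape[1]
    if names is None:
        names = [f"b{j}" for j in range(m)]
    y = np.asarray(outcome, dtype=float)
    keep = np.isfinite(y)
    X_coef = X_coef[keep]
    y = y[keep]
    cov = None if covariates is None else _design(covariates)[keep]
    n = len(y)

    rows = []
    for j in range(m):
        others = np.delete(X_coef, j, axis=1)
        Z = _design(cov, others) if cov is not None else others
        Z = sm.add_constant(Z)
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("controls rank-deficient in partial correlation")
        H_resid = lambda v: v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
        rx = H_resid(X_coef[:, j])
        ry = H_resid(y)
        denom = np.linalg.norm(rx) * np.linalg.norm(ry)
        if denom == 0.0:
            raise ValueError(f"zero residual variance for coefficient {names[j]}")
        r = float(rx @ ry / denom)
        n_controls = Z.shape[1] - 1  # excluding the intercept
        dof = n - n_controls - 2
        if dof <= 0:
            raise ValueError("not enough observations for partial correlation")
        t = r * np.sqrt(dof / max(1.0 - r**2, np.finfo(float).tiny))
        p = float(2.0 * sps.t.sf(abs(t), dof))
        rows.append({"coefficient": names[j], "r_partial": r, "p": p, "df": dof})
    return pd.DataFrame(rows)


def contamination_checks(
    tsm_coeffs: np.ndarray | pd.DataFrame,
    subject_table: pd.DataFrame,
    outcomes: list[str] | None = None,
    group_col: str = "group",
    alpha_group: float = 0.0125,
    alpha_assoc: float = 0.05,
) -> dict:
    """Post-hoc motion and age contamination checks.

    (a) Re-runs the omnibus group test and each outcome association with
    meanFD appended to the age/gender covariates, reporting whether
    significance at the applicable alpha is retained. (b) Reports the
    coefficient-by-{age, meanFD, DVARS} Pearson correlation table with
    p-values.
    """
    if "meanFD" not in subject_table.columns:
        raise ValueError("subject table lacks the meanFD motion column")
    names = (
        list(tsm_coeffs.columns)
        if isinstance(tsm_coeffs, pd.DataFrame)
        else None
    )
    X = np.asarray(tsm_coeffs, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"b{j}" for j in range(X.shape[1])]

    base_cov = subject_table[["age", "gender"]].to_numpy(dtype=float)
    fd = subject_table["meanFD"].to_numpy(dtype=float)
    cov_fd = np.c_[base_cov, fd]

    report: dict = {"correlations": [], "group_lrt_with_meanfd": None, "associations_with_meanfd": {}}

    nuisance_cols = [c for c in ("age", "meanFD", "dvars") if c in subject_table.columns]
    for j, name in enumerate(names):
        row = {"coefficient": name}
        for col in nuisance_cols:
            v = subject_table[col].to_numpy(dtype=float)
            r, p = sps.pearsonr(X[:, j], v)
            row[f"r_{col}"] = float(r)
            row[f"p_{col}"] = float(p)
        report["correlations"].append(row)
    report["correlations"] = pd.DataFrame(report["correlations"])

    if group_col in subject_table.columns and subject_table[group_col].nunique() == 2:
        base = omnibus_group_lrt(X, subject_table[group_col], base_cov, alpha=alpha_group)
        with_fd = omnibus_group_lrt(X, subject_table[group_col], cov_fd, alpha=alpha_group)
        report["group_lrt_with_meanfd"] = {
            "result": with_fd,
            "significant_without_meanfd": base.significant,
            "significant_with_meanfd": with_fd.significant,
            "conclusion_retained": base.significant == with_fd.significant,
        }

    for out in outcomes or []:
        base = association_glm(
            X, subject_table[out], base_cov, outcome_name=out, alpha=alpha_assoc
        )
        with_fd = association_glm(
            X, subject_table[out], cov_fd, outcome_name=out, alpha=alpha_assoc
        )
        report["associations_with_meanfd"][out] = {
            "result": with_fd,
            "significant_without_meanfd": base.significant,
            "significant_with_meanfd": with_fd.significant,
            "conclusion_retained": base.significant == with_fd.significant,
        }
    return report


def motion_qc(
    fd_trace: np.ndarray,
    spike_threshold_mm: float = 0.25,
    mean_fd_max: float = 0.2,
    spike_fraction_max: float = 0.2,
    any_fd_max: float = 5.0,
) -> MotionQCResult:
    """Head-motion exclusion rules on a framewise-displacement trace.

    A subject is excluded iff meanFD exceeds ``mean_fd_max`` (0.2 mm),
    the fraction of suprathreshold spikes (FD > ``spike_threshold_mm``)
    exceeds ``spike_fraction_max`` (20%), or any single FD exceeds
    ``any_fd_max`` (5 mm). All triggered reasons are listed.
    """
    fd = np.asarray(fd_trace, dtype=float)
    if fd.ndim != 1 or len(fd) < 2:
        raise ValueError("FD trace must be 1D with at least 2 frames")
    if np.any(fd < 0):
        raise ValueError("FD must be nonnegative")
    mean_fd = float(fd.mean())
    spike_fraction = float(np.mean(fd > spike_threshold_mm))
    max_fd = float(fd.max())

    reasons = []
    if mean_fd > mean_fd_max:
        reasons.append(f"meanFD > {mean_fd_max:g}")
    if spike_fraction > spike_fraction_max:
        reasons.append(
            f"sum of suprathreshold spikes > {spike_fraction_max:.0%}"
        )
    if max_fd > any_fd_max:
        reasons.append(f"any FD > {any_fd_max:g} mm")
    return MotionQCResult(
        keep=not reasons,
        reasons=reasons,
        mean_fd=mean_fd,
        spike_fraction=spike_fraction,
        max_fd=max_fd,
    )


def framewise_displacement(
    motion_params: np.ndarray, radius_mm: float = 50.0
) -> np.ndarray:
    """Power-style framewise displacement from six realignment parameters.

    ``motion_params`` is (T, 6): three translations in mm and three
    rotations in radians; rotations are converted to arc length on a
    sphere of ``radius_mm``. FD is the sum of absolute backward
    differences (first frame = 0).
    """
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameters must have shape (T, 6)")
    p = p.copy()
    p[:, 3:] *= radius_mm
    fd = np.zeros(len(p))
    fd[1:] = np.abs(np.diff(p, axis=0)).sum(axis=1)
    return fd
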