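"""Per-protein separate curve-fitting and quality control.

The comparison baseline: each protein's curve is fitted independently by
nonlinear least squares (scipy ``curve_fit``) with no pooling, then judged
by a simplified quality-control rule in the style of the original meltome
protocol — a lower-bound (plateau) threshold and a goodness-of-fit floor,
with the normalized area under the curve reported alongside.  Proteins
failing QC are the ones the hierarchical model imputes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from .curve import melting_curve
from .io import validate_measurements
from .posterior import PosteriorDraws

__all__ = [
    "QCConfig",
    "SeparateFitResult",
    "SeparateCurveFit",
    "fit_separate",
    "qc",
    "compare_estimates",
    "residual_uncertainty_correlation",
]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds deciding whether a fitted curve counts as a melter.

    ``plateau_max``: maximum fitted lower plateau L (default 0.3) — a
    curve that never decays below ~0.3 of its initial level shows no
    clear melting transition.  ``r2_min``: minimum coefficient of
    determination of the fit (default 0.8).  Both are stand-ins for the
    meltome protocol's unpublished thresholds and are configurable.
    """

    plateau_max: float = 0.3
    r2_min: float = 0.8
    require_convergence: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau_max <= 1.0:
            raise ValueError("plateau_max must lie in [0, 1]")
        if not 0.0 <= self.r2_min <= 1.0:
            raise ValueError("r2_min must lie in [0, 1]")


@dataclass
class SeparateFitResult:
    """Outcome of one protein's independent least-squares curve fit."""

    run_name: str
    protein_id: str
    converged: bool
    L: float | None = None
    a: float | None = None
    b: float | None = None
    tm_mle: float | None = None
    r2: float | None = None
    nauc: float | None = None
    qc_pass: bool = False
    failure_reason: str | None = None


def _nauc(T: np.ndarray, y: np.ndarray) -> float:
    """Trapezoid area under the measured curve divided by the T span."""
    span = T[-1] - T[0]
    if span <= 0:
        return float("nan")
    return float(np.trapezoid(y, T) / span)


def fit_separate(table: pd.DataFrame, protein) -> SeparateFitResult:
    """Least-squares fit of the melting curve to one protein's data.

    Deterministic, data-driven initialization: L0 = clipped min(y),
    Tm0 = temperature where y is closest to the midpoint (1 + L0)/2,
    b0 = 10, a0 = b0·Tm0.  Bounds: L in [0, 1], a and b positive.
    Non-convergence is reported as a failure flag, never an exception.
    """
    if isinstance(protein, tuple):
        run, pid = protein
        sub = table[(table["run_name"] == run) & (table["protein_id"] == pid)]
    else:
        sub = table[table["protein_id"] == protein]
        if sub["run_name"].nunique() > 1:
            raise KeyError(f"protein_id {protein!r} is ambiguous; pass (run_name, protein_id)")
        run, pid = (sub["run_name"].iloc[0], protein) if len(sub) else (None, protein)
    if sub.empty:
        raise KeyError(f"unknown protein {protein!r}")
    sub = sub.sort_values("temperature")
    T = sub["temperature"].to_numpy(dtype=float)
    y = sub["fold_change"].to_numpy(dtype=float)
    res = SeparateFitResult(run_name=run, protein_id=pid, converged=False)
    res.nauc = _nauc(T, y)
    if len(T) < 3:
        res.failure_reason = "underdetermined"
        return res

    L0 = float(np.clip(np.min(y), 0.0, 0.9))
    mid = (1.0 + L0) / 2.0
    Tm0 = float(T[int(np.argmin(np.abs(y - mid)))])
    b0 = 10.0
    a0 = b0 * Tm0

    def f(T, L, a, b):
        return melting_curve(L=L, a=a, b=b, T=T)

    try:
        popt, _ = curve_fit(
            f,
            T,
            y,
            p0=[L0, a0, b0],
            bounds=([0.0, 1e-8, 1e-8], [1.0, np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError):
        res.failure_reason = "no_convergence"
        return res

    L, a, b = (float(v) for v in popt)
    yhat = np.asarray(f(T, L, a, b))
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    res.converged = True
    res.L, res.a, res.b = L, a, b
    res.tm_mle = a / b
    res.r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return res


def qc(fit: SeparateFitResult, config: QCConfig | None = None) -> SeparateFitResult:
    """Apply the quality-control rule; fills qc_pass and failure_reason.

    Pass iff the fit converged, the fitted plateau L ≤ plateau_max, and
    R² ≥ r2_min. The reason string names the first failed rule.
    """
    config = config or QCConfig()
    if not fit.converged:
        fit.qc_pass = False
        if config.require_convergence:
            fit.failure_reason = fit.failure_reason or "no_convergence"
        return fit
    if fit.L is not None and fit.L > config.plateau_max:
        fit.qc_pass = False
        fit.failure_reason = f"plateau L={fit.L:.3f} > {config.plateau_max}"
        return fit
    if fit.r2 is not None and fit.r2 < config.r2_min:
        fit.qc_pass = False
        fit.failure_reason = f"R2={fit.r2:.3f} < {config.r2_min}"
        return fit
    fit.qc_pass = True
    fit.failure_reason = None
    return fit


class SeparateCurveFit(BaseEstimator):
    """Independent per-protein curve fits with QC, as an estimator.

    ``fit(X)`` runs :func:`fit_separate` + :func:`qc` for every protein in
    the table and stores one row each in ``results_``.
    """

    def __init__(self, plateau_max: float = 0.3, r2_min: float = 0.8,
                 require_convergence: bool = True):
        self.plateau_max = plateau_max
        self.r2_min = r2_min
        self.require_convergence = require_convergence

    def fit(self, X: pd.DataFrame, y=None) -> "SeparateCurveFit":
        table = validate_measurements(X)
        config = QCConfig(
            plateau_max=self.plateau_max,
            r2_min=self.r2_min,
            require_convergence=self.require_convergence,
        )
        rows = []
        keys = sorted(
            map(tuple, table[["run_name", "protein_id"]].drop_duplicates().itertuples(index=False))
        )
        for key in keys:
            r = qc(fit_separate(table, key), config)
            rows.append(vars(r).copy())
        self.results_ = pd.DataFrame(rows)
        self.qc_config_ = config
        return self

    def results(self) -> pd.DataFrame:
        if not hasattr(self, "results_"):
            raise AttributeError("estimator is not fitted; call fit(table) first")
        return self.results_


def compare_estimates(bayes: PosteriorDraws, mle: pd.DataFrame) -> pd.DataFrame:
    """Residuals between Bayesian and separate-curve melting points.

    One row per protein present in both inputs: posterior-mean Tm,
    posterior sd, the MLE Tm, and residual = posterior mean − MLE.
    Proteins without a converged MLE are kept with residual NaN and
    ``excluded=True``.  Raises if the protein sets are disjoint.
    """
    if isinstance(mle, SeparateCurveFit):
        mle = mle.results()
    mle_keys = set(map(tuple, mle[["run_name", "protein_id"]].itertuples(index=False)))
    common = [k for k in bayes.proteins if k in mle_keys]
    if not common:
        raise ValueError("posterior and MLE results share no proteins")
    mle_idx = mle.set_index(["run_name", "protein_id"])
    rows = []
    for key in common:
        t = bayes.tm_draws(key)
        m = mle_idx.loc[key]
        tm_mle = m["tm_mle"] if m["converged"] else np.nan
        rows.append(
            {
                "run_name": key[0],
                "protein_id": key[1],
                "tm_bayes": float(np.mean(t)),
                "tm_sd": float(np.std(t, ddof=1)),
                "tm_mle": float(tm_mle) if np.isfinite(tm_mle) else np.nan,
                "residual": float(np.mean(t) - tm_mle) if np.isfinite(tm_mle) else np.nan,
                "qc_pass": bool(m["qc_pass"]),
                "excluded": not np.isfinite(tm_mle),
            }
        )
    return pd.DataFrame(rows)


def residual_uncertainty_correlation(comparison: pd.DataFrame) -> float:
    """Spearman correlation of |residual| with posterior Tm sd."""
    sub = comparison.dropna(subset=["residual"])
    if len(sub) < 3:
        raise ValueError("need at least 3 residuals for a rank correlation")
    rho, _ = spearmanr(sub["residual"].abs(), sub["tm_sd"])
    return float(rho)
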