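"""Posterior curve bands, validation diagnostics and per-run summaries.

Posterior curve bands are built by passing every joint parameter draw
through the melting-curve link function and summarising pointwise —
never by evaluating the curve at parameter means, which would be biased
through the nonlinearity.  The diagnostics bundle mirrors the standard
validation views for this model class: spot-check curve panels across
the posterior-uncertainty range, residual-vs-uncertainty scatter against
the separate-fit baseline, and the imputed-vs-measured uncertainty
comparison, plus a per-run summary table of posterior-mean Tm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .curve import melting_curve
from .posterior import PosteriorDraws

__all__ = [
    "PosteriorCurveBand",
    "posterior_curves",
    "summarize_by_run",
    "diagnostics_bundle",
]


@dataclass
class PosteriorCurveBand:
    """Distribution over melting curves for one protein.

    ``curves`` holds one evaluated curve per posterior draw; ``central``
    is the pointwise median and ``lower``/``upper`` the equal-tailed
    credible bounds at the stated level.
    """

    protein: tuple
    grid: np.ndarray
    curves: np.ndarray  # (n_draws, len(grid))
    central: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    ci: float


def posterior_curves(
    posterior: PosteriorDraws, protein, grid, ci: float = 0.94
) -> PosteriorCurveBand:
    """Evaluate every posterior draw's curve on ``grid`` and summarise.

    The band is computed draw-wise: curve d is f(L_p^d, a_p^d, b_p^d, ·),
    and the central/interval curves are pointwise quantiles over draws.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("grid must be non-empty positive temperatures")
    a = posterior.a_draws(protein)
    b = posterior.b_draws(protein)
    L = posterior.plateau_draws(protein)
    # draws from an unbounded sum can stray outside the curve's domain;
    # evaluate the same link function directly
    from scipy.special import expit

    curves = L[:, None] + (1.0 - L[:, None]) * expit(a[:, None] / grid[None, :] - b[:, None])
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    return PosteriorCurveBand(
        protein=protein if isinstance(protein, tuple) else (None, protein),
        grid=grid,
        curves=curves,
        central=np.quantile(curves, 0.5, axis=0),
        lower=np.quantile(curves, lo_q, axis=0),
        upper=np.quantile(curves, hi_q, axis=0),
        ci=ci,
    )


def summarize_by_run(
    tm_estimates: pd.DataFrame,
    group: str = "run_name",
    value: str = "tm_mean",
    imputed_only: bool = False,
) -> pd.DataFrame:
    """Per-run summary of melting-temperature estimates.

    Columns: n, mean, std, min, 25%, 50%, 75%, max of the ``value``
    column per ``group``.  Quantiles use linear interpolation between
    order statistics; the sd of a single-value group is reported as 0.
    With ``imputed_only`` the table is filtered to rows whose
    ``qc_pass`` is False (the imputed proteins) first.
    """
    df = tm_estimates
    if imputed_only:
        if "qc_pass" not in df.columns:
            raise ValueError("imputed_only requires a qc_pass column")
        df = df[~df["qc_pass"].astype(bool)]
    if df.empty:
        raise ValueError("no estimates to summarize")
    rows = []
    for name, sub in df.groupby(group, sort=True):
        v = sub[value].to_numpy(dtype=float)
        rows.append(
            {
                group: name,
                "n": v.size,
                "mean": float(np.mean(v)),
                "std": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                "min": float(np.min(v)),
                "25%": float(np.quantile(v, 0.25)),
                "50%": float(np.quantile(v, 0.50)),
                "75%": float(np.quantile(v, 0.75)),
                "max": float(np.max(v)),
            }
        )
    return pd.DataFrame(rows)


def _curve_panel(ax, data, posterior, key, mle_row, band_grid):
    band = posterior_curves(posterior, key, band_grid)
    sub = data[(data["run_name"] == key[0]) & (data["protein_id"] == key[1])]
    ax.fill_between(band.grid, band.lower, band.upper, alpha=0.3, label=f"{int(band.ci*100)}% band")
    ax.plot(band.grid, band.central, lw=1.5, label="posterior median")
    ax.scatter(sub["temperature"], sub["fold_change"], s=14, c="k", zorder=3, label="data")
    if mle_row is not None and mle_row["converged"]:
        f = melting_curve(L=mle_row["L"], a=mle_row["a"], b=mle_row["b"], T=band_grid)
        ax.plot(band_grid, f, "r:", lw=1.2, label="separate fit")
    ax.set_title(f"{key[0]} / {key[1]}", fontsize=8)
    ax.set_xlabel("T (°C)")
    ax.set_ylabel("fold change")


def diagnostics_bundle(
    data: pd.DataFrame,
    posterior: PosteriorDraws,
    mle_results: pd.DataFrame,
    outdir,
    ci: float = 0.94,
) -> dict:
    """Emit the validation report directory; returns paths of artifacts.

    Artifacts: ``curve_panels.png`` (lowest / middle / highest posterior
    Tm sd protein per run, with the separate fit overlaid where it
    converged), ``residual_vs_sd.png``, ``imputed_sd.png`` +
    ``imputed_sd.csv`` (posterior sd by imputation status, "imputed"
    meaning qc_pass is False), and ``tm_by_run.csv`` (per-run summary of
    posterior-mean Tm).
    """
    from .mle import compare_estimates

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary = posterior.tm_summary(ci=ci)
    mle_idx = mle_results.set_index(["run_name", "protein_id"])
    tgrid = np.linspace(
        max(data["temperature"].min() - 5, 1.0), data["temperature"].max() + 5, 100
    )

    # (i) curve panels: per run, proteins at min / median / max posterior sd
    runs = sorted(summary["run_name"].unique())
    fig, axes = plt.subplots(len(runs), 3, figsize=(10, 3 * len(runs)), squeeze=False)
    for i, run in enumerate(runs):
        sub = summary[summary["run_name"] == run].sort_values("tm_sd").reset_index(drop=True)
        picks = [0, len(sub) // 2, len(sub) - 1]
        for j, k in enumerate(picks):
            key = (run, sub.loc[k, "protein_id"])
            mle_row = mle_idx.loc[key] if key in mle_idx.index else None
            _curve_panel(axes[i][j], data, posterior, key, mle_row, tgrid)
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    paths["curve_panels"] = outdir / "curve_panels.png"
    fig.savefig(paths["curve_panels"], dpi=100)
    plt.close(fig)

    # (ii) residual vs posterior sd
    comp = compare_estimates(posterior, mle_results)
    fig, ax = plt.subplots(figsize=(5, 4))
    ok = comp.dropna(subset=["residual"])
    ax.scatter(ok["residual"], ok["tm_sd"], s=15)
    ax.axvline(0.0, color="gray", lw=0.8)
    ax.set_xlabel("posterior mean Tm − separate-fit Tm (°C)")
    ax.set_ylabel("posterior sd of Tm (°C)")
    fig.tight_layout()
    paths["residual_vs_sd"] = outdir / "residual_vs_sd.png"
    fig.savefig(paths["residual_vs_sd"], dpi=100)
    plt.close(fig)
    paths["comparison_csv"] = outdir / "bayes_vs_mle.csv"
    comp.to_csv(paths["comparison_csv"], index=False)

    # (iii) imputed vs measured posterior sd
    merged = summary.merge(
        mle_results[["run_name", "protein_id", "qc_pass"]], on=["run_name", "protein_id"],
        how="left",
    )
    merged["qc_pass"] = merged["qc_pass"].fillna(False).astype(bool)
    merged["imputed"] = ~merged["qc_pass"]
    groups = merged.groupby("imputed")["tm_sd"]
    sd_table = groups.agg(["count", "mean", "median"]).reset_index()
    paths["imputed_sd_csv"] = outdir / "imputed_sd.csv"
    sd_table.to_csv(paths["imputed_sd_csv"], index=False)
    fig, ax = plt.subplots(figsize=(4, 4))
    labels, vals = [], []
    for imput, sub in merged.groupby("imputed"):
        labels.append("imputed" if imput else "measured")
        vals.append(sub["tm_sd"].to_numpy())
    ax.boxplot(vals, tick_labels=labels)
    ax.set_ylabel("posterior sd of Tm (°C)")
    fig.tight_layout()
    paths["imputed_sd"] = outdir / "imputed_sd.png"
    fig.savefig(paths["imputed_sd"], dpi=100)
    plt.close(fig)

    # (iv) per-run summary of posterior-mean Tm
    paths["tm_by_run"] = outdir / "tm_by_run.csv"
    summarize_by_run(summary).to_csv(paths["tm_by_run"], index=False)
    paths["tm_summary"] = outdir / "tm_summary.csv"
    merged.to_csv(paths["tm_summary"], index=False)
    return paths
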