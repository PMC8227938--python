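"""Posterior decision framework for high-throughput screens.

Turns per-protein posterior Tm draws into principled rankings for three
recurring questions: which samples to re-measure (highest posterior
uncertainty), which to push to confirmatory assays (highest probability
of exceeding an a-priori threshold), and which to take as an engineering
baseline (highest probability of superiority over the rest).

All probabilities are computed on *paired* joint draws — the draws come
from one joint posterior, so pairing is the faithful Monte-Carlo
estimator.  Exact Tm ties count as ½, so P(i,j) + P(j,i) = 1 holds
exactly and P(i,i) = ½.  Ties in scores are broken by lexicographic
protein key so every report is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .posterior import PosteriorDraws

__all__ = [
    "DecisionReport",
    "rank_by_uncertainty",
    "prob_exceeds",
    "prob_superiority",
    "superiority_matrix_and_ranking",
]


@dataclass
class DecisionReport:
    """A ranked list of proteins with the score that produced the ranking."""

    criterion: str
    table: pd.DataFrame  # columns: run_name, protein_id, score (sorted), rank
    params: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _ranked(rows, criterion, params, posterior, ascending=False) -> DecisionReport:
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["score", "run_name", "protein_id"],
        ascending=[ascending, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    prov = {"n_draws": posterior.n_draws}
    prov.update({k: posterior.meta.get(k) for k in ("method", "seed") if k in posterior.meta})
    return DecisionReport(criterion=criterion, table=df, params=params, provenance=prov)


def rank_by_uncertainty(posterior: PosteriorDraws) -> DecisionReport:
    """Rank proteins by posterior Tm standard deviation, highest first.

    The top of the list is the next best candidate for re-measurement:
    its melting temperature is the least constrained by the data.
    """
    rows = [
        {
            "run_name": r,
            "protein_id": p,
            "score": float(np.std(posterior.tm_draws((r, p)), ddof=1)),
        }
        for r, p in posterior.proteins
    ]
    return _ranked(rows, "posterior_uncertainty", {}, posterior)


def prob_exceeds(posterior: PosteriorDraws, threshold: float) -> DecisionReport:
    """Rank proteins by P(Tm > threshold), highest first.

    The score equals 1 − (empirical CDF of the Tm draws at the
    threshold); draws exactly at the threshold do not count as exceeding
    it (right-continuous convention).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    rows = [
        {
            "run_name": r,
            "protein_id": p,
            "score": float(np.mean(posterior.tm_draws((r, p)) > threshold)),
        }
        for r, p in posterior.proteins
    ]
    return _ranked(rows, "prob_exceeds", {"threshold": float(threshold)}, posterior)


def prob_superiority(posterior: PosteriorDraws, i, j) -> float:
    """P(Tm_i > Tm_j) over paired joint draws, ties counted as ½."""
    ti = posterior.tm_draws(i)
    tj = posterior.tm_draws(j)
    if ti.size != tj.size:
        raise ValueError("draw vectors must have equal length")
    return float(np.mean((ti > tj) + 0.5 * (ti == tj)))


def superiority_matrix_and_ranking(
    posterior: PosteriorDraws, direction: str = "max"
) -> tuple[pd.DataFrame, DecisionReport]:
    """Full pairwise probability-of-superiority matrix and its ranking.

    The primary score per protein is its mean pairwise probability of
    superiority over all rivals (self excluded); ``p_best`` — the
    fraction of joint draws in which the protein attains the extreme Tm,
    with exact ties splitting the credit — is reported as a companion
    column.  ``direction="min"`` flips every comparison for objectives
    where smaller is better (low-IC50-style screens).
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    keys = list(posterior.proteins)
    if len(keys) < 2:
        raise ValueError("superiority ranking needs at least 2 proteins")
    tm = np.vstack([posterior.tm_draws(k) for k in keys])  # (P, n_draws)
    if direction == "min":
        tm = -tm
    P = len(keys)
    mat = np.full((P, P), 0.5)
    for i in range(P):
        for j in range(i + 1, P):
            pij = float(np.mean((tm[i] > tm[j]) + 0.5 * (tm[i] == tm[j])))
            mat[i, j] = pij
            mat[j, i] = 1.0 - pij

    # P(best): per-draw credit split among tied maxima
    best = np.zeros(P)
    col_max = tm.max(axis=0)
    is_max = tm == col_max[None, :]
    best = (is_max / is_max.sum(axis=0)[None, :]).mean(axis=1)

    labels = [f"{r}/{p}" for r, p in keys]
    mat_df = pd.DataFrame(mat, index=labels, columns=labels)
    mean_sup = (mat.sum(axis=1) - 0.5) / (P - 1)  # exclude the ½ diagonal
    rows = [
        {
            "run_name": r,
            "protein_id": p,
            "score": float(mean_sup[k]),
            "p_best": float(best[k]),
        }
        for k, (r, p) in enumerate(keys)
    ]
    report = _ranked(rows, "prob_superiority", {"direction": direction}, posterior)
    return mat_df, report
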