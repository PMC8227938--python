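"""Synthetic meltome-style data with known ground truth.

Samples the generative hierarchy forward: global curve locations
(a ≈ 500, b ≈ 10, so Tm ≈ 50 °C), per-run positive locations (a_r, b_r),
per-protein offsets (δ_a, δ_b) and plateaus L_p, then a single-replicate
fold-change observation per temperature with homoskedastic Gaussian noise
per protein.  A configurable fraction of proteins receive corrupted
("non-melter") curves while keeping a ground-truth Tm, so downstream
imputation accuracy can be scored.

Defaults are the standard benchmark conditions used throughout the test
suite: 2 runs × 20 proteins × 10 temperatures (37–67 °C), noise sd 0.05,
20% corrupted via within-protein scrambling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .curve import melting_curve

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate", "corrupt", "sample_plateau_rates"]

#: global hyperprior locations for the curve parameters
A_GLOBAL_MEAN, A_GLOBAL_SD = 500.0, 1.0
B_GLOBAL_MEAN, B_GLOBAL_SD = 10.0, 1.0
A_RUN_SD = 10.0
B_RUN_SD = 1.0
PLATEAU_RATE_PRIOR_MEAN = 30.0  # L_e ~ Exponential(mean 30); L_p ~ Exponential(rate L_e)


@dataclass
class SimulationConfig:
    """Conditions for one synthetic dataset.

    ``noise_sd`` is either a fold-change sd (shared by all clean proteins)
    or the string ``"sample-from-prior"`` to draw per-protein sds from the
    model's HalfCauchy(1) prior.  ``plateau_rate`` is the exponential rate
    for per-protein plateaus L_p; the string ``"sample"`` draws a per-run
    rate L_e from its own exponential hyperprior (mean 30), and ``None``
    pins every plateau to 0.  ``run_level_params`` optionally pins
    (a_r, b_r) per run instead of drawing them; ``delta_a_sd``/``delta_b_sd``
    of 0 pin the per-protein offsets to 0.
    """

    n_runs: int = 2
    proteins_per_run: int = 20
    temperature_grid: tuple = tuple(np.linspace(37.0, 67.0, 10).round(6))
    noise_sd: float | str = 0.05
    corrupt_fraction: float = 0.2
    corruption_mode: str = "scrambled"  # flat | scrambled | high-noise
    high_noise_factor: float = 5.0
    run_level_params: list[tuple[float, float]] | None = None
    delta_a_sd: float = 3.0
    delta_b_sd: float = 1.0
    plateau_rate: float | str | None = PLATEAU_RATE_PRIOR_MEAN
    clip_negative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.temperature_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("temperature_grid must be non-empty")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("temperature_grid must be strictly increasing and positive")
        if not 0.0 <= self.corrupt_fraction <= 1.0:
            raise ValueError("corrupt_fraction must lie in [0, 1]")
        if self.corruption_mode not in ("flat", "scrambled", "high-noise"):
            raise ValueError(f"unknown corruption_mode {self.corruption_mode!r}")
        if self.n_runs < 1 or self.proteins_per_run < 1:
            raise ValueError("n_runs and proteins_per_run must be positive")
        if self.run_level_params is not None and len(self.run_level_params) != self.n_runs:
            raise ValueError("run_level_params must give one (a_r, b_r) pair per run")


@dataclass
class SyntheticDataset:
    """A simulated measurement table plus its generating truth."""

    table: pd.DataFrame
    truth: pd.DataFrame  # one row per protein: run, id, a_r, b_r, deltas, L, sigma, tm, corrupted
    run_params: pd.DataFrame  # one row per run: a_r, b_r, plateau_rate
    corrupted_ids: list  # [(run_name, protein_id), ...]

    @property
    def clean_ids(self) -> list:
        mask = ~self.truth["corrupted"]
        return list(map(tuple, self.truth.loc[mask, ["run_name", "protein_id"]].itertuples(index=False)))


def sample_plateau_rates(n: int, rng: np.random.Generator, mean: float = PLATEAU_RATE_PRIOR_MEAN):
    """Draw plateau hyper-rates L_e from their exponential prior (mean 30)."""
    return rng.exponential(scale=mean, size=n)


def _draw_positive_normal(rng, loc, sd):
    # zero-truncated normal draw; loc/sd here make rejection essentially free
    while True:
        x = rng.normal(loc, sd)
        if x > 0:
            return x


def simulate(config: SimulationConfig | None = None, **kwargs) -> SyntheticDataset:
    """Sample one dataset from the generative hierarchy.

    Row count is exactly n_runs × proteins_per_run × len(temperature_grid);
    identical seeds give byte-identical tables.
    """
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimulationConfig or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.temperature_grid, dtype=float)

    a_l = rng.normal(A_GLOBAL_MEAN, A_GLOBAL_SD)
    b_l = rng.normal(B_GLOBAL_MEAN, B_GLOBAL_SD)

    run_rows, truth_rows, data_rows = [], [], []
    for r in range(config.n_runs):
        run_name = f"run{r:02d}"
        if config.run_level_params is not None:
            a_r, b_r = config.run_level_params[r]
        else:
            a_r = _draw_positive_normal(rng, a_l, A_RUN_SD)
            b_r = _draw_positive_normal(rng, b_l, B_RUN_SD)
        if config.plateau_rate == "sample":
            rate = float(sample_plateau_rates(1, rng)[0])
        else:
            rate = config.plateau_rate
        run_rows.append({"run_name": run_name, "a_r": a_r, "b_r": b_r, "plateau_rate": rate})

        for p in range(config.proteins_per_run):
            pid = f"P{p:03d}"
            da = rng.normal(0.0, config.delta_a_sd) if config.delta_a_sd > 0 else 0.0
            db = rng.normal(0.0, config.delta_b_sd) if config.delta_b_sd > 0 else 0.0
            if rate is None:
                L = 0.0
            else:
                L = rng.exponential(scale=1.0 / rate)
                while L >= 0.95:  # plateau of a fold-change curve; resample pathological tails
                    L = rng.exponential(scale=1.0 / rate)
            if config.noise_sd == "sample-from-prior":
                sigma = float(np.abs(stats.cauchy.rvs(scale=1.0, random_state=rng)))
            else:
                sigma = float(config.noise_sd)
            a_p, b_p = a_r + da, b_r + db
            y = np.asarray(melting_curve(L=L, a=a_p, b=b_p, T=grid))
            if sigma > 0:
                y = y + rng.normal(0.0, sigma, size=grid.size)
            if config.clip_negative:
                y = np.clip(y, 0.0, None)
            truth_rows.append(
                {
                    "run_name": run_name,
                    "protein_id": pid,
                    "a_r": a_r,
                    "b_r": b_r,
                    "delta_a": da,
                    "delta_b": db,
                    "a": a_p,
                    "b": b_p,
                    "L": L,
                    "sigma": sigma,
                    "tm": a_p / b_p,
                    "corrupted": False,
                }
            )
            for t, yy in zip(grid, y):
                data_rows.append(
                    {
                        "run_name": run_name,
                        "protein_id": pid,
                        "gene_name": f"g{r:02d}_{p:03d}",
                        "temperature": t,
                        "fold_change": yy,
                    }
                )

    table = pd.DataFrame(data_rows)
    truth = pd.DataFrame(truth_rows)
    run_params = pd.DataFrame(run_rows)

    corrupted_ids: list = []
    if config.corrupt_fraction > 0:
        n_corrupt = int(round(config.corrupt_fraction * config.proteins_per_run))
        for r in range(config.n_runs):
            run_name = f"run{r:02d}"
            picks = rng.choice(config.proteins_per_run, size=n_corrupt, replace=False)
            corrupted_ids.extend((run_name, f"P{p:03d}") for p in sorted(picks))
        sigma_map = {
            (t.run_name, t.protein_id): t.sigma for t in truth.itertuples(index=False)
        }
        base_sd = np.mean([sigma_map[k] for k in corrupted_ids]) if corrupted_ids else 0.0
        table = corrupt(
            table,
            corrupted_ids,
            config.corruption_mode,
            rng=rng,
            noise_sd=float(base_sd),
            factor=config.high_noise_factor,
            truth=truth,
        )
        mask = truth.set_index(["run_name", "protein_id"]).index.isin(corrupted_ids)
        truth.loc[mask, "corrupted"] = True

    return SyntheticDataset(table=table, truth=truth, run_params=run_params, corrupted_ids=corrupted_ids)


def corrupt(
    table: pd.DataFrame,
    ids,
    mode: str,
    *,
    rng: np.random.Generator | int | None = None,
    noise_sd: float = 0.05,
    factor: float = 5.0,
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Return a copy of ``table`` with the named proteins' curves corrupted.

    Modes: ``flat`` sets y to 1 plus noise (no melting signal); ``scrambled``
    permutes each protein's y values across temperatures; ``high-noise``
    re-draws observation noise at ``factor`` times the original sd (using
    the true curve when ``truth`` is supplied, otherwise adding the extra
    noise on top of the observed values).  Rows of other proteins are
    untouched.
    """
    if mode not in ("flat", "scrambled", "high-noise"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ids = [tuple(i) for i in ids]
    table = table.copy()
    keyed = table.set_index(["run_name", "protein_id"]).index
    known = set(keyed)
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise KeyError(f"unknown protein id(s): {unknown}")

    truth_idx = None
    if truth is not None:
        truth_idx = truth.set_index(["run_name", "protein_id"])
    for key in ids:
        sel = keyed == key
        n = int(sel.sum())
        if mode == "flat":
            table.loc[sel, "fold_change"] = 1.0 + rng.normal(0.0, noise_sd, size=n)
        elif mode == "scrambled":
            vals = table.loc[sel, "fold_change"].to_numpy()
            table.loc[sel, "fold_change"] = rng.permutation(vals)
        else:  # high-noise
            if truth_idx is not None and key in truth_idx.index:
                row = truth_idx.loc[key]
                T = table.loc[sel, "temperature"].to_numpy()
                f = np.asarray(melting_curve(L=row["L"], a=row["a"], b=row["b"], T=T))
                sd = factor * float(row["sigma"])
                table.loc[sel, "fold_change"] = f + rng.normal(0.0, sd, size=n)
            else:
                extra = noise_sd * np.sqrt(max(factor**2 - 1.0, 0.0))
                table.loc[sel, "fold_change"] += rng.normal(0.0, extra, size=n)
    return table
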