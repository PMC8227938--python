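"""Hierarchical Bayesian melting-curve estimator.

`HierarchicalMeltingModel` is a scikit-learn-style estimator: ``fit`` takes
a long-format measurement table (DataFrame) and produces ``posterior_``, a
:class:`~bayesmelt.posterior.PosteriorDraws` of the full joint model.
Inference is NUTS at desk scale and switches to ADVI above a configurable
observation-count threshold, mirroring the large-data motivation for
variational inference; either can be forced via ``method``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .infer import advi, nuts
from .io import validate_measurements
from .joint import HierarchicalJoint
from .posterior import PosteriorDraws

__all__ = ["HierarchicalMeltingModel", "fit_hierarchical"]


class HierarchicalMeltingModel(BaseEstimator):
    """Partial-pooling Bayesian model of high-throughput melting curves.

    Parameters
    ----------
    method : {"auto", "nuts", "advi"}
        Inference engine. "auto" uses NUTS below ``auto_advi_threshold``
        observations and ADVI above it.
    n_draws : int
        Posterior draws to return (default 2000).
    warmup : int
        NUTS warmup iterations.
    advi_steps : int
        ADVI optimization steps (default 200 000).
    advi_learning_rate : float
        Adam step size for ADVI.
    target_accept, max_treedepth : NUTS adaptation settings.
    plateau_rate_prior_mean : float
        Mean of the exponential hyperprior on the plateau rate L_e.
    per_run_plateau : bool
        One plateau hyper-rate per run (default) or a single global one.
    auto_advi_threshold : int
        Observation count above which "auto" switches to ADVI.
    random_state : int or None
        Seed for all randomness in the fit.

    Attributes
    ----------
    posterior_ : PosteriorDraws
        Joint draws in natural space.
    elbo_trace_ : ndarray of shape (k, 2)
        (step, smoothed ELBO) pairs; ADVI fits only.
    diagnostics_ : dict
        Divergence counts / acceptance rate (NUTS) or convergence info
        (ADVI), plus warnings raised during the fit.
    method_used_ : str
    """

    def __init__(
        self,
        method: str = "auto",
        n_draws: int = 2000,
        warmup: int = 1000,
        advi_steps: int = 200_000,
        advi_learning_rate: float = 0.01,
        target_accept: float = 0.8,
        max_treedepth: int = 10,
        plateau_rate_prior_mean: float = 30.0,
        per_run_plateau: bool = True,
        auto_advi_threshold: int = 5000,
        random_state: int | None = None,
    ):
        self.method = method
        self.n_draws = n_draws
        self.warmup = warmup
        self.advi_steps = advi_steps
        self.advi_learning_rate = advi_learning_rate
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.plateau_rate_prior_mean = plateau_rate_prior_mean
        self.per_run_plateau = per_run_plateau
        self.auto_advi_threshold = auto_advi_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalMeltingModel":
        """Fit the joint model to a long-format measurement table."""
        if X is None or len(X) == 0:
            raise ValueError("cannot fit on an empty measurement table")
        if self.method not in ("auto", "nuts", "advi"):
            raise ValueError(f"unknown method {self.method!r}")
        table = validate_measurements(X)
        joint = HierarchicalJoint(
            table,
            plateau_rate_prior_mean=self.plateau_rate_prior_mean,
            per_run_plateau=self.per_run_plateau,
        )
        rng = np.random.default_rng(self.random_state)
        z0 = joint.initial_point(rng)

        method = self.method
        if method == "auto":
            method = "advi" if joint.n_obs > self.auto_advi_threshold else "nuts"

        diagnostics: dict = {"n_obs": joint.n_obs, "n_proteins": joint.P, "n_runs": joint.R}
        if method == "nuts":
            res = nuts(
                joint.logp_grad,
                z0,
                n_warmup=self.warmup,
                n_draws=self.n_draws,
                rng=rng,
                target_accept=self.target_accept,
                max_treedepth=self.max_treedepth,
            )
            z_draws = res.draws
            diagnostics.update(
                n_divergent=res.n_divergent,
                accept_rate=res.accept_rate,
                step_size=res.step_size,
                mean_treedepth=res.mean_treedepth,
            )
            if res.n_divergent > 0:
                warnings.warn(f"{res.n_divergent} divergent transitions after warmup")
            self.elbo_trace_ = None
        else:
            res = advi(
                joint.logp_grad,
                z0,
                n_steps=self.advi_steps,
                n_draws=self.n_draws,
                rng=rng,
                learning_rate=self.advi_learning_rate,
            )
            z_draws = res.draws
            self.elbo_trace_ = res.elbo_trace
            diagnostics.update(
                final_elbo=float(res.elbo_trace[-1, 1]) if len(res.elbo_trace) else None
            )

        draws = pd.DataFrame(self._natural_matrix(joint, z_draws), columns=joint.param_names)

        # diagnostic: a_p, b_p are untruncated sums; flag the (practically
        # impossible) event of a non-positive draw
        neg = 0
        for run, pid in joint.proteins:
            a_p = draws[f"a_r[{run}]"].to_numpy() + draws[f"delta_a[{run}/{pid}]"].to_numpy()
            b_p = draws[f"b_r[{run}]"].to_numpy() + draws[f"delta_b[{run}/{pid}]"].to_numpy()
            neg += int(np.sum(a_p <= 0) + np.sum(b_p <= 0))
        if neg:
            warnings.warn(f"{neg} posterior draws give non-positive a_p or b_p")
        diagnostics["n_nonpositive_curve_draws"] = neg

        meta = {
            "method": method,
            "seed": self.random_state,
            "n_draws": self.n_draws,
            "warmup": self.warmup if method == "nuts" else None,
            "advi_steps": self.advi_steps if method == "advi" else None,
            "plateau_rate_prior_mean": self.plateau_rate_prior_mean,
            "per_run_plateau": self.per_run_plateau,
            "diagnostics": diagnostics,
        }
        if method == "advi":
            meta["elbo_trace"] = self.elbo_trace_
        self.posterior_ = PosteriorDraws(
            draws=draws, runs=joint.runs, proteins=joint.proteins, meta=meta
        )
        self.joint_ = joint
        self.method_used_ = method
        self.diagnostics_ = diagnostics
        return self

    @staticmethod
    def _natural_matrix(joint: HierarchicalJoint, z_draws: np.ndarray) -> np.ndarray:
        nat = z_draws.copy()
        for sl in (joint.sl_ar, joint.sl_br, joint.sl_le, joint.sl_lp, joint.sl_ls):
            nat[:, sl] = np.exp(nat[:, sl])
        return nat

    # ------------------------------------------------------------ conveniences

    def tm_draws(self, protein) -> np.ndarray:
        """Per-draw Tm for one protein (requires a fitted model)."""
        self._check_fitted()
        return self.posterior_.tm_draws(protein)

    def tm_summary(self, ci: float = 0.94) -> pd.DataFrame:
        self._check_fitted()
        return self.posterior_.tm_summary(ci=ci)

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise AttributeError("model is not fitted; call fit(table) first")


def fit_hierarchical(table: pd.DataFrame, **kwargs) -> PosteriorDraws:
    """Fit the hierarchical model and return its posterior draws."""
    return HierarchicalMeltingModel(**kwargs).fit(table).posterior_
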