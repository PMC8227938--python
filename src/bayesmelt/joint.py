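"""Joint log-density of the hierarchical melting-curve model.

The model partially pools melting curves across proteins within a run
(one organism × extraction method) and across runs globally:

    a_l ~ Normal(500, 1)                global location of the a scale
    b_l ~ Normal(10, 1)                 global location of the b offset
    a_r ~ Normal(a_l, 10) truncated > 0    per-run location
    b_r ~ Normal(b_l, 1)  truncated > 0    per-run location
    delta_a_p ~ Normal(0, 3)            per-protein shift, a_p = a_r + delta_a_p
    delta_b_p ~ Normal(0, 1)            per-protein shift, b_p = b_r + delta_b_p
    L_e ~ Exponential(mean 30)          per-run plateau hyper-rate
    L_p ~ Exponential(rate L_e)         per-protein lower plateau
    sigma_p ~ HalfCauchy(1)             per-protein homoskedastic noise sd
    y ~ Normal(f(L_p, a_p, b_p, T), sigma_p)

with f the sigmoid melting curve and Tm_p = a_p / b_p.  All second Normal
parameters are standard deviations.  The per-protein sums a_p, b_p are not
truncated: against locations near 500 and 10, negative draws are
practically impossible (a fit-time diagnostic warns if any occur).

Two evaluation paths are provided: :meth:`HierarchicalJoint.log_joint`
works on natural-space parameters (−inf outside the support), while
:meth:`HierarchicalJoint.logp_grad` evaluates the density plus
log-transform Jacobians on the unconstrained vector used by the samplers,
returning the analytic gradient.  The two paths are cross-checked in the
test suite, and the gradient against finite differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr

__all__ = ["HierarchicalJoint", "log_joint"]

HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)

# prior constants (shared with the synthetic generator)
A_GLOBAL_MEAN, A_GLOBAL_SD = 500.0, 1.0
B_GLOBAL_MEAN, B_GLOBAL_SD = 10.0, 1.0
A_RUN_SD = 10.0
B_RUN_SD = 1.0
DELTA_A_SD = 3.0
DELTA_B_SD = 1.0


def _norm_logpdf(x, loc, sd):
    return -HALF_LOG_2PI - np.log(sd) - 0.5 * ((x - loc) / sd) ** 2


class HierarchicalJoint:
    """Joint density of the hierarchical model bound to one dataset.

    Builds a deterministic (sorted) run/protein index from the measurement
    table so parameter columns are stable across fits of the same input.

    Parameters
    ----------
    table : DataFrame
        Validated long-format measurements.
    plateau_rate_prior_mean : float
        Mean of the exponential hyperprior on the plateau rate L_e
        (default 30, so plateaus average about 1/30).
    per_run_plateau : bool
        One plateau hyper-rate per run (default) or a single global one.
    """

    def __init__(self, table: pd.DataFrame, *, plateau_rate_prior_mean: float = 30.0,
                 per_run_plateau: bool = True):
        if table.empty:
            raise ValueError("cannot build a model from an empty table")
        self.plateau_rate_prior_mean = float(plateau_rate_prior_mean)
        self.per_run_plateau = bool(per_run_plateau)
        self._lam0 = 1.0 / self.plateau_rate_prior_mean

        self.runs = sorted(table["run_name"].unique().tolist())
        keys = table[["run_name", "protein_id"]].drop_duplicates()
        self.proteins = sorted(map(tuple, keys.itertuples(index=False)))
        self.R = len(self.runs)
        self.P = len(self.proteins)
        self.E = self.R if self.per_run_plateau else 1

        run_idx = {r: i for i, r in enumerate(self.runs)}
        prot_idx = {k: i for i, k in enumerate(self.proteins)}
        self.run_of_protein = np.array([run_idx[k[0]] for k in self.proteins], dtype=np.intp)
        self.le_of_protein = (
            self.run_of_protein if self.per_run_plateau else np.zeros(self.P, dtype=np.intp)
        )

        obs_keys = list(zip(table["run_name"], table["protein_id"]))
        self.pidx = np.array([prot_idx[k] for k in obs_keys], dtype=np.intp)
        self.y = table["fold_change"].to_numpy(dtype=float)
        self.T = table["temperature"].to_numpy(dtype=float)
        self.n_obs = self.y.size
        self.obs_count = np.bincount(self.pidx, minlength=self.P).astype(float)

        # unconstrained layout: a_l, b_l | log a_r | log b_r | log L_e |
        #                       delta_a | delta_b | log L_p | log sigma_p
        R, P, E = self.R, self.P, self.E
        off = 2
        self.sl_ar = slice(off, off + R); off += R
        self.sl_br = slice(off, off + R); off += R
        self.sl_le = slice(off, off + E); off += E
        self.sl_da = slice(off, off + P); off += P
        self.sl_db = slice(off, off + P); off += P
        self.sl_lp = slice(off, off + P); off += P
        self.sl_ls = slice(off, off + P); off += P
        self.n_params = off

    # ------------------------------------------------------------------ names

    @property
    def param_names(self) -> list[str]:
        names = ["a_l", "b_l"]
        names += [f"a_r[{r}]" for r in self.runs]
        names += [f"b_r[{r}]" for r in self.runs]
        if self.per_run_plateau:
            names += [f"L_e[{r}]" for r in self.runs]
        else:
            names += ["L_e"]
        for block in ("delta_a", "delta_b", "L_p", "sigma_p"):
            names += [f"{block}[{r}/{p}]" for r, p in self.proteins]
        return names

    # ------------------------------------------------------ natural-space path

    def unpack(self, z: np.ndarray) -> dict:
        """Map an unconstrained vector to natural-space parameter arrays."""
        return {
            "a_l": float(z[0]),
            "b_l": float(z[1]),
            "a_r": np.exp(z[self.sl_ar]),
            "b_r": np.exp(z[self.sl_br]),
            "L_e": np.exp(z[self.sl_le]),
            "delta_a": np.asarray(z[self.sl_da], dtype=float).copy(),
            "delta_b": np.asarray(z[self.sl_db], dtype=float).copy(),
            "L_p": np.exp(z[self.sl_lp]),
            "sigma_p": np.exp(z[self.sl_ls]),
        }

    def pack(self, params: dict) -> np.ndarray:
        """Inverse of :meth:`unpack` (natural → unconstrained)."""
        z = np.empty(self.n_params)
        z[0], z[1] = params["a_l"], params["b_l"]
        z[self.sl_ar] = np.log(params["a_r"])
        z[self.sl_br] = np.log(params["b_r"])
        z[self.sl_le] = np.log(params["L_e"])
        z[self.sl_da] = params["delta_a"]
        z[self.sl_db] = params["delta_b"]
        z[self.sl_lp] = np.log(params["L_p"])
        z[self.sl_ls] = np.log(params["sigma_p"])
        return z

    def log_joint(self, params: dict) -> float:
        """Natural-space joint log-density (priors + likelihood).

        Returns −inf for parameters outside the support (non-positive
        sigma_p, L_e, a_r or b_r, or negative L_p).
        """
        a_l, b_l = params["a_l"], params["b_l"]
        a_r = np.asarray(params["a_r"], dtype=float)
        b_r = np.asarray(params["b_r"], dtype=float)
        L_e = np.asarray(params["L_e"], dtype=float)
        da = np.asarray(params["delta_a"], dtype=float)
        db = np.asarray(params["delta_b"], dtype=float)
        L_p = np.asarray(params["L_p"], dtype=float)
        sig = np.asarray(params["sigma_p"], dtype=float)
        if (a_r.size, b_r.size, L_e.size) != (self.R, self.R, self.E):
            raise ValueError("run-level parameter arrays do not match the run index")
        if da.size != self.P or db.size != self.P or L_p.size != self.P or sig.size != self.P:
            raise ValueError("protein-level parameter arrays do not match the protein index")
        if (
            np.any(sig <= 0) or np.any(L_e <= 0) or np.any(L_p < 0)
            or np.any(a_r <= 0) or np.any(b_r <= 0)
        ):
            return -np.inf

        lp = _norm_logpdf(a_l, A_GLOBAL_MEAN, A_GLOBAL_SD)
        lp += _norm_logpdf(b_l, B_GLOBAL_MEAN, B_GLOBAL_SD)
        # zero-truncated normals, properly renormalized by Phi(loc/sd)
        lp += np.sum(_norm_logpdf(a_r, a_l, A_RUN_SD) - log_ndtr(a_l / A_RUN_SD))
        lp += np.sum(_norm_logpdf(b_r, b_l, B_RUN_SD) - log_ndtr(b_l / B_RUN_SD))
        lam0 = self._lam0
        lp += np.sum(np.log(lam0) - lam0 * L_e)
        le_p = L_e[self.le_of_protein]
        lp += np.sum(np.log(le_p) - le_p * L_p)
        lp += np.sum(_norm_logpdf(da, 0.0, DELTA_A_SD))
        lp += np.sum(_norm_logpdf(db, 0.0, DELTA_B_SD))
        lp += np.sum(np.log(2.0 / np.pi) - np.log1p(sig**2))

        a_p = a_r[self.run_of_protein] + da
        b_p = b_r[self.run_of_protein] + db
        g = expit(a_p[self.pidx] / self.T - b_p[self.pidx])
        f = L_p[self.pidx] + (1.0 - L_p[self.pidx]) * g
        sig_o = sig[self.pidx]
        e = self.y - f
        lp += np.sum(-HALF_LOG_2PI - np.log(sig_o) - 0.5 * (e / sig_o) ** 2)
        return float(lp)

    # -------------------------------------------------- unconstrained gradient

    def logp_grad(self, z: np.ndarray):
        """Unconstrained log-density (with Jacobians) and its gradient."""
        # extreme z during early warmup can overflow; the samplers treat a
        # non-finite density as a rejected point, so silence the warnings
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_grad(z)

    def _logp_grad(self, z: np.ndarray):
        a_l, b_l = z[0], z[1]
        a_r = np.exp(z[self.sl_ar])
        b_r = np.exp(z[self.sl_br])
        L_e = np.exp(z[self.sl_le])
        da = z[self.sl_da]
        db = z[self.sl_db]
        L_p = np.exp(z[self.sl_lp])
        sig = np.exp(z[self.sl_ls])
        rop, leop, pidx = self.run_of_protein, self.le_of_protein, self.pidx
        R, P, E = self.R, self.P, self.E
        lam0 = self._lam0

        a_p = a_r[rop] + da
        b_p = b_r[rop] + db
        g = expit(a_p[pidx] / self.T - b_p[pidx])
        Lo = L_p[pidx]
        f = Lo + (1.0 - Lo) * g
        sig_o = sig[pidx]
        e = self.y - f

        lp = _norm_logpdf(a_l, A_GLOBAL_MEAN, A_GLOBAL_SD)
        lp += _norm_logpdf(b_l, B_GLOBAL_MEAN, B_GLOBAL_SD)
        lp += np.sum(_norm_logpdf(a_r, a_l, A_RUN_SD) - log_ndtr(a_l / A_RUN_SD))
        lp += np.sum(_norm_logpdf(b_r, b_l, B_RUN_SD) - log_ndtr(b_l / B_RUN_SD))
        lp += np.sum(np.log(lam0) - lam0 * L_e)
        le_p = L_e[leop]
        lp += np.sum(np.log(le_p) - le_p * L_p)
        lp += np.sum(_norm_logpdf(da, 0.0, DELTA_A_SD))
        lp += np.sum(_norm_logpdf(db, 0.0, DELTA_B_SD))
        lp += np.sum(np.log(2.0 / np.pi) - np.log1p(sig**2))
        lp += np.sum(-HALF_LOG_2PI - np.log(sig_o) - 0.5 * (e / sig_o) ** 2)
        # log-transform Jacobians
        lp += z[self.sl_ar].sum() + z[self.sl_br].sum() + z[self.sl_le].sum()
        lp += z[self.sl_lp].sum() + z[self.sl_ls].sum()

        grad = np.zeros_like(z)

        # likelihood partials
        w = e / sig_o**2                      # d loglik / d f * (-1)... sign: d/d f = e/sig^2
        gg = g * (1.0 - g)
        d_ap = w * (1.0 - Lo) * gg / self.T    # d loglik / d a_p, per observation
        d_bp = -w * (1.0 - Lo) * gg
        d_Lp = w * (1.0 - g)
        glik_ap = np.bincount(pidx, weights=d_ap, minlength=P)
        glik_bp = np.bincount(pidx, weights=d_bp, minlength=P)
        glik_Lp = np.bincount(pidx, weights=d_Lp, minlength=P)
        glik_sig = np.bincount(pidx, weights=e**2, minlength=P) / sig**3 - self.obs_count / sig

        # a_l, b_l: own prior + run-level priors (incl. truncation normalizer)
        ratio_a = np.exp(_norm_logpdf(a_l / A_RUN_SD, 0.0, 1.0) - log_ndtr(a_l / A_RUN_SD))
        ratio_b = np.exp(_norm_logpdf(b_l / B_RUN_SD, 0.0, 1.0) - log_ndtr(b_l / B_RUN_SD))
        grad[0] = (
            -(a_l - A_GLOBAL_MEAN) / A_GLOBAL_SD**2
            + np.sum(a_r - a_l) / A_RUN_SD**2
            - R * ratio_a / A_RUN_SD
        )
        grad[1] = (
            -(b_l - B_GLOBAL_MEAN) / B_GLOBAL_SD**2
            + np.sum(b_r - b_l) / B_RUN_SD**2
            - R * ratio_b / B_RUN_SD
        )

        d_ar = -(a_r - a_l) / A_RUN_SD**2 + np.bincount(rop, weights=glik_ap, minlength=R)
        grad[self.sl_ar] = a_r * d_ar + 1.0
        d_br = -(b_r - b_l) / B_RUN_SD**2 + np.bincount(rop, weights=glik_bp, minlength=R)
        grad[self.sl_br] = b_r * d_br + 1.0

        nprot = np.bincount(leop, minlength=E).astype(float)
        sum_Lp = np.bincount(leop, weights=L_p, minlength=E)
        d_le = -lam0 + nprot / L_e - sum_Lp
        grad[self.sl_le] = L_e * d_le + 1.0

        grad[self.sl_da] = -da / DELTA_A_SD**2 + glik_ap
        grad[self.sl_db] = -db / DELTA_B_SD**2 + glik_bp

        d_lp = -L_e[leop] + glik_Lp
        grad[self.sl_lp] = L_p * d_lp + 1.0

        d_sig = -2.0 * sig / (1.0 + sig**2) + glik_sig
        grad[self.sl_ls] = sig * d_sig + 1.0

        return float(lp), grad

    # ------------------------------------------------------------ initial point

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.01) -> np.ndarray:
        """Data-informed starting vector in unconstrained space.

        Curve locations start at the hyperprior means; per-protein noise
        starts at a rough detrended scale of the protein's observations.
        """
        z = np.empty(self.n_params)
        z[0] = A_GLOBAL_MEAN
        z[1] = B_GLOBAL_MEAN
        z[self.sl_ar] = np.log(A_GLOBAL_MEAN)
        z[self.sl_br] = np.log(B_GLOBAL_MEAN)
        z[self.sl_le] = np.log(self.plateau_rate_prior_mean)
        z[self.sl_da] = 0.0
        z[self.sl_db] = 0.0
        z[self.sl_lp] = np.log(0.05)
        # successive differences remove the sigmoid trend to first order
        sig0 = np.full(self.P, 0.1)
        for p in range(self.P):
            yy = self.y[self.pidx == p]
            if yy.size >= 3:
                s = np.std(np.diff(yy)) / np.sqrt(2.0)
                sig0[p] = np.clip(s, 0.02, 1.0)
        z[self.sl_ls] = np.log(sig0)
        return z + jitter * rng.standard_normal(self.n_params)


def log_joint(params: dict, table: pd.DataFrame, **kwargs) -> float:
    """Natural-space joint log-density of the model on ``table``.

    Thin functional wrapper over :class:`HierarchicalJoint`; see its
    docstring for the parameter-array layout.
    """
    return HierarchicalJoint(table, **kwargs).log_joint(params)
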