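"""Gradient-based inference engines: NUTS and mean-field ADVI.

Both operate on an unconstrained log-density ``logp_grad(z) -> (lp, grad)``
such as :meth:`bayesmelt.joint.HierarchicalJoint.logp_grad`.

``nuts`` is the No-U-Turn Sampler with dual-averaging step-size adaptation
(target acceptance 0.8) and a diagonal mass matrix estimated midway
through warmup.  ``advi`` is automatic-differentiation variational
inference with a fully factorized Gaussian in the unconstrained space,
optimized by Adam with single-sample reparameterization gradients; it is
the scalable default for large tables but is known to under-estimate
posterior variance relative to MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitError", "nuts", "advi", "NutsResult", "AdviResult"]

_DELTA_MAX = 1000.0  # divergence threshold on the Hamiltonian error


class FitError(RuntimeError):
    """Inference failed (non-finite objective / divergent trajectories).

    Carries whatever objective trace was accumulated up to the failure in
    ``trace`` so convergence can still be inspected.
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = np.asarray(trace) if trace is not None else None


@dataclass
class NutsResult:
    draws: np.ndarray               # (n_draws, dim), unconstrained space
    n_divergent: int
    accept_rate: float
    step_size: float
    mean_treedepth: float
    inv_mass: np.ndarray


@dataclass
class AdviResult:
    draws: np.ndarray               # (n_draws, dim), unconstrained space
    mu: np.ndarray
    omega: np.ndarray               # log posterior sd of q
    elbo_trace: np.ndarray          # (n_recorded, 2): step, smoothed ELBO
    converged: bool = True


# ----------------------------------------------------------------------- NUTS


def _hamiltonian(lp, r, inv_mass) -> float:
    with np.errstate(over="ignore", invalid="ignore"):
        h = lp - 0.5 * float(np.sum(inv_mass * r**2))
    return h if np.isfinite(h) else -np.inf


def _find_reasonable_step_size(logp_grad, z, rng, inv_mass):
    lp0, g0 = logp_grad(z)
    eps = 1.0
    r = rng.standard_normal(z.size) / np.sqrt(inv_mass)
    h0 = _hamiltonian(lp0, r, inv_mass)
    z1, r1, lp1, _ = _leapfrog(logp_grad, z, r, g0, eps, inv_mass)
    h1 = _hamiltonian(lp1, r1, inv_mass)
    a = 1.0 if h1 - h0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**a
        z1, r1, lp1, _ = _leapfrog(logp_grad, z, r, g0, eps, inv_mass)
        h1 = _hamiltonian(lp1, r1, inv_mass)
        if a * (h1 - h0) <= a * np.log(0.5):
            break
    return eps


def _leapfrog(logp_grad, z, r, grad, eps, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        r_half = r + 0.5 * eps * grad
        z_new = z + eps * inv_mass * r_half
        lp_new, grad_new = logp_grad(z_new)
        if not np.isfinite(lp_new) or not np.all(np.isfinite(grad_new)):
            lp_new = -np.inf
            grad_new = np.zeros_like(grad)
        r_new = r_half + 0.5 * eps * grad_new
    return z_new, r_new, lp_new, grad_new


def _no_uturn(z_minus, z_plus, r_minus, r_plus, inv_mass):
    dz = z_plus - z_minus
    return (dz @ (inv_mass * r_minus) >= 0) and (dz @ (inv_mass * r_plus) >= 0)


def _build_tree(logp_grad, z, r, grad, log_u, v, j, eps, h0, inv_mass, rng):
    """Recursively double the trajectory (slice-sampling NUTS variant)."""
    if j == 0:
        z1, r1, lp1, g1 = _leapfrog(logp_grad, z, r, grad, v * eps, inv_mass)
        h1 = _hamiltonian(lp1, r1, inv_mass)
        n1 = int(log_u <= h1)
        diverged = log_u >= h1 + _DELTA_MAX
        s1 = int(not diverged)
        alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0))))
        return z1, r1, g1, z1, r1, g1, z1, n1, s1, alpha, 1, diverged
    (zm, rm, gm, zp, rp, gp, zprop, n1, s1, alpha, nalpha, div) = _build_tree(
        logp_grad, z, r, grad, log_u, v, j - 1, eps, h0, inv_mass, rng
    )
    if s1 == 1:
        if v == -1:
            zm, rm, gm, _, _, _, zprop2, n2, s2, a2, na2, div2 = _build_tree(
                logp_grad, zm, rm, gm, log_u, v, j - 1, eps, h0, inv_mass, rng
            )
        else:
            _, _, _, zp, rp, gp, zprop2, n2, s2, a2, na2, div2 = _build_tree(
                logp_grad, zp, rp, gp, log_u, v, j - 1, eps, h0, inv_mass, rng
            )
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            zprop = zprop2
        alpha += a2
        nalpha += na2
        s1 = s2 * int(_no_uturn(zm, zp, rm, rp, inv_mass))
        n1 += n2
        div = div or div2
    return zm, rm, gm, zp, rp, gp, zprop, n1, s1, alpha, nalpha, div


def nuts(
    logp_grad,
    z0: np.ndarray,
    *,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> NutsResult:
    """Sample with the No-U-Turn Sampler.

    Dual averaging adapts the step size toward ``target_accept`` during
    warmup; the diagonal mass matrix is set from the warmup draws halfway
    through, after which step-size adaptation restarts.
    """
    z = np.asarray(z0, dtype=float).copy()
    dim = z.size
    lp, grad = logp_grad(z)
    if not np.isfinite(lp):
        raise FitError("non-finite log-density at the initial point")
    inv_mass = np.ones(dim)

    eps = _find_reasonable_step_size(logp_grad, z, rng, inv_mass)
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    mass_window_start = max(n_warmup // 4, 1)
    mass_update_at = max(n_warmup // 2, 2)
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    n_divergent = 0
    accept_sum, accept_n = 0.0, 0
    depth_sum = 0
    da_iter = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        r = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = _hamiltonian(lp, r, inv_mass)
        log_u = h0 - rng.exponential(1.0)
        zm = zp = z
        rm = rp = r
        gm = gp = grad
        zprop = z
        n, s, j = 1, 1, 0
        alpha, nalpha = 0.0, 1
        diverged = False
        while s == 1 and j < max_treedepth:
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                zm, rm, gm, _, _, _, zprop2, n2, s2, a2, na2, div2 = _build_tree(
                    logp_grad, zm, rm, gm, log_u, v, j, eps, h0, inv_mass, rng
                )
            else:
                _, _, _, zp, rp, gp, zprop2, n2, s2, a2, na2, div2 = _build_tree(
                    logp_grad, zp, rp, gp, log_u, v, j, eps, h0, inv_mass, rng
                )
            if s2 == 1 and rng.random() < min(1.0, n2 / max(n, 1)):
                zprop = zprop2
            n += n2
            s = s2 * int(_no_uturn(zm, zp, rm, rp, inv_mass))
            alpha, nalpha = a2, na2
            diverged = diverged or div2
            j += 1

        if not np.array_equal(zprop, z):
            z = zprop
            lp, grad = logp_grad(z)

        accept_prob = alpha / max(nalpha, 1)
        if warming:
            da_iter += 1
            frac = 1.0 / (da_iter + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu_da - np.sqrt(da_iter) / gamma * h_bar
            eta = da_iter ** (-kappa)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if mass_window_start <= it < mass_update_at:
                window.append(z.copy())
            if it == mass_update_at and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                n_w = len(window)
                inv_mass = (n_w / (n_w + 5.0)) * var + 1e-3 * (5.0 / (n_w + 5.0))
                inv_mass = np.clip(inv_mass, 1e-10, None)
                eps = _find_reasonable_step_size(logp_grad, z, rng, inv_mass)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = z
            if diverged:
                n_divergent += 1
            accept_sum += accept_prob
            accept_n += 1
            depth_sum += j

    return NutsResult(
        draws=draws,
        n_divergent=n_divergent,
        accept_rate=accept_sum / max(accept_n, 1),
        step_size=eps,
        mean_treedepth=depth_sum / max(accept_n, 1),
        inv_mass=inv_mass,
    )


# ----------------------------------------------------------------------- ADVI


def advi(
    logp_grad,
    z0: np.ndarray,
    *,
    n_steps: int = 200_000,
    n_draws: int = 2000,
    rng: np.random.Generator,
    learning_rate: float = 0.01,
    omega0: float = -2.0,
    trace_every: int = 200,
) -> AdviResult:
    """Mean-field ADVI with Adam and single-sample reparameterization.

    The variational family is N(mu, diag(exp(omega))^2) in unconstrained
    space.  The recorded ELBO trace (exponentially smoothed) is the
    convergence diagnostic to inspect.  Raises :class:`FitError` if the
    objective stays non-finite.
    """
    mu = np.asarray(z0, dtype=float).copy()
    dim = mu.size
    omega = np.full(dim, float(omega0))

    m_mu = np.zeros(dim); v_mu = np.zeros(dim)
    m_om = np.zeros(dim); v_om = np.zeros(dim)
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8

    trace = []
    smoothed = None
    bad_streak = 0
    t_adam = 0

    for step in range(n_steps):
        epsilon = rng.standard_normal(dim)
        sd = np.exp(omega)
        zs = mu + sd * epsilon
        lp, g = logp_grad(zs)
        if not np.isfinite(lp) or not np.all(np.isfinite(g)):
            bad_streak += 1
            if bad_streak > 100:
                raise FitError(
                    "ADVI objective non-finite for 100 consecutive steps",
                    trace=np.asarray(trace) if trace else None,
                )
            continue
        bad_streak = 0
        # ELBO = E[logp] + entropy; entropy = sum(omega) + const
        elbo = lp + np.sum(omega)
        g_mu = g
        g_om = g * sd * epsilon + 1.0

        t_adam += 1
        m_mu = beta1 * m_mu + (1 - beta1) * g_mu
        v_mu = beta2 * v_mu + (1 - beta2) * g_mu**2
        m_om = beta1 * m_om + (1 - beta1) * g_om
        v_om = beta2 * v_om + (1 - beta2) * g_om**2
        bc1 = 1 - beta1**t_adam
        bc2 = 1 - beta2**t_adam
        mu = mu + learning_rate * (m_mu / bc1) / (np.sqrt(v_mu / bc2) + eps_adam)
        omega = omega + learning_rate * (m_om / bc1) / (np.sqrt(v_om / bc2) + eps_adam)

        smoothed = elbo if smoothed is None else 0.99 * smoothed + 0.01 * elbo
        if step % trace_every == 0:
            trace.append((step, smoothed))

    trace = np.asarray(trace) if trace else np.empty((0, 2))
    sd = np.exp(omega)
    draws = mu + sd * rng.standard_normal((n_draws, dim))
    return AdviResult(draws=draws, mu=mu, omega=omega, elbo_trace=trace)
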