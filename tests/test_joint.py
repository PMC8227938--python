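"""Joint log-density: term-by-term oracle, support, additivity, gradients.

The oracle sums textbook closed-form log-pdfs via scipy.stats for every
node of the hierarchy on a fixed 2-protein toy instance, completely
independently of the packed/vectorized implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bayesmelt import HierarchicalJoint, log_joint, melting_curve


def toy_table():
    rows = []
    for pid, curve in [("p1", (0.05, 495.0, 9.8)), ("p2", (0.10, 505.0, 10.3))]:
        L, a, b = curve
        for T in (40.0, 50.0, 60.0):
            rows.append(
                {
                    "run_name": "r1",
                    "protein_id": pid,
                    "gene_name": "",
                    "temperature": T,
                    "fold_change": melting_curve(L=L, a=a, b=b, T=T) + 0.01,
                }
            )
    return pd.DataFrame(rows)


def toy_params():
    return {
        "a_l": 499.0,
        "b_l": 10.2,
        "a_r": np.array([497.0]),
        "b_r": np.array([9.9]),
        "L_e": np.array([25.0]),
        "delta_a": np.array([-2.0, 8.0]),   # ordered by sorted protein key: p1, p2
        "delta_b": np.array([-0.1, 0.4]),
        "L_p": np.array([0.05, 0.10]),
        "sigma_p": np.array([0.05, 0.08]),
    }


def oracle_log_joint(params, table, rate_mean=30.0):
    """Independent term-by-term summation with scipy.stats closed forms."""
    p = params
    lp = stats.norm.logpdf(p["a_l"], 500.0, 1.0)
    lp += stats.norm.logpdf(p["b_l"], 10.0, 1.0)
    # zero-truncated normals
    lp += stats.truncnorm.logpdf(
        p["a_r"][0], a=(0.0 - p["a_l"]) / 10.0, b=np.inf, loc=p["a_l"], scale=10.0
    )
    lp += stats.truncnorm.logpdf(
        p["b_r"][0], a=(0.0 - p["b_l"]) / 1.0, b=np.inf, loc=p["b_l"], scale=1.0
    )
    lp += stats.expon.logpdf(p["L_e"][0], scale=rate_mean)
    for k in range(2):
        lp += stats.expon.logpdf(p["L_p"][k], scale=1.0 / p["L_e"][0])
        lp += stats.norm.logpdf(p["delta_a"][k], 0.0, 3.0)
        lp += stats.norm.logpdf(p["delta_b"][k], 0.0, 1.0)
        lp += stats.halfcauchy.logpdf(p["sigma_p"][k], scale=1.0)
    for pid, k in (("p1", 0), ("p2", 1)):
        sub = table[table["protein_id"] == pid]
        a_p = p["a_r"][0] + p["delta_a"][k]
        b_p = p["b_r"][0] + p["delta_b"][k]
        f = melting_curve(L=p["L_p"][k], a=a_p, b=b_p, T=sub["temperature"].to_numpy())
        lp += stats.norm.logpdf(sub["fold_change"].to_numpy(), f, p["sigma_p"][k]).sum()
    return float(lp)


def test_log_joint_matches_term_by_term_oracle():
    table = toy_table()
    params = toy_params()
    ours = log_joint(params, table)
    theirs = oracle_log_joint(params, table)
    assert ours == pytest.approx(theirs, abs=1e-8)


def test_out_of_support_gives_minus_inf():
    table = toy_table()
    for key, bad in [
        ("sigma_p", np.array([0.05, -0.1])),
        ("sigma_p", np.array([0.0, 0.08])),
        ("L_e", np.array([-1.0])),
        ("a_r", np.array([-5.0])),
        ("b_r", np.array([0.0])),
        ("L_p", np.array([-0.01, 0.1])),
    ]:
        params = toy_params()
        params[key] = bad
        assert log_joint(params, table) == -np.inf


def _likelihood_only(params, table):
    p = params
    lik = 0.0
    for pid, k in (("p1", 0), ("p2", 1)):
        sub = table[table["protein_id"] == pid]
        a_p = p["a_r"][0] + p["delta_a"][k]
        b_p = p["b_r"][0] + p["delta_b"][k]
        f = melting_curve(L=p["L_p"][k], a=a_p, b=b_p, T=sub["temperature"].to_numpy())
        lik += stats.norm.logpdf(sub["fold_change"].to_numpy(), f, p["sigma_p"][k]).sum()
    return float(lik)


def test_likelihood_doubles_when_data_doubles():
    # concatenating the dataset with itself adds exactly one likelihood
    # copy while the prior terms are unchanged
    table = toy_table()
    params = toy_params()
    shifted = table.copy()
    shifted["temperature"] += 0.001  # keep (run, protein, T) keys unique
    doubled = pd.concat([table, shifted], ignore_index=True)
    lp1 = log_joint(params, table)
    lp2 = log_joint(params, doubled)
    lik_shifted = _likelihood_only(params, shifted)
    assert lp2 - lp1 == pytest.approx(lik_shifted, abs=1e-8)


def test_structural_error_on_mismatched_indexing():
    table = toy_table()
    params = toy_params()
    params["delta_a"] = np.array([1.0])  # wrong length
    with pytest.raises(ValueError):
        log_joint(params, table)


def test_unconstrained_logp_equals_natural_plus_jacobian():
    j = HierarchicalJoint(toy_table())
    rng = np.random.default_rng(0)
    for _ in range(5):
        z = j.initial_point(rng, jitter=0.3)
        lp, _ = j.logp_grad(z)
        nat = j.log_joint(j.unpack(z))
        jac = sum(z[sl].sum() for sl in (j.sl_ar, j.sl_br, j.sl_le, j.sl_lp, j.sl_ls))
        assert lp == pytest.approx(nat + jac, abs=1e-9)


def test_gradient_matches_finite_differences():
    from bayesmelt import SimulationConfig, simulate

    ds = simulate(SimulationConfig(n_runs=2, proteins_per_run=4, seed=0))
    j = HierarchicalJoint(ds.table)
    rng = np.random.default_rng(1)
    z = j.initial_point(rng, jitter=0.2)
    _, g = j.logp_grad(z)
    eps = 1e-6
    for i in rng.choice(j.n_params, size=30, replace=False):
        zp, zm = z.copy(), z.copy()
        zp[i] += eps
        zm[i] -= eps
        fd = (j.logp_grad(zp)[0] - j.logp_grad(zm)[0]) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_pack_unpack_round_trip():
    j = HierarchicalJoint(toy_table())
    z = j.initial_point(np.random.default_rng(2), jitter=0.1)
    np.testing.assert_allclose(j.pack(j.unpack(z)), z, rtol=1e-12)


def test_empty_table_rejected():
    with pytest.raises(ValueError):
        HierarchicalJoint(pd.DataFrame(columns=["run_name", "protein_id", "temperature", "fold_change"]))


def test_global_plateau_mode_has_single_rate():
    from bayesmelt import SimulationConfig, simulate

    ds = simulate(SimulationConfig(n_runs=2, proteins_per_run=3, seed=0))
    per_run = HierarchicalJoint(ds.table, per_run_plateau=True)
    global_ = HierarchicalJoint(ds.table, per_run_plateau=False)
    assert per_run.E == 2 and global_.E == 1
    assert per_run.n_params == global_.n_params + 1
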