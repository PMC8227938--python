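"""Posterior curve bands, per-run summaries, diagnostics bundle."""

import numpy as np
import pandas as pd
import pytest

from bayesmelt import (
    PosteriorDraws,
    melting_curve,
    posterior_curves,
    summarize_by_run,
)


def posterior_from(a, b, L, run="r", pid="p"):
    a = np.asarray(a, float)
    draws = pd.DataFrame(
        {
            f"a_r[{run}]": a,
            f"b_r[{run}]": np.asarray(b, float),
            f"delta_a[{run}/{pid}]": np.zeros_like(a),
            f"delta_b[{run}/{pid}]": np.zeros_like(a),
            f"L_p[{run}/{pid}]": np.asarray(L, float),
        }
    )
    return PosteriorDraws(draws=draws, runs=[run], proteins=[(run, pid)])


class TestPosteriorCurves:
    def test_single_draw_band_collapses(self):
        post = posterior_from([500.0], [10.0], [0.05])
        band = posterior_curves(post, ("r", "p"), np.linspace(37, 67, 5))
        np.testing.assert_allclose(band.lower, band.upper)
        np.testing.assert_allclose(band.central, band.curves[0])

    def test_constant_draws_zero_width(self):
        post = posterior_from([500.0] * 4, [10.0] * 4, [0.0] * 4)
        band = posterior_curves(post, ("r", "p"), np.linspace(37, 67, 7))
        assert np.all(band.upper - band.lower == 0)

    def test_band_equals_direct_quantiles_of_evaluated_curves(self):
        rng = np.random.default_rng(0)
        n = 100
        a = rng.normal(500, 10, n)
        b = rng.normal(10, 0.5, n)
        L = rng.uniform(0, 0.1, n)
        post = posterior_from(a, b, L)
        grid = np.linspace(37, 67, 9)
        band = posterior_curves(post, ("r", "p"), grid, ci=0.94)
        # independent recomputation: evaluate each draw then take quantiles
        curves = np.array(
            [melting_curve(L=L[d], a=a[d], b=b[d], T=grid) for d in range(n)]
        )
        np.testing.assert_allclose(band.lower, np.quantile(curves, 0.03, axis=0), atol=1e-12)
        np.testing.assert_allclose(band.upper, np.quantile(curves, 0.97, axis=0), atol=1e-12)
        np.testing.assert_allclose(band.central, np.quantile(curves, 0.5, axis=0), atol=1e-12)

    def test_band_ordering_invariant(self):
        rng = np.random.default_rng(1)
        post = posterior_from(rng.normal(500, 20, 50), rng.normal(10, 1, 50),
                              rng.uniform(0, 0.2, 50))
        band = posterior_curves(post, ("r", "p"), np.linspace(37, 67, 11))
        assert np.all(band.lower <= band.central + 1e-12)
        assert np.all(band.central <= band.upper + 1e-12)

    def test_drawwise_band_differs_from_mean_parameter_curve(self):
        # Jensen counterexample: skewed b draws bend the mean curve away
        # from the curve at the parameter means
        b = np.concatenate([np.full(50, 8.0), np.full(10, 16.0)])
        a = np.full(60, 500.0)
        post = posterior_from(a, b, np.zeros(60))
        grid = np.array([45.0])
        band = posterior_curves(post, ("r", "p"), grid)
        mean_curve = band.curves.mean(axis=0)[0]
        curve_at_means = melting_curve(L=0.0, a=500.0, b=b.mean(), T=45.0)
        assert abs(mean_curve - curve_at_means) > 0.01

    def test_bad_grid_errors(self):
        post = posterior_from([500.0], [10.0], [0.0])
        with pytest.raises(ValueError):
            posterior_curves(post, ("r", "p"), [])
        with pytest.raises(ValueError):
            posterior_curves(post, ("r", "p"), [-5.0, 40.0])
        with pytest.raises(KeyError):
            posterior_curves(post, ("r", "nope"), [40.0])


class TestSummarizeByRun:
    def test_three_value_run(self):
        df = pd.DataFrame({"run_name": ["r"] * 3, "tm_mean": [40.0, 50.0, 60.0]})
        s = summarize_by_run(df).iloc[0]
        assert s["mean"] == 50.0 and s["50%"] == 50.0
        assert s["min"] == 40.0 and s["max"] == 60.0

    def test_quartiles_match_hand_order_statistics(self):
        # 7 sorted values: with linear interpolation the quartiles are the
        # 2.5th, 4th and 5.5th order statistics
        vals = [40.0, 42.0, 44.0, 47.0, 51.0, 56.0, 62.0]
        df = pd.DataFrame({"run_name": "r", "tm_mean": vals})
        s = summarize_by_run(df).iloc[0]
        assert s["25%"] == pytest.approx((42.0 + 44.0) / 2)
        assert s["50%"] == pytest.approx(47.0)
        assert s["75%"] == pytest.approx((51.0 + 56.0) / 2)

    def test_single_protein_run_sd_zero(self):
        df = pd.DataFrame({"run_name": ["r"], "tm_mean": [50.0]})
        assert summarize_by_run(df).iloc[0]["std"] == 0.0

    def test_imputed_only_filter(self):
        df = pd.DataFrame(
            {
                "run_name": ["r"] * 4,
                "tm_mean": [40.0, 50.0, 60.0, 70.0],
                "qc_pass": [True, False, True, False],
            }
        )
        s = summarize_by_run(df, imputed_only=True).iloc[0]
        assert s["n"] == 2 and s["mean"] == 60.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_by_run(pd.DataFrame({"run_name": [], "tm_mean": []}))


class TestDiagnosticsBundle:
    def test_bundle_emits_all_artifacts(self, benchmark_dataset, nuts_fit, mle_fit, tmp_path):
        from bayesmelt import diagnostics_bundle

        paths = diagnostics_bundle(
            benchmark_dataset.table, nuts_fit.posterior_, mle_fit.results_, tmp_path
        )
        for name in ("curve_panels", "residual_vs_sd", "imputed_sd", "imputed_sd_csv", "tm_by_run"):
            assert paths[name].exists() and paths[name].stat().st_size > 0, name
        sd_table = pd.read_csv(paths["imputed_sd_csv"])
        if set(sd_table["imputed"]) == {True, False}:
            by = sd_table.set_index("imputed")["mean"]
            assert by[True] > by[False]

    def test_bundle_degenerates_gracefully_without_corruption(self, tmp_path, tiny_table):
        from bayesmelt import HierarchicalMeltingModel, SeparateCurveFit, diagnostics_bundle

        m = HierarchicalMeltingModel(method="nuts", warmup=150, n_draws=100,
                                     random_state=0).fit(tiny_table)
        mle = SeparateCurveFit().fit(tiny_table)
        paths = diagnostics_bundle(tiny_table, m.posterior_, mle.results_, tmp_path)
        sd_table = pd.read_csv(paths["imputed_sd_csv"])
        assert len(sd_table) >= 1  # single group, still reported
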