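"""Decision operators against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesmelt import (
    PosteriorDraws,
    prob_exceeds,
    prob_superiority,
    rank_by_uncertainty,
    superiority_matrix_and_ranking,
)


def hand_posterior(seed=0, n_proteins=5, n_draws=200):
    rng = np.random.default_rng(seed)
    arrays = {
        f"P{i}": rng.normal(45.0 + 3 * i, 0.5 + 0.8 * i, n_draws) for i in range(n_proteins)
    }
    return arrays, PosteriorDraws.from_arrays(arrays)


# ------------------------------------------------------- brute-force oracles


def brute_prob_superiority(x, y):
    wins = 0.0
    for xi, yi in zip(x, y):  # paired joint draws
        if xi > yi:
            wins += 1.0
        elif xi == yi:
            wins += 0.5
    return wins / len(x)


def brute_prob_exceeds(x, t):
    return sum(1.0 for xi in x if xi > t) / len(x)


def brute_p_best(arrays, keys):
    n = len(arrays[keys[0]])
    credit = {k: 0.0 for k in keys}
    for d in range(n):
        vals = {k: arrays[k][d] for k in keys}
        m = max(vals.values())
        winners = [k for k in keys if vals[k] == m]
        for k in winners:
            credit[k] += 1.0 / len(winners)
    return {k: credit[k] / n for k in keys}


# ------------------------------------------------------------------- tests


def test_rank_by_uncertainty_orders_by_sd_descending():
    post = PosteriorDraws.from_arrays(
        {
            "A": np.array([50.0, 51.0, 49.0]),     # sd 1
            "B": np.array([50.0, 53.0, 47.0]),     # sd 3
            "C": np.array([50.0, 52.0, 48.0]),     # sd 2
        }
    )
    rep = rank_by_uncertainty(post)
    assert list(rep.table["protein_id"]) == ["B", "C", "A"]
    assert (rep.table["score"].diff().dropna() <= 0).all()


def test_constant_draws_rank_last_with_zero_score():
    post = PosteriorDraws.from_arrays(
        {"A": np.array([50.0, 50.0, 50.0]), "B": np.array([40.0, 60.0, 50.0])}
    )
    rep = rank_by_uncertainty(post)
    assert rep.table.iloc[-1]["protein_id"] == "A"
    assert rep.table.iloc[-1]["score"] == 0.0


def test_prob_exceeds_counting():
    post = PosteriorDraws.from_arrays({"A": np.array([40.0, 50.0, 60.0])})
    assert prob_exceeds(post, 45.0).table["score"].iloc[0] == pytest.approx(2 / 3)
    assert prob_exceeds(post, 30.0).table["score"].iloc[0] == 1.0
    assert prob_exceeds(post, 70.0).table["score"].iloc[0] == 0.0


def test_prob_exceeds_monotone_in_threshold():
    _, post = hand_posterior(seed=3)
    thresholds = np.linspace(40.0, 60.0, 9)
    scores = np.array([prob_exceeds(post, t).table.set_index("protein_id")["score"]
                       .sort_index().to_numpy() for t in thresholds])
    assert (np.diff(scores, axis=0) <= 1e-12).all()


def test_prob_exceeds_is_one_minus_ecdf():
    arrays, post = hand_posterior(seed=4)
    t = 47.0
    rep = prob_exceeds(post, t).table.set_index("protein_id")
    for pid, x in arrays.items():
        assert rep.loc[pid, "score"] == pytest.approx(brute_prob_exceeds(x, t), abs=1e-12)


def test_prob_superiority_tie_convention():
    post = PosteriorDraws.from_arrays(
        {"i": np.array([1.0, 2.0, 3.0]), "j": np.array([2.0, 2.0, 2.0])}
    )
    # paired comparisons: (0 + 1/2 + 1)/3
    assert prob_superiority(post, "i", "j") == pytest.approx(0.5)
    assert prob_superiority(post, "i", "i") == 0.5


def test_prob_superiority_dominance():
    post = PosteriorDraws.from_arrays(
        {"hi": np.array([60.0, 61.0, 62.0]), "lo": np.array([40.0, 41.0, 42.0])}
    )
    assert prob_superiority(post, "hi", "lo") == 1.0
    assert prob_superiority(post, "lo", "hi") == 0.0


def test_matrix_and_rankings_match_brute_force():
    arrays, post = hand_posterior(seed=7, n_proteins=5, n_draws=200)
    mat, rep = superiority_matrix_and_ranking(post)
    keys = sorted(arrays)
    for i, ki in enumerate(keys):
        for j, kj in enumerate(keys):
            expected = 0.5 if i == j else brute_prob_superiority(arrays[ki], arrays[kj])
            assert mat.iloc[i, j] == pytest.approx(expected, abs=1e-12)
    # mean pairwise superiority over rivals
    t = rep.table.set_index("protein_id")
    for ki in keys:
        rivals = [brute_prob_superiority(arrays[ki], arrays[kj]) for kj in keys if kj != ki]
        assert t.loc[ki, "score"] == pytest.approx(np.mean(rivals), abs=1e-12)
    # P(best) with tie splitting
    pb = brute_p_best(arrays, keys)
    for ki in keys:
        assert t.loc[ki, "p_best"] == pytest.approx(pb[ki], abs=1e-12)
    assert t["p_best"].sum() == pytest.approx(1.0, abs=1e-12)


def test_identical_draws_all_half_ties_broken_by_key():
    x = np.linspace(40, 60, 50)
    post = PosteriorDraws.from_arrays({"c": x.copy(), "a": x.copy(), "b": x.copy()})
    mat, rep = superiority_matrix_and_ranking(post)
    off = mat.to_numpy()[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 0.5)
    assert list(rep.table["protein_id"]) == ["a", "b", "c"]


def test_direction_min_flips_comparisons():
    post = PosteriorDraws.from_arrays(
        {"hi": np.array([60.0, 61.0]), "lo": np.array([40.0, 41.0])}
    )
    _, rep_max = superiority_matrix_and_ranking(post, "max")
    _, rep_min = superiority_matrix_and_ranking(post, "min")
    assert rep_max.table.iloc[0]["protein_id"] == "hi"
    assert rep_min.table.iloc[0]["protein_id"] == "lo"


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 10_000))
def test_skew_symmetry_about_half(seed):
    rng = np.random.default_rng(seed)
    arrays = {f"P{i}": np.round(rng.normal(50, 2, 40), 1) for i in range(4)}  # rounding forces ties
    post = PosteriorDraws.from_arrays(arrays)
    mat, _ = superiority_matrix_and_ranking(post)
    m = mat.to_numpy()
    np.testing.assert_allclose(m + m.T, np.ones_like(m), atol=1e-12)


def test_errors():
    post = PosteriorDraws.from_arrays({"A": np.array([1.0, 2.0])})
    with pytest.raises(ValueError):
        superiority_matrix_and_ranking(post)
    with pytest.raises(KeyError):
        prob_superiority(post, "A", "ZZZ")
    with pytest.raises(ValueError):
        prob_exceeds(post, np.inf)
    with pytest.raises(ValueError):
        superiority_matrix_and_ranking(post, direction="sideways")


def test_probability_scores_in_unit_interval():
    _, post = hand_posterior(seed=11)
    rep = prob_exceeds(post, 50.0)
    assert rep.table["score"].between(0, 1).all()
    mat, rep2 = superiority_matrix_and_ranking(post)
    assert rep2.table["score"].between(0, 1).all()
    assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1)).all()
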