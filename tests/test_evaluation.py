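"""Scores, SMC, marginal closed forms, and the nonparametric statistics."""

import itertools
import math
import random

import numpy as np
import pytest
from scipy import stats

from moralagent.evaluation import (ALL_EMOTIONS, MEASURES, MORAL_EMOTIONS,
                                   NONMORAL_EMOTIONS, action_score,
                                   confusion_counts, mann_whitney_u,
                                   mean_smc_from_marginals, reproduce_tables,
                                   score_selection, smc, spearman_rho)
from moralagent.respondents import (generate_respondents, get_marginal_table,
                                    reconstruct_counts)


# ---------------------------------------------------------------------------
# per-participant scores
# ---------------------------------------------------------------------------

def test_perfect_match_scores():
    assert score_selection({"shame"}, {"shame"}, "ETS") == 1
    assert score_selection({"shame"}, {"shame"}, "ERTS") == 0


def test_hand_counted_error_scores():
    """selected {joy, anger} vs predicted {shame}."""
    sel, pred = {"joy", "anger"}, {"shame"}
    assert score_selection(sel, pred, "ETS") == 0
    # anger commission + shame omission
    assert score_selection(sel, pred, "MERS") == 2
    # joy commission only; hope (unselected) plays no role
    assert score_selection(sel, pred, "N-MERS") == 1
    # hope commission is forgiven under the hope rule, counted without it
    assert score_selection({"hope"}, set(), "N-MERS", hope_rule=True) == 0
    assert score_selection({"hope"}, set(), "N-MERS", hope_rule=False) == 1


def test_unknown_emotion_label_rejected():
    with pytest.raises(ValueError):
        score_selection({"ennui"}, {"shame"}, "ETS")
    with pytest.raises(ValueError):
        score_selection({"joy"}, {"shame"}, "XTS")


def test_action_score_indicator():
    assert action_score("giving_key", "giving_key") == 1
    assert action_score("refusing_key", "giving_key") == 0
    with pytest.raises(ValueError):
        action_score("other", "giving_key", ("giving_key", "refusing_key"))


def test_partition_additivity_random_selections():
    """ETS = MES + N-MES and ERTS = MERS + N-MERS, any hope_rule."""
    rng = random.Random(5)
    emotions = sorted(ALL_EMOTIONS)
    for _ in range(200):
        sel = {e for e in emotions if rng.random() < 0.4}
        pred = {e for e in emotions if rng.random() < 0.3}
        for hope_rule in (True, False):
            s = {m: score_selection(sel, pred, m, hope_rule)
                 for m in MEASURES}
            assert s["ETS"] == s["MES"] + s["N-MES"]
            assert s["ERTS"] == s["MERS"] + s["N-MERS"]


# ---------------------------------------------------------------------------
# SMC
# ---------------------------------------------------------------------------

def test_smc_basic_values():
    assert smc({"shame"}, {"shame"}) == 1.0
    # forced by the defining ratio: (M00 + M11) / 12
    sel = {"joy", "pride", "shame", "hope", "fear", "anger"}
    pred = {"joy", "pride", "shame", "distress"}
    c = confusion_counts(sel, pred, ALL_EMOTIONS)
    assert (c.m11, c.m00, c.m01, c.m10) == (3, 5, 3, 1)
    assert smc(sel, pred) == pytest.approx(8 / 12)
    # complementary selections over the subset: no agreement at all
    assert smc(MORAL_EMOTIONS, NONMORAL_EMOTIONS, MORAL_EMOTIONS) == 0.0


def test_smc_symmetry_and_bounds():
    rng = random.Random(9)
    emotions = sorted(ALL_EMOTIONS)
    for _ in range(100):
        a = frozenset(e for e in emotions if rng.random() < 0.5)
        b = frozenset(e for e in emotions if rng.random() < 0.5)
        v = smc(a, b)
        assert 0.0 <= v <= 1.0
        assert v == smc(b, a)


def test_smc_empty_subset_rejected():
    with pytest.raises(ValueError):
        smc({"joy"}, {"joy"}, set())


def test_mean_smc_from_marginals_wallace_tbi():
    t = get_marginal_table(reconstruct_counts(), "wallace", "TBI")
    assert mean_smc_from_marginals(t.counts, t.predicted, 13) == \
        pytest.approx(120 / 156)


def test_mean_smc_all_true_negative():
    counts = {e: 0 for e in ALL_EMOTIONS}
    assert mean_smc_from_marginals(counts, set(), 7) == 1.0


@pytest.mark.parametrize("seed", [0, 1, 17, 123])
def test_mean_smc_equals_matrix_averaging_any_seed(seed):
    """The marginal closed form equals per-participant averaging exactly."""
    tables = reconstruct_counts()
    for t in tables[:6]:
        m = generate_respondents(t, "exact_marginal", seed)
        for subset in (ALL_EMOTIONS, MORAL_EMOTIONS):
            direct = np.mean([smc(s, t.predicted, subset)
                              for s in m.selected_sets()])
            closed = mean_smc_from_marginals(t.counts, t.predicted, t.n,
                                             subset)
            assert direct == pytest.approx(closed, abs=1e-12)


# ---------------------------------------------------------------------------
# Mann–Whitney
# ---------------------------------------------------------------------------

def brute_force_mann_whitney(a, b):
    """Enumerate every assignment of the pooled values to the two samples."""
    pooled = list(a) + list(b)
    na = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2)
    us = []
    for idx in itertools.combinations(range(len(pooled)), na):
        u = float(ranks[list(idx)].sum() - na * (na + 1) / 2)
        us.append(u)
    us = np.array(us)
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2 * min(lo, hi))


def test_mann_whitney_tiny_example():
    res = mann_whitney_u([1, 2], [3, 4])
    assert res.u == 0
    assert res.p == pytest.approx(2 / 6)


def test_mann_whitney_identical_samples():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.u == pytest.approx(9 / 2)
    res = mann_whitney_u([2, 2, 2], [2, 2])
    assert res.p == 1.0 and res.ties


def test_mann_whitney_complement_and_swap():
    rng = random.Random(13)
    for _ in range(50):
        a = [rng.randint(0, 6) for _ in range(rng.randint(2, 7))]
        b = [rng.randint(0, 6) for _ in range(rng.randint(2, 7))]
        ra, rb = mann_whitney_u(a, b), mann_whitney_u(b, a)
        assert ra.u + rb.u == pytest.approx(len(a) * len(b))
        assert ra.p == pytest.approx(rb.p, abs=1e-9)


def test_mann_whitney_agrees_with_enumeration_oracle():
    rng = random.Random(21)
    for _ in range(50):
        na, nb = rng.randint(2, 7), rng.randint(2, 7)
        if rng.random() < 0.5:        # continuous, tie-free
            a = [round(rng.uniform(0, 10), 3) for _ in range(na)]
            b = [round(rng.uniform(0, 10), 3) for _ in range(nb)]
        else:                          # heavy ties
            a = [rng.randint(0, 3) for _ in range(na)]
            b = [rng.randint(0, 3) for _ in range(nb)]
        u_want, p_want = brute_force_mann_whitney(a, b)
        got = mann_whitney_u(a, b)
        assert got.u == pytest.approx(u_want)
        assert got.p == pytest.approx(p_want, abs=1e-9)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_trivial_directions():
    x = [1.0, 2.5, 3.0, 7.0]
    assert spearman_rho(x, x).rho == pytest.approx(1.0)
    assert spearman_rho(x, x[::-1]).rho == pytest.approx(-1.0)


def test_spearman_constant_input_rejected():
    with pytest.raises(ValueError):
        spearman_rho([1, 1, 1], [1, 2, 3])


def test_spearman_agrees_with_rank_formula_oracle():
    """rho = 1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data."""
    rng = random.Random(31)
    for _ in range(50):
        n = rng.randint(3, 8)
        x = rng.sample(range(100), n)
        y = rng.sample(range(100), n)
        d = stats.rankdata(x) - stats.rankdata(y)
        want = 1 - 6 * float(d @ d) / (n * (n * n - 1))
        assert spearman_rho(x, y).rho == pytest.approx(want)


# ---------------------------------------------------------------------------
# table reproduction
# ---------------------------------------------------------------------------

def test_from_marginals_equals_from_matrices_linear_statistics():
    base = reproduce_tables(mode="from_marginals")
    for seed in (0, 7):
        rep = reproduce_tables(mode="from_matrices", seed=seed)
        assert (base.means - rep.means).abs().max().max() < 1e-12
        assert (base.smc_all - rep.smc_all).abs().max().max() < 1e-12
        assert (base.smc_moral - rep.smc_moral).abs().max().max() < 1e-12
        for label in ("all", "moral"):
            for group in ("TBI", "control"):
                assert rep.global_smc[label][group] == pytest.approx(
                    base.global_smc[label][group], abs=1e-12)


def test_report_exports(tmp_path):
    rep = reproduce_tables(mode="from_matrices", seed=1)
    rep.write_csvs(tmp_path)
    assert (tmp_path / "actor_score_means.csv").exists()
    assert (tmp_path / "actor_score_stds.csv").exists()
    assert (tmp_path / "summary.json").exists()
    assert "global_smc" in (tmp_path / "summary.json").read_text()
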