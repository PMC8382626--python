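import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from explorevar import (
    FixtureSpec,
    LearnerParams,
    Model,
    TrialSeries,
    attc_estimate,
    classify_attc,
    classify_ttc,
    correction_factor,
    make_fixture,
    median_sq,
    reward_history_series,
    similarity_ratio,
    single_draw_factor,
    single_draw_factor_derived,
    trial_to_trial_changes,
    ttc_estimate,
)

# ---------------------------------------------------------------- oracles


def ttc_oracle(ep, r):
    """Naive loop reference: lag-1 changes split by previous reward."""
    d_minus, d_plus = [], []
    for t in range(2, len(ep) + 1):
        d = ep[t - 1] - ep[t - 2]
        (d_plus if r[t - 2] == 1 else d_minus).append(d)
    if not d_minus or not d_plus:
        return math.nan
    return (math.pi / 4) * (
        np.median(np.square(d_minus)) - np.median(np.square(d_plus))
    )


def attc_oracle(ep, r):
    """Naive loop reference: lag-2 changes grouped by reward triples."""
    groups = {}
    for t in range(4, len(ep) + 1):
        d = ep[t - 1] - ep[t - 3]
        key = {(0, 0): "A", (1, 0): "B", (0, 1): "C", (1, 1): "D"}[
            (r[t - 4], r[t - 3])
        ]
        groups.setdefault(key + ("+" if r[t - 2] == 1 else "-"), []).append(d)

    def med(lab):
        g = groups.get(lab, [])
        return float(np.median(np.square(g))) if g else math.nan

    num = den = 0.0
    ok = False
    for cls, w_eta in (("C", 3.0), ("D", 1.0)):
        nm = len(groups.get(cls + "-", []))
        np_ = len(groups.get(cls + "+", []))
        if nm == 0 or np_ == 0:
            continue
        est = 2.19 * (med(cls + "-") - med(cls + "+"))
        w = w_eta * min(nm, np_)
        num += w * est
        den += w
        ok = True
    return num / den if ok else math.nan


def _series(ep, r):
    return TrialSeries(ep=np.asarray(ep, float), reward=np.asarray(r, np.int8))


def _random_series(rng, n=None):
    n = n if n is not None else int(rng.integers(8, 80))
    return rng.normal(scale=3.0, size=n), rng.integers(0, 2, size=n)


# ----------------------------------------------------------- unit pieces


class TestChanges:
    def test_lag1(self):
        cs = trial_to_trial_changes([0, 1, 3], lag=1)
        np.testing.assert_array_equal(cs.deltas, [1, 2])
        np.testing.assert_array_equal(cs.t, [2, 3])

    def test_lag2(self):
        cs = trial_to_trial_changes([0, 1, 3, 6], lag=2)
        np.testing.assert_array_equal(cs.deltas, [3, 5])

    def test_constant_series(self):
        assert np.all(trial_to_trial_changes([2.0] * 5, lag=1).deltas == 0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            trial_to_trial_changes([1.0, 2.0], lag=2)


class TestClassification:
    def test_ttc_labels(self):
        labels = classify_ttc([1, 0, 1, 0, 0])
        np.testing.assert_array_equal(labels, ["+", "-", "+", "-"])

    def test_ttc_single_category(self):
        assert set(classify_ttc([1, 1, 1, 1])) == {"+"}
        assert set(classify_ttc([0, 0, 0, 0])) == {"-"}

    def test_ttc_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            classify_ttc([0, 2, 1])

    @pytest.mark.parametrize(
        "triple, expected",
        [((0, 1, 0), "C-"), ((1, 1, 1), "D+"), ((0, 0, 0), "A-"),
         ((1, 0, 1), "B+"), ((1, 1, 0), "D-")],
    )
    def test_attc_triples(self, triple, expected):
        # put the triple at trials 1..3 so the change at t = 4 sees it
        r = list(triple) + [0]
        assert classify_attc(r)[1] == expected

    def test_attc_first_change_unclassified(self):
        labels = classify_attc([0, 1, 0, 1, 1])
        assert labels[0] == "unclassified"
        assert labels.shape == (3,)


class TestMedianSq:
    def test_small_sets(self):
        assert median_sq([1, -2, 3]) == 4
        assert median_sq([2]) == 4

    def test_empty_is_undefined(self):
        assert math.isnan(median_sq([]))

    def test_gaussian_median_matches_chi_square(self):
        rng = np.random.default_rng(0)
        x = rng.normal(scale=2.0, size=1_000_000)
        expected = 4.0 * stats.chi2.ppf(0.5, df=1)  # 0.4549 sigma^2
        assert median_sq(x) == pytest.approx(expected, rel=0.01)


class TestSingleDrawFactor:
    def test_constant(self):
        assert single_draw_factor() == 2.19

    def test_derivation_matches_constant(self):
        assert single_draw_factor_derived() == pytest.approx(2.198, abs=5e-4)

    def test_monte_carlo_variance_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.normal(scale=2.0, size=1_000_000)
        assert 2.19 * median_sq(x) == pytest.approx(4.0, rel=0.02)


class TestCorrectionFactor:
    def test_gated_models_need_no_correction(self):
        assert correction_factor(Model.THERRIEN16) == 1.0
        assert correction_factor(Model.CASHABACK19) == 1.0

    def test_therrien18(self):
        assert correction_factor(Model.THERRIEN18) == 1.14

    def test_dhawale_from_reference_reward_histories(self):
        # trials alternate failure/success; rbar on the following trials
        # pinned at the reference values 0.20 / 0.68
        n = 200
        reward = np.tile([0, 1], n // 2).astype(np.int8)
        rbar = np.empty(n)
        rbar[1:][reward[:-1] == 0] = 0.20
        rbar[1:][reward[:-1] == 1] = 0.68
        rbar[0] = 0.0
        s = TrialSeries(ep=np.zeros(n), reward=reward, rbar=rbar)
        assert correction_factor(Model.DHAWALE19, s) == pytest.approx(
            2.49, abs=5e-3
        )

    def test_dhawale_falls_back_to_reward_ewma(self):
        rng = np.random.default_rng(2)
        reward = rng.integers(0, 2, 300).astype(np.int8)
        bare = TrialSeries(ep=np.zeros(300), reward=reward)
        with_rbar = TrialSeries(
            ep=np.zeros(300),
            reward=reward,
            rbar=reward_history_series(reward, tau=5.0),
        )
        assert correction_factor(Model.DHAWALE19, bare) == pytest.approx(
            correction_factor(Model.DHAWALE19, with_rbar)
        )

    def test_dhawale_requires_series(self):
        with pytest.raises(ValueError):
            correction_factor(Model.DHAWALE19)


# ------------------------------------------------------------- estimates


class TestTTCEstimate:
    def test_hand_computed_example(self):
        s = _series([0, 1, 3, 0, 2], [1, 0, 1, 0, 0])
        est = ttc_estimate(s, model=Model.THERRIEN16)
        # deltas (1, 2, -3, 2); medians: post-failure 4, post-success 5
        assert est.sigma2_eta_hat == pytest.approx(math.pi / 4 * (4 - 5))
        assert est.counts == {"-": 2, "+": 2}

    def test_constant_series_gives_zero(self):
        s = _series([5.0] * 30, [0, 1] * 15)
        assert ttc_estimate(s, model=Model.THERRIEN16).sigma2_eta_hat == 0.0

    def test_missing_category_is_undefined_with_counts(self):
        s = _series([0.0, 1.0, 2.0, 3.0], [1, 1, 1, 1])
        est = ttc_estimate(s, model=Model.THERRIEN16)
        assert not est.defined
        assert est.counts["-"] == 0
        assert any("undefined" in w for w in est.warnings)

    def test_negative_estimates_preserved(self):
        s = _series([0, 1, 3, 0, 2], [1, 0, 1, 0, 0])
        assert ttc_estimate(s, model=Model.THERRIEN16).sigma2_eta_hat < 0


class TestATTCEstimate:
    def test_matches_brute_force_on_fixture(self):
        spec = FixtureSpec(
            rewards=[0, 1, 0, 1, 1, 0, 0, 1, 1, 1, 0, 1, 0, 0, 1, 1, 0, 1,
                     1, 1, 0, 0, 1, 0, 1, 1, 1, 0],
            model=Model.THERRIEN16,
            learner=LearnerParams(sigma2_m=1.0, sigma2_eta_star=4.0),
            seed=5,
        )
        s = make_fixture(spec)
        est = attc_estimate(s)
        oracle = attc_oracle(s.ep.tolist(), list(spec.rewards))
        assert est.sigma2_eta_hat == pytest.approx(oracle, abs=1e-12)
        assert est.weights["w_Neta,C"] == 3
        assert est.weights["w_Neta,D"] == 1

    def test_all_success_script_is_undefined(self):
        s = make_fixture(FixtureSpec(rewards=[1] * 40))
        est = attc_estimate(s)
        assert not est.defined
        assert est.counts["D+"] > 0 and est.counts["D-"] == 0

    def test_single_class_pair_used_alone(self):
        # no double successes anywhere: D sequences never occur; the one
        # trailing (0,1,1) gives the single C+ needed for estimate C
        # the extra trailing trial lets the (0,1,1) triple be observed as
        # the context of a change
        rewards = [0, 1, 0] * 10 + [0, 1, 1, 0]
        s = make_fixture(FixtureSpec(rewards=rewards, seed=3))
        est = attc_estimate(s)
        assert est.defined
        assert est.counts["D-"] == 0 and est.counts["D+"] == 0
        assert est.counts["C-"] > 0 and est.counts["C+"] == 1
        assert any("single class pair" in w for w in est.warnings)

    def test_no_exploration_detected_as_zero(self):
        # with zero input exploration the estimate has mean zero; the
        # motor-noise scale (2 sigma2_m = 8) sets the sampling noise
        rng = np.random.default_rng(7)
        vals = []
        for i in range(200):
            spec = FixtureSpec(
                rewards=rng.integers(0, 2, 200).tolist(),
                learner=LearnerParams(sigma2_m=4.0, sigma2_eta_star=0.0),
                seed=int(rng.integers(2**31)),
            )
            est = attc_estimate(make_fixture(spec))
            if est.defined:
                vals.append(est.sigma2_eta_hat)
        assert len(vals) > 150
        assert abs(np.mean(vals)) < 1.0


class TestSimilarityRatio:
    def test_values(self):
        assert similarity_ratio(16.0, 16.0) == 1.0
        assert similarity_ratio(8.0, 16.0) == 0.5
        assert similarity_ratio(-2.0, 16.0) == -0.125

    def test_zero_input_variance_rejected(self):
        with pytest.raises(ValueError):
            similarity_ratio(1.0, 0.0)


# ------------------------------------------------------------ properties


@st.composite
def _ep_reward(draw):
    n = draw(st.integers(min_value=10, max_value=60))
    ep = draw(
        st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=n, max_size=n
        )
    )
    r = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    return np.asarray(ep), np.asarray(r, np.int8)


@given(_ep_reward(), st.floats(-100, 100, allow_nan=False))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_shift_invariance(data, c):
    ep, r = data
    for fn in (ttc_estimate, attc_estimate):
        a = fn(_series(ep, r), model=Model.THERRIEN16).sigma2_eta_hat
        b = fn(_series(ep + c, r), model=Model.THERRIEN16).sigma2_eta_hat
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(
            b, abs=1e-6 * max(1.0, abs(a))
        )


@given(_ep_reward(), st.floats(0.1, 10, allow_nan=False))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_scale_equivariance(data, k):
    ep, r = data
    for fn in (ttc_estimate, attc_estimate):
        a = fn(_series(ep, r), model=Model.THERRIEN16).sigma2_eta_hat
        b = fn(_series(k * ep, r), model=Model.THERRIEN16).sigma2_eta_hat
        assert (math.isnan(a) and math.isnan(b)) or b == pytest.approx(
            k**2 * a, rel=1e-9, abs=1e-9
        )


def test_oracle_equivalence_on_random_series():
    """Vectorized implementations agree exactly with naive loops."""
    rng = np.random.default_rng(11)
    checked = 0
    for _ in range(150):
        ep, r = _random_series(rng)
        s = _series(ep, r)
        for fn, oracle in ((ttc_estimate, ttc_oracle), (attc_estimate, attc_oracle)):
            got = fn(s, model=Model.THERRIEN16).sigma2_eta_hat
            want = oracle(ep.tolist(), r.tolist())
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)
                checked += 1
    assert checked >= 100


def test_sequence_class_algebra_with_zero_motor_noise():
    """With sigma_m = 0 the realized lag-2 change in every classified
    sequence equals the closed-form expression in the exploration draws
    (up to sign, which squaring removes)."""
    for alpha in (1.0, 0.3, 0.0):
        rng = np.random.default_rng(42)
        rewards = rng.integers(0, 2, 300).tolist()
        s = make_fixture(
            FixtureSpec(
                rewards=rewards,
                model="gated",
                learner=LearnerParams(
                    sigma2_m=0.0, sigma2_eta_star=4.0, alpha=0.5
                ),
                alpha=alpha,
                seed=9,
            )
        )
        eta = s.eta
        exprs = {
            "A-": lambda t: eta[t - 1] - eta[t - 3],
            "A+": lambda t: alpha * eta[t - 2] - eta[t - 3],
            "B-": lambda t: eta[t - 1],
            "B+": lambda t: alpha * eta[t - 2],
            "C-": lambda t: eta[t - 1] - (1 - alpha) * eta[t - 3],
            "C+": lambda t: (1 - alpha) * eta[t - 3],
            "D-": lambda t: eta[t - 1],
            "D+": lambda t: 0.0,
        }
        labels = classify_attc(s.reward)
        changes = trial_to_trial_changes(s.ep, lag=2)
        n_checked = 0
        for d, t, lab in zip(changes.deltas, changes.t, labels):
            if lab == "unclassified":
                continue
            assert abs(d) == pytest.approx(abs(exprs[lab](t)), abs=1e-10)
            n_checked += 1
        assert n_checked > 250


def test_attc_insensitive_to_motor_noise_under_random_reward():
    """The subtracted class pairs share the motor-noise contribution, so
    the ATTC estimate does not drift with sigma2_m (random criterion)."""
    from explorevar import TaskParams, draw_noise_vectors, simulate_trials

    task = TaskParams(criterion="random")
    means = []
    for s2m in (1.0, 9.0, 25.0):
        learner = LearnerParams(sigma2_m=s2m, sigma2_eta_star=16.0)
        srs = []
        for d in draw_noise_vectors(500, 150, seed=21):
            series = simulate_trials(Model.THERRIEN16, learner, task, d)
            srs.append(similarity_ratio(attc_estimate(series), 16.0))
        means.append(np.nanmean(srs))
    assert max(means) - min(means) < 0.25
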