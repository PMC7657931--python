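"""Movement HMM: likelihood exactness, decoding, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chronomove.hmm import (MovementHMM, _log_emissions, _pack, _stationary,
                            _unpack, season_split, state_budget)
from chronomove.preprocess import compute_steps


def _steps_df(steps, turns=None, ind="a", start="2014-01-01"):
    n = len(steps)
    turns = np.full(n, np.nan) if turns is None else np.asarray(turns, float)
    return pd.DataFrame({
        "id": ind,
        "timestamp": pd.date_range(start, periods=n, freq="h"),
        "step_m": np.asarray(steps, float),
        "log_disp": np.log(np.asarray(steps, float) + 1),
        "turn_rad": turns,
        "turn_defined": np.isfinite(turns),
        "gap": False,
        "segment": 0,
    })


def brute_force_loglik(model, x):
    """Likelihood by explicit summation over every state path."""
    n = model.n_states
    mean, sd, zero, tmu, kappa, tm = _unpack(x, n)
    log_b = _log_emissions(model.obs, mean, sd, zero, tmu, kappa)
    b = np.exp(log_b)
    delta = _stationary(tm)
    total = 0.0
    t_len = len(b)
    for path in itertools.product(range(n), repeat=t_len):
        p = delta[path[0]] * b[0, path[0]]
        for t in range(1, t_len):
            p *= tm[path[t - 1], path[t]] * b[t, path[t]]
        total += p
    return np.log(total)


@pytest.fixture(scope="module")
def fitted(homogeneous_tracks):
    tracks, cfg = homogeneous_tracks
    steps = compute_steps(tracks)
    model = MovementHMM(steps, n_states=3)
    return tracks, cfg, model.fit(n_restarts=2, seed=0)


class TestForwardAlgorithm:
    @pytest.mark.parametrize("n_states,t_len", [(2, 6), (2, 8), (3, 6)])
    def test_forward_equals_path_enumeration(self, n_states, t_len, rng):
        """Scaled forward log-likelihood matches exhaustive enumeration."""
        steps = rng.gamma(2.0, 50.0, t_len)
        steps[1] = 0.0                       # exercise the zero atom
        turns = rng.vonmises(0.0, 1.0, t_len)
        turns[0] = np.nan
        df = _steps_df(steps, turns)
        df.loc[df.index[1], "turn_defined"] = False
        model = MovementHMM.__new__(MovementHMM)
        model.n_states = n_states
        from chronomove.hmm import _prepare_obs
        model.obs = _prepare_obs(df)
        mean = np.linspace(20, 200, n_states)
        sd = mean * 0.7
        zero = np.linspace(0.3, 0.05, n_states)
        tmu = np.zeros(n_states)
        kappa = np.linspace(0.5, 2.0, n_states)
        tm = np.full((n_states, n_states), 0.2 / (n_states - 1))
        np.fill_diagonal(tm, 0.8)
        x = _pack(mean, sd, zero, tmu, kappa, tm)
        assert model.loglik(x) == pytest.approx(
            brute_force_loglik(model, x), abs=1e-10)

    def test_single_state_degeneracy(self, rng):
        steps = rng.gamma(4.0, 25.0, 300)
        model = MovementHMM(_steps_df(steps), n_states=1)
        res = model.fit(n_restarts=1, seed=0)
        assert res.transition_matrix.tolist() == [[1.0]]
        assert res.step_mean[0] == pytest.approx(steps.mean(), rel=0.05)
        assert res.step_sd[0] == pytest.approx(steps.std(), rel=0.10)

    def test_invalid_state_count_rejected(self, rng):
        df = _steps_df(rng.gamma(2, 10, 100))
        with pytest.raises(ValueError):
            MovementHMM(df, n_states=6)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            MovementHMM(_steps_df(np.full(100, 5.0)), n_states=2)

    def test_too_few_steps_rejected(self, rng):
        with pytest.raises(ValueError):
            MovementHMM(_steps_df(rng.gamma(2, 10, 20)), n_states=2)


class TestRecovery:
    def test_parameters_recovered_from_simulation(self, fitted):
        tracks, cfg, res = fitted
        for i, state in enumerate((1, 2, 3)):
            e = cfg.emissions[state]
            assert res.step_mean[i] == pytest.approx(e.step_mean, rel=0.10)
            assert res.zero_mass[i] == pytest.approx(e.zero_mass, abs=0.05)
        assert np.abs(res.transition_matrix
                      - cfg.baseline_transition_matrix).max() < 0.05

    def test_best_of_restarts_at_least_single_restart(self, fitted):
        _, _, res = fitted
        assert res.loglik >= max(res.restart_logliks) - 1e-6
        assert res.loglik == pytest.approx(max(res.restart_logliks))

    def test_states_ordered_by_step_mean(self, fitted):
        _, _, res = fitted
        assert (np.diff(res.step_mean) > 0).all()

    def test_viterbi_recovers_true_states(self, fitted):
        # default emissions overlap moderately (resting vs foraging), so the
        # attainable decoding accuracy is below the well-separated regime
        tracks, _, res = fitted
        probs = res.state_probabilities()
        merged = probs.merge(tracks[["id", "timestamp", "true_state"]],
                             on=["id", "timestamp"])
        assert (merged["viterbi"] == merged["true_state"]).mean() >= 0.85


class TestDecoding:
    def test_posteriors_sum_to_one(self, fitted):
        _, _, res = fitted
        probs = res.state_probabilities()
        total = probs[["p_resting", "p_foraging", "p_transiting"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_disjoint_supports_give_hard_posteriors(self, rng):
        """With non-overlapping step distributions the posterior is 0/1 and
        equals the generating state."""
        truth = rng.integers(0, 2, 400)
        steps = np.where(truth == 0, rng.uniform(1, 3, 400),
                         rng.uniform(2000, 3000, 400))
        model = MovementHMM(_steps_df(steps), n_states=2)
        res = model.fit(n_restarts=2, seed=1)
        probs = res.state_probabilities()
        post = probs[["p_state1", "p_state2"]].to_numpy()
        assert np.minimum(post[:, 0], post[:, 1]).max() < 1e-6
        assert ((post[:, 1] > 0.5) == truth.astype(bool)).all()


class TestPseudoResiduals:
    def test_residuals_standard_normal_under_correct_model(self, fitted):
        _, _, res = fitted
        r = res.pseudo_residuals(seed=0)["residual"]
        assert len(r) > 4000
        assert abs(r.mean()) < 0.1
        assert abs(r.var() - 1.0) < 0.15

    def test_misspecified_model_has_higher_autocorrelation(self,
                                                           homogeneous_tracks):
        tracks, _, = homogeneous_tracks[0], None
        steps = compute_steps(homogeneous_tracks[0])
        sub = steps[steps["id"] == steps["id"].iloc[0]]
        good = MovementHMM(sub, n_states=3).fit(n_restarts=1, seed=0)
        bad = MovementHMM(sub, n_states=1).fit(n_restarts=1, seed=0)

        def lag1(series):
            v = series.to_numpy()
            return np.corrcoef(v[:-1], v[1:])[0, 1]

        assert lag1(bad.pseudo_residuals(seed=0)["residual"]) \
            > lag1(good.pseudo_residuals(seed=0)["residual"]) + 0.05


class TestSeasonSplit:
    def test_no_snow_means_single_snow_free_season(self):
        df = pd.DataFrame({"id": "a", "snow_m": np.zeros(1000)})
        assert not season_split(df).any()

    def test_threshold_above_max_depth(self):
        df = pd.DataFrame({"id": "a", "snow_m": np.full(1000, 0.3)})
        assert not season_split(df, threshold_m=0.5).any()

    def test_boundaries_match_configured_snow_curve(self, winter_tracks=None):
        from datetime import date

        from chronomove.simulate import SimulationConfig, simulate_tracks
        cfg = SimulationConfig(n_individuals=1, start_date=date(2014, 3, 1),
                               end_date=date(2014, 12, 15), timeout_prob=0.0,
                               seed=4)
        tracks = simulate_tracks(cfg)
        lab = season_split(tracks)
        change = tracks.loc[lab.astype(int).diff().abs() == 1, "timestamp"]
        melt, onset = change.iloc[0], change.iloc[1]
        cov = tracks.drop_duplicates("timestamp")
        true_melt = tracks.loc[(tracks["snow_m"] == 0).idxmax(), "timestamp"]
        assert abs((melt - true_melt).days) <= 3
        true_onset = tracks.loc[tracks["timestamp"] > true_melt].pipe(
            lambda d: d.loc[(d["snow_m"] > 0.05).idxmax(), "timestamp"])
        assert abs((onset - true_onset).days) <= 3

    def test_short_runs_are_merged(self):
        snow = np.concatenate([np.ones(600), np.zeros(24),   # 1-day dropout
                               np.ones(600), np.zeros(600)])
        df = pd.DataFrame({"id": "a", "snow_m": snow})
        lab = season_split(df, min_run_days=7.0)
        assert lab.iloc[600:624].all()          # dropout absorbed
        assert not lab.iloc[-300:].any()


class TestStateBudget:
    def test_uniform_posteriors_give_equal_budget(self):
        ts = pd.date_range("2014-01-08", periods=21 * 24, freq="h")
        probs = pd.DataFrame({"id": "a", "timestamp": ts,
                              "p_resting": 1 / 3, "p_foraging": 1 / 3,
                              "p_transiting": 1 / 3})
        budget = state_budget(probs, scale="week")
        for c in ("p_resting", "p_foraging", "p_transiting"):
            np.testing.assert_allclose(budget[c], 1 / 3)
        assert budget["eligible"].all()

    def test_budgets_sum_to_one_and_flag_short_windows(self):
        ts = pd.date_range("2014-01-06", periods=4 * 24, freq="h")
        probs = pd.DataFrame({"id": "a", "timestamp": ts,
                              "p_resting": 0.2, "p_foraging": 0.7,
                              "p_transiting": 0.1})
        budget = state_budget(probs, scale="week")
        total = budget[["p_resting", "p_foraging", "p_transiting"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0)
        assert not budget["eligible"].any()     # 4 days < 144 fixes
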