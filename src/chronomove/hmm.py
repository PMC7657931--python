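"""Multi-state hidden Markov models for hourly movement data.

States are latent behavioural modes (resting, foraging, transiting for the
canonical three-state model) emitting a zero-inflated gamma step length
and a von Mises turning angle, assumed independent given the state.  The
likelihood is maximized numerically over unconstrained working parameters
(log / logit / multinomial-logit transforms) with the scaled forward
algorithm, best of several randomized moment-based starts.  Decoding
provides forward-backward posteriors, the Viterbi path, and one-step-ahead
pseudo-residuals for goodness of fit.

Gap steps (spanning a missed fix) are excluded; each contiguous gap-free
run of an individual's track is treated as an independent sequence started
from the stationary distribution of the transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import gammaln, i0e, ndtri
from scipy.stats import gamma as gamma_dist

__all__ = [
    "MovementHMM",
    "MovementHMMResults",
    "season_split",
    "state_budget",
]

THREE_STATE_NAMES = ("resting", "foraging", "transiting")

#: window eligibility: minimum days of data per week / month
MIN_FIXES = {"week": 144, "month": 672}


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=False)
def _forward_ll(log_b, gamma_tm, delta, seg_start):
    """Scaled-forward log-likelihood over concatenated segments."""
    t_len, n = log_b.shape
    ll = 0.0
    alpha = np.zeros(n)
    pred = np.zeros(n)
    for t in range(t_len):
        if seg_start[t]:
            for i in range(n):
                pred[i] = delta[i]
        else:
            for j in range(n):
                s = 0.0
                for i in range(n):
                    s += alpha[i] * gamma_tm[i, j]
                pred[j] = s
        mx = log_b[t, 0]
        for i in range(1, n):
            if log_b[t, i] > mx:
                mx = log_b[t, i]
        c = 0.0
        for i in range(n):
            alpha[i] = pred[i] * np.exp(log_b[t, i] - mx)
            c += alpha[i]
        if c <= 0.0:
            return -np.inf
        ll += np.log(c) + mx
        for i in range(n):
            alpha[i] /= c
    return ll


@njit(cache=False)
def _forward_filter(log_b, gamma_tm, delta, seg_start):
    """Normalized filtered probabilities and one-step-ahead predictions."""
    t_len, n = log_b.shape
    alphas = np.zeros((t_len, n))
    preds = np.zeros((t_len, n))
    alpha = np.zeros(n)
    for t in range(t_len):
        if seg_start[t]:
            for i in range(n):
                preds[t, i] = delta[i]
        else:
            for j in range(n):
                s = 0.0
                for i in range(n):
                    s += alpha[i] * gamma_tm[i, j]
                preds[t, j] = s
        mx = log_b[t, 0]
        for i in range(1, n):
            if log_b[t, i] > mx:
                mx = log_b[t, i]
        c = 0.0
        for i in range(n):
            alpha[i] = preds[t, i] * np.exp(log_b[t, i] - mx)
            c += alpha[i]
        for i in range(n):
            alpha[i] /= c
            alphas[t, i] = alpha[i]
    return alphas, preds


@njit(cache=False)
def _backward_smooth(log_b, gamma_tm, alphas, seg_start):
    """Forward-backward posteriors from stored filtered probabilities."""
    t_len, n = log_b.shape
    post = np.zeros((t_len, n))
    beta = np.ones(n)
    for t in range(t_len - 1, -1, -1):
        if t == t_len - 1 or seg_start[t + 1]:
            for i in range(n):
                beta[i] = 1.0
        else:
            mx = log_b[t + 1, 0]
            for i in range(1, n):
                if log_b[t + 1, i] > mx:
                    mx = log_b[t + 1, i]
            nb = np.zeros(n)
            for i in range(n):
                s = 0.0
                for j in range(n):
                    s += gamma_tm[i, j] * np.exp(log_b[t + 1, j] - mx) * beta[j]
                nb[i] = s
            z = 0.0
            for i in range(n):
                z += nb[i]
            for i in range(n):
                beta[i] = nb[i] / z
        z = 0.0
        for i in range(n):
            post[t, i] = alphas[t, i] * beta[i]
            z += post[t, i]
        for i in range(n):
            post[t, i] /= z
    return post


# ---------------------------------------------------------------------------
# parameterization


@dataclass
class _Obs:
    """Flattened observation arrays for the fitter."""

    step: np.ndarray
    turn: np.ndarray          # NaN where undefined
    seg_start: np.ndarray     # bool
    index: pd.DataFrame       # id, timestamp for re-attachment


def _prepare_obs(steps: pd.DataFrame) -> _Obs:
    use = steps.loc[~steps["gap"].astype(bool)].copy()
    use = use.sort_values(["id", "timestamp"], kind="mergesort")
    seg_key = use["id"].astype(str) + "/" + use["segment"].astype(str)
    seg_start = (seg_key != seg_key.shift()).to_numpy()
    turn = np.where(use["turn_defined"].to_numpy(), use["turn_rad"].to_numpy(),
                    np.nan)
    return _Obs(step=use["step_m"].to_numpy(dtype=float), turn=turn,
                seg_start=seg_start,
                index=use[["id", "timestamp"]].reset_index(drop=True))


def _n_params(n_states: int) -> int:
    return 5 * n_states + n_states * (n_states - 1)


def _unpack(x: np.ndarray, n: int):
    e = x[:5 * n].reshape(n, 5)
    mean = np.exp(e[:, 0])
    sd = np.exp(e[:, 1])
    zero = 1.0 / (1.0 + np.exp(-e[:, 2]))
    turn_mean = np.arctan2(np.sin(e[:, 3]), np.cos(e[:, 3]))
    kappa = np.exp(e[:, 4])
    if n == 1:
        tm = np.ones((1, 1))
    else:
        logits = x[5 * n:].reshape(n, n - 1)
        full = np.zeros((n, n))
        for i in range(n):
            cols = [j for j in range(n) if j != i]
            full[i, cols] = logits[i]
        full -= full.max(axis=1, keepdims=True)
        tm = np.exp(full)
        tm /= tm.sum(axis=1, keepdims=True)
    return mean, sd, zero, turn_mean, kappa, tm


def _pack(mean, sd, zero, turn_mean, kappa, tm) -> np.ndarray:
    n = len(mean)
    e = np.column_stack([
        np.log(mean), np.log(sd),
        np.log(zero / (1 - zero)), turn_mean, np.log(kappa)])
    parts = [e.ravel()]
    if n > 1:
        logits = np.empty((n, n - 1))
        ref = np.log(np.clip(np.diag(tm), 1e-12, None))
        for i in range(n):
            cols = [j for j in range(n) if j != i]
            logits[i] = np.log(np.clip(tm[i, cols], 1e-12, None)) - ref[i]
        parts.append(logits.ravel())
    return np.concatenate(parts)


def _stationary(tm: np.ndarray) -> np.ndarray:
    n = len(tm)
    if n == 1:
        return np.ones(1)
    a = np.vstack([tm.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    sol = np.clip(sol, 1e-12, None)
    return sol / sol.sum()


def _log_emissions(obs: _Obs, mean, sd, zero, turn_mean, kappa) -> np.ndarray:
    """T x N log emission probabilities (step and turn jointly)."""
    step = obs.step[:, None]
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    with np.errstate(divide="ignore", invalid="ignore"):
        log_gamma_pdf = ((shape - 1) * np.log(step) - step / scale
                         - shape * np.log(scale) - gammaln(shape))
    is_zero = obs.step == 0.0
    log_step = np.where(is_zero[:, None],
                        np.log(zero)[None, :],
                        np.log1p(-zero)[None, :] + log_gamma_pdf)
    defined = np.isfinite(obs.turn)
    turn = np.where(defined, obs.turn, 0.0)[:, None]
    log_vm = (kappa * np.cos(turn - turn_mean)
              - np.log(2 * np.pi) - (np.log(i0e(kappa)) + kappa))
    log_turn = np.where(defined[:, None], log_vm, 0.0)
    out = log_step + log_turn
    return np.where(np.isfinite(out), out, -1e300)


# ---------------------------------------------------------------------------
# model / results


class MovementHMM:
    """Movement HMM over a step series (possibly many individuals).

    Parameters
    ----------
    steps : DataFrame from :func:`chronomove.preprocess.compute_steps`
        (columns id, timestamp, step_m, turn_rad, turn_defined, gap,
        segment).  Gap steps are dropped; each gap-free run is an
        independent sequence.
    n_states : number of behavioural states, 1-5 (3 canonical).
    """

    def __init__(self, steps: pd.DataFrame, n_states: int = 3):
        if not 1 <= n_states <= 5:
            raise ValueError("n_states must be between 1 and 5")
        self.n_states = n_states
        self.obs = _prepare_obs(steps)
        if len(self.obs.step) < 50:
            raise ValueError("need at least 50 usable (gap-free) steps")
        if np.ptp(self.obs.step) == 0:
            raise ValueError("degenerate data: all step lengths identical")

    # -- initial values ----------------------------------------------------
    def _moment_starts(self, rng: np.random.Generator, perturb: bool):
        n = self.n_states
        pos = self.obs.step[self.obs.step > 0]
        qs = np.quantile(pos, np.linspace(0, 1, n + 1))
        mean = np.empty(n)
        sd = np.empty(n)
        for i in range(n):
            grp = pos[(pos >= qs[i]) & (pos <= qs[i + 1])]
            mean[i] = max(grp.mean(), 1e-3) if len(grp) else np.quantile(pos, 0.5)
            sd[i] = max(grp.std(), mean[i] * 0.5)
        zero_frac = np.clip(np.mean(self.obs.step == 0.0), 1e-3, 0.5)
        zero = np.clip(zero_frac * np.linspace(1.5, 0.1, n), 1e-4, 0.6)
        turn_mean = np.zeros(n)
        kappa = np.linspace(0.5, 1.5, n)
        tm = np.full((n, n), 0.1 / max(n - 1, 1)) if n > 1 else np.ones((1, 1))
        if n > 1:
            np.fill_diagonal(tm, 0.9)
        if perturb:
            mean = mean * rng.lognormal(0.0, 0.3, n)
            sd = sd * rng.lognormal(0.0, 0.3, n)
            kappa = kappa * rng.lognormal(0.0, 0.3, n)
            turn_mean = rng.normal(0.0, 0.5, n)
        return _pack(mean, sd, zero, turn_mean, kappa, tm)

    def loglik(self, x: np.ndarray) -> float:
        mean, sd, zero, tmu, kappa, tm = _unpack(x, self.n_states)
        log_b = _log_emissions(self.obs, mean, sd, zero, tmu, kappa)
        delta = _stationary(tm)
        return float(_forward_ll(log_b, tm, delta, self.obs.seg_start))

    def fit(self, n_restarts: int = 10, seed: int | None = 0,
            maxiter: int = 300) -> "MovementHMMResults":
        """Maximize the likelihood from several randomized starts.

        The first start is purely moment-based; the rest perturb it.  The
        best optimum over all converged restarts is returned, with the
        per-restart log-likelihoods recorded.
        """
        rng = np.random.default_rng(seed)
        n = self.n_states
        bounds = []
        for _ in range(n):
            bounds += [(-5, 20), (-5, 20), (-12.0, 12.0), (-7, 7),
                       (np.log(1e-3), np.log(500.0))]
        bounds += [(-30, 30)] * (n * (n - 1))

        best = None
        restart_ll = []
        for r in range(max(1, n_restarts)):
            x0 = self._moment_starts(rng, perturb=r > 0)
            res = minimize(lambda x: -self.loglik(x), x0, method="L-BFGS-B",
                           bounds=bounds, options={"maxiter": maxiter})
            restart_ll.append(-res.fun)
            if best is None or -res.fun > -best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("HMM fit failed to converge in all restarts")
        x = self._sort_states(best.x)
        return MovementHMMResults(self, x, float(-best.fun),
                                  restart_logliks=restart_ll,
                                  converged=bool(best.success))

    def _sort_states(self, x: np.ndarray) -> np.ndarray:
        """Resolve label switching: order states by gamma mean step length."""
        mean, sd, zero, tmu, kappa, tm = _unpack(x, self.n_states)
        order = np.argsort(mean)
        tm = tm[np.ix_(order, order)]
        return _pack(mean[order], sd[order], zero[order], tmu[order],
                     kappa[order], tm)


class MovementHMMResults:
    """Fitted movement HMM: parameters, decoding and diagnostics."""

    def __init__(self, model: MovementHMM, x: np.ndarray, loglik: float,
                 restart_logliks: list[float] | None = None,
                 converged: bool = True):
        self.model = model
        self._x = x
        self.loglik = loglik
        self.restart_logliks = restart_logliks or []
        self.converged = converged
        n = model.n_states
        (self.step_mean, self.step_sd, self.zero_mass, self.turn_mean,
         self.turn_concentration, self.transition_matrix) = _unpack(x, n)
        self.initial_distribution = _stationary(self.transition_matrix)
        self.n_params = _n_params(n)
        self.aic = 2.0 * self.n_params - 2.0 * loglik
        self.state_names = (THREE_STATE_NAMES if n == 3
                            else tuple(f"state{i + 1}" for i in range(n)))

    # -- decoding ----------------------------------------------------------
    def _log_b(self) -> np.ndarray:
        return _log_emissions(self.model.obs, self.step_mean, self.step_sd,
                              self.zero_mass, self.turn_mean,
                              self.turn_concentration)

    def state_probabilities(self) -> pd.DataFrame:
        """Forward-backward posterior per fix plus the Viterbi state (1-based)."""
        obs = self.model.obs
        log_b = self._log_b()
        alphas, _ = _forward_filter(log_b, self.transition_matrix,
                                    self.initial_distribution, obs.seg_start)
        post = _backward_smooth(log_b, self.transition_matrix, alphas,
                                obs.seg_start)
        vit = self._viterbi_path(log_b)
        out = obs.index.copy()
        for i, name in enumerate(self.state_names):
            out[f"p_{name}"] = post[:, i]
        out["viterbi"] = vit + 1
        return out

    def _viterbi_path(self, log_b: np.ndarray) -> np.ndarray:
        """Viterbi decoding per segment (plain numpy; run once per fit)."""
        obs = self.model.obs
        n = self.model.n_states
        log_gamma = np.log(np.clip(self.transition_matrix, 1e-300, None))
        log_delta = np.log(np.clip(self.initial_distribution, 1e-300, None))
        starts = np.flatnonzero(obs.seg_start)
        ends = np.append(starts[1:], len(log_b))
        path = np.zeros(len(log_b), dtype=np.int64)
        for s, e in zip(starts, ends):
            t_len = e - s
            score = log_delta + log_b[s]
            back = np.zeros((t_len, n), dtype=np.int64)
            for t in range(1, t_len):
                cand = score[:, None] + log_gamma
                back[t] = np.argmax(cand, axis=0)
                score = cand[back[t], np.arange(n)] + log_b[s + t]
            state = int(np.argmax(score))
            for t in range(t_len - 1, -1, -1):
                path[s + t] = state
                state = back[t, state] if t > 0 else state
        return path

    def pseudo_residuals(self, seed: int | None = 0) -> pd.DataFrame:
        """One-step-ahead forecast pseudo-residuals for the step lengths.

        The forecast CDF of each step under the fitted model is mapped
        through the standard-normal quantile; a well-specified model gives
        approximately N(0, 1) residuals with little autocorrelation.  The
        discrete atom at zero is handled by randomizing uniformly within
        the CDF jump, the standard treatment for mixed distributions.
        """
        obs = self.model.obs
        log_b = self._log_b()
        _, preds = _forward_filter(log_b, self.transition_matrix,
                                   self.initial_distribution, obs.seg_start)
        shape = (self.step_mean / self.step_sd) ** 2
        scale = self.step_sd ** 2 / self.step_mean
        cont = gamma_dist.cdf(obs.step[:, None], shape[None, :],
                              scale=scale[None, :])
        cdf_at = (self.zero_mass[None, :]
                  + (1 - self.zero_mass)[None, :] * cont)
        u = np.sum(preds * cdf_at, axis=1)
        jump = np.sum(preds * self.zero_mass[None, :], axis=1)
        rng = np.random.default_rng(seed)
        is_zero = obs.step == 0.0
        u = np.where(is_zero, rng.uniform(0.0, 1.0, len(u)) * jump, u)
        z = ndtri(np.clip(u, 1e-12, 1 - 1e-12))
        out = obs.index.copy()
        out["residual"] = z
        return out

    def summary(self) -> str:
        lines = [f"Movement HMM ({self.model.n_states} states, "
                 f"{len(self.model.obs.step)} steps)",
                 f"log-likelihood {self.loglik:.2f}   AIC {self.aic:.2f}   "
                 f"converged {self.converged}", ""]
        hdr = (f"{'state':<12}{'step mean':>10}{'step sd':>10}{'P(zero)':>9}"
               f"{'turn mu':>9}{'kappa':>8}")
        lines.append(hdr)
        for i, name in enumerate(self.state_names):
            lines.append(f"{name:<12}{self.step_mean[i]:>10.1f}"
                         f"{self.step_sd[i]:>10.1f}{self.zero_mass[i]:>9.3f}"
                         f"{self.turn_mean[i]:>9.2f}"
                         f"{self.turn_concentration[i]:>8.2f}")
        lines.append("")
        lines.append("transition matrix (rows sum to 1):")
        for i in range(self.model.n_states):
            lines.append("  " + "  ".join(f"{p:.3f}"
                                          for p in self.transition_matrix[i]))
        return "\n".join(lines)

    def params_dict(self) -> dict:
        return {
            "n_states": self.model.n_states,
            "state_names": list(self.state_names),
            "step_mean_m": self.step_mean.tolist(),
            "step_sd_m": self.step_sd.tolist(),
            "zero_mass": self.zero_mass.tolist(),
            "turn_mean_rad": self.turn_mean.tolist(),
            "turn_concentration": self.turn_concentration.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "restart_logliks": self.restart_logliks,
        }


# ---------------------------------------------------------------------------
# season split and state budgets


def season_split(track: pd.DataFrame, threshold_m: float = 0.05,
                 min_run_days: float = 7.0,
                 fix_interval_h: float = 1.0) -> pd.Series:
    """Label each fix snow-covered or snow-free from per-fix snow depth.

    Thresholds snow depth and then removes runs shorter than
    ``min_run_days`` (merging them into the surrounding season) so brief
    melt or dusting events do not fragment the seasons.  Returns a boolean
    Series (True = snow-covered) aligned with the track.
    """
    if "snow_m" not in track.columns or track["snow_m"].isna().all():
        raise ValueError("track has no usable snow depth column")
    out = pd.Series(False, index=track.index)
    min_run = int(min_run_days * 24.0 / fix_interval_h)
    for _, g in track.groupby("id", sort=False):
        snow = (g["snow_m"].to_numpy() > threshold_m)
        # merge runs shorter than min_run into the previous season
        change = np.flatnonzero(np.diff(snow.astype(int))) + 1
        bounds = np.concatenate([[0], change, [len(snow)]])
        cur = snow[0]
        lab = np.empty(len(snow), dtype=bool)
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e - s >= min_run:
                cur = snow[s]
            lab[s:e] = cur
        out.loc[g.index] = lab
    return out


def state_budget(probs: pd.DataFrame, scale: str = "week",
                 fix_interval_h: float = 1.0) -> pd.DataFrame:
    """Mean posterior state occupancy per individual-window.

    Windows with fewer fixes than the eligibility rule (six full days per
    week, twenty-eight per month) are flagged ``eligible = False`` but
    still reported.
    """
    from .classify import week_of_year

    if scale not in MIN_FIXES:
        raise ValueError("scale must be 'week' or 'month'")
    p_cols = [c for c in probs.columns if c.startswith("p_")]
    df = probs.copy()
    ts = pd.DatetimeIndex(df["timestamp"])
    df["year"] = ts.year
    df["window"] = week_of_year(df["timestamp"]) if scale == "week" else ts.month
    rows = []
    need = MIN_FIXES[scale] * fix_interval_h
    for (ind, yr, w), g in df.groupby(["id", "year", "window"], sort=True):
        row = {"id": ind, "year": yr, "window": w, "scale": scale,
               "n_fixes": len(g), "eligible": len(g) * fix_interval_h >= need}
        for c in p_cols:
            row[c] = g[c].mean()
        rows.append(row)
    return pd.DataFrame(rows)
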