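"""Binomial mixed model linking rhythmicity to environmental conditions.

The rhythmic / arrhythmic outcome of each individual-window (any
significant band peak versus none) is modelled on the logit scale against
scaled environmental covariates — photoperiod, NDVI, snow depth, elevation
and the proportion of fixes in dense vegetation — with random intercepts
for year and for individual nested within year.  Estimation maximizes the
Laplace-approximate marginal likelihood over fixed effects and
random-intercept standard deviations.

Also provides the covariate collinearity screen (Pearson |r| < 0.5),
bootstrap prediction curves over a covariate's observed range, and the
growing-season NDVI contrast between rhythmic and arrhythmic individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "BinomialGLMM",
    "BinomialGLMMResults",
    "screen_collinearity",
    "scale_covariates",
    "build_rhythm_model_data",
    "fit_rhythm_glmm",
    "predict_response_curve",
    "ndvi_group_contrast",
]

DEFAULT_COVARIATES = ("photoperiod_h", "elev_m", "dense_veg", "snow_m", "ndvi")


# ---------------------------------------------------------------------------
# data preparation


def screen_collinearity(covariates: pd.DataFrame, threshold: float = 0.5,
                        ) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations with flagged high-|r| pairs.

    Pairs at or above the threshold are flagged for an explicit modelling
    decision, never dropped silently.
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least two covariates to screen")
    if (covariates.std(ddof=0) == 0).any():
        bad = covariates.columns[covariates.std(ddof=0) == 0].tolist()
        raise ValueError(f"constant covariate(s): {bad}")
    corr = covariates.corr(method="pearson")
    flagged = []
    cols = list(covariates.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    return corr, flagged


def scale_covariates(data: pd.DataFrame, columns) -> pd.DataFrame:
    """Scale columns to mean 0, sd 1 within the analysis set."""
    out = data.copy()
    for c in columns:
        v = out[c].astype(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"covariate {c!r} is constant; cannot scale")
        out[c] = (v - v.mean()) / sd
    return out


def build_rhythm_model_data(records: pd.DataFrame, steps: pd.DataFrame,
                            metric: str, scale: str = "week",
                            covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """One modelling row per individual-window for one activity metric.

    The binary response groups the three rhythmic classes against the
    arrhythmic class.  Covariates are averaged over the individual's fixes
    in the window (``dense_veg`` becomes the proportion of fixes in dense
    vegetation) and scaled to mean 0 / sd 1 across the analysis set.
    """
    from .classify import week_of_year

    rec = records[records["metric"] == metric].copy()
    if rec.empty:
        raise ValueError(f"no records for metric {metric!r}")
    fixes = steps.copy()
    ts = pd.DatetimeIndex(fixes["timestamp"])
    fixes["year"] = ts.year
    fixes["window"] = (week_of_year(fixes["timestamp"]) if scale == "week"
                       else ts.month)
    agg = {c: "mean" for c in covariates if c in fixes.columns}
    missing = [c for c in covariates if c not in fixes.columns]
    if missing:
        raise ValueError(f"covariates missing from step table: {missing}")
    cov = fixes.groupby(["id", "year", "window"], as_index=False).agg(agg)
    data = rec.merge(cov, on=["id", "year", "window"], how="left")
    data["rhythmic"] = (data["class"] != "arrhythmic").astype(int)
    data = data.dropna(subset=list(covariates))
    data = scale_covariates(data, covariates)
    data["id_year"] = data["id"].astype(str) + ":" + data["year"].astype(str)
    return data


# ---------------------------------------------------------------------------
# Laplace-approximation binomial GLMM


@dataclass
class _RandomStructure:
    names: list[str]
    codes: np.ndarray      # (n_obs, n_components) integer level codes
    sizes: list[int]
    offsets: np.ndarray    # start column of each component in u

    @property
    def q(self) -> int:
        return int(sum(self.sizes))


class BinomialGLMM:
    """Bernoulli mixed model with independent random intercepts.

    Parameters
    ----------
    endog : 0/1 response array.
    exog : fixed-effects design matrix (include the intercept column).
    exog_names : column labels for reporting.
    groups : mapping component name -> per-observation level labels; each
        component contributes i.i.d. N(0, sigma_c^2) intercepts.  An empty
        mapping reduces the model to plain logistic regression.
    """

    def __init__(self, endog, exog, exog_names=None, groups=None):
        self.y = np.asarray(endog, dtype=float)
        self.x = np.asarray(exog, dtype=float)
        if self.x.ndim != 2 or len(self.x) != len(self.y):
            raise ValueError("exog must be (n_obs, p) aligned with endog")
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if self.y.min() == self.y.max():
            raise ValueError("response is constant; nothing to model")
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{i}" for i in range(self.x.shape[1])])
        groups = groups or {}
        names, codes, sizes = [], [], []
        for name, labels in groups.items():
            lab = pd.Categorical(np.asarray(labels))
            if len(lab.categories) < 2:
                continue    # a single level carries no variance information
            names.append(name)
            codes.append(lab.codes.astype(int))
            sizes.append(len(lab.categories))
        offsets = np.concatenate([[0], np.cumsum(sizes)])[:len(sizes)] \
            if sizes else np.zeros(0, dtype=int)
        self.re = _RandomStructure(
            names=names,
            codes=np.column_stack(codes) if codes else
            np.zeros((len(self.y), 0), dtype=int),
            sizes=sizes, offsets=np.asarray(offsets, dtype=int))
        self._z = self._build_z()

    def _build_z(self) -> np.ndarray:
        n = len(self.y)
        z = np.zeros((n, self.re.q))
        for c in range(len(self.re.sizes)):
            z[np.arange(n), self.re.offsets[c] + self.re.codes[:, c]] = 1.0
        return z

    def _d_inv(self, sigmas: np.ndarray) -> np.ndarray:
        parts = [np.full(self.re.sizes[c], 1.0 / max(sigmas[c], 1e-8) ** 2)
                 for c in range(len(self.re.sizes))]
        return np.concatenate(parts) if parts else np.zeros(0)

    def _penalized_mode(self, beta, sigmas, u0=None):
        """Inner Newton solve for the random-effect mode given (beta, sigma)."""
        z = self._z
        d_inv = self._d_inv(sigmas)
        u = np.zeros(self.re.q) if u0 is None or len(u0) != self.re.q \
            else u0.copy()
        xb = self.x @ beta
        if self.re.q == 0:
            return u, np.zeros((0, 0)), d_inv
        for _ in range(50):
            eta = xb + z @ u
            p = expit(eta)
            g = z.T @ (self.y - p) - d_inv * u
            w = p * (1 - p)
            h = (z.T * w) @ z
            h[np.diag_indices_from(h)] += d_inv
            try:
                delta = np.linalg.solve(h, g)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(h, g, rcond=None)[0]
            # step-halving on the penalized objective
            obj0 = self._pen_ll(xb, u, d_inv)
            step = 1.0
            for _ in range(20):
                u_new = u + step * delta
                if self._pen_ll(xb, u_new, d_inv) >= obj0 - 1e-12:
                    break
                step *= 0.5
            u = u_new
            if np.max(np.abs(step * delta)) < 1e-9:
                break
        eta = xb + z @ u
        p = expit(eta)
        w = p * (1 - p)
        h = (z.T * w) @ z
        h[np.diag_indices_from(h)] += d_inv
        return u, h, d_inv

    def _pen_ll(self, xb, u, d_inv):
        eta = xb + self._z @ u
        ll = np.sum(self.y * eta - np.logaddexp(0.0, eta))
        return ll - 0.5 * np.sum(d_inv * u ** 2)

    def _laplace_nll(self, params, warm):
        p_fix = self.x.shape[1]
        beta = params[:p_fix]
        sigmas = np.exp(params[p_fix:])
        u, h, d_inv = self._penalized_mode(beta, sigmas, u0=warm.get("u"))
        warm["u"] = u
        pen = self._pen_ll(self.x @ beta, u, d_inv)
        if self.re.q:
            sign, logdet_h = np.linalg.slogdet(h)
            if sign <= 0:
                return 1e10
            log_det_d = -np.sum(np.log(d_inv))
            return -(pen - 0.5 * (log_det_d + logdet_h))
        return -pen

    def fit(self, maxiter: int = 200, start=None) -> "BinomialGLMMResults":
        p_fix = self.x.shape[1]
        n_sig = len(self.re.sizes)
        if start is None:
            start = np.zeros(p_fix + n_sig)
            start[p_fix:] = np.log(0.5)
        warm: dict = {}
        res = minimize(self._laplace_nll, start, args=(warm,),
                       method="L-BFGS-B",
                       bounds=[(None, None)] * p_fix + [(-10.0, 3.0)] * n_sig,
                       options={"maxiter": maxiter, "ftol": 1e-12,
                                "gtol": 1e-8})
        beta = res.x[:p_fix]
        sigmas = np.exp(res.x[p_fix:])
        u, h, d_inv = self._penalized_mode(beta, sigmas)
        cov_beta = self._beta_cov(beta, u, d_inv)
        separation = bool(np.any(np.abs(beta) > 15.0))
        return BinomialGLMMResults(
            model=self, params=beta, cov_params=cov_beta,
            vc_sd=dict(zip(self.re.names, sigmas)), u=u,
            llf=float(-res.fun), converged=bool(res.success),
            separation=separation)

    def _beta_cov(self, beta, u, d_inv) -> np.ndarray:
        """(beta, beta) block of the inverse joint Hessian at the mode."""
        eta = self.x @ beta + self._z @ u
        p = expit(eta)
        w = p * (1 - p)
        a = (self.x.T * w) @ self.x
        if self.re.q:
            b = (self.x.T * w) @ self._z
            c = (self._z.T * w) @ self._z
            c[np.diag_indices_from(c)] += d_inv
            a = a - b @ np.linalg.solve(c, b.T)
        return np.linalg.inv(a)


@dataclass
class BinomialGLMMResults:
    """Fixed effects, their uncertainty, and variance components."""

    model: BinomialGLMM
    params: np.ndarray
    cov_params: np.ndarray
    vc_sd: dict[str, float]
    u: np.ndarray
    llf: float
    converged: bool
    separation: bool = False
    bse: np.ndarray = field(init=False)
    pvalues: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.bse = np.sqrt(np.diag(self.cov_params))
        z = self.params / self.bse
        self.pvalues = 2.0 * norm.sf(np.abs(z))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def predict(self, exog: np.ndarray) -> np.ndarray:
        """Marginal predicted probability at the random-effect mean (u = 0)."""
        return expit(np.asarray(exog, dtype=float) @ self.params)

    def coef_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "term": self.model.exog_names,
            "estimate": self.params, "se": self.bse,
            "p": self.pvalues, "ci_low": ci[:, 0], "ci_high": ci[:, 1]})

    def summary(self) -> str:
        lines = [f"Binomial GLMM (logit link, Laplace), n = {len(self.model.y)}",
                 f"log-likelihood {self.llf:.2f}   converged {self.converged}"]
        if self.separation:
            lines.append("WARNING: possible complete separation "
                         "(|coefficient| > 15)")
        lines.append("")
        lines.append(f"{'term':<16}{'estimate':>10}{'se':>9}{'p':>10}")
        for name, b, s, p in zip(self.model.exog_names, self.params,
                                 self.bse, self.pvalues):
            lines.append(f"{name:<16}{b:>10.3f}{s:>9.3f}{p:>10.2g}")
        if self.vc_sd:
            lines.append("")
            for k, v in self.vc_sd.items():
                lines.append(f"random intercept sd ({k}): {v:.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model-level helpers


def fit_rhythm_glmm(data: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                    ) -> BinomialGLMMResults:
    """Fit the rhythmicity GLMM for one metric's model data.

    Random intercepts: year, and individual nested within year (id x year
    cells).  Components with a single observed level are dropped with a
    note in the result's variance table rather than fabricated.
    """
    if data["rhythmic"].nunique() < 2:
        raise ValueError("complete separation: response is constant")
    if data["id"].nunique() < 2:
        raise ValueError("need at least 2 individuals for the mixed model")
    x = np.column_stack([np.ones(len(data))]
                        + [data[c].to_numpy(float) for c in covariates])
    groups = {"year": data["year"].to_numpy(),
              "id_year": data["id_year"].to_numpy()}
    model = BinomialGLMM(data["rhythmic"].to_numpy(), x,
                         exog_names=["intercept", *covariates], groups=groups)
    return model.fit()


def predict_response_curve(results: BinomialGLMMResults, data: pd.DataFrame,
                           covariate: str, covariates=DEFAULT_COVARIATES,
                           n_boot: int = 100, seed: int | None = 0,
                           n_grid: int = 50) -> pd.DataFrame:
    """Predicted rhythmicity probability over one covariate's range.

    Other covariates are held at 0 (their scaled mean).  The 95 % band is a
    parametric bootstrap: fixed effects are redrawn from their asymptotic
    normal distribution and the curve recomputed ``n_boot`` times.
    """
    if covariate not in covariates:
        raise ValueError(f"unknown covariate {covariate!r}")
    rng = np.random.default_rng(seed)
    grid = np.linspace(data[covariate].min(), data[covariate].max(), n_grid)
    x = np.zeros((n_grid, len(covariates) + 1))
    x[:, 0] = 1.0
    x[:, 1 + list(covariates).index(covariate)] = grid
    fit = results.predict(x)
    draws = rng.multivariate_normal(results.params, results.cov_params,
                                    size=n_boot)
    curves = expit(x @ draws.T)
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=1)
    lo = np.minimum(lo, fit)
    hi = np.maximum(hi, fit)
    return pd.DataFrame({"covariate": covariate, "x": grid,
                         "fit": fit, "lo": lo, "hi": hi})


def ndvi_group_contrast(records: pd.DataFrame, steps: pd.DataFrame,
                        weeks: tuple[int, int] = (23, 37),
                        metric: str = "foraging") -> pd.DataFrame:
    """Growing-season NDVI contrast between rhythmic and arrhythmic weeks.

    For each week in the range, individuals are split by that week's
    foraging-metric rhythm class (rhythmic = any non-arrhythmic class) and
    the NDVI over their fixes is averaged with a normal-approximation 95 %
    CI.  Weeks where a group is empty are reported with NaN, not zero.
    """
    from .classify import week_of_year

    rec = records[(records["metric"] == metric)
                  & (records["scale"] == "week")].copy()
    fixes = steps.copy()
    fixes["year"] = pd.DatetimeIndex(fixes["timestamp"]).year
    fixes["window"] = week_of_year(fixes["timestamp"])
    rows = []
    for wk in range(weeks[0], weeks[1] + 1):
        r = rec[rec["window"] == wk]
        for group, sub in (("rhythmic", r[r["class"] != "arrhythmic"]),
                           ("arrhythmic", r[r["class"] == "arrhythmic"])):
            sel = fixes.merge(sub[["id", "year", "window"]],
                              on=["id", "year", "window"], how="inner")
            n = len(sel)
            if n == 0:
                rows.append({"week": wk, "group": group, "mean_ndvi": np.nan,
                             "lo": np.nan, "hi": np.nan, "n_fixes": 0})
                continue
            m = sel["ndvi"].mean()
            se = sel["ndvi"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            rows.append({"week": wk, "group": group, "mean_ndvi": m,
                         "lo": m - 1.96 * se, "hi": m + 1.96 * se,
                         "n_fixes": n})
    return pd.DataFrame(rows)
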