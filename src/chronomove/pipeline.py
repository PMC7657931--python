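"""End-to-end orchestration: tracks -> states -> rhythms -> covariate models.

Runs the full analysis chain over a simulated or user-supplied telemetry
table and writes every stage's output as CSV into one directory, together
with a manifest recording the configuration, seeds and row counts so any
run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, glmm, hmm, preprocess, simulate, transitions

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "summarize_run"]

METRICS = ("foraging", "resting", "transit", "displacement")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """All knobs of the full analysis chain."""

    input_csv: str | None = None          # None -> simulate
    sim: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)
    output_dir: str = "chronomove_run"
    scale: str = "week"                   # week | month | both
    alpha: float = 0.05
    n_states: int = 3
    n_restarts: int = 10
    hmm_per_season: bool = True
    max_speed_m_per_h: float = preprocess.DEFAULT_MAX_SPEED_M_PER_H
    pvalue_method: str = "permutation"
    n_perm: int = 999
    n_boot_transitions: int = 1000
    n_boot_curves: int = 100
    fix_interval_h: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.scale not in ("week", "month", "both"):
            raise ValueError("scale must be week, month or both")

    @property
    def scales(self) -> tuple[str, ...]:
        return ("week", "month") if self.scale == "both" else (self.scale,)


def _stage(name, fn, log, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:          # noqa: BLE001 - re-raised with stage name
        raise PipelineError(name, exc) from exc
    log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 2)})
    return out


def _fit_hmm_stage(steps: pd.DataFrame, config: PipelineConfig):
    """Fit the movement HMM, per snow season when configured, and decode."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]).
                                generate_state(1)[0] % (2 ** 31))
    params = []
    if config.hmm_per_season and "snow_m" in steps.columns:
        snow = hmm.season_split(steps, fix_interval_h=config.fix_interval_h)
        parts = []
        for label, mask in (("snow_covered", snow), ("snow_free", ~snow)):
            sub = steps.loc[mask]
            if len(sub) < 200:
                continue
            model = hmm.MovementHMM(sub, n_states=config.n_states)
            res = model.fit(n_restarts=config.n_restarts,
                            seed=int(rng.integers(2 ** 31)))
            d = res.params_dict()
            d["season"] = label
            params.append(d)
            parts.append(res.state_probabilities())
        probs = pd.concat(parts).sort_values(["id", "timestamp"]) \
            .reset_index(drop=True)
    else:
        model = hmm.MovementHMM(steps, n_states=config.n_states)
        res = model.fit(n_restarts=config.n_restarts,
                        seed=int(rng.integers(2 ** 31)))
        d = res.params_dict()
        d["season"] = "all"
        params.append(d)
        probs = res.state_probabilities()
    return probs, params


def _activity_series(probs: pd.DataFrame, steps: pd.DataFrame):
    """Per-individual activity series for the four metrics."""
    merged = steps.merge(probs, on=["id", "timestamp"], how="inner")
    series = {}
    for metric, col in (("foraging", "p_foraging"), ("resting", "p_resting"),
                        ("transit", "p_transiting"),
                        ("displacement", "log_disp")):
        series[metric] = {
            ind: (g["timestamp"], g[col].to_numpy(float))
            for ind, g in merged.groupby("id", sort=False)}
    return series


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order and write all artifacts.

    Returns the output directory.  A failing stage aborts with the stage
    named in the exception; artifacts written before the failure are kept.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    counts: dict[str, int] = {}

    # -- input ------------------------------------------------------------
    if config.input_csv is None:
        tracks = _stage("simulate", simulate.simulate_tracks, log, config.sim)
        simulate.write_tracks(tracks, outdir / "tracks.csv")
        simulate.write_config(config.sim, outdir / "simulation_config.txt")
    else:
        tracks = _stage("read", preprocess.read_tracks, log, config.input_csv)
    counts["fixes_in"] = len(tracks)
    if tracks.empty:
        raise PipelineError("preprocess", ValueError("input track table is empty"))

    # -- preprocess --------------------------------------------------------
    def _pre():
        clean, removals = preprocess.filter_impossible_moves(
            tracks, max_speed=config.max_speed_m_per_h)
        steps = preprocess.compute_steps(clean,
                                         fix_interval_h=config.fix_interval_h)
        return clean, removals, steps

    clean, removals, steps = _stage("preprocess", _pre, log)
    removals.to_csv(outdir / "removed_fixes.csv", index=False)
    preprocess.write_steps(steps, outdir / "steps.csv")
    counts["fixes_removed"] = len(removals)
    counts["steps"] = len(steps)

    # -- HMM ---------------------------------------------------------------
    probs, hmm_params = _stage("hmm", _fit_hmm_stage, log, steps, config)
    with open(outdir / "hmm_params.json", "w") as fh:
        json.dump(hmm_params, fh, indent=2)
    p = probs.copy()
    p["timestamp"] = pd.to_datetime(p["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    p.to_csv(outdir / "state_probabilities.csv", index=False,
             float_format="%.6f")
    counts["decoded_fixes"] = len(probs)
    budget = hmm.state_budget(probs, scale=config.scales[0],
                              fix_interval_h=config.fix_interval_h)
    budget.to_csv(outdir / "state_budget.csv", index=False,
                  float_format="%.5f")

    # -- classification ----------------------------------------------------
    series = _activity_series(probs, steps)

    def _classify():
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2]).generate_state(1)[0]
            % (2 ** 31))
        frames = []
        for scale in config.scales:
            for metric, per_id in series.items():
                for ind, (ts, vals) in per_id.items():
                    frames.append(classify.classify_series(
                        ts, vals, individual=ind, metric=metric, scale=scale,
                        alpha=config.alpha, method=config.pvalue_method,
                        n_perm=config.n_perm,
                        fix_interval_h=config.fix_interval_h, rng=rng))
        return pd.concat(frames, ignore_index=True)

    records = _stage("classify", _classify, log)
    records.to_csv(outdir / "rhythm_records.csv", index=False,
                   float_format="%.6f")
    counts["windows_classified"] = len(records)
    classify.summarize_classes(records).to_csv(
        outdir / "class_summary.csv", index=False, float_format="%.4f")

    # -- transitions -------------------------------------------------------
    def _transitions():
        frames = []
        for scale in config.scales:
            for metric in METRICS:
                sub = records[(records["metric"] == metric)
                              & (records["scale"] == scale)]
                try:
                    tm = transitions.bootstrap_transitions(
                        sub, n_sims=config.n_boot_transitions,
                        seed=(config.seed * 7 + 3) % (2 ** 31))
                except ValueError:
                    continue
                f = tm.to_frame(metric=metric)
                f["scale"] = scale
                frames.append(f)
        return pd.concat(frames, ignore_index=True)

    trans = _stage("transitions", _transitions, log)
    trans.to_csv(outdir / "transition_matrices.csv", index=False,
                 float_format="%.4f")

    # -- GLMM + contrasts --------------------------------------------------
    def _models():
        coefs, curves = [], []
        scale = config.scales[0]
        for metric in METRICS:
            try:
                data = glmm.build_rhythm_model_data(
                    records[records["scale"] == scale], steps, metric,
                    scale=scale)
                fit = glmm.fit_rhythm_glmm(data)
            except ValueError:
                continue
            tab = fit.coef_table()
            tab.insert(0, "metric", metric)
            coefs.append(tab)
            for cov in glmm.DEFAULT_COVARIATES:
                c = glmm.predict_response_curve(
                    fit, data, cov, n_boot=config.n_boot_curves,
                    seed=(config.seed * 11 + 5) % (2 ** 31))
                c.insert(0, "metric", metric)
                curves.append(c)
        contrast = glmm.ndvi_group_contrast(records, steps)
        return (pd.concat(coefs, ignore_index=True) if coefs else
                pd.DataFrame(), pd.concat(curves, ignore_index=True)
                if curves else pd.DataFrame(), contrast)

    coefs, curves, contrast = _stage("glmm", _models, log)
    coefs.to_csv(outdir / "glmm_coefficients.csv", index=False,
                 float_format="%.5f")
    curves.to_csv(outdir / "prediction_curves.csv", index=False,
                  float_format="%.5f")
    contrast.to_csv(outdir / "ndvi_contrast.csv", index=False,
                    float_format="%.5f")

    # -- manifest ----------------------------------------------------------
    manifest = {
        "config": _config_dict(config),
        "row_counts": counts,
        "stages": log,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    sim = d.get("sim", {})
    for k, v in list(sim.items()):
        if isinstance(v, np.ndarray):
            sim[k] = v.tolist()
        elif hasattr(v, "isoformat"):
            sim[k] = v.isoformat()
    return d


def summarize_run(output_dir) -> str:
    """Human-readable report of a completed run."""
    outdir = Path(output_dir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {outdir}")
    manifest = json.loads(manifest_path.read_text())
    lines = [f"chronomove run in {outdir}",
             f"row counts: {manifest['row_counts']}", ""]
    def _read(path):
        try:
            return pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return pd.DataFrame()

    rec_path = outdir / "rhythm_records.csv"
    if rec_path.exists():
        records = _read(rec_path)
        if records.empty:
            lines.append("no eligible windows were classified")
        else:
            summary = classify.summarize_classes(records)
            lines.append("rhythm classes (% of windows):")
            for metric, g in summary.groupby("metric", sort=False):
                parts = ", ".join(f"{r['class']} {r['pct_windows']:.1f}%"
                                  for _, r in g.iterrows())
                lines.append(f"  {metric}: {parts}")
    trans_path = outdir / "transition_matrices.csv"
    if trans_path.exists():
        trans = _read(trans_path)
        if not trans.empty:
            lines.append("")
            lines.append("probability of remaining in the same rhythm:")
            diag = trans[trans["from_class"] == trans["to_class"]]
            for metric, g in diag.groupby("metric", sort=False):
                parts = ", ".join(
                    f"{r['from_class']} {r['probability']:.2f}"
                    for _, r in g.iterrows() if pd.notna(r["probability"]))
                lines.append(f"  {metric}: {parts}")
    coef_path = outdir / "glmm_coefficients.csv"
    if coef_path.exists():
        coefs = _read(coef_path)
        if not coefs.empty:
            lines.append("")
            lines.append("GLMM fixed-effect signs (p < 0.05 starred):")
            for metric, g in coefs.groupby("metric", sort=False):
                parts = ", ".join(
                    f"{r['term']} {'+' if r['estimate'] > 0 else '-'}"
                    f"{'*' if r['p'] < 0.05 else ''}"
                    for _, r in g.iterrows() if r["term"] != "intercept")
                lines.append(f"  {metric}: {parts}")
    return "\n".join(lines)
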