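"""Track cleaning and movement-variable derivation.

Reads hourly telemetry tables (id, timestamp, x_m, y_m plus optional
covariate columns), removes physically impossible fixes with an iterative
speed filter, and derives the step series consumed by the behavioural HMM
and periodicity stages: Euclidean step lengths, signed turning angles, and
log-transformed hourly net displacement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_tracks",
    "filter_impossible_moves",
    "compute_steps",
    "write_steps",
]

#: offset added before the log transform so a zero displacement maps to 0
LOG_DISPLACEMENT_OFFSET_M = 1.0

#: generous upper bound on sustained hourly travel for a large ungulate
DEFAULT_MAX_SPEED_M_PER_H = 15_000.0


def read_tracks(path) -> pd.DataFrame:
    """Read a telemetry CSV with at least id, timestamp, x_m, y_m columns."""
    df = pd.read_csv(path)
    required = {"id", "timestamp", "x_m", "y_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    df = df.sort_values(["id", "timestamp"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["id", "timestamp"]).any():
        raise ValueError("duplicate id/timestamp rows in track CSV")
    return df


def _neighbour_speeds(t_h: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Speed (m/h) from each fix to its previous and next neighbour."""
    d = np.hypot(np.diff(x), np.diff(y))
    dt = np.diff(t_h)
    seg = d / dt
    to_prev = np.concatenate([[np.nan], seg])
    to_next = np.concatenate([seg, [np.nan]])
    return to_prev, to_next


def filter_impossible_moves(track: pd.DataFrame,
                            max_speed: float = DEFAULT_MAX_SPEED_M_PER_H,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively remove fixes implying impossible travel speeds.

    A fix is removed when the implied speed to *every* existing neighbour
    (previous and next fix of the same individual) exceeds ``max_speed``;
    removal is repeated until stable, so isolated position spikes are
    deleted without discarding the genuine fixes around them.  Returns the
    cleaned table and a removal log.
    """
    if track.empty:
        raise ValueError("empty track")
    out = []
    removed = []
    for ind, g in track.groupby("id", sort=False):
        g = g.sort_values("timestamp")
        if len(g) < 2:
            out.append(g)
            continue
        while True:
            t_h = (g["timestamp"] - g["timestamp"].iloc[0]) / pd.Timedelta(hours=1)
            to_prev, to_next = _neighbour_speeds(
                t_h.to_numpy(), g["x_m"].to_numpy(), g["y_m"].to_numpy())
            bad_prev = np.where(np.isnan(to_prev), True, to_prev > max_speed)
            bad_next = np.where(np.isnan(to_next), True, to_next > max_speed)
            bad = bad_prev & bad_next
            # endpoints only have one real neighbour
            bad[0] = to_next[0] > max_speed if len(g) > 1 else False
            bad[-1] = to_prev[-1] > max_speed if len(g) > 1 else False
            if not bad.any():
                break
            speeds = np.fmax(np.nan_to_num(to_prev), np.nan_to_num(to_next))
            for idx in np.flatnonzero(bad):
                removed.append({"id": ind,
                                "timestamp": g["timestamp"].iloc[idx],
                                "speed_m_per_h": speeds[idx]})
            g = g.loc[~bad]
            if len(g) < 2:
                break
        out.append(g)
    clean = pd.concat(out).sort_values(["id", "timestamp"]).reset_index(drop=True)
    log = pd.DataFrame(removed, columns=["id", "timestamp", "speed_m_per_h"])
    return clean, log


def compute_steps(track: pd.DataFrame, fix_interval_h: float = 1.0,
                  gap_factor: float = 1.5) -> pd.DataFrame:
    """Derive the per-step movement series from a cleaned track.

    One row per consecutive fix pair, indexed by the *ending* fix.  Columns:

    - ``step_m`` — Euclidean distance between the fixes (the hourly net
      displacement when sampling is nominal);
    - ``log_disp`` — ``ln(step_m + 1)``, the variance-stabilized metric;
    - ``turn_rad`` — signed heading change in (-pi, pi], NaN (and
      ``turn_defined`` False) after a zero-length or gap step;
    - ``gap`` — True when the pair spans more than ``gap_factor`` nominal
      intervals (a missed fix); gap steps are excluded from HMM emissions;
    - ``segment`` — index of the contiguous gap-free run, per individual.

    Covariate columns present on the track are carried through from the
    ending fix.
    """
    frames = []
    carry = [c for c in track.columns
             if c not in ("id", "timestamp", "x_m", "y_m")]
    for ind, g in track.groupby("id", sort=False):
        g = g.sort_values("timestamp")
        if len(g) < 3:
            raise ValueError(
                f"individual {ind!r}: need at least 3 fixes to define turning angles")
        t = g["timestamp"].to_numpy()
        x = g["x_m"].to_numpy()
        y = g["y_m"].to_numpy()
        dt_h = np.diff(t) / np.timedelta64(1, "h")
        dx = np.diff(x)
        dy = np.diff(y)
        step = np.hypot(dx, dy)
        gap = dt_h > gap_factor * fix_interval_h

        heading = np.arctan2(dy, dx)            # undefined for zero steps
        turn = np.full(len(step), np.nan)
        last_heading = np.nan
        for i in range(len(step)):
            if gap[i]:
                last_heading = np.nan
            if step[i] == 0.0:
                last_heading = np.nan   # heading through a zero step is undefined
                continue
            if np.isfinite(last_heading):
                a = heading[i] - last_heading
                turn[i] = np.arctan2(np.sin(a), np.cos(a))
            last_heading = heading[i]
        turn_defined = np.isfinite(turn)

        df = pd.DataFrame({
            "id": ind,
            "timestamp": g["timestamp"].to_numpy()[1:],
            "dt_h": dt_h,
            "step_m": step,
            "log_disp": np.log(step + LOG_DISPLACEMENT_OFFSET_M),
            "turn_rad": turn,
            "turn_defined": turn_defined,
            "gap": gap,
            "segment": np.cumsum(gap),
        })
        for c in carry:
            df[c] = g[c].to_numpy()[1:]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_steps(steps: pd.DataFrame, path) -> None:
    out = steps.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.6f")
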