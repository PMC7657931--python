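"""Windowed classification of activity series into rhythm classes.

Each individual-week (or individual-month) of an activity series — the
posterior probability of one behavioural state, or log net displacement —
is scanned for significant Lomb-Scargle peaks in an ultradian band
([2, 18) h) and a circadian band ([18, 36] h) and assigned one of four
classes: ``ultradian``, ``circadian``, ``ultradian_circadian`` (peaks in
both bands) or ``arrhythmic`` (no significant peak).

When both band peaks are significant, lie within 18 h of each other in
period, and the smaller has less than one-third the power of the larger,
the smaller peak is rejected as a likely spectral artefact before
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .periodicity import lomb_scargle, peak_pvalue

__all__ = [
    "BandPeak",
    "make_windows",
    "detect_band_peaks",
    "reject_minor_peak",
    "classify_window",
    "classify_series",
    "summarize_classes",
    "ULTRADIAN_BAND",
    "CIRCADIAN_BAND",
    "RHYTHM_CLASSES",
]

ULTRADIAN_BAND = (2.0, 18.0)   # [2, 18) h
CIRCADIAN_BAND = (18.0, 36.0)  # [18, 36] h
RHYTHM_CLASSES = ("arrhythmic", "ultradian_circadian", "circadian", "ultradian")

#: minimum data coverage for window eligibility, in days
MIN_DAYS = {"week": 6.0, "month": 28.0}

#: height ratio below which a nearby secondary peak is discarded
MINOR_PEAK_RATIO = 1.0 / 3.0
#: maximum period separation (h) for the rejection rule to apply
MINOR_PEAK_WINDOW_H = 18.0


@dataclass
class BandPeak:
    band: tuple[float, float]
    period_h: float
    power: float
    pvalue: float

    @property
    def is_ultradian(self) -> bool:
        return self.band[1] <= ULTRADIAN_BAND[1]


@dataclass
class WindowSeries:
    """One eligible calendar window of one individual's activity series."""

    id: str
    scale: str                  # week | month
    year: int
    window: int                 # week-of-year (from 1 Jan) or month number
    times_h: np.ndarray         # hours since window start
    values: np.ndarray
    coverage_days: float

    @property
    def ordinal(self) -> int:
        per_year = 53 if self.scale == "week" else 12
        return self.year * per_year + (self.window - 1)


def week_of_year(timestamps: pd.Series) -> np.ndarray:
    """Seven-day week index counted from 1 January (week 1 = days 1-7)."""
    return ((pd.DatetimeIndex(timestamps).dayofyear - 1) // 7 + 1).to_numpy()


def make_windows(timestamps: pd.Series, values: np.ndarray, *,
                 individual: str, scale: str = "week",
                 min_days: float | None = None,
                 fix_interval_h: float = 1.0) -> list[WindowSeries]:
    """Split a series into eligible calendar-aligned windows.

    Weeks are numbered from 1 January, months are calendar months.  A
    window is kept only when its data coverage (fix count times the nominal
    interval) reaches ``min_days`` — 6 days for weeks, 28 for months — so
    sparsely observed windows never enter the periodogram.
    """
    if scale not in MIN_DAYS:
        raise ValueError("scale must be 'week' or 'month'")
    if min_days is None:
        min_days = MIN_DAYS[scale]
    ts = pd.DatetimeIndex(timestamps)
    values = np.asarray(values, dtype=float)
    year = ts.year.to_numpy()
    win = week_of_year(pd.Series(ts)) if scale == "week" else ts.month.to_numpy()
    order = np.lexsort((ts.asi8, win, year))
    out: list[WindowSeries] = []
    df = pd.DataFrame({"t": ts.asi8, "y": values, "year": year, "win": win}
                      ).iloc[order]
    for (yr, w), g in df.groupby(["year", "win"], sort=True):
        coverage = len(g) * fix_interval_h / 24.0
        if coverage < min_days:
            continue
        t_ns = g["t"].to_numpy()
        out.append(WindowSeries(
            id=individual, scale=scale, year=int(yr), window=int(w),
            times_h=(t_ns - t_ns[0]) / 3.6e12,
            values=g["y"].to_numpy(), coverage_days=coverage))
    return out


def detect_band_peaks(window: WindowSeries, *, alpha: float = 0.05,
                      method: str = "permutation", n_perm: int = 999,
                      oversampling: float = 4.0,
                      rng: np.random.Generator | None = None,
                      ) -> list[BandPeak]:
    """Maximum-power peak (with p-value) in each of the two period bands."""
    peaks = []
    for band in (ULTRADIAN_BAND, CIRCADIAN_BAND):
        res = lomb_scargle(window.times_h, window.values, band[0], band[1],
                           oversampling=oversampling)
        res = peak_pvalue(window.times_h, window.values, res, method=method,
                          n_perm=n_perm, rng=rng)
        peaks.append(BandPeak(band=band, period_h=res.peak_period,
                              power=res.peak_power, pvalue=res.peak_pvalue))
    return peaks


def reject_minor_peak(peaks: list[BandPeak], *, alpha: float = 0.05,
                      ) -> tuple[list[BandPeak], list[BandPeak]]:
    """Apply the one-third-height rejection rule to significant peaks.

    Returns (retained, rejected).  Only peaks with p < alpha enter; when
    exactly two are significant, separated by at most 18 h in period, and
    the smaller's power is below one-third of the larger's, the smaller is
    rejected.
    """
    sig = [p for p in peaks if p.pvalue < alpha]
    if len(sig) != 2:
        return sig, []
    a, b = sig
    lo, hi = (a, b) if a.power < b.power else (b, a)
    if (abs(a.period_h - b.period_h) <= MINOR_PEAK_WINDOW_H
            and lo.power < MINOR_PEAK_RATIO * hi.power):
        return [hi], [lo]
    return sig, []


def classify_window(retained: list[BandPeak]) -> str:
    """Four-class assignment from the retained significant band peaks."""
    has_u = any(p.is_ultradian for p in retained)
    has_c = any(not p.is_ultradian for p in retained)
    if has_u and has_c:
        return "ultradian_circadian"
    if has_u:
        return "ultradian"
    if has_c:
        return "circadian"
    return "arrhythmic"


def classify_series(timestamps: pd.Series, values: np.ndarray, *,
                    individual: str, metric: str, scale: str = "week",
                    alpha: float = 0.05, method: str = "permutation",
                    n_perm: int = 999, oversampling: float = 4.0,
                    min_days: float | None = None,
                    fix_interval_h: float = 1.0,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Classify every eligible window of one activity series.

    Returns the rhythmicity record table: one row per window with the
    assigned class, the retained ultradian/circadian peak periods, powers
    and p-values, and any rejected peak with its period.
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for w in make_windows(timestamps, values, individual=individual,
                          scale=scale, min_days=min_days,
                          fix_interval_h=fix_interval_h):
        try:
            peaks = detect_band_peaks(w, alpha=alpha, method=method,
                                      n_perm=n_perm, oversampling=oversampling,
                                      rng=rng)
        except ValueError:      # zero-variance window: nothing periodic
            rows.append(_record_row(w, metric, "arrhythmic", [], [], []))
            continue
        retained, rejected = reject_minor_peak(peaks, alpha=alpha)
        cls = classify_window(retained)
        rows.append(_record_row(w, metric, cls, peaks, retained, rejected))
    cols = ["id", "scale", "year", "window", "ordinal", "metric", "class",
            "ultradian_period_h", "ultradian_power", "ultradian_p",
            "circadian_period_h", "circadian_power", "circadian_p",
            "rejected_period_h", "coverage_days"]
    return pd.DataFrame(rows, columns=cols)


def _record_row(w: WindowSeries, metric: str, cls: str,
                peaks: list[BandPeak], retained: list[BandPeak],
                rejected: list[BandPeak]) -> dict:
    row = {"id": w.id, "scale": w.scale, "year": w.year, "window": w.window,
           "ordinal": w.ordinal, "metric": metric, "class": cls,
           "ultradian_period_h": np.nan, "ultradian_power": np.nan,
           "ultradian_p": np.nan, "circadian_period_h": np.nan,
           "circadian_power": np.nan, "circadian_p": np.nan,
           "rejected_period_h": np.nan, "coverage_days": w.coverage_days}
    for p in retained:
        key = "ultradian" if p.is_ultradian else "circadian"
        row[f"{key}_period_h"] = p.period_h
        row[f"{key}_power"] = p.power
        row[f"{key}_p"] = p.pvalue
    if rejected:
        row["rejected_period_h"] = rejected[0].period_h
    return row


def summarize_classes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-metric class summary: counts, percentages, mean +/- sd peak period.

    For the two-peak class both band means are reported; for the arrhythmic
    class no peak statistics are given (its peaks are not significant).
    """
    rows = []
    for metric, g in records.groupby("metric", sort=False):
        n_tot = len(g)
        for cls in RHYTHM_CLASSES:
            sub = g[g["class"] == cls]
            row = {"metric": metric, "class": cls, "n_windows": len(sub),
                   "pct_windows": 100.0 * len(sub) / n_tot if n_tot else np.nan,
                   "ultradian_mean_h": np.nan, "ultradian_sd_h": np.nan,
                   "circadian_mean_h": np.nan, "circadian_sd_h": np.nan}
            if cls in ("ultradian", "ultradian_circadian"):
                row["ultradian_mean_h"] = sub["ultradian_period_h"].mean()
                row["ultradian_sd_h"] = sub["ultradian_period_h"].std()
            if cls in ("circadian", "ultradian_circadian"):
                row["circadian_mean_h"] = sub["circadian_period_h"].mean()
                row["circadian_sd_h"] = sub["circadian_period_h"].std()
            rows.append(row)
    return pd.DataFrame(rows)
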