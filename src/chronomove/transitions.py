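"""Markov transition structure of rhythm classes across consecutive windows.

Pooled maximum-likelihood estimation of the 4x4 transition matrix over
(arrhythmic, ultradian_circadian, circadian, ultradian), counting only
transitions between consecutive eligible windows of the same individual —
a dropped or missing window breaks the chain — with an individual-level
block bootstrap for per-cell confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import RHYTHM_CLASSES

__all__ = ["TransitionMatrix", "estimate_transitions", "bootstrap_transitions"]


@dataclass
class TransitionMatrix:
    """Row-stochastic rhythm-class transition estimate with counts and CIs."""

    classes: tuple[str, ...]
    counts: np.ndarray                       # (k, k) transition counts
    probabilities: np.ndarray                # count(i->j) / count(i->.)
    ci_low: np.ndarray | None = field(default=None)
    ci_high: np.ndarray | None = field(default=None)
    n_sims: int | None = field(default=None)

    @property
    def empty_rows(self) -> np.ndarray:
        """Classes never observed as a transition origin (rows left NaN)."""
        return self.counts.sum(axis=1) == 0

    def to_frame(self, metric: str | None = None) -> pd.DataFrame:
        rows = []
        k = len(self.classes)
        for i in range(k):
            for j in range(k):
                rows.append({
                    "metric": metric, "from_class": self.classes[i],
                    "to_class": self.classes[j],
                    "probability": self.probabilities[i, j],
                    "ci_low": None if self.ci_low is None else self.ci_low[i, j],
                    "ci_high": None if self.ci_high is None else self.ci_high[i, j],
                    "count": int(self.counts[i, j]),
                })
        return pd.DataFrame(rows)


def _sequences(records: pd.DataFrame) -> list[np.ndarray]:
    """Per-individual runs of consecutive-window class indices."""
    idx = {c: i for i, c in enumerate(RHYTHM_CLASSES)}
    seqs = []
    for _, g in records.groupby("id", sort=False):
        g = g.sort_values("ordinal")
        ords = g["ordinal"].to_numpy()
        cls = g["class"].map(idx).to_numpy()
        breaks = np.flatnonzero(np.diff(ords) != 1) + 1
        for run in np.split(cls, breaks):
            if len(run) >= 2:
                seqs.append(run)
    return seqs


def _count(seqs: list[np.ndarray], k: int) -> np.ndarray:
    counts = np.zeros((k, k))
    for s in seqs:
        np.add.at(counts, (s[:-1], s[1:]), 1.0)
    return counts


def _normalize(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / totals
    return p      # rows with zero counts stay NaN, never fabricated


def estimate_transitions(records: pd.DataFrame) -> TransitionMatrix:
    """Pooled ML transition estimate for one metric's rhythm records.

    ``records`` is the per-window classification table of a single metric
    (columns id, ordinal, class).  Transitions are counted only where the
    next window immediately follows the previous one in the calendar.
    """
    k = len(RHYTHM_CLASSES)
    seqs = _sequences(records)
    if not seqs:
        raise ValueError("no consecutive-window transitions in the records")
    counts = _count(seqs, k)
    return TransitionMatrix(classes=RHYTHM_CLASSES, counts=counts,
                            probabilities=_normalize(counts))


def bootstrap_transitions(records: pd.DataFrame, n_sims: int = 1000,
                          seed: int | None = None,
                          ci: float = 0.95) -> TransitionMatrix:
    """Individual-level block bootstrap CIs for the transition matrix.

    Individuals (with their whole window sequences) are resampled with
    replacement ``n_sims`` times; percentile intervals are taken per cell.
    Cells whose origin row never occurs in a replicate are ignored for that
    replicate.
    """
    if n_sims < 20:
        raise ValueError("need n_sims >= 20")
    est = estimate_transitions(records)
    k = len(RHYTHM_CLASSES)
    by_id = {i: g for i, g in records.groupby("id", sort=False)}
    ids = list(by_id)
    rng = np.random.default_rng(seed)
    sims = np.full((n_sims, k, k), np.nan)
    seqs_by_id = {i: _sequences(g) for i, g in by_id.items()}
    for b in range(n_sims):
        pick = rng.choice(len(ids), size=len(ids), replace=True)
        seqs = [s for j in pick for s in seqs_by_id[ids[j]]]
        if not seqs:
            continue
        sims[b] = _normalize(_count(seqs, k))
    lo = (1.0 - ci) / 2.0
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ci_low = np.nanpercentile(sims, 100 * lo, axis=0)
        ci_high = np.nanpercentile(sims, 100 * (1 - lo), axis=0)
    est.ci_low = ci_low
    est.ci_high = ci_high
    est.n_sims = n_sims
    return est
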