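"""Static figure analogues: wavelet heat maps, rhythm timelines, curves."""

from __future__ import annotations

import numpy as np

from .periodicity import WaveletSpectrum


def plot_wavelet_spectrum(spectrum: WaveletSpectrum, ax=None, title=None):
    """Heat map of Morlet power over time x period with the COI shaded.

    Significant cells (if a mask was computed) are outlined by a contour.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    t_days = spectrum.times_h / 24.0
    mesh = ax.pcolormesh(t_days, spectrum.periods_h, spectrum.power,
                         shading="auto", cmap="viridis")
    if spectrum.significant is not None and spectrum.significant.any():
        ax.contour(t_days, spectrum.periods_h,
                   spectrum.significant.astype(float), levels=[0.5],
                   colors="white", linewidths=0.7)
    ax.plot(t_days, np.clip(spectrum.coi_max_period_h, None,
                            spectrum.periods_h[-1]), "w--", lw=0.8)
    for p in (12.0, 24.0):
        ax.axhline(p, color="grey", ls=":", lw=0.8)
    ax.set_yscale("log", base=2)
    ax.set_ylim(spectrum.periods_h[0], spectrum.periods_h[-1])
    ax.set_xlabel("time (days)")
    ax.set_ylabel("period (h)")
    if title:
        ax.set_title(title)
    plt.colorbar(mesh, ax=ax, label="power / scale")
    return ax


def plot_response_curves(curves, ax=None):
    """Predicted rhythmicity probability with bootstrap band per covariate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cov, g in curves.groupby("covariate"):
        line, = ax.plot(g["x"], g["fit"], label=cov)
        ax.fill_between(g["x"], g["lo"], g["hi"], alpha=0.2,
                        color=line.get_color())
    ax.set_xlabel("scaled covariate")
    ax.set_ylabel("P(rhythmic)")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
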