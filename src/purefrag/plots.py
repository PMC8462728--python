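"""Diagnostic figures: the log-log moment decay with its fitted asymptotic
line, and the overlay of self-similarly rescaled profiles."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_moment_fit", "plot_rescaled_profiles"]


def plot_moment_fit(moments, fit, ax=None):
    """Average length versus time (log-log) with the fitted piecewise model.

    The data points are crosses; the asymptotic line has slope -1/gamma_e
    and the level before t_e is flat.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = np.asarray(moments.times, dtype=float)
    m = moments.order(1.0)
    pos = t > 0
    ax.loglog(t[pos], m[pos], "rx", label="data $M_1(t)$")
    tt = np.geomspace(t[pos].min(), t[pos].max(), 200)
    model = np.where(
        tt <= fit.t_e, fit.C * fit.t_e ** (-1.0 / fit.gamma_e), fit.C * tt ** (-1.0 / fit.gamma_e)
    )
    ax.loglog(tt, model, "g-", label=rf"fit: $\gamma_e$ = {fit.gamma_e:.3g}, $T_e$ = {fit.t_e:.3g}")
    ax.set_xlabel("time $t$")
    ax.set_ylabel("average length $M_1$")
    ax.legend()
    return ax


def plot_rescaled_profiles(dists, gamma, ax=None):
    """Overlay of t^{-1/gamma} f(t, t^{-1/gamma} x) for each distribution:
    collapse onto a single shape signals the self-similar regime."""
    import matplotlib.pyplot as plt

    from .observables import rescaled_profile

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xs = [d for d in dists if d.time > 0]
    x_grid = np.geomspace(
        max(1e-4, min(d.x[d.x > 0].min() for d in xs)), max(d.x.max() for d in xs), 600
    )
    prof = None
    for d in xs:
        prof = rescaled_profile(d, gamma, x_grid=x_grid)
        ax.plot(prof.x, prof.g, label=f"t = {d.time:g}")
    ax.set_xlabel("rescaled length $x$")
    ax.set_ylabel(r"$\hat g(x)$")
    ax.set_xlim(0.0, 5.0 * prof.moment(1.0))
    ax.legend(fontsize=8)
    return ax
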