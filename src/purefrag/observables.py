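"""Quantities measured on solutions or samples.

The observable layer mirrors what a nano-imaging experiment gives access to:
the unit-integral length distribution f(t, x), its moments
M_q(t) = int x^q f dx, the self-similar rescaling
g_hat(x) = t^{-1/gamma} f(t, t^{-1/gamma} x) that converges to the steady
profile, numeric Mellin transforms G_hat(s), and the functional-equation
recursion (2 - s) G(s) = alpha gamma (K(s) - 1) G(s + gamma) that predicts
steady-profile Mellin values independently of any simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .kernels import FragmentationKernel, FragmentationParameters
from .solver import SimulationResult

__all__ = [
    "NormalizedDistribution",
    "MomentSeries",
    "SteadyProfile",
    "normalize",
    "moment",
    "moment_series",
    "rescaled_profile",
    "mellin_numeric",
    "steady_moments_recursion",
    "classify_profile",
    "ResonanceError",
]


class ResonanceError(ArithmeticError):
    """The Mellin recursion chain hit s = 2 or a zero of K(s) - 1."""


# ----------------------------------------------------------------------
@dataclass
class NormalizedDistribution:
    """Measured length distribution f on a grid, with int f dx = 1."""

    x: np.ndarray
    f: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.x.shape != self.f.shape or self.x.ndim != 1:
            raise ValueError("x and f must be matching 1-d arrays")
        if np.any(self.f < 0):
            raise ValueError("density values must be nonnegative")

    def integral(self) -> float:
        return float(np.trapezoid(self.f, self.x))

    def moment(self, q: float) -> float:
        return float(np.trapezoid(self.x**q * self.f, self.x))

    def cdf(self) -> np.ndarray:
        from scipy.integrate import cumulative_trapezoid

        c = cumulative_trapezoid(self.f, self.x, initial=0.0)
        return c / c[-1]


@dataclass
class MomentSeries:
    """M_q(t_i) for a set of orders q along a trajectory."""

    times: np.ndarray
    orders: np.ndarray
    values: np.ndarray  # shape (n_times, n_orders)

    def order(self, q: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.orders - q)))
        if abs(self.orders[j] - q) > 1e-12:
            raise KeyError(f"order {q} not in series (have {self.orders})")
        return self.values[:, j]

    def to_frame(self):
        import pandas as pd

        recs = [
            {"time": t, "q": q, "M_q": self.values[i, j]}
            for i, t in enumerate(self.times)
            for j, q in enumerate(self.orders)
        ]
        return pd.DataFrame(recs)


@dataclass
class SteadyProfile:
    """Rescaled asymptotic shape g_hat on a grid, int g_hat dx = 1."""

    x: np.ndarray
    g: np.ndarray
    t_source: float = np.inf
    gamma: float = np.nan

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.g = np.asarray(self.g, dtype=float)

    def integral(self) -> float:
        return float(np.trapezoid(self.g, self.x))

    def moment(self, q: float) -> float:
        return float(np.trapezoid(self.x**q * self.g, self.x))

    def mellin(self, s: complex) -> complex:
        return mellin_numeric(self, s)


# ----------------------------------------------------------------------
def normalize(x, u, time: float = 0.0) -> NormalizedDistribution:
    """f = u / int u dx (trapezoid quadrature on the given grid)."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    total = np.trapezoid(u, x)
    if not total > 0:
        raise ValueError("cannot normalize a zero-mass density")
    return NormalizedDistribution(x=x, f=u / total, time=time)


def moment(dist, q: float) -> float:
    """Moment of order q: grid distributions by quadrature, samples by mean."""
    if q < 0:
        raise ValueError("q must be >= 0")
    if isinstance(dist, (NormalizedDistribution, SteadyProfile)):
        return dist.moment(q)
    sample = np.asarray(dist, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    return float(np.mean(sample**q))


def moment_series(result_or_dists, orders=(1.0,)) -> MomentSeries:
    """Moment trajectory from a SimulationResult or a list of distributions."""
    orders = np.atleast_1d(np.asarray(orders, dtype=float))
    if isinstance(result_or_dists, SimulationResult):
        res = result_or_dists
        dists = [normalize(res.x, res.u(k), time=t) for k, t in enumerate(res.times)]
    else:
        dists = list(result_or_dists)
    times = np.array([d.time for d in dists])
    values = np.array([[d.moment(q) for q in orders] for d in dists])
    return MomentSeries(times=times, orders=orders, values=values)


def rescaled_profile(dist: NormalizedDistribution, gamma: float, x_grid=None) -> SteadyProfile:
    """Self-similar rescaling g_hat(x) = t^{-1/gamma} f(t, t^{-1/gamma} x).

    By default the rescaling is exact (a pure axis transformation carrying
    the source values verbatim); when a target ``x_grid`` is requested, the
    shape is interpolated onto it by monotone cubic in log x, clipped at 0
    to preserve positivity.  Either way the result is renormalized to unit
    integral.  At t = 1 the rescaling is the identity.
    """
    t = dist.time
    if not t > 0:
        raise ValueError("rescaling requires a positive time stamp")
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    scale = t ** (-1.0 / gamma)
    x_src = dist.x
    if x_grid is None:
        # exact path: g_hat on the rescaled axis X = x / scale carries the
        # source values verbatim (no interpolation artifacts near x = 0)
        x_out = x_src / scale
        g = scale * np.clip(dist.f, 0.0, None)
    else:
        x_out = np.asarray(x_grid, dtype=float)
        pos = x_src > 0
        interp = PchipInterpolator(np.log(x_src[pos]), dist.f[pos], extrapolate=False)
        x_back = scale * x_out  # where f must be read to form g_hat(x_out)
        with np.errstate(divide="ignore"):
            vals = interp(np.log(np.where(x_back > 0, x_back, np.nan)))
        vals = np.nan_to_num(vals, nan=0.0)
        g = scale * np.clip(vals, 0.0, None)
    total = np.trapezoid(g, x_out)
    if not total > 0:
        raise ValueError("rescaled profile lost all mass; grid mismatch")
    return SteadyProfile(x=x_out, g=g / total, t_source=t, gamma=gamma)


def mellin_numeric(profile, s: complex) -> complex:
    """G_hat(s) = int x^{s-1} g_hat(x) dx by trapezoid on the profile grid.

    Issues an accuracy warning when the boundary terms contribute more than
    1% of |G_hat| (unresolved tail for that s).
    """
    s = complex(s)
    x = profile.x
    g = profile.g
    pos = x > 0
    x, g = x[pos], g[pos]
    integrand = np.exp((s - 1.0) * np.log(x)) * g
    val = np.trapezoid(integrand, x)
    edge = 0.5 * (
        np.abs(integrand[0]) * (x[1] - x[0]) + np.abs(integrand[-1]) * (x[-1] - x[-2])
    )
    if np.abs(val) > 0 and edge > 0.01 * np.abs(val):
        warnings.warn(
            f"Mellin transform at s = {s}: boundary terms are {edge / np.abs(val):.1%} "
            "of the result; the grid may not resolve the integrand's tail",
            RuntimeWarning,
            stacklevel=2,
        )
    if abs(s.imag) == 0.0:
        return complex(val.real if np.iscomplexobj(val) else val)
    return complex(val)


def steady_moments_recursion(
    params: FragmentationParameters,
    kernel: FragmentationKernel,
    start_s: float = 1.0,
    n_steps: int = 3,
    g_start: float = 1.0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Chain G_hat(s + gamma) = (2 - s) G_hat(s) / (alpha gamma (K(s) - 1)).

    Starting from the normalization anchor G_hat(1) = 1 (default), returns
    the values G_hat(start_s + k gamma) for k = 0..n_steps: independent
    predictions of the steady profile's Mellin values usable to cross-check
    simulations.  Raises :class:`ResonanceError` when the chain passes
    through s = 2, where both (2 - s) and K(s) - 1 vanish.
    """
    values = [complex(g_start)]
    s = complex(start_s)
    for _ in range(n_steps):
        if abs(s - 2.0) < tol:
            raise ResonanceError(
                f"chain hit the resonance s = 2 (s = {s}); choose a different start_s"
            )
        ks = kernel.mellin(s)
        if abs(ks - 1.0) < tol:
            raise ResonanceError(f"K(s) - 1 vanishes at s = {s}; choose a different start_s")
        nxt = (2.0 - s) * values[-1] / (params.alpha * params.gamma * (ks - 1.0))
        values.append(nxt)
        s = s + params.gamma
    out = np.array(values)
    return out.real if np.allclose(out.imag, 0.0, atol=1e-12) else out


# ----------------------------------------------------------------------
def _smooth5(y: np.ndarray) -> np.ndarray:
    kern = np.ones(5) / 5.0
    return np.convolve(np.pad(y, 2, mode="edge"), kern, mode="valid")


def classify_profile(profile: SteadyProfile, theta: float = 0.05) -> str:
    """Read the kernel class off a steady profile's shape.

    Class A kernels (vanishing at both endpoints, interior breakage) give a
    unimodal profile with g_hat(0+) = 0; class B kernels (positive at the
    endpoints, end breakage) give a profile positive and decreasing near 0.
    ``theta`` sets the near-zero threshold relative to max g_hat; profiles
    matching neither pattern return "undetermined".
    """
    x = profile.x
    g = _smooth5(profile.g)
    gmax = g.max()
    # read g_hat(0+) at the smallest resolved positive-x nodes (skip exact
    # leading zeros, which can only be clipping artifacts of interpolation)
    pos = np.where((x > 0) & (g > 0))[0]
    if pos.size < 5:
        return "undetermined"
    # extrapolate g_hat to x -> 0 linearly from the first resolved nodes
    head = pos[:6]
    slope, intercept = np.polyfit(x[head], g[head], 1)
    g0 = float(max(intercept, 0.0))
    # count interior peaks on the part that carries mass
    idx = np.where(g > 1e-3 * gmax)[0]
    seg = g[idx[0] : idx[-1] + 1]
    d = np.sign(np.diff(seg))
    d = d[d != 0]
    n_peaks = int(np.sum((d[:-1] > 0) & (np.diff(d) < 0))) if d.size > 1 else 0
    decreasing_from_origin = idx[0] <= pos[0] + 2 and (n_peaks == 0 or np.argmax(g) <= idx[0] + 2)
    if g0 < theta * gmax and n_peaks == 1:
        return "A"
    if g0 >= theta * gmax and decreasing_from_origin:
        return "B"
    return "undetermined"
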