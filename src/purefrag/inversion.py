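"""Inverse problem: recover (gamma, alpha, kappa) from length distributions.

Three nested inversions, in increasing order of ill-posedness:

* **gamma** from the average-length trajectory: log M1(t) versus log t tends
  to a straight line of slope -1/gamma once the self-similar regime is
  reached.  The fitted model is piecewise (flat level before the equilibrium
  time t_e, power decay after), minimizing the quadratic misfit
  E(gamma, C, t_e) = sum_i (M_e(t_i) - M1(t_i))^2 with the level constant C
  profiled out in closed form.
* **alpha** from the binary-fission Mellin identity at s = 1: for the
  unit-mass rescaled late-time profile, alpha = 1 / (gamma * G_hat(1+gamma)).
* **kappa** from the inverse Mellin contour integral of
  K(s) = 1 + (2-s) G_hat(s) / (alpha gamma G_hat(s+gamma)), regularized by a
  Gaussian low-pass filter along the contour (the step is ill-posed; all
  regularization settings are recorded in the output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .observables import (
    MomentSeries,
    NormalizedDistribution,
    SteadyProfile,
    classify_profile,
    mellin_numeric,
    moment_series,
    rescaled_profile,
)

__all__ = [
    "GammaFit",
    "KappaEstimate",
    "EstimationResult",
    "estimate_gamma",
    "estimate_alpha",
    "estimate_kappa",
    "analyze_experiment",
    "FragmentationEstimator",
]


# ----------------------------------------------------------------------
@dataclass
class GammaFit:
    """Result of the piecewise log-log moment fit."""

    gamma_e: float
    C: float
    t_e: float
    residual: float
    gamma_grid: np.ndarray = field(repr=False, default=None)
    residual_grid: np.ndarray = field(repr=False, default=None)  # min over t_e per gamma


@dataclass
class KappaEstimate:
    """Recovered fragmentation kernel with its regularization record."""

    z: np.ndarray
    values: np.ndarray
    s0: float
    tau_max: float
    n_tau: int
    filter_scale: float
    symmetrized: bool
    clipped: bool = True
    renormalized: bool = True

    def __call__(self, z):
        return np.interp(np.asarray(z, dtype=float), self.z, self.values)


@dataclass
class EstimationResult:
    """Full output of the estimation pipeline."""

    gamma_fit: GammaFit
    alpha_e: float
    kernel_class: str
    profile: SteadyProfile
    moments: MomentSeries
    kappa: KappaEstimate | None = None
    settings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def gamma_e(self) -> float:
        return self.gamma_fit.gamma_e

    @property
    def t_e(self) -> float:
        return self.gamma_fit.t_e

    def to_report(self) -> dict:
        rep = {
            "gamma_e": self.gamma_e,
            "alpha_e": self.alpha_e,
            "T_e": self.t_e,
            "C": self.gamma_fit.C,
            "fit_residual": self.gamma_fit.residual,
            "kernel_class": self.kernel_class,
            "settings": self.settings,
            "warnings": list(self.warnings),
        }
        if self.kappa is not None:
            rep["kappa"] = {
                "z": self.kappa.z.tolist(),
                "values": self.kappa.values.tolist(),
                "s0": self.kappa.s0,
                "tau_max": self.kappa.tau_max,
                "n_tau": self.kappa.n_tau,
                "filter_scale": self.kappa.filter_scale,
                "symmetrized": self.kappa.symmetrized,
            }
        return rep


# ----------------------------------------------------------------------
def _profiled_misfit(
    gammas: np.ndarray, t_es: np.ndarray, t: np.ndarray, m: np.ndarray, log_scale: bool = False
):
    """E(gamma, t_e) with the level C profiled out, vectorized.

    Linear scale (the printed objective): the model is a_i = C t_e^{-1/gamma}
    for t_i <= t_e and C t_i^{-1/gamma} after; the optimal C for given
    (gamma, t_e) is <a, m>/<a, a> and E = |m|^2 - <a, m>^2/<a, a>.
    Log scale: the misfit is summed on log M, where profiling out log C is a
    plain mean shift; this weights all decades equally.
    """
    inv_g = 1.0 / gammas[:, None, None]  # (G, 1, 1)
    te = t_es[None, :, None]  # (1, E, 1)
    tt = t[None, None, :]  # (1, 1, n)
    if log_scale:
        la = np.where(tt <= te, -inv_g * np.log(te), -inv_g * np.log(tt))
        r = np.log(m)[None, None, :] - la
        rbar = r.mean(axis=-1, keepdims=True)
        E = np.sum((r - rbar) ** 2, axis=-1)
        C = np.exp(rbar[..., 0])
        return E, C
    a = np.where(tt <= te, te**-inv_g, tt**-inv_g)
    am = np.sum(a * m[None, None, :], axis=-1)
    aa = np.sum(a * a, axis=-1)
    mm = float(np.dot(m, m))
    E = mm - am**2 / aa
    C = am / aa
    return E, C


def estimate_gamma(
    moments: MomentSeries | tuple[np.ndarray, np.ndarray],
    gamma_grid: np.ndarray | None = None,
    refine: bool = True,
    log_scale: bool = False,
) -> GammaFit:
    """Fit gamma (and the equilibrium time t_e) to the M1 trajectory.

    A coarse search over gamma in [0.1, 5] (step 0.01) and t_e over the data
    times plus midpoints is followed by a local simplex polish of
    (gamma, t_e); ties on the coarse grid break toward smaller gamma.
    Needs at least 3 positive-time points.
    """
    if isinstance(moments, MomentSeries):
        t = np.asarray(moments.times, dtype=float)
        m = np.asarray(moments.order(1.0), dtype=float)
    else:
        t, m = (np.asarray(v, dtype=float) for v in moments)
    keep = t > 0
    t, m = t[keep], m[keep]
    if t.size < 3:
        raise ValueError("gamma estimation needs at least 3 time points with t > 0")
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise ValueError("moments must be finite and positive")
    order = np.argsort(t)
    t, m = t[order], m[order]

    if gamma_grid is None:
        gamma_grid = np.arange(0.1, 5.0 + 1e-9, 0.01)
    mids = 0.5 * (t[:-1] + t[1:])
    te_grid = np.unique(np.concatenate((t, mids)))

    E, C = _profiled_misfit(gamma_grid, te_grid, t, m, log_scale=log_scale)
    Emin_per_gamma = E.min(axis=1)
    ig, ie = np.unravel_index(np.argmin(E), E.shape)
    g0, te0, c0, e0 = gamma_grid[ig], te_grid[ie], C[ig, ie], E[ig, ie]

    if refine:
        lo_t, hi_t = float(t[0]), float(t[-1])

        def objective(p):
            g, te = p
            if not (0.05 <= g <= 10.0 and lo_t <= te <= hi_t):
                return 1e6 * (1.0 + np.sum(np.square(p)))
            e, _ = _profiled_misfit(np.array([g]), np.array([te]), t, m, log_scale=log_scale)
            return float(e[0, 0])

        res = optimize.minimize(
            objective, x0=[g0, te0], method="Nelder-Mead", options={"xatol": 1e-5, "fatol": 1e-14}
        )
        if res.fun <= e0:
            g0, te0 = float(res.x[0]), float(res.x[1])
            e1, c1 = _profiled_misfit(np.array([g0]), np.array([te0]), t, m, log_scale=log_scale)
            c0, e0 = float(c1[0, 0]), float(e1[0, 0])

    return GammaFit(
        gamma_e=float(g0),
        C=float(c0),
        t_e=float(te0),
        residual=float(max(e0, 0.0)),
        gamma_grid=gamma_grid,
        residual_grid=Emin_per_gamma,
    )


# ----------------------------------------------------------------------
def estimate_alpha(profile: SteadyProfile, gamma: float) -> float:
    """alpha = 1 / (gamma * G_hat(1 + gamma)) from the unit-mass profile.

    This is the binary-fission identity alpha = G(1)/(gamma G(1+gamma))
    specialized to the normalized profile (G_hat = G / G(1)).
    """
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    g1g = mellin_numeric(profile, 1.0 + gamma).real
    if not np.isfinite(g1g) or g1g <= 0:
        raise ArithmeticError(f"G_hat(1 + gamma) = {g1g}; cannot form alpha")
    return 1.0 / (gamma * g1g)


def estimate_kappa(
    profile: SteadyProfile,
    gamma: float,
    alpha: float,
    s0: float = 2.5,
    tau_max: float = 40.0,
    n_tau: int = 2001,
    filter_scale: float = 15.0,
    symmetrize: bool = True,
    z_grid: np.ndarray | None = None,
) -> KappaEstimate:
    """Recover kappa by the regularized inverse Mellin contour integral.

    K(s) is reconstructed on the contour Re(s) = s0 from the profile's
    Mellin transform, damped by the Gaussian filter exp(-(tau/filter_scale)^2)
    (the inversion is ill-posed), and transformed back by trapezoid in tau.
    Post-processing clips negatives, optionally symmetrizes
    (kappa(z) + kappa(1-z))/2 — daughters of a binary division come in
    complementary pairs — and renormalizes to integral 2.
    """
    if not (gamma > 0 and alpha > 0):
        raise ValueError("gamma and alpha must be > 0")
    if s0 <= 2.0:
        raise ValueError("the contour abscissa s0 must exceed 2")
    tau = np.linspace(-tau_max, tau_max, n_tau)
    s = s0 + 1j * tau

    x = profile.x
    pos = (x > 0) & np.isfinite(profile.g)
    x, g = x[pos], profile.g[pos]
    logx = np.log(x)

    G_s = _mellin_contour(logx, g, s0, tau)
    G_sg = _mellin_contour(logx, g, s0 + gamma, tau)
    # Where either transform falls below ~1e-12 of its tau = 0 magnitude it
    # is dominated by floating-point cancellation noise and the ratio is
    # meaningless; there K is clamped to its high-frequency limit 0
    # (Riemann-Lebesgue for a bounded kernel density: the leading "1" of the
    # reconstruction formula is cancelled by the fraction at large |tau|).
    # A dip below noise in the small-|tau| core, where the filter passes
    # signal, indicates an actual zero of the denominator on the contour.
    mid = np.argmin(np.abs(tau))
    trustworthy = (np.abs(G_sg) > 1e-12 * np.abs(G_sg[mid])) & (
        np.abs(G_s) > 1e-12 * np.abs(G_s[mid])
    )
    core = np.abs(tau) <= 0.5 * filter_scale
    if not trustworthy[core].all():
        raise ArithmeticError("G_hat(s + gamma) vanishes on the contour core; increase s0")

    K = np.zeros_like(G_s)
    np.divide((2.0 - s) * G_s, alpha * gamma * G_sg, out=K, where=trustworthy)
    K[trustworthy] += 1.0

    # physical sanity: |K(s0 + i tau)| <= K(s0) for any nonnegative kernel,
    # so an excursion above the tau = 0 value marks the frequency where the
    # profile's departure from exact self-similarity takes over the ratio
    k0 = abs(K[mid])
    if k0 > 0:
        unphysical = np.abs(K) > 1.1 * k0
        trustworthy &= ~unphysical
        K[unphysical] = 0.0

    # the filter never passes frequencies the data cannot support: cap the
    # filter scale so the trust boundary sits deep in the Gaussian tail
    if trustworthy.all():
        tau_star = tau_max
    else:
        first_bad = np.abs(tau[~trustworthy]).min()
        tau_star = max(first_bad, 1e-6)
    filter_eff = min(filter_scale, tau_star / 2.5)
    filt = np.exp(-((tau / filter_eff) ** 2))

    if z_grid is None:
        z_grid = np.linspace(0.002, 0.998, 499)
    z_grid = np.asarray(z_grid, dtype=float)
    # kappa(z) = z^{-s0} m(ln z), with m the filtered inverse transform
    # m(u) = 1/(2 pi) int e^{-i tau u} K(s0 + i tau) filt(tau) dtau.
    # The Gaussian filter smears the edge at z = 1 outward; evaluating m at
    # -ln z as well and folding it back (reflection at the boundary, as in
    # edge-corrected KDE) restores the mass that leaked past z = 1.
    u = np.log(z_grid)
    m_in = _inverse_contour(tau, K * filt, u)
    m_out = _inverse_contour(tau, K * filt, -u)
    vals = z_grid**-s0 * (m_in + m_out) / (2.0 * np.pi)

    vals = np.clip(vals, 0.0, None)
    if symmetrize:
        vals = 0.5 * (vals + vals[::-1])
    total = np.trapezoid(vals, z_grid)
    if not total > 0:
        raise ArithmeticError("recovered kernel carries no mass")
    vals *= 2.0 / total
    return KappaEstimate(
        z=z_grid,
        values=vals,
        s0=s0,
        tau_max=tau_max,
        n_tau=n_tau,
        filter_scale=filter_eff,
        symmetrized=symmetrize,
    )


def _mellin_contour(logx: np.ndarray, g: np.ndarray, sigma: float, tau: np.ndarray) -> np.ndarray:
    """G(sigma + i tau) for a gridded profile, accurate far down its decay.

    Direct trapezoid keeps excellent *relative* accuracy until the transform
    decays to the float64 cancellation floor (~1e-16 of the integrand's
    scale).  Writing G = -(1/tau^2) * F[q''] (two integrations by parts of
    q(w) = g(e^w) e^{sigma w}, boundary terms vanishing with the profile)
    rescales the floor by tau^2 and extends the usable contour; it is used
    for |tau| > 8 when the log-grid is uniform.
    """
    x = np.exp(logx)
    direct = np.trapezoid(
        np.exp(np.multiply.outer(sigma - 1.0 + 1j * tau, logx)) * g[None, :], x, axis=-1
    )
    dw = np.diff(logx)
    if dw.size < 8 or not np.allclose(dw, dw[0], rtol=1e-8):
        return direct
    h = dw[0]
    q = g * np.exp(sigma * logx)
    qpp = np.zeros_like(q)
    qpp[1:-1] = (q[2:] - 2.0 * q[1:-1] + q[:-2]) / (h * h)
    big = np.abs(tau) > 8.0
    if not big.any():
        return direct
    parts = np.trapezoid(
        np.exp(1j * np.multiply.outer(tau[big], logx)) * qpp[None, :], logx, axis=-1
    )
    out = direct.copy()
    out[big] = -parts / tau[big] ** 2
    return out


def _inverse_contour(tau: np.ndarray, integrand: np.ndarray, u: np.ndarray) -> np.ndarray:
    """int e^{-i tau u} integrand(tau) dtau by trapezoid, real part."""
    phase = np.exp(-1j * np.multiply.outer(u, tau))
    return np.trapezoid(phase * integrand[None, :], tau, axis=-1).real


# ----------------------------------------------------------------------
def analyze_experiment(
    dataset,
    kde_bandwidth=None,
    estimate_kernel: bool = False,
    s0: float = 2.5,
    tau_max: float = 40.0,
    n_tau: int = 2001,
    filter_scale: float = 15.0,
    symmetrize: bool = True,
    x_grid: np.ndarray | None = None,
) -> EstimationResult:
    """Run the full estimation pipeline on measured data.

    ``dataset`` is either a list of :class:`NormalizedDistribution` (each
    time-stamped), a pandas DataFrame with columns ``time, length`` (finite
    samples, turned into densities by reflected KDE), or a
    :class:`~purefrag.synthetic.LengthSampleSet`.

    Pipeline: densities -> M1 series -> gamma fit -> rescaled profile at the
    last time -> alpha -> profile-shape class -> (optional) kappa inversion.
    """
    stage = "densities"
    try:
        dists = _coerce_to_distributions(dataset, kde_bandwidth, x_grid)
        if len(dists) < 3:
            raise ValueError("need measurements at >= 3 time points")
        dists = sorted(dists, key=lambda d: d.time)

        stage = "moments"
        moments = moment_series(dists, orders=(1.0,))
        stage = "estimate_gamma"
        fit = estimate_gamma(moments)
        stage = "rescaled_profile"
        profile = rescaled_profile(dists[-1], fit.gamma_e)
        stage = "estimate_alpha"
        alpha_e = estimate_alpha(profile, fit.gamma_e)
        stage = "classify_profile"
        k_class = classify_profile(profile)
        kappa = None
        if estimate_kernel:
            stage = "estimate_kappa"
            kappa = estimate_kappa(
                profile,
                fit.gamma_e,
                alpha_e,
                s0=s0,
                tau_max=tau_max,
                n_tau=n_tau,
                filter_scale=filter_scale,
                symmetrize=symmetrize,
            )
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return EstimationResult(
        gamma_fit=fit,
        alpha_e=alpha_e,
        kernel_class=k_class,
        profile=profile,
        moments=moments,
        kappa=kappa,
        settings={
            "kde_bandwidth": kde_bandwidth,
            "estimate_kernel": estimate_kernel,
            "s0": s0,
            "tau_max": tau_max,
            "n_tau": n_tau,
            "filter_scale": filter_scale,
            "symmetrize": symmetrize,
        },
    )


def _coerce_to_distributions(dataset, kde_bandwidth, x_grid):
    from .synthetic import LengthSampleSet, density_from_sample

    if isinstance(dataset, LengthSampleSet):
        if dataset.samples is None:
            return list(dataset.densities)
        dataset = dataset.samples
    if isinstance(dataset, (list, tuple)) and all(
        isinstance(d, NormalizedDistribution) for d in dataset
    ):
        return list(dataset)
    import pandas as pd

    if isinstance(dataset, pd.DataFrame):
        cols = set(dataset.columns)
        if {"time", "length"} <= cols:
            out = []
            for tv, grp in dataset.groupby("time"):
                lengths = grp["length"].to_numpy(dtype=float)
                if lengths.size == 0:
                    raise ValueError(f"empty sample at time {tv}")
                d = density_from_sample(lengths, bandwidth=kde_bandwidth, x_grid=x_grid)
                d.time = float(tv)
                out.append(d)
            return out
        if {"time", "x", "f"} <= cols:
            out = []
            for tv, grp in dataset.sort_values("x").groupby("time"):
                from .observables import normalize

                out.append(
                    normalize(grp["x"].to_numpy(float), grp["f"].to_numpy(float), time=float(tv))
                )
            return out
        raise ValueError("DataFrame must have columns (time, length) or (time, x, f)")
    raise TypeError(f"unsupported dataset type {type(dataset).__name__}")


# ----------------------------------------------------------------------
try:  # sklearn is an optional convenience; the functional API never needs it
    from sklearn.base import BaseEstimator as _SkBase
except Exception:  # pragma: no cover
    _SkBase = object


class FragmentationEstimator(_SkBase):
    """Scikit-learn-style front end to :func:`analyze_experiment`.

    ``fit(X)`` accepts the same inputs as :func:`analyze_experiment` (a
    DataFrame of (time, length) records or per-time densities) and exposes
    the recovered division-rate parameters as fitted attributes
    ``gamma_``, ``alpha_``, ``t_e_``, ``kernel_class_`` and ``kappa_``.
    """

    def __init__(
        self,
        kde_bandwidth=None,
        estimate_kernel: bool = False,
        s0: float = 2.5,
        tau_max: float = 40.0,
        n_tau: int = 2001,
        filter_scale: float = 15.0,
        symmetrize: bool = True,
    ):
        self.kde_bandwidth = kde_bandwidth
        self.estimate_kernel = estimate_kernel
        self.s0 = s0
        self.tau_max = tau_max
        self.n_tau = n_tau
        self.filter_scale = filter_scale
        self.symmetrize = symmetrize

    def fit(self, X, y=None):
        result = analyze_experiment(
            X,
            kde_bandwidth=self.kde_bandwidth,
            estimate_kernel=self.estimate_kernel,
            s0=self.s0,
            tau_max=self.tau_max,
            n_tau=self.n_tau,
            filter_scale=self.filter_scale,
            symmetrize=self.symmetrize,
        )
        self.result_ = result
        self.gamma_ = result.gamma_e
        self.alpha_ = result.alpha_e
        self.t_e_ = result.t_e
        self.kernel_class_ = result.kernel_class
        self.kappa_ = result.kappa
        return self

    def predict_moment(self, times):
        """Fitted asymptotic-model M1 at the given times."""
        from sklearn.utils.validation import check_is_fitted

        if _SkBase is not object:
            check_is_fitted(self, "result_")
        fit = self.result_.gamma_fit
        t = np.asarray(times, dtype=float)
        return np.where(
            t <= fit.t_e, fit.C * fit.t_e ** (-1.0 / fit.gamma_e), fit.C * t ** (-1.0 / fit.gamma_e)
        )
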