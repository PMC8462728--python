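"""Experimental-design helper.

Given a guess for (gamma, alpha, kappa) and the initial length distribution
that can actually be prepared, simulate the experiment, locate the
equilibrium time T_e at which log M1 versus log t has straightened onto the
asymptotic line, and recommend measuring until 5 * T_e.  Late, well-spaced
time points serve the (gamma, alpha) estimates; dense early points (and a
monodisperse initial sample) are what carries information about the kernel
shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inversion import estimate_gamma
from .kernels import FragmentationKernel, FragmentationParameters
from .observables import moment_series
from .solver import LogGrid, solve_continuous
from .synthetic import initial_condition

__all__ = ["DesignRecommendation", "design_experiment"]


@dataclass
class DesignRecommendation:
    t_e: float
    recommended_horizon: float
    gamma_probe: float
    probe_times: np.ndarray
    advice: tuple


def design_experiment(
    params_guess: FragmentationParameters,
    kernel_guess: FragmentationKernel,
    ic_name: str = "exponential",
    probe_times=None,
    probe_horizon: float | None = None,
    n_probe_times: int = 24,
    grid: LogGrid | None = None,
    target_kernel: bool = False,
) -> DesignRecommendation:
    """Recommend a measurement horizon of 5 * T_e for the guessed dynamics.

    When ``probe_times`` (the schedule the experiment intends to use) is
    given, T_e is the equilibrium time of the standard moment fit on exactly
    that schedule — the approach to the asymptotic line is gradual, so the
    onset time is meaningful only relative to a measurement schedule.
    Otherwise an automatic log-spaced probe is used, with the horizon
    doubling until the fitted T_e is comfortably interior; the automatic
    probe fits on the log scale so its early-heavy schedule cannot let the
    large early moments swamp the bend.
    """
    u0 = initial_condition(ic_name)
    if probe_times is not None:
        times = np.asarray(sorted(float(t) for t in probe_times))
        result = solve_continuous(
            params_guess, kernel_guess, u0, grid=grid, t_final=times[-1], output_times=times
        )
        fit = estimate_gamma(moment_series(result))
    else:
        horizon = probe_horizon if probe_horizon is not None else 50.0 / params_guess.alpha
        for _ in range(6):
            times = np.geomspace(horizon / 200.0, horizon, n_probe_times)
            result = solve_continuous(
                params_guess, kernel_guess, u0, grid=grid, t_final=horizon, output_times=times
            )
            fit = estimate_gamma(moment_series(result), log_scale=True)
            if fit.t_e <= horizon / 3.0 or probe_horizon is not None:
                break
            horizon *= 2.0
    t_e = fit.t_e
    advice = [
        f"measure until t = {5.0 * t_e:.3g} (5 x the estimated equilibrium time T_e = {t_e:.3g})",
        "place several well-spaced time points after T_e for the gamma and alpha estimates",
    ]
    if target_kernel:
        advice.append(
            "for the kernel shape, add dense time points well before T_e and start from a "
            "monodisperse (highly peaked) initial distribution"
        )
    return DesignRecommendation(
        t_e=float(t_e),
        recommended_horizon=float(5.0 * t_e),
        gamma_probe=float(fit.gamma_e),
        probe_times=times,
        advice=tuple(advice),
    )
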