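"""Synthetic fragmentation experiments.

Emulates what a time-point nano-imaging experiment measures: at each
observation time, N filament lengths drawn from the population's current
length distribution.  Sampling noise is the only noise model — for length
measurements the device noise is negligible next to the finite-sample
error.  An optional detection limit (lengths below a threshold discarded,
off by default) mimics small particles dropping below the imaging
resolution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import gaussian_kde

from .kernels import FragmentationKernel, FragmentationParameters
from .observables import NormalizedDistribution, normalize
from .solver import LogGrid, solve_continuous

__all__ = [
    "INITIAL_CONDITIONS",
    "initial_condition",
    "sample_lengths",
    "density_from_sample",
    "simulate_experiment",
    "LengthSampleSet",
]

INITIAL_CONDITIONS = ("peaked_gaussian", "spread_gaussian", "exponential")


def _truncated_gaussian(center: float, sd: float):
    from scipy.stats import norm

    c = 1.0 / (sd * math.sqrt(2.0 * math.pi) * norm.cdf(center / sd))

    def density(x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, c * np.exp(-0.5 * ((x - center) / sd) ** 2), 0.0)

    return density


def initial_condition(name: str):
    """The three reference initial length densities.

    * ``peaked_gaussian`` — N(1, 0.01) truncated to x > 0: a monodisperse
      suspension (all filaments start at essentially the same length).
    * ``spread_gaussian`` — N(1, 1) truncated to x > 0 and renormalized.
    * ``exponential`` — f0(x) = exp(-x).
    """
    if name == "peaked_gaussian":
        return _truncated_gaussian(1.0, 1e-2)
    if name == "spread_gaussian":
        return _truncated_gaussian(1.0, 1.0)
    if name == "exponential":
        return lambda x: np.exp(-np.asarray(x, dtype=float))
    raise KeyError(f"unknown initial condition {name!r}; choose from {INITIAL_CONDITIONS}")


# ----------------------------------------------------------------------
def sample_lengths(dist: NormalizedDistribution, n: int, seed=None, rng=None) -> np.ndarray:
    """Draw n lengths from a gridded density by inverse-CDF sampling.

    The CDF is piecewise linear between grid nodes; the same seed always
    reproduces the same sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cdf = cumulative_trapezoid(dist.f, dist.x, initial=0.0)
    if cdf[-1] <= 0:
        raise ValueError("degenerate density: zero total mass")
    cdf = cdf / cdf[-1]
    # strictly increasing knots only, so interp is well-defined
    keep = np.concatenate(([True], np.diff(cdf) > 0))
    u = rng.uniform(0.0, 1.0, size=n)
    return np.interp(u, cdf[keep], dist.x[keep])


def density_from_sample(
    lengths, bandwidth=None, x_grid: np.ndarray | None = None
) -> NormalizedDistribution:
    """Reflected Gaussian KDE of a length sample, on a standard grid.

    Silverman bandwidth by default; reflection at x = 0 keeps all the
    reconstructed mass on positive lengths.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 5:
        raise ValueError("need at least 5 lengths for a density estimate")
    kde = gaussian_kde(lengths, bw_method=bandwidth if bandwidth is not None else "silverman")
    bw = math.sqrt(float(kde.covariance[0, 0]))
    if x_grid is None:
        x_grid = np.linspace(0.0, float(lengths.max()) + 5.0 * bw, 800)
    x_grid = np.asarray(x_grid, dtype=float)
    vals = kde(x_grid) + kde(-x_grid)  # reflection at the origin
    vals = np.clip(vals, 0.0, None)
    return normalize(x_grid, vals)


# ----------------------------------------------------------------------
@dataclass
class LengthSampleSet:
    """Time-stamped length samples plus the generator's provenance.

    ``samples`` is a long-format DataFrame (time, length), or None in
    noiseless mode (N = 0), in which case only the exact per-time densities
    are carried.
    """

    times: np.ndarray
    densities: list
    samples: "object | None" = None  # pandas DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_per_time(self) -> dict:
        if self.samples is None:
            return {}
        return self.samples.groupby("time").size().to_dict()

    def to_csv(self, path, provenance_sidecar: bool = True) -> None:
        path = Path(path)
        if self.samples is None:
            import pandas as pd

            rows = [
                pd.DataFrame({"time": d.time, "x": d.x, "f": d.f}) for d in self.densities
            ]
            pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        else:
            self.samples.to_csv(path, index=False)
        if provenance_sidecar:
            path.with_suffix(".json").write_text(json.dumps(self.provenance, indent=2))

    @classmethod
    def from_csv(cls, path) -> "LengthSampleSet":
        import pandas as pd

        path = Path(path)
        frame = pd.read_csv(path)
        prov_path = path.with_suffix(".json")
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        if {"time", "length"} <= set(frame.columns):
            times = np.array(sorted(frame["time"].unique()))
            return cls(times=times, densities=[], samples=frame, provenance=prov)
        if {"time", "x", "f"} <= set(frame.columns):
            dens = []
            for tv, grp in frame.sort_values("x").groupby("time"):
                dens.append(
                    NormalizedDistribution(
                        grp["x"].to_numpy(float), grp["f"].to_numpy(float), time=float(tv)
                    )
                )
            return cls(times=np.array([d.time for d in dens]), densities=dens, provenance=prov)
        raise ValueError("CSV must have columns (time, length) or (time, x, f)")


def simulate_experiment(
    params: FragmentationParameters,
    kernel: FragmentationKernel,
    ic_name: str = "exponential",
    times: Sequence[float] = (5.0, 10.0, 20.0, 30.0, 40.0),
    n: int = 200,
    seed: int = 0,
    grid: LogGrid | None = None,
    delta_t: float | None = None,
    detection_limit: float | None = None,
) -> LengthSampleSet:
    """Full synthetic fragmentation experiment.

    Solves the continuous model from the named initial condition, normalizes
    each requested snapshot, and draws ``n`` lengths per time point
    (``n = 0``: noiseless mode, exact densities only).  ``detection_limit``
    optionally discards sampled lengths below a threshold, as small
    particles fall below the imaging resolution.
    """
    u0 = initial_condition(ic_name)
    times = sorted(float(t) for t in times)
    result = solve_continuous(
        params, kernel, u0, grid=grid, delta_t=delta_t, t_final=max(times), output_times=times
    )
    densities = []
    for t in times:
        k = result.index_of_time(t)
        densities.append(normalize(result.x, result.u(k), time=t))

    provenance = {
        "gamma": params.gamma,
        "alpha": params.alpha,
        "kernel": {"kind": kernel.kind_label, "params": kernel.params},
        "initial_condition": ic_name,
        "times": list(times),
        "n": int(n),
        "seed": int(seed),
        "detection_limit": detection_limit,
        "grid": {
            "delta_w": result.grid.delta_w,
            "pivot": result.grid.pivot,
            "size": result.grid.size,
        },
    }
    if n == 0:
        return LengthSampleSet(
            times=np.array(times), densities=densities, samples=None, provenance=provenance
        )

    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for d in densities:
        lengths = sample_lengths(d, n, rng=rng)
        if detection_limit is not None:
            lengths = lengths[lengths >= detection_limit]
        rows.append(pd.DataFrame({"time": d.time, "length": lengths}))
    samples = pd.concat(rows, ignore_index=True)
    return LengthSampleSet(
        times=np.array(times), densities=densities, samples=samples, provenance=provenance
    )
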