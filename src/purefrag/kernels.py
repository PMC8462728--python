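"""Division-rate parameters and fragmentation kernels.

The pure fragmentation model is parametrized by a power-law division rate
``B(x) = alpha * x**gamma`` and a self-similar fragmentation kernel
``kappa(z)`` giving the distribution of relative daughter sizes
``z = x/y in (0, 1)``.  Binary fission imposes the two normalizations

* ``int_0^1 kappa(z) dz = 2``  (two daughters per division),
* ``int_0^1 z kappa(z) dz = 1``  (mass conservation).

Every symmetric kernel (``kappa(z) = kappa(1-z)``) with integral 2
automatically satisfies the second condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate

__all__ = [
    "FragmentationParameters",
    "FragmentationKernel",
    "make_kernel",
    "kernel_from_table",
    "kernel_mellin",
    "classify_kernel",
    "KERNEL_KINDS",
]

KERNEL_KINDS = (
    "uniform",
    "gaussian",
    "two_peaked_gaussian",
    "parabolic",
    "dirac_half",
    "custom",
)

#: relative threshold (w.r.t. max kappa) below which an endpoint value counts
#: as zero for the class-A/class-B dichotomy
TOL_ZERO = 1e-3


@dataclass(frozen=True)
class FragmentationParameters:
    """Power-law division rate B(x) = alpha * x**gamma.

    gamma > 0 means larger filaments are more likely to break (required for
    the self-similar long-time behaviour; gamma <= 0 gives no self-similar
    regime or finite-time shattering and is outside this package's scope).
    alpha > 0 sets the overall rate; time is unitless (seconds / 1 s).
    """

    gamma: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")

    def rate(self, x):
        """Division rate B(x) = alpha * x**gamma."""
        return self.alpha * np.asarray(x, dtype=float) ** self.gamma


@dataclass
class FragmentationKernel:
    """Relative daughter-size distribution kappa(z) on (0, 1).

    ``density`` evaluates the (renormalized) density; for the atomic
    ``dirac_half`` kernel the measure is 2*delta_{1/2} and ``density`` is
    None.  ``mellin_closed_form`` holds an exact Mellin transform when one
    is known, otherwise the transform falls back to adaptive quadrature.
    """

    kind_label: str
    params: dict = field(default_factory=dict)
    density: Callable[[np.ndarray], np.ndarray] | None = None
    mellin_closed_form: Callable[[complex], complex] | None = None

    # ------------------------------------------------------------------
    @property
    def is_atomic(self) -> bool:
        return self.kind_label == "dirac_half"

    def __call__(self, z):
        if self.is_atomic:
            raise TypeError("dirac_half kernel has no density; it is an atom of weight 2 at z = 1/2")
        return self.density(np.asarray(z, dtype=float))

    # ------------------------------------------------------------------
    def mellin(self, s: complex) -> complex:
        """Mellin transform K(s) = int_0^1 z^{s-1} kappa(z) dz.

        Converges for Re(s) >= 1 for every bounded kernel on (0, 1); values
        with 0 < Re(s) < 1 are accepted (the built-in densities are bounded
        so the integral still converges) but Re(s) <= 0 is refused.
        """
        s = complex(s)
        if s.real <= 0:
            raise ValueError(f"Mellin transform requires Re(s) > 0, got {s}")
        if self.mellin_closed_form is not None:
            return self.mellin_closed_form(s)
        return _mellin_quad(self.density, s)

    @property
    def kernel_class(self) -> str:
        return classify_kernel(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ps = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"FragmentationKernel({self.kind_label}{', ' + ps if ps else ''})"


def _mellin_quad(density, s: complex) -> complex:
    def re(z):
        return (np.power(z, s - 1) * density(np.asarray(z))).real

    def im(z):
        return (np.power(z, s - 1) * density(np.asarray(z))).imag

    # split at 1/2 to tame endpoint behaviour of peaked kernels
    pts = [0.0, 0.5, 1.0]
    r = sum(integrate.quad(re, a, b, limit=200)[0] for a, b in zip(pts[:-1], pts[1:]))
    i = sum(integrate.quad(im, a, b, limit=200)[0] for a, b in zip(pts[:-1], pts[1:]))
    return complex(r, i)


# ----------------------------------------------------------------------
# construction


def _renormalized(raw: Callable[[np.ndarray], np.ndarray], breaks: tuple[float, ...] = ()):
    """Rescale a raw nonnegative density so its integral over (0,1) is 2.

    ``breaks`` are interior points (peak locations) passed to the adaptive
    quadrature so that narrow peaks cannot be stepped over; a fixed grid
    would break the integral-2 contract at the 1e-8 level.
    """
    zg = np.linspace(0.0, 1.0, 4001)
    if np.any(raw(zg) < 0):
        raise ValueError("kernel density must be nonnegative on (0, 1)")
    pts = sorted({0.0, 0.5, 1.0, *breaks})
    total = sum(
        integrate.quad(lambda z: float(raw(np.asarray(z))), a, b, limit=200)[0]
        for a, b in zip(pts[:-1], pts[1:])
    )
    if total <= 0:
        raise ValueError("kernel density integrates to zero")
    c = 2.0 / total

    def density(z):
        z = np.asarray(z, dtype=float)
        out = c * raw(z)
        return np.where((z < 0) | (z > 1), 0.0, out)

    return density


def _gauss(z, center, sd):
    return np.exp(-0.5 * ((z - center) / sd) ** 2)


def make_kernel(kind_label: str, **params) -> FragmentationKernel:
    """Build one of the built-in fragmentation kernels.

    Parameters
    ----------
    kind_label:
        One of ``uniform``, ``gaussian`` (params ``center`` in (0,1), ``sd`` > 0),
        ``two_peaked_gaussian`` (params ``offset`` in (0, 1/2), ``sd`` > 0;
        symmetric sum of Gaussians at 1/2 +- offset), ``parabolic``
        (12 z (1-z)), ``dirac_half`` (atom of weight 2 at z = 1/2).

    Gaussian-family kernels are truncated to (0, 1) and renormalized to
    integral 2 by adaptive quadrature; being symmetric, they then satisfy
    the mass-conservation condition ``int z kappa = 1`` automatically.
    """
    if kind_label == "uniform":
        return FragmentationKernel(
            "uniform",
            {},
            density=lambda z: np.where((np.asarray(z) >= 0) & (np.asarray(z) <= 1), 2.0, 0.0),
            mellin_closed_form=lambda s: 2.0 / s,
        )
    if kind_label == "parabolic":
        return FragmentationKernel(
            "parabolic",
            {},
            density=lambda z: np.where(
                (np.asarray(z) >= 0) & (np.asarray(z) <= 1),
                12.0 * np.asarray(z) * (1.0 - np.asarray(z)),
                0.0,
            ),
            mellin_closed_form=lambda s: 12.0 / ((s + 1.0) * (s + 2.0)),
        )
    if kind_label == "dirac_half":
        return FragmentationKernel(
            "dirac_half",
            {},
            density=None,
            mellin_closed_form=lambda s: 2.0 ** (2.0 - s),
        )
    if kind_label == "gaussian":
        center = float(params.pop("center", 0.5))
        sd = float(params.pop("sd", 0.1))
        if params:
            raise ValueError(f"unknown gaussian kernel params: {sorted(params)}")
        if not (0.0 < center < 1.0):
            raise ValueError(f"gaussian kernel center must lie in (0, 1), got {center}")
        if not sd > 0:
            raise ValueError(f"gaussian kernel sd must be > 0, got {sd}")
        density = _renormalized(lambda z: _gauss(np.asarray(z, float), center, sd), breaks=(center,))
        return FragmentationKernel("gaussian", {"center": center, "sd": sd}, density=density)
    if kind_label == "two_peaked_gaussian":
        offset = float(params.pop("offset", 0.25))
        sd = float(params.pop("sd", 0.05))
        if params:
            raise ValueError(f"unknown two_peaked_gaussian params: {sorted(params)}")
        if not (0.0 < offset < 0.5):
            raise ValueError(f"two-peaked offset must lie in (0, 1/2), got {offset}")
        if not sd > 0:
            raise ValueError(f"two-peaked sd must be > 0, got {sd}")

        def raw(z):
            z = np.asarray(z, float)
            return _gauss(z, 0.5 - offset, sd) + _gauss(z, 0.5 + offset, sd)

        density = _renormalized(raw, breaks=(0.5 - offset, 0.5 + offset))
        return FragmentationKernel(
            "two_peaked_gaussian", {"offset": offset, "sd": sd}, density=density
        )
    raise ValueError(f"unknown kernel kind {kind_label!r}; choose from {KERNEL_KINDS}")


def kernel_from_table(z: np.ndarray, values: np.ndarray) -> FragmentationKernel:
    """Custom kernel from tabulated (z, kappa(z)) pairs, renormalized on load.

    Values are linearly interpolated inside the tabulated range and set to the
    endpoint values outside it (then cut at 0 and 1).
    """
    z = np.asarray(z, dtype=float)
    values = np.asarray(values, dtype=float)
    if z.ndim != 1 or z.shape != values.shape or z.size < 2:
        raise ValueError("need matching 1-d arrays of at least 2 tabulated points")
    if np.any(values < 0):
        raise ValueError("tabulated kernel values must be nonnegative")
    order = np.argsort(z)
    z, values = z[order], values[order]

    def raw(zz):
        return np.interp(np.asarray(zz, float), z, values)

    density = _renormalized(raw)
    return FragmentationKernel("custom", {"n_points": int(z.size)}, density=density)


def kernel_mellin(kernel: FragmentationKernel, s: complex) -> complex:
    """K(s) = int_0^1 z^{s-1} kappa(z) dz (closed form where available)."""
    return kernel.mellin(s)


def classify_kernel(kernel: FragmentationKernel, tol_zero: float = TOL_ZERO) -> str:
    """Class A (kappa vanishes at both endpoints: interior breakage),
    class B (kappa positive at both endpoints: end breakage), or 'mixed'.

    Endpoint values are compared against ``tol_zero`` times the kernel's
    maximum over (0, 1).
    """
    if kernel.is_atomic:
        return "A"  # all mass strictly inside (0, 1)
    eps = 1e-6
    k0 = float(kernel.density(np.array([eps]))[0])
    k1 = float(kernel.density(np.array([1.0 - eps]))[0])
    zg = np.linspace(eps, 1.0 - eps, 2001)
    kmax = float(np.max(kernel.density(zg)))
    lo, hi = k0 < tol_zero * kmax, k1 < tol_zero * kmax
    if lo and hi:
        return "A"
    if (not lo) and (not hi):
        return "B"
    return "mixed"


def kernel_check(kernel: FragmentationKernel) -> tuple[float, float]:
    """Return (int kappa, int z kappa) by adaptive quadrature (atoms exact)."""
    if kernel.is_atomic:
        return 2.0, 1.0
    pts = sorted({0.0, 0.5, 1.0, *(v for v in kernel.params.values() if 0 < v < 1)})
    if kernel.kind_label == "two_peaked_gaussian":
        off = kernel.params["offset"]
        pts = sorted(set(pts) | {0.5 - off, 0.5 + off})

    def piecewise(f):
        return sum(integrate.quad(f, a, b, limit=200)[0] for a, b in zip(pts[:-1], pts[1:]))

    total = piecewise(lambda z: float(kernel.density(np.asarray(z))))
    first = piecewise(lambda z: z * float(kernel.density(np.asarray(z))))
    return total, first
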