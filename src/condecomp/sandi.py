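"""Two-compartment (soma and neurite density) diffusion signal model.

Closed-form, direction-averaged signal fractions for the three water pools
used throughout this package:

* extracellular space — isotropic Gaussian diffusion,
* neurites — a powder average over randomly oriented sticks,
* soma — water restricted in an impermeable sphere, evaluated with the
  Gaussian phase distribution (GPD) approximation for a pulsed-gradient
  spin-echo sequence.

The total normalized signal at diffusion weighting ``b`` is

    S_b / S_0 = f_ic * (f_in * A_in + f_is * A_is) + f_ec * A_ec

with f_ic + f_ec = 1 (intra-/extracellular split) and f_in + f_is = 1
(neurite/soma split of the intracellular pool).

Units: b in s/mm², diffusivities in mm²/s, soma radius in mm (helpers accept
µm where stated), gradient timings in s, γ in rad·s⁻¹·T⁻¹ and the gradient
amplitude G in T/mm so that b = γ²G²δ²(Δ − δ/3) closes dimensionally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, spherical_jn

__all__ = [
    "GAMMA_PROTON",
    "D_IS_DEFAULT",
    "PulseSequence",
    "SandiParams",
    "GpdSeries",
    "gpd_roots",
    "signal_extracellular",
    "signal_neurite",
    "signal_soma",
    "sandi_signal",
]

#: Proton gyromagnetic ratio [rad s^-1 T^-1].
GAMMA_PROTON = 2.6752218744e8

#: Bulk diffusivity of water inside soma [mm^2/s], conventionally fixed to
#: control the ill-posedness of the six-parameter fit.
D_IS_DEFAULT = 2.0e-3


@dataclass(frozen=True)
class PulseSequence:
    """Single pulsed-gradient spin-echo timing.

    Parameters
    ----------
    delta : float
        Gradient pulse duration δ [s].
    Delta : float
        Separation of the two gradient pulses Δ [s].
    gamma : float
        Gyromagnetic ratio [rad s^-1 T^-1].
    """

    delta: float
    Delta: float
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        if not (0 < self.delta < self.Delta):
            raise ValueError(
                f"require 0 < delta < Delta, got delta={self.delta}, Delta={self.Delta}"
            )

    def gradient_amplitude(self, b):
        """Gradient amplitude G [T/mm] realizing diffusion weighting ``b`` [s/mm²].

        Uses the Stejskal–Tanner relation b = γ²G²δ²(Δ − δ/3).
        """
        b = np.asarray(b, dtype=float)
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        return np.sqrt(b / (self.gamma**2 * self.delta**2 * (self.Delta - self.delta / 3.0)))

    def bvalue(self, G):
        """Inverse of :meth:`gradient_amplitude` (G in T/mm → b in s/mm²)."""
        G = np.asarray(G, dtype=float)
        return self.gamma**2 * G**2 * self.delta**2 * (self.Delta - self.delta / 3.0)


@dataclass(frozen=True)
class SandiParams:
    """Voxel-level microstructure parameters.

    f_in is the neurite fraction of the *intracellular* space, f_ec the
    extracellular volume fraction; the remaining fractions are derived:
    f_ic = 1 − f_ec, f_is = 1 − f_in, f_ne = f_ic·f_in, f_so = f_ic·f_is.
    """

    f_in: float
    f_ec: float
    D_in: float  # mm^2/s
    D_ec: float  # mm^2/s
    r_s: float  # mm
    D_is: float = D_IS_DEFAULT  # mm^2/s, fixed by convention

    def __post_init__(self) -> None:
        for name in ("f_in", "f_ec"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("D_in", "D_ec", "D_is", "r_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def f_ic(self) -> float:
        return 1.0 - self.f_ec

    @property
    def f_is(self) -> float:
        return 1.0 - self.f_in

    @property
    def f_ne(self) -> float:
        return self.f_ic * self.f_in

    @property
    def f_so(self) -> float:
        return self.f_ic * self.f_is

    @property
    def r_s_um(self) -> float:
        return self.r_s * 1e3


def _root_equation(x):
    """x * [(1/x) J_{3/2}(x) - J_{5/2}(x)] rewritten through trigonometric form.

    Using half-integer Bessel identities the root condition
    (1/x) J_{3/2}(x) = J_{5/2}(x) reduces to
    2 sin x − 2 x cos x − x² sin x = 0 (equivalently tan x = 2x / (2 − x²)),
    which is continuous and convenient to bracket.
    """
    return 2.0 * np.sin(x) - 2.0 * x * np.cos(x) - x**2 * np.sin(x)


@lru_cache(maxsize=None)
def _cached_roots(n_terms: int) -> tuple:
    roots = []
    for m in range(1, n_terms + 1):
        lo = (m - 1) * np.pi + 1e-9
        hi = m * np.pi - 1e-9
        r = brentq(_root_equation, lo, hi, xtol=1e-14, rtol=8.9e-16)
        roots.append(r)
    return tuple(roots)


def gpd_roots(n_terms: int) -> np.ndarray:
    """First ``n_terms`` positive roots x_m of (1/x)J_{3/2}(x) = J_{5/2}(x).

    The m-th root lies in ((m−1)π, mπ) and approaches mπ from below; the
    first root is x₁ ≈ 2.0816. Roots are cached.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    return np.array(_cached_roots(int(n_terms)))


@dataclass(frozen=True)
class GpdSeries:
    """Truncated root series for the GPD sphere signal."""

    n_terms: int = 50
    roots: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.roots is None:
            object.__setattr__(self, "roots", gpd_roots(self.n_terms))
        r = np.asarray(self.roots)
        if not np.all(np.diff(r) > 0):
            raise ValueError("roots must be strictly increasing")
        # the factor 1/(x_m² − 2) below is safe: the smallest root ≈ 2.08 > √2
        if r[0] ** 2 <= 2.0:
            raise ValueError("first root must satisfy x² > 2")
        # spot-check the defining Bessel equation
        resid = np.abs(spherical_jn(1, r, derivative=True))
        # x^{-1}J_{3/2} = J_{5/2}  <=>  j1'(x) = 0 (spherical Bessel derivative)
        if np.any(resid > 1e-10):
            raise ValueError("root residual exceeds 1e-10")


def signal_extracellular(b, D_ec):
    """Normalized extracellular signal A_ec = exp(−b·D_ec)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if np.any(np.asarray(D_ec) <= 0):
        raise ValueError("D_ec must be > 0")
    return np.exp(-b * np.asarray(D_ec, dtype=float))


def signal_neurite(b, D_in):
    """Powder-averaged stick signal A_in = √(π/(4bD)) · erf(√(bD)).

    The b·D_in → 0 limit is 1; evaluated via the closed form with a series
    guard below 1e-12.
    """
    bD = np.asarray(b, dtype=float) * np.asarray(D_in, dtype=float)
    if np.any(bD < 0):
        raise ValueError("b * D_in must be non-negative")
    scalar = bD.ndim == 0
    bD = np.atleast_1d(bD)
    out = np.ones_like(bD)
    nz = bD >= 1e-12
    out[nz] = np.sqrt(np.pi / (4.0 * bD[nz])) * erf(np.sqrt(bD[nz]))
    return float(out[0]) if scalar else out


def log_signal_soma(b, r_s, seq: PulseSequence, D_is: float = D_IS_DEFAULT,
                    series: GpdSeries | None = None):
    """log of the GPD sphere signal; broadcasts over b and r_s.

    log A_is = −(2(γG)²/D_is) Σ_m [α_m⁻⁴ / (α_m²r_s² − 2)] (2δ − Ψ_m),
    α_m = x_m / r_s, and Ψ_m the standard exponential bracket of the GPD
    approximation.
    """
    if series is None:
        series = GpdSeries()
    b = np.asarray(b, dtype=float)
    r_s = np.asarray(r_s, dtype=float)
    if np.any(r_s <= 0):
        raise ValueError("r_s must be > 0")
    G = seq.gradient_amplitude(b)
    shape = np.broadcast_shapes(b.shape, r_s.shape)
    r_ = np.broadcast_to(r_s, shape)[..., None]
    G_ = np.broadcast_to(G, shape)

    x = series.roots  # (M,)
    alpha2D = (x / r_) ** 2 * D_is  # [1/s]
    d, D = seq.delta, seq.Delta
    psi = (
        2.0
        + np.exp(-alpha2D * (D - d))
        - 2.0 * np.exp(-alpha2D * d)
        - 2.0 * np.exp(-alpha2D * D)
        + np.exp(-alpha2D * (D + d))
    ) / alpha2D
    # alpha^{-4} = r_s^4 / x^4 ;  alpha^2 r_s^2 − 2 = x² − 2
    terms = (r_**4 / x**4) / (x**2 - 2.0) * (2.0 * d - psi)
    s = terms.sum(axis=-1)
    return -(2.0 * (seq.gamma * G_) ** 2 / D_is) * s


def signal_soma(b, r_s, seq: PulseSequence, D_is: float = D_IS_DEFAULT,
                series: GpdSeries | None = None, check_convergence: bool = False):
    """Normalized soma signal A_is under the GPD approximation.

    A_is(b=0) = 1 exactly; A_is → 1 as r_s → 0 (fully restricted spins
    accumulate no net phase). With ``check_convergence`` the truncation is
    compared against a series twice as long and a warning is raised if
    log A_is moves by more than 1e-8.
    """
    if series is None:
        series = GpdSeries()
    logA = log_signal_soma(b, r_s, seq, D_is=D_is, series=series)
    if check_convergence:
        longer = GpdSeries(n_terms=2 * series.n_terms)
        logA2 = log_signal_soma(b, r_s, seq, D_is=D_is, series=longer)
        if np.max(np.abs(logA - logA2)) > 1e-8:
            warnings.warn(
                "GPD series truncation not converged to 1e-8 in log-signal; "
                "increase n_terms",
                RuntimeWarning,
            )
    return np.exp(logA)


def sandi_signal(b_list, params: SandiParams, seq: PulseSequence,
                 series: GpdSeries | None = None):
    """Total normalized signal S_b/S_0 of the three-pool mixture per shell.

    Exactly 1 at b = 0; bounded by the min/max of the pool signals at any b.
    """
    b = np.atleast_1d(np.asarray(b_list, dtype=float))
    a_ec = signal_extracellular(b, params.D_ec)
    a_in = signal_neurite(b, params.D_in)
    a_is = signal_soma(b, params.r_s, seq, D_is=params.D_is, series=series)
    return params.f_ic * (params.f_in * a_in + params.f_is * a_is) + params.f_ec * a_ec
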