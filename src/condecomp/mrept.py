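"""Phase-based MREPT: high-frequency conductivity from the transceive phase.

Under the assumption σ_H ≫ ωε_H, the transceive phase φ^tr and the
resistivity τ_H = 1/σ_H satisfy the convection–reaction equation

    ∇φ^tr · ∇τ_H + τ_H ∇²φ^tr = 2ωμ₀.

The equation is noise-sensitive, so a small artificial diffusion term is
added as a stabilizer (it acts as a low-pass filter on the recovered map):

    −c ∇²τ_H + ∇φ^tr · ∇τ_H + τ_H ∇²φ^tr = 2ωμ₀.

Discretization is plain central differences on the (possibly anisotropic)
voxel grid; all spatial derivatives are taken in SI meters so σ_H lands in
S/m, and the usual printed values of c (0.02 … 1) apply verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import lgmres, spilu, splu, LinearOperator

from .volumes import PhaseVolume

__all__ = ["MU_0", "PdeConfig", "ConductivityMap", "laplacian_estimate_sigma", "solve_stabilized_pde"]

log = logging.getLogger(__name__)

#: Vacuum permeability [T·m/A].
MU_0 = 4.0e-7 * np.pi

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class PdeConfig:
    """Configuration of the stabilized conductivity PDE.

    Parameters
    ----------
    c : float
        Artificial diffusion coefficient (dimensionless as conventionally
        printed; typical values 0.02–1, larger = smoother maps).
    omega : float
        Larmor angular frequency [rad/s]; defaults to 2π × 128 MHz (3 T).
    boundary_band : int
        Width in voxels of the band along the mask edge where Dirichlet
        values of τ_H are estimated from the Laplacian-based formula.
    smooth_sigma : float
        Gaussian pre-smoothing (in voxels) of the phase before forming the
        Laplacian-based boundary estimate; 0 disables.
    """

    c: float = 0.05
    omega: float = 2.0 * np.pi * 128e6
    mu0: float = MU_0
    boundary_band: int = 2
    smooth_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.boundary_band < 1:
            raise ValueError("boundary_band must be >= 1")

    @classmethod
    def at_field_strength(cls, b0_tesla: float, **kw) -> "PdeConfig":
        """Config with ω = γ·B0 for the proton Larmor frequency."""
        from .sandi import GAMMA_PROTON

        return cls(omega=GAMMA_PROTON * b0_tesla, **kw)


@dataclass
class ConductivityMap:
    """High-frequency conductivity σ_H [S/m] and its reciprocal τ_H."""

    sigma_h: np.ndarray
    valid_mask: np.ndarray
    residual: float = 0.0

    @property
    def tau_h(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            tau = np.where(self.valid_mask, 1.0 / self.sigma_h, 0.0)
        return tau


def _derivatives(phi: np.ndarray, spacing_m, mask: np.ndarray):
    """Central first/second differences of φ in meters, valid on eroded mask."""
    grads = []
    lap = np.zeros_like(phi)
    for ax, h in enumerate(spacing_m):
        plus = np.roll(phi, -1, axis=ax)
        minus = np.roll(phi, 1, axis=ax)
        grads.append((plus - minus) / (2.0 * h))
        lap += (plus - 2.0 * phi + minus) / h**2
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6)
    return grads, lap, interior


def laplacian_estimate_sigma(phase: PhaseVolume, config: PdeConfig) -> ConductivityMap:
    """Pointwise conductivity estimate σ ≈ ∇²φ^tr / (2ωμ₀).

    Valid where the homogeneous-tissue approximation (locally constant τ)
    holds; used here as the boundary/initial estimate for the full PDE.
    Voxels whose finite-difference stencil leaves the mask, or where the
    estimate is non-positive, are excluded from ``valid_mask``.
    """
    phi = phase.phi_tr
    margin = 0
    if config.smooth_sigma > 0:
        phi = ndimage.gaussian_filter(phi, config.smooth_sigma)
        # smoothing drags boundary-condition artifacts a few voxels inward
        margin = int(np.ceil(2.0 * config.smooth_sigma))
    spacing_m = [s * 1e-3 for s in phase.spacing]
    _, lap, interior = _derivatives(phi, spacing_m, phase.mask)
    if margin:
        interior = ndimage.binary_erosion(interior, structure=_STRUCT6, iterations=margin)
    sigma = lap / (2.0 * config.omega * config.mu0)
    valid = interior & (sigma > 0)
    sigma = np.where(valid, sigma, 0.0)
    return ConductivityMap(sigma_h=sigma, valid_mask=valid)


def solve_stabilized_pde(phase: PhaseVolume, config: PdeConfig,
                         rtol: float = 1e-8,
                         ilu_drop_tol: float = 1e-4,
                         ilu_fill_factor: float = 8.0) -> ConductivityMap:
    """Solve the stabilized convection–reaction PDE for τ_H and return σ_H.

    Dirichlet boundary values of τ_H on a ``boundary_band``-voxel band along
    the mask edge are taken from the band average of the Laplacian-based
    estimate. The sparse linear system is solved directly for small problems
    and with an ILU-preconditioned Krylov method otherwise; the relative
    residual is recorded on the result and must reach ``rtol``.

    Voxels where the recovered τ_H is non-positive are removed from
    ``valid_mask`` and their count logged.
    """
    mask = phase.mask
    band = config.boundary_band
    core = ndimage.binary_erosion(mask, structure=_STRUCT6, iterations=band)
    if not core.any():
        raise ValueError("mask too thin: no interior left after boundary band erosion")
    band_mask = mask & ~core

    est = laplacian_estimate_sigma(phase, config)
    # average the pointwise estimate over a collar just inside the band;
    # widen the collar if smoothing has invalidated the nearest voxels
    collar_width = band
    band_sigma = np.empty(0)
    while collar_width <= max(mask.shape):
        collar = mask & ~ndimage.binary_erosion(mask, structure=_STRUCT6,
                                                iterations=collar_width)
        band_sigma = est.sigma_h[collar & est.valid_mask]
        if band_sigma.size:
            break
        collar_width += 1
    if band_sigma.size == 0:
        raise ValueError("no valid Laplacian estimate available near the boundary band")
    tau_boundary = 1.0 / float(np.mean(band_sigma))

    # the same pre-smoothing used for the boundary estimate is applied to the
    # data term: derivatives of raw phase at realistic SNR are noise-dominated
    phi = phase.phi_tr
    if config.smooth_sigma > 0:
        phi = ndimage.gaussian_filter(phi, config.smooth_sigma)
    spacing_m = [s * 1e-3 for s in phase.spacing]
    grads, lap, _ = _derivatives(phi, spacing_m, mask)

    idx = -np.ones(mask.shape, dtype=np.int64)
    pts = np.argwhere(core)
    idx[core] = np.arange(len(pts))
    n = len(pts)

    rows, cols, vals = [], [], []
    rhs = np.full(n, 2.0 * config.omega * config.mu0)
    diag = lap[core].copy()  # reaction term τ∇²φ

    tau_fixed = np.full(mask.shape, tau_boundary)

    for ax, h in enumerate(spacing_m):
        g = grads[ax][core]
        for sgn in (+1, -1):
            nb = pts.copy()
            nb[:, ax] += sgn
            nb_idx = idx[tuple(nb.T)]
            # -c ∂²/∂x² -> off-diag -c/h², diag +2c/h² (added once per axis below)
            # convection g ∂/∂x -> ±g/(2h)
            coef = -config.c / h**2 + sgn * g / (2.0 * h)
            inside = nb_idx >= 0
            rows.append(np.nonzero(inside)[0])
            cols.append(nb_idx[inside])
            vals.append(coef[inside])
            out = ~inside
            if out.any():
                nb_out = tuple(nb[out].T)
                rhs[out] -= coef[out] * tau_fixed[nb_out]
        diag += 2.0 * config.c / h**2

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )

    bnorm = np.linalg.norm(rhs)
    if n <= 40_000:
        try:
            tau = splu(A.tocsc()).solve(rhs)
        except RuntimeError as e:  # pragma: no cover - singular systems
            raise RuntimeError(
                f"PDE system is singular or ill-conditioned ({e}); "
                "consider increasing the diffusion coefficient c"
            ) from e
    else:
        ilu = spilu(A.tocsc(), drop_tol=ilu_drop_tol, fill_factor=ilu_fill_factor)
        M = LinearOperator(A.shape, ilu.solve)
        x0 = np.full(n, tau_boundary)
        tau, info = lgmres(A, rhs, x0=x0, M=M, rtol=rtol * 0.1, maxiter=2000)
        if info != 0:
            raise RuntimeError(f"Krylov solver failed to converge (info={info})")
    resid = float(np.linalg.norm(A @ tau - rhs) / bnorm)
    if resid > rtol:
        raise RuntimeError(
            f"linear solve residual {resid:.2e} exceeds tolerance {rtol:.1e}; "
            "system may be ill-conditioned (try larger c)"
        )

    tau_full = np.where(mask, tau_boundary, 0.0)
    tau_full[core] = tau

    valid = mask & (tau_full > 0)
    n_bad = int(np.count_nonzero(mask & ~valid))
    if n_bad:
        frac = n_bad / int(mask.sum())
        log.warning("solve_stabilized_pde: %d voxels (%.1f%%) with non-positive tau excluded",
                    n_bad, 100 * frac)
    sigma = np.zeros_like(tau_full)
    sigma[valid] = 1.0 / tau_full[valid]
    return ConductivityMap(sigma_h=sigma, valid_mask=valid, residual=resid)


def total_variation(arr: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Anisotropic total variation Σ|∇arr| over in-mask voxel pairs.

    Used to quantify the low-pass action of the diffusion coefficient c:
    on fixed noisy input, TV of σ_H is non-increasing in c.
    """
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    tv = 0.0
    for ax in range(arr.ndim):
        d = np.diff(arr, axis=ax)
        m = np.logical_and(
            np.take(mask, range(0, mask.shape[ax] - 1), axis=ax),
            np.take(mask, range(1, mask.shape[ax]), axis=ax),
        )
        tv += float(np.abs(d[m]).sum())
    return tv
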