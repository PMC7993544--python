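"""Synthetic phantom generators: every input the pipeline consumes.

Provides

* a forward B1-phase simulator consistent with a prescribed conductivity map
  (divergence-form elliptic solve, plus the closed-form quadratic phase for
  uniform conductivity),
* a giant-vesicle suspension diffusion phantom (spheres + free water; no
  neurites), emulating an electrolyte phantom whose inclusion holds a
  lipid-vesicle suspension,
* Gaussian acquisition noise at stated phase/diffusion SNR levels, and
* sinusoidal-motion corruption applied through the k-space point spread
  function.

All generators are seed-deterministic and emit ground-truth maps so every
downstream stage can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import lgmres, splu, LinearOperator, spilu

from .mrept import MU_0, PdeConfig
from .sandi import PulseSequence, SandiParams, signal_extracellular, signal_soma
from .volumes import DwiDataset, PhaseVolume

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "MotionSpec",
    "vesicle_phantom",
    "quadratic_phase",
    "forward_phase",
    "vesicle_dwi",
    "add_acquisition_noise",
    "apply_motion_psf",
]


@dataclass
class PhantomSpec:
    """Two-region phantom geometry and per-region ground truth.

    ``geometry`` labels each voxel: 0 = background electrolyte, 1 = ROI
    inclusion. ``sigma_true`` maps labels to conductivity [S/m];
    ``sandi_true`` maps labels to microstructure parameters. The vesicle
    statistics describe the diameter distribution of the suspension
    (truncated normal, mean 13 µm, sd 4.7 µm).
    """

    geometry: np.ndarray
    spacing: tuple
    sigma_true: dict
    sandi_true: dict
    vesicle_diameter_um: tuple = (13.0, 4.7)

    def __post_init__(self) -> None:
        self.geometry = np.asarray(self.geometry, dtype=int)
        labels = set(np.unique(self.geometry))
        if not labels <= set(self.sigma_true):
            raise ValueError("sigma_true must cover all geometry labels")
        if any(s <= 0 for s in self.sigma_true.values()):
            raise ValueError("conductivities must be > 0")

    @property
    def mask(self) -> np.ndarray:
        return np.ones(self.geometry.shape, dtype=bool)

    @property
    def sigma_map(self) -> np.ndarray:
        out = np.zeros(self.geometry.shape)
        for lab, s in self.sigma_true.items():
            out[self.geometry == lab] = s
        return out

    def true_param_maps(self) -> dict:
        """Ground-truth voxel maps of the microstructure parameters."""
        maps = {k: np.zeros(self.geometry.shape) for k in ("f_in", "f_ec", "D_in", "D_ec", "r_s")}
        for lab, p in self.sandi_true.items():
            sel = self.geometry == lab
            for k in maps:
                maps[k][sel] = getattr(p, k)
        return maps


@dataclass(frozen=True)
class NoiseSpec:
    """Acquisition noise levels: Gaussian std = ⟨S⟩ / (√2 · SNR).

    ``snr_p`` applies to the (complex) phase data, ``snr_d`` to the b = 0
    diffusion signal; ``None`` or ``inf`` means noise-free. Per the shared
    convention, the realization drawn for S_0 is re-used for every S_b.
    """

    snr_p: float | None = None
    snr_d: float | None = None
    seed: int = 0
    shared_realization: bool = True

    def __post_init__(self) -> None:
        for v in (self.snr_p, self.snr_d):
            if v is not None and v <= 0:
                raise ValueError("SNR must be positive (or None for noise-free)")


@dataclass(frozen=True)
class MotionSpec:
    """Sinusoidal in-plane motion during the phase-encode loop.

    Amplitude in pixel-displacement units, frequency in Hz; one k-space line
    is acquired per TR along the phase-encode axis.
    """

    amplitude: float = 1.0
    frequency_hz: float = 2.0
    axis: int = 1
    tr_s: float = 2.2

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.axis not in (0, 1):
            raise ValueError("motion axis must be an in-plane axis (0 or 1)")


def vesicle_phantom(shape=(48, 48, 24), spacing=(2.0, 2.0, 2.0),
                    roi_radius_frac: float = 0.55,
                    sigma_bg: float = 0.8, sigma_roi: float = 1.0,
                    f_ic_roi: float = 0.425, d_ec_roi: float = 1.4e-3,
                    d_free: float = 2.0e-3) -> PhantomSpec:
    """Standard vesicle-suspension phantom: cylindrical ROI in electrolyte.

    The ROI mixes electrolyte and vesicles in equal volume so the
    intracellular fraction is ≈ 0.40–0.45 (default 0.425, i.e. f_ec = 0.575);
    the background is pure NaCl solution modelled as free Gaussian water.
    Extracellular diffusivity inside the suspension is hindered (default
    1.4×10⁻³ mm²/s); background water uses the free value 2.0×10⁻³ mm²/s.
    """
    nx, ny, nz = shape
    x, y = np.meshgrid(np.arange(nx) - (nx - 1) / 2, np.arange(ny) - (ny - 1) / 2, indexing="ij")
    r2 = (x / nx) ** 2 + (y / ny) ** 2
    roi2d = r2 <= (roi_radius_frac / 2) ** 2
    geometry = np.zeros(shape, dtype=int)
    geometry[roi2d] = 1

    mean_r_mm = vesicle_phantom_mean_radius_mm()
    sandi_true = {
        0: SandiParams(f_in=0.0, f_ec=1.0 - 1e-12, D_in=d_free, D_ec=d_free, r_s=mean_r_mm),
        1: SandiParams(f_in=0.0, f_ec=1.0 - f_ic_roi, D_in=d_ec_roi, D_ec=d_ec_roi, r_s=mean_r_mm),
    }
    # background f_ec numerically 1 (pure electrolyte); keep strictly < 1 for validity
    return PhantomSpec(
        geometry=geometry,
        spacing=spacing,
        sigma_true={0: sigma_bg, 1: sigma_roi},
        sandi_true=sandi_true,
    )


def vesicle_phantom_mean_radius_mm(diameter_um=(13.0, 4.7)) -> float:
    return diameter_um[0] / 2.0 * 1e-3


def _grid_coords_m(shape, spacing_mm):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s * 1e-3
        for n, s in zip(shape, spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def quadratic_phase(shape, spacing_mm, sigma: float, omega: float = PdeConfig.omega,
                    mu0: float = MU_0) -> np.ndarray:
    """Closed-form transceive phase for uniform conductivity.

    φ = ωμ₀σ (x² + y² + z²)/3 has ∇²φ = 2ωμ₀σ and solves the conductivity
    PDE exactly with constant τ = 1/σ.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    xx, yy, zz = _grid_coords_m(shape, spacing_mm)
    return omega * mu0 * sigma * (xx**2 + yy**2 + zz**2) / 3.0


def forward_phase(spec: PhantomSpec, config: PdeConfig | None = None) -> PhaseVolume:
    """Forward-simulate the transceive phase for a prescribed conductivity map.

    Solves the divergence form ∇·(τ∇φ) = 2ωμ₀ (the conductivity PDE read as
    an equation for φ at known τ) by a finite-volume scheme with harmonic
    face averaging of τ, with Dirichlet boundary values from the closed-form
    quadratic phase of the *boundary-region* conductivity. For a uniform map
    the result coincides with the closed form.
    """
    if config is None:
        config = PdeConfig()
    sigma = spec.sigma_map
    if np.any(sigma <= 0):
        raise ValueError("sigma_true must be positive everywhere")
    tau = 1.0 / sigma
    shape = sigma.shape
    spacing_m = [s * 1e-3 for s in spec.spacing]

    # Dirichlet boundary from the closed form of the conductivity most
    # common on the domain boundary (the background electrolyte).
    edge = np.zeros(shape, dtype=bool)
    for ax in range(3):
        edge[tuple(slice(0, 1) if a == ax else slice(None) for a in range(3))] = True
        edge[tuple(slice(-1, None) if a == ax else slice(None) for a in range(3))] = True
    sigma_edge = float(np.median(sigma[edge]))
    phi_bc = quadratic_phase(shape, spec.spacing, sigma_edge, config.omega, config.mu0)

    interior = ~edge
    idx = -np.ones(shape, dtype=np.int64)
    pts = np.argwhere(interior)
    idx[interior] = np.arange(len(pts))
    n = len(pts)

    rows, cols, vals = [], [], []
    rhs = np.full(n, 2.0 * config.omega * config.mu0)
    diag = np.zeros(n)
    for ax, h in enumerate(spacing_m):
        for sgn in (+1, -1):
            nb = pts.copy()
            nb[:, ax] += sgn
            tau_face = 2.0 / (1.0 / tau[tuple(pts.T)] + 1.0 / tau[tuple(nb.T)])
            coef = tau_face / h**2
            diag -= coef
            nb_idx = idx[tuple(nb.T)]
            inside = nb_idx >= 0
            rows.append(np.nonzero(inside)[0])
            cols.append(nb_idx[inside])
            vals.append(coef[inside])
            out = ~inside
            if out.any():
                rhs[out] -= coef[out] * phi_bc[tuple(nb[out].T)]
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )

    # A is symmetric negative definite (finite-volume Laplacian-type operator)
    if n <= 40_000:
        phi_in = splu(A.tocsc()).solve(rhs)
    else:
        ilu = spilu(A.tocsc(), drop_tol=1e-5, fill_factor=10)
        M = LinearOperator(A.shape, ilu.solve)
        phi_in, info = lgmres(A, rhs, x0=phi_bc[interior], M=M, rtol=1e-10, maxiter=3000)
        if info != 0:
            raise RuntimeError(f"forward phase solve failed to converge (info={info})")
        resid = np.linalg.norm(A @ phi_in - rhs) / np.linalg.norm(rhs)
        if resid > 1e-8:
            raise RuntimeError(f"forward phase residual {resid:.2e} too large")

    phi = phi_bc.copy()
    phi[interior] = phi_in
    return PhaseVolume(phi_tr=phi, spacing=spec.spacing, mask=spec.mask)


def _radius_quadrature(diameter_um=(13.0, 4.7), n_points: int = 64):
    """Quadrature nodes/weights over the truncated-normal vesicle radius [mm].

    Radius = diameter/2; the normal is truncated to positive support, and the
    generator refuses distributions whose non-positive mass exceeds 1%.
    """
    from scipy.stats import norm

    mu, sd = diameter_um[0] / 2.0, diameter_um[1] / 2.0
    if norm.cdf(0.0, loc=mu, scale=sd) > 0.01:
        raise ValueError("vesicle radius distribution has >1% non-positive mass")
    lo, hi = max(1e-3, mu - 4 * sd), mu + 4 * sd
    x, w = np.polynomial.legendre.leggauss(n_points)
    r = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    wt = w * norm.pdf(r, loc=mu, scale=sd)
    wt /= wt.sum()
    return r * 1e-3, wt  # mm


def vesicle_dwi(spec: PhantomSpec, shells, directions, seq: PulseSequence,
                s0_value: float = 100.0, n_b0: int = 1,
                distributed_radius: bool = True, n_quad: int = 64) -> DwiDataset:
    """Diffusion signals of the vesicle phantom (isotropic; no neurites).

    ROI voxels: S_b/S_0 = f_ec·exp(−b·D_ec) + f_ic·⟨A_is(r)⟩ with the soma
    signal averaged over the vesicle radius distribution (or evaluated at the
    mean radius when ``distributed_radius`` is off). Background voxels are
    pure Gaussian free water. Spheres and free water are isotropic, so the
    signal is identical in every gradient direction.
    """
    shells = np.asarray(shells, dtype=float)
    directions = np.asarray(directions, dtype=float)
    if directions.ndim != 2 or directions.shape[1] != 3:
        raise ValueError("directions must be (N, 3)")
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)

    if distributed_radius:
        r_mm, wts = _radius_quadrature(spec.vesicle_diameter_um, n_quad)
        a_is_shell = {}
        for b in shells:
            a_is_shell[b] = float(np.sum(wts * signal_soma(b, r_mm, seq)))
    else:
        r0 = vesicle_phantom_mean_radius_mm(spec.vesicle_diameter_um)
        a_is_shell = {b: float(signal_soma(b, r0, seq)) for b in shells}

    shape = spec.geometry.shape
    per_region = {}
    for lab, p in spec.sandi_true.items():
        sig = np.empty(len(shells))
        for i, b in enumerate(shells):
            a_ec = float(signal_extracellular(b, p.D_ec))
            sig[i] = p.f_ec * a_ec + p.f_ic * a_is_shell[b]
        per_region[lab] = sig

    n_dir = len(directions)
    bvals = np.concatenate([np.zeros(n_b0), np.repeat(shells, n_dir)])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), np.tile(directions, (len(shells), 1))])

    signals = np.empty(shape + (len(bvals),))
    s0 = np.full(shape, s0_value)
    norm_sig = np.ones(shape + (len(shells),))
    for lab, sig in per_region.items():
        norm_sig[spec.geometry == lab] = sig
    signals[..., :n_b0] = s0_value
    for i, _ in enumerate(shells):
        start = n_b0 + i * n_dir
        signals[..., start : start + n_dir] = (s0_value * norm_sig[..., i])[..., None]

    return DwiDataset(signals=signals, s0=s0, bvals=bvals, bvecs=bvecs, seq=seq,
                      spacing=spec.spacing, mask=spec.mask)


def add_acquisition_noise(phase: PhaseVolume, dwi: DwiDataset | None,
                          noise: NoiseSpec):
    """Add zero-mean Gaussian acquisition noise at the stated SNR levels.

    Phase channel: Gaussian noise of std ⟨S⟩/(√2·SNR_P) is added to the real
    and imaginary parts of a unit-magnitude complex signal carrying the
    phase, and the phase re-extracted (the standard complex-channel noise
    convention; ⟨S⟩ = 1 on the unit-magnitude signal).

    Diffusion channel: std = ⟨S₀⟩/(√2·SNR_D) added to S₀ and to every S_b;
    with ``shared_realization`` the same draw made for S₀ corrupts each S_b,
    otherwise each volume gets an independent draw.
    """
    rng = np.random.default_rng(noise.seed)

    new_phase = phase
    if noise.snr_p is not None and np.isfinite(noise.snr_p):
        std = 1.0 / (np.sqrt(2.0) * noise.snr_p)
        z = np.exp(1j * phase.phi_tr)
        z = z + rng.normal(0.0, std, phase.phi_tr.shape) \
              + 1j * rng.normal(0.0, std, phase.phi_tr.shape)
        # re-anchor each voxel's noisy phase near the clean value so smooth
        # (possibly multi-cycle) simulated phase fields stay unwrapped
        dphi = np.angle(z * np.exp(-1j * phase.phi_tr))
        new_phase = PhaseVolume(phi_tr=phase.phi_tr + dphi, spacing=phase.spacing,
                                mask=phase.mask, affine=phase.affine)

    new_dwi = dwi
    if dwi is not None and noise.snr_d is not None and np.isfinite(noise.snr_d):
        std = float(np.mean(dwi.s0[dwi.mask])) / (np.sqrt(2.0) * noise.snr_d)
        n0 = rng.normal(0.0, std, dwi.s0.shape)
        s0 = dwi.s0 + n0
        signals = dwi.signals.copy()
        if noise.shared_realization:
            signals += n0[..., None]
        else:
            signals += rng.normal(0.0, std, signals.shape)
        s0 = np.clip(s0, 1e-6, None)
        new_dwi = DwiDataset(signals=signals, s0=s0, bvals=dwi.bvals, bvecs=dwi.bvecs,
                             seq=dwi.seq, spacing=dwi.spacing, mask=dwi.mask,
                             affine=dwi.affine)
    return new_phase, new_dwi


def apply_motion_psf(volume: np.ndarray, motion: MotionSpec) -> np.ndarray:
    """Corrupt a complex slice stack with sinusoidal-motion k-space modulation.

    One phase-encode line is acquired per TR; a rigid in-plane displacement
    d(t) = A·sin(2πft) at acquisition time t multiplies that k-space line by
    exp(−2πi·k·d/N) (Fourier shift theorem), which is equivalent to
    convolving the image with the motion point spread function. The
    modulation is phase-only, so k-space energy is preserved; amplitude 0 is
    the identity. Periodic motion produces ghost replicas along the
    phase-encode axis.
    """
    vol = np.asarray(volume, dtype=complex)
    if vol.ndim == 2:
        vol = vol[..., None]
        squeeze = True
    else:
        squeeze = False
    if motion.amplitude == 0:
        out = vol.copy()
        return out[..., 0] if squeeze else out

    pe = motion.axis
    n_pe = vol.shape[pe]
    lines = np.arange(n_pe)
    t = lines * motion.tr_s
    disp = motion.amplitude * np.sin(2.0 * np.pi * motion.frequency_hz * t)
    k = lines - n_pe // 2  # fftshifted frequency index of each line
    mod = np.exp(-2j * np.pi * k * disp / n_pe)

    out = np.empty_like(vol)
    for z in range(vol.shape[2]):
        ksp = np.fft.fftshift(np.fft.fft2(vol[:, :, z]))
        if pe == 0:
            ksp *= mod[:, None]
        else:
            ksp *= mod[None, :]
        out[:, :, z] = np.fft.ifft2(np.fft.ifftshift(ksp))
    return out[..., 0] if squeeze else out
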