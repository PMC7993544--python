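"""Volume containers, NIfTI / gradient-table IO, echo combination and
k-space zero-filling.

Conventions: 0-based voxel indices, spacing in mm, phases stored wrapped in
(−π, π] unless explicitly unwrapped. World (affine) transforms are carried as
metadata for round-trip writing; all computation happens in voxel/mm space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import nibabel as nib
import numpy as np

from .sandi import GAMMA_PROTON, PulseSequence

__all__ = [
    "Volume",
    "PhaseVolume",
    "EchoSet",
    "DwiDataset",
    "read_volume",
    "write_volume",
    "read_gradient_table",
    "combine_echo_phases",
    "zero_fill_interpolate",
    "unwrap_phase_volume",
]

log = logging.getLogger(__name__)


class Volume(NamedTuple):
    """A raw image array with voxel spacing [mm] and optional affine."""

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray | None = None


@dataclass
class PhaseVolume:
    """3D transceive phase field φ^tr [rad] on a voxel grid.

    The transceive phase is the sum of the transmit and receive B1 phases,
    the quantity measurable with spin-echo MRI and the data term of the
    conductivity PDE.
    """

    phi_tr: np.ndarray
    spacing: tuple
    mask: np.ndarray = None  # type: ignore[assignment]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phi_tr = np.asarray(self.phi_tr, dtype=float)
        if self.phi_tr.ndim != 3:
            raise ValueError("phi_tr must be 3D")
        if self.mask is None:
            self.mask = np.ones(self.phi_tr.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.phi_tr.shape:
            raise ValueError("mask shape must match phase shape")
        if not self.mask.any():
            raise ValueError("mask is empty")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 strictly positive values")
        if not np.all(np.isfinite(self.phi_tr[self.mask])):
            raise ValueError("phase must be finite inside the mask")


@dataclass
class EchoSet:
    """Per-echo complex spin-echo signals S̃_k, k = 1..NE (1-based indices).

    ``echo_parity_used`` lists the 1-based echo indices entering the phase
    combination; odd echoes by default, avoiding the alternating background
    phase of consecutive 180° refocusing pulses.
    """

    complex_signals: list
    echo_parity_used: tuple = (1, 3, 5)
    spacing: tuple = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.complex_signals = [np.asarray(s, dtype=complex) for s in self.complex_signals]
        shapes = {s.shape for s in self.complex_signals}
        if len(shapes) != 1:
            raise ValueError("all echo volumes must share a shape")
        if any(k < 1 or k > len(self.complex_signals) for k in self.echo_parity_used):
            raise ValueError("selected echo index out of range")


@dataclass
class DwiDataset:
    """Multi-b, multi-direction diffusion dataset.

    ``signals`` is 4D (x, y, z, n_meas) with one volume per (b, direction)
    pair in ``bvals``/``bvecs``; ``s0`` is the b = 0 reference volume.
    """

    signals: np.ndarray
    s0: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    seq: PulseSequence
    spacing: tuple = (1.0, 1.0, 1.0)
    mask: np.ndarray = None  # type: ignore[assignment]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.signals.ndim != 4:
            raise ValueError("signals must be 4D (x, y, z, n_meas)")
        n = self.signals.shape[-1]
        if self.bvals.shape != (n,) or self.bvecs.shape != (n, 3):
            raise ValueError("bvals/bvecs lengths must match the 4th axis")
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(self.bvecs, axis=1)
        bad = (self.bvals > 0) & ~np.isclose(norms, 1.0, atol=1e-6)
        if np.any(bad):
            raise ValueError("gradient directions with b > 0 must be unit length")
        if self.mask is None:
            self.mask = np.ones(self.s0.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.s0[self.mask] <= 0):
            raise ValueError("s0 must be positive inside the mask")

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique non-zero b-values."""
        return np.unique(self.bvals[self.bvals > 0])


def read_volume(path) -> Volume:
    """Read a 3D or 4D NIfTI volume; returns data, spacing [mm] and affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3D/4D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[: min(3, data.ndim)]
    return Volume(data=data, spacing=tuple(float(z) for z in zooms), affine=img.affine)


def write_volume(path, data, spacing=(1.0, 1.0, 1.0), affine=None) -> None:
    """Write an array as NIfTI, recording spacing in the header."""
    data = np.asarray(data)
    if affine is None:
        affine = np.diag(list(spacing[:3]) + [1.0])
    img = nib.Nifti1Image(data.astype(np.float64, copy=False), affine)
    img.header.set_zooms(tuple(spacing[:3]) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def read_gradient_table(bval_path, bvec_path):
    """Read FSL-dialect .bval/.bvec text files.

    Returns ``(bvals, bvecs, is_b0)`` with directions of b > 0 entries
    normalized to unit length and b = 0 entries flagged.
    """
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=float))
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] != 3:
        if bvecs.shape[1] == 3:
            bvecs = bvecs.T
        else:
            raise ValueError("bvec file must have 3 rows (or columns) of N numbers")
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"column-count mismatch: {bvals.size} b-values vs {bvecs.shape[1]} directions"
        )
    if np.any(bvals < 0):
        raise ValueError("negative b-value in bval file")
    bvecs = bvecs.T.astype(float)  # (N, 3)
    is_b0 = bvals == 0
    norms = np.linalg.norm(bvecs, axis=1)
    if np.any(~is_b0 & (norms == 0)):
        raise ValueError("zero gradient direction with non-zero b")
    nz = ~is_b0
    bvecs[nz] /= norms[nz][:, None]
    return bvals, bvecs, is_b0


def combine_echo_phases(echoes: EchoSet) -> PhaseVolume:
    """Magnitude-weighted multi-echo phase combination.

    Voxel-wise phase = Σ_k w_k · phase(S̃_k) over the selected echoes with
    w_k = |S̃_k|² / Σ_j |S̃_j|² (sum over the same selected set), so the
    weights form a convex combination at every voxel. Later-echo phases are
    aligned to the first selected echo before averaging to avoid wrap
    inconsistencies. Voxels where every selected magnitude vanishes are
    dropped from the mask.
    """
    sel = [echoes.complex_signals[k - 1] for k in echoes.echo_parity_used]
    mags2 = np.stack([np.abs(s) ** 2 for s in sel])
    total = mags2.sum(axis=0)
    mask = np.ones(total.shape, dtype=bool) if echoes.mask is None else echoes.mask.copy()
    dead = mask & (total == 0)
    if dead.any():
        log.warning("combine_echo_phases: dropping %d voxels with zero magnitude", dead.sum())
        mask &= ~dead
    total = np.where(total == 0, 1.0, total)
    w = mags2 / total

    ref = np.angle(sel[0])
    phases = [ref]
    for s in sel[1:]:
        # wrapped offset from the reference echo, then re-anchored to it
        phases.append(ref + np.angle(s * np.conj(sel[0])))
    phi = sum(wk * pk for wk, pk in zip(w, phases))
    return PhaseVolume(phi_tr=phi, spacing=echoes.spacing, mask=mask)


def zero_fill_interpolate(volume: np.ndarray, target_shape: Sequence[int]) -> np.ndarray:
    """Zero-filling k-space interpolation of the two in-plane axes.

    Each slice is Fourier transformed, the measured spectrum is placed in the
    central region of a larger k-space and the rest filled with zeros; the
    inverse transform yields the up-interpolated image. Intensities are
    rescaled so a constant image stays constant (DC preserved).
    """
    volume = np.asarray(volume)
    nx, ny = volume.shape[:2]
    tx, ty = int(target_shape[0]), int(target_shape[1])
    if tx < nx or ty < ny:
        raise ValueError("target in-plane shape must be >= source shape")
    if (tx, ty) == (nx, ny):
        out = volume.astype(complex)
        return out if np.iscomplexobj(volume) else out.real

    lead = volume.reshape(nx, ny, -1)
    out = np.zeros((tx, ty, lead.shape[2]), dtype=complex)
    ox, oy = (tx - nx) // 2, (ty - ny) // 2
    scale = (tx * ty) / (nx * ny)
    for i in range(lead.shape[2]):
        k = np.fft.fftshift(np.fft.fft2(lead[:, :, i]))
        big = np.zeros((tx, ty), dtype=complex)
        big[ox : ox + nx, oy : oy + ny] = k * scale
        out[:, :, i] = np.fft.ifft2(np.fft.ifftshift(big))
    out = out.reshape((tx, ty) + volume.shape[2:])
    return out if np.iscomplexobj(volume) else out.real


def unwrap_phase_volume(phase: PhaseVolume) -> PhaseVolume:
    """Quality-guided 3D phase unwrapping of a wrapped phase volume."""
    from skimage.restoration import unwrap_phase

    arr = np.ma.array(phase.phi_tr, mask=~phase.mask)
    unwrapped = np.asarray(unwrap_phase(arr))
    out = phase.phi_tr.copy()
    out[phase.mask] = unwrapped[phase.mask]
    return PhaseVolume(phi_tr=out, spacing=phase.spacing, mask=phase.mask, affine=phase.affine)
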