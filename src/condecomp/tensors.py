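"""Diffusion-tensor fitting and the shared-eigenvector tensor decomposition.

The apparent diffusion tensor D_b is fitted at a single shell (b = 1000
s/mm² by convention; the higher shells are reserved for the compartment
model) by log-linear least squares. It is then split into extracellular,
intra-neurite and (residual, nominally isotropic) soma tensors that share
its eigenvectors:

    η_ec = f_ec · 3D_ec / tr(D_b),  η_ne = f_ne · 3D_in / tr(D_b),
    D_ec = η_ec·D_b,  D_ne = η_ne·D_b,  D_so = D_b − D_ec − D_ne,

and the compartment conductivity tensors follow by scaling with the apparent
ion concentrations: C_ec = c̄_ec·η_ec·D_b, C_ne = c̄_in·η_ne·D_b. The mean
eigenvalue of C_ec (resp. C_ne) equals the scalar σ_ec (σ_ne) voxel-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import ConcentrationModel
from .forest import SandiParamMaps
from .volumes import DwiDataset

__all__ = ["TensorField", "TensorSplit", "fit_dti", "split_tensor",
           "conductivity_tensors", "lta_summary", "tensor_glyph_summary"]

log = logging.getLogger(__name__)

EIGVAL_FLOOR = 1e-12


def _sorted_eig(tensors: np.ndarray):
    """Eigen-decomposition with eigenvalues sorted descending and a
    deterministic eigenvector sign convention (largest-|component| positive)."""
    vals, vecs = np.linalg.eigh(tensors)  # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    comp = np.argmax(np.abs(vecs), axis=-2, keepdims=True)
    signs = np.sign(np.take_along_axis(vecs, comp, axis=-2))
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    return vals, vecs


@dataclass
class TensorField:
    """Per-voxel 3×3 symmetric tensors with eigen-system accessors."""

    tensors: np.ndarray  # (..., 3, 3)
    mask: np.ndarray
    negative_clamped: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.tensors, dtype=float)
        if t.shape[-2:] != (3, 3):
            raise ValueError("tensors must be (..., 3, 3)")
        if not np.allclose(t, np.swapaxes(t, -1, -2), atol=1e-12):
            raise ValueError("tensors must be symmetric")
        self.tensors = t

    @property
    def trace(self) -> np.ndarray:
        return np.trace(self.tensors, axis1=-2, axis2=-1)

    def eig(self):
        """(eigvals desc, orthonormal eigvecs) over the full field."""
        return _sorted_eig(self.tensors)


@dataclass
class TensorSplit:
    """Shared-eigenvector split of D_b into compartment tensors."""

    eta_ec: np.ndarray
    eta_ne: np.ndarray
    D_b: TensorField
    valid_mask: np.ndarray
    residual_not_psd: np.ndarray  # voxels where D_so = (1−η_ec−η_ne)·D_b < 0

    @property
    def D_ec_tensor(self) -> np.ndarray:
        return self.eta_ec[..., None, None] * self.D_b.tensors

    @property
    def D_ne_tensor(self) -> np.ndarray:
        return self.eta_ne[..., None, None] * self.D_b.tensors

    @property
    def D_so_tensor(self) -> np.ndarray:
        return self.D_b.tensors - self.D_ec_tensor - self.D_ne_tensor


def fit_dti(dwi: DwiDataset, shell: float = 1000.0) -> TensorField:
    """Log-linear least-squares tensor fit on one shell plus b0.

    Solves ln(S/S₀) = −b·gᵀDg per voxel for the six independent components.
    Requires ≥ 6 non-collinear directions; rank deficiency raises with the
    design-matrix condition number. Negative eigenvalues are clamped to a
    small positive floor and flagged.
    """
    sel = dwi.bvals == shell
    if not sel.any():
        raise ValueError(f"shell b={shell} not present; available: {list(dwi.shells)}")
    g = dwi.bvecs[sel]
    if g.shape[0] < 6:
        raise ValueError(f"need >= 6 directions at b={shell}, got {g.shape[0]}")
    design = np.stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]],
        axis=1,
    )
    cond = np.linalg.cond(design)
    if cond > 1e8:
        raise ValueError(
            f"direction set is rank-deficient for a tensor fit (cond={cond:.2e})"
        )

    s = dwi.signals[..., sel]
    s0 = dwi.s0[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        y = -np.log(np.clip(s / s0, 1e-12, None)) / shell
    vox = dwi.mask
    coef = y[vox] @ np.linalg.pinv(design).T  # (n_vox, 6)

    shape = dwi.s0.shape
    tens = np.zeros(shape + (3, 3))
    xx, yy, zz, xy, xz, yz = coef.T
    t = np.zeros((coef.shape[0], 3, 3))
    t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = xx, yy, zz
    t[:, 0, 1] = t[:, 1, 0] = xy
    t[:, 0, 2] = t[:, 2, 0] = xz
    t[:, 1, 2] = t[:, 2, 1] = yz
    tens[vox] = t

    vals, vecs = _sorted_eig(tens[vox])
    neg = np.any(vals < 0, axis=-1)
    if neg.any():
        log.warning("fit_dti: clamping negative eigenvalues in %d voxels", int(neg.sum()))
        vals = np.clip(vals, EIGVAL_FLOOR, None)
        fixed = np.einsum("...ij,...j,...kj->...ik", vecs, vals, vecs)
        t2 = tens[vox]
        t2[neg] = fixed[neg]
        tens[vox] = t2
    neg_map = np.zeros(shape, dtype=bool)
    neg_map[vox] = neg
    return TensorField(tensors=tens, mask=vox.copy(), negative_clamped=neg_map)


def split_tensor(field: TensorField, params: SandiParamMaps) -> TensorSplit:
    """Scale-parameter split of D_b into compartment diffusion tensors.

    Zero-trace voxels are masked. Voxels where the residual soma tensor is
    not positive semidefinite (η_ec + η_ne > 1) are flagged and counted —
    they indicate model inconsistency between the tensor trace and the
    microstructure maps — but the residual is reported as-is.
    """
    tr = field.trace
    valid = field.mask & params.mask & (tr > 0)
    n_zero = int(np.count_nonzero(field.mask & params.mask & ~(tr > 0)))
    if n_zero:
        log.warning("split_tensor: masking %d zero-trace voxels", n_zero)
    eta_ec = np.zeros_like(tr)
    eta_ne = np.zeros_like(tr)
    eta_ec[valid] = params.f_ec[valid] * 3.0 * params.D_ec[valid] / tr[valid]
    eta_ne[valid] = params.f_ne[valid] * 3.0 * params.D_in[valid] / tr[valid]
    not_psd = valid & (eta_ec + eta_ne > 1.0 + 1e-12)
    if not_psd.any():
        log.warning("split_tensor: residual soma tensor not PSD in %d voxels "
                    "(eta_ec + eta_ne > 1)", int(not_psd.sum()))
    return TensorSplit(eta_ec=eta_ec, eta_ne=eta_ne, D_b=field, valid_mask=valid,
                       residual_not_psd=not_psd)


def conductivity_tensors(split: TensorSplit, conc: ConcentrationModel):
    """Compartment conductivity tensors C_ec, C_ne [S/m].

    C_ec = c̄_ec·η_ec·D_b and C_ne = c̄_in·η_ne·D_b; both inherit the
    eigenvectors of D_b, so longitudinal/transverse/average (L/T/A) summaries
    are eigenvalue rescalings of the diffusion eigenvalues.
    """
    c_ec = conc.c_ec_bar
    c_in = conc.c_in_bar
    d = split.D_b.tensors
    C_ec = (c_ec * split.eta_ec)[..., None, None] * d
    C_ne = (c_in * split.eta_ne)[..., None, None] * d
    valid = split.valid_mask & conc.valid_mask
    return (TensorField(tensors=C_ec, mask=valid),
            TensorField(tensors=C_ne, mask=valid))


def lta_summary(field: TensorField, roi: np.ndarray | None = None) -> dict:
    """Longitudinal / transverse / average eigenvalue summary over a region.

    L = mean principal eigenvalue, T = mean of the other two eigenvalues,
    A = mean of all three, each averaged over the region.
    """
    roi = field.mask if roi is None else (field.mask & roi)
    vals, _ = _sorted_eig(field.tensors[roi])
    return {
        "L": float(vals[:, 0].mean()),
        "T": float(vals[:, 1:].mean()),
        "A": float(vals.mean()),
    }


def tensor_glyph_summary(field: TensorField, roi: np.ndarray | None = None) -> pd.DataFrame:
    """Per-voxel ellipsoid parameters for glyph plotting.

    Radii are the eigenvalues (descending); orientation columns give the
    principal eigenvector, whose absolute components double as the
    conventional RGB direction coding. Non-PSD voxels are excluded and
    counted in ``df.attrs['n_excluded']``.
    """
    roi = field.mask if roi is None else (field.mask & roi)
    pts = np.argwhere(roi)
    if len(pts) == 0:
        df = pd.DataFrame(columns=["i", "j", "k", "r1", "r2", "r3",
                                   "v1x", "v1y", "v1z", "red", "green", "blue"])
        df.attrs["n_excluded"] = 0
        return df
    vals, vecs = _sorted_eig(field.tensors[roi])
    psd = vals[:, -1] >= -1e-15
    n_excl = int((~psd).sum())
    if n_excl:
        log.warning("tensor_glyph_summary: excluding %d non-PSD voxels", n_excl)
    v1 = vecs[..., 0]
    df = pd.DataFrame({
        "i": pts[psd, 0], "j": pts[psd, 1], "k": pts[psd, 2],
        "r1": vals[psd, 0], "r2": vals[psd, 1], "r3": vals[psd, 2],
        "v1x": v1[psd, 0], "v1y": v1[psd, 1], "v1z": v1[psd, 2],
        "red": np.abs(v1[psd, 0]), "green": np.abs(v1[psd, 1]), "blue": np.abs(v1[psd, 2]),
    })
    df.attrs["n_excluded"] = n_excl
    return df
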