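"""Scalar decomposition of σ_H into compartment conductivities.

Conductivity is the product of apparent carrier concentration and mobility;
taking water diffusivity as the mobility surrogate per compartment,

    σ_ec = f_ec · c̄_ec · D_ec,   σ_ne = f_ne · c̄_in · D_in,
    σ_so = f_so · c̄_is · D_is,   σ_H = σ_ne + σ_so + σ_ec,

with the lumped "apparent ion concentrations" c̄ absorbing charges, Stokes
radii and temperature. Assuming equal intra-neurite and soma concentrations
and a fixed intra/extracellular concentration ratio β (c̄_in = c̄_is = β·c̄_ec),
the extracellular concentration follows from σ_H and the microstructure maps:

    c̄_ec = σ_H / (β (f_ne D_in + f_so D_is) + f_ec D_ec).

The compartment sums then close on σ_H exactly, by construction.

β defaults: 1.0 for an electrolyte vesicle phantom (same solution inside and
out), 0.41 for human brain (literature ratio over the four predominant ions).
With diffusivities in mm²/s, c̄ carries the reciprocal units that land σ in
S/m; the conventional report scale quotes c̄ per 10⁻³ mm²/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forest import SandiParamMaps
from .sandi import D_IS_DEFAULT

__all__ = ["BETA_BRAIN", "BETA_PHANTOM", "ConcentrationModel",
           "CompartmentConductivity", "estimate_c_ec", "compartment_sigmas"]

log = logging.getLogger(__name__)

BETA_BRAIN = 0.41
BETA_PHANTOM = 1.0


@dataclass
class ConcentrationModel:
    """Apparent ion concentrations per compartment.

    c̄_ec is a voxel map; the intracellular concentrations are tied to it by
    the scalar ratio β (c̄_in = c̄_is = β·c̄_ec).
    """

    beta: float
    c_ec_bar: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if np.any(self.c_ec_bar[self.valid_mask] < 0):
            raise ValueError("c̄_ec must be nonnegative on valid voxels")

    @property
    def c_in_bar(self) -> np.ndarray:
        return self.beta * self.c_ec_bar

    @property
    def c_is_bar(self) -> np.ndarray:
        return self.beta * self.c_ec_bar


@dataclass
class CompartmentConductivity:
    """σ_H and its extracellular / intra-neurite / soma split [S/m]."""

    sigma_h: np.ndarray
    sigma_ec: np.ndarray
    sigma_ne: np.ndarray
    sigma_so: np.ndarray
    valid_mask: np.ndarray

    def closure_residual(self) -> float:
        """Max relative deviation of σ_ne + σ_so + σ_ec from σ_H (valid voxels)."""
        m = self.valid_mask & (self.sigma_h != 0)
        total = self.sigma_ne + self.sigma_so + self.sigma_ec
        return float(np.max(np.abs(total[m] - self.sigma_h[m]) / np.abs(self.sigma_h[m]),
                            initial=0.0))


def estimate_c_ec(sigma_h: np.ndarray, params: SandiParamMaps, beta: float,
                  D_is: float = D_IS_DEFAULT,
                  valid_mask: np.ndarray | None = None) -> ConcentrationModel:
    """Voxel-wise apparent extracellular ion concentration.

    c̄_ec = σ_H / (β(f_ne·D_in + f_so·D_is) + f_ec·D_ec). Voxels with a
    non-positive denominator (or outside the quality mask) are masked out and
    counted, never zero-filled into downstream products.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0 (0 = no intracellular charge carriers)")
    sigma_h = np.asarray(sigma_h, dtype=float)
    denom = beta * (params.f_ne * params.D_in + params.f_so * D_is) + params.f_ec * params.D_ec
    valid = params.mask.copy() if valid_mask is None else (params.mask & valid_mask)
    bad = valid & (denom <= 0)
    if bad.any():
        log.warning("estimate_c_ec: masking %d voxels with non-positive denominator",
                    int(bad.sum()))
        valid &= ~bad
    c_ec = np.zeros_like(sigma_h)
    c_ec[valid] = sigma_h[valid] / denom[valid]
    return ConcentrationModel(beta=beta, c_ec_bar=c_ec, valid_mask=valid)


def compartment_sigmas(params: SandiParamMaps, conc: ConcentrationModel,
                       D_is: float = D_IS_DEFAULT) -> CompartmentConductivity:
    """Compartment conductivities from the concentration model.

    σ_ec = f_ec·c̄_ec·D_ec, σ_ne = f_ne·c̄_in·D_in, σ_so = f_so·c̄_is·D_is.
    Their sum reproduces the σ_H that defined c̄_ec exactly (machine
    precision) — an algebraic identity of the decomposition.
    """
    valid = conc.valid_mask
    sigma_ec = np.where(valid, params.f_ec * conc.c_ec_bar * params.D_ec, 0.0)
    sigma_ne = np.where(valid, params.f_ne * conc.c_in_bar * params.D_in, 0.0)
    sigma_so = np.where(valid, params.f_so * conc.c_is_bar * D_is, 0.0)
    sigma_h = sigma_ec + sigma_ne + sigma_so
    return CompartmentConductivity(sigma_h=sigma_h, sigma_ec=sigma_ec,
                                   sigma_ne=sigma_ne, sigma_so=sigma_so,
                                   valid_mask=valid)
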