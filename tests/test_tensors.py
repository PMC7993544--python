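"""Diffusion-tensor fit and the shared-eigenvector conductivity tensors."""

import numpy as np
import pytest

from condecomp import (DwiDataset, SandiParamMaps, conductivity_tensors,
                       estimate_c_ec, compartment_sigmas, fit_dti, lta_summary,
                       split_tensor, tensor_glyph_summary)
from condecomp.pipeline import uniform_directions
from condecomp.tensors import TensorField


def dwi_from_tensor(D, seq, b=1000.0, n_dir=15, shape=(3, 3, 2), dirs=None):
    dirs = uniform_directions(n_dir) if dirs is None else dirs
    bvals = np.concatenate([[0.0], np.full(len(dirs), b)])
    bvecs = np.concatenate([np.zeros((1, 3)), dirs])
    s0 = np.ones(shape)
    att = np.exp(-b * np.einsum("ni,ij,nj->n", dirs, D, dirs))
    sig = np.concatenate([[1.0], att])
    signals = np.broadcast_to(sig, shape + (len(bvals),)).copy()
    return DwiDataset(signals=signals, s0=s0, bvals=bvals, bvecs=bvecs, seq=seq)


def maps_from_scalars(f_in, f_ec, d_in, d_ec, shape=(3, 3, 2)):
    ones = np.ones(shape)
    return SandiParamMaps(f_in=f_in * ones, f_ec=f_ec * ones, D_in=d_in * ones,
                          D_ec=d_ec * ones, r_s=8e-3 * ones,
                          mask=np.ones(shape, dtype=bool))


class TestFitDti:
    def test_exact_recovery_of_diagonal_tensor(self, phantom_seq):
        D = np.diag([1.5e-3, 1.0e-3, 0.5e-3])
        dwi = dwi_from_tensor(D, phantom_seq)
        field = fit_dti(dwi, shell=1000.0)
        assert np.max(np.abs(field.tensors - D)) < 1e-9

    def test_isotropic_signals_give_isotropic_tensor(self, phantom_seq):
        D = 1.1e-3 * np.eye(3)
        dwi = dwi_from_tensor(D, phantom_seq)
        field = fit_dti(dwi, shell=1000.0)
        assert np.allclose(field.tensors, D, atol=1e-12)

    def test_rotational_equivariance_of_eigenvalues(self, phantom_seq):
        from scipy.spatial.transform import Rotation

        D = np.diag([2.0e-3, 1.0e-3, 0.4e-3])
        R = Rotation.from_euler("zyx", [30, 45, 10], degrees=True).as_matrix()
        dirs = uniform_directions(15)
        a = fit_dti(dwi_from_tensor(D, phantom_seq, dirs=dirs), shell=1000.0)
        b = fit_dti(dwi_from_tensor(R @ D @ R.T, phantom_seq, dirs=dirs @ R.T),
                    shell=1000.0)
        va, _ = a.eig()
        vb, _ = b.eig()
        assert np.allclose(va, vb, atol=1e-12)

    def test_too_few_directions_raise(self, phantom_seq):
        D = 1e-3 * np.eye(3)
        with pytest.raises(ValueError, match=">= 6"):
            fit_dti(dwi_from_tensor(D, phantom_seq, n_dir=5), shell=1000.0)

    def test_collinear_directions_raise(self, phantom_seq):
        dirs = np.tile(np.array([[1.0, 0, 0]]), (8, 1))
        D = 1e-3 * np.eye(3)
        with pytest.raises(ValueError, match="rank-deficient|cond"):
            fit_dti(dwi_from_tensor(D, phantom_seq, dirs=dirs), shell=1000.0)


class TestSplit:
    def test_eta_example_unit_scale(self, phantom_seq):
        # f_ec = 0.6, D_ec = 1.5e-3, tr(D_b) = 2.7e-3 -> eta_ec = 1
        D = np.diag([1.2e-3, 0.9e-3, 0.6e-3])
        dwi = dwi_from_tensor(D, phantom_seq)
        field = fit_dti(dwi, shell=1000.0)
        maps = maps_from_scalars(f_in=0.0, f_ec=0.6, d_in=1e-3, d_ec=1.5e-3)
        split = split_tensor(field, maps)
        assert np.allclose(split.eta_ec, 1.0, rtol=1e-9)
        assert np.allclose(split.D_ec_tensor, field.tensors, rtol=1e-9)

    def test_empty_compartment_gives_zero_tensor(self, phantom_seq):
        D = 1e-3 * np.eye(3)
        field = fit_dti(dwi_from_tensor(D, phantom_seq), shell=1000.0)
        maps = maps_from_scalars(f_in=0.5, f_ec=0.0, d_in=1e-3, d_ec=1.5e-3)
        split = split_tensor(field, maps)
        assert np.allclose(split.eta_ec, 0.0)
        assert np.allclose(split.D_ec_tensor, 0.0)

    def test_trace_identity_and_closure(self, phantom_seq, rng):
        D = np.diag([1.8e-3, 1.1e-3, 0.7e-3])
        field = fit_dti(dwi_from_tensor(D, phantom_seq), shell=1000.0)
        maps = maps_from_scalars(f_in=0.4, f_ec=0.45, d_in=1.9e-3, d_ec=1.3e-3)
        split = split_tensor(field, maps)
        tr_ec = np.trace(split.D_ec_tensor, axis1=-2, axis2=-1)
        assert np.allclose(tr_ec / 3.0, maps.f_ec * maps.D_ec, rtol=1e-12)
        total = split.D_ec_tensor + split.D_ne_tensor + split.D_so_tensor
        assert np.allclose(total, field.tensors, atol=1e-20)

    def test_shared_eigenvectors(self, phantom_seq):
        D = np.diag([2.0e-3, 1.0e-3, 0.5e-3])
        field = fit_dti(dwi_from_tensor(D, phantom_seq), shell=1000.0)
        maps = maps_from_scalars(f_in=0.3, f_ec=0.5, d_in=1.5e-3, d_ec=1.2e-3)
        split = split_tensor(field, maps)
        # compartment tensors are scalar multiples of D_b -> same eigenvectors
        _, v_b = field.eig()
        ec = TensorField(tensors=split.D_ec_tensor, mask=field.mask)
        _, v_ec = ec.eig()
        assert np.allclose(np.abs(v_b), np.abs(v_ec), atol=1e-9)

    def test_non_psd_residual_flagged(self, phantom_seq):
        D = 0.5e-3 * np.eye(3)  # small trace forces eta_ec + eta_ne > 1
        field = fit_dti(dwi_from_tensor(D, phantom_seq), shell=1000.0)
        maps = maps_from_scalars(f_in=0.9, f_ec=0.5, d_in=3e-3, d_ec=3e-3)
        split = split_tensor(field, maps)
        assert split.residual_not_psd.all()


class TestConductivityTensors:
    def _setup(self, phantom_seq, D, f_in=0.3, f_ec=0.5, d_in=1.4e-3, d_ec=1.2e-3,
               beta=0.41):
        field = fit_dti(dwi_from_tensor(D, phantom_seq), shell=1000.0)
        maps = maps_from_scalars(f_in=f_in, f_ec=f_ec, d_in=d_in, d_ec=d_ec)
        sigma_h = np.full(D.shape[:0] + (3, 3, 2), 0.8)
        conc = estimate_c_ec(sigma_h, maps, beta=beta)
        split = split_tensor(field, maps)
        return field, maps, conc, split

    def test_mean_eigenvalue_matches_scalar_sigma(self, phantom_seq):
        D = np.diag([1.7e-3, 1.0e-3, 0.6e-3])
        field, maps, conc, split = self._setup(phantom_seq, D)
        comps = compartment_sigmas(maps, conc)
        c_ec_t, c_ne_t = conductivity_tensors(split, conc)
        mean_eig_ec = np.trace(c_ec_t.tensors, axis1=-2, axis2=-1) / 3.0
        mean_eig_ne = np.trace(c_ne_t.tensors, axis1=-2, axis2=-1) / 3.0
        m = c_ec_t.mask
        assert np.allclose(mean_eig_ec[m], comps.sigma_ec[m], rtol=1e-12)
        assert np.allclose(mean_eig_ne[m], comps.sigma_ne[m], rtol=1e-12)

    def test_isotropic_tensor_has_equal_lta(self, phantom_seq):
        D = 1.0e-3 * np.eye(3)
        _, _, conc, split = self._setup(phantom_seq, D)
        c_ec_t, _ = conductivity_tensors(split, conc)
        s = lta_summary(c_ec_t)
        assert s["L"] == pytest.approx(s["T"], rel=1e-9)
        assert s["L"] == pytest.approx(s["A"], rel=1e-9)

    def test_prolate_ratio_invariant_under_scaling(self, phantom_seq):
        D = np.diag([2.0e-3, 1.0e-3, 1.0e-3])
        _, _, conc, split = self._setup(phantom_seq, D)
        c_ec_t, _ = conductivity_tensors(split, conc)
        s = lta_summary(c_ec_t)
        assert s["L"] / s["T"] == pytest.approx(2.0, rel=1e-9)


class TestGlyphs:
    def test_isotropic_half_siemens_sphere(self):
        shape = (2, 2, 1)
        t = np.broadcast_to(0.5 * np.eye(3), shape + (3, 3)).copy()
        field = TensorField(tensors=t, mask=np.ones(shape, dtype=bool))
        df = tensor_glyph_summary(field)
        assert np.allclose(df[["r1", "r2", "r3"]].to_numpy(), 0.5)

    def test_rank1_dominant_elongated_along_principal(self):
        shape = (1, 1, 1)
        v = np.array([1.0, 0.0, 0.0])
        t = (np.outer(v, v) + 1e-3 * np.eye(3)).reshape(shape + (3, 3))
        field = TensorField(tensors=t, mask=np.ones(shape, dtype=bool))
        df = tensor_glyph_summary(field)
        assert df.loc[0, "r1"] > 100 * df.loc[0, "r2"]
        assert abs(df.loc[0, "v1x"]) > 0.999

    def test_empty_roi_gives_empty_table(self):
        shape = (2, 2, 1)
        t = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
        field = TensorField(tensors=t, mask=np.ones(shape, dtype=bool))
        df = tensor_glyph_summary(field, roi=np.zeros(shape, dtype=bool))
        assert len(df) == 0
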