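"""Training-grid generation, Rician noise, forest recovery, map prediction."""

import numpy as np
import pytest

from condecomp import (DwiDataset, PulseSequence, SandiParams, add_rician_noise,
                       build_training_grid, direction_average, fit_sandi_maps,
                       load_model, sandi_signal, save_model, signal_neurite,
                       train_forest)
from condecomp.forest import PARAM_NAMES
from condecomp.pipeline import uniform_directions


@pytest.fixture(scope="module")
def small_grid(phantom_seq, shells):
    return build_training_grid(shells, phantom_seq, n_per_param=5, seed=3)


@pytest.fixture(scope="module")
def small_model(small_grid):
    return train_forest(small_grid, noise_snr=None, n_trees=50, seed=3)


class TestTrainingGrid:
    def test_cartesian_row_count(self, phantom_seq, shells):
        grid = build_training_grid(shells, phantom_seq, n_per_param=2, seed=0)
        assert grid.signals.shape == (32, 4)
        assert grid.targets.shape == (32, 5)
        # endpoints of every interval appear
        for j, name in enumerate(PARAM_NAMES):
            lo, hi = grid.intervals[name]
            assert set(np.unique(grid.targets[:, j])) == {lo, hi}

    def test_default_grid_row_count_formula(self):
        # 13 points per parameter over 5 parameters = 371,293 dictionary rows
        assert 13**5 == 371_293

    def test_signals_match_fresh_forward_evaluations(self, small_grid, phantom_seq, shells):
        rng = np.random.default_rng(0)
        idx = rng.choice(len(small_grid.targets), size=25, replace=False)
        for i in idx:
            f_in, f_ec, d_in, d_ec, r_s = small_grid.targets[i]
            p = SandiParams(f_in=f_in, f_ec=f_ec, D_in=d_in, D_ec=d_ec, r_s=r_s)
            fresh = sandi_signal(shells, p, phantom_seq)
            assert np.allclose(small_grid.signals[i], fresh, rtol=1e-10)

    def test_signals_in_unit_interval(self, small_grid):
        assert np.all(small_grid.signals > 0)
        assert np.all(small_grid.signals <= 1)

    def test_memory_guard(self, phantom_seq, shells):
        with pytest.raises(ValueError, match="17"):
            build_training_grid(shells, phantom_seq, n_per_param=18)


class TestRicianNoise:
    def test_infinite_snr_is_identity(self, rng):
        s = rng.uniform(0.1, 1.0, size=(100, 4))
        assert np.array_equal(add_rician_noise(s, None, seed=0), s)
        assert np.array_equal(add_rician_noise(s, np.inf, seed=0), s)

    def test_zero_signal_gives_rayleigh_mean(self):
        s = np.zeros(100_000)
        snr = 25.0
        noisy = add_rician_noise(s, snr, seed=11)
        sigma = 1.0 / snr
        assert noisy.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)

    def test_high_snr_gaussian_limit(self):
        s = np.ones(100_000)
        snr = 100.0
        noisy = add_rician_noise(s, snr, seed=5)
        assert noisy.std() == pytest.approx(1.0 / snr, rel=0.05)

    def test_reproducible_under_seed(self, rng):
        s = rng.uniform(0.2, 1.0, size=(50, 4))
        assert np.array_equal(add_rician_noise(s, 50.0, seed=9),
                              add_rician_noise(s, 50.0, seed=9))


class TestForestTraining:
    def test_noise_free_recovery_of_f_ec(self, small_grid, small_model):
        from sklearn.model_selection import train_test_split

        _, x_te, _, y_te = train_test_split(small_grid.signals, small_grid.targets,
                                            test_size=0.2, random_state=3)
        pred = small_model.predict(x_te)
        r = np.corrcoef(pred[:, 1], y_te[:, 1])[0, 1]
        assert r > 0.9

    def test_determinism_under_seed(self, small_grid):
        a = train_forest(small_grid, noise_snr=30.0, n_trees=20, seed=4)
        b = train_forest(small_grid, noise_snr=30.0, n_trees=20, seed=4)
        assert np.array_equal(a.test_mse, b.test_mse)

    def test_shuffled_targets_destroy_recovery(self, small_grid):
        from sklearn.model_selection import train_test_split

        rng = np.random.default_rng(0)
        shuffled = small_grid.targets[rng.permutation(len(small_grid.targets))]
        import dataclasses

        broken = dataclasses.replace(small_grid, targets=shuffled)
        model = train_forest(broken, noise_snr=None, n_trees=30, seed=0)
        _, x_te, _, y_te = train_test_split(broken.signals, broken.targets,
                                            test_size=0.2, random_state=0)
        pred = model.predict(x_te)
        r = np.corrcoef(pred[:, 1], y_te[:, 1])[0, 1]
        assert abs(r) < 0.2

    def test_memory_guard_refuses_oversized_forest(self, small_grid):
        with pytest.raises(ValueError, match="tree storage"):
            train_forest(small_grid, noise_snr=None, n_trees=10**6, seed=0)

    def test_tree_grid_selection_reports_choice(self, small_grid):
        model = train_forest(small_grid, noise_snr=None, tree_grid=[10, 30], seed=2)
        assert model.n_trees in (10, 30)

    def test_predictions_clipped_to_intervals(self, small_model, rng):
        # extreme out-of-manifold features still yield in-interval parameters
        x = rng.uniform(0.0, 1.0, size=(64, 4))
        pred = small_model.predict(x)
        for j, name in enumerate(PARAM_NAMES):
            lo, hi = small_model.intervals[name]
            assert np.all(pred[:, j] >= lo) and np.all(pred[:, j] <= hi)

    def test_serialization_round_trip(self, small_model, tmp_path, rng):
        p = tmp_path / "model.bin"
        save_model(small_model, p)
        loaded = load_model(p)
        x = rng.uniform(0.2, 1.0, size=(10, 4))
        assert np.array_equal(loaded.predict(x), small_model.predict(x))
        assert loaded.seq == small_model.seq


def _isotropic_dwi(phantom_seq, shells, d=1.2e-3, n_dir=12, shape=(4, 4, 2)):
    dirs = uniform_directions(n_dir)
    bvals = np.concatenate([[0.0], np.repeat(shells, n_dir)])
    bvecs = np.concatenate([np.zeros((1, 3)), np.tile(dirs, (len(shells), 1))])
    s0 = np.full(shape, 200.0)
    sig = np.empty(shape + (len(bvals),))
    sig[..., 0] = 200.0
    for i, b in enumerate(bvals[1:], start=1):
        sig[..., i] = 200.0 * np.exp(-b * d)
    return DwiDataset(signals=sig, s0=s0, bvals=bvals, bvecs=bvecs, seq=phantom_seq)


class TestDirectionAverage:
    def test_isotropic_voxel_mean_is_exponential(self, phantom_seq, shells):
        dwi = _isotropic_dwi(phantom_seq, shells)
        means, sh = direction_average(dwi)
        assert np.allclose(sh, shells)
        for i, b in enumerate(shells):
            assert np.allclose(means[..., i], np.exp(-b * 1.2e-3), rtol=1e-12)

    def test_single_stick_matches_powder_formula(self, phantom_seq):
        # one voxel containing a single stick along z, many uniform directions
        dirs = uniform_directions(10_000)
        b = 2200.0
        bvals = np.concatenate([[0.0], np.full(len(dirs), b)])
        bvecs = np.concatenate([np.zeros((1, 3)), dirs])
        d_in = 1.5e-3
        shape = (1, 1, 1)
        s0 = np.ones(shape)
        att = np.exp(-b * d_in * (dirs @ np.array([0, 0, 1.0])) ** 2)
        sig = np.concatenate([[1.0], att]).reshape(shape + (-1,))
        dwi = DwiDataset(signals=sig, s0=s0, bvals=bvals, bvecs=bvecs, seq=phantom_seq)
        means, _ = direction_average(dwi, shells=[b])
        powder = signal_neurite(b, d_in)
        assert means[0, 0, 0, 0] == pytest.approx(float(powder), rel=5e-3)

    def test_missing_shell_raises(self, phantom_seq, shells):
        dwi = _isotropic_dwi(phantom_seq, shells)
        with pytest.raises(ValueError, match="not present|available"):
            direction_average(dwi, shells=[555.0])

    def test_single_direction_identity(self, phantom_seq):
        dwi = _isotropic_dwi(phantom_seq, np.array([1000.0]), n_dir=1)
        means, _ = direction_average(dwi)
        assert np.allclose(means[..., 0], np.exp(-1000.0 * 1.2e-3))


class TestFitMaps:
    def test_constant_signal_gives_constant_maps(self, phantom_seq, shells, small_model):
        dwi = _isotropic_dwi(phantom_seq, shells, d=1.0e-3)
        maps = fit_sandi_maps(dwi, small_model)
        for arr in (maps.f_ec, maps.D_ec, maps.r_s):
            assert np.ptp(arr[maps.mask]) == 0.0

    def test_protocol_mismatch_raises(self, phantom_seq, small_model):
        dwi = _isotropic_dwi(phantom_seq, np.array([800.0, 1600.0]))
        with pytest.raises(ValueError, match="protocol mismatch"):
            fit_sandi_maps(dwi, small_model)

    def test_single_compartment_extreme_recovered(self, phantom_seq, shells, small_model):
        # nearly pure extracellular voxel at an interval-interior point
        dwi = _isotropic_dwi(phantom_seq, shells, d=1.5e-3)
        maps = fit_sandi_maps(dwi, small_model)
        assert maps.f_ec[maps.mask].mean() > 0.9

    def test_fraction_identities_hold_voxelwise(self, phantom_seq, shells, small_model):
        dwi = _isotropic_dwi(phantom_seq, shells, d=0.9e-3)
        maps = fit_sandi_maps(dwi, small_model)
        assert np.allclose(maps.f_ne + maps.f_so + maps.f_ec, 1.0, atol=1e-12)
        assert np.allclose(maps.f_ic + maps.f_ec, 1.0, atol=1e-12)


class TestRecoveryDegradation:
    def test_rmse_non_decreasing_as_snr_drops(self, small_grid):
        """Recovery error grows monotonically as evaluation SNR decreases."""
        from sklearn.model_selection import train_test_split

        model = train_forest(small_grid, noise_snr=None, n_trees=50, seed=3)
        _, x_te, _, y_te = train_test_split(small_grid.signals, small_grid.targets,
                                            test_size=0.2, random_state=3)
        rmses = []
        for snr in (None, 100.0, 50.0, 10.0):
            x = add_rician_noise(x_te, snr, seed=21)
            pred = model.predict(x)
            rmses.append(float(np.sqrt(np.mean((pred[:, 1] - y_te[:, 1]) ** 2))))
        assert all(b >= a for a, b in zip(rmses, rmses[1:]))
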