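"""Random-forest regression of microstructure parameters from shell signals.

A synthetic dictionary of direction-averaged signals is generated on a full
Cartesian grid of the five free model parameters (f_in, f_ec, D_in, D_ec,
r_s), optionally corrupted with Rician noise, and a multi-output random
forest regressor is trained to invert the forward model. Voxel-wise maps are
then predicted from the direction-averaged normalized signals of a measured
(or simulated) multi-shell dataset.

Feature vector: the direction-averaged normalized signals at the non-zero
shells only (the b = 0 feature is identically 1 and carries no information).
The soma bulk diffusivity D_is is fixed (not regressed) to control the
ill-posedness of the six-parameter problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .sandi import (
    D_IS_DEFAULT,
    GpdSeries,
    PulseSequence,
    signal_extracellular,
    signal_neurite,
    signal_soma,
)
from .volumes import DwiDataset

__all__ = [
    "DEFAULT_INTERVALS",
    "TrainingGrid",
    "ForestModel",
    "SandiParamMaps",
    "build_training_grid",
    "add_rician_noise",
    "train_forest",
    "direction_average",
    "fit_sandi_maps",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

PARAM_NAMES = ("f_in", "f_ec", "D_in", "D_ec", "r_s")

#: Training intervals: fractions, diffusivities [mm²/s], soma radius [mm].
DEFAULT_INTERVALS = {
    "f_in": (0.01, 0.99),
    "f_ec": (0.01, 0.99),
    "D_in": (0.1e-3, 3.0e-3),
    "D_ec": (0.1e-3, 3.0e-3),
    "r_s": (3.0e-3, 20.0e-3),
}


@dataclass
class TrainingGrid:
    """Cartesian training dictionary: signals (N, K) and targets (N, 5)."""

    signals: np.ndarray
    targets: np.ndarray
    shells: np.ndarray
    seq: PulseSequence
    n_per_param: int
    intervals: dict = field(default_factory=lambda: dict(DEFAULT_INTERVALS))
    seed: int = 0


@dataclass
class ForestModel:
    """Trained multi-output forest with its acquisition fingerprint."""

    regressor: RandomForestRegressor
    shells: np.ndarray
    seq: PulseSequence
    intervals: dict
    n_trees: int
    test_mse: np.ndarray  # per-parameter held-out MSE
    seed: int
    noise_snr: float | None = None
    version: str = "condecomp-forest-1"

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predict (N, 5) parameters, clipped to the training intervals."""
        pred = self.regressor.predict(np.asarray(features, dtype=float))
        pred = np.atleast_2d(pred)
        for j, name in enumerate(PARAM_NAMES):
            lo, hi = self.intervals[name]
            pred[:, j] = np.clip(pred[:, j], lo, hi)
        return pred


def build_training_grid(shells, seq: PulseSequence, n_per_param: int = 13,
                        seed: int = 0, intervals: dict | None = None,
                        series: GpdSeries | None = None) -> TrainingGrid:
    """Full Cartesian grid of uniformly spaced parameters and their signals.

    The default 13 points per parameter give 13⁵ = 371,293 dictionary rows.
    A memory guard refuses n_per_param > 17 (17⁵ ≈ 1.4M rows); subsample the
    intervals or train in chunks instead.
    """
    shells = np.asarray(shells, dtype=float)
    if shells.size == 0:
        raise ValueError("shells must be nonempty")
    if np.any(shells <= 0):
        raise ValueError("shells must be positive b-values (b0 is not a feature)")
    if n_per_param < 2:
        raise ValueError("n_per_param must be >= 2")
    if n_per_param > 17:
        raise ValueError(
            "n_per_param > 17 would allocate more than ~1.4M dictionary rows; "
            "reduce the grid or build it in chunks"
        )
    intervals = dict(DEFAULT_INTERVALS if intervals is None else intervals)
    axes = [np.linspace(*intervals[name], n_per_param) for name in PARAM_NAMES]
    mesh = np.meshgrid(*axes, indexing="ij")
    targets = np.stack([m.ravel() for m in mesh], axis=1)  # (N, 5)
    f_in, f_ec, d_in, d_ec, r_s = targets.T

    if series is None:
        series = GpdSeries()
    # soma signal depends only on (b, r_s): evaluate per unique radius
    uniq_r, inv = np.unique(r_s, return_inverse=True)
    a_is_table = np.empty((uniq_r.size, shells.size))
    for i, r in enumerate(uniq_r):
        a_is_table[i] = signal_soma(shells, r, seq, series=series)
    a_is = a_is_table[inv]  # (N, K)

    a_ec = signal_extracellular(shells[None, :], d_ec[:, None])
    a_in = signal_neurite(shells[None, :], d_in[:, None])
    f_ic = 1.0 - f_ec
    signals = (
        f_ic[:, None] * (f_in[:, None] * a_in + (1.0 - f_in)[:, None] * a_is)
        + f_ec[:, None] * a_ec
    )
    return TrainingGrid(signals=signals, targets=targets, shells=shells, seq=seq,
                        n_per_param=n_per_param, intervals=intervals, seed=seed)


def add_rician_noise(signals: np.ndarray, snr: float | None, seed: int = 0) -> np.ndarray:
    """Rician-corrupt normalized signals: s' = √((s+n₁)² + n₂²), σ = 1/snr.

    ``snr`` of None or +inf returns a copy (noise-free limit). At s = 0 the
    output is Rayleigh with mean σ√(π/2); at high SNR the distribution tends
    to Gaussian with std σ.
    """
    signals = np.asarray(signals, dtype=float)
    if snr is None or np.isinf(snr):
        return signals.copy()
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    sigma = 1.0 / snr
    n1 = rng.normal(0.0, sigma, signals.shape)
    n2 = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + n1) ** 2 + n2**2)


def train_forest(grid: TrainingGrid, noise_snr: float | None = 50.0,
                 n_trees: int = 300, tree_grid=None, seed: int = 0,
                 test_fraction: float = 0.2, n_jobs: int = 1) -> ForestModel:
    """Train the multi-output random forest on the (optionally noised) grid.

    An 80/20 random split is made; when ``tree_grid`` is given the tree count
    is chosen by the summed per-parameter held-out MSE over that grid,
    otherwise ``n_trees`` is used directly. All remaining forest
    hyperparameters stay at the toolkit defaults. Training is deterministic
    under fixed seeds.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    # fully grown regression trees hold ~2 nodes per training sample at
    # ~40 bytes each; refuse forests that would exceed ~6 GiB of tree storage
    n_train = int(len(grid.signals) * (1.0 - test_fraction))
    max_trees = max(tree_grid) if tree_grid else n_trees
    est_bytes = max_trees * 2 * n_train * 40
    if est_bytes > 6e9:
        raise ValueError(
            f"forest of {max_trees} trees on {n_train} samples needs roughly "
            f"{est_bytes / 1e9:.0f} GB of tree storage; reduce n_trees or the "
            "dictionary density (e.g. 13^5 rows support about 50 trees in 8 GB)"
        )
    x = add_rician_noise(grid.signals, noise_snr, seed=seed)
    y = grid.targets
    x_tr, x_te, y_tr, y_te = train_test_split(x, y, test_size=test_fraction,
                                              random_state=seed)
    if min(len(x_tr), len(x_te)) < 2:
        raise ValueError("degenerate train/test split")

    def fit(n):
        rf = RandomForestRegressor(n_estimators=int(n), random_state=seed, n_jobs=n_jobs)
        rf.fit(x_tr, y_tr)
        mse = np.mean((rf.predict(x_te) - y_te) ** 2, axis=0)
        return rf, mse

    if tree_grid:
        best = None
        for n in tree_grid:
            rf, mse = fit(n)
            score = float(mse.sum())
            log.info("tree grid n=%d summed test MSE %.4e", n, score)
            if best is None or score < best[2]:
                best = (rf, mse, score, int(n))
        rf, mse, _, chosen = best
    else:
        rf, mse = fit(n_trees)
        chosen = int(n_trees)

    return ForestModel(regressor=rf, shells=grid.shells, seq=grid.seq,
                       intervals=grid.intervals, n_trees=chosen, test_mse=mse,
                       seed=seed, noise_snr=noise_snr)


def direction_average(dwi: DwiDataset, shells=None):
    """Per-shell, per-voxel arithmetic mean of S_b/S_0 over directions.

    Shells are matched on exact b-value. Returns ``(means, shells)`` with
    ``means`` of shape ``dwi.s0.shape + (n_shells,)``.
    """
    shells = dwi.shells if shells is None else np.asarray(shells, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = dwi.signals / dwi.s0[..., None]
    means = np.zeros(dwi.s0.shape + (len(shells),))
    for i, b in enumerate(shells):
        sel = dwi.bvals == b
        if not sel.any():
            raise ValueError(
                f"shell b={b} not present; available shells: {list(dwi.shells)}"
            )
        means[..., i] = norm[..., sel].mean(axis=-1)
    return means, shells


@dataclass
class SandiParamMaps:
    """Voxel-wise microstructure maps plus a quality mask."""

    f_in: np.ndarray
    f_ec: np.ndarray
    D_in: np.ndarray
    D_ec: np.ndarray
    r_s: np.ndarray
    mask: np.ndarray
    clipped: np.ndarray | None = None

    @property
    def f_ic(self) -> np.ndarray:
        return 1.0 - self.f_ec

    @property
    def f_is(self) -> np.ndarray:
        return 1.0 - self.f_in

    @property
    def f_ne(self) -> np.ndarray:
        return self.f_ic * self.f_in

    @property
    def f_so(self) -> np.ndarray:
        return self.f_ic * self.f_is

    def as_dict(self) -> dict:
        return {
            "f_in": self.f_in, "f_ec": self.f_ec, "f_ic": self.f_ic,
            "f_is": self.f_is, "f_ne": self.f_ne, "f_so": self.f_so,
            "D_in": self.D_in, "D_ec": self.D_ec, "r_s": self.r_s,
        }


def fit_sandi_maps(dwi: DwiDataset, model: ForestModel) -> SandiParamMaps:
    """Predict voxel-wise microstructure maps from a multi-shell dataset.

    The dataset's shell set must equal the model's training shells exactly
    (no silent retraining or shell merging). Predictions outside the training
    intervals are clipped and flagged in ``clipped``.
    """
    data_shells = dwi.shells
    if data_shells.shape != model.shells.shape or not np.array_equal(
        np.sort(data_shells), np.sort(model.shells)
    ):
        raise ValueError(
            f"protocol mismatch: data shells {list(data_shells)} != "
            f"model shells {list(model.shells)}"
        )
    feats, _ = direction_average(dwi, shells=model.shells)
    vox = dwi.mask
    x = feats[vox]
    raw = np.atleast_2d(model.regressor.predict(x))
    pred = raw.copy()
    for j, name in enumerate(PARAM_NAMES):
        lo, hi = model.intervals[name]
        pred[:, j] = np.clip(pred[:, j], lo, hi)
    was_clipped = np.any(raw != pred, axis=1)

    shape = dwi.s0.shape
    maps = {}
    for j, name in enumerate(PARAM_NAMES):
        m = np.zeros(shape)
        m[vox] = pred[:, j]
        maps[name] = m
    clip_map = np.zeros(shape, dtype=bool)
    clip_map[vox] = was_clipped
    return SandiParamMaps(mask=vox.copy(), clipped=clip_map, **maps)


def save_model(model: ForestModel, path) -> None:
    """Serialize a trained model with a versioned header."""
    payload = {
        "version": model.version,
        "shells": np.asarray(model.shells).tolist(),
        "delta": model.seq.delta,
        "Delta": model.seq.Delta,
        "gamma": model.seq.gamma,
        "intervals": model.intervals,
        "n_trees": model.n_trees,
        "seed": model.seed,
        "noise_snr": model.noise_snr,
        "test_mse": np.asarray(model.test_mse).tolist(),
        "regressor": model.regressor,
    }
    joblib.dump(payload, path)


def load_model(path) -> ForestModel:
    payload = joblib.load(path)
    if not str(payload.get("version", "")).startswith("condecomp-forest"):
        raise ValueError("not a condecomp forest model file")
    seq = PulseSequence(delta=payload["delta"], Delta=payload["Delta"],
                        gamma=payload["gamma"])
    return ForestModel(regressor=payload["regressor"],
                       shells=np.asarray(payload["shells"], dtype=float), seq=seq,
                       intervals=payload["intervals"], n_trees=payload["n_trees"],
                       test_mse=np.asarray(payload["test_mse"]), seed=payload["seed"],
                       noise_snr=payload["noise_snr"], version=payload["version"])
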