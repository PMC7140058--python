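"""ANN-based free-water elimination.

A small fully connected network maps a voxel's b0-normalized
diffusion-weighted signal vector to its tissue-volume fraction f.  The
network is trained purely on synthetic signals from the two-compartment
forward model with known f, so no fitting of the ill-posed bitensor model
is needed at inference time.  The architecture is tied to the acquisition:
an input unit per diffusion-weighted measurement (N_b), two hidden layers
of N_b/2 and N_b/4 units (integer division), and a single output unit with
a bounded nonlinearity so estimates stay in [0, 1] by construction.

Given an estimated fraction map, the measured attenuation is corrected by
algebraically removing the isotropic free-water compartment::

    A_tissue,k = (S_k/S0 - (1 - f) * exp(-b_k * d_free)) / f

The inversion divides by f, so voxels with f below a configurable floor are
excluded (with a reason code) instead of being corrected into noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .schemes import GradientScheme
from .signal import (
    D_FREE_DEFAULT,
    DWIStudy,
    add_rician_noise,
    bitensor_signal,
    random_rotation_matrices,
    tensor_from_eigs,
)

__all__ = [
    "TrainingSet",
    "TrainConfig",
    "FractionEstimator",
    "FractionMap",
    "CorrectedDWI",
    "EXCLUDE_NONE",
    "EXCLUDE_F_BELOW_FLOOR",
    "EXCLUDE_NEGATIVE_NUMERATOR",
    "EXCLUDE_INVALID_VOXEL",
    "make_training_set",
    "train_fraction_estimator",
    "estimate_fractions",
    "correct_signal",
]

# exclusion reason codes written to the int8 exclusion map
EXCLUDE_NONE = 0
EXCLUDE_F_BELOW_FLOOR = 1
EXCLUDE_NEGATIVE_NUMERATOR = 2
EXCLUDE_INVALID_VOXEL = 3

_CORRECTION_EPS = 1e-6


@dataclass
class TrainingSet:
    """Synthetic (signal, fraction) pairs tied to one gradient scheme."""

    signals: np.ndarray  # (n, N_b) b0-normalized diffusion-weighted signals
    fractions: np.ndarray  # (n,) true tissue fractions in [0, 1]
    scheme_fingerprint: str
    d_free: float = D_FREE_DEFAULT


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay: float = 0.3  # multiplier applied when validation plateaus
    lr_patience: int = 10  # plateau length (epochs) triggering a decay
    min_lr: float = 1e-5
    batch_size: int = 128
    max_epochs: int = 400
    patience: int = 40  # epochs without validation improvement -> stop
    val_fraction: float = 0.1
    output_activation: str = "hardsigmoid"  # bounded to [0,1] by construction


def _relu(x):
    return np.maximum(x, 0.0)


def _output_act(z, kind):
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if kind == "hardsigmoid":
        return np.clip(z + 0.5, 0.0, 1.0)
    raise ValueError(f"unknown output activation {kind!r}")


def _output_act_grad(z, kind):
    if kind == "sigmoid":
        s = 1.0 / (1.0 + np.exp(-z))
        return s * (1.0 - s)
    if kind == "hardsigmoid":
        return ((z > -0.5) & (z < 0.5)).astype(float)
    raise ValueError(kind)


@dataclass
class FractionEstimator:
    """Trained tissue-fraction network (weights + training metadata).

    ``weights``/``biases`` hold the three layer transforms
    N_b -> N_b//2 -> N_b//4 -> 1.  The estimator refuses to run on a study
    whose gradient table does not match its training-scheme fingerprint.
    """

    weights: list
    biases: list
    scheme_fingerprint: str
    output_activation: str = "hardsigmoid"
    metadata: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def _forward(self, X):
        z1 = X @ self.weights[0] + self.biases[0]
        a1 = _relu(z1)
        z2 = a1 @ self.weights[1] + self.biases[1]
        a2 = _relu(z2)
        z3 = a2 @ self.weights[2] + self.biases[2]
        return (z1, a1, z2, a2, z3, _output_act(z3, self.output_activation))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Estimated tissue fractions in [0, 1] for rows of signals."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"estimator expects {self.n_inputs} diffusion-weighted inputs, "
                f"got {X.shape[1]}"
            )
        return self._forward(X)[-1].ravel()

    def save(self, path) -> None:
        """Portable serialization: .npz weights + JSON sidecar."""
        import os

        path = str(path)
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
        sidecar = {
            "layer_sizes": self.layer_sizes,
            "scheme_fingerprint": self.scheme_fingerprint,
            "output_activation": self.output_activation,
            "metadata": {
                k: v for k, v in self.metadata.items() if not isinstance(v, np.ndarray)
            },
        }
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path) -> "FractionEstimator":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        data = np.load(base + ".npz")
        n_layers = len([k for k in data.files if k.startswith("w")])
        weights = [data[f"w{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
        with open(base + ".json") as fh:
            sidecar = json.load(fh)
        return cls(
            weights,
            biases,
            sidecar["scheme_fingerprint"],
            sidecar["output_activation"],
            sidecar.get("metadata", {}),
        )


@dataclass
class FractionMap:
    """3-D map of estimated tissue fractions with a validity mask."""

    values: np.ndarray  # NaN at invalid voxels
    valid: np.ndarray  # bool

    def __post_init__(self) -> None:
        v = self.values[self.valid]
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValueError("estimated fractions must lie in [0, 1]")


@dataclass
class CorrectedDWI:
    """Free-water-suppressed tissue attenuations with exclusion bookkeeping.

    ``s0`` and ``fraction`` are kept alongside the attenuations because the
    correction rescales the measurement noise by 1/f; downstream noise-aware
    estimators need both to reconstruct the per-voxel noise level.
    """

    attenuation: np.ndarray  # (x, y, z, n_measurements); b=0 entries are 1
    scheme: GradientScheme
    included: np.ndarray  # bool (x, y, z)
    exclusion_reason: np.ndarray  # int8 (x, y, z), codes EXCLUDE_*
    s0: np.ndarray  # (x, y, z) mean b=0 signal used for normalization
    fraction: np.ndarray  # (x, y, z) tissue fraction used in the inversion
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)


def sample_tissue_tensors(
    n: int,
    rng: np.random.Generator,
    md_range: tuple[float, float] = (0.7e-3, 0.8e-3),
    shape_range: tuple[float, float] = (0.2, 1.0),
) -> np.ndarray:
    """Eigenvalues (n, 3, descending) for physiological tissue tensors.

    Mean diffusivity is uniform over the parenchymal band ``md_range``
    (white matter MD is about 0.7e-3 and cortical gray matter about
    0.8e-3 mm^2/s); the eigenvalue shape (hence FA) varies freely by sampling
    three raw values in ``shape_range`` and rescaling to the target MD.
    The tight MD prior is what makes the single-shell free-water inverse
    problem well posed: with tissue MD approaching the free-water
    diffusivity the decomposition is degenerate.
    """
    md = rng.uniform(*md_range, size=n)
    raw = np.sort(rng.uniform(*shape_range, size=(n, 3)), axis=-1)[:, ::-1]
    return raw * (3.0 * md / raw.sum(axis=1))[:, None]


def make_training_set(
    scheme: GradientScheme,
    n_samples: int = 50_000,
    md_range: tuple[float, float] = (0.7e-3, 0.8e-3),
    snr_range: tuple[float, float] = (20.0, 2000.0),
    noiseless_fraction: float = 0.25,
    d_free: float = D_FREE_DEFAULT,
    seed: int | None = 0,
) -> TrainingSet:
    """Draw synthetic training pairs (normalized signal, true f).

    Tissue tensors come from :func:`sample_tissue_tensors` (narrow
    parenchymal MD band, free eigenvalue shape, Haar-random orientation);
    f is uniform on [0, 1]; SNR is log-uniform over ``snr_range`` except
    for a ``noiseless_fraction`` of rows kept noise-free so the network
    also learns the exact inverse map.  Signals are normalized by the
    (noisy) mean b = 0 signal, exactly as at inference time.
    """
    if n_samples < 1000:
        raise ValueError("need at least 1000 training samples")
    rng = np.random.default_rng(seed)
    eigs = sample_tissue_tensors(n_samples, rng, md_range)
    rot = random_rotation_matrices(n_samples, rng)
    tensors = tensor_from_eigs(eigs, rot)
    f = rng.uniform(0.0, 1.0, size=n_samples)
    clean = bitensor_signal(tensors, f, scheme, s0=1.0, d_free=d_free)
    log_snr = rng.uniform(np.log(snr_range[0]), np.log(snr_range[1]), size=n_samples)
    snr = np.exp(log_snr)
    sigma = 1.0 / snr  # per-row noise level; s0 = 1 here
    n1 = rng.normal(size=clean.shape) * sigma[:, None]
    n2 = rng.normal(size=clean.shape) * sigma[:, None]
    noisy = np.sqrt((clean + n1) ** 2 + n2**2)
    keep_clean = rng.uniform(size=n_samples) < noiseless_fraction
    signal = np.where(keep_clean[:, None], clean, noisy)
    s0_obs = signal[:, scheme.b0_mask].mean(axis=1)
    X = signal[:, scheme.dwi_mask] / s0_obs[:, None]
    return TrainingSet(X, f, scheme.fingerprint(), d_free)


def _hidden_sizes(n_inputs: int) -> tuple[int, int]:
    return n_inputs // 2, n_inputs // 4


def train_fraction_estimator(
    train_set: TrainingSet,
    config: TrainConfig | None = None,
    seed: int | None = 0,
) -> FractionEstimator:
    """Train the fraction network with Adam on an MSE loss.

    A validation split drives early stopping; the best-validation weights
    are kept.  If validation loss never improves after the first epoch the
    estimator is flagged ``converged: False`` in its metadata rather than
    failing silently.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(seed)
    X = np.asarray(train_set.signals, dtype=float)
    y = np.asarray(train_set.fractions, dtype=float)
    n, n_in = X.shape
    h1, h2 = _hidden_sizes(n_in)
    sizes = [n_in, h1, h2, 1]

    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    weights = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(3)
    ]
    biases = [np.zeros(sizes[i + 1]) for i in range(3)]
    est = FractionEstimator(weights, biases, train_set.scheme_fingerprint,
                            cfg.output_activation)

    m = [np.zeros_like(w) for w in weights] + [np.zeros_like(b) for b in biases]
    v = [np.zeros_like(x) for x in m]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    def val_loss():
        pred = est.predict(Xval)
        return float(np.mean((pred - yval) ** 2))

    best = (np.inf, None)
    loss_curve = []
    epochs_since_best = 0
    plateau = 0
    lr = cfg.learning_rate
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            z1, a1, z2, a2, z3, out = est._forward(xb)
            bsz = len(xb)
            delta = (out.ravel() - yb) * _output_act_grad(
                z3.ravel(), cfg.output_activation
            )
            delta = (2.0 / bsz) * delta[:, None]
            grads_w = [None, None, None]
            grads_b = [None, None, None]
            grads_w[2] = a2.T @ delta
            grads_b[2] = delta.sum(axis=0)
            d2 = (delta @ est.weights[2].T) * (z2 > 0)
            grads_w[1] = a1.T @ d2
            grads_b[1] = d2.sum(axis=0)
            d1 = (d2 @ est.weights[1].T) * (z1 > 0)
            grads_w[0] = xb.T @ d1
            grads_b[0] = d1.sum(axis=0)
            t += 1
            params = est.weights + est.biases
            grads = grads_w + grads_b
            for k, (p, g) in enumerate(zip(params, grads)):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mh = m[k] / (1 - beta1**t)
                vh = v[k] / (1 - beta2**t)
                p -= lr * mh / (np.sqrt(vh) + eps)
        vl = val_loss()
        loss_curve.append(vl)
        if vl < best[0] - 1e-9:
            best = (vl, ([w.copy() for w in est.weights], [b.copy() for b in est.biases]))
            epochs_since_best = 0
            plateau = 0
        else:
            epochs_since_best += 1
            plateau += 1
            if plateau >= cfg.lr_patience and lr > cfg.min_lr:
                lr = max(lr * cfg.lr_decay, cfg.min_lr)
                plateau = 0
            if epochs_since_best >= cfg.patience:
                break
    if best[1] is not None:
        est.weights, est.biases = best[1]
    est.metadata = {
        "final_val_mse": best[0],
        "n_epochs": len(loss_curve),
        "loss_curve": [float(x) for x in loss_curve],
        "converged": best[1] is not None and best[0] < loss_curve[0] + 1e-12,
        "seed": seed,
        "n_train": int(len(tr_idx)),
        "n_val": int(n_val),
    }
    return est


def estimate_fractions(
    est: FractionEstimator,
    study: DWIStudy,
    mask: np.ndarray | None = None,
) -> FractionMap:
    """Voxelwise tissue-fraction inference on a study.

    Raises on an estimator/scheme mismatch (input size or fingerprint).
    Voxels outside the mask or with non-positive S0 are invalid (NaN).
    """
    n_b = study.scheme.n_dwi
    if est.n_inputs != n_b:
        raise ValueError(
            f"scheme mismatch: estimator expects N_b={est.n_inputs}, "
            f"study has N_b={n_b}"
        )
    if est.scheme_fingerprint != study.scheme.fingerprint():
        raise ValueError(
            "scheme mismatch: study gradient table differs from the table "
            "the estimator was trained on"
        )
    s0 = study.s0_map()
    valid = s0 > 0
    if mask is not None:
        valid = valid & np.asarray(mask, bool)
    values = np.full(study.shape, np.nan)
    dwi = study.signal[..., study.scheme.dwi_mask]
    if np.any(valid):
        X = dwi[valid] / s0[valid][:, None]
        values[valid] = est.predict(X)
    return FractionMap(values, valid)


def correct_signal(
    study: DWIStudy,
    fmap: FractionMap,
    d_free: float = D_FREE_DEFAULT,
    f_floor: float = 0.1,
) -> CorrectedDWI:
    """Remove the free-water compartment from the measured attenuations.

    Voxels with estimated f below ``f_floor`` are excluded (the inversion
    divides by f), as are voxels where more than half of the corrected
    entries would be negative (free water dominates the signal there and
    the tissue residual is noise).  Remaining attenuations are clipped to
    (eps, 1].
    """
    if fmap.values.shape != study.shape:
        raise ValueError("fraction map not aligned with the study")
    scheme = study.scheme
    s0 = study.s0_map()
    reason = np.full(study.shape, EXCLUDE_INVALID_VOXEL, dtype=np.int8)
    reason[fmap.valid & (s0 > 0)] = EXCLUDE_NONE
    f = fmap.values
    below = (reason == EXCLUDE_NONE) & (f < f_floor)
    reason[below] = EXCLUDE_F_BELOW_FLOOR

    atten = np.ones(study.shape + (scheme.n_measurements,))
    usable = reason == EXCLUDE_NONE
    if np.any(usable):
        b = scheme.bvals[scheme.dwi_mask]
        meas = study.signal[usable][:, scheme.dwi_mask] / s0[usable][:, None]
        fw = np.exp(-b * d_free)[None, :]
        fv = f[usable][:, None]
        numer = meas - (1.0 - fv) * fw
        frac_negative = (numer <= 0).mean(axis=1)
        corrected = np.clip(numer / fv, _CORRECTION_EPS, 1.0)
        full = np.ones((corrected.shape[0], scheme.n_measurements))
        full[:, scheme.dwi_mask] = corrected
        atten[usable] = full
        bad = np.zeros(study.shape, dtype=bool)
        bad[usable] = frac_negative > 0.5
        reason[bad] = EXCLUDE_NEGATIVE_NUMERATOR
    included = reason == EXCLUDE_NONE
    fraction = np.where(np.isfinite(f), f, 1.0)
    return CorrectedDWI(atten, scheme, included, reason, s0, fraction, study.voxel_size)
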