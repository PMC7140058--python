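"""Two-compartment ("bitensor") diffusion signal model and Rician noise.

Each voxel's signal is modelled as a mixture of an anisotropic tissue
compartment, described by a 3x3 symmetric positive-semidefinite diffusion
tensor D, and an isotropic free-water compartment with fixed diffusivity
``d_free``::

    S_k = S0 * [ f * exp(-b_k g_k^T D g_k) + (1 - f) * exp(-b_k d_free) ]

where f in [0, 1] is the tissue-volume fraction (f = 1 means no free-water
contamination).  Magnitude MR noise is Rician: the noiseless signal is
perturbed in two quadrature channels and the magnitude taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schemes import GradientScheme

__all__ = [
    "D_FREE_DEFAULT",
    "DWIStudy",
    "bitensor_signal",
    "add_rician_noise",
    "tensor_from_eigs",
    "random_rotation_matrices",
]

#: Free-water diffusivity at body temperature, mm^2/s.
D_FREE_DEFAULT = 3.0e-3

#: Physiological upper bound for ground-truth tensor eigenvalues, mm^2/s.
EIG_MAX_PHYSIOLOGICAL = 4.0e-3


@dataclass
class DWIStudy:
    """One synthetic patient's 4-D diffusion-weighted acquisition."""

    signal: np.ndarray  # (x, y, z, n_measurements), arbitrary signal units
    scheme: GradientScheme
    voxel_size: tuple[float, float, float]
    patient_id: str

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, measurement)")
        if self.signal.shape[-1] != self.scheme.n_measurements:
            raise ValueError(
                f"signal has {self.signal.shape[-1]} measurements, scheme has "
                f"{self.scheme.n_measurements}"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def s0_map(self) -> np.ndarray:
        """Mean over the b = 0 volumes."""
        return self.signal[..., self.scheme.b0_mask].mean(axis=-1)


def quadratic_forms(tensors: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """g^T D g for a batch of tensors (..., 3, 3) and directions (k, 3)."""
    return np.einsum("ki,...ij,kj->...k", directions, tensors, directions)


def bitensor_signal(
    tensor: np.ndarray,
    f,
    scheme: GradientScheme,
    s0: float = 1.0,
    d_free: float = D_FREE_DEFAULT,
) -> np.ndarray:
    """Noiseless two-compartment signal for one tensor or a batch.

    Parameters
    ----------
    tensor:
        Symmetric PSD tensor(s), shape (3, 3) or (..., 3, 3), mm^2/s.
    f:
        Tissue-volume fraction(s) in [0, 1]; scalar or shape matching the
        tensor batch.
    scheme:
        Gradient table; the output has one entry per measurement (b = 0
        entries equal ``s0`` exactly).
    s0:
        Unweighted signal amplitude (> 0).
    d_free:
        Isotropic free-water diffusivity, mm^2/s.

    Returns
    -------
    Signal array of shape (..., n_measurements).
    """
    tensor = np.asarray(tensor, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("tissue fraction f must lie in [0, 1]")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    b = scheme.bvals
    quad = quadratic_forms(tensor, scheme.bvecs)  # (..., k)
    tissue = np.exp(-b * quad)
    water = np.exp(-b * d_free)
    return s0 * (f[..., None] * tissue + (1.0 - f[..., None]) * water)


def add_rician_noise(
    signal: np.ndarray,
    snr: float,
    s0: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Corrupt a magnitude signal with Rician noise.

    Two independent zero-mean Gaussian channels of standard deviation
    ``s0 / snr`` are added (one in phase with the signal, one in
    quadrature) and the magnitude is returned.  Deterministic given a seed.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    signal = np.asarray(signal, dtype=float)
    sigma = s0 / snr
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def estimate_noise_sigma(study: DWIStudy, background_mask: np.ndarray) -> float:
    """Estimate the magnitude-noise sigma from signal-free background voxels.

    In background the Rician distribution reduces to Rayleigh, whose mean
    is sigma * sqrt(pi/2); inverting the sample mean gives sigma in signal
    units.
    """
    bg = study.signal[np.asarray(background_mask, bool)]
    if bg.size == 0:
        raise ValueError("background mask selects no voxels")
    return float(bg.mean() / np.sqrt(np.pi / 2.0))


def tensor_from_eigs(eigvals, rotation: np.ndarray | None = None) -> np.ndarray:
    """Assemble symmetric tensor(s) R diag(eigvals) R^T.

    ``eigvals`` has shape (..., 3); ``rotation`` (..., 3, 3) or None for an
    axis-aligned tensor.
    """
    eigvals = np.asarray(eigvals, dtype=float)
    if rotation is None:
        out = np.zeros(eigvals.shape[:-1] + (3, 3))
        for i in range(3):
            out[..., i, i] = eigvals[..., i]
        return out
    return np.einsum("...ij,...j,...kj->...ik", rotation, eigvals, rotation)


def random_rotation_matrices(n: int, rng: np.random.Generator) -> np.ndarray:
    """n rotation matrices drawn uniformly (Haar) via QR of Gaussians."""
    a = rng.normal(size=(n, 3, 3))
    q, r = np.linalg.qr(a)
    # fix signs so the decomposition is unique and uniform
    d = np.sign(np.einsum("nii->ni", r))
    d[d == 0] = 1.0
    q = q * d[:, None, :]
    det = np.linalg.det(q)
    q[det < 0, :, 0] *= -1.0
    return q
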