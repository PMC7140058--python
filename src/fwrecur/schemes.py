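"""Diffusion gradient schemes (b-values and unit directions).

A scheme bundles the per-measurement diffusion weighting ``bvals`` (s/mm^2)
and unit gradient directions ``bvecs``.  The b = 0 entries carry a zero
direction vector and provide the unweighted reference signal S0; the
diffusion-weighted entries define the design of the tensor fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["GradientScheme", "make_scheme", "read_fsl_gradients", "write_fsl_gradients"]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientScheme:
    """Per-measurement b-values (s/mm^2) and unit gradient directions.

    Invariants enforced at construction: equal lengths, at least one b = 0
    entry, unit-norm directions for weighted entries and zero vectors for
    unweighted ones.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} incompatible with {bvals.size} b-values"
            )
        if not np.any(bvals == 0):
            raise ValueError("scheme needs at least one b=0 measurement for S0")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > _UNIT_TOL):
            raise ValueError("directions with b>0 must be unit vectors")
        if np.any(norms[~weighted] > _UNIT_TOL):
            raise ValueError("b=0 entries must carry zero direction vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        self.bvals.setflags(write=False)
        self.bvecs.setflags(write=False)

    @property
    def n_measurements(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    @property
    def n_dwi(self) -> int:
        """Number of diffusion-weighted measurements (the ANN input size)."""
        return int(np.count_nonzero(self.dwi_mask))

    def fingerprint(self) -> str:
        """Stable hash of the rounded gradient table.

        Used to tie a trained fraction estimator to the scheme it was
        trained for, so a scheme mismatch fails loudly instead of silently
        producing garbage fractions.
        """
        import hashlib

        payload = np.round(
            np.column_stack([self.bvals, self.bvecs]), 8
        ).tobytes()
        return hashlib.sha256(payload).hexdigest()[:16]


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere via the Fibonacci lattice."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_scheme(
    n_directions: int, b: float, n_b0: int = 1, seed: int | None = 0
) -> GradientScheme:
    """Build a single-shell scheme with quasi-uniform directions.

    Parameters
    ----------
    n_directions:
        Number of diffusion-weighted directions; at least 6 are required to
        determine the six unique tensor components.
    b:
        Shell b-value in s/mm^2 (must be positive).
    n_b0:
        Number of unweighted (b = 0) measurements, placed first.
    seed:
        Seeds the random global rotation applied to the deterministic
        Fibonacci lattice, so distinct seeds give distinct but equally
        uniform tables and a fixed seed is fully reproducible.
    """
    if n_directions < 6:
        raise ValueError("need at least 6 directions to determine a tensor")
    if b <= 0:
        raise ValueError("shell b-value must be positive")
    if n_b0 < 1:
        raise ValueError("need at least one b=0 measurement")
    dirs = _fibonacci_directions(n_directions)
    rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
    dirs = dirs @ rot.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals, bvecs)


def write_fsl_gradients(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """Write FSL-dialect gradient tables (bvals one row; bvecs three rows)."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{v:g}" for v in scheme.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.8f}" for v in scheme.bvecs[:, axis]) + "\n")


def read_fsl_gradients(bval_path, bvec_path) -> GradientScheme:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientScheme(bvals, bvecs)
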