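"""Synthetic glioblastoma DWI phantoms with known ground truth.

The phantom is deliberately geometric rather than anatomical: a spherical
contrast-enhancing tumor core sits at the centre of a spherical "brain" of
white matter, surrounded by an edema shell that is split into a contiguous
sector destined to show tumor recurrence and a recurrence-free remainder.
Every labelled voxel carries a ground-truth tissue diffusion tensor and a
ground-truth tissue-volume fraction f, so the free-water elimination, the
tensor metrics and the downstream statistics can all be validated against
known truth.

Label codes (fixed): 0 background, 1 normal white matter, 2 contrast-
enhancing tumor, 3 edema without later recurrence, 4 edema with later
recurrence.

Tissue classes differ in eigenvalue structure and free-water load: white
matter is anisotropic with little free water; edema carries heavy free-water
contamination (low f); recurrence-destined edema additionally has a
mean-diffusivity-preserving reduction in tensor anisotropy (the tissue-FA
deficit), whose magnitude is the configurable ``effect_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .schemes import GradientScheme
from .signal import (
    D_FREE_DEFAULT,
    EIG_MAX_PHYSIOLOGICAL,
    DWIStudy,
    add_rician_noise,
    bitensor_signal,
    random_rotation_matrices,
    tensor_from_eigs,
)

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_WM",
    "LABEL_TUMOR",
    "LABEL_EDEMA_PURE",
    "LABEL_EDEMA_RECUR",
    "PhantomParams",
    "PhantomTruth",
    "build_phantom",
    "simulate_study",
    "simulate_cohort",
]

LABEL_BACKGROUND = 0
LABEL_WM = 1
LABEL_TUMOR = 2
LABEL_EDEMA_PURE = 3
LABEL_EDEMA_RECUR = 4

_EIG_FLOOR = 5.0e-5  # mm^2/s; keeps jittered ground-truth tensors PSD


@dataclass
class PhantomParams:
    """Geometry and tissue-property configuration of the phantom.

    Radii are in voxels.  Eigenvalues are mm^2/s.  ``effect_size`` is the
    axial-eigenvalue reduction applied to recurrence-destined edema (with
    half of it added to each radial eigenvalue, so MD is preserved and only
    anisotropy drops).  ``patient_fa_sd`` is the standard deviation of a
    per-patient random shift of the same MD-preserving kind applied to both
    edema classes alike -- the patient-level random effect that makes the
    random-intercept model identifiable on synthetic cohorts.
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    r_tumor: float = 5.0
    r_edema: float = 12.0
    r_brain: float = 18.0
    recur_frac: float = 0.5  # azimuthal fraction of the edema shell
    wm_eigs: tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3)
    wm_f: tuple[float, float] = (0.85, 1.0)
    wm_f_center: float = 0.93
    tumor_eigs: tuple[float, float, float] = (1.0e-3, 0.7e-3, 0.7e-3)
    tumor_f: tuple[float, float] = (0.5, 0.8)
    tumor_f_center: float = 0.68
    edema_eigs: tuple[float, float, float] = (1.4e-3, 0.45e-3, 0.45e-3)
    edema_f: tuple[float, float] = (0.3, 0.7)
    edema_f_center: float = 0.5
    effect_size: float = 0.22e-3
    eig_jitter_sd: float = 0.03e-3
    # spatial structure of the free-water load: edema wetness varies as a
    # smooth random field (regional gradients), not voxelwise white noise,
    # so free-water contamination does not average out over patches
    f_smooth_sigma: float = 4.0  # Gaussian correlation length, voxels
    f_field_amplitude: float = 0.40
    # patient-level random effects (between-patient heterogeneity)
    patient_fa_sd: float = 0.06e-3
    patient_f_sd: float = 0.06


@dataclass
class PhantomTruth:
    """Per-voxel ground truth for one synthetic patient."""

    label: np.ndarray  # int16 (x, y, z)
    tissue_tensor: np.ndarray  # float (x, y, z, 3, 3), mm^2/s
    f_true: np.ndarray  # float (x, y, z) in [0, 1]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if np.any((self.f_true < 0) | (self.f_true > 1)):
            raise ValueError("f_true must lie in [0, 1]")
        if np.any((self.f_true == 0) & (self.label != LABEL_BACKGROUND)):
            raise ValueError("f_true == 0 only allowed in background")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label.shape

    def brain_mask(self) -> np.ndarray:
        return self.label > 0


def _anisotropy_shift(eigs: np.ndarray, delta) -> np.ndarray:
    """Reduce lambda1 by delta and raise lambda2,3 by delta/2 (MD kept)."""
    out = np.array(eigs, dtype=float, copy=True)
    delta = np.asarray(delta, dtype=float)
    out[..., 0] -= delta
    out[..., 1] += delta / 2.0
    out[..., 2] += delta / 2.0
    return out


def _sample_class_tensors(
    eigs: tuple[float, float, float],
    n: int,
    rng: np.random.Generator,
    jitter_sd: float,
) -> np.ndarray:
    base = np.tile(np.asarray(eigs, dtype=float), (n, 1))
    base += rng.normal(0.0, jitter_sd, size=base.shape)
    base = np.clip(base, _EIG_FLOOR, EIG_MAX_PHYSIOLOGICAL)
    rot = random_rotation_matrices(n, rng)
    return tensor_from_eigs(base, rot)


def build_phantom(
    shape: tuple[int, int, int] | None = None,
    params: PhantomParams | None = None,
    seed: int | None = 0,
    effect_size: float | None = None,
) -> PhantomTruth:
    """Generate a labelled phantom with ground-truth tensors and fractions.

    Raises ``ValueError`` if the requested geometry leaves any tissue class
    empty (e.g. a shape too small for the concentric radii).
    """
    params = params or PhantomParams()
    if shape is not None:
        params = replace(params, shape=tuple(shape))
    if effect_size is not None:
        params = replace(params, effect_size=effect_size)
    rng = np.random.default_rng(seed)

    nx, ny, nz = params.shape
    center = (np.array(params.shape) - 1) / 2.0
    ix, iy, iz = np.indices(params.shape)
    dx, dy, dz = ix - center[0], iy - center[1], iz - center[2]
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    azimuth = np.arctan2(dy, dx)  # (-pi, pi]

    label = np.zeros(params.shape, dtype=np.int16)
    label[r <= params.r_brain] = LABEL_WM
    shell = (r > params.r_tumor) & (r <= params.r_edema)
    recur = shell & (azimuth >= -np.pi + 2 * np.pi * (1 - params.recur_frac))
    label[shell] = LABEL_EDEMA_PURE
    label[recur] = LABEL_EDEMA_RECUR
    label[r <= params.r_tumor] = LABEL_TUMOR

    for code in (LABEL_WM, LABEL_TUMOR, LABEL_EDEMA_PURE, LABEL_EDEMA_RECUR):
        if not np.any(label == code):
            raise ValueError(f"degenerate geometry: label {code} is empty")

    tensors = np.zeros(params.shape + (3, 3))
    f_true = np.zeros(params.shape, dtype=np.float32)

    # smooth unit-variance random field shared by all tissue classes:
    # free-water load varies regionally with correlation length
    # f_smooth_sigma, so patch averages retain wetness variability
    from scipy.ndimage import gaussian_filter

    white = rng.normal(size=params.shape)
    smooth = gaussian_filter(white, params.f_smooth_sigma)
    smooth /= max(smooth.std(), 1e-12)

    class_spec = {
        LABEL_WM: (params.wm_eigs, params.wm_f, params.wm_f_center),
        LABEL_TUMOR: (params.tumor_eigs, params.tumor_f, params.tumor_f_center),
        LABEL_EDEMA_PURE: (params.edema_eigs, params.edema_f, params.edema_f_center),
        LABEL_EDEMA_RECUR: (
            tuple(_anisotropy_shift(np.asarray(params.edema_eigs), params.effect_size)),
            params.edema_f,
            params.edema_f_center,
        ),
    }
    for code, (eigs, f_range, f_center) in class_spec.items():
        mask = label == code
        n = int(mask.sum())
        tensors[mask] = _sample_class_tensors(eigs, n, rng, params.eig_jitter_sd)
        f_true[mask] = np.clip(
            f_center + params.f_field_amplitude * smooth[mask],
            f_range[0],
            f_range[1],
        )

    return PhantomTruth(label, tensors, f_true, params.voxel_size)


def simulate_study(
    truth: PhantomTruth,
    scheme: GradientScheme,
    s0: float = 1000.0,
    snr: float = 30.0,
    seed: int | np.random.Generator | None = 0,
    d_free: float = D_FREE_DEFAULT,
    patient_id: str = "sub-000",
) -> DWIStudy:
    """Forward-simulate the 4-D DWI signal of a phantom patient.

    Labelled voxels follow the two-compartment model; background voxels are
    pure noise.  ``snr = numpy.inf`` gives the noiseless signal.
    """
    mask = truth.brain_mask()
    n_meas = scheme.n_measurements
    signal = np.zeros(truth.shape + (n_meas,))
    signal[mask] = bitensor_signal(
        truth.tissue_tensor[mask], truth.f_true[mask].astype(float), scheme, s0, d_free
    )
    if np.isfinite(snr):
        signal = add_rician_noise(signal, snr, s0=s0, seed=seed)
    return DWIStudy(signal, scheme, truth.voxel_size, patient_id)


def simulate_cohort(
    n_patients: int,
    scheme: GradientScheme,
    params: PhantomParams | None = None,
    s0: float = 1000.0,
    snr: float = 30.0,
    seed: int = 0,
) -> list[tuple[DWIStudy, PhantomTruth]]:
    """Simulate a multi-patient cohort with patient-level FA random effects.

    Each patient receives an independent noise stream and an MD-preserving
    per-patient shift of the edema tensor anisotropy drawn from
    N(0, ``params.patient_fa_sd``), applied identically to both edema
    classes, so between-patient FA heterogeneity exists on top of the
    within-patient recurrence effect.  Deterministic given the seed.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    params = params or PhantomParams()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_patients)
    cohort = []
    for i, child in enumerate(children):
        # each patient gets an independent phantom realization (wetness
        # field, voxel jitter): sector-level wetness differences must be
        # exchangeable across patients, or the cohort would carry a
        # systematic tissue-fraction offset between the edema classes
        s_effect, s_noise, s_phantom = child.spawn(3)
        eff_rng = np.random.default_rng(s_effect)
        shift_fa = (
            float(eff_rng.normal(0.0, params.patient_fa_sd))
            if params.patient_fa_sd > 0 else 0.0
        )
        shift_f = (
            float(eff_rng.normal(0.0, params.patient_f_sd))
            if params.patient_f_sd > 0 else 0.0
        )
        p = replace(
            params,
            edema_eigs=tuple(
                _anisotropy_shift(np.asarray(params.edema_eigs), shift_fa)
            ),
            edema_f_center=float(
                np.clip(params.edema_f_center + shift_f, 0.35, 0.65)
            ),
        )
        truth = build_phantom(params=p, seed=np.random.default_rng(s_phantom))
        study = simulate_study(
            truth,
            scheme,
            s0=s0,
            snr=snr,
            seed=np.random.default_rng(s_noise),
            patient_id=f"sub-{i:03d}",
        )
        cohort.append((study, truth))
    return cohort
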