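import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fwrecur.schemes import GradientScheme, make_scheme
from fwrecur.signal import (
    add_rician_noise,
    bitensor_signal,
    random_rotation_matrices,
    tensor_from_eigs,
)
from fwrecur.tensors import (
    RestoreConfig,
    compute_fa,
    compute_md,
    fit_tensor_restore,
    fit_tensor_wls,
    map_metrics,
    tensor_eigenvalues,
)


@pytest.fixture(scope="module")
def scheme():
    return make_scheme(32, 800.0, 1, seed=7)


def _random_psd_tensors(n, rng):
    eigs = np.sort(rng.uniform(0.1e-3, 2.5e-3, size=(n, 3)), axis=-1)[:, ::-1]
    return tensor_from_eigs(eigs, random_rotation_matrices(n, rng))


def test_wls_noiseless_recovery(scheme):
    rng = np.random.default_rng(0)
    for D in _random_psd_tensors(50, rng):
        atten = bitensor_signal(D, 1.0, scheme)
        fit, _ = fit_tensor_wls(atten, scheme)
        assert np.abs(fit - D).max() / np.abs(D).max() < 1e-10


def test_isotropic_attenuation_gives_isotropic_tensor(scheme):
    d = 1.2e-3
    atten = np.exp(-scheme.bvals * d)
    fit, _ = fit_tensor_wls(atten, scheme)
    assert np.allclose(fit, d * np.eye(3), atol=1e-12)


def test_no_decay_gives_zero_tensor(scheme):
    fit, _ = fit_tensor_wls(np.ones(scheme.n_measurements), scheme)
    assert np.allclose(fit, 0.0, atol=1e-15)


def test_rank_deficient_design_rejected():
    g = np.tile([1.0, 0.0, 0.0], (6, 1))  # six collinear directions
    scheme = GradientScheme(
        np.concatenate([[0.0], np.full(6, 800.0)]), np.vstack([np.zeros(3), g])
    )
    with pytest.raises(ValueError, match="rank"):
        fit_tensor_wls(np.ones(7), scheme)


def test_restore_equals_wls_on_clean_data(scheme):
    rng = np.random.default_rng(1)
    for D in _random_psd_tensors(10, rng):
        atten = bitensor_signal(D, 1.0, scheme)
        w, _ = fit_tensor_wls(atten, scheme)
        r, diag = fit_tensor_restore(atten, scheme)
        assert np.abs(w - r).max() < 1e-8
        assert diag["n_outliers"] == 0 and not diag["fallback"]


def _outlier_monte_carlo(corrupt_mult: float, snr: float, n_rep: int = 100):
    """Count reps where the robust FA error beats the WLS FA error when one
    measurement is corrupted by the given multiplier."""
    scheme = make_scheme(32, 800.0, 1, seed=7)
    D = tensor_from_eigs([1.5e-3, 0.4e-3, 0.3e-3])
    fa_true = compute_fa(tensor_eigenvalues(D))
    wins = 0
    err_w_sum = err_r_sum = 0.0
    for rep in range(n_rep):
        rng = np.random.default_rng(rep)
        sig = bitensor_signal(D, 1.0, scheme, s0=1.0)
        sig = add_rician_noise(sig, snr=snr, s0=1.0, seed=rng)
        k = int(rng.integers(0, 32))
        dwi_idx = np.flatnonzero(scheme.dwi_mask)
        sig[dwi_idx[k]] *= corrupt_mult
        atten = sig[scheme.dwi_mask] / sig[scheme.b0_mask].mean()
        fw, _ = fit_tensor_wls(atten, scheme)
        fr, _ = fit_tensor_restore(atten, scheme)
        err_w = abs(compute_fa(tensor_eigenvalues(fw)) - fa_true)
        err_r = abs(compute_fa(tensor_eigenvalues(fr)) - fa_true)
        wins += err_r < err_w
        err_w_sum += err_w
        err_r_sum += err_r
    return wins, err_r_sum / n_rep, err_w_sum / n_rep


def test_restore_beats_wls_under_spike_outlier():
    # a 3x signal spike in one measurement at SNR 40: the spike carries
    # full weight in the signal-weighted fit, so robust exclusion wins
    # in the vast majority of seeded repetitions
    wins, _, _ = _outlier_monte_carlo(3.0, 40.0)
    assert wins >= 90


def test_restore_not_worse_under_signal_drop():
    # a 50% signal drop is quadratically down-weighted by the WLS weights,
    # so per-rep wins are near chance; the robust fit must still be at
    # least as accurate on average
    wins, err_r, err_w = _outlier_monte_carlo(0.5, 40.0)
    assert err_r <= err_w
    assert wins >= 40  # never systematically worse


def test_restore_falls_back_when_too_few_retained():
    # near-total dropout in 4 of 9 measurements: exclusion would leave
    # fewer than six directions, so the non-robust fit is returned flagged
    scheme9 = make_scheme(9, 800.0, 1, seed=1)
    D = tensor_from_eigs([1.5e-3, 0.4e-3, 0.3e-3])
    rng = np.random.default_rng(0)
    atten = bitensor_signal(D, 1.0, scheme9)[scheme9.dwi_mask]
    atten = atten * (1 + rng.normal(0, 0.005, atten.size))
    atten[[0, 2, 5, 7]] = 1e-7
    _, diag = fit_tensor_restore(atten, scheme9)
    assert diag["fallback"]
    assert diag["n_outliers"] >= 4


def test_eigenvalues_descending_and_clamped():
    assert np.allclose(
        tensor_eigenvalues(np.diag([0.2e-3, 1.7e-3, 0.2e-3])),
        [1.7e-3, 0.2e-3, 0.2e-3],
    )
    assert np.allclose(tensor_eigenvalues(np.zeros((3, 3))), 0.0)
    clamped = tensor_eigenvalues(np.diag([1e-3, 1e-3, -1e-4]))
    assert clamped.min() == 0.0
    with pytest.raises(ValueError, match="symmetric"):
        tensor_eigenvalues(np.array([[1.0, 1.0, 0], [0, 1, 0], [0, 0, 1]]) * 1e-3)


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 2**31 - 1))
def test_eigenvalues_rotation_invariant(seed):
    rng = np.random.default_rng(seed)
    eigs = np.sort(rng.uniform(0, 2.5e-3, 3))[::-1]
    R = random_rotation_matrices(1, rng)[0]
    rotated = tensor_from_eigs(eigs, R)
    assert np.allclose(tensor_eigenvalues(rotated), eigs, atol=1e-12)


@pytest.mark.parametrize(
    "eigs,expected_md,expected_fa",
    [
        ((1.7e-3, 0.2e-3, 0.2e-3), 0.7e-3, 0.8704),
        ((1e-3, 1e-3, 1e-3), 1e-3, 0.0),
        ((1.0, 0.0, 0.0), 1.0 / 3, 1.0),
        ((0.0, 0.0, 0.0), 0.0, 0.0),
    ],
)
def test_md_fa_closed_form(eigs, expected_md, expected_fa):
    eigs = np.asarray(eigs)
    assert np.isclose(compute_md(eigs), expected_md)
    assert np.isclose(compute_fa(eigs), expected_fa, atol=5e-4)


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
def test_fa_bounded_and_scale_invariant(seed, scale):
    eigs = np.sort(np.random.default_rng(seed).uniform(0, 3e-3, 3))[::-1]
    fa = compute_fa(eigs)
    assert 0.0 <= fa <= 1.0
    assert np.isclose(compute_fa(eigs * scale), fa, atol=1e-9)
    assert np.isclose(compute_md(eigs * scale), compute_md(eigs) * scale)


def test_map_metrics_noiseless_pure_tissue(scheme):
    from dataclasses import replace
    from fwrecur.phantom import PhantomParams, build_phantom, simulate_study

    params = PhantomParams(
        shape=(20, 20, 20), r_tumor=2.5, r_edema=6.0, r_brain=8.5,
        wm_f=(1.0, 1.0), tumor_f=(1.0, 1.0), edema_f=(1.0, 1.0),
        wm_f_center=1.0, tumor_f_center=1.0, edema_f_center=1.0,
        f_field_amplitude=0.0,
    )
    truth = build_phantom(params=params, seed=2)
    study = simulate_study(truth, scheme, snr=np.inf, seed=0)
    fa_map, md_map = map_metrics(study, mask=truth.brain_mask())
    fa_truth = compute_fa(tensor_eigenvalues(truth.tissue_tensor))
    mask = truth.brain_mask()
    assert np.nanmax(np.abs(fa_map.values[mask] - fa_truth[mask])) < 1e-6
    # masked-out voxels are missing in both maps
    assert np.isnan(fa_map.values[~mask]).all()
    assert np.isnan(md_map.values[~mask]).all()
    # MD of the maps matches the eigenvalue mean
    md_truth = compute_md(tensor_eigenvalues(truth.tissue_tensor))
    assert np.nanmax(np.abs(md_map.values[mask] - md_truth[mask])) < 1e-9


def test_free_water_md_when_uncorrected(scheme):
    # an f = 0 voxel fit uncorrected shows MD near the free-water diffusivity
    D = tensor_from_eigs([1.5e-3, 0.4e-3, 0.3e-3])
    atten = bitensor_signal(D, 0.0, scheme)
    fit, _ = fit_tensor_wls(atten, scheme)
    assert np.isclose(compute_md(tensor_eigenvalues(fit)), 3.0e-3, rtol=1e-6)


def test_corrected_md_contrast_reduced(trained_estimator, phantom_study, phantom_truth):
    # free water drives MD contrast; suppressing it shrinks the MD spread
    from fwrecur.freewater import correct_signal, estimate_fractions
    from fwrecur.signal import estimate_noise_sigma

    edema = (phantom_truth.label == 3) | (phantom_truth.label == 4)
    fmap = estimate_fractions(trained_estimator, phantom_study, phantom_truth.brain_mask())
    corr = correct_signal(phantom_study, fmap)
    sigma = estimate_noise_sigma(phantom_study, phantom_truth.label == 0)
    _, md_c = map_metrics(corr, mask=edema, noise_sigma=sigma)
    _, md_u = map_metrics(phantom_study, mask=edema, noise_sigma=sigma)
    assert np.nanstd(md_c.values[edema]) < np.nanstd(md_u.values[edema])
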