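import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fwrecur.freewater import (
    EXCLUDE_F_BELOW_FLOOR,
    FractionMap,
    TrainConfig,
    correct_signal,
    estimate_fractions,
    make_training_set,
    train_fraction_estimator,
)
from fwrecur.phantom import build_phantom, simulate_study
from fwrecur.schemes import make_scheme
from fwrecur.signal import DWIStudy, bitensor_signal, tensor_from_eigs


def test_training_set_shape_and_range(scheme32):
    ts = make_training_set(scheme32, 5000, seed=0)
    assert ts.signals.shape == (5000, 32)
    assert np.all(ts.signals > 0)
    assert np.all((ts.fractions >= 0) & (ts.fractions <= 1))
    assert ts.scheme_fingerprint == scheme32.fingerprint()


def test_training_set_deterministic(scheme32):
    a = make_training_set(scheme32, 2000, seed=3)
    b = make_training_set(scheme32, 2000, seed=3)
    assert np.array_equal(a.signals, b.signals)
    assert np.array_equal(a.fractions, b.fractions)
    with pytest.raises(ValueError):
        make_training_set(scheme32, 500)


def test_architecture_follows_acquisition(trained_estimator, scheme_small):
    # 32 weighted measurements -> hidden layers of 16 and 8, one output
    assert trained_estimator.layer_sizes == [32, 16, 8, 1]
    ts = make_training_set(scheme_small, 2000, seed=0)
    est = train_fraction_estimator(ts, TrainConfig(max_epochs=3), seed=0)
    assert est.layer_sizes == [12, 6, 3, 1]


def test_training_deterministic(scheme_small):
    ts = make_training_set(scheme_small, 2000, seed=1)
    cfg = TrainConfig(max_epochs=5)
    e1 = train_fraction_estimator(ts, cfg, seed=4)
    e2 = train_fraction_estimator(ts, cfg, seed=4)
    for w1, w2 in zip(e1.weights, e2.weights):
        assert np.array_equal(w1, w2)
    assert "final_val_mse" in e1.metadata and "loss_curve" in e1.metadata


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**32 - 1), st.floats(-100, 100))
def test_estimator_output_bounded(trained_estimator, seed, scale):
    # arbitrary finite inputs can never push the estimate outside [0, 1]
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(8, 32)) * scale
    out = trained_estimator.predict(X)
    assert np.all((out >= 0.0) & (out <= 1.0))


def test_estimated_fraction_monotone_in_true_fraction(trained_estimator, scheme32):
    D = tensor_from_eigs([1.5e-3, 0.4e-3, 0.35e-3])
    fgrid = np.arange(0.0, 1.01, 0.1)
    sig = bitensor_signal(np.broadcast_to(D, (len(fgrid), 3, 3)), fgrid, scheme32)
    X = sig[:, scheme32.dwi_mask] / sig[:, scheme32.b0_mask].mean(axis=1, keepdims=True)
    fhat = trained_estimator.predict(X)
    assert np.all(np.diff(fhat) >= -0.02)


def test_pure_water_estimated_low(trained_estimator, scheme32):
    rng = np.random.default_rng(0)
    D = tensor_from_eigs([1.5e-3, 0.4e-3, 0.35e-3])
    sig = bitensor_signal(np.broadcast_to(D, (50, 3, 3)), np.zeros(50), scheme32)
    X = sig[:, scheme32.dwi_mask] / sig[:, scheme32.b0_mask].mean(axis=1, keepdims=True)
    assert np.all(trained_estimator.predict(X) <= 0.15)


def test_fraction_map_on_phantom(trained_estimator, phantom_study, phantom_truth):
    fmap = estimate_fractions(trained_estimator, phantom_study, phantom_truth.brain_mask())
    err = np.abs(fmap.values - phantom_truth.f_true)[fmap.valid]
    assert np.median(err) <= 0.1
    # mask contract: excluded voxel has no value
    assert not fmap.valid[0, 0, 0]
    assert np.isnan(fmap.values[0, 0, 0])


def test_scheme_mismatch_rejected(trained_estimator, scheme_small, phantom_truth):
    study = simulate_study(phantom_truth, scheme_small, snr=50.0, seed=0)
    with pytest.raises(ValueError, match="N_b"):
        estimate_fractions(trained_estimator, study)
    other = make_scheme(32, 800.0, 1, seed=99)  # same size, different table
    study2 = simulate_study(phantom_truth, other, snr=50.0, seed=0)
    with pytest.raises(ValueError, match="fingerprint|gradient table"):
        estimate_fractions(trained_estimator, study2)


def _study_from_voxels(signal_rows, scheme):
    sig = np.asarray(signal_rows)[None, None, :, :]
    return DWIStudy(sig, scheme, (2.0, 2.0, 2.0), "t")


def test_correction_identity_when_no_contamination(scheme32):
    D = tensor_from_eigs([1.6e-3, 0.3e-3, 0.3e-3])
    sig = bitensor_signal(D, 1.0, scheme32, s0=500.0)
    study = _study_from_voxels([sig], scheme32)
    fmap = FractionMap(np.ones((1, 1, 1)), np.ones((1, 1, 1), bool))
    corr = correct_signal(study, fmap)
    raw = sig[scheme32.dwi_mask] / 500.0
    assert np.allclose(corr.attenuation[0, 0, 0][scheme32.dwi_mask], raw, atol=1e-12)


def test_correction_inverts_forward_model_exactly(scheme32):
    # noiseless voxel with known f: corrected attenuation == tissue decay
    D = tensor_from_eigs([1.4e-3, 0.5e-3, 0.4e-3])
    f = 0.5
    sig = bitensor_signal(D, f, scheme32, s0=1000.0)
    study = _study_from_voxels([sig], scheme32)
    fmap = FractionMap(np.full((1, 1, 1), f), np.ones((1, 1, 1), bool))
    corr = correct_signal(study, fmap)
    g = scheme32.bvecs[scheme32.dwi_mask]
    expected = np.exp(-800.0 * np.einsum("ki,ij,kj->k", g, D, g))
    assert np.allclose(corr.attenuation[0, 0, 0][scheme32.dwi_mask], expected, atol=1e-12)


def test_low_fraction_voxels_excluded(scheme32):
    D = tensor_from_eigs([1.4e-3, 0.5e-3, 0.4e-3])
    sig = bitensor_signal(D, 0.05, scheme32, s0=1000.0)
    study = _study_from_voxels([sig], scheme32)
    fmap = FractionMap(np.full((1, 1, 1), 0.05), np.ones((1, 1, 1), bool))
    corr = correct_signal(study, fmap, f_floor=0.1)
    assert not corr.included[0, 0, 0]
    assert corr.exclusion_reason[0, 0, 0] == EXCLUDE_F_BELOW_FLOOR


def test_estimator_serialization_roundtrip(trained_estimator, tmp_path):
    trained_estimator.save(tmp_path / "model.npz")
    from fwrecur.freewater import FractionEstimator

    back = FractionEstimator.load(tmp_path / "model.npz")
    X = np.random.default_rng(0).uniform(0.05, 1.0, size=(10, 32))
    assert np.allclose(back.predict(X), trained_estimator.predict(X))
    assert back.scheme_fingerprint == trained_estimator.scheme_fingerprint
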