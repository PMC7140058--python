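import subprocess

import numpy as np
import pandas as pd
import pytest

from fwrecur.phantom import LABEL_EDEMA_PURE, LABEL_EDEMA_RECUR
from fwrecur.recurrence import (
    crossval_scores,
    delong_compare,
    fit_mixed_logit,
    roc_auc,
    sample_patches,
)
from fwrecur.tensors import ScalarMap


def _const_map(shape, value):
    return ScalarMap(np.full(shape, value), "FA", True)


def _bar_labels():
    """Label-4 bar admitting exactly one set of 4 disjoint 3x3x3 patches,
    plus an ample label-3 block."""
    labels = np.zeros((20, 20, 20), dtype=int)
    labels[1:4, 1:13, 1:4] = LABEL_EDEMA_RECUR  # 3 x 12 x 3 bar
    labels[6:17, 6:17, 6:17] = LABEL_EDEMA_PURE
    return labels


def test_forced_patch_placement_unique():
    labels = _bar_labels()
    maps = _const_map(labels.shape, 0.5), _const_map(labels.shape, 0.4)
    expected = {(2, 2, 2), (2, 5, 2), (2, 8, 2), (2, 11, 2)}
    for seed in range(5):
        df = sample_patches(maps[0], maps[1], labels, "p0", seed=seed)
        recur = df[df["label"] == 1]
        got = set(zip(recur.center_x, recur.center_y, recur.center_z))
        assert got == expected


def test_constant_map_gives_constant_predictors():
    labels = _bar_labels()
    df = sample_patches(
        _const_map(labels.shape, 0.37), _const_map(labels.shape, 0.21),
        labels, "p0", seed=1,
    )
    assert np.allclose(df["fa_fwc"], 0.37)
    assert np.allclose(df["fa_uncorrected"], 0.21)
    assert (df["n_valid_voxels"] == 27).all()


def test_default_patch_count_on_phantom(phantom_truth):
    maps = (
        _const_map(phantom_truth.shape, 0.5),
        _const_map(phantom_truth.shape, 0.4),
    )
    df = sample_patches(maps[0], maps[1], phantom_truth.label, "p0", seed=0)
    assert len(df) == 8
    assert (df["label"].value_counts() == 4).all()
    # patches are disjoint and inside their class
    centers = df[["center_x", "center_y", "center_z"]].to_numpy()
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            assert np.any(np.abs(centers[i] - centers[j]) >= 3)


def test_infeasible_region_raises():
    labels = np.zeros((10, 10, 10), dtype=int)
    labels[1:4, 1:4, 1:4] = LABEL_EDEMA_RECUR  # room for one patch only
    labels[5:9, 5:9, 5:9] = LABEL_EDEMA_PURE
    maps = _const_map(labels.shape, 0.5), _const_map(labels.shape, 0.4)
    with pytest.raises(ValueError, match="cannot place"):
        sample_patches(maps[0], maps[1], labels, "p7", seed=0)


def _sim_glmm(n_pat, sigma2, seed, beta0=2.0, beta1=-8.0, n_obs=8):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(sigma2), n_pat) if sigma2 > 0 else np.zeros(n_pat)
    rows = []
    for i in range(n_pat):
        x = rng.uniform(0.1, 0.6, n_obs)
        eta = beta0 + beta1 * x + u[i]
        y = rng.uniform(size=n_obs) < 1 / (1 + np.exp(-eta))
        rows += [
            {"patient_id": f"p{i}", "fa_fwc": xi, "fa_uncorrected": xi, "label": int(yi)}
            for xi, yi in zip(x, y)
        ]
    return pd.DataFrame(rows)


def test_mixed_logit_sigma_zero_reduces_to_plain_logistic():
    import statsmodels.api as sm

    df = _sim_glmm(100, 0.0, seed=1)
    fit = fit_mixed_logit(df, "fwc", fix_sigma=0.0)
    plain = sm.Logit(df["label"], sm.add_constant(df["fa_fwc"])).fit(disp=0)
    assert np.max(np.abs(fit.beta - plain.params.values)) < 1e-3


def test_mixed_logit_matches_lme4_oracle(tmp_path):
    # independent cross-check against R's glmer (adaptive GH, 15 nodes)
    df = _sim_glmm(150, 0.5, seed=7)
    fit = fit_mixed_logit(df, "fwc")
    csv = tmp_path / "glmm.csv"
    df.to_csv(csv, index=False)
    rscript = (
        "suppressMessages(library(lme4));"
        f"d <- read.csv('{csv}');"
        "m <- glmer(label ~ fa_fwc + (1|patient_id), data=d, family=binomial, nAGQ=15);"
        "cat(fixef(m), as.data.frame(VarCorr(m))$vcov, sep=',')"
    )
    out = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
    )
    b0, b1, s2 = map(float, out.stdout.strip().split(","))
    assert np.allclose(fit.beta, [b0, b1], atol=1e-3)
    assert np.isclose(fit.sigma_u2, s2, atol=1e-3)


def test_mixed_logit_recovers_simulated_effects():
    fits = [fit_mixed_logit(_sim_glmm(200, 0.5, seed=s), "fwc") for s in range(3)]
    assert abs(np.mean([f.beta[1] for f in fits]) - (-8.0)) < 2.0
    assert 0.1 < np.mean([f.sigma_u2 for f in fits]) < 1.5


def test_crossval_scores_grouped_and_complete():
    df = _sim_glmm(12, 0.3, seed=2)
    scores = crossval_scores(df, "fwc", k=3, seed=5)
    assert scores.shape == (len(df),)
    assert np.all((scores > 0) & (scores < 1))
    again = crossval_scores(df, "fwc", k=3, seed=5)
    assert np.array_equal(scores, again)
    other = crossval_scores(df, "fwc", k=3, seed=6)
    assert not np.array_equal(scores, other)


def test_crossval_separable_predictor_gives_perfect_auc():
    rows = []
    rng = np.random.default_rng(0)
    for i in range(9):
        for j in range(8):
            y = j % 2
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "fa_fwc": (0.8 if y else 0.2) + rng.normal(0, 0.01),
                    "label": y,
                }
            )
    df = pd.DataFrame(rows)
    scores = crossval_scores(df, "fwc", k=3, seed=1)
    auc, *_ = roc_auc(scores, df["label"].to_numpy())
    assert auc == 1.0


def test_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = int(rng.integers(10, 60))
        scores = np.round(rng.uniform(size=n), 2)  # rounding induces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc, fpr, tpr, _ = roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        diff = pos[:, None] - neg[None, :]
        brute = np.mean(np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0)))
        assert np.isclose(auc, brute)
        assert fpr[0] == 0 and fpr[-1] == 1


def test_auc_edge_cases():
    labels = np.array([1, 1, 0, 0])
    assert roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), labels)[0] == 1.0
    assert roc_auc(np.array([0.5, 0.5, 0.5, 0.5]), labels)[0] == 0.5
    with pytest.raises(ValueError):
        roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


def test_delong_self_comparison_and_antisymmetry():
    rng = np.random.default_rng(9)
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    s1 = rng.uniform(size=40)
    s2 = np.clip(s1 + rng.normal(0, 0.2, 40), 0, 1)
    self_cmp = delong_compare(s1, s1, labels)
    assert self_cmp.p_value == 1.0 and self_cmp.z == 0.0
    ab = delong_compare(s1, s2, labels)
    ba = delong_compare(s2, s1, labels)
    assert np.isclose(ab.z, -ba.z)
    assert np.isclose(ab.p_value, ba.p_value)


def test_delong_single_auc_variance_closed_form():
    # without ties, var(AUC) reduces to the Mann-Whitney closed form
    # computable from the structural components themselves; check against
    # a direct small-sample computation
    rng = np.random.default_rng(2)
    labels = np.array([1] * 6 + [0] * 7)
    scores = rng.permutation(np.arange(13, dtype=float))
    cmp = delong_compare(scores, scores, labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    v10, v01 = psi.mean(axis=1), psi.mean(axis=0)
    expected = np.var(v10, ddof=1) / 6 + np.var(v01, ddof=1) / 7
    assert np.isclose(cmp.var_a, expected)
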