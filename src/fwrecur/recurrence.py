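"""Recurrence prediction from edema patches.

Pipeline stage mirroring a patch-based predictive analysis: small cubic
patches are randomly sampled from each patient's peritumoral edema (half
from the sector with later recurrence, half from recurrence-free edema);
per-patch mean FA values -- free-water-corrected and uncorrected -- feed
random-intercept logistic models (patient as the random effect); grouped
threefold cross-validation yields out-of-fold scores, ROC curves and AUCs;
and correlated AUCs are compared with DeLong's structural-components test.

The mixed model is

    logit P(recurrence_ij) = x_ij' beta + u_i,   u_i ~ N(0, sigma_u^2)

fit by marginal maximum likelihood with adaptive Gauss-Hermite quadrature
(the per-patient integrand is centred at its posterior mode and scaled by
its curvature, so few nodes suffice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit
from sklearn.metrics import roc_auc_score, roc_curve

from .phantom import LABEL_EDEMA_PURE, LABEL_EDEMA_RECUR
from .tensors import ScalarMap

__all__ = [
    "MixedLogitFit",
    "ROCComparison",
    "sample_patches",
    "fit_mixed_logit",
    "crossval_scores",
    "roc_auc",
    "delong_compare",
]

PREDICTOR_COLUMNS = {
    "fwc": ["fa_fwc"],
    "uncorrected": ["fa_uncorrected"],
    "both": ["fa_fwc", "fa_uncorrected"],
}


@dataclass
class MixedLogitFit:
    """Marginal-ML fit of the random-intercept logistic model."""

    predictors: list[str]
    beta: np.ndarray  # intercept first
    sigma_u2: float
    loglik: float
    se: np.ndarray
    wald_p: np.ndarray
    converged: bool
    separation: bool
    n_quad: int

    def predict_fixed(self, X: np.ndarray) -> np.ndarray:
        """Population-level probabilities (random intercept at its mean 0)."""
        from scipy.special import expit

        eta = self.beta[0] + X @ self.beta[1:]
        return expit(eta)


@dataclass
class ROCComparison:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p_value: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# patch sampling


def _admissible_centers(labels: np.ndarray, code: int, patch: tuple[int, int, int],
                        valid: np.ndarray, min_valid: int) -> list[tuple[int, int, int]]:
    px, py, pz = patch
    hx, hy, hz = px // 2, py // 2, pz // 2
    centers = []
    idx = np.argwhere(labels == code)
    for x, y, z in idx:
        sl = (slice(x - hx, x + hx + 1), slice(y - hy, y + hy + 1),
              slice(z - hz, z + hz + 1))
        if x - hx < 0 or y - hy < 0 or z - hz < 0:
            continue
        if (x + hx >= labels.shape[0] or y + hy >= labels.shape[1]
                or z + hz >= labels.shape[2]):
            continue
        block = labels[sl]
        if block.shape != patch or not np.all(block == code):
            continue
        if valid[sl].sum() < min_valid:
            continue
        centers.append((int(x), int(y), int(z)))
    return centers


def _pick_disjoint(centers: list, n: int, patch: tuple[int, int, int],
                   rng: np.random.Generator, max_nodes: int = 20000):
    """Randomized backtracking search for n pairwise non-overlapping patches."""
    order = [centers[i] for i in rng.permutation(len(centers))]
    chosen: list = []
    nodes = 0

    def overlaps(c1, c2) -> bool:
        return all(abs(a - b) < p for a, b, p in zip(c1, c2, patch))

    def search(start: int) -> bool:
        nonlocal nodes
        if len(chosen) == n:
            return True
        for i in range(start, len(order)):
            nodes += 1
            if nodes > max_nodes:
                return False
            c = order[i]
            if any(overlaps(c, prev) for prev in chosen):
                continue
            chosen.append(c)
            if search(i + 1):
                return True
            chosen.pop()
        return False

    return chosen if search(0) else None


def sample_patches(
    fa_fwc: ScalarMap,
    fa_uncorrected: ScalarMap,
    labels: np.ndarray,
    patient_id: str,
    n_per_class: int = 4,
    patch_voxels: tuple[int, int, int] = (3, 3, 3),
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Sample disjoint cubic patches from both edema classes of one patient.

    Each patch lies wholly inside its class region and contains at least
    half a patch-volume of valid (non-missing) FA voxels in both maps; the
    patch predictor is the mean FA over those voxels.  Placement is
    uniform among admissible non-overlapping configurations via seeded
    randomized backtracking; an infeasible region raises with the patient
    and class named.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    patch = tuple(patch_voxels)
    n_half = int(np.ceil(np.prod(patch) / 2))
    valid = np.isfinite(fa_fwc.values) & np.isfinite(fa_uncorrected.values)
    rows = []
    for code, lab_name in ((LABEL_EDEMA_RECUR, 1), (LABEL_EDEMA_PURE, 0)):
        centers = _admissible_centers(labels, code, patch, valid, n_half)
        picked = _pick_disjoint(centers, n_per_class, patch, rng) if centers else None
        if not picked or len(picked) < n_per_class:
            raise ValueError(
                f"patient {patient_id}: cannot place {n_per_class} disjoint "
                f"patches in region {code}"
            )
        hx, hy, hz = (p // 2 for p in patch)
        for cx, cy, cz in picked:
            sl = (slice(cx - hx, cx + hx + 1), slice(cy - hy, cy + hy + 1),
                  slice(cz - hz, cz + hz + 1))
            m = valid[sl]
            rows.append(
                {
                    "patient_id": patient_id,
                    "center_x": cx,
                    "center_y": cy,
                    "center_z": cz,
                    "label": lab_name,
                    "fa_fwc": float(np.nanmean(fa_fwc.values[sl][m])),
                    "fa_uncorrected": float(np.nanmean(fa_uncorrected.values[sl][m])),
                    "n_valid_voxels": int(m.sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-intercept logistic model


def _group_arrays(df: pd.DataFrame, cols: list[str]):
    """Pad per-patient designs to rectangular arrays for vectorized AGQ."""
    pids = df["patient_id"].unique()
    n_max = df.groupby("patient_id").size().max()
    n_pat = len(pids)
    X = np.zeros((n_pat, n_max, len(cols)))
    y = np.zeros((n_pat, n_max))
    w = np.zeros((n_pat, n_max))  # 1 for real observations, 0 for padding
    for i, pid in enumerate(pids):
        sub = df[df["patient_id"] == pid]
        k = len(sub)
        X[i, :k] = sub[cols].to_numpy()
        y[i, :k] = sub["label"].to_numpy()
        w[i, :k] = 1.0
    return X, y, w, pids


def _mixed_loglik(params, X, y, w, nodes, weights):
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature.

    params = (beta..., log_sigma); X (n_pat, n_obs, p) includes intercept.
    """
    p = X.shape[2]
    beta = params[:p]
    sigma = params[p]
    eta0 = X @ beta  # (n_pat, n_obs)

    def obs_ll_flat(u):
        eta = eta0 + u[:, None]
        return (w * (y * eta - np.logaddexp(0.0, eta))).sum(axis=1)

    if sigma < 1e-8:
        # degenerate random effect: ordinary logistic likelihood
        return float(obs_ll_flat(np.zeros(X.shape[0])).sum())

    obs_ll = obs_ll_flat

    # Newton for the per-patient posterior mode
    u = np.zeros(X.shape[0])
    for _ in range(50):
        eta = eta0 + u[:, None]
        mu = expit(eta)
        grad = (w * (y - mu)).sum(axis=1) - u / sigma**2
        hess = (w * mu * (1 - mu)).sum(axis=1) + 1.0 / sigma**2
        step = grad / hess
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[:, None]
    mu = expit(eta)
    hess = (w * mu * (1 - mu)).sum(axis=1) + 1.0 / sigma**2
    scale = np.sqrt(2.0 / hess)  # (n_pat,)
    # sum_k w_k e^{x_k^2} f(u_hat + scale*x_k) * scale / sqrt(2*pi*sigma^2)
    ll = np.zeros(X.shape[0])
    total = np.zeros(X.shape[0])
    log_terms = []
    for xk, wk in zip(nodes, weights):
        uk = u + scale * xk
        g = obs_ll(uk) - 0.5 * uk**2 / sigma**2
        log_terms.append(np.log(wk) + xk**2 + g)
    log_terms = np.array(log_terms)  # (n_nodes, n_pat)
    m = log_terms.max(axis=0)
    integral = np.exp(log_terms - m).sum(axis=0)
    ll = m + np.log(integral) + np.log(scale) - 0.5 * np.log(2 * np.pi * sigma**2)
    return float(ll.sum())


def fit_mixed_logit(
    samples: pd.DataFrame,
    predictors: str | list[str] = "fwc",
    n_quad: int = 15,
    max_abs_beta: float = 50.0,
    fix_sigma: float | None = None,
) -> MixedLogitFit:
    """Fit the random-intercept logistic model by marginal ML.

    ``predictors`` is one of "fwc", "uncorrected", "both", or an explicit
    list of column names.  Wald standard errors come from the numerical
    Hessian of the negative marginal log-likelihood.  Quasi-separation
    (|beta| exceeding ``max_abs_beta``) is flagged, not silenced.
    """
    cols = PREDICTOR_COLUMNS[predictors] if isinstance(predictors, str) else predictors
    if samples["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients")
    if samples["label"].nunique() < 2:
        raise ValueError("both outcome classes must be present")
    Xr, y, w, _ = _group_arrays(samples, cols)
    n_pat, n_obs, p_raw = Xr.shape
    # standardize predictors internally: FA-scale covariates push |beta|
    # to O(30) and wreck the conditioning of the finite-difference
    # gradients; coefficients are transformed back afterwards
    obs_mask3 = w > 0
    loc = np.array([Xr[..., j][obs_mask3].mean() for j in range(p_raw)])
    scale = np.array([max(Xr[..., j][obs_mask3].std(), 1e-12) for j in range(p_raw)])
    Xs = (Xr - loc) / scale
    X = np.concatenate([np.ones((n_pat, n_obs, 1)), Xs], axis=2)
    nodes, weights = hermgauss(n_quad)

    # start from pooled logistic (sigma ~ 0.3)
    from sklearn.linear_model import LogisticRegression

    flat_mask = w.reshape(-1) > 0
    Xflat = X.reshape(-1, p_raw + 1)[flat_mask][:, 1:]
    yflat = y.reshape(-1)[flat_mask]
    lr = LogisticRegression(C=np.inf, max_iter=1000).fit(Xflat, yflat)
    x0 = np.concatenate([[lr.intercept_[0]], lr.coef_[0], [0.3]])

    def nll(params):
        return -_mixed_loglik(params, X, y, w, nodes, weights)

    if fix_sigma is not None:
        bounds = [(-500, 500)] * (p_raw + 1) + [(fix_sigma, fix_sigma)]
        x0[-1] = fix_sigma
    else:
        # sigma capped at 5: the 15-node adaptive quadrature is accurate in
        # this range, and larger fitted sigmas only arise when per-patient
        # intercepts absorb a separable outcome
        bounds = [(-500, 500)] * (p_raw + 1) + [(0.0, 5.0)]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    if not res.success:
        # L-BFGS-B line searches can fail on near-flat likelihoods (tiny or
        # separable data); polish with a derivative-free pass
        res2 = optimize.minimize(nll, res.x, method="Powell", bounds=bounds,
                                 options={"maxiter": 4000, "xtol": 1e-10})
        if res2.fun <= res.fun:
            res = res2
    nll_start = nll(x0)
    beta_std = res.x[: p_raw + 1]
    sigma = res.x[p_raw + 1]
    # back-transform to the original predictor scale
    jac = np.eye(p_raw + 1)
    jac[0, 1:] = -loc / scale
    for j in range(p_raw):
        jac[j + 1, j + 1] = 1.0 / scale[j]
    beta = jac @ beta_std
    # numerical Hessian (central differences) for Wald SEs
    k = len(res.x)
    h = np.maximum(1e-4, 1e-4 * np.abs(res.x))
    # keep sigma probes inside its bound
    x_h = res.x.copy()
    x_h[-1] = max(x_h[-1], h[-1] + 1e-6)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = nll(x_h + ei + ej)
            fpm = nll(x_h + ei - ej)
            fmp = nll(x_h - ei + ej)
            fmm = nll(x_h - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov_std = np.linalg.inv(H)[: p_raw + 1, : p_raw + 1]
        cov_fixed = jac @ cov_std @ jac.T
        se = np.sqrt(np.maximum(np.diag(cov_fixed), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p_raw + 1, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / se
    wald_p = 2 * stats.norm.sf(np.abs(zvals))
    # quasi-separation: runaway coefficients, or the fixed-effect score
    # already classifies every observation correctly (the likelihood then
    # plateaus and optimizers stall before any |beta| threshold)
    eta_flat = Xflat @ beta_std[1:] + beta_std[0]
    complete = bool(np.all((eta_flat > 0) == (yflat > 0.5)))
    # a near-zero marginal deviance per observation is the same plateau:
    # patient intercepts plus the score fit the outcomes almost perfectly
    near_perfect = res.fun / max(int(flat_mask.sum()), 1) < 0.05
    separation = (
        bool(np.any(np.abs(beta_std) > max_abs_beta)) or complete or near_perfect
    )
    if not res.success and not separation and res.fun >= nll_start - 1e-8:
        raise RuntimeError(f"mixed-logit fit did not converge: {res.message}")
    return MixedLogitFit(
        predictors=cols,
        beta=beta,
        sigma_u2=float(sigma**2),
        loglik=-float(res.fun),
        se=se,
        wald_p=wald_p,
        converged=bool(res.success),
        separation=separation,
        n_quad=n_quad,
    )


# ---------------------------------------------------------------------------
# cross-validation, ROC, DeLong


def crossval_scores(
    samples: pd.DataFrame,
    predictors: str | list[str] = "fwc",
    k: int = 3,
    seed: int | None = 0,
) -> np.ndarray:
    """Grouped k-fold out-of-fold scores (folds partition patients).

    A patient's patches never straddle folds.  Held-out patients are
    scored with the fixed effects only (random intercept at its zero
    mean).  If a fold ends up with a single outcome class the patients
    are reshuffled once; a second failure raises.
    """
    cols = PREDICTOR_COLUMNS[predictors] if isinstance(predictors, str) else predictors
    pids = samples["patient_id"].unique()
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pids) < k:
        raise ValueError("need at least k patients for k folds")
    rng = np.random.default_rng(seed)

    def make_folds():
        perm = rng.permutation(pids)
        return np.array_split(perm, k)

    for attempt in range(2):
        folds = make_folds()
        ok = True
        for fold in folds:
            test = samples[samples["patient_id"].isin(fold)]
            train = samples[~samples["patient_id"].isin(fold)]
            if test["label"].nunique() < 2 or train["label"].nunique() < 2:
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError("could not build folds with both classes after reshuffle")

    scores = np.full(len(samples), np.nan)
    for fold in folds:
        in_test = samples["patient_id"].isin(fold).to_numpy()
        train = samples[~in_test]
        fit = fit_mixed_logit(train, cols)
        Xtest = samples.loc[in_test, cols].to_numpy()
        scores[in_test] = fit.predict_fixed(Xtest)
    assert not np.any(np.isnan(scores))
    return scores


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """AUC (Mann-Whitney with half-weight ties) plus ROC curve points."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes required for ROC analysis")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return auc, fpr, tpr, thresholds


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi matrix via broadcasting: 1 if pos > neg, 0.5 ties
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)  # per positive case
    v01 = psi.mean(axis=0)  # per negative case
    return v10, v01, psi.mean()


def delong_compare(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> ROCComparison:
    """DeLong's test for two correlated AUCs computed on the same cases."""
    labels = np.asarray(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("both score vectors must cover the same cases")
    v10a, v01a, auc_a = _structural_components(scores_a, labels)
    v10b, v01b, auc_b = _structural_components(scores_b, labels)
    m = v10a.size
    n = v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    S = s10 / m + s01 / n
    var_a, var_b, cov_ab = S[0, 0], S[1, 1], S[0, 1]
    var_diff = var_a + var_b - 2 * cov_ab
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            return ROCComparison(auc_a, auc_b, var_a, var_b, cov_ab,
                                 z=0.0, p_value=1.0)
        return ROCComparison(auc_a, auc_b, var_a, var_b, cov_ab,
                             z=np.inf if auc_a > auc_b else -np.inf,
                             p_value=0.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return ROCComparison(float(auc_a), float(auc_b), float(var_a), float(var_b),
                         float(cov_ab), float(z), float(p))
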