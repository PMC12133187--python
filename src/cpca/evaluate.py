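"""ROC/AUC evaluation of composite and single biomarkers.

Scores here follow the protective orientation: a good marker gives
non-cases HIGHER scores than cases, so AUC = P(non-case > case) + 1/2
P(tie), the midrank Mann-Whitney estimate.  Confidence intervals use the
stratified percentile bootstrap (cases and non-cases resampled separately);
paired ROC comparison offers the studentized-bootstrap p-value (the
semantics of the standard R ROC toolkit, normal tail on
delta / sd(bootstrap deltas)) and the DeLong asymptotic test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "RocComparison",
    "LogisticResult",
    "auc",
    "bootstrap_auc_ci",
    "compare_paired_roc",
    "delong_test",
    "train_test_split",
    "fit_logistic_cp",
    "orient_marker",
    "odds_percent_change",
]


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


@dataclass
class RocComparison:
    auc_a: float
    auc_b: float
    delta: float
    p_value: float
    method: str
    n_boot: int = 0
    seed: int = 0


@dataclass
class LogisticResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    coef: float
    coef_se: float
    covariate_coefs: dict
    converged: bool
    separation_flag: bool


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _split_by_status(scores: np.ndarray, disease_status: np.ndarray):
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(disease_status).astype(bool)
    if scores.shape != status.shape:
        raise ValueError("scores and labels differ in length")
    cases = scores[status]
    ctrls = scores[~status]
    if cases.size == 0 or ctrls.size == 0:
        raise ValueError("need at least one case and one non-case")
    return ctrls, cases


def _auc_sorted_cases(ctrls: np.ndarray, cases_sorted: np.ndarray) -> float:
    # P(ctrl > case) + 1/2 P(tie) via binary search into sorted case scores
    lo = np.searchsorted(cases_sorted, ctrls, side="left")
    hi = np.searchsorted(cases_sorted, ctrls, side="right")
    return float((lo + 0.5 * (hi - lo)).sum() / (ctrls.size * cases_sorted.size))


def auc(scores: np.ndarray, disease_status: np.ndarray) -> float:
    """Midrank Mann-Whitney AUC = P(non-case > case) + 1/2 P(tie).

    Equals the trapezoidal area under the empirical ROC curve.
    """
    ctrls, cases = _split_by_status(scores, disease_status)
    return _auc_sorted_cases(ctrls, np.sort(cases))


def orient_marker(values: np.ndarray, disease_status: np.ndarray) -> int:
    """Training-data orientation for a raw single marker: -1 if cases have
    the higher mean (marker is risk-directed), else +1."""
    ctrls, cases = _split_by_status(values, disease_status)
    return -1 if cases.mean() > ctrls.mean() else 1


def odds_percent_change(odds_ratio: float) -> float:
    """Percent change in odds per unit increase: (1 - OR) * 100 for
    protective markers (OR 0.419 -> 58.1% decrease)."""
    return (1.0 - odds_ratio) * 100.0


# ---------------------------------------------------------------------------
# Stratified bootstrap
# ---------------------------------------------------------------------------

def _boot_aucs(
    ctrl_mats: list[np.ndarray], case_mats: list[np.ndarray]
) -> np.ndarray:
    """AUC per replicate for one or two markers sharing resample indices.

    ctrl_mats / case_mats are lists of (B, n) score matrices.
    """
    B = ctrl_mats[0].shape[0]
    out = np.empty((len(ctrl_mats), B))
    for m, (C, K) in enumerate(zip(ctrl_mats, case_mats)):
        Ks = np.sort(K, axis=1)
        for b in range(B):
            out[m, b] = _auc_sorted_cases(C[b], Ks[b])
    return out


def _stratified_indices(rng, n_ctrl: int, n_case: int, n_boot: int):
    ci = rng.integers(0, n_ctrl, size=(n_boot, n_ctrl))
    ki = rng.integers(0, n_case, size=(n_boot, n_case))
    return ci, ki


def bootstrap_auc_ci(
    scores: np.ndarray,
    disease_status: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> RocResult:
    """Stratified percentile bootstrap CI for the AUC: cases and non-cases
    are resampled with replacement separately, so every replicate keeps at
    least one member of each class."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ctrls, cases = _split_by_status(scores, disease_status)
    point = _auc_sorted_cases(ctrls, np.sort(cases))
    rng = np.random.default_rng(seed)
    ci, ki = _stratified_indices(rng, ctrls.size, cases.size, n_boot)
    reps = _boot_aucs([ctrls[ci]], [cases[ki]])[0]
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return RocResult(point, float(lo), float(hi), n_boot, seed)


# ---------------------------------------------------------------------------
# Paired ROC comparison
# ---------------------------------------------------------------------------

def _delong_placements(ctrls: np.ndarray, cases: np.ndarray):
    cases_sorted = np.sort(cases)
    lo = np.searchsorted(cases_sorted, ctrls, side="left")
    hi = np.searchsorted(cases_sorted, ctrls, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / cases.size  # per-control placement
    ctrls_sorted = np.sort(ctrls)
    lo = np.searchsorted(ctrls_sorted, cases, side="left")
    hi = np.searchsorted(ctrls_sorted, cases, side="right")
    # per-case placement of controls ABOVE the case, plus half-ties
    v01 = (ctrls.size - hi + 0.5 * (hi - lo)) / ctrls.size
    return v10, v01


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, disease_status: np.ndarray
) -> RocComparison:
    """DeLong paired test for the difference of two correlated AUCs."""
    ca, ka = _split_by_status(scores_a, disease_status)
    cb, kb = _split_by_status(scores_b, disease_status)
    v10a, v01a = _delong_placements(ca, ka)
    v10b, v01b = _delong_placements(cb, kb)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    delta = auc_a - auc_b
    n0, n1 = ca.size, ka.size
    var = (np.var(v10a - v10b, ddof=1) / n0 + np.var(v01a - v01b, ddof=1) / n1)
    if var <= 0:
        p = 1.0
    else:
        z = delta / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return RocComparison(auc_a, auc_b, delta, p, "delong")


def compare_paired_roc(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    disease_status: np.ndarray,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocComparison:
    """Compare two markers' ROC curves on the same samples.

    bootstrap: per stratified replicate (shared resample indices for both
    markers) compute the AUC difference; the statistic
    D = (auc_a - auc_b) / sd(bootstrap differences) is referred to the
    standard normal, two-sided.  delong: asymptotic paired test.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors differ in length")
    if method == "delong":
        return delong_test(scores_a, scores_b, disease_status)
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    status = np.asarray(disease_status).astype(bool)
    ca, ka = _split_by_status(scores_a, status)
    cb, kb = _split_by_status(scores_b, status)
    auc_a = _auc_sorted_cases(ca, np.sort(ka))
    auc_b = _auc_sorted_cases(cb, np.sort(kb))
    delta = auc_a - auc_b
    rng = np.random.default_rng(seed)
    ci, ki = _stratified_indices(rng, ca.size, ka.size, n_boot)
    reps = _boot_aucs([ca[ci], cb[ci]], [ka[ki], kb[ki]])
    diffs = reps[0] - reps[1]
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(delta / sd)))
    return RocComparison(auc_a, auc_b, delta, p, "bootstrap", n_boot, seed)


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def train_test_split(
    disease_status: np.ndarray, train_fraction: float = 0.70, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split: within cases and non-cases separately, a random
    round(train_fraction * n) samples go to train.  Returns (train_idx,
    test_idx) as disjoint, exhaustive integer index arrays."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0,1)")
    status = np.asarray(disease_status).astype(bool)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for stratum in (True, False):
        idx = np.flatnonzero(status == stratum)
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


# ---------------------------------------------------------------------------
# Logistic disease model
# ---------------------------------------------------------------------------

def fit_logistic_cp(
    cp_scores: np.ndarray,
    disease_status: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> LogisticResult:
    """Maximum-likelihood logistic fit of status ~ CP + age + sex.

    Returns the CP odds ratio per unit score with its Wald 95% CI.  A
    quasi-separated CP (its within-class score ranges do not overlap) is
    flagged; non-convergence raises with diagnostics.
    """
    import statsmodels.api as sm

    y = np.asarray(disease_status).astype(int)
    X = np.column_stack([np.asarray(cp_scores, float),
                         np.asarray(age, float), np.asarray(sex, float)])
    X = sm.add_constant(X, has_constant="add")
    cp = X[:, 1]
    separation = cp[y == 1].max() < cp[y == 0].min() or cp[y == 0].max() < cp[y == 1].min()
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit did not converge: {fit.mle_retvals}")
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    zcrit = stats.norm.ppf(0.975)
    return LogisticResult(
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zcrit * se)),
        ci_high=float(np.exp(coef + zcrit * se)),
        coef=coef,
        coef_se=se,
        covariate_coefs={"const": float(fit.params[0]),
                         "age": float(fit.params[2]),
                         "sex": float(fit.params[3])},
        converged=True,
        separation_flag=bool(separation),
    )
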