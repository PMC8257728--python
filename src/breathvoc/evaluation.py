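"""ROC/AUC machinery, cross-validated AUC, permutation significance, validation.

Model performance is estimated by the study's two-pronged design:

1. fivefold stratified cross-validation on the training set — each fold's
   model is rebuilt from scratch (penalty selection nested inside the
   training 4/5) and scored by AUC on the held-out fold; the summary AUC_CV
   is the mean of the five fold AUCs.  Model significance comes from a
   permutation test: class labels are permuted, the whole model-building
   procedure is re-run per permutation, and the add-one p-value
   (1 + #{null >= observed}) / (1 + B) compares the observed AUC_CV with its
   permutation null.
2. external validation — the model fitted on all training samples (at the
   cross-validated penalty) is applied to the held-out validation split,
   giving AUC_VS plus sensitivity/specificity at a prevalence-based cutoff.

AUC is the tie-corrected concordance probability, identical to the
trapezoidal area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .lasso_lr import (
    DesignMatrix,
    LassoModel,
    cv_select_lambda,
    fit_lasso_lr,
    predict_prob,
    standardize,
    stratified_folds,
)


@dataclass
class RocCurve:
    thresholds: np.ndarray  # decreasing
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CvResult:
    fold_aucs: np.ndarray
    auc_cv: float
    fold_indices: list
    seed: int
    chosen_lambdas: np.ndarray = None


@dataclass
class PermutationModelResult:
    observed_auc_cv: float
    null_auc_cv: np.ndarray
    B: int
    p_value: float
    seed: int
    refit_lambda: bool = True


@dataclass
class ValidationMetrics:
    auc_vs: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    confusion: np.ndarray  # [[TP, FN], [FP, TN]]


@dataclass
class FitConfig:
    """Model-building knobs threaded through CV and permutation loops."""

    n_lambda: int = 50
    inner_folds: int = 5
    metric: str = "deviance"
    tol: float = 1e-6
    max_iter: int = 100_000


def auc(scores, labels) -> float:
    """Tie-corrected concordance AUC.

    (#{case score > control score} + 0.5 * #{ties}) / (n_case * n_control),
    computed from mid-ranks; equals the trapezoidal ROC area.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores, labels) -> RocCurve:
    """ROC curve points (decreasing thresholds) with the concordance AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc(scores, labels))


def prevalence_cutoff(train_labels) -> float:
    """Probability cutoff = case prevalence in the training labels."""
    y = np.asarray(train_labels, dtype=float)
    if y.size == 0:
        raise ValueError("empty training labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain one class")
    return float(y.mean())


def _build_and_score_fold(dm, y, train_idx, test_idx, config, rng_seed, fixed_lambda):
    """Fit a full model on train_idx (nested lambda CV unless fixed) and
    return (held-out AUC, lambda used)."""
    dtrain_raw = dm.subset_rows(train_idx)
    if fixed_lambda is None:
        cv = cv_select_lambda(
            dtrain_raw,
            y[train_idx],
            k=config.inner_folds,
            n_lambda=config.n_lambda,
            seed=rng_seed,
            metric=config.metric,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        lam = cv.chosen_lambda
    else:
        lam = fixed_lambda
    dtrain = standardize(dtrain_raw)
    model = fit_lasso_lr(dtrain, y[train_idx], lam, tol=config.tol,
                         max_iter=config.max_iter)
    cols = [dm.variable_names.index(n) for n in model.variable_names]
    probs = predict_prob(model, dm.X[np.ix_(test_idx, cols)])
    return auc(probs, y[test_idx]), lam


def cross_validated_auc(
    dm: DesignMatrix,
    y,
    k: int = 5,
    seed: int = 0,
    fit_config: FitConfig | None = None,
    fixed_lambda: float | None = None,
) -> CvResult:
    """AUC_CV: mean held-out AUC over k stratified folds with nested rebuilds.

    Every fold's penalty is re-selected inside its own training portion
    unless ``fixed_lambda`` pins it (the fast, approximate protocol).
    Deterministic given ``seed``.
    """
    config = fit_config or FitConfig()
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    folds = stratified_folds(y, k, rng)
    all_idx = np.arange(len(y))
    fold_aucs = np.empty(k)
    lams = np.empty(k)
    for f, test_idx in enumerate(folds):
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError("held-out fold contains one class")
        train_idx = np.setdiff1d(all_idx, test_idx)
        fold_aucs[f], lams[f] = _build_and_score_fold(
            dm, y, train_idx, test_idx, config,
            int(rng.integers(2**31 - 1)), fixed_lambda,
        )
    return CvResult(
        fold_aucs=fold_aucs,
        auc_cv=float(fold_aucs.mean()),
        fold_indices=folds,
        seed=seed,
        chosen_lambdas=lams,
    )


def permutation_model_test(
    dm: DesignMatrix,
    y,
    B: int = 1000,
    k: int = 5,
    seed: int = 0,
    fit_config: FitConfig | None = None,
    refit_lambda: bool = True,
) -> PermutationModelResult:
    """Permutation significance of the cross-validated AUC.

    Default (``refit_lambda=True``): every permutation re-runs the entire
    model-building procedure, nested penalty selection included.  The fast
    mode freezes the penalty at the value cross-validated on the observed
    labels and evaluates both the observed statistic and every permutation
    under that same frozen-penalty protocol; it is approximate because the
    frozen penalty carries information from the observed labels.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = fit_config or FitConfig()
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    fixed = None
    if not refit_lambda:
        fixed = cv_select_lambda(
            dm, y, k=config.inner_folds, n_lambda=config.n_lambda,
            seed=int(rng.integers(2**31 - 1)), metric=config.metric,
            tol=config.tol, max_iter=config.max_iter,
        ).chosen_lambda
    observed = cross_validated_auc(
        dm, y, k=k, seed=int(rng.integers(2**31 - 1)), fit_config=config,
        fixed_lambda=fixed,
    ).auc_cv
    null = np.empty(B)
    for b in range(B):
        y_perm = rng.permutation(y)
        null[b] = cross_validated_auc(
            dm, y_perm, k=k, seed=int(rng.integers(2**31 - 1)),
            fit_config=config, fixed_lambda=fixed,
        ).auc_cv
    p = (1 + int((null >= observed).sum())) / (1 + B)
    return PermutationModelResult(
        observed_auc_cv=observed,
        null_auc_cv=null,
        B=B,
        p_value=p,
        seed=seed,
        refit_lambda=refit_lambda,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def external_validation(
    model: LassoModel, cutoff: float, X_val, y_val
) -> ValidationMetrics:
    """Score a fitted model on the validation split.

    AUC_VS from the predicted probabilities; the confusion table classifies a
    sample as case when its probability is >= ``cutoff`` (ties to case);
    sensitivity/specificity are reported as integer percentages (half-up).
    """
    y_val = np.asarray(y_val, dtype=float)
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation labels contain one class; AUC undefined")
    probs = predict_prob(model, X_val)
    auc_vs = auc(probs, y_val)
    pred_case = probs >= cutoff
    tp = int(np.sum(pred_case & (y_val == 1)))
    fn = int(np.sum(~pred_case & (y_val == 1)))
    fp = int(np.sum(pred_case & (y_val == 0)))
    tn = int(np.sum(~pred_case & (y_val == 0)))
    return ValidationMetrics(
        auc_vs=auc_vs,
        cutoff=cutoff,
        sensitivity_pct=_round_half_up(100 * tp / (tp + fn)),
        specificity_pct=_round_half_up(100 * tn / (tn + fp)),
        confusion=np.array([[tp, fn], [fp, tn]]),
    )
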