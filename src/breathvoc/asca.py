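"""ANOVA-simultaneous component analysis (ASCA) and exploratory PCA.

ASCA partitions a column-centered data matrix into additive effect matrices,
one per categorical design factor (here: season of measurement and residence
zone), plus a residual matrix E.  Each sample's row of a factor's effect
matrix is the per-feature mean of that factor level, so the residual matrix
is the data with the factor-driven variation removed; downstream models are
fit on E.  Effect matrices (and E) are scored by simultaneous component
analysis, an SVD-based PCA of the effect matrix.

The partition is sequential in the declared factor order: each factor's
level means are taken on the running remainder.  With a balanced design this
coincides with the classical orthogonal ANOVA partition (and the sums of
squares are additive); with unbalanced data it keeps the reconstruction
identity ``centered X = sum of effects + E`` exact.

New samples (the validation split) are corrected by subtracting the grand
mean and the stored training level means (:func:`residualize`), so no
validation information enters the decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class AscaDecomposition:
    grand_mean: np.ndarray  # per-feature
    factors: list  # factor names, in partition order
    level_means: dict  # factor -> {level -> per-feature effect vector}
    effect_matrices: dict  # factor -> (samples x features)
    residual_E: np.ndarray
    ssq: dict  # term ("centered", factors..., "residual") -> sum of squares
    factor_labels: dict  # factor -> per-sample levels (training design)


@dataclass
class ScaResult:
    term: str
    scores: np.ndarray  # samples x ncomp
    loadings: np.ndarray  # features x ncomp, orthonormal columns
    explained_variance_fraction: np.ndarray


@dataclass
class FactorPermutationResult:
    term: str
    observed_ssq: float
    null_ssq: np.ndarray
    p_value: float


def center_columns(X):
    """Remove per-column means; returns (centered matrix, grand-mean vector)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d matrix with at least 2 rows")
    grand_mean = X.mean(axis=0)
    return X - grand_mean, grand_mean


def asca_decompose(X, factor_labels: dict, order: list) -> AscaDecomposition:
    """Sequential main-effects ASCA partition of ``X``.

    ``factor_labels`` maps each factor name to its per-sample level labels;
    ``order`` lists the factors in partition order.  Factors constant across
    all samples contribute a zero effect matrix (with a warning).
    """
    X = np.asarray(X, dtype=float)
    centered, grand_mean = center_columns(X)
    n = X.shape[0]
    for name in order:
        if name not in factor_labels:
            raise ValueError(f"no labels for factor {name!r}")
        if len(factor_labels[name]) != n:
            raise ValueError(f"factor {name!r}: labels do not cover every row")
    remainder = centered.copy()
    effects = {}
    level_means = {}
    labels_used = {}
    for name in order:
        labels = np.asarray(factor_labels[name])
        labels_used[name] = labels
        levels = np.unique(labels)
        if levels.size == 1:
            logger.warning("factor %r is constant; zero effect matrix", name)
        effect = np.zeros_like(remainder)
        means = {}
        for lev in levels:
            mask = labels == lev
            mu = remainder[mask].mean(axis=0)
            effect[mask] = mu
            means[lev] = mu
        if levels.size == 1:
            # a single level is indistinguishable from the grand mean
            effect[:] = 0.0
            means = {levels[0]: np.zeros(X.shape[1])}
        effects[name] = effect
        level_means[name] = means
        remainder = remainder - effect
    ssq = {"centered": float((centered**2).sum())}
    for name in order:
        ssq[name] = float((effects[name] ** 2).sum())
    ssq["residual"] = float((remainder**2).sum())
    return AscaDecomposition(
        grand_mean=grand_mean,
        factors=list(order),
        level_means=level_means,
        effect_matrices=effects,
        residual_E=remainder,
        ssq=ssq,
        factor_labels=labels_used,
    )


def sca_effect(matrix, ncomp: int, term: str = "") -> ScaResult:
    """Rank-``ncomp`` simultaneous-component (SVD) scores of an effect matrix.

    Scores are the left singular vectors scaled by the singular values;
    loadings are the orthonormal right singular vectors.  A zero matrix
    yields all-zero scores and zero explained fractions.
    """
    M = np.asarray(matrix, dtype=float)
    if ncomp <= 0:
        raise ValueError("ncomp must be positive")
    if ncomp > min(M.shape):
        raise ValueError(f"ncomp {ncomp} exceeds min(shape) {min(M.shape)}")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float((s**2).sum())
    if total == 0.0:
        logger.warning("zero matrix passed to sca_effect; explained fractions set to 0")
        frac = np.zeros(ncomp)
    else:
        frac = (s[:ncomp] ** 2) / total
    return ScaResult(
        term=term,
        scores=U[:, :ncomp] * s[:ncomp],
        loadings=Vt[:ncomp].T,
        explained_variance_fraction=frac,
    )


def asca_permutation_factor_test(
    X, factor_labels: dict, order: list, term: str, B: int = 199, seed: int = 0
) -> FactorPermutationResult:
    """Permutation test of one factor's effect sum of squares.

    Only the labels of ``term`` are permuted; the other factors keep their
    observed labels.  p follows the add-one rule (1 + #{null >= obs})/(1 + B).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    observed = asca_decompose(X, factor_labels, order).ssq[term]
    labels = np.asarray(factor_labels[term])
    null = np.empty(B)
    for b in range(B):
        perm_labels = dict(factor_labels)
        perm_labels[term] = rng.permutation(labels)
        null[b] = asca_decompose(X, perm_labels, order).ssq[term]
    p = (1 + int((null >= observed).sum())) / (1 + B)
    return FactorPermutationResult(term, observed, null, p)


def residualize(decomp: AscaDecomposition, X_new, labels_new: dict) -> np.ndarray:
    """Correct new samples with the fitted grand mean and level means.

    For each factor, the stored training level mean of the sample's level is
    subtracted; a level unseen at fit time contributes nothing beyond the
    grand mean (logged).  Applying this to the training data with the
    training labels returns ``residual_E`` exactly.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != decomp.grand_mean.size:
        raise ValueError(
            f"column mismatch: {X_new.shape[1]} vs fitted {decomp.grand_mean.size}"
        )
    out = X_new - decomp.grand_mean
    for name in decomp.factors:
        labels = np.asarray(labels_new[name])
        if labels.size != X_new.shape[0]:
            raise ValueError(f"factor {name!r}: labels do not cover every new row")
        means = decomp.level_means[name]
        unseen = sorted({str(l) for l in labels if l not in means})
        if unseen:
            logger.warning(
                "factor %r: unseen level(s) %s corrected by grand mean only",
                name,
                unseen,
            )
        for lev, mu in means.items():
            mask = labels == lev
            if mask.any():
                out[mask] -= mu
    return out


def pca_explore(X, ncomp: int) -> ScaResult:
    """Exploratory PCA: SCA of the column-centered data matrix."""
    centered, _ = center_columns(X)
    return sca_effect(centered, ncomp, term="pca")
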