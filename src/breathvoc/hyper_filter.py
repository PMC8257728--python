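"""Hyper-filtering of breath features against named contaminants and room air.

Two screens, applied in order, produce the "hyper-filtered" feature set:

1. features annotated as gas-bag artifacts (N,N-dimethylacetamide, phenol),
   pump oils or column siloxanes are dropped by their contaminant class;
2. for every remaining feature, the non-normalized intensities of each breath
   sample and its paired room-air sample are compared with a one-sided
   Wilcoxon signed-rank test; features significantly *higher* in ambient air
   are dropped — they are dominated by the sampling environment rather than
   by the subject.

The signed-rank p-value is exact (full enumeration of the 2^n sign
assignments, computed by dynamic programming over the integerized mid-ranks)
whenever the number of non-zero differences is at most ``EXACT_THRESHOLD``,
and a normal approximation with continuity and tie corrections otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import FeatureMeta, FeatureTable, SampleMeta

logger = logging.getLogger(__name__)

#: maximum number of non-zero differences for which the exact null
#: distribution of W is enumerated
EXACT_THRESHOLD = 25

ALTERNATIVES = ("greater", "less", "two_sided")


@dataclass
class WilcoxonResult:
    statistic_W: float  # sum of ranks of positive differences
    n_effective: int  # non-zero differences entering the test
    p_value: float
    alternative: str
    method: str  # "exact" or "normal_approx"


@dataclass
class FilterReport:
    removed_contaminants: list
    removed_ambient_dominant: list  # (feature_id, p_value) pairs
    retained: list
    alpha: float
    correction: str


def _exact_sf_signed_rank(ranks: np.ndarray, w: float):
    """P(W >= w) and P(W <= w) under the signed-rank null, by enumeration.

    The null assigns each |difference| a positive sign independently with
    probability 1/2; W is the sum of the (mid-)ranks with positive sign.
    Mid-ranks are multiples of 1/2, so doubling them gives integers and the
    distribution of 2W is a polynomial convolution — equivalent to full
    enumeration of the 2^n sign assignments at O(n^3) cost.
    """
    d = np.rint(2 * ranks).astype(np.int64)  # integerized ranks
    total = int(d.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for di in d:
        counts[di : top + di + 1] += counts[0 : top + 1]
        top += di
    counts /= counts.sum()
    w2 = 2 * w
    # >= / <= with a small guard against float fuzz in w2
    ge = counts[int(np.ceil(w2 - 1e-9)) :].sum()
    le = counts[: int(np.floor(w2 + 1e-9)) + 1].sum()
    return float(ge), float(le)


def paired_wilcoxon(breath, ambient, alternative: str = "greater") -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired intensity vectors.

    ``alternative="greater"`` tests whether the first vector (``breath``)
    tends to exceed the second; the ambient screen therefore calls this with
    ambient first.  Zero differences are dropped; ties among the absolute
    differences receive mid-ranks.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(breath, dtype=float)
    y = np.asarray(ambient, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("paired vectors must be equal-length 1-d with n >= 1")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; returning p = 1")
        return WilcoxonResult(0.0, 0, 1.0, alternative, "exact")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_THRESHOLD:
        ge, le = _exact_sf_signed_rank(ranks, w_pos)
        method = "exact"
    else:
        mean = n * (n + 1) / 4
        var = n * (n + 1) * (2 * n + 1) / 24
        # mid-rank tie correction
        _, t = np.unique(ranks, return_counts=True)
        var -= (t**3 - t).sum() / 48
        sd = np.sqrt(var)
        ge = stats.norm.sf((w_pos - 0.5 - mean) / sd)
        le = stats.norm.cdf((w_pos + 0.5 - mean) / sd)
        method = "normal_approx"
    if alternative == "greater":
        p = ge
    elif alternative == "less":
        p = le
    else:
        p = min(1.0, 2 * min(ge, le))
    return WilcoxonResult(w_pos, n, float(min(p, 1.0)), alternative, method)


def remove_named_contaminants(
    table: FeatureTable, feature_meta: list[FeatureMeta]
):
    """Drop features whose contaminant class is not ``none``.

    Returns the filtered table and the removed feature ids, preserving the
    column order of survivors.
    """
    by_id = {m.feature_id: m for m in feature_meta}
    missing = [f for f in table.feature_ids if f not in by_id]
    if missing:
        raise ValueError(f"features without metadata: {missing}")
    removed = [
        f for f in table.feature_ids if by_id[f].contaminant_class != "none"
    ]
    kept = [f for f in table.feature_ids if by_id[f].contaminant_class == "none"]
    if not kept:
        logger.warning("all features are annotated contaminants; empty feature set")
    return table.subset_features(kept), removed


def _aligned_pairs(table: FeatureTable, sample_meta: list[SampleMeta]):
    """Row indices of (breath, ambient) pairs aligned by pair_key."""
    by_id = {m.sample_id: m for m in sample_meta}
    row = {s: i for i, s in enumerate(table.sample_ids)}
    ambient_rows = {}
    for s in table.sample_ids:
        m = by_id[s]
        if m.sample_type == "ambient":
            ambient_rows[m.pair_key] = row[s]
    breath_idx, ambient_idx = [], []
    for s in table.sample_ids:
        m = by_id[s]
        if m.sample_type == "breath" and m.pair_key in ambient_rows:
            breath_idx.append(row[s])
            ambient_idx.append(ambient_rows[m.pair_key])
    return np.array(breath_idx, dtype=int), np.array(ambient_idx, dtype=int)


def hyper_filter(
    table: FeatureTable,
    feature_meta: list[FeatureMeta],
    sample_meta: list[SampleMeta],
    alpha: float = 0.05,
    correction: str = "none",
):
    """Produce the hyper-filtered feature table.

    Contaminant-annotated features are removed first; then each surviving
    feature is tested one-sided for *higher* intensity in the paired ambient
    samples and removed when its (optionally BH-adjusted) p-value falls below
    ``alpha``.  Returns the filtered table (breath and ambient rows retained,
    columns reduced) and a :class:`FilterReport` partitioning the input
    feature set.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")
    decontaminated, removed_contaminants = remove_named_contaminants(
        table, feature_meta
    )
    breath_idx, ambient_idx = _aligned_pairs(decontaminated, sample_meta)
    if breath_idx.size == 0:
        raise ValueError("no breath/ambient pairs available for the ambient screen")
    pvals = np.empty(len(decontaminated.feature_ids))
    for j, _ in enumerate(decontaminated.feature_ids):
        res = paired_wilcoxon(
            decontaminated.intensities[ambient_idx, j],
            decontaminated.intensities[breath_idx, j],
            alternative="greater",
        )
        pvals[j] = res.p_value
    adjusted = _bh_adjust(pvals) if correction == "BH" else pvals
    removed_ambient = [
        (f, float(adjusted[j]))
        for j, f in enumerate(decontaminated.feature_ids)
        if adjusted[j] < alpha
    ]
    removed_set = {f for f, _ in removed_ambient}
    retained = [f for f in decontaminated.feature_ids if f not in removed_set]
    report = FilterReport(
        removed_contaminants=removed_contaminants,
        removed_ambient_dominant=removed_ambient,
        retained=retained,
        alpha=alpha,
        correction=correction,
    )
    return decontaminated.subset_features(retained), report


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
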