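"""End-to-end orchestration of the discrimination workflow and model catalog.

One comparison (:func:`run_comparison`) executes, in order: ambient-aware
hyper-filtering (feature set determined on the training split by default),
ASCA correction for season and residence zone (fitted on training samples,
applied to validation samples), design-matrix assembly from the requested
variable blocks (residualized VOC features plus clinical covariates),
cross-validated AUC with nested penalty selection, a label-permutation
significance test, and external validation of the final model on the
held-out split at a prevalence-based probability cutoff.

:func:`default_catalog` enumerates the study's sixteen comparisons: seven
for cases versus all non-asthmatics (I), four versus non-atopic controls
(II), four versus atopic controls (III), and one contrast among the controls
(IV), with variable blocks (VOC / parental history / white-blood-cell counts
/ atopic-disorder flags) added block-wise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .asca import asca_decompose, residualize
from .core_data import FeatureMeta, FeatureTable, SampleMeta, WBC_COVARIATES
from .evaluation import (
    FitConfig,
    cross_validated_auc,
    external_validation,
    permutation_model_test,
    prevalence_cutoff,
)
from .hyper_filter import hyper_filter
from .lasso_lr import DesignMatrix, cv_select_lambda, fit_lasso_lr, standardize

logger = logging.getLogger(__name__)

ASCA_FACTOR_ORDER = ["season", "zone"]

BLOCK_VARIABLES = {
    "parental_history": ("parental_asthma", "parental_rhinitis", "parental_dermatitis"),
    "wbc": tuple(WBC_COVARIATES),
    "atopic_flag": (
        "allergic_rhinitis",
        "atopic_dermatitis",
        "allergic_conjunctivitis",
        "food_allergy",
        "drug_allergy",
    ),
}


@dataclass
class ComparisonSpec:
    model_id: str
    case_category: str
    control_categories: tuple
    variable_blocks: tuple = ("voc",)
    folds: int = 5
    permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.case_category in self.control_categories:
            raise ValueError("case and control categories must be disjoint")
        for b in self.variable_blocks:
            if b != "voc" and b not in BLOCK_VARIABLES:
                raise ValueError(f"unknown variable block {b!r}")


@dataclass
class ModelReport:
    model_id: str
    n_train: int
    n_validation: int
    selected_variables: list  # (name, block) pairs
    auc_cv: float
    p_value: float
    auc_vs: float
    sensitivity_pct: float
    specificity_pct: float
    cutoff: float
    chosen_lambda: float
    n_features_hyperfiltered: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "n_train": self.n_train,
            "n_validation": self.n_validation,
            "selected_variables": [list(v) for v in self.selected_variables],
            "auc_cv": self.auc_cv,
            "p_value": self.p_value,
            "auc_vs": self.auc_vs,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "cutoff": self.cutoff,
            "chosen_lambda": self.chosen_lambda,
            "n_features_hyperfiltered": self.n_features_hyperfiltered,
            "provenance": self.provenance,
        }


def default_catalog(folds: int = 5, permutations: int = 1000, seed: int = 0) -> list:
    """The sixteen-comparison model catalog.

    Blocks per model mirror the study's groupings: VOC only; +parental
    history; +WBC counts; +parental history and WBC; and, for comparisons
    against controls that can carry atopic disorders, +atopic-disorder flags.
    """
    NA = ("NA-AD", "NA-NAD")
    rows = [
        ("I.A", "A-AD", NA, ("voc",)),
        ("I.B", "A-AD", NA, ("voc", "parental_history")),
        ("I.C", "A-AD", NA, ("voc", "wbc")),
        ("I.D", "A-AD", NA, ("voc", "parental_history", "wbc")),
        ("I.E", "A-AD", NA, ("voc", "atopic_flag")),
        ("I.F", "A-AD", NA, ("voc", "parental_history", "atopic_flag")),
        ("I.G", "A-AD", NA, ("voc", "parental_history", "wbc", "atopic_flag")),
        ("II.A", "A-AD", ("NA-NAD",), ("voc",)),
        ("II.B", "A-AD", ("NA-NAD",), ("voc", "parental_history")),
        ("II.C", "A-AD", ("NA-NAD",), ("voc", "wbc")),
        ("II.D", "A-AD", ("NA-NAD",), ("voc", "parental_history", "wbc")),
        ("III.A", "A-AD", ("NA-AD",), ("voc",)),
        ("III.B", "A-AD", ("NA-AD",), ("voc", "parental_history")),
        ("III.C", "A-AD", ("NA-AD",), ("voc", "wbc")),
        ("III.D", "A-AD", ("NA-AD",), ("voc", "parental_history", "wbc")),
        ("IV.A", "NA-AD", ("NA-NAD",), ("voc",)),
    ]
    return [
        ComparisonSpec(
            model_id=mid,
            case_category=case,
            control_categories=ctrl,
            variable_blocks=blocks,
            folds=folds,
            permutations=permutations,
            seed=seed + i,
        )
        for i, (mid, case, ctrl, blocks) in enumerate(rows)
    ]


def _design_for_split(E, feature_ids, metas, blocks):
    """Assemble the design matrix: residualized VOC features + covariates."""
    names = []
    cols = []
    block_of = {}
    if "voc" in blocks:
        names.extend(feature_ids)
        cols.append(np.asarray(E))
        block_of.update({f: "voc" for f in feature_ids})
    for block in ("parental_history", "wbc", "atopic_flag"):
        if block not in blocks:
            continue
        for var in BLOCK_VARIABLES[block]:
            col = np.array([float(m.covariates.get(var, 0.0)) for m in metas])
            names.append(var)
            cols.append(col[:, None])
            block_of[var] = block
    X = np.hstack(cols)
    return DesignMatrix(X, names, block_of)


def run_comparison(
    spec: ComparisonSpec,
    table: FeatureTable,
    sample_meta: list[SampleMeta],
    feature_meta: list[FeatureMeta],
    alpha: float = 0.05,
    p_adjust: str = "none",
    filter_scope: str = "train",
    log_transform: bool = True,
    fit_config: FitConfig | None = None,
    refit_lambda: bool = True,
) -> ModelReport:
    """Run the full workflow for one comparison and emit a ModelReport.

    ``filter_scope`` chooses whether the ambient screen sees only training
    pairs (default, leak-free) or all pairs; ``log_transform`` applies a
    log10 transform to the intensities before ASCA (the intensity model is
    multiplicative).  ``refit_lambda=False`` switches the permutation test to
    its fast frozen-penalty mode.
    """
    config = fit_config or FitConfig()
    by_id = {m.sample_id: m for m in sample_meta}
    wanted = set((spec.case_category,) + tuple(spec.control_categories))
    breath = [
        by_id[s]
        for s in table.sample_ids
        if by_id[s].sample_type == "breath"
        and by_id[s].category in wanted
        and by_id[s].split is not None
    ]
    train_meta = [m for m in breath if m.split == "train"]
    val_meta = [m for m in breath if m.split == "validation"]
    if len([m for m in train_meta if m.category == spec.case_category]) < 10:
        logger.warning("%s: fewer than 10 training case samples", spec.model_id)

    # 1. hyper-filter: feature set determined on filter-scope pairs
    scope_breath = train_meta if filter_scope == "train" else breath
    ambient_by_key = {
        m.pair_key: m.sample_id
        for m in sample_meta
        if m.sample_type == "ambient" and m.sample_id in set(table.sample_ids)
    }
    scope_ids = [m.sample_id for m in scope_breath] + [
        ambient_by_key[m.pair_key] for m in scope_breath
        if m.pair_key in ambient_by_key
    ]
    filtered, filter_report = hyper_filter(
        table.subset_samples(scope_ids), feature_meta, sample_meta,
        alpha=alpha, correction=p_adjust,
    )
    feature_ids = filtered.feature_ids

    # 2. ASCA on the training breath samples; validation residualized
    sub = table.subset_features(feature_ids)
    X_train = sub.subset_samples([m.sample_id for m in train_meta]).intensities
    X_val = sub.subset_samples([m.sample_id for m in val_meta]).intensities
    if log_transform:
        X_train = np.log10(np.maximum(X_train, 1e-12))
        X_val = np.log10(np.maximum(X_val, 1e-12))
    labels_train = {
        "season": [m.season for m in train_meta],
        "zone": [m.zone for m in train_meta],
    }
    labels_val = {
        "season": [m.season for m in val_meta],
        "zone": [m.zone for m in val_meta],
    }
    decomp = asca_decompose(X_train, labels_train, ASCA_FACTOR_ORDER)
    E_train = decomp.residual_E
    E_val = residualize(decomp, X_val, labels_val)

    # 3. design matrices and labels
    dm_train = _design_for_split(E_train, feature_ids, train_meta, spec.variable_blocks)
    dm_val = _design_for_split(E_val, feature_ids, val_meta, spec.variable_blocks)
    y_train = np.array(
        [1.0 if m.category == spec.case_category else 0.0 for m in train_meta]
    )
    y_val = np.array(
        [1.0 if m.category == spec.case_category else 0.0 for m in val_meta]
    )

    # 4. cross-validated AUC (nested rebuild) and permutation significance
    cv = cross_validated_auc(
        dm_train, y_train, k=spec.folds, seed=spec.seed, fit_config=config
    )
    perm = permutation_model_test(
        dm_train, y_train, B=spec.permutations, k=spec.folds,
        seed=spec.seed, fit_config=config, refit_lambda=refit_lambda,
    )

    # 5. final model on all training samples, validated externally
    lam = cv_select_lambda(
        dm_train, y_train, k=spec.folds, n_lambda=config.n_lambda,
        seed=spec.seed, metric=config.metric, tol=config.tol,
        max_iter=config.max_iter,
    ).chosen_lambda
    model = fit_lasso_lr(
        standardize(dm_train), y_train, lam, tol=config.tol,
        max_iter=config.max_iter,
        class_labels=(spec.case_category, "+".join(spec.control_categories)),
    )
    cutoff = prevalence_cutoff(y_train)
    cols = [dm_val.variable_names.index(n) for n in model.variable_names]
    metrics = external_validation(model, cutoff, dm_val.X[:, cols], y_val)

    selected = [(n, dm_train.variable_block.get(n, "voc")) for n in model.selected]
    return ModelReport(
        model_id=spec.model_id,
        n_train=len(train_meta),
        n_validation=len(val_meta),
        selected_variables=selected,
        auc_cv=cv.auc_cv,
        p_value=perm.p_value,
        auc_vs=metrics.auc_vs,
        sensitivity_pct=metrics.sensitivity_pct,
        specificity_pct=metrics.specificity_pct,
        cutoff=cutoff,
        chosen_lambda=lam,
        n_features_hyperfiltered=len(feature_ids),
        provenance={
            "seed": spec.seed,
            "folds": spec.folds,
            "permutations": spec.permutations,
            "refit_lambda": refit_lambda,
            "filter_scope": filter_scope,
            "log_transform": log_transform,
            "alpha": alpha,
            "p_adjust": p_adjust,
            "removed_contaminants": len(filter_report.removed_contaminants),
            "removed_ambient_dominant": len(filter_report.removed_ambient_dominant),
        },
    )


SUMMARY_COLUMNS = [
    "model_id", "AUC_CV", "p-value", "AUC_VS", "sensitivity", "specificity",
    "variables",
]


def run_all(
    catalog: list,
    table: FeatureTable,
    sample_meta: list[SampleMeta],
    feature_meta: list[FeatureMeta],
    out_dir=None,
    **kwargs,
):
    """Run every catalog comparison; failures are recorded, the run continues.

    Returns ``(reports, summary)`` where ``summary`` is a DataFrame with one
    row per successful model; with ``out_dir`` set, per-model JSON reports
    and a summary CSV are written there.
    """
    reports, rows, failures = [], [], []
    for spec in catalog:
        try:
            report = run_comparison(spec, table, sample_meta, feature_meta, **kwargs)
        except Exception as exc:  # keep going; record the failure
            logger.error("model %s failed: %s", spec.model_id, exc)
            failures.append((spec.model_id, str(exc)))
            continue
        reports.append(report)
        rows.append(
            {
                "model_id": report.model_id,
                "AUC_CV": report.auc_cv,
                "p-value": report.p_value,
                "AUC_VS": report.auc_vs,
                "sensitivity": report.sensitivity_pct,
                "specificity": report.specificity_pct,
                "variables": ";".join(n for n, _ in report.selected_variables),
            }
        )
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for report in reports:
            with open(out / f"model_{report.model_id}.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
        summary.to_csv(out / "model_summary.csv", index=False)
        if failures:
            with open(out / "failures.json", "w") as fh:
                json.dump(dict(failures), fh, indent=2)
    return reports, summary
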