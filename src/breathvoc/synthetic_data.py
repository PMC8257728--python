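"""Synthetic breath-cohort generator and in-study fixtures.

The generator emulates the statistical structure the analysis assumes, so
every other module is testable without the (non-public) cohort measurements:

* log10 feature intensities: per-feature baseline + a class effect on a small
  set of discriminant features (cases only) + additive season and residence-
  zone batch effects + Gaussian noise; intensities are 10**log10, hence
  lognormal and non-negative (GC/MS relative intensities are multiplicative);
* one ambient (room-air) sample per breath sample, sharing the visit's
  season/zone effects, carrying ``ambient_fraction`` of the breath baseline
  and no class effect; a few planted ambient-dominant features are 10x that
  (these are what the ambient screen must remove), and named gas-bag /
  pump-oil / siloxane contaminant features are flagged in the feature
  metadata;
* clinical covariates drawn class-conditionally: binary atopy/parental-
  history flags with per-category rates patterned on the cohort tables, and
  white-blood-cell counts (per microlitre) with an elevated eosinophil mean
  in cases;
* a stratified train/validation split with sampling dates consistent with a
  date cutoff (training dates precede it) and seasons derived from the dates.

Everything is deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .cohort_stats import SubgroupTable
from .core_data import (
    BINARY_COVARIATES,
    FeatureMeta,
    FeatureTable,
    SampleMeta,
    WBC_COVARIATES,
)

LOG10_2 = float(np.log10(2.0))

#: date ranges for the two splits; the cutoff between them mirrors the
#: study's date-based division of the cohort
TRAIN_DATE_RANGE = (date(2017, 5, 1), date(2018, 2, 28))
VALIDATION_DATE_RANGE = (date(2018, 3, 1), date(2018, 10, 31))
SPLIT_CUTOFF = date(2018, 3, 1)

_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

#: per-category Bernoulli rates of the binary covariates, patterned on the
#: training-set cohort table (config, not hard-coded truth: override via
#: GeneratorConfig.category_rates)
DEFAULT_CATEGORY_RATES = {
    "parental_asthma": {"A-AD": 0.24, "NA-AD": 0.08, "NA-NAD": 0.04},
    "parental_rhinitis": {"A-AD": 0.40, "NA-AD": 0.29, "NA-NAD": 0.13},
    "parental_dermatitis": {"A-AD": 0.12, "NA-AD": 0.03, "NA-NAD": 0.05},
    "allergic_rhinitis": {"A-AD": 0.92, "NA-AD": 0.65, "NA-NAD": 0.0},
    "atopic_dermatitis": {"A-AD": 0.32, "NA-AD": 0.17, "NA-NAD": 0.0},
    "allergic_conjunctivitis": {"A-AD": 0.68, "NA-AD": 0.36, "NA-NAD": 0.0},
    "food_allergy": {"A-AD": 0.20, "NA-AD": 0.14, "NA-NAD": 0.0},
    "drug_allergy": {"A-AD": 0.20, "NA-AD": 0.19, "NA-NAD": 0.0},
}

#: per-category (mean, sd) of the white-blood-cell counts, cells/ul
DEFAULT_WBC_PARAMS = {
    "eosinophils": {"A-AD": (213, 70), "NA-AD": (131, 80), "NA-NAD": (143, 90)},
    "lymphocytes": {"A-AD": (1850, 450), "NA-AD": (2020, 500), "NA-NAD": (2015, 500)},
    "leucocytes": {"A-AD": (9550, 2000), "NA-AD": (9050, 2000), "NA-NAD": (9370, 2000)},
    "monocytes": {"A-AD": (590, 170), "NA-AD": (618, 180), "NA-NAD": (611, 180)},
    "basophils": {"A-AD": (32, 13), "NA-AD": (28, 13), "NA-NAD": (32, 14)},
    "neutrophils": {"A-AD": (6870, 1700), "NA-AD": (6255, 1600), "NA-NAD": (6570, 1600)},
}

#: named gas-bag artifact compounds
BAG_ARTIFACTS = (("N,N-dimethylacetamide", "127-19-5"), ("phenol", "108-95-2"))


@dataclass
class GeneratorConfig:
    n_case: int = 25
    n_control: int = 186
    n_features: int = 200
    n_discriminant: int = 3
    effect_log2: float = 1.0  # log2 mean shift of discriminant features in cases
    season_effect_sd: float = 0.2  # log10 units
    zone_effect_sd: float = 0.1  # log10 units
    n_zones: int = 3
    noise_sd_log: float = 0.3  # log10 units
    baseline_mean_log: float = 4.0
    baseline_sd_log: float = 0.8
    ambient_fraction: float = 0.3  # fraction of breath baseline seen in room air
    n_contaminants: int = 4
    n_ambient_dominant: int = 5
    na_ad_fraction: float = 72 / 186  # NA-AD share of the controls
    category_rates: dict = field(default_factory=lambda: DEFAULT_CATEGORY_RATES)
    wbc_params: dict = field(default_factory=lambda: DEFAULT_WBC_PARAMS)
    covariate_effects: dict = field(default_factory=dict)  # extra case log-odds
    validation_fraction: float = 125 / 336
    seed: int = 0

    def __post_init__(self):
        reserved = self.n_discriminant + self.n_contaminants + self.n_ambient_dominant
        if reserved > self.n_features:
            raise ValueError(
                "n_discriminant + n_contaminants + n_ambient_dominant exceeds "
                "n_features"
            )
        for sd in (self.season_effect_sd, self.zone_effect_sd, self.noise_sd_log):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.ambient_fraction <= 1:
            raise ValueError("ambient_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    discriminant_ids: list
    contaminant_ids: list
    ambient_dominant_ids: list
    true_betas: dict  # variable -> planted effect (log10 shift / log-odds)
    sample_assignments: dict  # sample_id -> {category, season, zone, split}


def _random_date(rng, lo: date, hi: date) -> date:
    return lo + timedelta(days=int(rng.integers((hi - lo).days + 1)))


def generate_cohort(config: GeneratorConfig):
    """Generate (FeatureTable, sample metadata, feature metadata, GroundTruth).

    The table holds breath rows first, then the paired ambient rows; both
    splits are present, stratified by diagnostic category.
    """
    rng = np.random.default_rng(config.seed)
    n_breath = config.n_case + config.n_control
    p = config.n_features

    # --- feature roles -------------------------------------------------
    feature_ids = [f"F{j + 1:04d}" for j in range(p)]
    special = rng.choice(
        p,
        size=config.n_discriminant + config.n_contaminants
        + config.n_ambient_dominant,
        replace=False,
    )
    disc_idx = special[: config.n_discriminant]
    contam_idx = special[
        config.n_discriminant : config.n_discriminant + config.n_contaminants
    ]
    dom_idx = special[config.n_discriminant + config.n_contaminants :]

    feature_meta = []
    rts = np.sort(rng.uniform(60, 1800, size=p))
    mzs = rng.uniform(35, 250, size=p)
    contam_classes = ["pump_oil", "siloxane"]
    for j in range(p):
        name, cas, cls = None, None, "none"
        if j in contam_idx:
            k = int(np.flatnonzero(contam_idx == j)[0])
            if k < len(BAG_ARTIFACTS):
                name, cas = BAG_ARTIFACTS[k]
                cls = "bag_artifact"
            else:
                cls = contam_classes[(k - len(BAG_ARTIFACTS)) % 2]
        feature_meta.append(
            FeatureMeta(
                feature_id=feature_ids[j],
                retention_time=float(rts[j]),
                quant_mz=float(mzs[j]),
                compound_name=name,
                cas_number=cas,
                contaminant_class=cls,
            )
        )

    # --- sample design -------------------------------------------------
    categories = ["A-AD"] * config.n_case
    n_na_ad = int(round(config.n_control * config.na_ad_fraction))
    categories += ["NA-AD"] * n_na_ad + ["NA-NAD"] * (config.n_control - n_na_ad)
    categories = list(rng.permutation(categories))

    split = np.empty(n_breath, dtype=object)
    for cat in sorted(set(categories)):  # fixed order: split must not depend
        # on the process hash seed
        idx = np.flatnonzero(np.array(categories) == cat)
        idx = idx[rng.permutation(idx.size)]
        n_val = int(round(idx.size * config.validation_fraction))
        split[idx[:n_val]] = "validation"
        split[idx[n_val:]] = "train"

    dates, seasons = [], []
    for i in range(n_breath):
        lo, hi = TRAIN_DATE_RANGE if split[i] == "train" else VALIDATION_DATE_RANGE
        d = _random_date(rng, lo, hi)
        dates.append(d)
        seasons.append(_SEASON_BY_MONTH[d.month])
    zones = [f"zone{int(z) + 1}" for z in rng.integers(config.n_zones, size=n_breath)]

    # --- intensities ---------------------------------------------------
    baseline = rng.normal(config.baseline_mean_log, config.baseline_sd_log, size=p)
    season_eff = {
        s: rng.normal(0.0, config.season_effect_sd, size=p)
        for s in ("winter", "spring", "summer", "autumn")
    }
    zone_eff = {
        f"zone{k + 1}": rng.normal(0.0, config.zone_effect_sd, size=p)
        for k in range(config.n_zones)
    }
    effect_log10 = config.effect_log2 * LOG10_2

    log_breath = np.tile(baseline, (n_breath, 1))
    log_ambient = np.tile(baseline, (n_breath, 1))
    log_ambient += np.log10(max(config.ambient_fraction, 1e-12))
    log_ambient[:, dom_idx] += 1.0  # ambient-dominant: 10x
    for i in range(n_breath):
        drift = season_eff[seasons[i]] + zone_eff[zones[i]]
        log_breath[i] += drift
        log_ambient[i] += drift  # room air collected at the same visit
        if categories[i] == "A-AD":
            log_breath[i, disc_idx] += effect_log10
    log_breath += rng.normal(0.0, config.noise_sd_log, size=(n_breath, p))
    log_ambient += rng.normal(0.0, config.noise_sd_log, size=(n_breath, p))

    # --- assemble ------------------------------------------------------
    breath_ids = [f"B{i + 1:04d}" for i in range(n_breath)]
    ambient_ids = [f"A{i + 1:04d}" for i in range(n_breath)]
    pair_keys = [f"P{i + 1:04d}" for i in range(n_breath)]
    table = FeatureTable(
        breath_ids + ambient_ids,
        feature_ids,
        np.vstack([10.0**log_breath, 10.0**log_ambient]),
    )

    sample_meta = []
    assignments = {}
    for i in range(n_breath):
        cov = _draw_covariates(rng, categories[i], config)
        sample_meta.append(
            SampleMeta(
                sample_id=breath_ids[i],
                subject_id=f"S{i + 1:04d}",
                sample_type="breath",
                pair_key=pair_keys[i],
                category=categories[i],
                season=seasons[i],
                zone=zones[i],
                split=str(split[i]),
                sampling_date=dates[i],
                covariates=cov,
            )
        )
        assignments[breath_ids[i]] = {
            "category": categories[i],
            "season": seasons[i],
            "zone": zones[i],
            "split": str(split[i]),
        }
    for i in range(n_breath):
        sample_meta.append(
            SampleMeta(
                sample_id=ambient_ids[i],
                subject_id=f"S{i + 1:04d}",
                sample_type="ambient",
                pair_key=pair_keys[i],
                season=seasons[i],
                zone=zones[i],
                split=str(split[i]),
                sampling_date=dates[i],
            )
        )

    true_betas = {feature_ids[j]: effect_log10 for j in disc_idx}
    true_betas.update(config.covariate_effects)
    truth = GroundTruth(
        discriminant_ids=[feature_ids[j] for j in disc_idx],
        contaminant_ids=[feature_ids[j] for j in contam_idx],
        ambient_dominant_ids=[feature_ids[j] for j in dom_idx],
        true_betas=true_betas,
        sample_assignments=assignments,
    )
    return table, sample_meta, feature_meta, truth


def _draw_covariates(rng, category: str, config: GeneratorConfig) -> dict:
    cov = {}
    for name in BINARY_COVARIATES:
        rate = config.category_rates.get(name, {}).get(category, 0.0)
        if category == "A-AD" and name in config.covariate_effects:
            logit = np.log(max(rate, 1e-9) / max(1 - rate, 1e-9))
            rate = 1.0 / (1.0 + np.exp(-(logit + config.covariate_effects[name])))
        cov[name] = float(rng.random() < rate)
    for name in WBC_COVARIATES:
        mean, sd = config.wbc_params[name][category]
        cov[name] = float(max(rng.normal(mean, sd), 0.0))
    return cov


def paper_fixtures():
    """In-study fixtures: subgroup tables for both cohort groups + flow counts.

    Returns ``(group1, group2, flow)`` where the groups are
    :class:`~breathvoc.cohort_stats.SubgroupTable` objects built from the
    printed per-category counts of the two cohort characteristics tables and
    ``flow`` holds the study-flow counts (337 sampled, 1 excluded for being
    asthmatic without other atopic diseases, 336 analyzed: 211 training /
    125 validation).
    """
    path = importlib.resources.files("breathvoc").joinpath(
        "fixtures/cohort_tables.csv"
    )
    with importlib.resources.as_file(path) as f:
        df = pd.read_csv(f, keep_default_na=False)
    sizes = {
        "group1": {"A-AD": 25, "NA": 186, "NA-AD": 72, "NA-NAD": 114},
        "group2": {"A-AD": 14, "NA": 111, "NA-AD": 47, "NA-NAD": 64},
    }
    tables = {}
    for group, n in sizes.items():
        sub = df[df["group"] == group]
        counts = {
            (r.variable, r.category): int(r.count_)
            for r in sub.rename(columns={"count": "count_"}).itertuples()
        }
        tables[group] = SubgroupTable(
            group_label=group,
            categories=["A-AD", "NA", "NA-AD", "NA-NAD"],
            n=n,
            counts=counts,
        )
    flow = {
        "sampled": 337,
        "excluded": 1,
        "analyzed": 336,
        "train": 211,
        "validation": 125,
    }
    return tables["group1"], tables["group2"], flow


def printed_table_rows() -> pd.DataFrame:
    """The raw fixture rows (count, subgroup size, printed percentage)."""
    path = importlib.resources.files("breathvoc").joinpath(
        "fixtures/cohort_tables.csv"
    )
    with importlib.resources.as_file(path) as f:
        return pd.read_csv(f, keep_default_na=False)


_PROFILE_PARAMS = {
    "null": dict(effect_log2=0.0, base_seed=10_000),
    "moderate": dict(effect_log2=1.0, base_seed=20_000),
    "strong": dict(effect_log2=2.0, base_seed=30_000),
}


def benchmark_suite(profile: str, n_configs: int = 20) -> list:
    """Named, seeded benchmark configurations.

    Profiles share the training-set case/control imbalance (25 vs 186) and
    3 discriminant features; they differ in planted effect size: ``null``
    (0), ``moderate`` (log2 shift 1.0), ``strong`` (log2 shift 2.0).  Seeds
    are fixed (base seed + replicate index) so benchmark runs reproduce.
    """
    if profile not in _PROFILE_PARAMS:
        raise ValueError(f"unknown profile {profile!r}")
    params = _PROFILE_PARAMS[profile]
    return [
        GeneratorConfig(
            n_case=25,
            n_control=186,
            n_discriminant=3,
            effect_log2=params["effect_log2"],
            seed=params["base_seed"] + i,
        )
        for i in range(n_configs)
    ]
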