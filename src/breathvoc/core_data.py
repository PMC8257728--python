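"""Data model and I/O for breath-volatilome feature tables and sample metadata.

A study dataset is a non-negative samples x features intensity matrix
(:class:`FeatureTable`), per-feature annotations (:class:`FeatureMeta`) and
per-sample annotations (:class:`SampleMeta`).  Every exhaled-breath sample is
paired, through ``pair_key``, with exactly one ambient (room-air) sample
collected at the same visit; that pairing is what the background screen in
:mod:`breathvoc.hyper_filter` relies on, so it is validated here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np
import pandas as pd

SEASONS = ("winter", "spring", "summer", "autumn")
SAMPLE_TYPES = ("breath", "ambient")
CATEGORIES = ("A-AD", "NA-AD", "NA-NAD")
SPLITS = ("train", "validation")
CONTAMINANT_CLASSES = ("none", "bag_artifact", "pump_oil", "siloxane")

#: binary clinical covariates (0/1)
BINARY_COVARIATES = (
    "parental_asthma",
    "parental_rhinitis",
    "parental_dermatitis",
    "allergic_rhinitis",
    "atopic_dermatitis",
    "allergic_conjunctivitis",
    "food_allergy",
    "drug_allergy",
)

#: white-blood-cell differential counts, cells per microlitre
WBC_COVARIATES = (
    "eosinophils",
    "lymphocytes",
    "leucocytes",
    "monocytes",
    "basophils",
    "neutrophils",
)


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class FeatureTable:
    """Samples x features matrix of non-negative relative intensities."""

    sample_ids: list
    feature_ids: list
    intensities: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        self.intensities = np.asarray(self.intensities, dtype=float)
        for kind, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({s for s in ids if ids.count(s) > 1})
                raise DataValidationError(f"duplicate {kind} ids: {dup}")
        if self.intensities.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise DataValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(self.intensities)):
            i, j = np.argwhere(~np.isfinite(self.intensities))[0]
            raise DataValidationError(
                f"non-finite intensity at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if np.any(self.intensities < 0):
            i, j = np.argwhere(self.intensities < 0)[0]
            raise DataValidationError(
                f"negative intensity at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def shape(self):
        return self.intensities.shape

    def sample_index(self, sample_id) -> int:
        return self.sample_ids.index(sample_id)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureTable(list(sample_ids), self.feature_ids, self.intensities[idx])

    def subset_features(self, feature_ids) -> "FeatureTable":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return FeatureTable(self.sample_ids, list(feature_ids), self.intensities[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_ids,
        )

    def write(self, path) -> None:
        """Write as CSV; decimals rendered with 12 significant digits."""
        self.to_dataframe().to_csv(path, float_format="%.12g")


@dataclass
class FeatureMeta:
    """Annotation of one GC/MS feature (ion peak)."""

    feature_id: str
    retention_time: float  # seconds
    quant_mz: float  # quantifier m/z
    compound_name: str | None = None
    cas_number: str | None = None
    contaminant_class: str = "none"

    def __post_init__(self):
        if self.retention_time < 0:
            raise DataValidationError(f"{self.feature_id}: retention_time < 0")
        if self.quant_mz <= 0:
            raise DataValidationError(f"{self.feature_id}: quant_mz <= 0")
        if self.contaminant_class not in CONTAMINANT_CLASSES:
            raise DataValidationError(
                f"{self.feature_id}: unknown contaminant_class "
                f"{self.contaminant_class!r}"
            )


@dataclass
class SampleMeta:
    """Annotation of one sample (breath or ambient room air)."""

    sample_id: str
    subject_id: str
    sample_type: str
    pair_key: str
    category: str | None = None
    season: str | None = None
    zone: str | None = None
    split: str | None = None
    sampling_date: date | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sample_type not in SAMPLE_TYPES:
            raise DataValidationError(
                f"{self.sample_id}: unknown sample_type {self.sample_type!r}"
            )
        if self.season is not None and self.season not in SEASONS:
            raise DataValidationError(
                f"{self.sample_id}: unknown season {self.season!r}"
            )
        if self.category is not None and self.category not in CATEGORIES:
            raise DataValidationError(
                f"{self.sample_id}: unknown category {self.category!r}"
            )
        if self.split is not None and self.split not in SPLITS:
            raise DataValidationError(f"{self.sample_id}: unknown split {self.split!r}")
        if self.sample_type == "ambient" and self.category is not None:
            raise DataValidationError(
                f"{self.sample_id}: ambient samples carry no diagnostic category"
            )
        if self.sample_type == "breath" and not self.pair_key:
            raise DataValidationError(
                f"{self.sample_id}: breath sample lacks a pair_key"
            )


@dataclass
class PairingReport:
    n_breath: int
    n_ambient: int
    unpaired_breath_ids: list
    orphan_ambient_ids: list

    @property
    def ok(self) -> bool:
        return not self.unpaired_breath_ids and not self.orphan_ambient_ids


def read_feature_table(path, impute_zero: bool = False) -> FeatureTable:
    """Read a CSV/TSV feature table (first column sample_id, header = feature ids).

    Missing cells are a hard error unless ``impute_zero`` is set, in which case
    they are replaced by 0.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and cell.strip() == ""
            ):
                if impute_zero:
                    values[i, j] = 0.0
                    continue
                raise DataValidationError(
                    f"missing intensity at sample {sample_ids[i]!r}, "
                    f"feature {feature_ids[j]!r} (pass impute_zero=True to zero-fill)"
                )
            try:
                v = float(cell)
            except ValueError as exc:
                raise DataValidationError(
                    f"non-numeric intensity {cell!r} at sample {sample_ids[i]!r}, "
                    f"feature {feature_ids[j]!r}"
                ) from exc
            if v < 0:
                raise DataValidationError(
                    f"negative intensity {v} at sample {sample_ids[i]!r}, "
                    f"feature {feature_ids[j]!r}"
                )
            values[i, j] = v
    return FeatureTable(sample_ids, feature_ids, values)


def read_feature_meta(path) -> list[FeatureMeta]:
    """Read feature annotations (retention time, m/z, contaminant class)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, keep_default_na=False)
    missing = [c for c in ("feature_id", "retention_time", "quant_mz")
               if c not in df.columns]
    if missing:
        raise DataValidationError(f"feature metadata missing columns: {missing}")
    metas = []
    for row in df.itertuples():
        metas.append(
            FeatureMeta(
                feature_id=str(row.feature_id),
                retention_time=float(row.retention_time),
                quant_mz=float(row.quant_mz),
                compound_name=getattr(row, "compound_name", None) or None,
                cas_number=getattr(row, "cas_number", None) or None,
                contaminant_class=getattr(row, "contaminant_class", "none")
                or "none",
            )
        )
    ids = [m.feature_id for m in metas]
    if len(set(ids)) != len(ids):
        raise DataValidationError("duplicate feature ids in metadata")
    return metas


def write_feature_meta(metas: list[FeatureMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "feature_id": m.feature_id,
                "retention_time": m.retention_time,
                "quant_mz": m.quant_mz,
                "compound_name": m.compound_name,
                "cas_number": m.cas_number,
                "contaminant_class": m.contaminant_class,
            }
            for m in metas
        ]
    ).to_csv(path, index=False)


_META_REQUIRED = ("sample_id", "subject_id", "sample_type", "pair_key")
_META_OPTIONAL = ("category", "season", "zone", "split", "sampling_date")


def _opt(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s if s else None


def read_sample_meta(path) -> list[SampleMeta]:
    """Read sample metadata CSV/TSV; unknown columns become covariates.

    Booleans are encoded 0/1; ``sampling_date`` is ISO-8601.  Row order is
    canonical: downstream matrices align to it.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise DataValidationError(f"metadata missing required columns: {missing}")
    covariate_cols = [
        c for c in df.columns if c not in _META_REQUIRED and c not in _META_OPTIONAL
    ]
    metas = []
    for _, row in df.iterrows():
        sampling_date = _opt(row.get("sampling_date"))
        if sampling_date is not None:
            sampling_date = datetime.strptime(sampling_date, "%Y-%m-%d").date()
        covariates = {}
        for c in covariate_cols:
            v = _opt(row[c])
            if v is not None:
                covariates[c] = float(v)
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                subject_id=str(row["subject_id"]),
                sample_type=_opt(row["sample_type"]) or "",
                pair_key=_opt(row["pair_key"]) or "",
                category=_opt(row.get("category")),
                season=_opt(row.get("season")),
                zone=_opt(row.get("zone")),
                split=_opt(row.get("split")),
                sampling_date=sampling_date,
                covariates=covariates,
            )
        )
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise DataValidationError(f"duplicate sample ids in metadata: {dup}")
    return metas


def write_sample_meta(metas: list[SampleMeta], path) -> None:
    rows = []
    for m in metas:
        row = {
            "sample_id": m.sample_id,
            "subject_id": m.subject_id,
            "sample_type": m.sample_type,
            "pair_key": m.pair_key,
            "category": m.category,
            "season": m.season,
            "zone": m.zone,
            "split": m.split,
            "sampling_date": m.sampling_date.isoformat() if m.sampling_date else None,
        }
        row.update(m.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_pairing(table: FeatureTable, metas: list[SampleMeta]) -> PairingReport:
    """Report breath samples without a resolvable ambient partner and orphans.

    Each breath sample's ``pair_key`` must resolve to exactly one ambient
    sample; ambient samples never referenced are orphans.
    """
    by_id = {m.sample_id: m for m in metas}
    not_covered = [s for s in table.sample_ids if s not in by_id]
    if not_covered:
        raise DataValidationError(f"metadata does not cover samples: {not_covered}")
    in_table = [by_id[s] for s in table.sample_ids]
    breath = [m for m in in_table if m.sample_type == "breath"]
    ambient = [m for m in in_table if m.sample_type == "ambient"]
    ambient_by_key: dict = {}
    for m in ambient:
        ambient_by_key.setdefault(m.pair_key, []).append(m.sample_id)
    unpaired = [
        m.sample_id
        for m in breath
        if len(ambient_by_key.get(m.pair_key, [])) != 1
    ]
    referenced = {m.pair_key for m in breath}
    orphans = [m.sample_id for m in ambient if m.pair_key not in referenced]
    return PairingReport(
        n_breath=len(breath),
        n_ambient=len(ambient),
        unpaired_breath_ids=unpaired,
        orphan_ambient_ids=orphans,
    )


def split_by_date(metas: list[SampleMeta], cutoff: date) -> list[SampleMeta]:
    """Assign train/validation splits by sampling date (half-open [start, cutoff)).

    Breath samples dated strictly before ``cutoff`` become training samples,
    the rest validation; ambient samples inherit their breath partner's split.
    Returns new metadata objects; the input is not modified.
    """
    out = []
    split_by_pair = {}
    for m in metas:
        if m.sample_type != "breath":
            continue
        if m.sampling_date is None:
            raise DataValidationError(f"{m.sample_id}: missing sampling_date")
        split = "train" if m.sampling_date < cutoff else "validation"
        split_by_pair[m.pair_key] = split
    for m in metas:
        if m.sample_type == "breath":
            split = split_by_pair[m.pair_key]
        else:
            split = split_by_pair.get(m.pair_key)
        out.append(dataclasses.replace(m, split=split))
    return out
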