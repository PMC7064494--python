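"""Feature table container, standardization and PCA dimension reduction.

The 24 morphometric features mix units (µm², µm, bits, 8-bit counts),
so each feature is z-scored before the principal-component analysis
(i.e. PCA of the correlation matrix). The number of retained
components is the smallest k whose cumulative explained-variance
fraction reaches the threshold (default 99%).

Patient age is the single non-image feature. It never enters the PCA:
the reduction is fitted on the 24 image features alone and age is
appended afterwards, z-scored by the fitted model's age statistics, so
a reduced design matrix always has width ``n_components + 1``.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import Micrograph, RegionMasks
from .annotation_io import SampleRecord
from .morphometry import (FEATURE_NAMES, FEATURE_UNITS, FeatureConfig,
                          extract_features)

__all__ = [
    "FeatureTable",
    "ReductionModel",
    "build_feature_table",
    "table_from_phantoms",
    "fit_reduction",
    "apply_reduction",
]

DEFAULT_VARIANCE_THRESHOLD = 0.99


@dataclass(frozen=True)
class FeatureTable:
    """n_samples × 24 feature matrix plus age and binary label columns."""

    features: pd.DataFrame
    age: pd.Series
    label: pd.Series
    sample_ids: tuple[str, ...]
    feature_units: dict = field(default_factory=lambda: dict(FEATURE_UNITS))

    def __post_init__(self) -> None:
        if list(self.features.columns) != list(FEATURE_NAMES):
            raise ValueError("feature columns must be the 24 canonical features "
                             "in canonical order")
        n = len(self.features)
        if n < 2:
            raise ValueError("feature table needs at least 2 samples")
        if len(self.age) != n or len(self.label) != n or len(self.sample_ids) != n:
            raise ValueError("features, age, label and ids must align")
        if self.features.isna().any().any() or self.age.isna().any():
            raise ValueError("feature table contains missing values")
        if not set(np.unique(self.label)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.features.columns)

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices)
        return FeatureTable(
            features=self.features.iloc[idx].reset_index(drop=True),
            age=self.age.iloc[idx].reset_index(drop=True),
            label=self.label.iloc[idx].reset_index(drop=True),
            sample_ids=tuple(np.asarray(self.sample_ids)[idx]),
        )

    def with_labels(self, labels: Sequence[int]) -> "FeatureTable":
        return FeatureTable(
            features=self.features,
            age=self.age,
            label=pd.Series(np.asarray(labels, dtype=int)),
            sample_ids=self.sample_ids,
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        cols = {"sample_id": list(self.sample_ids)}
        for name in FEATURE_NAMES:
            cols[f"{name}[{FEATURE_UNITS[name]}]"] = self.features[name].to_numpy()
        cols["age_years"] = self.age.to_numpy()
        cols["label"] = self.label.to_numpy()
        return pd.DataFrame(cols)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        rename = {}
        for col in df.columns:
            base = col.split("[")[0]
            if base in FEATURE_NAMES:
                rename[col] = base
        df = df.rename(columns=rename)
        missing = [n for n in FEATURE_NAMES if n not in df.columns]
        if missing:
            raise ValueError(f"feature CSV missing columns {missing}")
        for col in ("sample_id", "age_years", "label"):
            if col not in df.columns:
                raise ValueError(f"feature CSV missing column '{col}'")
        return cls(
            features=df[list(FEATURE_NAMES)].astype(float),
            age=df["age_years"].astype(float),
            label=df["label"].astype(int),
            sample_ids=tuple(df["sample_id"].astype(str)),
        )


def build_feature_table(
    entries: Sequence[tuple[Micrograph, RegionMasks, SampleRecord]],
    config: FeatureConfig = FeatureConfig(),
) -> FeatureTable:
    """Extract features for a loaded cohort into a :class:`FeatureTable`."""
    rows, ages, labels, ids = [], [], [], []
    for m, masks, rec in entries:
        fv = extract_features(m, masks, config)
        rows.append(fv.values)
        ages.append(rec.age_years)
        labels.append(rec.resolved_label())
        ids.append(rec.sample_id)
    return FeatureTable(
        features=pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES)),
        age=pd.Series(ages, dtype=float),
        label=pd.Series(labels, dtype=int),
        sample_ids=tuple(ids),
    )


def table_from_phantoms(cohort, config: FeatureConfig = FeatureConfig()
                        ) -> FeatureTable:
    """Extract the feature table of an in-memory phantom cohort."""
    entries = [
        (
            s.micrograph,
            s.masks,
            SampleRecord(
                sample_id=s.micrograph.sample_id,
                age_years=s.age_years,
                microns_per_pixel=s.micrograph.microns_per_pixel,
                bhcg_mUI_per_mL=s.bhcg_mUI_per_mL,
            ),
        )
        for s in cohort.samples
    ]
    return build_feature_table(entries, config)


@dataclass(frozen=True)
class ReductionModel:
    """Fitted standardization + PCA with the variance-threshold rule."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray                 # (n_components, n_kept_features)
    explained_variance_ratio: np.ndarray  # all components, non-increasing
    n_components: int
    variance_threshold: float
    age_mean: float
    age_sd: float
    dropped_features: tuple[str, ...] = ()

    @property
    def cumulative_explained_variance(self) -> float:
        """Cumulative explained-variance fraction of the retained set."""
        return float(self.explained_variance_ratio[: self.n_components].sum())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_components": self.n_components,
            "variance_threshold": self.variance_threshold,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "dropped_features": list(self.dropped_features),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReductionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(d["feature_names"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            loadings=np.asarray(d["loadings"]),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
            n_components=int(d["n_components"]),
            variance_threshold=float(d["variance_threshold"]),
            age_mean=float(d["age_mean"]),
            age_sd=float(d["age_sd"]),
            dropped_features=tuple(d["dropped_features"]),
        )


def fit_reduction(
    table: FeatureTable,
    threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> ReductionModel:
    """Fit the standardize+PCA reduction with minimal-k selection.

    Retains the smallest number of leading components whose cumulative
    explained-variance fraction is >= ``threshold``. Constant features
    carry no variance and are dropped with a warning before the fit.
    Component signs follow a fixed convention (the largest-magnitude
    loading element of each component is positive) so repeated fits are
    bit-identical.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"variance threshold must lie in (0, 1], got {threshold}")
    if len(table) < 3:
        raise ValueError("need at least 3 samples to fit the reduction")

    X = table.features.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = sds == 0
    if constant.all():
        raise ValueError("all features are constant; nothing to reduce")
    dropped = tuple(np.asarray(table.feature_names)[constant])
    if dropped:
        warnings.warn(f"dropping constant features {list(dropped)}",
                      stacklevel=2)
    kept = ~constant
    Z = (X[:, kept] - means[kept]) / sds[kept]

    pca = PCA(svd_solver="full")
    pca.fit(Z)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(ratios))

    loadings = pca.components_.copy()
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1

    age = table.age.to_numpy(dtype=float)
    age_sd = float(age.std(ddof=1))
    if age_sd == 0:
        warnings.warn("age is constant; z-scored age will be 0", stacklevel=2)
        age_sd = 1.0

    return ReductionModel(
        feature_names=tuple(np.asarray(table.feature_names)[kept]),
        means=means[kept],
        sds=sds[kept],
        loadings=loadings,
        explained_variance_ratio=ratios,
        n_components=k,
        variance_threshold=float(threshold),
        age_mean=float(age.mean()),
        age_sd=age_sd,
        dropped_features=dropped,
    )


def apply_reduction(model: ReductionModel, table: FeatureTable) -> pd.DataFrame:
    """Project a feature table onto the retained components, append age.

    Returns a frame with columns ``pc_1..pc_k``, ``age_z`` and
    ``label`` (width k+1 design columns), indexed by sample id.
    """
    available = set(table.feature_names)
    needed = set(model.feature_names)
    missing = sorted(needed - available)
    if missing:
        raise ValueError(f"table is missing model features {missing}")
    X = table.features[list(model.feature_names)].to_numpy(dtype=float)
    Z = (X - model.means) / model.sds
    scores = Z @ model.loadings[: model.n_components].T
    out = pd.DataFrame(
        scores,
        columns=[f"pc_{i + 1}" for i in range(model.n_components)],
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    out["age_z"] = (table.age.to_numpy(dtype=float) - model.age_mean) / model.age_sd
    out["label"] = table.label.to_numpy(dtype=int)
    return out
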