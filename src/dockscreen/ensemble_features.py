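"""Pose- and structure-level aggregation of term vectors into ML features.

Each ligand is scored as several poses against each structure of a receptor
ensemble.  The per-pose six-term vectors are averaged over poses (per
structure) and then over structures, yielding one six-feature row per ligand.
Activity labels come from a Ki table: a ligand is *active* at a threshold
when its Ki is strictly below it.  Feature standardisation (mean 0, variance
1) is learned on training rows only and applied unchanged to test rows.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import FEATURE_COLUMNS, TermVector

__all__ = [
    "LigandRecord",
    "EnsembleFeatureMatrix",
    "Scaler",
    "AggregationError",
    "aggregate_poses",
    "aggregate_structures",
    "ensemble_average_score",
    "label_activity",
    "fit_scaler",
    "apply_scaler",
    "pose_table_to_matrix",
    "read_activity_csv",
    "build_pose_table",
    "POSE_TABLE_COLUMNS",
]

logger = logging.getLogger(__name__)

POSE_TABLE_COLUMNS = ("ligand_id", "structure_id", "pose") + FEATURE_COLUMNS


class AggregationError(ValueError):
    pass


@dataclass(frozen=True)
class LigandRecord:
    """A ligand with an optional inhibition constant (µM)."""

    ligand_id: str
    ki_uM: float | None = None
    source: str = ""

    def __post_init__(self):
        if self.ki_uM is not None and not self.ki_uM > 0:
            raise AggregationError(
                f"ligand {self.ligand_id!r}: Ki must be positive, got {self.ki_uM}"
            )


@dataclass
class Scaler:
    """Column-wise standardisation learned from training rows only.

    A zero-variance column keeps scale 1 so it maps to 0 everywhere (and a
    warning is logged) — the degenerate-fixture rule.
    """

    mean_: np.ndarray
    scale_: np.ndarray

    def transform(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != self.mean_.shape[0]:
            raise AggregationError(
                f"expected {self.mean_.shape[0]} columns, got {rows.shape[1]}"
            )
        return (rows - self.mean_) / self.scale_

    def metadata_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.mean_).tobytes())
        h.update(np.ascontiguousarray(self.scale_).tobytes())
        return h.hexdigest()[:16]

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scaler":
        return cls(np.asarray(d["mean"], float), np.asarray(d["scale"], float))


@dataclass
class EnsembleFeatureMatrix:
    """Ligands × 6 features after pose and structure averaging.

    ``per_structure`` optionally retains the ligands × structures × 6 tensor
    of pose-averaged vectors for structure-individualised models.
    """

    ligand_ids: list[str]
    features: np.ndarray
    structure_ids: list[str] = field(default_factory=list)
    per_structure: np.ndarray | None = None
    scaler: Scaler | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (len(self.ligand_ids), len(FEATURE_COLUMNS)):
            raise AggregationError(
                f"feature matrix shape {self.features.shape} does not match "
                f"{len(self.ligand_ids)} ligands x {len(FEATURE_COLUMNS)} features"
            )
        if not np.isfinite(self.features).all():
            raise AggregationError("feature matrix contains non-finite cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.features, index=self.ligand_ids,
                            columns=list(FEATURE_COLUMNS))


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------


def aggregate_poses(pose_terms: Sequence[TermVector]) -> TermVector:
    """Component-wise mean over a ligand's poses (one structure).

    If the engine returned fewer poses than requested, the mean is over what
    exists; an empty list is a hard error, never silently imputed.
    """
    if not pose_terms:
        raise AggregationError("cannot aggregate an empty pose list")
    stacked = np.stack([t.as_array() for t in pose_terms])
    return TermVector.from_array(stacked.mean(axis=0))


def aggregate_structures(per_structure: Mapping[str, TermVector]) -> TermVector:
    """Component-wise mean of pose-averaged vectors over the ensemble."""
    if not per_structure:
        raise AggregationError("cannot aggregate an empty structure map")
    stacked = np.stack([t.as_array() for t in per_structure.values()])
    return TermVector.from_array(stacked.mean(axis=0))


def ensemble_average_score(per_structure_scores: Mapping[str, float]) -> float:
    """Mean composite score across the ensemble (the docking-only baseline)."""
    if not per_structure_scores:
        raise AggregationError("cannot average an empty score map")
    return float(np.mean(list(per_structure_scores.values())))


def label_activity(ki_uM: float | None, threshold_uM: float) -> bool | None:
    """Active iff Ki strictly below the threshold; a Ki exactly at the
    threshold is inactive.  ``None`` Ki yields ``None`` (screening mode)."""
    if ki_uM is None:
        return None
    if not ki_uM > 0:
        raise AggregationError(f"Ki must be positive, got {ki_uM}")
    if not threshold_uM > 0:
        raise AggregationError(f"threshold must be positive, got {threshold_uM}")
    return ki_uM < threshold_uM


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


def fit_scaler(train_rows: np.ndarray) -> Scaler:
    """Learn per-column mean/std from training rows (population std)."""
    rows = np.atleast_2d(np.asarray(train_rows, dtype=float))
    if rows.shape[0] < 2:
        raise AggregationError("need at least 2 training rows to fit a scaler")
    mean = rows.mean(axis=0)
    std = rows.std(axis=0)
    zero = std == 0.0
    if zero.any():
        logger.warning(
            "zero-variance feature column(s) %s: mapped to 0 after scaling",
            list(np.nonzero(zero)[0]),
        )
        std = np.where(zero, 1.0, std)
    return Scaler(mean_=mean, scale_=std)


def apply_scaler(scaler: Scaler, rows: np.ndarray) -> np.ndarray:
    return scaler.transform(rows)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def build_pose_table(records: Sequence[tuple[str, str, int, TermVector]]) -> pd.DataFrame:
    """Tidy per-pose table: (ligand_id, structure_id, pose, six features)."""
    rows = [
        {"ligand_id": lig, "structure_id": struct, "pose": pose,
         **dict(zip(FEATURE_COLUMNS, tv.as_array()))}
        for lig, struct, pose, tv in records
    ]
    return pd.DataFrame(rows, columns=list(POSE_TABLE_COLUMNS))


def pose_table_to_matrix(pose_df: pd.DataFrame, keep_per_structure: bool = True
                         ) -> EnsembleFeatureMatrix:
    """Average a per-pose table into the per-ligand ensemble feature matrix.

    Every ligand must be scored against every structure appearing in the
    table: a missing (ligand, structure) cell is an error naming both, never
    silently imputed.
    """
    missing = [c for c in POSE_TABLE_COLUMNS if c not in pose_df.columns]
    if missing:
        raise AggregationError(f"pose table missing columns: {missing}")
    feats = list(FEATURE_COLUMNS)
    per_ls = (
        pose_df.groupby(["ligand_id", "structure_id"], sort=True)[feats]
        .mean()
    )
    ligand_ids = sorted(pose_df["ligand_id"].unique())
    structure_ids = sorted(pose_df["structure_id"].unique())
    for lig in ligand_ids:
        have = set(per_ls.loc[lig].index) if lig in per_ls.index else set()
        lost = [s for s in structure_ids if s not in have]
        if lost:
            raise AggregationError(
                f"ligand {lig!r} has no poses for structure(s) {lost}"
            )
    tensor = per_ls.to_numpy().reshape(len(ligand_ids), len(structure_ids), len(feats))
    ensemble = tensor.mean(axis=1)
    return EnsembleFeatureMatrix(
        ligand_ids=ligand_ids,
        features=ensemble,
        structure_ids=structure_ids,
        per_structure=tensor if keep_per_structure else None,
    )


def read_activity_csv(path) -> pd.DataFrame:
    """Read a ``ligand_id, ki_uM`` activity table; validates positivity."""
    df = pd.read_csv(path)
    for col in ("ligand_id", "ki_uM"):
        if col not in df.columns:
            raise AggregationError(f"activity table missing column {col!r}")
    bad = df["ki_uM"].dropna()
    if (bad <= 0).any():
        offenders = df.loc[df["ki_uM"] <= 0, "ligand_id"].tolist()
        raise AggregationError(f"non-positive Ki for ligand(s) {offenders}")
    return df
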