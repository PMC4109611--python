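"""Core data containers and their delimited-text serialization.

All on-disk formats are tab-delimited text with header rows: a ROI table
(one row per region with hemisphere, centroid and anatomical-area label),
ROI × sample activity matrices, and symmetric ROI × ROI connectivity
matrices carrying number-of-fibers (NOF) weights.  Matrices carry the
roi_id labels as header row and first column so files remain
self-describing and order mismatches are detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiTable",
    "ActivityMatrix",
    "StructuralConnectome",
    "read_roi_table",
    "read_activity",
    "read_connectome",
    "write_manifest",
    "read_manifest",
]


@dataclass(frozen=True)
class RoiTable:
    """Region-of-interest (ROI) index: identities, hemispheres, centroids.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``roi_id`` (int), ``hemisphere`` ({'L','R'}), ``x``, ``y``,
        ``z`` (centroid coordinates in mm), ``area_label`` (str).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"roi_id", "hemisphere", "x", "y", "z", "area_label"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ROI table missing columns: {sorted(missing)}")
        ids = self.table["roi_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("roi_id values must be unique")
        if not np.isfinite(self.table[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("ROI centroids must be finite")
        bad = set(self.table["hemisphere"]) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere labels must be 'L' or 'R', got {bad}")

    @property
    def roi_ids(self) -> np.ndarray:
        return self.table["roi_id"].to_numpy()

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        """(n_rois, 3) centroid array in mm, in table order."""
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    def hemisphere_ids(self, hemisphere: str) -> np.ndarray:
        """roi_ids belonging to one hemisphere, in table order."""
        mask = self.table["hemisphere"].to_numpy() == hemisphere
        return self.table.loc[mask, "roi_id"].to_numpy()

    def index_of(self, roi_ids: Sequence[int]) -> np.ndarray:
        """Positional indices of the given roi_ids in table order."""
        lookup = {rid: i for i, rid in enumerate(self.roi_ids)}
        try:
            return np.array([lookup[r] for r in roi_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown roi_id {exc.args[0]}") from None

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ActivityMatrix:
    """ROI × sample activity matrix.

    ``values`` has one row per ROI (ordered as ``roi_ids``) and one column
    per temporal sample; entries are real-valued activity (arbitrary units
    before standardization, unit SD per ROI afterwards).
    """

    values: np.ndarray
    roi_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids)
        if self.values.ndim != 2:
            raise ValueError("activity values must be a 2-D (ROI x sample) array")
        if self.values.shape[0] != len(self.roi_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.roi_ids)} roi_ids"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("activity matrix contains non-finite values")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def rows(self, roi_ids: Sequence[int]) -> np.ndarray:
        lookup = {rid: i for i, rid in enumerate(self.roi_ids)}
        idx = [lookup[r] for r in roi_ids]
        return self.values[idx]

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values)
        df.insert(0, "roi_id", self.roi_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative ROI × ROI structural weight matrix (NOF units).

    The diagonal is zero and, because inter-hemispheric tractography is not
    trusted, the inter-hemispheric block is identically zero.
    """

    weights: np.ndarray
    roi_ids: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome weights must be square")
        if w.shape[0] != len(self.roi_ids):
            raise ValueError("weights shape does not match roi_ids")
        if not np.allclose(w, w.T):
            raise ValueError("connectome weights must be symmetric")
        if (w < 0).any():
            raise ValueError("connectome weights must be nonnegative")
        if np.diag(w).any():
            raise ValueError("connectome diagonal must be zero")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    def validate_hemispheres(self, rois: RoiTable) -> None:
        """Check the inter-hemispheric block is zero against a ROI table."""
        hemi = rois.hemispheres
        cross = np.not_equal.outer(hemi, hemi)
        if self.weights[cross].any():
            raise ValueError("inter-hemispheric connectome block must be zero")

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(self.weights, columns=self.roi_ids.astype(str))
        df.insert(0, "roi_id", self.roi_ids)
        df.to_csv(path, sep="\t", index=False)


def read_roi_table(path: str | Path) -> RoiTable:
    return RoiTable(pd.read_csv(path, sep="\t"))


def read_activity(path: str | Path) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ActivityMatrix(df.drop(columns="roi_id").to_numpy(float), df["roi_id"].to_numpy())


def read_connectome(path: str | Path) -> StructuralConnectome:
    df = pd.read_csv(path, sep="\t")
    return StructuralConnectome(
        df.drop(columns="roi_id").to_numpy(float), df["roi_id"].to_numpy()
    )


def write_manifest(path: str | Path, entries: dict) -> None:
    """Write a key=value provenance manifest (parameters, seeds, checksums)."""
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}={value}\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip() and "=" in line:
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
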