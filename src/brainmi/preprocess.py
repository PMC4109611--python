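"""Computational preprocessing: trimming, outlier screening, pooling.

Per-subject activity matrices are trimmed of their initial samples
(signal stabilization), screened for across-ROI variance spikes with
Tukey's rule, standardized per ROI (mean 0, SD 1), and concatenated into
a single pooled subject; structural connectomes are pooled by
element-wise averaging.  Pooling many subjects yields a larger, more
stable sample for the Gaussian information-theoretic estimators
downstream — the pooled sample covariance is the sufficient statistic
for every measure in this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ActivityMatrix, StructuralConnectome

__all__ = [
    "trim_initial_samples",
    "screen_variance_outliers",
    "pool_subjects",
    "pool_connectomes",
    "standardize",
    "ScreeningReport",
]


def trim_initial_samples(subject: ActivityMatrix, n_drop: int = 4) -> ActivityMatrix:
    """Drop the first ``n_drop`` samples of each ROI series."""
    if n_drop < 0:
        raise ValueError("n_drop must be nonnegative")
    if n_drop >= subject.n_samples:
        raise ValueError(
            f"cannot drop {n_drop} of {subject.n_samples} samples: nothing would remain"
        )
    return ActivityMatrix(subject.values[:, n_drop:], subject.roi_ids)


@dataclass(frozen=True)
class ScreeningReport:
    """Per-subject screening statistics and the Tukey threshold applied."""

    statistics: np.ndarray
    threshold: float
    kept: np.ndarray  # boolean mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": np.arange(len(self.statistics)),
                "statistic": self.statistics,
                "threshold": self.threshold,
                "kept": self.kept,
            }
        )


def screen_variance_outliers(
    subjects: list[ActivityMatrix],
) -> tuple[list[ActivityMatrix], list[int], ScreeningReport]:
    """Reject subjects with outlier across-ROI variance spikes.

    For each subject the statistic is the maximum over time points of the
    variance across ROIs at that time point; subjects whose statistic
    exceeds Q3 + 1.5 * IQR (Tukey's rule, quartiles by linear
    interpolation) are rejected.  With fewer than 4 subjects quartiles
    are not meaningful: a warning is issued and nobody is rejected.

    Returns (kept subjects, rejected indices, report).
    """
    stats = np.array([subj.values.var(axis=0, ddof=0).max() for subj in subjects])
    if len(subjects) < 4:
        warnings.warn(
            "fewer than 4 subjects: variance screening skipped", stacklevel=2
        )
        kept = np.ones(len(subjects), dtype=bool)
        report = ScreeningReport(stats, np.inf, kept)
        return list(subjects), [], report
    q1, q3 = np.percentile(stats, [25, 75])  # linear interpolation
    threshold = q3 + 1.5 * (q3 - q1)
    kept = stats <= threshold
    report = ScreeningReport(stats, float(threshold), kept)
    kept_subjects = [s for s, keep in zip(subjects, kept) if keep]
    rejected = np.flatnonzero(~kept).tolist()
    return kept_subjects, rejected, report


def standardize(subject: ActivityMatrix) -> ActivityMatrix:
    """Mean-center each ROI series and rescale it to standard deviation 1."""
    values = subject.values
    sd = values.std(axis=1, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance series for roi_id(s) {subject.roi_ids[zero].tolist()}; "
            "cannot standardize"
        )
    centered = values - values.mean(axis=1, keepdims=True)
    return ActivityMatrix(centered / sd[:, None], subject.roi_ids)


def pool_subjects(subjects: list[ActivityMatrix]) -> ActivityMatrix:
    """Standardize each subject per ROI, then concatenate samples.

    All subjects must carry the same roi_ids in the same order; a single
    subject simply comes back standardized.
    """
    if not subjects:
        raise ValueError("no subjects to pool")
    ref = subjects[0].roi_ids
    for i, subj in enumerate(subjects[1:], start=1):
        if len(subj.roi_ids) != len(ref) or (subj.roi_ids != ref).any():
            raise ValueError(f"subject {i} roi_ids differ from subject 0")
    std = [standardize(s) for s in subjects]
    return ActivityMatrix(np.concatenate([s.values for s in std], axis=1), ref)


def pool_connectomes(connectomes: list[StructuralConnectome]) -> StructuralConnectome:
    """Element-wise mean of the subjects' structural connectivity matrices."""
    if not connectomes:
        raise ValueError("no connectomes to pool")
    ref = connectomes[0]
    for i, c in enumerate(connectomes[1:], start=1):
        if c.weights.shape != ref.weights.shape or (c.roi_ids != ref.roi_ids).any():
            raise ValueError(f"connectome {i} shape or roi order differs")
    mean = np.mean([c.weights for c in connectomes], axis=0)
    return StructuralConnectome(mean, ref.roi_ids)
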