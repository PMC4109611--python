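"""Gaussian differential entropy, mutual information, and total correlation.

All quantities are reported in bits.  Two estimators are provided:

``umvu``
    The uniformly minimum-variance unbiased estimator of multivariate
    Gaussian differential entropy.  For a k × n data matrix X of n samples
    from a zero-mean k-variate Gaussian,

        H_hat = (1/ln 2) * [ (k/2) ln(e*pi)
                             + (1/2) ln|X X'|
                             - (1/2) sum_{i=1..k} psi((n + 1 - i)/2) ]

    with psi the digamma function.  The digamma corrections make the
    estimator exactly unbiased when the rows genuinely have mean zero
    (an n-degree-of-freedom Wishart Gram matrix) — the situation produced
    by the standardization step of the preprocessing pipeline.  Passing
    ``center=True`` removes row means first, which costs an O(1/n)
    residual bias.

``plugin``
    The maximum-likelihood plug-in, (1/ln 2) * [(k/2) ln(2*pi*e)
    + (1/2) ln det(S)] with S = X X'/n.  It is biased but its mutual
    information and total correlation are exactly nonnegative and exactly
    monotone under set inclusion, properties used by the invariant suite.

The difference umvu - plugin depends only on (k, n), never on the data, so
MI/TC orderings agree between the two up to that analytic correction.
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
from scipy.linalg import cholesky, LinAlgError
from scipy.special import digamma

from .data import ActivityMatrix

__all__ = [
    "gaussian_entropy",
    "mutual_information",
    "total_correlation",
    "EntropyCalculator",
    "SingularDataError",
]

Estimator = Literal["umvu", "plugin"]

_LN2 = np.log(2.0)


class SingularDataError(ValueError):
    """Raised when a Gram/covariance sub-block is numerically singular."""


def _logdet_psd(mat: np.ndarray, what: str) -> float:
    """log-determinant of a symmetric PD matrix via Cholesky.

    Never forms the raw determinant, so it survives dimensions of a few
    hundred without overflow.
    """
    try:
        chol = cholesky(mat, lower=True)
    except LinAlgError:
        raise SingularDataError(
            f"singular or indefinite matrix for {what}; "
            "check for duplicated or constant ROI series"
        ) from None
    diag = np.diag(chol)
    # a relative pivot at rounding scale means rank deficiency (duplicated
    # or linearly dependent series), not a usable log-determinant
    if diag.min() <= diag.max() * 1e-6:
        raise SingularDataError(
            f"numerically singular matrix for {what}; "
            "check for duplicated or constant ROI series"
        )
    return 2.0 * float(np.sum(np.log(diag)))


def _entropy_from_gram(logdet_gram: float, k: int, n: int, estimator: Estimator) -> float:
    """Entropy in bits given ln|XX'| for a k x n data matrix."""
    if estimator == "umvu":
        corr = digamma((n + 1 - np.arange(1, k + 1)) / 2.0).sum()
        nats = 0.5 * k * np.log(np.e * np.pi) + 0.5 * logdet_gram - 0.5 * corr
    elif estimator == "plugin":
        # S = XX'/n  =>  ln det S = ln|XX'| - k ln n
        nats = 0.5 * k * np.log(2 * np.pi * np.e) + 0.5 * (logdet_gram - k * np.log(n))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return float(nats / _LN2)


def umvu_plugin_gap(k: int, n: int) -> float:
    """Analytic (data-independent) difference umvu - plugin, in bits."""
    corr = digamma((n + 1 - np.arange(1, k + 1)) / 2.0).sum()
    nats = -0.5 * k * np.log(2.0) + 0.5 * k * np.log(n) - 0.5 * corr
    return float(nats / _LN2)


def gaussian_entropy(
    x: np.ndarray,
    estimator: Estimator = "umvu",
    center: bool = False,
) -> float:
    """Differential entropy (bits) of the rows of a k x n data matrix.

    Parameters
    ----------
    x : ndarray, shape (k, n)
        n samples of k jointly Gaussian variables.  Rows are assumed
        zero-mean (guaranteed after pooling/standardization); pass
        ``center=True`` to remove row means first.
    estimator : {'umvu', 'plugin'}

    Raises
    ------
    SingularDataError
        If the Gram matrix XX' is singular.
    ValueError
        If n <= k (the Gram matrix cannot be full rank).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    k, n = x.shape
    if n <= k:
        raise ValueError(
            f"need more samples than variables for a full-rank Gram matrix "
            f"(k={k}, n={n}); reduce the set or use more samples"
        )
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    gram = x @ x.T
    logdet = _logdet_psd(gram, f"entropy of a {k}-variable set")
    return _entropy_from_gram(logdet, k, n, estimator)


def _check_sets(a: Iterable[int], b: Iterable[int]) -> tuple[list, list]:
    a, b = list(a), list(b)
    if not a or not b:
        raise ValueError("variable sets must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"variable sets overlap: {sorted(set(a) & set(b))}")
    return a, b


def mutual_information(
    a: Iterable[int],
    b: Iterable[int],
    x: ActivityMatrix,
    estimator: Estimator = "umvu",
) -> float:
    """I(A;B) = H(A) + H(B) - H(A,B), in bits, between two disjoint ROI sets."""
    a, b = _check_sets(a, b)
    calc = EntropyCalculator(x, estimator=estimator)
    return calc.mutual_information(a, b)


def total_correlation(
    s: Iterable[int],
    x: ActivityMatrix,
    estimator: Estimator = "umvu",
) -> float:
    """TC(S) = sum_i H(X_i) - H(X_S), in bits; multivariate integration of S."""
    s = list(s)
    if len(s) < 2:
        raise ValueError("total correlation requires at least 2 ROIs")
    calc = EntropyCalculator(x, estimator=estimator)
    return calc.total_correlation(s)


class EntropyCalculator:
    """Cached entropy/MI/TC evaluation over subsets of one activity matrix.

    Precomputes the full Gram matrix XX' once; the entropy of any ROI
    subset then needs only the Cholesky log-determinant of the
    corresponding sub-block.  Joint entropies are cached by frozen ROI
    set, because environment entropies are reused heavily across seeds
    when scanning subsystem sizes.
    """

    def __init__(
        self,
        x: ActivityMatrix,
        estimator: Estimator = "umvu",
        center: bool = False,
    ) -> None:
        if estimator not in ("umvu", "plugin"):
            raise ValueError(f"unknown estimator {estimator!r}")
        self.estimator: Estimator = estimator
        self.roi_ids = np.asarray(x.roi_ids)
        self._pos = {rid: i for i, rid in enumerate(self.roi_ids)}
        values = x.values
        if center:
            values = values - values.mean(axis=1, keepdims=True)
        self.n = values.shape[1]
        self._gram = values @ values.T
        self._cache: dict[frozenset, float] = {}

    def _indices(self, roi_set: Iterable[int]) -> np.ndarray:
        try:
            return np.array([self._pos[r] for r in roi_set], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown roi_id {exc.args[0]}") from None

    def entropy(self, roi_set: Iterable[int]) -> float:
        """Joint differential entropy (bits) of a ROI set."""
        key = frozenset(roi_set)
        if not key:
            raise ValueError("entropy of an empty set is undefined")
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        idx = self._indices(key)
        # sort for a deterministic sub-block layout
        idx = np.sort(idx)
        k = len(idx)
        if self.n <= k:
            raise ValueError(
                f"need n > k for a full-rank Gram matrix (k={k}, n={self.n})"
            )
        sub = self._gram[np.ix_(idx, idx)]
        logdet = _logdet_psd(
            sub, f"roi set {sorted(self.roi_ids[idx].tolist())}"
        )
        value = _entropy_from_gram(logdet, k, self.n, self.estimator)
        self._cache[key] = value
        return value

    def mutual_information(self, a: Iterable[int], b: Iterable[int]) -> float:
        a, b = _check_sets(a, b)
        return self.entropy(a) + self.entropy(b) - self.entropy([*a, *b])

    def total_correlation(self, s: Iterable[int]) -> float:
        s = list(s)
        if len(s) < 2:
            raise ValueError("total correlation requires at least 2 ROIs")
        return sum(self.entropy([r]) for r in s) - self.entropy(s)
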