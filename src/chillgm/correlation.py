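"""Correlation, inverse and partial-correlation matrices.

For a sample correlation matrix R = (r_ij), the partial correlation between
variables i and j given all remaining variables is computed from the inverse
K = R^-1 = (r^ij) as

    r_ij.rest = -r^ij / sqrt(r^ii r^jj),

the standard Gaussian graphical-model identity: a zero partial correlation
is a zero entry of the precision matrix, i.e. conditional independence.
The diagonal of the partial matrix is not defined and is stored as NaN
(rendered "." in text output, null in JSON).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import LayeredDataset

__all__ = [
    "CorrelationBundle",
    "EllipseParams",
    "correlation_matrix",
    "partial_correlation",
    "strong_pairs",
    "probability_ellipse",
    "CHI2_95_SCALE",
    "TWO_SIGMA_SCALE",
]

#: Conventional "two sigma" ellipse scale.
TWO_SIGMA_SCALE = 2.0
#: Exact 95% coverage scale for a bivariate Gaussian: sqrt of the chi2(2) 0.95 quantile.
CHI2_95_SCALE = float(np.sqrt(stats.chi2.ppf(0.95, df=2)))

_INVERSE_TOL = 1e-8


def correlation_matrix(dataset: LayeredDataset) -> pd.DataFrame:
    """Pearson product-moment correlation matrix of a dataset.

    Raises if fewer than 3 samples are available or any variable is constant
    (zero variance), naming the degenerate variable.
    """
    if dataset.n < 3:
        raise ValueError(f"need at least 3 samples, have {dataset.n}")
    stds = dataset.samples.std(axis=0, ddof=1)
    for name, s in zip(dataset.variable_names, stds):
        if s == 0.0:
            raise ValueError(f"variable {name!r} is constant; correlation undefined")
    frame = dataset.to_frame()
    return frame.corr(method="pearson")


def _validate_correlation(R: np.ndarray) -> None:
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")


def _check_positive_definite(R: np.ndarray) -> None:
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValueError("correlation matrix is not positive definite") from None


def partial_correlation(correlation):
    """Invert a correlation matrix and derive the partial-correlation matrix.

    Returns ``(inverse, partial)``.  ``partial[i, j] = -K[i, j] /
    sqrt(K[i, i] K[j, j])`` for i != j with K the inverse; the diagonal is
    NaN.  Accepts and returns :class:`pandas.DataFrame` (labels preserved)
    or plain arrays.
    """
    labelled = isinstance(correlation, pd.DataFrame)
    R = correlation.to_numpy(dtype=float) if labelled else np.asarray(correlation, dtype=float)
    _validate_correlation(R)
    _check_positive_definite(R)
    K = np.linalg.inv(R)
    residual = np.abs(R @ K - np.eye(len(R))).max()
    if residual >= _INVERSE_TOL:
        raise ValueError(f"inverse failed accuracy contract: residual {residual:.3e}")
    d = np.sqrt(np.diag(K))
    partial = -K / np.outer(d, d)
    np.fill_diagonal(partial, np.nan)
    if labelled:
        idx, cols = correlation.index, correlation.columns
        return (pd.DataFrame(K, idx, cols), pd.DataFrame(partial, idx, cols))
    return K, partial


@dataclass
class CorrelationBundle:
    """Correlation matrix, its inverse and the partial-correlation matrix."""

    correlation: pd.DataFrame
    inverse: pd.DataFrame
    partial: pd.DataFrame

    @classmethod
    def from_dataset(cls, dataset: LayeredDataset) -> "CorrelationBundle":
        R = correlation_matrix(dataset)
        K, P = partial_correlation(R)
        return cls(R, K, P)

    @property
    def variable_names(self) -> list:
        return list(self.correlation.columns)

    def round(self, digits: int) -> "CorrelationBundle":
        return CorrelationBundle(
            self.correlation.round(digits), self.inverse.round(digits), self.partial.round(digits)
        )

    def to_json(self, round_digits: Optional[int] = None) -> str:
        """All three matrices in one JSON document; partial diagonal is null."""
        bundle = self.round(round_digits) if round_digits is not None else self
        def matrix(frame):
            return [[None if isinstance(v, float) and math.isnan(v) else v for v in row]
                    for row in frame.to_numpy().tolist()]
        doc = {
            "variables": self.variable_names,
            "correlation": matrix(bundle.correlation),
            "inverse": matrix(bundle.inverse),
            "partial": matrix(bundle.partial),
        }
        return json.dumps(doc, indent=2)

    def write_csvs(self, directory, round_digits: Optional[int] = None) -> list:
        """Write correlation.csv, inverse.csv, partial.csv; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        bundle = self.round(round_digits) if round_digits is not None else self
        paths = []
        for name, frame in [
            ("correlation", bundle.correlation),
            ("inverse", bundle.inverse),
            ("partial", bundle.partial),
        ]:
            path = directory / f"{name}.csv"
            frame.to_csv(path, na_rep=".", lineterminator="\n")
            paths.append(path)
        return paths


def strong_pairs(correlation, cutoff: float = 0.5) -> set:
    """Unordered variable pairs whose |correlation| meets the intensity cutoff.

    The conventional screen marks |r| >= 0.5 as a strong marginal
    association.  Returns a set of alphabetically ordered name tuples (or
    index tuples for unlabelled input).
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    labelled = isinstance(correlation, pd.DataFrame)
    R = correlation.to_numpy(dtype=float) if labelled else np.asarray(correlation, dtype=float)
    _validate_correlation(R)
    names = list(correlation.columns) if labelled else list(range(len(R)))
    out = set()
    for i in range(len(R)):
        for j in range(i + 1, len(R)):
            if abs(R[i, j]) >= cutoff:
                out.add(tuple(sorted((names[i], names[j]))))
    return out


@dataclass(frozen=True)
class EllipseParams:
    """Probability-ellipse geometry for one scatterplot panel."""

    center: tuple       # (mean x, mean y)
    semi_axes: tuple    # lengths in data units, major first
    orientation: float  # radians, in [-pi/2, pi/2]


def probability_ellipse(x, y, scale: float = TWO_SIGMA_SCALE) -> EllipseParams:
    """Probability ellipse of a bivariate sample.

    Centered at the sample means; axes along the eigenvectors of the 2x2
    sample covariance with semi-axis lengths ``scale * sqrt(eigenvalue)``.
    The default ``scale=2`` is the two-sigma ellipse drawn on scatterplot
    matrices; pass :data:`CHI2_95_SCALE` (about 2.447) for exact 95%
    bivariate-Gaussian coverage.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if scale <= 0:
        raise ValueError("scale must be positive")
    cov = np.cov(x, y, ddof=1)
    if cov[0, 0] == 0.0 or cov[1, 1] == 0.0:
        raise ValueError("zero variance in one coordinate")
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 1e-12 * eigvals[1]:
        raise ValueError("collinear input: covariance is rank deficient")
    # eigh sorts ascending; report the major axis first
    major, minor = eigvals[1], eigvals[0]
    v = eigvecs[:, 1]
    orientation = math.atan2(v[1], v[0])
    if orientation > math.pi / 2:
        orientation -= math.pi
    elif orientation < -math.pi / 2:
        orientation += math.pi
    if orientation == -math.pi / 2:
        orientation = math.pi / 2
    return EllipseParams(
        center=(float(x.mean()), float(y.mean())),
        semi_axes=(float(scale * math.sqrt(major)), float(scale * math.sqrt(minor))),
        orientation=float(orientation),
    )
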