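"""Benchmark metrics: MSE/RMSE, Pearson r, deviation bins, aggregation, PCA.

MSE is Σ(y_true − y_pred)²/n and RMSE its square root, in the units of the
property (logP or pKi). Agreement between experimental and calculated
values is the Pearson correlation coefficient

    r = Σ(a−ā)(b−b̄) / sqrt(Σ(a−ā)² · Σ(b−b̄)²).

(The benchmarking literature this package follows prints this formula
under the label R²; it is the unsquared r. This module names it
``pearson`` and exposes ``pearson_squared`` separately.)

Per-molecule accuracy is additionally classified into the three deviation
bins of Tetko's logP-assessment convention: |error| ≤ 0.5 "acceptable",
0.5 < |error| ≤ 1.0 "disputable", > 1.0 "unacceptable", reported as
percentages that sum to 100.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .models import PredictionSet

__all__ = [
    "MetricsReport",
    "AggregateReport",
    "mse",
    "rmse",
    "pearson",
    "pearson_squared",
    "deviation_bins",
    "evaluate_predictions",
    "aggregate",
    "pca_project",
    "write_report_csv",
]


def _vectors(p: PredictionSet | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, PredictionSet):
        return p.y_true, p.y_pred
    a, b = p
    return np.asarray(a, dtype=float).ravel(), np.asarray(b, dtype=float).ravel()


def mse(p: PredictionSet | tuple) -> float:
    """Mean squared error Σ(y_true − y_pred)²/n."""
    a, b = _vectors(p)
    if len(a) == 0:
        raise ValueError("MSE of an empty prediction set is undefined")
    d = a - b
    return float(d @ d) / len(a)


def rmse(p: PredictionSet | tuple) -> float:
    """Root mean squared error, same units as the property."""
    return float(np.sqrt(mse(p)))


def pearson(p: PredictionSet | tuple) -> float:
    """Pearson correlation coefficient of y_true and y_pred."""
    a, b = _vectors(p)
    if len(a) < 2:
        raise ValueError("Pearson correlation needs at least two points")
    ac, bc = a - a.mean(), b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0.0:
        raise ValueError("Pearson correlation is undefined for a constant vector")
    return float((ac @ bc) / denom)


def pearson_squared(p: PredictionSet | tuple) -> float:
    """Square of the Pearson coefficient (coefficient of determination r²)."""
    return pearson(p) ** 2


def deviation_bins(p: PredictionSet | tuple) -> tuple[float, float, float]:
    """Percentages of |error| in [0, 0.5], (0.5, 1.0], (1.0, ∞).

    Boundary convention (frozen): exactly 0.5 is acceptable, exactly 1.0
    is disputable.
    """
    a, b = _vectors(p)
    if len(a) == 0:
        raise ValueError("deviation bins of an empty prediction set are undefined")
    dev = np.abs(a - b)
    acceptable = float((dev <= 0.5).mean()) * 100.0
    disputable = float(((dev > 0.5) & (dev <= 1.0)).mean()) * 100.0
    unacceptable = float((dev > 1.0).mean()) * 100.0
    return acceptable, disputable, unacceptable


@dataclass(frozen=True)
class MetricsReport:
    """All benchmark metrics of one trial on one prediction set."""

    mse: float
    rmse: float
    pearson: float
    bin_acceptable: float
    bin_disputable: float
    bin_unacceptable: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "pearson": self.pearson,
            "bin_acceptable": self.bin_acceptable,
            "bin_disputable": self.bin_disputable,
            "bin_unacceptable": self.bin_unacceptable,
            "n": self.n,
        }


def evaluate_predictions(p: PredictionSet | tuple) -> MetricsReport:
    """Compute the full per-trial metrics report for one prediction set."""
    a, _ = _vectors(p)
    bins = deviation_bins(p)
    m = mse(p)
    return MetricsReport(
        mse=m,
        rmse=float(np.sqrt(m)),
        pearson=pearson(p),
        bin_acceptable=bins[0],
        bin_disputable=bins[1],
        bin_unacceptable=bins[2],
        n=len(a),
    )


@dataclass(frozen=True)
class AggregateReport:
    """Mean ± sample standard deviation of each metric across trials."""

    trials: tuple[MetricsReport, ...]
    mean: MetricsReport
    std: MetricsReport

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def aggregate(reports: Sequence[MetricsReport]) -> AggregateReport:
    """Aggregate repeated-trial reports (sample std; 0 for a single trial)."""
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")
    keys = ["mse", "rmse", "pearson", "bin_acceptable", "bin_disputable", "bin_unacceptable"]
    table = {k: np.array([getattr(r, k) for r in reports], dtype=float) for k in keys}
    means = {k: float(v.mean()) for k, v in table.items()}
    stds = {
        # identical trials have exactly zero spread (no float residue)
        k: (float(v.std(ddof=1)) if len(v) > 1 and v.min() != v.max() else 0.0)
        for k, v in table.items()
    }
    n_total = int(np.mean([r.n for r in reports]))
    return AggregateReport(
        trials=tuple(reports),
        mean=MetricsReport(**means, n=n_total),
        std=MetricsReport(**stds, n=len(reports)),
    )


def pca_project(
    X: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred principal-component projection of a fingerprint matrix.

    Returns (coordinates, explained-variance fractions), components
    ordered by decreasing explained variance — the standard view of how
    much chemical-space spread a representation retains.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds min(rows, columns)")
    if np.allclose(X, X[0]):
        raise ValueError("PCA of a rank-0 (constant) matrix is undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_


def write_report_csv(
    rows: Sequence[dict], path: str | Path
) -> Path:
    """Write benchmark rows (method, fingerprint, metrics...) as CSV."""
    path = Path(path)
    if not rows:
        raise ValueError("no report rows to write")
    fields = list(rows[0].keys())
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)
    return path
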