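"""Grid search with k-fold cross-validation, scored by negative MSE.

Every point of the hyperparameter grid is evaluated with seeded,
shuffled k-fold cross-validation (default 5 folds) on the training
portion only; the candidate with the highest mean negative MSE wins.
Ties go to the smaller-capacity model, then to grid order. Candidates
that fail to train score as worst and are logged — a large neural grid
may contain degenerate corners and must not abort the search.

The default DNN grid mirrors the searched space of the benchmarking
protocol: hidden widths {10, 20, 40, 50, 60, 100, 300, 500}, activations
{softsign, relu, linear, tanh}, dropout 0–0.6 in steps of 0.1; batch size
and epoch count are searchable (their candidate lists are package
choices).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from sklearn.model_selection import KFold

from .models import ModelSpec, model_capacity, predict, train

logger = logging.getLogger(__name__)

__all__ = ["SearchSpace", "CandidateScore", "SearchResult", "grid_search", "default_dnn_space"]


@dataclass(frozen=True)
class SearchSpace:
    """A model family plus name -> candidate-value lists."""

    family: str
    grid: dict[str, list[Any]]

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid must be non-empty with non-empty value lists")
        # validate names via ModelSpec's own hyperparameter check
        ModelSpec(family=self.family, hyperparams={k: v[0] for k, v in self.grid.items()})

    def candidates(self) -> list[dict[str, Any]]:
        """Cartesian product of the grid, in deterministic grid order."""
        names = list(self.grid)
        return [
            dict(zip(names, values))
            for values in itertools.product(*(self.grid[n] for n in names))
        ]


def default_dnn_space(epochs: Sequence[int] = (50, 100), batch_sizes: Sequence[int] = (32, 64)) -> SearchSpace:
    """The searched DNN space; epoch/batch candidate lists are package defaults."""
    return SearchSpace(
        family="dnn",
        grid={
            "width": [10, 20, 40, 50, 60, 100, 300, 500],
            "activation": ["softsign", "relu", "linear", "tanh"],
            "dropout": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            "epochs": list(epochs),
            "batch_size": list(batch_sizes),
        },
    )


@dataclass(frozen=True)
class CandidateScore:
    params: dict[str, Any]
    mean_score: float  # mean of per-fold negative MSE (higher is better)
    std_score: float
    fold_scores: tuple[float, ...]
    failed: bool = False


@dataclass(frozen=True)
class SearchResult:
    best_params: dict[str, Any]
    best_score: float
    scores: tuple[CandidateScore, ...]
    n_folds: int
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "best_params": self.best_params,
                    "best_score": self.best_score,
                    "n_folds": self.n_folds,
                    "seed": self.seed,
                    "scores": [
                        {
                            "params": s.params,
                            "mean_score": s.mean_score,
                            "std_score": s.std_score,
                            "fold_scores": list(s.fold_scores),
                            "failed": s.failed,
                        }
                        for s in self.scores
                    ],
                },
                indent=2,
            )
        )
        return path


def kfold_indices(n: int, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled k-fold partition: disjoint, covering, sizes within 1."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in kf.split(np.arange(n))]


def grid_search(
    space: SearchSpace,
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> SearchResult:
    """Exhaustive grid search scored by mean k-fold negative MSE.

    ``X``/``y`` must be the training portion only; the held-out test
    partition is never passed here.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = kfold_indices(len(y), n_folds, seed)
    scored: list[CandidateScore] = []
    for params in space.candidates():
        fold_scores: list[float] = []
        failed = False
        for tr, va in folds:
            try:
                spec = ModelSpec(family=space.family, hyperparams=params, seed=seed)
                model = train(spec, X[tr], y[tr])
                pred = predict(model, X[va])
                err = pred - y[va]
                fold_scores.append(-float(err @ err) / len(va))
            except Exception as exc:
                logger.warning("candidate %s failed: %s", params, exc)
                failed = True
                break
        if failed or not fold_scores:
            scored.append(
                CandidateScore(params=params, mean_score=-np.inf, std_score=np.nan,
                               fold_scores=tuple(fold_scores), failed=True)
            )
        else:
            arr = np.array(fold_scores)
            scored.append(
                CandidateScore(
                    params=params,
                    mean_score=float(arr.mean()),
                    std_score=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                    fold_scores=tuple(fold_scores),
                )
            )
    if all(s.failed for s in scored):
        raise RuntimeError("every grid candidate failed to train")
    # argmax of mean score; ties -> smaller capacity, then grid order
    best = min(
        range(len(scored)),
        key=lambda i: (
            -scored[i].mean_score,
            model_capacity(space.family, scored[i].params),
            i,
        ),
    )
    return SearchResult(
        best_params=scored[best].params,
        best_score=scored[best].mean_score,
        scores=tuple(scored),
        n_folds=n_folds,
        seed=seed,
    )
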