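"""Repeated-trial benchmark over (model family × fingerprint representation).

This is the experiment the package exists for: featurize a property
dataset under the MACCS, ECFP and conjoint schemes, then for every
requested family × representation pair run ``n_repeats`` independent
random-split trials (default 20) and aggregate RMSE, Pearson r and the
deviation-bin fractions as mean ± sample standard deviation. The
``consensus`` representation trains one model per standalone fingerprint
and averages their predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .evaluate import AggregateReport, aggregate, evaluate_predictions
from .fingerprints import FingerprintSpec, featurize_dataset
from .models import (
    ModelSpec,
    PredictionSet,
    consensus_predict,
    predict,
    train,
    train_consensus,
)
from .records import PropertyDataset
from .splitters import DataSplit, repeated_trials

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkRow", "run_benchmark", "featurize_blocks"]


@dataclass(frozen=True)
class BenchmarkRow:
    """Aggregated result of one family × representation cell."""

    family: str
    representation: str
    report: AggregateReport | None
    failed: bool = False

    def as_dict(self) -> dict[str, Any]:
        if self.failed or self.report is None:
            return {"method": self.family, "fingerprint": self.representation, "status": "failed"}
        m, s = self.report.mean, self.report.std
        return {
            "method": self.family,
            "fingerprint": self.representation,
            "status": "ok",
            "pearson_mean": round(m.pearson, 4),
            "pearson_std": round(s.pearson, 4),
            "rmse_mean": round(m.rmse, 4),
            "rmse_std": round(s.rmse, 4),
            "acceptable_mean": round(m.bin_acceptable, 2),
            "disputable_mean": round(m.bin_disputable, 2),
            "unacceptable_mean": round(m.bin_unacceptable, 2),
            "n_trials": self.report.n_trials,
        }


def featurize_blocks(ds: PropertyDataset, spec: FingerprintSpec | None = None):
    """MACCS and ECFP matrices for a molecule dataset, row-aligned.

    Returns (X_maccs, X_ecfp, ids); the conjoint matrix is their
    horizontal concatenation.
    """
    spec = spec or FingerprintSpec()
    X_m, ids_m, _ = featurize_dataset(ds, FingerprintSpec(scheme="maccs"))
    X_e, ids_e, _ = featurize_dataset(
        ds, FingerprintSpec(scheme="ecfp", ecfp_radius=spec.ecfp_radius, ecfp_nbits=spec.ecfp_nbits)
    )
    if ids_m != ids_e:
        raise RuntimeError("MACCS and ECFP featurization disagree on record set")
    return X_m, X_e, ids_m


def _trial_prediction(
    family: str,
    representation: str,
    X_m: np.ndarray,
    X_e: np.ndarray,
    y: np.ndarray,
    ids: Sequence[str],
    split: DataSplit,
    hyperparams: dict[str, Any],
    seed: int,
) -> PredictionSet:
    tr, va, te = list(split.train_idx), list(split.val_idx), list(split.test_idx)
    test_ids = [ids[i] for i in te]
    if representation == "consensus":
        cm = train_consensus(family, X_m[tr], X_e[tr], y[tr], hyperparams, seed=seed)
        pred = consensus_predict(cm, X_m[te], X_e[te])
        return PredictionSet(ids=test_ids, y_true=y[te], y_pred=pred)
    if representation == "maccs":
        X = X_m
    elif representation == "ecfp":
        X = X_e
    else:
        X = np.hstack([X_m, X_e])
    spec = ModelSpec(family=family, representation=representation, hyperparams=hyperparams, seed=seed)
    model = train(spec, X[tr], y[tr], X_val=X[va] if va else None, y_val=y[va] if va else None)
    return PredictionSet(ids=test_ids, y_true=y[te], y_pred=predict(model, X[te]))


def run_benchmark(
    ds: PropertyDataset,
    families: Sequence[str] = ("rf", "svr", "xgb", "lstm", "dnn"),
    representations: Sequence[str] = ("maccs", "ecfp", "consensus", "conjoint"),
    n_repeats: int = 20,
    base_seed: int = 0,
    test_frac: float = 0.20,
    hyperparams: dict[str, dict[str, Any]] | None = None,
    fingerprint_spec: FingerprintSpec | None = None,
) -> list[BenchmarkRow]:
    """Run the full repeated-trial benchmark on one supervised dataset.

    ``hyperparams`` maps family -> fixed hyperparameter assignment (e.g. a
    set frozen by an earlier grid search and reused across datasets). A
    family failing on every repeat yields a row marked failed; the run
    continues.
    """
    X_m, X_e, ids = featurize_blocks(ds, fingerprint_spec)
    kept = {rid: i for i, rid in enumerate(ids)}
    y = np.array([r.target for r in ds if r.id in kept], dtype=float)
    splits = repeated_trials(len(ids), n_repeats=n_repeats, base_seed=base_seed, test_frac=test_frac)
    rows: list[BenchmarkRow] = []
    for family in families:
        hp = (hyperparams or {}).get(family, {})
        for representation in representations:
            reports = []
            for t, split in enumerate(splits):
                try:
                    pred_set = _trial_prediction(
                        family, representation, X_m, X_e, y, ids, split, hp, seed=base_seed + t
                    )
                    reports.append(evaluate_predictions(pred_set))
                except Exception as exc:
                    logger.warning(
                        "trial %d failed for %s/%s: %s", t, family, representation, exc
                    )
            if reports:
                rows.append(BenchmarkRow(family, representation, aggregate(reports)))
            else:
                rows.append(BenchmarkRow(family, representation, None, failed=True))
    return rows
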