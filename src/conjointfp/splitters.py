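"""Reproducible random and scaffold train/validation/test splits.

The benchmarking protocol holds out 20% of the data as a test set and
splits the remainder 4:1 into training and validation. Random splits are
seeded and fully reproducible; scaffold splits group molecules by their
Bemis--Murcko scaffold (ring systems plus linkers, side chains removed)
and never divide a scaffold group across partitions, so the test set
contains only unseen chemotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .records import PropertyDataset

__all__ = ["DataSplit", "random_split", "scaffold_split", "repeated_trials", "murcko_scaffold"]

DEFAULT_TEST_FRAC = 0.20
DEFAULT_VAL_RATIO = 4  # train:val = 4:1 within the non-test portion


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/validation/test index partitions of a dataset."""

    train_idx: tuple[int, ...]
    val_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    seed: int | None
    method: str  # random | scaffold

    def __post_init__(self) -> None:
        parts = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split partitions overlap")

    @property
    def n(self) -> int:
        return len(self.train_idx) + len(self.val_idx) + len(self.test_idx)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "method": self.method,
                    "seed": self.seed,
                    "train_idx": list(self.train_idx),
                    "val_idx": list(self.val_idx),
                    "test_idx": list(self.test_idx),
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DataSplit":
        d = json.loads(Path(path).read_text())
        return cls(
            train_idx=tuple(d["train_idx"]),
            val_idx=tuple(d["val_idx"]),
            test_idx=tuple(d["test_idx"]),
            seed=d["seed"],
            method=d["method"],
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def random_split(
    ds: PropertyDataset | int,
    test_frac: float = DEFAULT_TEST_FRAC,
    val_ratio: int = DEFAULT_VAL_RATIO,
    seed: int = 0,
) -> DataSplit:
    """Uniform random split: ``test_frac`` held out, remainder train:val = 4:1.

    ``ds`` may be a dataset or a plain record count. Sizes follow
    |test| = round(test_frac * n), |val| = round(remaining / (1 + val_ratio)),
    remainder to train (round = half-up). Same (n, seed, fractions) give
    an identical split.
    """
    n = ds if isinstance(ds, int) else len(ds)
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    if n < 5:
        raise ValueError(f"need at least 5 records to honor both fractions (got {n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = _round_half_up(test_frac * n)
    n_val = _round_half_up((n - n_test) / (1 + val_ratio))
    test = order[:n_test]
    val = order[n_test : n_test + n_val]
    train = order[n_test + n_val :]
    return DataSplit(
        train_idx=tuple(int(i) for i in train),
        val_idx=tuple(int(i) for i in val),
        test_idx=tuple(int(i) for i in test),
        seed=seed,
        method="random",
    )


def murcko_scaffold(smiles: str) -> str:
    """Bemis--Murcko scaffold SMILES; acyclic molecules map to ''."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_split(
    ds: PropertyDataset,
    test_frac: float = DEFAULT_TEST_FRAC,
    val_ratio: int = DEFAULT_VAL_RATIO,
) -> DataSplit:
    """Deterministic scaffold split (no seed).

    Molecules are grouped by Bemis--Murcko scaffold; groups are assigned
    whole — largest first, ties broken by scaffold string — to train until
    its quota is filled, then to validation, then test. No scaffold ever
    spans two partitions, so zero scaffold leakage by construction.
    """
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(ds):
        groups.setdefault(murcko_scaffold(rec.smiles), []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(ds)
    n_test = _round_half_up(test_frac * n)
    n_val = _round_half_up((n - n_test) / (1 + val_ratio))
    n_train = n - n_test - n_val
    train: list[int] = []
    val: list[int] = []
    test: list[int] = []
    for _, idxs in ordered:
        if len(train) + len(idxs) <= n_train or not train:
            train.extend(idxs)
        elif len(val) + len(idxs) <= n_val or not val:
            val.extend(idxs)
        else:
            test.extend(idxs)
    return DataSplit(
        train_idx=tuple(train),
        val_idx=tuple(val),
        test_idx=tuple(test),
        seed=None,
        method="scaffold",
    )


def repeated_trials(
    ds: PropertyDataset | int,
    n_repeats: int = 20,
    base_seed: int = 0,
    test_frac: float = DEFAULT_TEST_FRAC,
    val_ratio: int = DEFAULT_VAL_RATIO,
) -> list[DataSplit]:
    """``n_repeats`` independent random splits with seeds base_seed + i.

    Backs the repeated-trial protocol (default 20 trials) used to quote
    every benchmark metric as mean ± spread across resampled splits.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    return [
        random_split(ds, test_frac=test_frac, val_ratio=val_ratio, seed=base_seed + i)
        for i in range(n_repeats)
    ]
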