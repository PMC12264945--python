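"""Token-pair feature tables and molecule-level splits.

Each eligible residue pair (i, j) of a molecule becomes one sample: its
feature vector is the L*H processed attention values at (i, j)
(layer-major order, names "layer{l}_head{h}"), its label the contact
map entry.  Contact maps are sparse, so training tables are balanced by
randomly undersampling the majority class to the minority count.
Train/test splitting and batching happen at the molecule level so no
pairs from a test molecule ever reach training.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attention import AttentionStack
from .contacts import ContactMap, eligible_pairs
from .errors import (
    AlignmentError,
    BalanceError,
    ConfigError,
    SplitError,
    StateError,
)


@dataclass
class PairDataset:
    """Columnar table of token-pair samples.

    ``features`` is (n_samples, L*H); ``molecule_ids``, ``i``, ``j`` and
    ``labels`` are aligned 1-D arrays.
    """

    molecule_ids: np.ndarray
    i: np.ndarray
    j: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    balanced: bool = False
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.labels)

    def __post_init__(self):
        n = len(self.labels)
        if not (len(self.molecule_ids) == len(self.i) == len(self.j) == n):
            raise AlignmentError("pair dataset columns have unequal lengths")
        if self.features.shape != (n, len(self.feature_names)):
            raise AlignmentError(
                f"feature block {self.features.shape} != ({n}, {len(self.feature_names)})"
            )

    def class_counts(self) -> tuple[int, int]:
        pos = int(self.labels.sum())
        return len(self.labels) - pos, pos

    def subset(self, indices: np.ndarray) -> "PairDataset":
        return PairDataset(
            molecule_ids=self.molecule_ids[indices],
            i=self.i[indices],
            j=self.j[indices],
            features=self.features[indices],
            labels=self.labels[indices],
            feature_names=self.feature_names,
            balanced=self.balanced,
            seed=self.seed,
        )

    def restrict_to_molecules(self, ids: list[str]) -> "PairDataset":
        keep = np.isin(self.molecule_ids, list(ids))
        return self.subset(np.nonzero(keep)[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"molecule_id": self.molecule_ids, "i": self.i, "j": self.j,
             "label": self.labels}
        )
        return pd.concat(
            [df, pd.DataFrame(self.features, columns=self.feature_names)], axis=1
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairDataset":
        df = pd.read_csv(path, sep="\t")
        feature_names = [c for c in df.columns if c.startswith("layer")]
        return cls(
            molecule_ids=df["molecule_id"].to_numpy(dtype=object),
            i=df["i"].to_numpy(dtype=np.int64),
            j=df["j"].to_numpy(dtype=np.int64),
            features=df[feature_names].to_numpy(dtype=np.float64),
            labels=df["label"].to_numpy(dtype=np.int8),
            feature_names=feature_names,
        )

    def content_hash(self) -> str:
        """SHA-256 over the table contents, for training provenance."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.features).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        h.update("\x00".join(map(str, self.molecule_ids.tolist())).encode())
        return h.hexdigest()


@dataclass
class SplitPlan:
    """Molecule-level train/test partition plus nested training batches."""

    train_ids: list[str]
    test_ids: list[str]
    batches: list[list[str]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise SplitError("train and test molecule sets overlap")
        prev: set[str] = set()
        for k, batch in enumerate(self.batches):
            if not prev <= set(batch):
                raise SplitError(f"batch {k} does not contain batch {k - 1}")
            prev = set(batch)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_ids": self.train_ids,
                    "test_ids": self.test_ids,
                    "batches": self.batches,
                    "seed": self.seed,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            train_ids=d["train_ids"],
            test_ids=d["test_ids"],
            batches=d.get("batches", []),
            seed=d.get("seed"),
        )


def feature_names(n_layers: int, n_heads: int) -> list[str]:
    return [
        f"layer{l}_head{h}" for l in range(n_layers) for h in range(n_heads)
    ]


def build_pair_dataset(
    stacks: list[AttentionStack],
    maps: list[ContactMap],
    window: int,
) -> PairDataset:
    """One sample per eligible pair (i < j, j - i > window) per molecule.

    Stacks must be processed (symmetrized + APC); labels come from the
    aligned contact maps.  The result is unbalanced.
    """
    if len(stacks) != len(maps):
        raise AlignmentError(f"{len(stacks)} stacks but {len(maps)} maps")
    mol_ids: list[np.ndarray] = []
    iis: list[np.ndarray] = []
    jjs: list[np.ndarray] = []
    feats: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    names: list[str] | None = None
    for stack, cmap in zip(stacks, maps):
        if not stack.processed:
            raise StateError(
                f"stack {stack.molecule_id} is unprocessed; run process_stack first"
            )
        if stack.n != cmap.n:
            raise AlignmentError(
                f"molecule {stack.molecule_id}: stack length {stack.n} != map {cmap.n}"
            )
        if names is None:
            names = feature_names(stack.n_layers, stack.n_heads)
        ii, jj = eligible_pairs(cmap.n, window)
        if ii.size == 0:
            continue
        # (L, H, P) -> (P, L*H), layer-major feature order
        block = stack.weights[:, :, ii, jj].reshape(len(names), -1).T
        mol_ids.append(np.full(ii.size, stack.molecule_id, dtype=object))
        iis.append(ii)
        jjs.append(jj)
        feats.append(block)
        labels.append(cmap.matrix[ii, jj].astype(np.int8))

    if names is None:
        raise AlignmentError("empty molecule set")
    if not feats:
        warnings.warn(
            f"no eligible pairs at window {window}; dataset is empty", stacklevel=2
        )
        return PairDataset(
            molecule_ids=np.empty(0, dtype=object),
            i=np.empty(0, dtype=np.int64),
            j=np.empty(0, dtype=np.int64),
            features=np.empty((0, len(names))),
            labels=np.empty(0, dtype=np.int8),
            feature_names=names,
        )
    return PairDataset(
        molecule_ids=np.concatenate(mol_ids),
        i=np.concatenate(iis).astype(np.int64),
        j=np.concatenate(jjs).astype(np.int64),
        features=np.vstack(feats),
        labels=np.concatenate(labels),
        feature_names=names,
    )


def balance_dataset(ds: PairDataset, seed: int) -> PairDataset:
    """Randomly undersample the majority class to the minority count.

    Minority samples are never discarded; the result has an exact 1:1
    class ratio and is deterministic for a fixed seed.
    """
    neg, pos = ds.class_counts()
    if neg == 0 or pos == 0:
        raise BalanceError(
            f"cannot balance a single-class dataset (neg={neg}, pos={pos})"
        )
    if neg == pos:
        out = ds.subset(np.arange(len(ds)))
        out.balanced, out.seed = True, seed
        return out
    rng = np.random.default_rng(seed)
    minority_label = 1 if pos < neg else 0
    minority = np.nonzero(ds.labels == minority_label)[0]
    majority = np.nonzero(ds.labels != minority_label)[0]
    kept = rng.choice(majority, size=len(minority), replace=False)
    indices = np.sort(np.concatenate([minority, kept]))
    out = ds.subset(indices)
    out.balanced, out.seed = True, seed
    return out


def split_molecules(
    ids: list[str], test_fraction: float, seed: int
) -> SplitPlan:
    """Molecule-level train/test split.

    The test set holds floor(test_fraction * n) molecules (at least 1),
    e.g. 425 molecules at 0.15 give 362 train / 63 test.
    """
    if not 0 < test_fraction < 1:
        raise SplitError(f"test_fraction must be in (0, 1), got {test_fraction}")
    if len(ids) < 2:
        raise SplitError(f"need at least 2 molecule ids, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise SplitError("duplicate molecule ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_test = max(1, int(test_fraction * len(ids)))
    test = sorted(ids[k] for k in order[:n_test])
    train = sorted(ids[k] for k in order[n_test:])
    return SplitPlan(train_ids=train, test_ids=test, seed=seed)


def default_batch_schedule(n_train: int, n_batches: int = 5, start: int = 20) -> list[int]:
    """Geometric interpolation from ``start`` molecules to the full set."""
    if n_train <= start:
        return [n_train]
    sizes = np.unique(
        np.round(
            np.geomspace(start, n_train, num=n_batches)
        ).astype(int)
    )
    return sizes.tolist()


def make_training_batches(
    train_ids: list[str], schedule: list[int], seed: int
) -> list[list[str]]:
    """Nested training subsets of the requested sizes.

    Batch k+1 contains batch k; the final batch equals the whole
    training set when the schedule ends with len(train_ids).
    """
    if any(b >= a for a, b in zip(schedule[1:], schedule[:-1])):
        raise ConfigError(f"batch schedule must be strictly ascending: {schedule}")
    if not schedule:
        raise ConfigError("empty batch schedule")
    if schedule[-1] > len(train_ids):
        raise ConfigError(
            f"largest batch {schedule[-1]} exceeds training set size {len(train_ids)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_ids))
    return [[train_ids[k] for k in order[:size]] for size in schedule]
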