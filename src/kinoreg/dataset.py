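"""Pair dataset assembly, splitting and mid-range oversampling.

Each kinase-compound pair becomes one design-matrix row: the 8,551-element
kinase vector followed by the compound descriptor vector with that pair's
(transformed) assay concentration appended — 11,308 columns at canonical
widths.  Rows are split 6:2:2 into train/validation/test at the pair level,
and random oversampling (ROS) duplicates mid-range training rows (percent
inhibition in the closed interval [1, 99]) so the sparse middle of the
bimodal target distribution is not swamped by the extremes.  Extreme rows
are never duplicated and validation/test rows are never touched.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .compound_features import ConcTransform, transform_concentration
from .errors import ConfigurationError, ValidationError

SPLIT_LABELS = ("train", "val", "test")


@dataclass
class PairDataset:
    """Assembled design matrix with targets, identifiers and split labels."""

    X: np.ndarray
    y: np.ndarray
    kinase_id: np.ndarray
    compound_id: np.ndarray
    feature_names: list[str]
    split: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.y)
        if self.X.shape != (n, len(self.feature_names)):
            raise ValidationError(
                f"X shape {self.X.shape} inconsistent with {n} targets and "
                f"{len(self.feature_names)} feature names"
            )
        if np.any((self.y < 0) | (self.y > 100)):
            raise ValidationError("percent inhibition outside [0, 100]")
        self.kinase_id = np.asarray(self.kinase_id, dtype=object)
        self.compound_id = np.asarray(self.compound_id, dtype=object)
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            bad = set(self.split) - set(SPLIT_LABELS)
            if bad:
                raise ValidationError(f"unknown split labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def rows(self, split: str) -> np.ndarray:
        if self.split is None:
            raise ValidationError("dataset has no split labels; call split_dataset first")
        if split not in SPLIT_LABELS:
            raise ValidationError(f"unknown split {split!r}")
        return np.flatnonzero(self.split == split)

    def subset(self, split: str) -> "PairDataset":
        idx = self.rows(split)
        if idx.size == 0:
            raise ValidationError(f"split {split!r} is empty")
        return self.take(idx)

    def take(self, idx: np.ndarray) -> "PairDataset":
        return PairDataset(
            X=self.X[idx],
            y=self.y[idx],
            kinase_id=self.kinase_id[idx],
            compound_id=self.compound_id[idx],
            feature_names=list(self.feature_names),
            split=None if self.split is None else self.split[idx],
        )


def assemble_pairs(
    pairs: pd.DataFrame,
    kinase_features: pd.DataFrame,
    compound_descriptors: pd.DataFrame,
    conc_transform: ConcTransform = "neg_log10",
) -> PairDataset:
    """Join per-entity feature tables into one design matrix, in pair order.

    ``pairs`` needs columns kinase_id, compound_id, concentration,
    percent_inhibition; ``kinase_features`` and ``compound_descriptors``
    are indexed by the respective ids.  Row i is the concatenation of the
    kinase vector and the compound descriptor vector with that pair's
    transformed concentration as the final element.
    """
    required = {"kinase_id", "compound_id", "concentration", "percent_inhibition"}
    missing_cols = required - set(pairs.columns)
    if missing_cols:
        raise ValidationError(f"pairs table missing columns: {sorted(missing_cols)}")
    y = pairs["percent_inhibition"].to_numpy(dtype=float)
    if np.any((y < 0) | (y > 100)):
        raise ValidationError("percent inhibition outside [0, 100] in pairs table")

    missing_k = sorted(set(pairs["kinase_id"]) - set(kinase_features.index))
    missing_c = sorted(set(pairs["compound_id"]) - set(compound_descriptors.index))
    if missing_k or missing_c:
        raise ValidationError(
            f"unresolvable ids — kinases: {missing_k[:10]}, compounds: {missing_c[:10]}"
        )

    Xk = kinase_features.loc[pairs["kinase_id"]].to_numpy(dtype=float)
    Xc = compound_descriptors.loc[pairs["compound_id"]].to_numpy(dtype=float)
    conc = transform_concentration(pairs["concentration"].to_numpy(dtype=float), conc_transform)
    X = np.hstack([Xk, Xc, np.asarray(conc, dtype=float)[:, None]])

    feature_names = (
        [str(c) for c in kinase_features.columns]
        + [str(c) for c in compound_descriptors.columns]
        + ["concentration"]
    )
    return PairDataset(
        X=X,
        y=y,
        kinase_id=pairs["kinase_id"].to_numpy(dtype=object),
        compound_id=pairs["compound_id"].to_numpy(dtype=object),
        feature_names=feature_names,
    )


def split_dataset(
    ds: PairDataset,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    group_by: str | None = None,
) -> PairDataset:
    """Shuffle rows by ``seed`` and label them train/val/test.

    Validation and test sizes are ``round(ratio * n)``; the remainder is
    training, so the three partitions always sum to ``n``.  The default
    split unit is the pair (row).  ``group_by='kinase'`` or
    ``'compound'`` keeps all pairs of an entity in one partition
    (leakage-aware split); partition sizes are then only approximate
    because whole groups are assigned.
    """
    if len(ratios) != 3 or any(r < 0 for r in ratios) or not math.isclose(sum(ratios), 1.0):
        raise ConfigurationError(f"ratios must be 3 nonnegative values summing to 1, got {ratios}")
    n = len(ds)
    if n < 3:
        raise ValidationError(f"need >= 3 rows to split, got {n}")
    n_val = int(round(ratios[1] * n))
    n_test = int(round(ratios[2] * n))
    if n_val + n_test > n:
        raise ConfigurationError("val + test rounding exceeds dataset size")
    rng = np.random.default_rng(seed)
    if group_by is None:
        perm = rng.permutation(n)
    elif group_by in ("kinase", "compound"):
        ids = ds.kinase_id if group_by == "kinase" else ds.compound_id
        groups = pd.unique(ids)
        order = rng.permutation(len(groups))
        perm = np.concatenate([np.flatnonzero(ids == groups[g]) for g in order])
    else:
        raise ConfigurationError(f"group_by must be 'kinase' or 'compound', got {group_by!r}")
    split = np.empty(n, dtype=object)
    split[perm[: n - n_val - n_test]] = "train"
    split[perm[n - n_val - n_test : n - n_test]] = "val"
    split[perm[n - n_test :]] = "test"
    if group_by is not None:
        # whole-group assignment: move any straddling group to where its majority sits
        ids = ds.kinase_id if group_by == "kinase" else ds.compound_id
        frame = pd.DataFrame({"id": ids, "split": split})
        majority = frame.groupby("id")["split"].agg(lambda s: s.value_counts().idxmax())
        split = majority.loc[frame["id"]].to_numpy(dtype=object)
    return replace(ds, split=split)


def ros_balance(
    ds: PairDataset,
    low_cut: float = 1.0,
    high_cut: float = 99.0,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> PairDataset:
    """Random oversampling of mid-range training rows.

    Training rows with ``low_cut <= y <= high_cut`` are duplicated with
    replacement until their count reaches ``ceil(target_ratio * n_extreme)``
    (never below the original count); extreme training rows (y < low_cut or
    y > high_cut) appear exactly once and validation/test rows are
    untouched.  Duplicates are appended after the original rows.
    """
    if target_ratio <= 0:
        raise ConfigurationError(f"target_ratio must be > 0, got {target_ratio}")
    if not low_cut < high_cut:
        raise ConfigurationError("low_cut must be < high_cut")
    if ds.split is None:
        raise ValidationError("ros_balance requires a split dataset (train rows only are resampled)")

    train_idx = ds.rows("train")
    y_train = ds.y[train_idx]
    mid_mask = (y_train >= low_cut) & (y_train <= high_cut)
    mid_idx = train_idx[mid_mask]
    n_extreme = int((~mid_mask).sum())
    if mid_idx.size == 0:
        warnings.warn("ros_balance: no mid-range training rows; returning input unchanged",
                      stacklevel=2)
        return ds
    target = max(mid_idx.size, math.ceil(target_ratio * n_extreme))
    n_add = target - mid_idx.size
    if n_add == 0:
        return ds
    rng = np.random.default_rng(seed)
    extra = rng.choice(mid_idx, size=n_add, replace=True)
    keep = np.arange(len(ds))
    idx = np.concatenate([keep, extra])
    out = ds.take(idx)
    out.split = np.concatenate([ds.split, np.full(n_add, "train", dtype=object)])
    return out


# ---------------------------------------------------------------------------
# bundle IO


def save_dataset(ds: PairDataset, outdir: str | Path) -> None:
    """Write a dataset bundle: X.npz, meta.csv (y/split/ids), feature_names.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(outdir / "X.npz", X=ds.X)
    meta = pd.DataFrame(
        {
            "kinase_id": ds.kinase_id,
            "compound_id": ds.compound_id,
            "percent_inhibition": ds.y,
            "split": ds.split if ds.split is not None else [""] * len(ds),
        }
    )
    meta.to_csv(outdir / "meta.csv", index=False)
    (outdir / "feature_names.json").write_text(json.dumps(ds.feature_names))


def load_dataset(indir: str | Path) -> PairDataset:
    indir = Path(indir)
    X = np.load(indir / "X.npz")["X"]
    meta = pd.read_csv(indir / "meta.csv")
    names = json.loads((indir / "feature_names.json").read_text())
    split = meta["split"].astype(str).to_numpy(dtype=object)
    has_split = set(split) <= set(SPLIT_LABELS) and len(set(split)) > 0
    return PairDataset(
        X=X,
        y=meta["percent_inhibition"].to_numpy(dtype=float),
        kinase_id=meta["kinase_id"].to_numpy(dtype=object),
        compound_id=meta["compound_id"].to_numpy(dtype=object),
        feature_names=list(names),
        split=split if has_split else None,
    )
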