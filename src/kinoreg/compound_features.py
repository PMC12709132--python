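"""Compound featurization.

A compound enters the model as a 2,757-element vector: a fixed-width
molecular-descriptor vector (2,756 columns in the canonical PaDEL-style
layout) with the assay concentration appended as the final element.
Descriptors are consumed from a precomputed table, not computed here; any
provider that yields a fixed-width vector can stand behind
:func:`load_descriptor_table`'s output format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: canonical descriptor width (PaDEL-style 2D descriptors + fingerprints)
DESCRIPTOR_WIDTH = 2756
#: descriptor width plus the concentration element
COMPOUND_FEATURE_LENGTH = DESCRIPTOR_WIDTH + 1

ConcTransform = Literal["identity", "log10", "neg_log10"]


@dataclass
class CompoundRecord:
    """One compound: identifier, optional SMILES, descriptors, assay concentration (molar)."""

    compound_id: str
    descriptors: np.ndarray
    concentration: float
    smiles: str | None = None
    expected_width: int = DESCRIPTOR_WIDTH

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        if self.descriptors.shape != (self.expected_width,):
            raise ValidationError(
                f"{self.compound_id}: descriptor vector has width "
                f"{self.descriptors.shape}, expected ({self.expected_width},)"
            )
        if not np.all(np.isfinite(self.descriptors)):
            raise ValidationError(f"{self.compound_id}: non-finite descriptor values")
        if not self.concentration > 0:
            raise ValidationError(
                f"{self.compound_id}: concentration must be > 0 (molar), got {self.concentration}"
            )


def load_descriptor_table(
    path: str | Path, expected_width: int = DESCRIPTOR_WIDTH
) -> tuple[pd.DataFrame, dict]:
    """Load a descriptor CSV (first column compound_id, header row).

    Missing cells are imputed to the column median (0 if a column is
    entirely missing).  Returns the imputed table indexed by compound_id
    plus an imputation report ``{column: n_imputed}``.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: descriptor table has no data rows")
    id_col = df.columns[0]
    df = df.set_index(id_col)
    df.index.name = "compound_id"
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate compound_id values: {dupes}")
    if df.shape[1] != expected_width:
        raise ValidationError(
            f"{path}: descriptor width mismatch: observed {df.shape[1]}, expected {expected_width}"
        )
    df = df.astype(float)
    report: dict[str, int] = {}
    n_missing = df.isna().sum()
    for col in df.columns[n_missing.to_numpy() > 0]:
        median = df[col].median()
        fill = 0.0 if np.isnan(median) else float(median)
        report[col] = int(n_missing[col])
        df[col] = df[col].fillna(fill)
    if report:
        logger.info("imputed %d cells across %d descriptor columns", sum(report.values()), len(report))
    return df, report


def records_from_table(
    descriptors: pd.DataFrame,
    concentrations: pd.Series,
    smiles: pd.Series | None = None,
) -> list[CompoundRecord]:
    """Join a descriptor table with per-compound concentrations into records."""
    missing = [str(c) for c in descriptors.index if c not in concentrations.index]
    if missing:
        raise ValidationError(f"no concentration for compounds: {missing[:10]}")
    return [
        CompoundRecord(
            compound_id=str(cid),
            descriptors=descriptors.loc[cid].to_numpy(),
            concentration=float(concentrations.loc[cid]),
            smiles=None if smiles is None else smiles.get(cid),
            expected_width=descriptors.shape[1],
        )
        for cid in descriptors.index
    ]


def transform_concentration(conc: float | np.ndarray, transform: ConcTransform) -> float | np.ndarray:
    """Apply the configured concentration encoding (concentration in molar)."""
    conc = np.asarray(conc, dtype=float)
    if transform == "identity":
        out = conc
    elif transform in ("log10", "neg_log10"):
        if np.any(conc <= 0):
            raise ValidationError("non-positive concentration with a log transform")
        out = np.log10(conc)
        if transform == "neg_log10":
            out = -out
    else:
        raise ValidationError(f"unknown concentration transform {transform!r}")
    return float(out) if out.ndim == 0 else out


def featurize_compound(rec: CompoundRecord, conc_transform: ConcTransform = "neg_log10") -> np.ndarray:
    """Descriptor vector with the transformed concentration appended (width + 1)."""
    conc = transform_concentration(rec.concentration, conc_transform)
    return np.concatenate([rec.descriptors, [conc]])


def compound_feature_names(descriptor_names: list[str]) -> list[str]:
    """Column names of the compound feature vector (descriptors + 'concentration')."""
    return [str(n) for n in descriptor_names] + ["concentration"]


def featurize_compounds(
    records: list[CompoundRecord],
    descriptor_names: list[str] | None = None,
    conc_transform: ConcTransform = "neg_log10",
) -> pd.DataFrame:
    """Feature matrix (compound_id x width+1) for a collection of records."""
    if not records:
        raise ValidationError("no compound records supplied")
    width = records[0].expected_width
    if descriptor_names is None:
        descriptor_names = [f"d{i}" for i in range(width)]
    mat = np.stack([featurize_compound(r, conc_transform) for r in records])
    df = pd.DataFrame(
        mat,
        index=pd.Index([r.compound_id for r in records], name="compound_id"),
        columns=compound_feature_names(descriptor_names),
    )
    return df
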