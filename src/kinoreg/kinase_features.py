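"""Kinase pocket featurization.

A kinase binding pocket is summarised as a fixed-length vector of 8,551
values built from four ingredients:

* the pocket amino-acid sequence — residue composition (20 values) and
  overlapping 3-mer frequencies (20^3 = 8,000 values);
* the per-residue 8-state secondary structure string (DSSP states
  G, H, I, T, E, B, S, C) — composition (8) and 3-mers (8^3 = 512);
* the per-residue solvent-exposure state, obtained by thresholding
  relative solvent accessibility (RSA >= 0.5 -> exposed ``E``, else
  buried ``B``) — composition (2) and 3-mers (2^3 = 8);
* the pocket volume in cubic angstroms (1 value).

All "frequencies" are relative: counts divided by the number of valid
residues (composition blocks) or valid windows (3-mer blocks), so vectors
are comparable across pockets of different length.  k-mer blocks are
indexed lexicographically over a fixed alphabet ordering (amino acids
``ACDEFGHIKLMNPQRSTVWY``, secondary structure ``GHITEBSC``, exposure
``EB``) so that the layout is reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
SS8_ALPHABET = "GHITEBSC"
EXPOSURE_ALPHABET = "EB"

#: Total length of the kinase feature vector.
KINASE_FEATURE_LENGTH = 8551

#: (name, length) of each block, in vector order.
KINASE_FEATURE_BLOCKS = (
    ("aa_freq", 20),
    ("aa_3mer", 8000),
    ("ss_freq", 8),
    ("ss_3mer", 512),
    ("exp_freq", 2),
    ("exp_3mer", 8),
    ("pocket_volume", 1),
)

RSA_EXPOSED_THRESHOLD = 0.5


def _load_max_asa() -> dict[str, float]:
    with resources.files("kinoreg.data").joinpath("max_asa.json").open() as fh:
        table = json.load(fh)
    return {k: float(v) for k, v in table.items() if len(k) == 1}


#: Per-residue maximal (ideal) accessible surface area in A^2, used to
#: convert absolute ASA to RSA.  Overridable in :func:`parse_dssp_output`.
MAX_ASA: dict[str, float] = _load_max_asa()


# ---------------------------------------------------------------------------
# feature names


def kmer_names(alphabet: str, k: int) -> list[str]:
    """All k-mers over ``alphabet`` in lexicographic order of the alphabet."""
    return ["".join(p) for p in product(alphabet, repeat=k)]


def kinase_feature_names() -> list[str]:
    """Column names for the 8,551-element kinase vector, in block order."""
    names: list[str] = []
    names += [f"aa_{a}" for a in AA_ALPHABET]
    names += [f"aa3_{m}" for m in kmer_names(AA_ALPHABET, 3)]
    names += [f"ss_{s}" for s in SS8_ALPHABET]
    names += [f"ss3_{m}" for m in kmer_names(SS8_ALPHABET, 3)]
    names += [f"exp_{e}" for e in EXPOSURE_ALPHABET]
    names += [f"exp3_{m}" for m in kmer_names(EXPOSURE_ALPHABET, 3)]
    names.append("pocket_volume")
    assert len(names) == KINASE_FEATURE_LENGTH
    return names


# ---------------------------------------------------------------------------
# core operations


def residue_frequencies(s: str, alphabet: str) -> np.ndarray:
    """Relative frequency of each alphabet symbol in ``s``.

    Symbols outside ``alphabet`` are dropped from both numerator and
    denominator (their count is logged).  Returns the all-zero vector with
    a warning if nothing remains.
    """
    index = {c: i for i, c in enumerate(alphabet)}
    counts = np.zeros(len(alphabet))
    n_removed = 0
    for c in s:
        i = index.get(c)
        if i is None:
            n_removed += 1
        else:
            counts[i] += 1
    if n_removed:
        logger.warning("residue_frequencies: dropped %d symbols outside alphabet", n_removed)
    total = counts.sum()
    if total == 0:
        warnings.warn("residue_frequencies: no valid symbols; returning zeros", stacklevel=2)
        return counts
    return counts / total


def kmer_frequencies(s: str, alphabet: str, k: int) -> np.ndarray:
    """Relative frequencies of overlapping k-mers of ``s``.

    The output is indexed by all len(alphabet)**k k-mers in lexicographic
    order of the supplied alphabet.  Windows containing a symbol outside
    the alphabet are skipped; frequencies are normalised by the number of
    valid windows.  If no valid window exists (including ``len(s) < k``),
    the all-zero vector is returned with a warning.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    base = len(alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    counts = np.zeros(base**k)
    n_windows = 0
    for start in range(len(s) - k + 1):
        idx = 0
        valid = True
        for c in s[start : start + k]:
            i = index.get(c)
            if i is None:
                valid = False
                break
            idx = idx * base + i
        if valid:
            counts[idx] += 1
            n_windows += 1
    if n_windows == 0:
        warnings.warn(
            f"kmer_frequencies: no valid {k}-mer window (len={len(s)}); returning zeros",
            stacklevel=2,
        )
        return counts
    return counts / n_windows


def classify_exposure(rsa: Sequence[float]) -> str:
    """Map per-residue RSA values to exposure states.

    A residue with RSA >= 0.5 is exposed (``E``), otherwise buried (``B``);
    the boundary value 0.5 counts as exposed.
    """
    out = []
    for pos, v in enumerate(rsa):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"RSA value {v!r} at position {pos} outside [0, 1]")
        out.append("E" if v >= RSA_EXPOSED_THRESHOLD else "B")
    return "".join(out)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PocketAnnotation:
    """Per-residue annotation of one kinase binding pocket."""

    kinase_id: str
    sequence: str
    ss8: str
    rsa: np.ndarray
    pocket_volume: float

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.ss8 = self.ss8.upper()
        self.rsa = np.asarray(self.rsa, dtype=float)
        n = len(self.sequence)
        if n < 3:
            raise ValidationError(f"{self.kinase_id}: pocket must have >= 3 residues, got {n}")
        if len(self.ss8) != n or len(self.rsa) != n:
            raise ValidationError(
                f"{self.kinase_id}: length mismatch among sequence ({n}), "
                f"ss8 ({len(self.ss8)}) and rsa ({len(self.rsa)})"
            )
        if not self.pocket_volume > 0:
            raise ValidationError(f"{self.kinase_id}: pocket_volume must be > 0")
        bad = set(self.ss8) - set(SS8_ALPHABET)
        if bad:
            raise ValidationError(f"{self.kinase_id}: ss8 symbols outside GHITEBSC: {sorted(bad)}")
        if np.any((self.rsa < 0) | (self.rsa > 1)):
            raise ValidationError(f"{self.kinase_id}: RSA values outside [0, 1]")

    @property
    def exposure(self) -> str:
        return classify_exposure(self.rsa)


@dataclass
class KinaseFeatureVector:
    """The ordered 8,551-element kinase feature vector with named blocks."""

    kinase_id: str
    values: np.ndarray
    feature_names: list[str] = field(default_factory=kinase_feature_names, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (KINASE_FEATURE_LENGTH,):
            raise ValidationError(
                f"kinase feature vector must have length {KINASE_FEATURE_LENGTH}, "
                f"got {self.values.shape}"
            )

    def block(self, name: str) -> np.ndarray:
        """Return one named block of the vector (a view)."""
        start = 0
        for bname, blen in KINASE_FEATURE_BLOCKS:
            if bname == name:
                return self.values[start : start + blen]
            start += blen
        raise KeyError(name)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.feature_names, name=self.kinase_id)


def featurize_kinase(p: PocketAnnotation) -> KinaseFeatureVector:
    """Compute the full 8,551-element feature vector for one pocket."""
    exposure = p.exposure
    parts = [
        residue_frequencies(p.sequence, AA_ALPHABET),
        kmer_frequencies(p.sequence, AA_ALPHABET, 3),
        residue_frequencies(p.ss8, SS8_ALPHABET),
        kmer_frequencies(p.ss8, SS8_ALPHABET, 3),
        residue_frequencies(exposure, EXPOSURE_ALPHABET),
        kmer_frequencies(exposure, EXPOSURE_ALPHABET, 3),
        np.array([p.pocket_volume]),
    ]
    return KinaseFeatureVector(p.kinase_id, np.concatenate(parts))


def featurize_kinases(annotations: Iterable[PocketAnnotation]) -> pd.DataFrame:
    """Feature matrix (kinase_id x 8,551) for a collection of pockets."""
    rows = [featurize_kinase(p).to_series() for p in annotations]
    if not rows:
        raise ValidationError("no pocket annotations supplied")
    df = pd.DataFrame(rows)
    df.index.name = "kinase_id"
    return df


# ---------------------------------------------------------------------------
# input parsing

# DSSP residue codes: lowercase letters denote disulfide-bonded cysteines.
_DSSP_HEADER = "#  RESIDUE AA STRUCTURE"
# states some DSSP builds emit that we fold into coil
_SS8_NORMALISE = {" ": "C", "-": "C", "P": "C", "~": "C"}


def normalize_ss8(symbol: str) -> str:
    """Map a raw DSSP structure symbol onto the 8-letter alphabet.

    Blank / ``-`` (no assignment) and ``P`` (polyproline II, emitted by
    newer DSSP versions) are folded into coil ``C``.
    """
    s = _SS8_NORMALISE.get(symbol, symbol)
    if s not in SS8_ALPHABET:
        raise ValidationError(f"unknown secondary-structure symbol {symbol!r}")
    return s


def parse_dssp_output(
    path: str | Path,
    max_asa: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Read per-residue (aa, ss8, rsa) records from a file.

    Two layouts are auto-detected:

    * classic DSSP output (fixed-column; ASA is converted to RSA using the
      ``max_asa`` reference table, clipped to [0, 1]);
    * the package's TSV annotation layout with columns
      ``kinase_id  position  aa  ss8  rsa``.

    Returns a DataFrame with columns kinase_id, position, aa, ss8, rsa.
    Residues with unknown one-letter codes are skipped with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if _DSSP_HEADER in text:
        return _parse_classic_dssp(path, text, max_asa or MAX_ASA)
    return _parse_annotation_tsv(path, text)


def _parse_classic_dssp(path: Path, text: str, max_asa: Mapping[str, float]) -> pd.DataFrame:
    lines = text.splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if _DSSP_HEADER in ln) + 1
    except StopIteration:  # pragma: no cover - guarded by caller
        raise ValidationError(f"{path}: no DSSP residue header found")
    records = []
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        if not ln.strip():
            continue
        aa = ln[13] if len(ln) > 13 else "!"
        if aa == "!":  # chain break
            continue
        if aa.islower():  # SS-bonded cysteine
            aa = "C"
        try:
            position = int(ln[0:5])
            ss_raw = ln[16] if len(ln) > 16 else " "
            asa = float(ln[34:38])
        except (ValueError, IndexError):
            raise ValidationError(f"{path}:{lineno}: unparseable DSSP line: {ln!r}")
        if aa not in AA_ALPHABET:
            warnings.warn(f"{path}:{lineno}: unknown residue code {aa!r}; skipped", stacklevel=3)
            continue
        rsa = min(1.0, max(0.0, asa / max_asa[aa]))
        records.append((path.stem, position, aa, normalize_ss8(ss_raw), rsa))
    return pd.DataFrame(records, columns=["kinase_id", "position", "aa", "ss8", "rsa"])


def _parse_annotation_tsv(path: Path, text: str) -> pd.DataFrame:
    records = []
    for lineno, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split()
        if fields[0] == "kinase_id":  # header row
            continue
        if len(fields) != 5:
            raise ValidationError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        kid, pos, aa, ss8, rsa = fields
        if aa.upper() not in AA_ALPHABET:
            warnings.warn(f"{path}:{lineno}: unknown residue code {aa!r}; skipped", stacklevel=3)
            continue
        try:
            records.append((kid, int(pos), aa.upper(), normalize_ss8(ss8.upper()), float(rsa)))
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: unparseable annotation line: {ln!r}")
    return pd.DataFrame(records, columns=["kinase_id", "position", "aa", "ss8", "rsa"])


def annotations_from_table(
    table: pd.DataFrame, volumes: Mapping[str, float]
) -> list[PocketAnnotation]:
    """Assemble :class:`PocketAnnotation` objects from a per-residue table.

    ``table`` must have columns kinase_id, position, aa, ss8, rsa (as
    produced by :func:`parse_dssp_output`); ``volumes`` maps kinase_id to
    pocket volume.
    """
    out = []
    for kid, grp in table.groupby("kinase_id", sort=True):
        grp = grp.sort_values("position")
        if kid not in volumes:
            raise ValidationError(f"no pocket volume for kinase {kid!r}")
        out.append(
            PocketAnnotation(
                kinase_id=str(kid),
                sequence="".join(grp["aa"]),
                ss8="".join(grp["ss8"]),
                rsa=grp["rsa"].to_numpy(),
                pocket_volume=float(volumes[kid]),
            )
        )
    return out


def load_annotations(annotations_path: str | Path, volumes_path: str | Path) -> list[PocketAnnotation]:
    """Load pockets from an annotation TSV plus a volumes TSV (kinase_id, pocket_volume)."""
    table = parse_dssp_output(annotations_path)
    vol = pd.read_csv(volumes_path, sep="\t")
    volumes = dict(zip(vol["kinase_id"].astype(str), vol["pocket_volume"].astype(float)))
    return annotations_from_table(table, volumes)
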