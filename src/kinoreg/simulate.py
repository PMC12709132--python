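"""Synthetic kinase-inhibition data generator.

Emulates the statistical structure of a KINOMEscan-style percent-inhibition
screen — a 234-kinase x 163-compound panel with roughly half the grid
measured (~18,771 pairs) and a bimodal target distribution concentrated at
the 0% and 100% extremes with a sparse mid-range — while planting a
learnable kinase x compound interaction signal whose ground truth is kept
alongside the data.

The generative model per pair (kinase i, compound j)::

    y_ij = clamp( base_ij + s * (u_i . v_j + c * logconc_j) + eps ,  0, 100)

where ``base`` is a three-component mixture (point mass at 0, point mass at
100, Beta(2,2) rescaled to (1, 99)), ``s`` is the signal strength, ``u_i``
and ``v_j`` are latent vectors, ``logconc`` is the standardized log10 assay
concentration and ``eps`` is Gaussian noise.  Crucially the latents are
*observable*: ``u_i`` is a seeded random projection of the pocket's
amino-acid composition (plus a constant coordinate) and ``v_j`` is read off
designated continuous descriptor columns (plus a constant coordinate), so
the dot product decomposes into kinase main effect + compound main effect +
interaction and a regressor on the features can in principle recover it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .kinase_features import AA_ALPHABET, SS8_ALPHABET, PocketAnnotation, residue_frequencies

# grid scale of the emulated screen: 234 x 163 with ~18,771 measured pairs
_PAPER_GRID = 234 * 163
_PAPER_PAIRS = 18771


@dataclass
class SimConfig:
    """Configuration of the synthetic screen.

    Defaults emulate the real panel's scale: 234 kinases x 163 compounds
    with ~49.2% of the grid measured, and a strongly bimodal target with
    40% of base mass at each extreme.
    """

    n_kinases: int = 234
    n_compounds: int = 163
    pair_fraction: float = _PAPER_PAIRS / _PAPER_GRID
    pocket_length_range: tuple[int, int] = (20, 40)
    extreme_low_weight: float = 0.4
    extreme_high_weight: float = 0.4
    signal_strength: float = 10.0
    noise_sd: float = 5.0
    seed: int = 0
    # latent structure of the planted signal
    latent_dim: int = 2          # interaction dimensions (main effects are extra)
    concentration_coeff: float = 0.5
    conc_range: tuple[float, float] = (1e-9, 1e-5)  # molar, log-uniform

    def __post_init__(self) -> None:
        if self.n_kinases < 1 or self.n_compounds < 1:
            raise ConfigurationError("n_kinases and n_compounds must be >= 1")
        if not 0 < self.pair_fraction <= 1:
            raise ConfigurationError("pair_fraction must be in (0, 1]")
        lo, hi = self.pocket_length_range
        if lo < 3 or hi < lo:
            raise ConfigurationError(
                f"pocket_length_range must satisfy 3 <= min <= max, got ({lo}, {hi})"
            )
        if self.extreme_low_weight < 0 or self.extreme_high_weight < 0:
            raise ConfigurationError("mixture weights must be nonnegative")
        if self.extreme_low_weight + self.extreme_high_weight >= 1 + 1e-12:
            # equality is tolerated so a pure two-point mixture is expressible
            if self.extreme_low_weight + self.extreme_high_weight > 1:
                raise ConfigurationError("extreme weights must sum to <= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.signal_strength < 0:
            raise ConfigurationError("signal_strength must be >= 0")
        if self.latent_dim < 0:
            raise ConfigurationError("latent_dim must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generator stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class SimulatedCompounds:
    """Descriptor table (compound_id x n_descriptors) with per-compound assay concentrations."""

    descriptors: pd.DataFrame
    concentrations: pd.Series

    @property
    def continuous_columns(self) -> list[str]:
        """Columns generated as continuous (non-binary) descriptors."""
        desc = self.descriptors
        return [c for c in desc.columns if not set(np.unique(desc[c])) <= {0.0, 1.0}]


@dataclass
class SyntheticTruth:
    """Ground truth of the planted signal, stored alongside the generated data."""

    kinase_latents: dict[str, list[float]]
    compound_latents: dict[str, list[float]]
    concentration_coeff: float
    generating_function: dict
    pair_scores: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def driver_feature_names(self) -> list[str]:
        """Descriptor columns that carry the compound latent (the planted drivers)."""
        return list(self.generating_function["driver_descriptor_columns"])


def simulate_kinases(cfg: SimConfig) -> list[PocketAnnotation]:
    """Random pocket annotations: sequence, SS8 string, RSA series, volume.

    Sequences are uniform over the 20 standard amino acids with length
    uniform in ``pocket_length_range``; volumes are log-normal around a few
    hundred cubic angstroms.  Deterministic given ``cfg.seed``.
    """
    rng = cfg.rng(1)
    lo, hi = cfg.pocket_length_range
    width = len(str(cfg.n_kinases))
    out = []
    for i in range(cfg.n_kinases):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AA_ALPHABET), size=n))
        ss8 = "".join(rng.choice(list(SS8_ALPHABET), size=n))
        rsa = rng.uniform(0.0, 1.0, size=n)
        volume = float(rng.lognormal(mean=np.log(500.0), sigma=0.4))
        out.append(
            PocketAnnotation(
                kinase_id=f"K{i + 1:0{width}d}",
                sequence=seq,
                ss8=ss8,
                rsa=rsa,
                pocket_volume=volume,
            )
        )
    return out


def simulate_compounds(cfg: SimConfig, n_descriptors: int = 2756) -> SimulatedCompounds:
    """Synthetic descriptor table with mixed continuous and binary columns.

    The first half of the columns are continuous (Gaussian with per-column
    location/scale), the second half binary fingerprint-like bits with
    per-column on-frequency.  Assay concentrations are log-uniform over
    ``cfg.conc_range`` (molar).  Deterministic given ``cfg.seed``.
    """
    if n_descriptors < 1:
        raise ConfigurationError(f"n_descriptors must be >= 1, got {n_descriptors}")
    rng = cfg.rng(2)
    n = cfg.n_compounds
    n_cont = max(1, n_descriptors // 2)
    n_bin = n_descriptors - n_cont
    loc = rng.normal(0.0, 2.0, size=n_cont)
    scale = rng.uniform(0.5, 2.0, size=n_cont)
    cont = rng.normal(loc, scale, size=(n, n_cont))
    freq = rng.beta(1.0, 3.0, size=n_bin)
    bits = (rng.uniform(size=(n, n_bin)) < freq).astype(float)
    width = len(str(n))
    ids = [f"C{j + 1:0{width}d}" for j in range(n)]
    columns = [f"cont_{i}" for i in range(n_cont)] + [f"fp_{i}" for i in range(n_bin)]
    desc = pd.DataFrame(
        np.hstack([cont, bits]) if n_bin else cont,
        index=pd.Index(ids, name="compound_id"),
        columns=columns,
    )
    lo, hi = cfg.conc_range
    conc = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    return SimulatedCompounds(desc, pd.Series(conc, index=desc.index, name="concentration"))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 1e-12 else 1.0)


def _kinase_latents(cfg: SimConfig, kinases: list[PocketAnnotation]) -> np.ndarray:
    """Latent matrix (n_kinases x (2 + latent_dim)) from aa composition projections.

    Coordinate 0 is the kinase main effect, coordinate 1 is the constant 1
    that picks up the compound main effect, coordinates 2.. are interaction
    loadings.  All non-constant coordinates are standardized across kinases.
    """
    rng = cfg.rng(3)
    comp = np.stack([residue_frequencies(p.sequence, AA_ALPHABET) for p in kinases])
    proj = rng.normal(size=(20, cfg.latent_dim + 1))
    raw = comp @ proj  # (n_kinases, latent_dim + 1)
    raw = np.apply_along_axis(_standardize, 0, raw) if len(kinases) > 1 else raw
    u = np.ones((len(kinases), 2 + cfg.latent_dim))
    u[:, 0] = raw[:, 0]
    u[:, 2:] = raw[:, 1:]
    return u


def _compound_latents(cfg: SimConfig, compounds: SimulatedCompounds) -> tuple[np.ndarray, list[str]]:
    """Latent matrix (n_compounds x (2 + latent_dim)) read off descriptor columns.

    Coordinate 0 is the constant 1 (picks up the kinase main effect),
    coordinate 1 is the compound main effect, coordinates 2.. are the
    interaction loadings; each is a standardized continuous descriptor
    column, so the latent is observable by construction.
    """
    cont = compounds.continuous_columns
    need = cfg.latent_dim + 1
    if len(cont) < need:
        raise ConfigurationError(
            f"need >= {need} continuous descriptor columns to carry the latent, got {len(cont)}"
        )
    drivers = cont[:need]
    vals = compounds.descriptors[drivers].to_numpy()
    vals = np.apply_along_axis(_standardize, 0, vals) if len(vals) > 1 else vals
    v = np.ones((len(compounds.descriptors), 2 + cfg.latent_dim))
    v[:, 1] = vals[:, 0]
    v[:, 2:] = vals[:, 1:]
    return v, drivers


def simulate_pairs(
    cfg: SimConfig,
    kinases: list[PocketAnnotation],
    compounds: SimulatedCompounds,
    return_truth: bool = False,
):
    """Sample measured pairs and their percent-inhibition values.

    Returns a pairs DataFrame (kinase_id, compound_id, concentration,
    percent_inhibition), plus a :class:`SyntheticTruth` when
    ``return_truth`` is set.  Values are in [0, 100] and the generator is
    deterministic given ``cfg.seed``.
    """
    if not kinases or len(compounds.descriptors) == 0:
        raise ValidationError("simulate_pairs requires nonempty kinase and compound sets")
    rng = cfg.rng(4)
    n_k, n_c = len(kinases), len(compounds.descriptors)
    grid = n_k * n_c
    n_pairs = max(1, int(round(cfg.pair_fraction * grid)))
    flat = rng.choice(grid, size=n_pairs, replace=False)
    ki, cj = np.divmod(flat, n_c)

    u = _kinase_latents(cfg, kinases)
    v, drivers = _compound_latents(cfg, compounds)
    conc = compounds.concentrations.to_numpy()
    logc = _standardize(np.log10(conc)) if n_c > 1 else np.zeros(n_c)

    score = np.einsum("ij,ij->i", u[ki], v[cj]) + cfg.concentration_coeff * logc[cj]

    # base mixture: point masses at the assay floor/ceiling, Beta(2,2) mid-range
    w_low, w_high = cfg.extreme_low_weight, cfg.extreme_high_weight
    comp_draw = rng.uniform(size=n_pairs)
    base = np.empty(n_pairs)
    low = comp_draw < w_low
    high = (comp_draw >= w_low) & (comp_draw < w_low + w_high)
    mid = ~(low | high)
    base[low] = 0.0
    base[high] = 100.0
    base[mid] = 1.0 + 98.0 * rng.beta(2.0, 2.0, size=int(mid.sum()))

    noise = rng.normal(0.0, cfg.noise_sd, size=n_pairs) if cfg.noise_sd > 0 else 0.0
    y = np.clip(base + cfg.signal_strength * score + noise, 0.0, 100.0)

    pairs = pd.DataFrame(
        {
            "kinase_id": [kinases[i].kinase_id for i in ki],
            "compound_id": [compounds.descriptors.index[j] for j in cj],
            "concentration": conc[cj],
            "percent_inhibition": y,
        }
    )
    if not return_truth:
        return pairs
    truth = SyntheticTruth(
        kinase_latents={kinases[i].kinase_id: u[i].tolist() for i in range(n_k)},
        compound_latents={
            str(compounds.descriptors.index[j]): v[j].tolist() for j in range(n_c)
        },
        concentration_coeff=cfg.concentration_coeff,
        generating_function={
            "kind": "clipped mixture base + signal_strength * (u.v + c*logconc) + noise",
            "signal_strength": cfg.signal_strength,
            "noise_sd": cfg.noise_sd,
            "extreme_low_weight": cfg.extreme_low_weight,
            "extreme_high_weight": cfg.extreme_high_weight,
            "latent_dim": cfg.latent_dim,
            "driver_descriptor_columns": drivers,
            "kinase_latent_source": "seeded random projection of pocket aa composition",
        },
        pair_scores=score.tolist(),
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# file output


def write_simulation(
    outdir: str | Path,
    kinases: list[PocketAnnotation],
    compounds: SimulatedCompounds,
    pairs: pd.DataFrame,
    truth: SyntheticTruth | None = None,
) -> dict[str, Path]:
    """Write the generated study to disk in plain-text formats.

    Produces: ``annotations.tsv`` (kinase_id, position, aa, ss8, rsa),
    ``volumes.tsv``, ``pockets.fasta``, ``descriptors.csv``,
    ``compounds.csv`` (compound_id, concentration), ``pairs.csv`` and
    optionally ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ann_rows = []
    for p in kinases:
        for pos, (aa, ss, r) in enumerate(zip(p.sequence, p.ss8, p.rsa), start=1):
            ann_rows.append((p.kinase_id, pos, aa, ss, r))
    ann = pd.DataFrame(ann_rows, columns=["kinase_id", "position", "aa", "ss8", "rsa"])
    paths["annotations"] = outdir / "annotations.tsv"
    ann.to_csv(paths["annotations"], sep="\t", index=False)

    vol = pd.DataFrame(
        {"kinase_id": [p.kinase_id for p in kinases],
         "pocket_volume": [p.pocket_volume for p in kinases]}
    )
    paths["volumes"] = outdir / "volumes.tsv"
    vol.to_csv(paths["volumes"], sep="\t", index=False)

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    paths["fasta"] = outdir / "pockets.fasta"
    records = [SeqRecord(Seq(p.sequence), id=p.kinase_id, description="") for p in kinases]
    seqio_write(records, paths["fasta"], "fasta")

    paths["descriptors"] = outdir / "descriptors.csv"
    compounds.descriptors.to_csv(paths["descriptors"])

    paths["compounds"] = outdir / "compounds.csv"
    compounds.concentrations.rename("concentration").to_csv(paths["compounds"])

    paths["pairs"] = outdir / "pairs.csv"
    pairs.to_csv(paths["pairs"], index=False)

    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    return paths


def simulate_study(cfg: SimConfig, n_descriptors: int = 2756):
    """One-call generator: kinases, compounds, pairs and truth."""
    kinases = simulate_kinases(cfg)
    compounds = simulate_compounds(cfg, n_descriptors)
    pairs, truth = simulate_pairs(cfg, kinases, compounds, return_truth=True)
    return kinases, compounds, pairs, truth
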