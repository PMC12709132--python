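"""Local surrogate explanations of percent-inhibition predictions.

Workflow mirroring the interpretability analysis the package supports:
rank kinases by how well the model predicts their pairs (per-kinase Pearson
correlation), pick the best-predicted kinases, explain individual
predictions with a LIME-style local linear surrogate, and aggregate the
per-instance weights into a ranked feature-importance table — annotating
amino-acid 3-mer features that contain the phospho-acceptor residues
S, T or Y.

The surrogate works on perturbed copies of one instance: continuous columns
are resampled from Gaussian background statistics, binary (fingerprint-like)
columns are redrawn as Bernoulli at their background frequency; samples are
weighted by an exponential kernel on standardized distance to the instance
and a weighted sparse linear model restricted to the strongest
``max_features`` features is fitted to the model's outputs.  Coefficients
are reported on the standardized feature scale so magnitudes are comparable
across features.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import PairDataset
from .errors import ValidationError
from .metrics import pcc

PHOSPHO_RESIDUES = frozenset("STY")
_AA3_RE = re.compile(r"^aa3_([A-Z]{3})$")


# ---------------------------------------------------------------------------
# per-kinase prediction ranking


@dataclass
class KinaseRanking:
    """Kinases ranked by Pearson correlation between observed and predicted values."""

    table: pd.DataFrame  # kinase_id, n_pairs, pcc — sorted descending by pcc

    def top(self, n: int = 5) -> pd.DataFrame:
        """The ``n`` best-predicted kinases (default: top five)."""
        return self.table.head(n)

    def __len__(self) -> int:
        return len(self.table)


def rank_kinases(ds: PairDataset, preds: np.ndarray, min_pairs: int = 3) -> KinaseRanking:
    """Per-kinase PCC between observed and predicted inhibition, descending.

    Kinases with fewer than ``min_pairs`` pairs, or with constant observed
    values (PCC undefined), are excluded with a warning.
    """
    preds = np.asarray(preds, dtype=float).ravel()
    if preds.shape != ds.y.shape:
        raise ValidationError(
            f"predictions ({preds.shape}) not aligned with dataset rows ({ds.y.shape})"
        )
    rows = []
    for kid in pd.unique(ds.kinase_id):
        mask = ds.kinase_id == kid
        n = int(mask.sum())
        if n < min_pairs:
            continue
        obs = ds.y[mask]
        if np.std(obs) == 0:
            warnings.warn(f"rank_kinases: kinase {kid} has constant observed values; excluded",
                          stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = pcc(obs, preds[mask])
        if np.isnan(r):
            warnings.warn(f"rank_kinases: PCC undefined for kinase {kid}; excluded", stacklevel=2)
            continue
        rows.append({"kinase_id": kid, "n_pairs": n, "pcc": r})
    table = pd.DataFrame(rows, columns=["kinase_id", "n_pairs", "pcc"])
    table = table.sort_values(["pcc", "kinase_id"], ascending=[False, True]).reset_index(drop=True)
    return KinaseRanking(table)


# ---------------------------------------------------------------------------
# local surrogate


@dataclass
class Explanation:
    """Sparse local linear surrogate around one instance."""

    instance_id: str
    feature_weights: dict[str, float]
    intercept: float
    surrogate_fit_quality: float  # weighted R^2 of the surrogate
    n_samples: int
    kernel_width: float
    seed: int


def _detect_binary_columns(background: np.ndarray) -> np.ndarray:
    mins = background.min(axis=0)
    maxs = background.max(axis=0)
    is01 = (mins >= 0) & (maxs <= 1)
    frac_int = np.all((background == 0) | (background == 1), axis=0)
    return is01 & frac_int


def lime_explain(
    model,
    instance: np.ndarray,
    background: np.ndarray,
    n_samples: int = 2000,
    kernel_width: float | None = None,
    max_features: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
    instance_id: str = "instance",
) -> Explanation:
    """Explain one prediction with a weighted sparse linear surrogate.

    ``model`` is anything with ``predict(X)`` (or a callable).  Perturbed
    samples are drawn feature-wise from background statistics (Gaussian for
    continuous columns, Bernoulli flips at background frequency for binary
    columns); the first sample is the instance itself.  Samples are
    weighted by ``exp(-d^2 / kernel_width^2)`` on standardized distance, a
    ridge fit selects the ``max_features`` strongest features, and a
    weighted least-squares refit on those features yields the reported
    weights (ridge-regularized with a warning if singular).  Deterministic
    given ``seed``.
    """
    if n_samples < 10:
        raise ValidationError(f"n_samples must be >= 10, got {n_samples}")
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.asarray(background, dtype=float)
    d = instance.size
    if background.ndim != 2 or background.shape[1] != d:
        raise ValidationError(
            f"background width {background.shape} does not match instance width {d}"
        )
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(d)]
    if len(feature_names) != d:
        raise ValidationError("feature_names length does not match instance width")
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)

    rng = np.random.default_rng(seed)
    mean = background.mean(axis=0)
    std = background.std(axis=0)
    std_safe = np.where(std < 1e-12, 1.0, std)
    binary = _detect_binary_columns(background)

    Z = np.empty((n_samples, d))
    Z[0] = instance
    n_draw = n_samples - 1
    cont = ~binary
    if cont.any():
        Z[1:, cont] = rng.normal(mean[cont], std_safe[cont], size=(n_draw, int(cont.sum())))
    if binary.any():
        freq = background[:, binary].mean(axis=0)
        Z[1:, binary] = (rng.uniform(size=(n_draw, int(binary.sum()))) < freq).astype(float)

    predict = model.predict if hasattr(model, "predict") else model
    fx = np.asarray(predict(Z), dtype=float).ravel()

    Zs = (Z - mean) / std_safe
    inst_s = (instance - mean) / std_safe
    dist = np.sqrt(((Zs - inst_s) ** 2).sum(axis=1))
    w = np.exp(-(dist**2) / kernel_width**2)

    # selection pass: weighted ridge on all standardized features
    from sklearn.linear_model import Ridge

    ridge = Ridge(alpha=1.0)
    ridge.fit(Zs, fx, sample_weight=w)
    order = np.argsort(-np.abs(ridge.coef_), kind="stable")
    keep = np.sort(order[: min(max_features, d)])

    # refit pass: weighted least squares restricted to the selected features
    A = np.hstack([Zs[:, keep], np.ones((n_samples, 1))])
    sw = np.sqrt(w)
    lhs = A * sw[:, None]
    rhs = fx * sw
    coef, _, rank, _ = np.linalg.lstsq(lhs, rhs, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("lime_explain: singular weighted fit; ridge-regularized fallback",
                      stacklevel=2)
        ridge2 = Ridge(alpha=1e-6)
        ridge2.fit(Zs[:, keep], fx, sample_weight=w)
        coef = np.append(ridge2.coef_, ridge2.intercept_)

    fitted = A @ coef
    wmean = np.average(fx, weights=w)
    ss_tot = float(np.sum(w * (fx - wmean) ** 2))
    ss_res = float(np.sum(w * (fx - fitted) ** 2))
    quality = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    weights = {feature_names[j]: float(c) for j, c in zip(keep, coef[:-1])}
    return Explanation(
        instance_id=instance_id,
        feature_weights=weights,
        intercept=float(coef[-1]),
        surrogate_fit_quality=quality,
        n_samples=int(n_samples),
        kernel_width=float(kernel_width),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# aggregation


def phospho_motif_flag(feature_name: str) -> bool:
    """True iff the feature is an amino-acid 3-mer containing S, T or Y.

    Serine, threonine and tyrosine are the phospho-acceptor residues;
    non-3-mer features always return False.
    """
    m = _AA3_RE.match(feature_name)
    return bool(m) and bool(PHOSPHO_RESIDUES & set(m.group(1)))


@dataclass
class AggregatedImportance:
    """Mean absolute surrogate weight per feature across explanations."""

    table: pd.DataFrame  # feature, score, phospho_motif — sorted descending
    top_k: int = 10

    def top(self, k: int | None = None) -> pd.DataFrame:
        return self.table.head(self.top_k if k is None else k)


def aggregate_importance(explanations: list[Explanation], top_k: int = 10) -> AggregatedImportance:
    """Aggregate per-instance weights into one ranked importance table.

    The score of a feature is the mean of its absolute surrogate weight
    across all explanations (zero where the feature was not selected), so
    the result is invariant to the order of explanations.  Ties are broken
    by feature name.
    """
    if not explanations:
        raise ValidationError("aggregate_importance requires at least one explanation")
    features = sorted({name for e in explanations for name in e.feature_weights})
    n = len(explanations)
    scores = {
        name: sum(abs(e.feature_weights.get(name, 0.0)) for e in explanations) / n
        for name in features
    }
    table = pd.DataFrame(
        {
            "feature": features,
            "score": [scores[f] for f in features],
            "phospho_motif": [phospho_motif_flag(f) for f in features],
        }
    )
    table = table.sort_values(["score", "feature"], ascending=[False, True]).reset_index(drop=True)
    return AggregatedImportance(table=table, top_k=top_k)


def explain_top_kinases(
    results,
    ds: PairDataset,
    split: str = "test",
    n_kinases: int = 5,
    top_k: int = 10,
    n_samples: int = 2000,
    max_features: int = 10,
    seed: int = 0,
    min_pairs: int = 3,
) -> tuple[KinaseRanking, list[Explanation], AggregatedImportance]:
    """End-to-end interpretability pass on one split.

    Ranks kinases by per-kinase PCC, explains every pair of the ``n_kinases``
    best-predicted kinases with the local surrogate (training rows as
    background), and aggregates the weights into a top-``top_k`` table.
    """
    sub = ds.subset(split)
    preds = np.asarray(results.predict(sub.X), dtype=float).ravel()
    ranking = rank_kinases(sub, preds, min_pairs=min_pairs)
    chosen = set(ranking.top(n_kinases)["kinase_id"])
    background = ds.subset("train").X
    explanations = []
    for i in np.flatnonzero(np.isin(sub.kinase_id, list(chosen))):
        explanations.append(
            lime_explain(
                results,
                sub.X[i],
                background,
                n_samples=n_samples,
                max_features=max_features,
                seed=seed + i,
                feature_names=ds.feature_names,
                instance_id=f"{sub.kinase_id[i]}:{sub.compound_id[i]}",
            )
        )
    agg = aggregate_importance(explanations, top_k=top_k)
    return ranking, explanations, agg
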