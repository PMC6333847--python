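"""Permutation-null relevance of classifier weights.

At each CV fold, ~1000 classifiers are retrained on the fold's training
features with labels randomly relabelled (a permutation of the observed
label vector, so class counts are preserved).  The per-feature mean and
standard deviation of the weights across these refits form the null
distribution; the relevance of feature f in that fold is the distance of
its real weight from the null in null SDs, z_f = |w_f - mean_f| / SD_f.
Per-fold z values are aggregated across folds (mean by default) and edges
with aggregate z at or above a conservative threshold of five null SDs
(motivated by the Chebyshev bound) are reported as prominent longitudinal
connections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from longconn.atlas import edge_feature_map
from longconn.connectome import METRICS
from longconn.model import ModelEnsemble, ModelSpec, train_fold

#: Null SDs below this are treated as degenerate (z undefined, not infinite).
SD_FLOOR = 1e-12

AGGREGATIONS = ("mean", "median", "max")


@dataclass
class NullDistribution:
    """Per-feature mean/SD of classifier weights under label permutation."""

    mean: np.ndarray
    sd: np.ndarray
    n_permutations: int
    fold_index: int = -1

    @property
    def degenerate(self) -> np.ndarray:
        return self.sd < SD_FLOOR


def permutation_null(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    spec: ModelSpec = ModelSpec(),
    n_perm: int = 1000,
    seed: int = 0,
    fold_index: int = -1,
) -> NullDistribution:
    """Refit the model ``n_perm`` times with permuted labels.

    Each refit uses the same features and model spec as the real fit;
    only the label vector is shuffled (class counts preserved, so no
    permutation can be single-class for two-class input).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("permutation null requires two classes")

    rng = np.random.default_rng(seed)
    s = np.zeros(X.shape[1])
    ss = np.zeros(X.shape[1])
    for p in range(n_perm):
        y_perm = rng.permutation(y)
        w = train_fold(X, y_perm, spec, seed=int(rng.integers(2**31))).weights
        s += w
        ss += w * w
    mean = s / n_perm
    var = np.maximum(ss / n_perm - mean**2, 0.0)
    return NullDistribution(
        mean=mean, sd=np.sqrt(var), n_permutations=n_perm, fold_index=fold_index
    )


def weight_z(weights: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Distance of each weight from its null, in null SDs.

    Returns |w - mean| / SD, with NaN where the null SD is degenerate
    (below ``SD_FLOOR``) — degenerate features are flagged, never
    assigned an infinite z.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != null.mean.shape:
        raise ValueError(f"weight/null dimension mismatch: {w.shape} vs {null.mean.shape}")
    z = np.full(w.shape, np.nan)
    ok = ~null.degenerate
    z[ok] = np.abs(w[ok] - null.mean[ok]) / null.sd[ok]
    return z


def aggregate_relevance(
    per_fold_z: np.ndarray, aggregation: str = "mean"
) -> pd.DataFrame:
    """Summarize per-fold z values into a ranked relevance table.

    ``per_fold_z`` is (k folds x 360 features); folds where a feature was
    degenerate (NaN) are excluded from that feature's summary.  The table
    has one row per (node pair, metric), sorted by descending summary z,
    with degenerate-everywhere features last.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    Z = np.atleast_2d(np.asarray(per_fold_z, dtype=float))
    fmap = edge_feature_map(METRICS)
    if Z.shape[1] != len(fmap):
        raise ValueError(f"expected {len(fmap)} features, got {Z.shape[1]}")

    import warnings as _warnings

    with _warnings.catch_warnings():
        # features degenerate in every fold produce all-NaN slices by design
        _warnings.simplefilter("ignore", RuntimeWarning)
        agg = {"mean": np.nanmean, "median": np.nanmedian, "max": np.nanmax}[
            aggregation
        ](Z, axis=0)
        z_min = np.nanmin(Z, axis=0)
        z_max = np.nanmax(Z, axis=0)
    degenerate = np.isnan(Z).all(axis=0)

    table = pd.DataFrame(
        {
            "feature_index": [f.feature_index for f in fmap],
            "node_1": [f.node_a.label for f in fmap],
            "node_2": [f.node_b.label for f in fmap],
            "metric": [f.metric for f in fmap],
            "z": agg,
            "z_min": z_min,
            "z_max": z_max,
            "degenerate": degenerate,
        }
    )
    table.attrs["aggregation"] = aggregation
    table.attrs["n_folds"] = Z.shape[0]
    return table.sort_values("z", ascending=False, na_position="last").reset_index(
        drop=True
    )


def prominent_connections(table: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Rows whose summary z reaches the prominence threshold (default 5 SD)."""
    out = table[table["z"] >= threshold].copy()
    out.attrs.update(table.attrs)
    out.attrs["threshold"] = threshold
    return out


def ensemble_relevance(
    ensemble: ModelEnsemble,
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Per-fold permutation nulls for a trained ensemble, aggregated.

    For every fold, the null is built on that fold's *training* subjects
    (the same data its model saw) and the fold model's weights are scored
    against it.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    y = np.asarray(labels)
    seeds = np.random.SeedSequence(seed).spawn(ensemble.k)
    per_fold = []
    for f, model in enumerate(ensemble.fold_models):
        train = ensemble.fold_assignment != f
        null = permutation_null(
            X[train], y[train], ensemble.spec, n_perm=n_perm,
            seed=int(seeds[f].generate_state(1)[0] % 2**31), fold_index=f,
        )
        per_fold.append(weight_z(model.weights, null))
    return aggregate_relevance(np.vstack(per_fold), aggregation=aggregation)
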