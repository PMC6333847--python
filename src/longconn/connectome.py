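"""Connectome data model and longitudinal feature extraction.

A connectome here is a symmetric 16x16 matrix summarising white-matter
connectivity between parcellation regions for one subject at one timepoint,
for one of three metrics: streamline count, streamline-averaged fractional
anisotropy (FA, dimensionless in [0, 1]) or streamline-averaged mean
diffusivity (MD, mm^2/s).  The longitudinal feature vector of a subject is
the element-wise absolute difference between follow-up and baseline edge
vectors, concatenated over the three metrics (sign is discarded: the
feature measures magnitude of change, not direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from longconn.atlas import EDGE_PAIRS, N_EDGES, N_NODES, edge_feature_map

#: Metric block order in the concatenated feature vector.
METRICS: tuple[str, ...] = ("streamline_count", "mean_fa", "mean_md")

TIMEPOINTS: tuple[str, ...] = ("baseline", "followup")

N_FEATURES = len(METRICS) * N_EDGES  # 360

#: Maximum tolerated |A - A.T| before a matrix is rejected as asymmetric.
ASYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class Connectome:
    """One validated, symmetric connectivity matrix."""

    subject_id: str
    timepoint: str
    metric: str
    matrix: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class EdgeVector:
    """The 120 strict-upper-triangle cells of a connectome, canonical order."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        if self.values.shape != (N_EDGES,):
            raise ValueError(f"edge vector must have length {N_EDGES}")


@dataclass(frozen=True)
class LongitudinalFeatureVector:
    """360 non-negative |follow-up - baseline| features for one subject."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")


def _check_ranges(matrix: np.ndarray, metric: str) -> None:
    off = matrix[~np.eye(N_NODES, dtype=bool)]
    if metric == "streamline_count":
        if (off < 0).any():
            raise ValueError("streamline counts must be non-negative")
    elif metric == "mean_fa":
        if (off < 0).any() or (off > 1).any():
            raise ValueError("mean FA values must lie in [0, 1]")
    elif metric == "mean_md":
        if (off < 0).any():
            raise ValueError("mean MD values must be non-negative")
    else:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def validate_connectome(
    raw_matrix: np.ndarray,
    metric: str,
    subject_id: str = "",
    timepoint: str = "baseline",
    symmetrize: bool = True,
) -> Connectome:
    """Validate a raw 16x16 matrix and wrap it as a `Connectome`.

    The matrix must be square 16x16, finite, symmetric within
    ``ASYMMETRY_TOL`` (file round-trip noise only; larger asymmetry is an
    error, never silently averaged away) and within the metric's range.
    With ``symmetrize`` the within-tolerance residual is removed by
    averaging with the transpose.
    """
    m = np.asarray(raw_matrix, dtype=float)
    if m.shape != (N_NODES, N_NODES):
        raise ValueError(f"expected a {N_NODES}x{N_NODES} matrix, got shape {m.shape}")
    if not np.isfinite(m).all():
        raise ValueError("connectome matrix contains non-finite values")
    asym = np.abs(m - m.T).max()
    if asym > ASYMMETRY_TOL:
        raise ValueError(
            f"matrix asymmetry {asym:.3g} exceeds tolerance {ASYMMETRY_TOL:g}"
        )
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
    _check_ranges(m, metric)
    if symmetrize:
        m = (m + m.T) / 2.0
    m.setflags(write=False)
    return Connectome(subject_id=subject_id, timepoint=timepoint, metric=metric, matrix=m)


def vectorize_upper_triangle(c: Connectome) -> EdgeVector:
    """Flatten the strict upper triangle (i < j, diagonal excluded).

    Self-loops are not connections between regions (and streamline-averaged
    FA/MD of a self-loop is ill-defined), so the diagonal is dropped,
    leaving the 120 region pairs in canonical row-major order.
    """
    iu = np.triu_indices(N_NODES, k=1)
    return EdgeVector(values=c.matrix[iu].copy(), metric=c.metric)


def longitudinal_distance(x_b: EdgeVector, x_fu: EdgeVector) -> EdgeVector:
    """Element-wise L1 distance |x_fu - x_b|; the sign of change is discarded."""
    if x_b.metric != x_fu.metric:
        raise ValueError(f"metric mismatch: {x_b.metric!r} vs {x_fu.metric!r}")
    return EdgeVector(values=np.abs(x_fu.values - x_b.values), metric=x_b.metric)


def build_feature_vector(connectomes: Iterable[Connectome]) -> LongitudinalFeatureVector:
    """Assemble the 360-long longitudinal feature vector of one subject.

    Requires all six connectomes ({baseline, followup} x 3 metrics) with a
    consistent subject id.  Block m of the result (indices [120m, 120m+120))
    is the per-edge absolute change of metric m, metrics in ``METRICS``
    order.  No feature selection is applied.
    """
    by_key: dict[tuple[str, str], Connectome] = {}
    subject_ids = set()
    for c in connectomes:
        key = (c.timepoint, c.metric)
        if key in by_key:
            raise ValueError(f"duplicate connectome for {key}")
        by_key[key] = c
        subject_ids.add(c.subject_id)
    if len(subject_ids) > 1:
        raise ValueError(f"connectomes mix subjects: {sorted(subject_ids)}")
    missing = [
        (tp, m) for m in METRICS for tp in TIMEPOINTS if (tp, m) not in by_key
    ]
    if missing:
        raise ValueError(f"missing connectomes: {missing}")
    blocks = []
    for metric in METRICS:
        x_b = vectorize_upper_triangle(by_key[("baseline", metric)])
        x_fu = vectorize_upper_triangle(by_key[("followup", metric)])
        blocks.append(longitudinal_distance(x_b, x_fu).values)
    return LongitudinalFeatureVector(
        subject_id=next(iter(subject_ids)), values=np.concatenate(blocks)
    )


def matrix_from_edge_vector(v: EdgeVector, diagonal: float = 0.0) -> np.ndarray:
    """Rebuild the symmetric 16x16 matrix whose strict upper triangle is ``v``."""
    m = np.full((N_NODES, N_NODES), diagonal, dtype=float)
    iu = np.triu_indices(N_NODES, k=1)
    m[iu] = v.values
    m[(iu[1], iu[0])] = v.values
    return m


def feature_names() -> list[str]:
    """Column names of the 360 features, e.g. ``L-RN__R-RN__streamline_count``."""
    return [f.name for f in edge_feature_map(METRICS)]


# ---------------------------------------------------------------------------
# File interfaces: per-connectome CSV matrices plus a TSV manifest.

MANIFEST_COLUMNS = ["subject_id", "group", "age", "gender", "days_between_scans"]


def connectome_filename(subject_id: str, timepoint: str, metric: str) -> str:
    return f"{subject_id}_{timepoint}_{metric}.csv"


def write_connectome_csv(c: Connectome, path: str | Path) -> None:
    """Write a 16x16 headerless CSV matrix (full float64 precision)."""
    np.savetxt(path, c.matrix, delimiter=",", fmt="%.17g")


def read_connectome_csv(
    path: str | Path, metric: str, subject_id: str = "", timepoint: str = "baseline"
) -> Connectome:
    m = np.loadtxt(path, delimiter=",")
    return validate_connectome(m, metric, subject_id=subject_id, timepoint=timepoint)


def featurize_directory(
    directory: str | Path, manifest: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Build the n x 360 feature table from a directory of connectome CSVs.

    The manifest (TSV ``manifest.tsv`` in the directory unless given) must
    carry one path column per (timepoint, metric); paths are resolved
    relative to the directory.  Returns a DataFrame indexed by subject_id.
    """
    directory = Path(directory)
    if manifest is None:
        manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    rows = []
    for _, rec in manifest.iterrows():
        sid = str(rec["subject_id"])
        conns = []
        for tp in TIMEPOINTS:
            for metric in METRICS:
                col = f"path_{tp}_{metric}"
                path = directory / str(rec[col])
                if not path.exists():
                    raise FileNotFoundError(
                        f"connectome file missing for subject {sid}: {path}"
                    )
                conns.append(read_connectome_csv(path, metric, sid, tp))
        rows.append(build_feature_vector(conns).values)
    return pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, N_FEATURES)),
        index=pd.Index(manifest["subject_id"].astype(str), name="subject_id"),
        columns=feature_names(),
    )
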