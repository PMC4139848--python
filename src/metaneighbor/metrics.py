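"""The six profile distance measures and pairwise distance matrices.

Profiles are compared with City block (L1), Euclidean (L2), standardized
Euclidean, Pearson-correlation distance (1 - rho), Spearman-correlation
distance (1 - rho on average ranks) and the Jensen-Shannon divergence
(symmetrized Kullback-Leibler, natural log).  On relative-abundance vectors
the City block distance is twice the ecological Bray-Curtis dissimilarity.

Scalar functions spell the formulas out; :func:`pairwise_distances`
dispatches to scipy's vectorized pdist kernels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import rel_entr
from scipy.stats import rankdata

from .profile_io import ProfileCollection

__all__ = [
    "VALID_METRICS",
    "DistanceMatrix",
    "city_block",
    "euclidean",
    "std_euclidean",
    "pearson_distance",
    "spearman_distance",
    "jensen_shannon",
    "feature_std",
    "pairwise_distances",
    "write_distance_matrix",
    "read_distance_matrix",
]

VALID_METRICS = (
    "cityblock",
    "euclidean",
    "std_euclidean",
    "pearson",
    "spearman",
    "jensen_shannon",
)

#: row-sum tolerance for declaring a vector a relative-abundance profile
_NORM_TOL = 1e-6


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities tagged with the producing metric."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} sample IDs")
        if not np.allclose(v, v.T, atol=1e-8, rtol=0):
            raise ValueError("distance matrix is not symmetric")
        v = (v + v.T) / 2.0
        if np.any(v < -1e-12):
            i, j = np.argwhere(v < -1e-12)[0]
            raise ValueError(
                f"negative distance {v[i, j]} between "
                f"{self.sample_ids[i]!r} and {self.sample_ids[j]!r}"
            )
        v = np.clip(v, 0.0, None)
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _check_lengths(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return x, y


def city_block(x, y) -> float:
    """L1 distance sum_i |x_i - y_i|."""
    x, y = _check_lengths(x, y)
    return float(np.abs(x - y).sum())


def euclidean(x, y) -> float:
    """L2 distance sqrt(sum_i (x_i - y_i)^2)."""
    x, y = _check_lengths(x, y)
    return float(np.sqrt(((x - y) ** 2).sum()))


def std_euclidean(x, y, sigma) -> float:
    """Euclidean distance with each dimension divided by its standard deviation.

    Dimensions with ``sigma == 0`` are skipped (they carry no information over
    the reference collection and would otherwise produce infinities).
    """
    x, y = _check_lengths(x, y)
    sigma = np.asarray(sigma, dtype=float).ravel()
    if sigma.size != x.size:
        raise ValueError(f"sigma length {sigma.size} does not match {x.size}")
    if np.any(sigma < 0) or not np.all(np.isfinite(sigma)):
        raise ValueError("sigma must be finite and nonnegative")
    mask = sigma > 0
    if not np.any(mask):
        raise ValueError("all feature standard deviations are zero")
    z = (x[mask] - y[mask]) / sigma[mask]
    return float(np.sqrt((z**2).sum()))


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0 or ny == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((xc @ yc) / (nx * ny))


def pearson_distance(x, y) -> float:
    """Correlation distance 1 - rho(x, y), in [0, 2]."""
    x, y = _check_lengths(x, y)
    if x.size < 2:
        raise ValueError("correlation requires vectors of length >= 2")
    return 1.0 - _pearson_r(x, y)


def spearman_distance(x, y) -> float:
    """Rank-correlation distance 1 - rho(rank(x), rank(y)); ties get average ranks."""
    x, y = _check_lengths(x, y)
    if x.size < 2:
        raise ValueError("correlation requires vectors of length >= 2")
    return 1.0 - _pearson_r(rankdata(x), rankdata(y))


def jensen_shannon(x, y) -> float:
    """Jensen-Shannon divergence between two relative-abundance vectors.

    0.5*KL(x || m) + 0.5*KL(y || m) with m = (x+y)/2 and natural logarithm.
    Dimensions where both vectors are zero are excluded; a zero entry
    contributes nothing to its own KL term (0*ln 0 = 0).  Bounded by ln 2.
    """
    x, y = _check_lengths(x, y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Jensen-Shannon requires nonnegative vectors")
    for name, v in (("x", x), ("y", y)):
        if abs(v.sum() - 1.0) > _NORM_TOL:
            raise ValueError(
                f"vector {name} is not a relative-abundance profile "
                f"(sum {v.sum()!r}); normalize first"
            )
    keep = (x > 0) | (y > 0)
    x, y = x[keep], y[keep]
    m = 0.5 * (x + y)
    return float(0.5 * rel_entr(x, m).sum() + 0.5 * rel_entr(y, m).sum())


def feature_std(collection: ProfileCollection, ddof: int = 1) -> np.ndarray:
    """Per-feature sample standard deviation over the collection."""
    if collection.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate standard deviations")
    return collection.counts.std(axis=0, ddof=ddof)


def _check_non_constant_rows(collection: ProfileCollection) -> None:
    ptp = collection.counts.max(axis=1) - collection.counts.min(axis=1)
    if np.any(ptp == 0):
        i = int(np.argmax(ptp == 0))
        raise ValueError(
            f"sample {collection.sample_ids[i]!r} has a constant profile; "
            "correlation distance undefined"
        )


def pairwise_distances(
    collection: ProfileCollection, metric_name: str
) -> DistanceMatrix:
    """All pairwise distances between the collection's samples.

    For ``std_euclidean`` the per-feature standard deviations are estimated
    once from this collection (query included).  ``jensen_shannon`` requires a
    normalized collection.
    """
    if metric_name not in VALID_METRICS:
        raise ValueError(
            f"unknown metric {metric_name!r}; valid metrics are "
            + ", ".join(VALID_METRICS)
        )
    X = collection.counts
    if metric_name == "cityblock":
        condensed = pdist(X, "cityblock")
    elif metric_name == "euclidean":
        condensed = pdist(X, "euclidean")
    elif metric_name == "std_euclidean":
        sigma = feature_std(collection)
        mask = sigma > 0
        if not np.any(mask):
            raise ValueError("all feature standard deviations are zero")
        condensed = pdist(X[:, mask], "seuclidean", V=sigma[mask] ** 2)
    elif metric_name == "pearson":
        _check_non_constant_rows(collection)
        condensed = pdist(X, "correlation")
    elif metric_name == "spearman":
        _check_non_constant_rows(collection)
        condensed = pdist(rankdata(X, axis=1), "correlation")
    else:  # jensen_shannon
        sums = X.sum(axis=1)
        bad = np.abs(sums - 1.0) > _NORM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"sample {collection.sample_ids[i]!r} is not normalized "
                f"(row sum {sums[i]!r}); apply normalize_relative first"
            )
        condensed = pdist(X, "jensenshannon") ** 2
    values = squareform(np.clip(condensed, 0.0, None))
    return DistanceMatrix(
        sample_ids=collection.sample_ids, values=values, metric_name=metric_name
    )


def write_distance_matrix(dm: DistanceMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Square delimited matrix with ID header row/column; metric in a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# metric: {dm.metric_name}\n")
        df = pd.DataFrame(dm.values, index=list(dm.sample_ids), columns=list(dm.sample_ids))
        df.index.name = "sample_id"
        df.to_csv(fh, sep=delimiter)


def read_distance_matrix(path: str | Path, delimiter: str = "\t") -> DistanceMatrix:
    metric_name = "unknown"
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if line.lower().startswith("# metric:"):
                metric_name = line.split(":", 1)[1].strip()
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep=delimiter, index_col=0)
    return DistanceMatrix(
        sample_ids=tuple(str(s) for s in df.index),
        values=df.to_numpy(dtype=float),
        metric_name=metric_name,
    )
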