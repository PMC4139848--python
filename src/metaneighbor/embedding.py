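"""2D visualization of profile collections and its neighborhood evaluation.

Four dimensionality-reduction methods produce 2D scatter-plot coordinates of
a metagenome collection:

* PCA on the (mean-centered) profile matrix,
* classical (Torgerson) MDS on an arbitrary distance matrix,
* Sammon mapping, a nonlinear refinement weighting small distances heavily,
* unsupervised kernel regression (UKR) with the L1 kernel
  ``K(u) = exp(-||u||_1)``, optimizing latent coordinates of a
  Nadaraya-Watson regressor under a leave-one-out reconstruction objective.

Sammon is initialized from classical MDS and UKR from L1-kernel PCA.  The
quality of a 2D map is scored by the same leave-one-out neighborhood
accuracy used in the high-dimensional profile space, on 2D Euclidean
distances.

City-block distance matrices are not Euclidean-realizable, so classical MDS
routinely produces negative eigenvalues; these are clamped and explained
variance is reported over the positive spectrum only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .metrics import DistanceMatrix
from .neighborhood import NeighborhoodReport, loocv_accuracy
from .profile_io import ProfileCollection

__all__ = [
    "Embedding",
    "pca_embed",
    "mds_embed",
    "sammon_embed",
    "l1_kernel_pca_init",
    "ukr_embed",
    "embedding_accuracy",
    "write_embedding",
    "plot_embedding",
]

EMBEDDING_METHODS = ("pca", "mds", "sammon", "ukr")

_DIST_FLOOR = 1e-12


@dataclass(frozen=True)
class Embedding:
    """Per-sample low-dimensional coordinates with method metadata.

    ``explained_variance`` is defined for the spectral methods (pca, mds);
    ``trace`` records the per-iteration objective of the iterative methods
    (sammon, ukr) and is non-increasing by construction.
    """

    sample_ids: tuple[str, ...]
    coords: np.ndarray
    method: str
    explained_variance: tuple[float, ...] | None = None
    trace: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite embedding coordinates")


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca_embed(collection: ProfileCollection, n_dims: int = 2) -> Embedding:
    """Principal component projection of the profile matrix."""
    n, d = collection.counts.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_dims > min(n, d):
        raise ValueError(f"n_dims={n_dims} exceeds min(n, D)={min(n, d)}")
    pca = PCA(n_components=n_dims, svd_solver="full")
    scores = pca.fit_transform(collection.counts)
    # re-impose our sign convention on the loadings, mirrored to the scores
    for j in range(n_dims):
        comp = pca.components_[j]
        if comp[int(np.argmax(np.abs(comp)))] < 0:
            scores[:, j] = -scores[:, j]
    return Embedding(
        sample_ids=collection.sample_ids,
        coords=scores,
        method="pca",
        explained_variance=tuple(float(v) for v in pca.explained_variance_ratio_),
    )


def mds_embed(distances: DistanceMatrix, n_dims: int = 2) -> Embedding:
    """Classical (Torgerson) MDS: double centering plus eigendecomposition.

    Negative eigenvalues of the implied inner-product matrix (expected for
    non-Euclidean inputs such as L1 distances) are clamped to zero; the
    explained-variance fractions are taken over the positive spectrum.
    """
    D = distances.values
    n = distances.n_samples
    if n_dims > n:
        raise ValueError(f"n_dims={n_dims} exceeds n={n}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos_sum = float(w[w > 0].sum())
    lam = np.clip(w[:n_dims], 0.0, None)
    # eigenvalues at numerical-noise level are rank deficiency, not structure
    lam[lam < 1e-12 * max(float(w[0]), 0.0)] = 0.0
    coords = _fix_signs(V[:, :n_dims]) * np.sqrt(lam)
    ev = tuple(float(l / pos_sum) if pos_sum > 0 else 0.0 for l in lam)
    return Embedding(
        sample_ids=distances.sample_ids,
        coords=coords,
        method="mds",
        explained_variance=ev,
    )


def _descend(
    x0: np.ndarray,
    objective_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, list[float]]:
    """Gradient descent with backtracking step halving (monotone by design)."""
    x = x0.copy()
    f, g = objective_grad(x)
    if not np.isfinite(f):
        raise ValueError("non-finite objective at the initial configuration")
    trace = [f]
    gmax = float(np.abs(g).max())
    scale = float(np.abs(x).max())
    step = 0.1 * (scale + 1.0) / (gmax + 1e-30)
    for _ in range(max_iter):
        if f == 0.0 or gmax == 0.0:
            break
        accepted = False
        for _ in range(60):
            x_new = x - step * g
            f_new, g_new = objective_grad(x_new)
            if np.isfinite(f_new) and f_new < f:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel = (f - f_new) / max(abs(f), 1e-300)
        x, f, g = x_new, f_new, g_new
        gmax = float(np.abs(g).max())
        trace.append(f)
        step *= 1.3
        if rel < tol:
            break
    return x, trace


def sammon_embed(
    distances: DistanceMatrix,
    init: Embedding | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> Embedding:
    """Sammon mapping of a distance matrix into 2D.

    Minimizes the Sammon stress
    ``E = (1/sum delta) * sum_{i<j} (delta_ij - d_ij)^2 / delta_ij``
    (``delta`` input distances, ``d`` 2D Euclidean distances) by gradient
    descent with step halving, starting from the classical MDS configuration
    unless another init is supplied.  Zero input distances (duplicate
    samples) are floored at 1e-12 so duplicates simply co-locate.
    """
    n = distances.n_samples
    if init is None:
        init = mds_embed(distances, n_dims=2)
    if init.coords.shape != (n, 2):
        raise ValueError(f"init coords shape {init.coords.shape}, expected ({n}, 2)")
    delta = np.maximum(distances.values, _DIST_FLOOR)
    np.fill_diagonal(delta, 1.0)  # diagonal never enters the off-diagonal sums
    off = ~np.eye(n, dtype=bool)
    c = distances.values[np.triu_indices(n, 1)].sum()
    if c <= 0:
        raise ValueError("degenerate distance matrix: all distances zero")

    def stress_of(X: np.ndarray) -> tuple[float, np.ndarray]:
        diff = X[:, None, :] - X[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, 1.0)
        dd = d - delta
        ratio = np.where(off, dd**2 / delta, 0.0)
        stress = float(ratio[np.triu_indices(n, 1)].sum() / c)
        if not np.isfinite(stress):
            i, j = np.argwhere(~np.isfinite(ratio))[0]
            raise ValueError(
                f"non-finite stress for pair "
                f"({distances.sample_ids[i]!r}, {distances.sample_ids[j]!r})"
            )
        return stress, d

    def direction(X: np.ndarray, d: np.ndarray) -> np.ndarray:
        # classic diagonal-Newton step: grad / |diagonal Hessian|, per coordinate
        diff = X[:, None, :] - X[None, :, :]
        ds = np.maximum(d, _DIST_FLOOR)
        dd = ds - delta
        w = np.where(off, 1.0 / (delta * ds), 0.0)
        grad = (2.0 / c) * ((w * dd)[:, :, None] * diff).sum(axis=1)
        hess = (2.0 / c) * (
            w[:, :, None] * (dd[:, :, None] + (diff**2 / ds[:, :, None]) * (1.0 - dd[:, :, None] / ds[:, :, None]))
        ).sum(axis=1)
        return grad / np.maximum(np.abs(hess), 1e-12)

    X = init.coords.copy()
    stress, d = stress_of(X)
    trace = [stress]
    for _ in range(max_iter):
        if stress == 0.0:
            break
        step_dir = direction(X, d)
        step = 0.5
        accepted = False
        for _ in range(40):
            X_new = X - step * step_dir
            s_new, d_new = stress_of(X_new)
            if np.isfinite(s_new) and s_new < stress:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel = (stress - s_new) / max(stress, 1e-300)
        X, stress, d = X_new, s_new, d_new
        trace.append(stress)
        if rel < tol:
            break
    coords = X
    return Embedding(
        sample_ids=distances.sample_ids,
        coords=coords,
        method="sammon",
        trace=tuple(trace),
    )


def l1_kernel_pca_init(collection: ProfileCollection) -> Embedding:
    """Kernel PCA with the L1 kernel, used to initialize UKR.

    ``K_ij = exp(-||y_i - y_j||_1 / s)`` with ``s`` the median off-diagonal
    L1 distance; the kernel matrix is double-centered and the top-2
    eigenvectors (scaled by the square roots of their eigenvalues) give
    centered starting coordinates.
    """
    n = collection.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    D = squareform(pdist(collection.counts, "cityblock"))
    offdiag = D[~np.eye(n, dtype=bool)]
    s = float(np.median(offdiag))
    if s <= 0:
        s = 1.0  # all samples identical; kernel matrix is constant
    K = np.exp(-D / s)
    J = np.eye(n) - np.ones((n, n)) / n
    Kc = J @ K @ J
    Kc = (Kc + Kc.T) / 2.0
    w, V = np.linalg.eigh(Kc)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if w[0] <= 1e-12:
        raise ValueError("degenerate (rank-0) kernel matrix; cannot initialize")
    lam = np.clip(w[:2], 0.0, None)
    coords = _fix_signs(V[:, :2]) * np.sqrt(lam)
    return Embedding(sample_ids=collection.sample_ids, coords=coords, method="ukr")


def _ukr_objective_grad(X: np.ndarray, Y: np.ndarray, ids) -> tuple[float, np.ndarray]:
    """Leave-one-out L1 reconstruction error of the L1-kernel regressor.

    R(X) = sum_i ||y_i - f_{-i}(X_i)||_1 with
    f_{-i}(x) = sum_{j != i} y_j K(x - X_j) / sum_{j != i} K(x - X_j) and
    K(u) = exp(-||u||_1).  Returns R and its (sub)gradient with respect to X.
    """
    diff = X[:, None, :] - X[None, :, :]
    B = np.exp(-np.abs(diff).sum(-1))
    np.fill_diagonal(B, 0.0)
    s = B.sum(axis=1)
    if np.any(s < 1e-290):
        i = int(np.argmin(s))
        raise ValueError(
            f"leave-one-out kernel weight vanished for sample {ids[i]!r}; "
            "latent point is isolated"
        )
    F = (B @ Y) / s[:, None]
    E = Y - F
    R = float(np.abs(E).sum())
    G = np.sign(E)
    # dR/dB_ij = g_i . (f_i - y_j) / s_i  (j != i)
    gf = (G * F).sum(axis=1)
    gY = G @ Y.T
    C = (gf[:, None] - gY) / s[:, None]
    np.fill_diagonal(C, 0.0)
    M = B * (C + C.T)
    grad = -(M[:, :, None] * np.sign(diff)).sum(axis=1)
    return R, grad


def ukr_embed(
    collection: ProfileCollection,
    init: Embedding | None = None,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> Embedding:
    """Unsupervised kernel regression embedding with the L1 kernel.

    Latent 2D coordinates are optimized so the leave-one-out Nadaraya-Watson
    reconstruction of each profile from its latent neighbors is as close as
    possible (in L1) to the profile itself; leaving sample i out of its own
    reconstruction prevents the trivial collapse solution.  The kernel
    bandwidth is absorbed into the latent scale: the initial configuration
    (L1-kernel PCA unless given) is rescaled over a deterministic grid to
    the scale minimizing the objective before descent starts.
    """
    n = collection.n_samples
    Y = collection.counts
    if init is None:
        init = l1_kernel_pca_init(collection)
    if init.coords.shape != (n, 2):
        raise ValueError(f"init coords shape {init.coords.shape}, expected ({n}, 2)")
    X0 = init.coords - init.coords.mean(axis=0)
    spread = float(np.abs(X0).max())
    if spread == 0:
        X0 = X0 + 0.0
        base = np.zeros_like(X0)
        best = X0
    else:
        base = X0 / spread
        best, best_r = None, np.inf
        for mult in np.logspace(-1.5, 2.0, 15):
            try:
                r, _ = _ukr_objective_grad(base * mult, Y, collection.sample_ids)
            except ValueError:
                continue
            if r < best_r:
                best, best_r = base * mult, r
        if best is None:
            raise ValueError("no usable latent scale for the UKR initialization")

    coords, trace = _descend(
        best, lambda X: _ukr_objective_grad(X, Y, collection.sample_ids), max_iter, tol
    )
    return Embedding(
        sample_ids=collection.sample_ids,
        coords=coords,
        method="ukr",
        trace=tuple(trace),
    )


def embedding_accuracy(
    embedding: Embedding, labels: Sequence[str], k: int = 10
) -> NeighborhoodReport:
    """Neighborhood accuracy of the 2D map under Euclidean distances."""
    values = squareform(pdist(embedding.coords, "euclidean"))
    dm = DistanceMatrix(
        sample_ids=embedding.sample_ids, values=values, metric_name="euclidean"
    )
    return loocv_accuracy(dm, labels, k=k)


def write_embedding(
    embedding: Embedding,
    path: str | Path,
    labels: Sequence[str] | None = None,
    delimiter: str = "\t",
) -> None:
    """Delimited text: sample ID, x, y (and label when given)."""
    with open(path, "w") as fh:
        fh.write(f"# method: {embedding.method}\n")
        if embedding.explained_variance is not None:
            ev = ",".join(f"{v:.6f}" for v in embedding.explained_variance)
            fh.write(f"# explained_variance: {ev}\n")
        header = ["sample_id", "x", "y"] + (["label"] if labels is not None else [])
        fh.write(delimiter.join(header) + "\n")
        for i, sid in enumerate(embedding.sample_ids):
            row = [sid, f"{embedding.coords[i, 0]:.10g}", f"{embedding.coords[i, 1]:.10g}"]
            if labels is not None:
                row.append(str(labels[i]))
            fh.write(delimiter.join(row) + "\n")


def plot_embedding(
    embedding: Embedding, labels: Sequence[str], path: str | Path
) -> None:
    """Scatter plot with habitat-colored markers and a legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        ax.scatter(
            embedding.coords[idx, 0], embedding.coords[idx, 1], s=14, label=lab
        )
    ax.set_title(embedding.method.upper())
    if embedding.explained_variance is not None:
        ev = embedding.explained_variance
        ax.set_xlabel(f"dim 1 ({100 * ev[0]:.1f}%)")
        ax.set_ylabel(f"dim 2 ({100 * ev[1]:.1f}%)")
    ax.legend(fontsize=8, markerscale=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
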