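"""Diffusion-map embedding of marker space.

Standard diffusion-map construction: Gaussian kernel
``K = exp(-d^2 / eps)`` on pairwise squared Euclidean distances,
density normalization with alpha = 1 (Laplace-Beltrami, removing
sampling-density artifacts), row normalization to a Markov transition
matrix, and eigendecomposition. Diffusion components (DCs) are the
nontrivial right eigenvectors scaled by their eigenvalues; along a DC
axis, marker expression can be profiled in equal-width bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["DiffusionEmbedding", "diffusion_map", "axis_profile"]


@dataclass
class DiffusionEmbedding:
    coords: pd.DataFrame        # cells x DC1..DCm
    eigenvalues: np.ndarray     # descending, |lambda| <= 1
    epsilon: float
    transition: np.ndarray | None = None  # row-stochastic Markov matrix


def diffusion_map(
    data,
    epsilon: float | str = "auto",
    n_components: int = 3,
    max_cells: int = 6000,
    seed: int = 0,
    keep_transition: bool = False,
) -> DiffusionEmbedding:
    """Diffusion-map coordinates of a cells x features matrix.

    ``epsilon`` is the Gaussian kernel bandwidth on squared distances;
    ``"auto"`` uses the median pairwise squared distance. Inputs
    larger than ``max_cells`` are randomly subsampled (the kernel is
    dense O(n^2)). Duplicate points that would make the normalization
    singular trigger a jitter warning and a tiny perturbation. Each
    component's sign is fixed so that its largest-magnitude coordinate
    is positive.
    """
    X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, dtype=float)
    index = data.index if isinstance(data, pd.DataFrame) else pd.RangeIndex(len(X))
    if len(X) > max_cells:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(X), size=max_cells, replace=False))
        X, index = X[keep], index[keep]
    n = len(X)
    if n < n_components + 2:
        raise ValueError("need at least n_components + 2 cells")

    d2 = squareform(pdist(X, metric="sqeuclidean"))
    if epsilon == "auto":
        off = d2[np.triu_indices(n, k=1)]
        epsilon = float(np.median(off))
        if epsilon == 0:
            epsilon = 1.0
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    K = np.exp(-d2 / epsilon)

    # alpha = 1 density normalization, then symmetric conjugate of the
    # Markov matrix for a stable eigendecomposition
    q = K.sum(axis=1)
    if (q <= 0).any() or np.any(~np.isfinite(q)):
        warnings.warn("degenerate kernel rows; jittering input", stacklevel=2)
        rng = np.random.default_rng(seed)
        d2 += rng.uniform(0, 1e-12, size=d2.shape)
        K = np.exp(-d2 / epsilon)
        q = K.sum(axis=1)
    K1 = K / np.outer(q, q)
    d = K1.sum(axis=1)
    S = K1 / np.sqrt(np.outer(d, d))
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1][: n_components + 1]
    lam = evals[order]
    psi = evecs[:, order] / np.sqrt(d)[:, None]
    # drop the trivial constant eigenvector (eigenvalue 1)
    lam, psi = lam[1:], psi[:, 1:]
    psi /= np.linalg.norm(psi, axis=0)
    coords = psi * lam
    for j in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] *= -1
    cols = [f"DC{j + 1}" for j in range(coords.shape[1])]
    P = K1 / d[:, None] if keep_transition else None
    return DiffusionEmbedding(
        coords=pd.DataFrame(coords, index=index, columns=cols),
        eigenvalues=lam,
        epsilon=float(epsilon),
        transition=P,
    )


def axis_profile(
    axis_values, marker_values, n_bins: int = 20
) -> pd.DataFrame:
    """Binned mean +/- SD of a marker along an embedding axis.

    Equal-width bins over the axis range; empty bins are reported with
    NaN mean/SD. Returns columns ``bin_center``, ``n``, ``mean``, ``sd``.
    """
    x = np.asarray(axis_values, dtype=float)
    y = np.asarray(marker_values, dtype=float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    which = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = y[which == b]
        rows.append(
            dict(
                bin_center=0.5 * (edges[b] + edges[b + 1]),
                n=len(sel),
                mean=float(sel.mean()) if len(sel) else np.nan,
                sd=float(sel.std()) if len(sel) else np.nan,
            )
        )
    return pd.DataFrame(rows)
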