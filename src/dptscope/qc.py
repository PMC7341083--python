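"""Single-cell RNA-seq quality control and normalization.

Four per-cell indices are computed — UMI count, detected genes,
mitochondrial UMI fraction and dissociation/sorting-stress UMI
fraction — and a cell is discarded if any index is a boxplot upper
outlier (value > Q3 + k*IQR, Tukey fence, k = 1.5) or if it has fewer
than 200 detected genes. Retained counts are depth-normalized to
10,000 per cell and log-transformed with pseudocount 1. Highly
variable genes are ranked by mean-standardized dispersion with
ribosomal and heat-shock genes excluded from the list.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "compute_qc",
    "flag_low_quality",
    "normalize_tpm_like",
    "select_hvg",
    "regress_out_confounders",
]


def _dense(X) -> np.ndarray:
    import scipy.sparse as sp

    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def compute_qc(
    adata,
    mito_genes: list[str] | None = None,
    dissoc_genes: list[str] | None = None,
    mito_prefix: str = "MT-",
) -> pd.DataFrame:
    """Per-cell QC indices from a cells x genes AnnData of raw counts.

    ``mito_genes`` defaults to genes with the ``MT-`` name prefix. An
    empty matching gene set yields a zero fraction with a warning.
    Returns columns ``n_umi``, ``n_gene``, ``pct_mito``, ``pct_dissoc``.
    """
    X = _dense(adata.X).astype(float)
    genes = pd.Index(adata.var_names)
    if mito_genes is None:
        mito_genes = [g for g in genes if g.startswith(mito_prefix)]
    dissoc_genes = dissoc_genes or []
    for name, gs in (("mitochondrial", mito_genes), ("dissociation", dissoc_genes)):
        if not set(gs) & set(genes):
            warnings.warn(f"no {name} genes found in matrix; fraction set to 0", stacklevel=2)
    n_umi = X.sum(axis=1)
    n_gene = (X > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_umi > 0, X[:, genes.isin(mito_genes)].sum(axis=1) / n_umi, 0.0)
        pct_dissoc = np.where(n_umi > 0, X[:, genes.isin(dissoc_genes)].sum(axis=1) / n_umi, 0.0)
    return pd.DataFrame(
        {"n_umi": n_umi, "n_gene": n_gene, "pct_mito": pct_mito, "pct_dissoc": pct_dissoc},
        index=adata.obs_names,
    )


_OUTLIER_METRICS = ("n_umi", "n_gene", "pct_mito", "pct_dissoc")


def flag_low_quality(
    qc: pd.DataFrame, iqr_k: float = 1.5, min_genes: int = 200
) -> tuple[pd.Series, pd.DataFrame]:
    """Mark low-quality cells by the joint upper-outlier rule.

    A cell is removed if any of the four indices exceeds its Tukey
    upper fence Q3 + ``iqr_k``*IQR (quartiles by linear interpolation
    over all cells jointly), or if ``n_gene < min_genes``. Returns
    ``(remove_mask, reasons)`` where ``reasons`` holds one boolean
    column per rule. Fewer than 4 cells leaves the quartiles
    undefined and raises.
    """
    if len(qc) < 4:
        raise ValueError("need at least 4 cells to define quartiles")
    reasons = pd.DataFrame(index=qc.index)
    for m in _OUTLIER_METRICS:
        q1, q3 = np.percentile(qc[m].to_numpy(dtype=float), [25, 75])
        fence = q3 + iqr_k * (q3 - q1)
        reasons[f"outlier_{m}"] = qc[m].to_numpy(dtype=float) > fence
    reasons["min_genes"] = qc["n_gene"].to_numpy() < min_genes
    return reasons.any(axis=1).rename("remove"), reasons


def normalize_tpm_like(adata, scale: float = 10_000.0):
    """Depth normalization: per cell, counts are divided by the cell's
    UMI total and multiplied by 10,000, then ln(1 + v) transformed.

    Zero-UMI cells are excluded with a warning. Returns a new AnnData
    with the log-normalized matrix in ``.X``, raw counts in
    ``.layers["counts"]`` and the pre-log values summing to ``scale``
    per cell.
    """
    X = _dense(adata.X).astype(float)
    tot = X.sum(axis=1)
    keep = tot > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-UMI cells", stacklevel=2)
    out = adata[keep].copy()
    Xk = X[keep]
    v = Xk / Xk.sum(axis=1, keepdims=True) * scale
    out.layers["counts"] = Xk
    out.X = np.log1p(v)
    return out


def select_hvg(
    adata, n_hvg: int = 2000, exclude: list[str] | None = None,
    flavor: str = "cell_ranger",
) -> list[str]:
    """Top highly variable genes by mean-standardized dispersion
    (median-normalized within equal-frequency mean bins; computed on
    the log-normalized matrix), with the exclusion sets (ribosomal /
    heat-shock response genes) removed before the top-``n_hvg`` cut.
    The median-based bin normalization is robust to the low-mean
    dispersion inflation that a z-score normalization shows.
    """
    import scanpy as sc

    if n_hvg <= 0:
        raise ValueError("n_hvg must be positive")
    tmp = adata.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(tmp, flavor=flavor, n_top_genes=min(n_hvg, tmp.n_vars))
    disp = tmp.var["dispersions_norm"].sort_values(ascending=False)
    excluded = set(exclude or [])
    ranked = [g for g in disp.index if g not in excluded and np.isfinite(disp[g])]
    if n_hvg > len(ranked):
        warnings.warn("n_hvg exceeds available genes; returning all", stacklevel=2)
    return ranked[:n_hvg]


def regress_out_confounders(
    adata, qc: pd.DataFrame, covariates: tuple[str, ...] = ("n_umi", "pct_mito")
):
    """Residualize each gene on per-cell confounders (UMI depth and
    mitochondrial fraction) by ordinary least squares; optional stage
    applied to the normalized matrix."""
    X = _dense(adata.X).astype(float)
    C = qc.loc[adata.obs_names, list(covariates)].to_numpy(dtype=float)
    C = np.column_stack([np.ones(len(C)), C])
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    out = adata.copy()
    out.X = X - C @ beta
    return out
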