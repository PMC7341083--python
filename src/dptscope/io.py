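"""Readers and writers for the on-disk formats the toolkit consumes.

Count matrices travel as 10x-dialect Matrix Market triples
(``matrix.mtx`` genes x cells, ``genes.tsv``, ``barcodes.tsv``,
uncompressed); everything else is plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["write_10x_mtx", "read_10x_mtx", "read_marker_csv"]


def write_10x_mtx(adata, outdir: str | Path) -> Path:
    """Write a cells x genes AnnData as genes x cells MTX + TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    M = sp.csc_matrix(X.T if not sp.issparse(X) else X.T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), M)
    pd.DataFrame({"gene_id": adata.var_names, "gene_name": adata.var_names}).to_csv(
        outdir / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "cell_metadata.csv")
    return outdir


def read_10x_mtx(indir: str | Path):
    """Read a 10x-dialect MTX directory into a cells x genes AnnData."""
    import anndata as ad

    indir = Path(indir)
    M = scipy.io.mmread(str(indir / "matrix.mtx")).tocsr().T
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.DataFrame(index=barcodes.to_numpy())
    meta_path = indir / "cell_metadata.csv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, index_col=0)
    adata = ad.AnnData(
        X=np.asarray(M.todense()), obs=obs,
        var=pd.DataFrame(index=genes.iloc[:, -1].astype(str).to_numpy()),
    )
    return adata


def read_marker_csv(path: str | Path, annotation_cols: tuple[str, ...] = ("patient", "region")):
    """Split a cells x (markers + annotation) CSV into marker matrix
    and annotation frames."""
    df = pd.read_csv(path)
    ann_cols = [c for c in annotation_cols if c in df.columns]
    ann = df[ann_cols]
    markers = df.drop(columns=ann_cols)
    return markers, ann
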