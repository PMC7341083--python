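"""Radius-based spatial proximity statistics on multiplex-IF cell maps.

Around each index-phenotype cell, target-phenotype cells within fixed
radii (15 and 45 um by default) are counted per tissue core with an
inclusive boundary (d <= r) and the index cell excluded from its own
counts. Count distributions are compared between phenotypes with a
pooled-variance Student's t-test, and per-sample phenotype densities
are correlated across a cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .cytof import compare_group_levels

__all__ = [
    "PHENOTYPES",
    "neighbor_counts",
    "neighbor_counts_bruteforce",
    "compare_neighbor_counts",
    "density_correlation",
    "cell_density",
]

PHENOTYPES = ("DPT_PD1pos", "DPT_PD1neg", "CD4_PD1pos", "CD8_PD1pos", "other")

_REQUIRED = ("x_um", "y_um", "phenotype")


def _check_map(cells: pd.DataFrame, labels) -> None:
    for c in _REQUIRED:
        if c not in cells.columns:
            raise KeyError(f"spatial table lacks column '{c}'")
    known = set(cells["phenotype"].unique())
    bad = set(labels) - known
    if bad:
        raise ValueError(
            f"unknown phenotype label(s) {sorted(bad)}; present: {sorted(known)}"
        )


def neighbor_counts(
    cells: pd.DataFrame,
    index_label: str,
    target_labels: tuple[str, ...],
    radii: tuple[float, ...] = (15.0, 45.0),
) -> pd.DataFrame:
    """Counts of each target phenotype within each radius of every
    index cell, computed per core (no cross-core neighbors; KD-tree
    radius queries, boundary inclusive).

    Returns one row per index cell with columns ``core_id`` and
    ``{target}|r{radius}``.
    """
    _check_map(cells, [index_label, *target_labels])
    if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
        raise ValueError("radii must be positive and sorted ascending")
    core_col = cells["core_id"] if "core_id" in cells.columns else pd.Series("core", index=cells.index)
    out_rows = []
    out_index = []
    for core, grp in cells.groupby(core_col, observed=True, sort=True):
        idx_cells = grp[grp["phenotype"] == index_label]
        if idx_cells.empty:
            continue
        P = idx_cells[["x_um", "y_um"]].to_numpy(dtype=float)
        row_block = {}
        for target in target_labels:
            tgt = grp[grp["phenotype"] == target]
            T = tgt[["x_um", "y_um"]].to_numpy(dtype=float)
            if len(T) == 0:
                for r in radii:
                    row_block[f"{target}|r{r:g}"] = np.zeros(len(P), dtype=int)
                continue
            tree = cKDTree(T)
            self_target = target == index_label
            for r in radii:
                counts = np.array([len(h) for h in tree.query_ball_point(P, r)])
                if self_target:
                    counts -= 1  # index cell never counts itself
                row_block[f"{target}|r{r:g}"] = counts
        block = pd.DataFrame(row_block, index=idx_cells.index)
        block.insert(0, "core_id", core)
        out_rows.append(block)
        out_index.extend(idx_cells.index)
    if not out_rows:
        cols = ["core_id"] + [f"{t}|r{r:g}" for t in target_labels for r in radii]
        return pd.DataFrame(columns=cols)
    return pd.concat(out_rows)


def neighbor_counts_bruteforce(
    cells: pd.DataFrame,
    index_label: str,
    target_labels: tuple[str, ...],
    radii: tuple[float, ...] = (15.0, 45.0),
) -> pd.DataFrame:
    """O(n^2) reference implementation of :func:`neighbor_counts`."""
    _check_map(cells, [index_label, *target_labels])
    core_col = cells["core_id"] if "core_id" in cells.columns else pd.Series("core", index=cells.index)
    blocks = []
    for core, grp in cells.groupby(core_col, observed=True, sort=True):
        idx_cells = grp[grp["phenotype"] == index_label]
        if idx_cells.empty:
            continue
        block = {}
        P = idx_cells[["x_um", "y_um"]].to_numpy(dtype=float)
        for target in target_labels:
            tgt = grp[grp["phenotype"] == target]
            T = tgt[["x_um", "y_um"]].to_numpy(dtype=float)
            d = np.sqrt(((P[:, None, :] - T[None, :, :]) ** 2).sum(-1)) if len(T) else np.empty((len(P), 0))
            for r in radii:
                c = (d <= r).sum(axis=1)
                if target == index_label:
                    c -= 1
                block[f"{target}|r{r:g}"] = c
        b = pd.DataFrame(block, index=idx_cells.index)
        b.insert(0, "core_id", core)
        blocks.append(b)
    return pd.concat(blocks) if blocks else pd.DataFrame()


def compare_neighbor_counts(counts_a, counts_b) -> pd.DataFrame:
    """Pooled-variance two-sided t-test per matching count column.

    ``counts_a`` / ``counts_b`` are count frames from
    :func:`neighbor_counts` (e.g. two targets around the same index
    cells, or one target around two index phenotypes); columns are
    matched by radius suffix when the targets differ.
    """
    a_cols = [c for c in counts_a.columns if "|r" in str(c)]
    b_cols = [c for c in counts_b.columns if "|r" in str(c)]
    pairs = []
    if set(a_cols) == set(b_cols):
        pairs = [(c, c) for c in a_cols]
    else:
        by_r_a = {str(c).split("|r")[1]: c for c in a_cols}
        by_r_b = {str(c).split("|r")[1]: c for c in b_cols}
        pairs = [(by_r_a[r], by_r_b[r]) for r in by_r_a if r in by_r_b]
    rows = []
    for ca, cb in pairs:
        a = counts_a[ca].to_numpy(dtype=float)
        b = counts_b[cb].to_numpy(dtype=float)
        t, p = compare_group_levels(a, b)
        rows.append(
            dict(
                column_a=ca, column_b=cb, radius=float(str(ca).split("|r")[1]),
                t=t, p=p,
                mean_a=a.mean(), sd_a=a.std(ddof=1), n_a=len(a),
                mean_b=b.mean(), sd_b=b.std(ddof=1), n_b=len(b),
            )
        )
    return pd.DataFrame(rows)


def cell_density(
    cells: pd.DataFrame, phenotype: str, area_mm2: float | None = None
) -> float:
    """Phenotype density in cells per mm^2 for one core; the core area
    defaults to the convex hull of all cells in the table."""
    _check_map(cells, [phenotype])
    if area_mm2 is None:
        from scipy.spatial import ConvexHull

        pts = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        area_mm2 = ConvexHull(pts).volume / 1e6  # um^2 -> mm^2
    n = int((cells["phenotype"] == phenotype).sum())
    return n / area_mm2


def density_correlation(density_a, density_b) -> dict[str, float]:
    """Pearson correlation between two per-sample density vectors,
    with the least-squares line. Returns r, p, slope, intercept, n."""
    a = np.asarray(density_a, dtype=float)
    b = np.asarray(density_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two equal-length vectors of >= 3 samples")
    r, p = stats.pearsonr(a, b)
    fit = stats.linregress(a, b)
    return dict(r=float(r), p=float(p), slope=float(fit.slope),
                intercept=float(fit.intercept), n=len(a))
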