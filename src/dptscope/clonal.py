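"""Clonotype construction and Shannon-entropy clonal indices.

Clonotypes are defined by identical sets of productive CDR3 sequences,
scoped within a patient. Three entropy-based indices summarize the
repertoire structure of cell clusters:

* ``expa`` — clonal expansion of a cluster: one minus the normalized
  Shannon entropy of its within-cluster clone-size distribution. A
  cluster of singletons scores 0; a monoclonal cluster scores 1.
* ``tran`` — state transition of a cluster: the clone-size-weighted
  mean of each clone's normalized entropy over cluster assignments.
  Clones confined to one cluster contribute 0.
* ``ptran`` — pairwise transition between two clusters: the same
  quantity with clone occupancies renormalized over the pair and the
  entropy normalized by ln 2; symmetric in the pair.

All entropies use natural logarithms.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "build_clonotypes",
    "startrac_expa",
    "startrac_tran",
    "pstartrac_tran",
    "pstartrac_tran_matrix",
    "shared_clone_counts",
    "venn_regions",
    "expanded_clone_cooccurrence",
    "top_clone_projection",
]


class ClonotypeError(ValueError):
    """Raised on malformed contig or clonotype input."""


def build_clonotypes(
    contigs: pd.DataFrame,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group cells into clonotypes by their productive CDR3 set.

    Parameters
    ----------
    contigs
        Long table with one row per contig: columns ``barcode``,
        ``chain`` (e.g. TRA/TRB), ``cdr3``, ``productive`` (bool or
        the 10x "True"/"False" strings). Cells without any productive
        contig are dropped (their number is recorded in
        ``result.attrs["n_dropped"]``).
    labels
        Optional per-barcode annotation with columns ``barcode`` and
        any of ``compartment``, ``cluster``, ``patient``; merged onto
        the output. Clonotype identity is scoped by patient: the same
        CDR3 set in two patients yields two distinct clonotype ids.

    Returns
    -------
    DataFrame with one row per cell: ``barcode``, ``clonotype_id``,
    ``cdr3`` (chain-annotated, ';'-joined) plus any label columns.
    """
    required = {"barcode", "chain", "cdr3", "productive"}
    missing = required - set(contigs.columns)
    if missing:
        raise ClonotypeError(f"contig table lacks columns: {sorted(missing)}")
    prod = contigs["productive"]
    if prod.dtype == object:
        prod = prod.astype(str).str.lower().isin({"true", "t", "1", "yes"})
    kept = contigs.loc[prod.astype(bool)].copy()

    n_total = contigs["barcode"].nunique()
    # CDR3 key: sorted chain:cdr3 pairs so contig order is irrelevant
    kept["pair"] = kept["chain"].astype(str) + ":" + kept["cdr3"].astype(str)
    key = (
        kept.groupby("barcode")["pair"]
        .apply(lambda s: ";".join(sorted(s)))
        .rename("cdr3")
        .reset_index()
    )
    if labels is not None:
        if "barcode" not in labels.columns:
            raise ClonotypeError("labels table lacks a 'barcode' column")
        key = key.merge(labels, on="barcode", how="left")
    patient = key["patient"] if "patient" in key.columns else pd.Series("P0", index=key.index)
    scoped = patient.astype(str) + "|" + key["cdr3"]
    codes, _ = pd.factorize(scoped, sort=True)
    key["clonotype_id"] = [f"clone_{c:05d}" for c in codes]
    key = key[[c for c in ("barcode", "clonotype_id", "cdr3", "compartment", "cluster", "patient") if c in key.columns]]
    key.attrs["n_dropped"] = n_total - len(key)
    return key


def _check_table(table: pd.DataFrame, by: str) -> None:
    for col in ("clonotype_id", by):
        if col not in table.columns:
            raise ClonotypeError(f"clonotype table lacks column '{col}'")


def startrac_expa(table: pd.DataFrame, by: str = "cluster") -> pd.DataFrame:
    """Per-cluster clonal-expansion index.

    For cluster *i* with clone sizes :math:`n_{ij}` summing to
    :math:`n_i` over :math:`N_i` distinct clones, the within-cluster
    entropy is :math:`H_i = -\\sum_j p_j \\ln p_j` with
    :math:`p_j = n_{ij}/n_i`, and
    ``expa_i = 1 - H_i / ln(N_i)`` for :math:`N_i \\ge 2`. A
    monoclonal cluster (:math:`N_i = 1`) is assigned ``expa = 1``.

    Returns a DataFrame indexed by cluster with columns
    ``n_cells``, ``n_clones``, ``entropy``, ``expa``.
    """
    _check_table(table, by)
    rows = {}
    for cl, grp in table.groupby(by, sort=True, observed=True):
        sizes = grp["clonotype_id"].value_counts().to_numpy(dtype=float)
        n = sizes.sum()
        p = sizes / n
        H = float(-(p * np.log(p)).sum())
        N = len(sizes)
        expa = 1.0 if N == 1 else 1.0 - H / np.log(N)
        rows[cl] = dict(n_cells=int(n), n_clones=N, entropy=H, expa=expa)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = by
    return out


def _clone_cluster_counts(table: pd.DataFrame, by: str) -> pd.DataFrame:
    return pd.crosstab(table["clonotype_id"], table[by])


def startrac_tran(table: pd.DataFrame, by: str = "cluster") -> pd.DataFrame:
    """Per-cluster state-transition index.

    Clone *j* occupies clusters with fractions
    :math:`q_{jc}`; its normalized entropy is
    :math:`\\tilde H_j = -\\sum_c q_{jc} \\ln q_{jc} / \\ln K` over the
    :math:`K \\ge 2` clusters present. The cluster index is the
    clone-mass-weighted mean
    ``tran_i = sum_j (n_{ij} / n_i) * H~_j``.
    """
    _check_table(table, by)
    ct = _clone_cluster_counts(table, by)
    K = ct.shape[1]
    if K < 2:
        raise ClonotypeError("tran is undefined with fewer than 2 clusters")
    M = ct.to_numpy(dtype=float)
    q = M / M.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(q), 0.0)
    H_clone = -terms.sum(axis=1) / np.log(K)
    n_i = M.sum(axis=0)
    w = M / n_i  # (clone, cluster) weight within each cluster
    tran = (w * H_clone[:, None]).sum(axis=0)
    out = pd.DataFrame({"n_cells": n_i.astype(int), "tran": tran}, index=ct.columns)
    out.index.name = by
    return out


def pstartrac_tran(table: pd.DataFrame, i, k, by: str = "cluster") -> float:
    """Pairwise transition index between clusters *i* and *k*.

    Each clone is restricted to its cells in the pair, its occupancy
    renormalized over the two clusters and its entropy normalized by
    ln 2; clones are weighted by their cell mass within the pair.
    Symmetric in (i, k); 0 when no clone spans both clusters, 1 when
    every clone splits evenly.
    """
    _check_table(table, by)
    if i == k:
        raise ClonotypeError("pairwise transition needs two distinct clusters")
    sub = table.loc[table[by].isin([i, k])]
    if sub.empty:
        return float("nan")
    ct = pd.crosstab(sub["clonotype_id"], sub[by]).reindex(columns=[i, k], fill_value=0)
    M = ct.to_numpy(dtype=float)
    tot = M.sum(axis=1)
    q = M / tot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(q), 0.0)
    H = -terms.sum(axis=1) / np.log(2.0)
    w = tot / tot.sum()
    return float((w * H).sum())


def pstartrac_tran_matrix(table: pd.DataFrame, by: str = "cluster") -> pd.DataFrame:
    """Symmetric matrix of pairwise transition indices over all clusters."""
    clusters = sorted(table[by].unique())
    out = pd.DataFrame(0.0, index=clusters, columns=clusters)
    for a, b in combinations(clusters, 2):
        v = pstartrac_tran(table, a, b, by=by)
        out.loc[a, b] = out.loc[b, a] = v
    return out


def shared_clone_counts(
    table: pd.DataFrame, by_a: str = "cluster", by_b: str | None = None
) -> pd.DataFrame:
    """Count distinct clonotypes shared between groups.

    Entry (a, b) is the number of distinct clonotype ids observed in
    both group *a* of partition ``by_a`` and group *b* of partition
    ``by_b`` (default: the same partition, so the diagonal holds each
    group's unique-clone count).
    """
    by_b = by_b or by_a
    _check_table(table, by_a)
    _check_table(table, by_b)
    inc_a = (pd.crosstab(table["clonotype_id"], table[by_a]) > 0).astype(int)
    inc_b = (pd.crosstab(table["clonotype_id"], table[by_b]) > 0).astype(int)
    inc_b = inc_b.reindex(inc_a.index, fill_value=0)
    out = inc_a.T @ inc_b
    out.index.name, out.columns.name = by_a, by_b
    return out


def venn_regions(table: pd.DataFrame, by: str = "compartment") -> dict[str, int]:
    """Exclusive region sizes of the clone-overlap Venn diagram.

    Keys are '&'-joined sorted group names; values count clonotypes
    found in exactly that set of groups.
    """
    _check_table(table, by)
    membership = table.groupby("clonotype_id")[by].apply(lambda s: "&".join(sorted(set(s))))
    return membership.value_counts().to_dict()


def expanded_clone_cooccurrence(
    table: pd.DataFrame, min_freq: int = 10, by: str = "compartment"
) -> tuple[pd.DataFrame, pd.Series]:
    """Compartment incidence of expanded clones.

    Clones whose total cell count is strictly greater than ``min_freq``
    (default 10) are listed with their per-compartment presence; the
    summary gives, for every unordered compartment pair, the fraction
    of expanded clones present in both.
    """
    _check_table(table, by)
    sizes = table["clonotype_id"].value_counts()
    expanded = sizes.index[sizes > min_freq]
    inc = (
        pd.crosstab(table["clonotype_id"], table[by]).reindex(expanded, fill_value=0) > 0
    )
    groups = list(inc.columns)
    pair_frac = {}
    for a, b in combinations(groups, 2):
        pair_frac[f"{a}&{b}"] = float((inc[a] & inc[b]).mean()) if len(inc) else float("nan")
    inc = inc.copy()
    inc["clone_size"] = sizes.reindex(expanded)
    return inc, pd.Series(pair_frac, name="fraction_coexisting")


def top_clone_projection(
    table: pd.DataFrame, coords: pd.DataFrame | None = None, n_top: int = 6
) -> pd.DataFrame:
    """Highlight cells of the ``n_top`` largest clones.

    Clones are ranked by total size (descending), ties broken by
    clonotype id. Returns one boolean column per top clone, indexed
    like ``table`` (joined with ``coords`` when given, matched on
    barcode/index).
    """
    _check_table(table, "clonotype_id")
    sizes = (
        table["clonotype_id"]
        .value_counts()
        .rename_axis("clonotype_id")
        .reset_index(name="size")
        .sort_values(["size", "clonotype_id"], ascending=[False, True])
    )
    top = sizes["clonotype_id"].head(max(n_top, 0)).tolist()
    out = pd.DataFrame(
        {cid: (table["clonotype_id"] == cid).to_numpy() for cid in top},
        index=table.index,
    )
    if coords is not None:
        out = pd.concat([coords.reset_index(drop=True), out.reset_index(drop=True)], axis=1)
    return out
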