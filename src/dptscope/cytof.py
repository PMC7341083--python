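"""Mass-cytometry phenotyping: transform, gating, region enrichment,
marker coexpression.

T cells are partitioned on CD4/CD8 into single-positive (CD4SPT,
CD8SPT), double-positive (DPT) and double-negative (DNT) compartments.
Cluster frequencies are computed per patient and region (tumor core T,
leading edge L, nontumor N) and each cluster is assigned the region
where it is most abundant, with a paired test across patients for
significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "arcsinh_transform",
    "gmm_threshold",
    "gate_compartments",
    "subset_phenotype",
    "cluster_region_frequencies",
    "assign_region_enrichment",
    "coexpression_matrix",
    "compare_group_levels",
    "subsample_per_sample",
    "kmeans_standin_clusters",
    "GateResult",
]

COMPARTMENTS = ("CD4SPT", "CD8SPT", "DPT", "DNT")


def arcsinh_transform(raw, cofactor: float = 5.0):
    """Elementwise ``asinh(x / cofactor)``, the conventional CyTOF
    variance-stabilizing transform (cofactor 5 for mass cytometry).

    Negative raw intensities are clipped to 0 with a warning.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if isinstance(raw, pd.DataFrame):
        vals = raw.to_numpy(dtype=float)
    else:
        vals = np.asarray(raw, dtype=float)
    if (vals < 0).any():
        warnings.warn("negative raw intensities clipped to 0", stacklevel=2)
        vals = np.clip(vals, 0.0, None)
    out = np.arcsinh(vals / cofactor)
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out


def gmm_threshold(values: np.ndarray, random_state: int = 0) -> float:
    """Positive/negative cutoff for one marker: the trough between the
    two components of a univariate Gaussian-mixture fit (the point
    between the component means where posterior membership flips)."""
    from sklearn.mixture import GaussianMixture

    v = np.asarray(values, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3).fit(v)
    lo, hi = np.sort(gm.means_.ravel())
    grid = np.linspace(lo, hi, 512).reshape(-1, 1)
    post = gm.predict_proba(grid)
    hi_comp = int(np.argmax(gm.means_.ravel()))
    flip = np.argmax(post[:, hi_comp] >= 0.5)
    return float(grid[flip, 0])


@dataclass
class GateResult:
    """Four-way CD4/CD8 gate: per-cell compartment and the thresholds
    used."""

    compartment: pd.Series
    thresholds: dict[str, float] = field(default_factory=dict)

    def counts(self, ann: pd.DataFrame | None = None, by: tuple[str, ...] = ("patient", "region")):
        """Compartment counts, optionally per sample."""
        if ann is None:
            return self.compartment.value_counts()
        df = ann.copy()
        df["compartment"] = self.compartment.to_numpy()
        return df.groupby([*by, "compartment"], observed=True).size().unstack(fill_value=0)


def gate_compartments(
    markers: pd.DataFrame,
    theta_cd4: float | None = None,
    theta_cd8: float | None = None,
    cd4: str = "CD4",
    cd8: str = "CD8",
) -> GateResult:
    """Partition cells on CD4/CD8 positivity.

    DPT requires CD4 > theta_cd4 AND CD8 > theta_cd8; the four
    compartments are exhaustive and mutually exclusive. Thresholds
    default to univariate two-component GMM troughs.
    """
    for col in (cd4, cd8):
        if col not in markers.columns:
            raise KeyError(f"marker column '{col}' absent from matrix")
    if theta_cd4 is None:
        theta_cd4 = gmm_threshold(markers[cd4].to_numpy())
    if theta_cd8 is None:
        theta_cd8 = gmm_threshold(markers[cd8].to_numpy())
    pos4 = markers[cd4].to_numpy() > theta_cd4
    pos8 = markers[cd8].to_numpy() > theta_cd8
    comp = np.where(
        pos4 & pos8, "DPT",
        np.where(pos4, "CD4SPT", np.where(pos8, "CD8SPT", "DNT")),
    )
    return GateResult(
        compartment=pd.Series(pd.Categorical(comp, categories=COMPARTMENTS), index=markers.index),
        thresholds={cd4: float(theta_cd4), cd8: float(theta_cd8)},
    )


def subset_phenotype(
    markers: pd.DataFrame,
    gate: GateResult,
    compartment: str,
    predicate: dict[str, float] | None = None,
) -> pd.Index:
    """Cells of a compartment satisfying a marker-threshold conjunction.

    ``predicate`` maps marker -> cutoff, each condition ``value > cutoff``;
    an empty predicate returns the whole compartment (e.g. PD-1+DPT via
    ``{"PD1": theta}``).
    """
    mask = (gate.compartment == compartment).to_numpy()
    for marker, cutoff in (predicate or {}).items():
        if marker not in markers.columns:
            raise KeyError(f"predicate marker '{marker}' absent from matrix")
        mask &= markers[marker].to_numpy() > cutoff
    return markers.index[mask]


def cluster_region_frequencies(labels: pd.Series, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-(patient, region) proportion of each cluster among that
    sample's cells. Rows sum to 1 over clusters."""
    df = ann[["patient", "region"]].copy()
    df["cluster"] = np.asarray(labels)
    counts = df.groupby(["patient", "region", "cluster"], observed=True).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def assign_region_enrichment(freq: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign each cluster the region where it is most abundant.

    The enriched region is the argmax of the cluster's patient-mean
    frequency; significance is a paired two-sided t-test, across
    patients, of the frequency in that region against the mean of the
    other regions. Exact ties in the means yield label ``none``.
    Requires >= 2 patients (with one patient the p-value is undefined
    and flagged NaN).
    """
    idx = freq.index.to_frame(index=False)
    patients = idx["patient"].unique()
    regions = idx["region"].unique()
    single_patient = len(patients) < 2
    rows = {}
    for cluster in freq.columns:
        wide = freq[cluster].unstack("region").reindex(columns=regions)
        means = wide.mean(axis=0)
        if (means == means.max()).sum() > 1:
            rows[cluster] = dict(region="none", p_value=np.nan, mean_freq=means.max())
            continue
        best = means.idxmax()
        if single_patient:
            rows[cluster] = dict(region=best, p_value=np.nan, mean_freq=means[best])
            continue
        others = wide.drop(columns=[best]).mean(axis=1)
        paired = pd.concat([wide[best], others], axis=1).dropna()
        if len(paired) < 2 or np.allclose(paired.iloc[:, 0], paired.iloc[:, 1]):
            p = np.nan if len(paired) < 2 else 1.0
        else:
            p = float(stats.ttest_rel(paired.iloc[:, 0], paired.iloc[:, 1]).pvalue)
        rows[cluster] = dict(
            region=best, p_value=p, mean_freq=float(means[best]),
            significant=bool(p < alpha) if np.isfinite(p) else False,
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cluster"
    return out


def coexpression_matrix(
    markers: pd.DataFrame, cells: pd.Index | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of markers over a cell subset.

    Returns ``(r, p)`` DataFrames; symmetric, unit diagonal,
    pairwise-complete over finite values.
    """
    sub = markers.loc[cells] if cells is not None else markers
    cols = sub.columns
    n = len(cols)
    r = np.eye(n)
    p = np.zeros((n, n))
    vals = sub.to_numpy(dtype=float)
    for a in range(n):
        for b in range(a + 1, n):
            ok = np.isfinite(vals[:, a]) & np.isfinite(vals[:, b])
            if ok.sum() < 3:
                r[a, b] = r[b, a] = np.nan
                p[a, b] = p[b, a] = np.nan
                continue
            res = stats.pearsonr(vals[ok, a], vals[ok, b])
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def compare_group_levels(values_a, values_b) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test between two groups of
    per-cell (or per-sample) values. Returns ``(t, p)``."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def subsample_per_sample(
    markers: pd.DataFrame, ann: pd.DataFrame, n: int = 6000, seed: int = 0
) -> pd.Index:
    """Random subsample of up to ``n`` cells per (patient, region)
    sample, mirroring per-file downsampling before embedding or
    clustering."""
    rng = np.random.default_rng(seed)
    keep = []
    for _, grp in ann.groupby(["patient", "region"], observed=True, sort=True):
        idx = grp.index.to_numpy()
        if len(idx) > n:
            idx = rng.choice(idx, size=n, replace=False)
        keep.append(np.sort(idx))
    return markers.index[np.isin(markers.index, np.concatenate(keep))]


def kmeans_standin_clusters(markers: pd.DataFrame, n_clusters: int = 40, seed: int = 0) -> pd.Series:
    """k-means stand-in for an external clustering step. This is
    plumbing so downstream stages have labels to consume; it is not a
    faithful reproduction of any published clustering."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=4)
    lab = km.fit_predict(markers.to_numpy(dtype=float))
    return pd.Series([f"K{c:02d}" for c in lab], index=markers.index, name="cluster")
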