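"""Synthetic cohort generators with known ground truth.

Every downstream stage of the toolkit has a parameter-recovery test
against data produced here: a mass-cytometry-like cohort with
region-dependent population frequencies and planted marker
coexpression, cluster-structured negative-binomial UMI counts with
anchor-coupled signature genes and planted low-quality cells, a
clonotype table whose cross-cluster clone sharing follows a configured
transition matrix, a marked point pattern with tunable phenotype
attraction, and per-patient survival records with a configured hazard
ratio.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "PopulationSpec",
    "CohortConfig",
    "ScRnaTruth",
    "ClonalTruth",
    "gen_cytof_cohort",
    "gen_scrna",
    "gen_tcr",
    "gen_spatial",
    "gen_survival",
    "gen_y_branches",
    "default_cohort_config",
    "make_scrna_truth",
    "default_clonal_truth",
]

# 35-marker immune panel mirroring a surface-marker CyTOF design
DEFAULT_MARKERS = [
    "CD45", "CD3", "CD4", "CD8", "CD19", "CD56", "CD14", "CD16", "CD11b",
    "CD11c", "CD123", "PD1", "CD45RO", "CD45RA", "TIM3", "CTLA4", "LAG3",
    "HLADR", "ICOS", "CD28", "CD69", "CD25", "CD127", "FOXP3", "CXCR3",
    "CCR4", "CCR7", "CD161", "CD9", "CD38", "CD27", "CD57", "CD44",
    "CD103", "TCRgd",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# CyTOF-like cohort
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """One cell population: region frequencies and marker distribution.

    Marker values are generated directly on the arcsinh scale as a
    multivariate Gaussian with mean ``marker_means`` (markers absent
    from the map default to a low background) and covariance
    ``marker_cov`` over ``cov_markers`` (other markers get independent
    noise of scale ``noise_sd``). Planted coexpression, e.g. a PD-1 to
    CD45RO correlation, is encoded in ``marker_cov``.
    """

    name: str
    region_freq: dict[str, float]
    marker_means: dict[str, float] = field(default_factory=dict)
    marker_cov: np.ndarray | None = None
    cov_markers: tuple[str, ...] = ()
    noise_sd: float = 0.35
    background_mean: float = 0.15

    def __post_init__(self) -> None:
        for r, f in self.region_freq.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"{self.name}: frequency for {r} outside [0,1]")
        if self.marker_cov is not None:
            cov = np.asarray(self.marker_cov, dtype=float)
            if cov.shape != (len(self.cov_markers),) * 2:
                raise ConfigurationError(f"{self.name}: marker_cov shape does not match cov_markers")
            if not np.allclose(cov, cov.T):
                raise ConfigurationError(f"{self.name}: marker_cov is not symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ConfigurationError(f"{self.name}: marker_cov is not PSD")
            self.marker_cov = cov


@dataclass
class CohortConfig:
    n_patients: int = 13
    regions: tuple[str, ...] = ("T", "L", "N")
    cells_per_sample: int = 2000
    populations: list[PopulationSpec] = field(default_factory=list)
    markers: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.cells_per_sample < 1:
            raise ConfigurationError("n_patients and cells_per_sample must be >= 1")
        for region in self.regions:
            tot = sum(p.region_freq.get(region, 0.0) for p in self.populations)
            if abs(tot - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"population frequencies in region {region} sum to {tot}, not 1"
                )


def gen_cytof_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a marker matrix and per-cell annotation for a full cohort.

    Per patient and region, population counts are multinomial with the
    configured frequencies; marker values are Gaussian on the arcsinh
    scale. Returns ``(markers, annotation)`` with aligned row index;
    annotation columns: ``patient``, ``region``, ``population``.
    """
    rng = np.random.default_rng(config.seed)
    marker_rows: list[np.ndarray] = []
    ann_rows: list[tuple[str, str, str]] = []
    for p in range(config.n_patients):
        patient = f"patient_{p + 1:02d}"
        for region in config.regions:
            freqs = np.array([pop.region_freq.get(region, 0.0) for pop in config.populations])
            counts = rng.multinomial(config.cells_per_sample, freqs)
            for pop, n in zip(config.populations, counts):
                if n == 0:
                    continue
                X = rng.normal(pop.background_mean, pop.noise_sd, size=(n, len(config.markers)))
                for j, m in enumerate(config.markers):
                    if m in pop.marker_means and m not in pop.cov_markers:
                        X[:, j] = rng.normal(pop.marker_means[m], pop.noise_sd, size=n)
                if pop.marker_cov is not None and pop.cov_markers:
                    mean = np.array([pop.marker_means.get(m, pop.background_mean) for m in pop.cov_markers])
                    corr = rng.multivariate_normal(mean, pop.marker_cov, size=n)
                    for jj, m in enumerate(pop.cov_markers):
                        X[:, config.markers.index(m)] = corr[:, jj]
                marker_rows.append(np.clip(X, 0.0, None))
                ann_rows.extend([(patient, region, pop.name)] * n)
    markers = pd.DataFrame(np.vstack(marker_rows), columns=config.markers)
    ann = pd.DataFrame(ann_rows, columns=["patient", "region", "population"])
    markers.index = ann.index = pd.RangeIndex(len(ann))
    return markers, ann


def default_cohort_config(
    n_patients: int = 13, cells_per_sample: int = 2000, seed: int = 0,
    dpt_rho: float = 0.6,
) -> CohortConfig:
    """Study-like cohort: matched T/L/N samples where double-positive
    T cells are enriched at the leading edge (L) and the PD-1+ subset
    carries a planted PD-1/CD45RO correlation ``dpt_rho``."""
    hi, lo = 2.2, 0.15
    sd = 0.35

    def cov(rho: float, k: int = 2) -> np.ndarray:
        c = np.full((k, k), rho * sd * sd)
        np.fill_diagonal(c, sd * sd)
        return c

    t_base = {"CD45": hi, "CD3": hi}
    pops = [
        PopulationSpec(
            "DPT_PD1pos",
            {"T": 0.015, "L": 0.08, "N": 0.01},
            {**t_base, "CD4": hi, "CD8": hi, "PD1": 2.0, "CD45RO": 2.0,
             "HLADR": 1.8, "ICOS": 1.6, "CD28": 1.8, "TIM3": 1.0, "CTLA4": 1.0},
            marker_cov=cov(dpt_rho), cov_markers=("PD1", "CD45RO"),
        ),
        PopulationSpec(
            "DPT_PD1neg",
            {"T": 0.01, "L": 0.04, "N": 0.01},
            {**t_base, "CD4": hi, "CD8": hi, "PD1": lo, "CD45RO": lo, "CD45RA": 1.5},
        ),
        PopulationSpec(
            "CD4SPT",
            {"T": 0.42, "L": 0.33, "N": 0.28},
            {**t_base, "CD4": hi, "CD8": lo, "CD45RO": 1.2, "PD1": 0.8},
        ),
        PopulationSpec(
            "CD8SPT",
            {"T": 0.25, "L": 0.35, "N": 0.45},
            {**t_base, "CD4": lo, "CD8": hi, "CD45RA": 1.2, "PD1": 0.9},
        ),
        PopulationSpec(
            "DNT",
            {"T": 0.305, "L": 0.20, "N": 0.25},
            {**t_base, "CD4": lo, "CD8": lo, "CD161": 1.2},
        ),
    ]
    return CohortConfig(
        n_patients=n_patients, cells_per_sample=cells_per_sample,
        populations=pops, seed=seed,
    )


# ---------------------------------------------------------------------------
# scRNA-seq counts
# ---------------------------------------------------------------------------

@dataclass
class ScRnaTruth:
    """Ground truth for the UMI-count generator.

    ``signature_genes`` maps each anchor gene to its planted member
    set (disjoint from the anchors); ``program_multiplier`` gives each
    cluster's activity multiplier per anchor program, so cluster-level
    signature scores are separable downstream. Low-quality cells are
    planted either by multiplicatively inflating the mitochondrial
    fraction or by shrinking the library below the detected-gene
    threshold.
    """

    gene_names: list[str]
    anchors: list[str]
    signature_genes: dict[str, list[str]]
    mito_genes: list[str]
    dissoc_genes: list[str]
    ribo_genes: list[str]
    n_clusters: int = 4
    base_mean: np.ndarray | None = None          # per-gene baseline
    dispersion: float = 2.0                      # NB shape (gamma) parameter
    coupling: float = 1.0                        # anchor->member coupling strength
    program_multiplier: np.ndarray | None = None  # clusters x anchors
    lib_size: float = 2500.0
    lib_sigma: float = 0.2
    frac_low_quality: float = 0.05
    frac_low_genes: float = 0.01                 # planted <200-gene cells
    mito_inflation: float = 10.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ConfigurationError("NB dispersion must be > 0")
        for a, members in self.signature_genes.items():
            if set(members) & set(self.anchors):
                raise ConfigurationError(f"signature members of {a} overlap the anchors")


def make_scrna_truth(
    n_genes: int = 1500,
    n_signature: int = 20,
    n_clusters: int = 4,
    seed: int = 0,
    frac_low_quality: float = 0.05,
    frac_low_genes: float = 0.01,
    coupling: float = 1.0,
) -> ScRnaTruth:
    """Assemble a default truth object with a plausible gene universe:
    three anchor programs (cytotoxicity/activation/exhaustion anchored
    at FGFBP2/IFNG/HAVCR2), 20 planted members each, mitochondrial,
    dissociation-stress, ribosomal and heat-shock gene families, PDCD1,
    and negative-binomial background genes."""
    rng = np.random.default_rng(seed)
    anchors = ["FGFBP2", "IFNG", "HAVCR2"]
    mito = [f"MT-{g}" for g in ("ND1", "ND2", "CO1", "CO2", "ATP6", "CYB", "ND4", "ND5")]
    dissoc = ["FOS", "FOSB", "JUN", "JUNB", "EGR1", "HSPA1A", "HSPA1B", "DNAJB1"]
    ribo = [f"RPL{i}" for i in range(3, 16)] + [f"RPS{i}" for i in range(2, 10)]
    heat = ["HSPB1", "HSPH1", "HSP90AA1", "HSPA8"]
    sig = {a: [f"{a}.M{j + 1:02d}" for j in range(n_signature)] for a in anchors}
    named = anchors + sum(sig.values(), []) + mito + dissoc + ribo + heat + ["PDCD1", "CD3E"]
    n_bg = max(n_genes - len(named), 0)
    genes = named + [f"G{j:04d}" for j in range(n_bg)]
    base = rng.lognormal(mean=-1.0, sigma=1.0, size=len(genes))
    base = np.clip(base, 0.02, 30.0)
    gidx = {g: i for i, g in enumerate(genes)}
    for m in mito:
        base[gidx[m]] = 1.2   # ~4% of library in mitochondrial genes
    for d in dissoc:
        base[gidx[d]] = 0.8
    for a in anchors:
        base[gidx[a]] = 2.0
    base[gidx["PDCD1"]] = 0.8
    mult = np.ones((n_clusters, len(anchors)))
    for k in range(min(n_clusters - 1, len(anchors))):
        mult[k, k] = 3.0
    return ScRnaTruth(
        gene_names=genes, anchors=anchors, signature_genes=sig,
        mito_genes=mito, dissoc_genes=dissoc, ribo_genes=ribo + heat,
        n_clusters=n_clusters, base_mean=base, coupling=coupling,
        program_multiplier=mult, frac_low_quality=frac_low_quality,
        frac_low_genes=frac_low_genes,
    )


def gen_scrna(truth: ScRnaTruth, n_cells: int, seed: int = 0):
    """Draw a cells x genes UMI count matrix as an AnnData.

    Counts are gamma-Poisson (negative binomial). Each planted
    signature gene's expectation is linearly coupled to its anchor's
    latent per-cell activity, so its sample correlation with the anchor
    exceeds background. Obs columns: ``cluster``, ``planted_low_quality``,
    ``low_quality_reason``; truth bookkeeping lands in ``uns``.
    """
    import anndata as ad

    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    genes = truth.gene_names
    G = len(genes)
    gidx = {g: i for i, g in enumerate(genes)}
    base = truth.base_mean if truth.base_mean is not None else np.ones(G)

    clusters = rng.integers(0, truth.n_clusters, size=n_cells)
    lib = rng.lognormal(np.log(truth.lib_size), truth.lib_sigma, size=n_cells)

    # latent anchor activity per cell: lognormal noise x cluster program level
    mult = truth.program_multiplier
    if mult is None:
        mult = np.ones((truth.n_clusters, len(truth.anchors)))
    activity = np.empty((n_cells, len(truth.anchors)))
    for a_i in range(len(truth.anchors)):
        activity[:, a_i] = rng.lognormal(0.0, 0.6, size=n_cells) * mult[clusters, a_i]

    mean = np.tile(base, (n_cells, 1))
    for a_i, a in enumerate(truth.anchors):
        act = activity[:, a_i]
        mean[:, gidx[a]] = base[gidx[a]] * act
        beta = truth.coupling
        for g in truth.signature_genes[a]:
            mean[:, gidx[g]] = base[gidx[g]] * ((1 - beta) + beta * act)

    # per-cell noise on mito/dissociation propensity
    mito_prop = rng.lognormal(0.0, 0.15, size=n_cells)
    dissoc_prop = rng.lognormal(0.0, 0.15, size=n_cells)
    mito_cols = [gidx[g] for g in truth.mito_genes]
    dissoc_cols = [gidx[g] for g in truth.dissoc_genes]
    mean[:, mito_cols] *= mito_prop[:, None]
    mean[:, dissoc_cols] *= dissoc_prop[:, None]

    # plant low-quality cells
    n_lq = int(round(truth.frac_low_quality * n_cells))
    n_lg = int(round(truth.frac_low_genes * n_cells))
    perm = rng.permutation(n_cells)
    lq_mito = perm[:n_lq]
    lq_genes = perm[n_lq:n_lq + n_lg]
    mean[lq_mito[:, None], mito_cols] *= truth.mito_inflation
    lib[lq_genes] = 100.0  # tiny library -> < 200 detected genes

    # scale expectations to the target library size, then NB draw
    mean *= (lib / mean.sum(axis=1))[:, None]
    shape = truth.dispersion
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam).astype(np.int64)

    reason = np.array([""] * n_cells, dtype=object)
    reason[lq_mito] = "mito_inflated"
    reason[lq_genes] = "low_genes"
    obs = pd.DataFrame(
        {
            "cluster": pd.Categorical([f"C{c}" for c in clusters]),
            "planted_low_quality": reason != "",
            "low_quality_reason": reason,
        },
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=genes))
    adata.uns["truth"] = {
        "anchors": list(truth.anchors),
        "signature_genes": {a: list(m) for a, m in truth.signature_genes.items()},
        "mito_genes": list(truth.mito_genes),
        "dissoc_genes": list(truth.dissoc_genes),
        "ribo_genes": list(truth.ribo_genes),
    }
    return adata


# ---------------------------------------------------------------------------
# TCR clonotypes
# ---------------------------------------------------------------------------

@dataclass
class ClonalTruth:
    """Clone-sharing ground truth.

    ``transition_matrix`` rows give, for a clone seeded in cluster *i*,
    the expected allocation of its cells over clusters; the identity
    matrix confines every clone to its home cluster. Clone sizes follow
    a discrete power law with exponent ``clone_size_exponent``,
    truncated at ``max_clone_size``.
    """

    transition_matrix: pd.DataFrame
    clone_size_exponent: float = 2.5
    max_clone_size: int = 60
    singleton_fraction: float = 0.0  # extra mass forced to singletons

    def __post_init__(self) -> None:
        M = self.transition_matrix
        if (M.to_numpy() < 0).any():
            raise ConfigurationError("transition_matrix entries must be nonnegative")
        if list(M.index) != list(M.columns):
            raise ConfigurationError("transition_matrix must be square with matching labels")


def default_clonal_truth(
    focus_pair: tuple[str, str] = ("TDPT_10", "TCD8T_2"),
    clusters: tuple[str, ...] = (
        "TDPT_1", "TDPT_3", "TDPT_10", "TCD4T_2", "TCD4T_3",
        "TCD8T_2", "TCD8T_5", "PBMC_1",
    ),
    focus_weight: float = 0.45,
    background_sharing: float = 0.02,
) -> ClonalTruth:
    """Mostly-confined clones with transition mass concentrated on one
    (double-positive cluster, CD8 cluster) pair."""
    K = len(clusters)
    M = np.full((K, K), background_sharing / (K - 1))
    np.fill_diagonal(M, 1.0 - background_sharing)
    df = pd.DataFrame(M, index=clusters, columns=clusters)
    a, b = focus_pair
    df.loc[a, :] = background_sharing / (K - 1)
    df.loc[a, a] = 1.0 - focus_weight - background_sharing
    df.loc[a, b] = focus_weight + background_sharing / (K - 1)
    return ClonalTruth(transition_matrix=df)


def _sample_power_law(rng: np.random.Generator, gamma: float, smax: int, size: int) -> np.ndarray:
    s = np.arange(1, smax + 1, dtype=float)
    p = s ** (-gamma)
    p /= p.sum()
    return rng.choice(np.arange(1, smax + 1), size=size, p=p)


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def gen_tcr(
    truth: ClonalTruth,
    cluster_labels: pd.Series,
    seed: int = 0,
    patient: str = "P1",
) -> pd.DataFrame:
    """Assign every cell a clonotype under the configured sharing law.

    ``cluster_labels`` maps cell id -> cluster; every label must appear
    in the transition matrix. Clones are seeded in a home cluster
    (chosen with probability proportional to unassigned cells), sized
    by the truncated power law, and their cells spread over clusters by
    a multinomial on the home cluster's transition row, clipped to the
    cells still unassigned in each cluster.

    Returns a ClonotypeTable: barcode, clonotype_id, cdr3, compartment
    (cluster-name prefix), cluster, patient.
    """
    if cluster_labels.isna().any():
        raise ConfigurationError("cluster label missing for some cells")
    clusters = list(truth.transition_matrix.index)
    unknown = set(cluster_labels.unique()) - set(clusters)
    if unknown:
        raise ConfigurationError(f"labels missing from transition_matrix: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    pool: dict[str, list] = {
        c: list(rng.permutation(cluster_labels.index[cluster_labels == c].to_numpy()))
        for c in clusters
    }
    remaining = np.array([len(pool[c]) for c in clusters], dtype=float)
    T = truth.transition_matrix.to_numpy(dtype=float)
    T = T / T.sum(axis=1, keepdims=True)

    assignments: dict[object, str] = {}
    clone_i = 0
    # draw sizes in blocks to amortize the power-law sampling
    sizes = iter(_sample_power_law(rng, truth.clone_size_exponent, truth.max_clone_size, 4096))
    while remaining.sum() > 0:
        home = rng.choice(len(clusters), p=remaining / remaining.sum())
        try:
            s = next(sizes)
        except StopIteration:
            sizes = iter(_sample_power_law(rng, truth.clone_size_exponent, truth.max_clone_size, 4096))
            s = next(sizes)
        if truth.singleton_fraction and rng.random() < truth.singleton_fraction:
            s = 1
        s = int(min(s, remaining.sum()))
        alloc = rng.multinomial(s, T[home])
        alloc = np.minimum(alloc, remaining.astype(int))
        if alloc.sum() == 0:
            alloc = np.zeros(len(clusters), dtype=int)
            alloc[home] = min(1, int(remaining[home])) or 0
            if alloc.sum() == 0:  # home exhausted; put one cell anywhere
                j = int(np.argmax(remaining))
                alloc[j] = 1
        cid = f"{patient}:clone_{clone_i:05d}"
        clone_i += 1
        for j, c in enumerate(clusters):
            for _ in range(alloc[j]):
                assignments[pool[c].pop()] = cid
        remaining -= alloc

    cdr3 = {
        cid: "CASS" + "".join(rng.choice(_AA, size=8)) + "F"
        for cid in dict.fromkeys(assignments.values())
    }
    cells = list(assignments)
    out = pd.DataFrame(
        {
            "barcode": cells,
            "clonotype_id": [assignments[c] for c in cells],
            "cdr3": [cdr3[assignments[c]] for c in cells],
            "cluster": cluster_labels.loc[cells].to_numpy(),
            "patient": patient,
        }
    )
    out["compartment"] = out["cluster"].str.rsplit("_", n=1).str[0]
    return out.sort_values("barcode", ignore_index=True)


def gen_y_branches(
    n_per_branch: int = 200,
    noise_sd: float = 0.12,
    seed: int = 0,
    stem_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three-branch "Y" in marker space for trajectory tests.

    Two long arms leave a common junction: along the CD4 arm CD8 decays
    while CD4 stays high, and vice versa; a shorter stem decays in
    both. PD-1 and CD45RO peak at the junction (the double-positive
    region) and fade outward, while CD45RA rises toward the arm ends.
    Returns ``(markers, labels)`` with labels ``branch`` and pseudotime
    ``t`` (0 at the junction).
    """
    rng = np.random.default_rng(seed)
    branch_funcs = {
        "CD4": (lambda t: 2.0 + 0.5 * t, lambda t: 2.0 - 2.0 * t),
        "CD8": (lambda t: 2.0 - 2.0 * t, lambda t: 2.0 + 0.5 * t),
        "stem": (lambda t: 2.0 - 1.2 * t, lambda t: 2.0 - 1.2 * t),
    }
    blocks, labels = [], []
    for branch, (f4, f8) in branch_funcs.items():
        n = n_per_branch if branch != "stem" else max(int(stem_fraction * n_per_branch), 1)
        t = rng.uniform(0, 1, n)
        X = np.column_stack(
            [f4(t), f8(t), 2.0 * np.exp(-2.5 * t), 2.0 * np.exp(-2.5 * t), 1.5 * t]
        ) + rng.normal(0, noise_sd, (n, 5))
        blocks.append(X)
        labels.extend((branch, ti) for ti in t)
    markers = pd.DataFrame(np.vstack(blocks), columns=["CD4", "CD8", "PD1", "CD45RO", "CD45RA"])
    lab = pd.DataFrame(labels, columns=["branch", "t"])
    return markers, lab


# ---------------------------------------------------------------------------
# Spatial point pattern
# ---------------------------------------------------------------------------

def gen_spatial(
    attraction: float = 0.0,
    n_cells: int = 2000,
    field_size_um: float = 1000.0,
    seed: int = 0,
    composition: dict[str, float] | None = None,
    scatter_sd_um: float = 8.0,
    core_id: str = "core_1",
) -> pd.DataFrame:
    """Marked parent-offspring point pattern on a square tissue core.

    PD-1+ double-positive T cells (parents) are uniform; a fraction
    ``min(attraction, 1)`` of PD-1+CD8+ cells are offspring scattered
    around random parents with isotropic Gaussian scatter
    ``scatter_sd_um``; all other phenotypes (and the remaining CD8
    cells) are uniform. ``attraction = 0`` gives complete spatial
    randomness for every phenotype.
    """
    if attraction < 0:
        raise ConfigurationError("attraction must be nonnegative")
    comp = composition or {
        "DPT_PD1pos": 0.06, "DPT_PD1neg": 0.06,
        "CD4_PD1pos": 0.14, "CD8_PD1pos": 0.14, "other": 0.60,
    }
    if abs(sum(comp.values()) - 1.0) > 1e-9:
        raise ConfigurationError("composition fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = {k: int(round(v * n_cells)) for k, v in comp.items()}
    rows = []
    parents = rng.uniform(0, field_size_um, size=(counts.get("DPT_PD1pos", 0), 2))
    for (x, y) in parents:
        rows.append((x, y, "DPT_PD1pos"))
    for pheno, n in counts.items():
        if pheno == "DPT_PD1pos":
            continue
        if pheno == "CD8_PD1pos" and len(parents) and attraction > 0:
            n_off = int(round(min(attraction, 1.0) * n))
            idx = rng.integers(0, len(parents), size=n_off)
            off = parents[idx] + rng.normal(0.0, scatter_sd_um, size=(n_off, 2))
            off = np.clip(off, 0.0, field_size_um)
            for (x, y) in off:
                rows.append((x, y, pheno))
            n -= n_off
        pts = rng.uniform(0, field_size_um, size=(n, 2))
        for (x, y) in pts:
            rows.append((x, y, pheno))
    out = pd.DataFrame(rows, columns=["x_um", "y_um", "phenotype"])
    out["core_id"] = core_id
    return out


# ---------------------------------------------------------------------------
# Survival records
# ---------------------------------------------------------------------------

def gen_survival(
    groups: pd.Series | np.ndarray,
    hr: float = 0.35,
    baseline_shape: float = 1.5,
    baseline_scale: float = 40.0,
    censor_rate: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Weibull event times under a proportional-hazards group effect.

    The hazard of the "high" group is ``hr`` times baseline; times are
    in months. Censoring is independent Weibull with the baseline
    shape, its scale set so that roughly ``censor_rate`` of baseline
    subjects are censored; ``censor_rate = 0`` disables censoring.
    """
    if hr <= 0:
        raise ConfigurationError("hazard ratio must be positive")
    groups = pd.Series(groups)
    rng = np.random.default_rng(seed)
    n = len(groups)
    x = (groups.astype(str) == "high").to_numpy().astype(float)
    u = rng.uniform(size=n)
    t_event = baseline_scale * (-np.log(u) / np.exp(np.log(hr) * x)) ** (1.0 / baseline_shape)
    if censor_rate > 0:
        # P(C < T) = r  =>  scale_c = scale * ((1-r)/r)^(1/shape) for Weibull pairs
        scale_c = baseline_scale * ((1 - censor_rate) / censor_rate) ** (1.0 / baseline_shape)
        t_cens = scale_c * (-np.log(rng.uniform(size=n))) ** (1.0 / baseline_shape)
        event = t_event <= t_cens
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=bool)
        time = t_event
    return pd.DataFrame(
        {
            "patient_id": [f"pt_{i + 1:04d}" for i in range(n)],
            "time_months": np.maximum(time, 1e-6),
            "event": event,
            "group": groups.to_numpy(),
        }
    )
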