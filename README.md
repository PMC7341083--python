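# dptscope

Analysis toolkit for **tumor-associated CD4⁺CD8⁺ double-positive T (DPT)
cells** in hepatocellular carcinoma and similar settings. Mature DPT cells
— conventionally a thymic developmental stage — appear at the tumor
leading edge with a PD-1⁺CD45RO⁺ activated/exhausted phenotype, and the
question of where they come from (thymic escapees vs. locally transformed
single-positive T cells) is addressed with clonotype sharing, trajectory
geometry and spatial proximity. `dptscope` implements the full
computational chain for that kind of study:

- **CyTOF phenotyping** — arcsinh transform, CD4/CD8 four-way gating
  (CD4SPT / CD8SPT / DPT / DNT), per-patient cluster frequencies by
  tissue region (tumor core T, leading edge L, nontumor N),
  region-enrichment assignment, and marker coexpression matrices.
- **scRNA-seq QC** — four per-cell indices (UMIs, detected genes,
  mitochondrial fraction, dissociation-stress fraction), removal of
  boxplot upper outliers (Q3 + 1.5·IQR) and cells with < 200 detected
  genes, depth normalization to 10,000 counts per cell with log1p, and
  variable-gene selection excluding ribosomal/heat-shock genes.
- **Signature scoring** — cytotoxicity / activation / exhaustion scores
  from the top 20 genes correlated with the anchors FGFBP2 / IFNG /
  HAVCR2, plus per-cluster summaries with the PDCD1 detection rate.
- **Clonal analysis** — CDR3-defined clonotypes and Shannon-entropy
  indices of clonal expansion (`expa`), cross-cluster state transition
  (`tran`) and pairwise transition (`ptran`), shared-clone counts,
  clone-overlap Venn regions, and expanded-clone (size > 10)
  compartment co-occurrence.
- **Trajectory** — diffusion-map embedding of marker space (Gaussian
  kernel, α = 1 density normalization) and marker profiles along
  diffusion components.
- **Spatial proximity** — neighbor counts of target phenotypes within
  15/45 µm of index cells on multiplex-IF cell maps, count comparisons
  by Student's t-test, and cross-sample density correlations.
- **Survival** — median dichotomization, Kaplan–Meier + log-rank, and
  univariate Cox proportional hazards (Efron ties).
- **Synthetic cohorts** — generators for all five input kinds with
  controllable ground truth, so every stage has a parameter-recovery
  test.

## The clonal indices

For cluster *i* with clone sizes \(n_{ij}\) (total \(n_i\), \(N_i\)
distinct clones) and within-cluster clone frequencies
\(p_j = n_{ij}/n_i\):

- **expa**: \( \mathrm{expa}_i = 1 - H_i/\ln N_i \) with
  \( H_i = -\sum_j p_j \ln p_j \); all singletons → 0, monoclonal → 1.
- **tran**: clone *j* occupies clusters with fractions \(q_{jc}\);
  \( \tilde H_j = -\sum_c q_{jc}\ln q_{jc} / \ln K \) over the *K*
  clusters, and \( \mathrm{tran}_i = \sum_j (n_{ij}/n_i)\,\tilde H_j \).
- **ptran**: the same quantity with occupancies renormalized over a
  cluster pair and the entropy normalized by \(\ln 2\); symmetric.

All three are bounded in [0, 1]; higher values mean stronger clonal
expansion or state transition.

## Worked example

```python
import numpy as np, pandas as pd
from dptscope import synthetic, clonal

truth = synthetic.default_clonal_truth()          # sharing focused on (TDPT_10, TCD8T_2)
rng = np.random.default_rng(0)
labels = pd.Series(rng.choice(list(truth.transition_matrix.index), 3000),
                   index=[f"c{i}" for i in range(3000)])
table = synthetic.gen_tcr(truth, labels, seed=2)

print(clonal.startrac_expa(table).round(3).head(3))
ptran = clonal.pstartrac_tran_matrix(table)
arr = ptran.to_numpy().copy(); np.fill_diagonal(arr, -1)
i, j = np.unravel_index(arr.argmax(), arr.shape)
print("strongest pair:", ptran.index[i], ptran.columns[j], round(arr.max(), 3))
```

prints

```
         n_cells  n_clones  entropy   expa
cluster
PBMC_1       396       220    4.921  0.088
TCD4T_2      347       176    4.596  0.111
TCD4T_3      396       210    4.923  0.079
```

and

```
strongest pair: TCD8T_2 TDPT_10 0.179
```

i.e. every cluster shows mild clonal expansion (`expa` ≈ 0.1 under the
heavy-tailed clone-size law), and the pairwise transition index singles
out exactly the (DPT cluster, CD8 cluster) pair into which the generator
concentrated clone sharing — the ancestry signal the study design relies
on.

The whole chain runs end-to-end on a synthetic cohort with

```bash
dptscope synth-demo --out demo_run --seed 0
```

which writes gating results, enrichment tables, QC reports, signature
scores, clonal indices, diffusion coordinates, neighbor-count
comparisons, survival statistics and a SHA-256 manifest under
`demo_run/`.

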