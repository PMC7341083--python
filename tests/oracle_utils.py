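"""Independent brute-force oracles used by the test suite.

Deliberately written as plain double loops over dictionaries so they
share no code path with the package implementations they check.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
import pandas as pd


def expa_bruteforce(table: pd.DataFrame) -> dict:
    """Per-cluster expansion index via explicit loops."""
    by_cluster: dict = defaultdict(lambda: defaultdict(int))
    for _, row in table.iterrows():
        by_cluster[row["cluster"]][row["clonotype_id"]] += 1
    out = {}
    for cl, clones in by_cluster.items():
        n = sum(clones.values())
        H = 0.0
        for c in clones.values():
            p = c / n
            H -= p * math.log(p)
        N = len(clones)
        out[cl] = 1.0 if N == 1 else 1.0 - H / math.log(N)
    return out


def tran_bruteforce(table: pd.DataFrame) -> dict:
    """Per-cluster transition index via explicit loops."""
    clusters = sorted(set(table["cluster"]))
    K = len(clusters)
    clone_counts: dict = defaultdict(lambda: defaultdict(int))
    for _, row in table.iterrows():
        clone_counts[row["clonotype_id"]][row["cluster"]] += 1
    H_clone = {}
    for j, counts in clone_counts.items():
        tot = sum(counts.values())
        H = 0.0
        for c in counts.values():
            q = c / tot
            H -= q * math.log(q)
        H_clone[j] = H / math.log(K)
    out = {}
    for cl in clusters:
        n_i = sum(counts.get(cl, 0) for counts in clone_counts.values())
        s = 0.0
        for j, counts in clone_counts.items():
            s += counts.get(cl, 0) / n_i * H_clone[j]
        out[cl] = s
    return out


def ptran_bruteforce(table: pd.DataFrame, i, k) -> float:
    """Pairwise transition index via explicit loops."""
    clone_counts: dict = defaultdict(lambda: defaultdict(int))
    for _, row in table.iterrows():
        if row["cluster"] in (i, k):
            clone_counts[row["clonotype_id"]][row["cluster"]] += 1
    total = sum(sum(c.values()) for c in clone_counts.values())
    s = 0.0
    for counts in clone_counts.values():
        tot = sum(counts.values())
        H = 0.0
        for c in counts.values():
            q = c / tot
            H -= q * math.log(q)
        s += tot / total * H / math.log(2)
    return s


def shared_clones_bruteforce(table: pd.DataFrame, by: str = "cluster") -> pd.DataFrame:
    """Distinct-clone intersection counts via python sets."""
    groups = sorted(set(table[by]))
    sets = {g: set(table.loc[table[by] == g, "clonotype_id"]) for g in groups}
    mat = [[len(sets[a] & sets[b]) for b in groups] for a in groups]
    return pd.DataFrame(mat, index=groups, columns=groups)


def random_clonotype_table(rng: np.random.Generator, max_cells: int = 300) -> pd.DataFrame:
    """A random clonotype table with heavy-tailed clone sizes."""
    n = int(rng.integers(20, max_cells + 1))
    k = int(rng.integers(2, 6))
    n_clones = max(int(rng.integers(2, n)), 2)
    clone_of = rng.integers(0, n_clones, size=n)
    cluster_of = rng.integers(0, k, size=n)
    return pd.DataFrame(
        {
            "clonotype_id": [f"c{j}" for j in clone_of],
            "cluster": [f"K{j}" for j in cluster_of],
        }
    )
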