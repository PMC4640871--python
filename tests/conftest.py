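import numpy as np
import pandas as pd
import pytest

from hippostress.pipeline import PipelineConfig, run_pipeline
from hippostress.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced synthetic study (same structure, fewer genes) for fast tests."""
    return SimulationConfig(n_genes=150, gene_cluster_sizes={1: 12, 2: 12, 3: 12},
                            marker_gene_count=8, seed=7)


@pytest.fixture(scope="session")
def small_run(small_config):
    return run_pipeline(PipelineConfig(seed=7, simulation=small_config))


def upgma_bruteforce(sim_values: np.ndarray):
    """Independent O(n^3) UPGMA: cluster-to-cluster distance recomputed at
    every step as the mean over all cross-pairs of ORIGINAL items."""
    n = sim_values.shape[0]
    d0 = 1.0 - sim_values
    clusters = [[i] for i in range(n)]
    ids = list(range(n))
    merges = []
    nxt = n
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dd = float(np.mean([d0[i, j] for i in clusters[a] for j in clusters[b]]))
                if best is None or dd < best[0]:
                    best = (dd, a, b)
        dd, a, b = best
        merges.append((ids[a], ids[b], 1.0 - dd, len(clusters[a]) + len(clusters[b])))
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        ids = [i for k, i in enumerate(ids) if k not in (a, b)] + [nxt]
        nxt += 1
    return merges


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: adj_i = min over j with rank >= rank(i)
    of m * p_j / rank_j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        adj[idx] = min(1.0, min(m * p[order[j]] / (j + 1) for j in range(pos, m)))
    return adj


def check_cut_soundness(dend, assignment, r_main, r_sub):
    """Every within-cluster merge similarity > r_main; every merge whose
    leaves span more than one cluster <= r_main; within a cluster, merges
    inside one subcluster >= r_sub and merges spanning units < r_sub."""
    ids = dend.ids
    table = assignment.assignment
    for node_offset, (left, right, sim, _) in enumerate(dend.merges):
        leaves = dend.leaves_under(dend.n_leaves + node_offset)
        clusters = {table.loc[ids[i], "cluster"] for i in leaves}
        if len(clusters) == 1:
            assert sim > r_main, f"internal merge at {sim} not > {r_main}"
        else:
            assert sim <= r_main, f"cluster-joining merge at {sim} not <= {r_main}"
        if len(clusters) == 1:
            units = set()
            for i in leaves:
                sub = table.loc[ids[i], "subcluster"]
                units.add(sub if sub else f"singleton:{ids[i]}")
            if len(units) == 1 and not next(iter(units)).startswith("singleton"):
                assert sim >= r_sub, f"subcluster-internal merge at {sim} not >= {r_sub}"
            elif len(units) > 1:
                assert sim < r_sub, f"unit-joining merge at {sim} not < {r_sub}"
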