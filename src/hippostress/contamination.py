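"""Cluster-level tissue cross-contamination screen.

Dissection spillover from tissues bordering the hippocampus (choroid
plexus, habenula, septal nuclei) shows up as a coherent cluster of
tissue-marker genes whose apparent fold changes track the per-sample
contamination fraction rather than the animal's stress physiology.
Three lines of evidence are combined per cluster: atlas-based
enrichment of representative genes in adjacent tissue, overlap with
bundled marker panels (hypergeometric enrichment), and the absence of
correlation between a gene's expression and the organ-weight stress
indices (thymus %bw falls and spleen %bw rises under chronic stress).

The per-gene verdict rule: contamination-consistent if the gene sits
in a suspect cluster or belongs to a marker panel AND its expression
is uncorrelated with the stress indices; stress-responsive if it is
differentially expressed, not panel/suspect, and stress-correlated;
indeterminate otherwise.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerPanel",
    "StressIndexTable",
    "ContaminationReport",
    "load_panel",
    "default_panels",
    "spearman_correlation",
    "stress_index_screen",
    "marker_overlap",
    "build_report",
]


@dataclass(frozen=True)
class MarkerPanel:
    """Named set of tissue-marker gene symbols (uppercased for matching)."""

    name: str
    genes: frozenset
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("marker panel must not be empty")
        object.__setattr__(self, "genes", frozenset(str(g).upper() for g in self.genes))

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in self.genes


def load_panel(path, name: str | None = None, source: str = "") -> MarkerPanel:
    """Read a plain-text gene list (one symbol per line, '#' comments)."""
    with open(path) as fh:
        genes = [line.strip() for line in fh
                 if line.strip() and not line.lstrip().startswith("#")]
    return MarkerPanel(name or str(path), frozenset(genes), source)


def default_panels() -> dict[str, MarkerPanel]:
    """The three bundled adjacent-tissue panels."""
    panels = {}
    base = resources.files("hippostress").joinpath("data/panels")
    for fname, name in [("choroid_plexus.txt", "choroid_plexus"),
                        ("habenula.txt", "habenula"),
                        ("septal_nuclei.txt", "septal_nuclei")]:
        with resources.as_file(base.joinpath(fname)) as path:
            panels[name] = load_panel(path, name=name, source="bundled tissue-marker list")
    return panels


@dataclass
class StressIndexTable:
    """Per-animal organ-weight stress indices (% of body weight)."""

    table: pd.DataFrame  # columns: animal, group, thymus_pct, spleen_pct

    def __post_init__(self) -> None:
        required = {"animal", "group", "thymus_pct", "spleen_pct"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"stress-index table lacks columns: {sorted(missing)}")
        if self.table["animal"].duplicated().any():
            raise ValueError("one record per animal required")
        if (self.table[["thymus_pct", "spleen_pct"]] <= 0).any().any():
            raise ValueError("organ weights must be positive")


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all n! orderings of one rank vector."""
    n = len(rx)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    hits = total = 0
    perm_iter = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perm_iter, 200_000))
        if not chunk:
            break
        rhos = (ry[np.asarray(chunk)] @ rx) / denom
        hits += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        total += len(chunk)
    return hits / total


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average-rank vectors (ties get
    mid-ranks).  The p-value is an exact permutation probability for
    n <= 10 and the usual t approximation with n - 2 df above.
    Constant input has no defined rank correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    rho = float((rxc @ ryc) / np.sqrt((rxc @ rxc) * (ryc @ ryc)))
    if n <= 10:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def stress_index_screen(expression: pd.DataFrame, indices: StressIndexTable,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Correlate each gene's per-animal expression with the stress indices.

    ``expression`` is animals x genes, aligned on the index table's
    animal ids (data pooled across stress groups).  A gene is
    classified "stress-correlated" when it is significant (two-sided,
    ``alpha``) for at least one organ with the physiological sign
    pattern (thymus negative or spleen positive); otherwise
    "uncorrelated".  Raw rho/p for both organs are always reported.
    """
    tab = indices.table.set_index("animal")
    common = [a for a in expression.index if a in tab.index]
    if len(common) < 10:
        raise ValueError("need >= 10 animals with both expression and indices")
    expr = expression.loc[common]
    thymus = tab.loc[common, "thymus_pct"].to_numpy(dtype=float)
    spleen = tab.loc[common, "spleen_pct"].to_numpy(dtype=float)
    rows = []
    for gene in expr.columns:
        vals = expr[gene].to_numpy(dtype=float)
        try:
            rho_t, p_t = spearman_correlation(vals, thymus)
            rho_s, p_s = spearman_correlation(vals, spleen)
        except ValueError:
            rows.append({"gene": gene, "rho_thymus": np.nan, "p_thymus": np.nan,
                         "rho_spleen": np.nan, "p_spleen": np.nan,
                         "classification": "undefined"})
            continue
        stress_like = (p_t < alpha and rho_t < 0) or (p_s < alpha and rho_s > 0)
        rows.append({"gene": gene, "rho_thymus": rho_t, "p_thymus": p_t,
                     "rho_spleen": rho_s, "p_spleen": p_s,
                     "classification": "stress-correlated" if stress_like else "uncorrelated"})
    return pd.DataFrame(rows).set_index("gene")


def marker_overlap(cluster_genes: list[str], panel: MarkerPanel,
                   background_size: int) -> tuple[int, float]:
    """Panel genes in the cluster and the hypergeometric upper-tail p.

    Draws of size len(cluster) from a background of ``background_size``
    genes containing len(panel) panel members.
    """
    if len(cluster_genes) == 0:
        raise ValueError("empty cluster")
    if background_size < len(cluster_genes):
        raise ValueError("background must be at least the cluster size")
    count = sum(1 for g in cluster_genes if g in panel)
    k_panel = min(len(panel.genes), background_size)
    p = float(stats.hypergeom.sf(count - 1, background_size, k_panel, len(cluster_genes)))
    return count, min(p, 1.0)


@dataclass
class ContaminationReport:
    """Machine-readable verdicts with the evidence behind them."""

    clusters: pd.DataFrame   # per cluster: suspect, evidence columns
    genes: pd.DataFrame      # per gene: cluster, verdict, evidence columns
    metadata: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        def frame_to_records(df: pd.DataFrame) -> list[dict]:
            out = []
            for key, row in df.sort_index().iterrows():
                rec = {"id": key if not isinstance(key, np.generic) else key.item()}
                for col, val in row.items():
                    if isinstance(val, (np.floating, float)):
                        val = None if not np.isfinite(val) else round(float(val), 10)
                    elif isinstance(val, np.generic):
                        val = val.item()
                    rec[col] = val
                out.append(rec)
            return out

        payload = {
            "clusters": frame_to_records(self.clusters),
            "genes": frame_to_records(self.genes),
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def build_report(assignment: pd.DataFrame, suspect_clusters: dict[int, str],
                 overlaps: pd.DataFrame, stress_screen: pd.DataFrame,
                 de_significant: pd.Series, panels: dict[str, MarkerPanel],
                 config: dict | None = None) -> ContaminationReport:
    """Combine cluster membership, atlas calls, panel overlaps and
    stress-index correlations into per-cluster and per-gene verdicts.

    Parameters
    ----------
    assignment
        Gene-indexed DataFrame with a ``cluster`` column (the clustered,
        i.e. significant, genes).
    suspect_clusters
        Cluster id -> atlas screen status ("clean" / "suspect" /
        "insufficient imagery").
    overlaps
        Cluster-indexed DataFrame with columns ``panel``,
        ``overlap_count``, ``overlap_p`` (best panel per cluster).
    stress_screen
        Output of :func:`stress_index_screen`.
    de_significant
        Gene-indexed boolean Series of differential-expression calls.
    """
    genes = list(assignment.index)
    missing = [g for g in genes if g not in stress_screen.index]
    if missing:
        raise KeyError(f"genes missing from stress screen, e.g. {missing[:5]}")

    panel_of: dict[str, str] = {}
    for name, panel in panels.items():
        for g in genes:
            if g in panel:
                panel_of.setdefault(g, name)

    gene_rows = {}
    for g in genes:
        cluster = int(assignment.loc[g, "cluster"])
        suspect = suspect_clusters.get(cluster, "clean") == "suspect"
        in_panel = g in panel_of
        corr_class = stress_screen.loc[g, "classification"]
        uncorrelated = corr_class == "uncorrelated"
        significant = bool(de_significant.get(g, False))
        if (suspect or in_panel) and uncorrelated:
            verdict = "contamination-consistent"
        elif significant and not suspect and not in_panel and corr_class == "stress-correlated":
            verdict = "stress-responsive"
        else:
            verdict = "indeterminate"
        gene_rows[g] = {
            "cluster": cluster,
            "verdict": verdict,
            "suspect_cluster": suspect,
            "panel": panel_of.get(g, ""),
            "stress_correlation": corr_class,
            "de_significant": significant,
        }
    genes_df = pd.DataFrame.from_dict(gene_rows, orient="index").sort_index()

    cluster_rows = {}
    for cluster, sub in genes_df.groupby("cluster"):
        status = suspect_clusters.get(int(cluster), "clean")
        row = {
            "status": status,
            "suspect": status == "suspect",
            "n_genes": int(len(sub)),
            "n_flagged_members": int((sub["verdict"] == "contamination-consistent").sum()),
            "fraction_uncorrelated": float((sub["stress_correlation"] == "uncorrelated").mean()),
        }
        if int(cluster) in overlaps.index:
            row["best_panel"] = overlaps.loc[int(cluster), "panel"]
            row["overlap_count"] = int(overlaps.loc[int(cluster), "overlap_count"])
            row["overlap_p"] = float(overlaps.loc[int(cluster), "overlap_p"])
        else:
            row["best_panel"] = ""
            row["overlap_count"] = 0
            row["overlap_p"] = 1.0
        cluster_rows[int(cluster)] = row
    clusters_df = pd.DataFrame.from_dict(cluster_rows, orient="index").sort_index()

    return ContaminationReport(clusters_df, genes_df, dict(config or {}))
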