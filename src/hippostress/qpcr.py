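"""qPCR validation statistics.

Amplification efficiency E is estimated per gene from a dilution
series by regressing Ct on log10 relative input (E = 10^(-1/slope),
with E = 2 for perfect doubling chemistry, slope -3.3219).  Relative
expression follows the efficiency-corrected (Pfaffl) model

    R = E_target^dCt_target / E_reference^dCt_reference,

with dCt = Ct(control) - Ct(stressed sample), so R > 1 means higher
expression in the stressed animal.  Paired differences are tested
with the Wilcoxon signed-rank test (exact sign enumeration up to
n = 12, normal approximation with continuity correction above);
variance-homogeneity (Levene) and normality (Lilliefors, Monte-Carlo
p) gates document why the nonparametric route is taken.  A simple
variance-decomposition stability score ranks candidate reference
genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrPlate",
    "EfficiencyEstimate",
    "RelativeExpression",
    "estimate_efficiency",
    "collapse_replicate_wells",
    "pfaffl_ratio",
    "relative_expression_table",
    "wilcoxon_signed_rank",
    "variance_gates",
    "reference_stability",
]

WELL_COLUMNS = ["sample", "gene", "ct", "replicate", "role", "dilution", "pair_id", "arm"]


@dataclass
class QpcrPlate:
    """Well-level Ct observations.

    ``wells`` columns: sample, gene, ct, replicate, role (unknown /
    standard / negative), dilution (relative input for standards,
    NaN otherwise), pair_id (stress/control sibling pairing) and arm
    ("stress" or "control").  Negative-control wells carry NaN Ct.
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate table lacks columns: {missing}")
        non_negative = self.wells["role"] != "negative"
        cts = self.wells.loc[non_negative, "ct"]
        if (cts <= 0).any() or cts.isna().any():
            raise ValueError("non-negative wells must have Ct > 0")
        standards = self.wells["role"] == "standard"
        if standards.any() and self.wells.loc[standards, "dilution"].isna().any():
            raise ValueError("standard wells must carry a dilution factor")

    def standards(self, gene: str) -> pd.DataFrame:
        return self.wells[(self.wells["gene"] == gene) & (self.wells["role"] == "standard")]

    def unknowns(self, gene: str) -> pd.DataFrame:
        return self.wells[(self.wells["gene"] == gene) & (self.wells["role"] == "unknown")]


@dataclass
class EfficiencyEstimate:
    gene: str
    slope: float
    efficiency: float
    r_squared: float
    flagged: bool  # True when the fit quality is below R^2 = 0.98

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.5):
            raise ValueError(f"{self.gene}: efficiency {self.efficiency:.3f} outside (1, 2.5]")


def estimate_efficiency(plate: QpcrPlate, gene: str) -> EfficiencyEstimate:
    """Least-squares fit of Ct on log10(relative input) for the gene's
    dilution series; E = 10^(-1/slope).

    Requires >= 3 distinct dilution points; a nonnegative slope means
    no amplification and is an error; fits with R^2 < 0.98 are flagged.
    """
    std = plate.standards(gene)
    if std["dilution"].nunique() < 3:
        raise ValueError(f"{gene}: need >= 3 distinct dilution points")
    x = np.log10(std["dilution"].to_numpy(dtype=float))
    y = std["ct"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(f"{gene}: nonnegative dilution slope (non-amplifying)")
    eff = 10.0 ** (-1.0 / fit.slope)
    r2 = float(fit.rvalue**2)
    return EfficiencyEstimate(gene, float(fit.slope), float(eff), r2, r2 < 0.98)


def collapse_replicate_wells(wells: pd.DataFrame, outlier_ct: float = 1.0) -> pd.DataFrame:
    """Mean Ct per (sample, gene) after dropping outlier wells.

    A well farther than ``outlier_ct`` cycles from its replicate median
    is dropped and logged with a warning (pipetting failures).
    """
    rows = []
    for (sample, gene), sub in wells.groupby(["sample", "gene"], sort=False):
        cts = sub["ct"].to_numpy(dtype=float)
        med = np.median(cts)
        keep = np.abs(cts - med) <= outlier_ct
        if not keep.all():
            warnings.warn(
                f"dropping {np.sum(~keep)} outlier well(s) for {sample}/{gene}",
                RuntimeWarning, stacklevel=2)
        rows.append({"sample": sample, "gene": gene, "ct": float(np.mean(cts[keep])),
                     "pair_id": sub["pair_id"].iloc[0], "arm": sub["arm"].iloc[0]})
    return pd.DataFrame(rows)


@dataclass
class RelativeExpression:
    pair_id: str
    gene: str
    dct_target: float
    dct_reference: float
    ratio: float
    log2_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if self.ratio <= 0 or not np.isfinite(self.ratio):
            raise ValueError("relative expression ratio must be positive and finite")
        self.log2_ratio = float(np.log2(self.ratio))


def pfaffl_ratio(e_target: float, dct_target: float, e_reference: float,
                 dct_reference: float, pair_id: str = "", gene: str = "") -> RelativeExpression:
    """Efficiency-corrected relative expression:
    R = E_t^dCt_t / E_r^dCt_r with dCt = Ct(control) - Ct(sample)."""
    for e in (e_target, e_reference):
        if not (1.0 < e <= 2.5):
            raise ValueError(f"amplification efficiency {e} outside (1, 2.5]")
    ratio = e_target**dct_target / e_reference**dct_reference
    return RelativeExpression(pair_id, gene, float(dct_target), float(dct_reference),
                              float(ratio))


def relative_expression_table(plate: QpcrPlate, target_gene: str, reference_gene: str,
                              efficiencies: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-pair Pfaffl ratios for one target gene against the reference.

    Triplicate wells are collapsed by mean Ct (with the >1-cycle
    outlier drop) before pairing; efficiencies default to dilution-
    series estimates from the same plate.
    """
    if efficiencies is None:
        efficiencies = {g: estimate_efficiency(plate, g).efficiency
                        for g in (target_gene, reference_gene)}
    collapsed = collapse_replicate_wells(
        plate.wells[(plate.wells["role"] == "unknown")
                    & (plate.wells["gene"].isin([target_gene, reference_gene]))])
    rows = []
    for pair_id, sub in collapsed.groupby("pair_id", sort=False):
        try:
            ct = {(r["gene"], r["arm"]): r["ct"] for _, r in sub.iterrows()}
            dct_t = ct[(target_gene, "control")] - ct[(target_gene, "stress")]
            dct_r = ct[(reference_gene, "control")] - ct[(reference_gene, "stress")]
        except KeyError as err:
            raise ValueError(f"pair {pair_id}: missing well {err}") from err
        rel = pfaffl_ratio(efficiencies[target_gene], dct_t,
                           efficiencies[reference_gene], dct_r,
                           pair_id=str(pair_id), gene=target_gene)
        rows.append({"pair_id": pair_id, "gene": target_gene, "dct_target": dct_t,
                     "dct_reference": dct_r, "ratio": rel.ratio,
                     "log2_ratio": rel.log2_ratio})
    return pd.DataFrame(rows)


@lru_cache(maxsize=32)
def _sign_matrix(n: int) -> np.ndarray:
    bits = np.arange(2**n, dtype=np.int64)[:, None] >> np.arange(n)[None, :]
    return (bits & 1).astype(float)


def wilcoxon_signed_rank(differences: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of paired differences.

    Zero differences are dropped; ties get mid-ranks.  The statistic W
    is the positive-rank sum.  For n <= 12 (after zero removal) the
    p-value is exact by enumeration of all 2^n sign assignments,
    p = 2 * min tail probability capped at 1; above that a normal
    approximation with continuity and tie correction is used.  All
    differences zero is degenerate and returns p = 1.
    """
    d = np.asarray(differences, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = stats.rankdata(np.abs(d), method="average")
    w_pos = float(ranks[d > 0].sum())
    if n <= 12:
        signs = _sign_matrix(n)
        w_all = signs @ ranks
        upper = float(np.mean(w_all >= w_pos - 1e-12))
        lower = float(np.mean(w_all <= w_pos + 1e-12))
        p = min(1.0, 2.0 * min(upper, lower))
        return w_pos, p
    mean = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
    return w_pos, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_mc, n))
    draws.sort(axis=1)
    means = draws.mean(axis=1, keepdims=True)
    sds = draws.std(axis=1, ddof=1, keepdims=True)
    z = stats.norm.cdf((draws - means) / sds)
    i = np.arange(1, n + 1)
    d_plus = (i / n - z).max(axis=1)
    d_minus = (z - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors_statistic(values: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance to the normal fitted by sample moments."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    z = stats.norm.cdf((x - x.mean()) / x.std(ddof=1))
    i = np.arange(1, n + 1)
    return float(max((i / n - z).max(), (z - (i - 1) / n).max()))


@dataclass
class GateReport:
    levene_stat: float
    levene_p: float
    lilliefors: pd.DataFrame  # per group: statistic, p
    homogeneous: bool
    normal: bool
    recommend_nonparametric: bool


def variance_gates(groups: dict[str, np.ndarray], alpha: float = 0.05,
                   n_mc: int = 10_000, seed: int = 0) -> GateReport:
    """Levene (mean-centered, F reference) and Lilliefors gates.

    The Lilliefors p-value is Monte-Carlo (``n_mc`` seeded standard-
    normal samples of matching size).  When either gate fails at
    ``alpha`` the report recommends the nonparametric route.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2 or any(len(v) < 3 for v in arrays.values()):
        raise ValueError("Levene gate needs >= 2 groups of >= 3 values")
    levene = stats.levene(*arrays.values(), center="mean")
    rows = []
    for name, vals in arrays.items():
        if len(vals) < 5:
            raise ValueError("Lilliefors gate needs >= 5 values per group")
        dstat = lilliefors_statistic(vals)
        null = _lilliefors_null(len(vals), n_mc, seed)
        p = float((np.sum(null >= dstat - 1e-12) + 1) / (len(null) + 1))
        rows.append({"group": name, "statistic": dstat, "p": p})
    lf = pd.DataFrame(rows).set_index("group")
    homogeneous = levene.pvalue >= alpha
    normal = bool((lf["p"] >= alpha).all())
    return GateReport(float(levene.statistic), float(levene.pvalue), lf,
                      homogeneous, normal, not (homogeneous and normal))


def reference_stability(ct_table: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Rank candidate reference genes by expression stability.

    ``ct_table`` is samples x candidate genes (log-scale Ct values);
    ``groups`` assigns each sample to an experimental group.  Stability
    is sqrt(mean intra-group variance + variance of group means) -
    lower is more stable.  This is a plain variance decomposition, not
    a model-based estimator.
    """
    if ct_table.shape[1] < 2:
        raise ValueError("need >= 2 candidate reference genes")
    groups = groups.reindex(ct_table.index)
    if groups.nunique() < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for gene in ct_table.columns:
        per_group = ct_table[gene].groupby(groups)
        counts = per_group.count()
        if (counts == 0).any():
            raise ValueError(f"{gene}: missing in group(s) {list(counts.index[counts == 0])}")
        intra = float(per_group.var(ddof=1).fillna(0.0).mean())
        inter = float(per_group.mean().var(ddof=1))
        rows.append({"gene": gene, "intra_group_var": intra, "inter_group_var": inter,
                     "stability": float(np.sqrt(intra + inter))})
    out = pd.DataFrame(rows).set_index("gene").sort_values("stability", kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
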