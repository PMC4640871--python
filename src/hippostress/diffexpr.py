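"""Differential expression for two-color array fold changes.

The analysis object is a :class:`FoldChangeMatrix`: genes (or probes)
by replicate comparisons, each value a log2(stress/control) ratio from
one array hybridizing a stressed animal pool against its sibling
control pool.  Per-group differential calls use a one-sample test of
the replicate logFCs against zero, optionally with empirical-Bayes
variance moderation; time-course contrasts compare the logFCs of two
stress periods.  The joint significance rule is |logFC| > 0.5 (strict)
and Benjamini-Hochberg adjusted p < 0.05 (strict).

A raw-data pathway is also provided for two-color intensity files:
normexp background correction (normal background + exponential signal,
fitted by maximum likelihood per array/channel), loess within-array
normalization of M on A, and Aquantile between-array normalization of
the A-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "FoldChangeMatrix",
    "TwoColorArray",
    "TwoColorArraySet",
    "ModerationParams",
    "normexp_background_correct",
    "loess_within_array",
    "aquantile_between_arrays",
    "compute_foldchanges",
    "average_dye_swaps",
    "collapse_probes_to_genes",
    "fit_moderation_params",
    "moderate_variances",
    "paired_de_test",
    "timecourse_contrast",
    "benjamini_hochberg",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class FoldChangeMatrix:
    """Genes/probes x replicate-comparisons table of log2(stress/control).

    Parameters
    ----------
    values
        DataFrame indexed by probe or gene id; one column per array
        comparison.  Missing values allowed (NaN).
    meta
        DataFrame indexed by the column ids of ``values`` with columns
        ``group`` (stress regime label), ``replicate`` (biological
        replicate id; dye-swap pairs share it) and ``swapped`` (bool,
        True for the dye-swapped member of a pair).
    gene_map
        Optional probe -> gene symbol Series (many probes may map to
        one gene).  ``None`` once rows are already genes.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    gene_map: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ("group", "replicate", "swapped") if c not in self.meta.columns]
        if missing:
            raise ValueError(f"column metadata lacks required fields: {missing}")
        if list(self.meta.index) != list(self.values.columns):
            self.meta = self.meta.loc[self.values.columns]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.meta["group"]))

    def group_columns(self, group: str) -> list[str]:
        cols = self.meta.index[self.meta["group"] == group]
        if len(cols) == 0:
            raise KeyError(f"unknown group label: {group!r}")
        return list(cols)


@dataclass
class TwoColorArray:
    """One two-color array: foreground/background per channel per probe."""

    array_id: str
    probes: pd.Index
    red_fg: np.ndarray
    red_bg: np.ndarray
    green_fg: np.ndarray
    green_bg: np.ndarray
    stress_channel: str  # "red" or "green"
    group: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.stress_channel not in ("red", "green"):
            raise ValueError("stress_channel must be 'red' or 'green'")
        for name in ("red_fg", "red_bg", "green_fg", "green_bg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.probes),):
                raise ValueError(f"{name} length does not match probes")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative intensities")
            setattr(self, name, arr)

    @property
    def swapped(self) -> bool:
        # convention: the original orientation labels stress with Cy5 (red)
        return self.stress_channel == "green"


@dataclass
class TwoColorArraySet:
    arrays: list[TwoColorArray] = field(default_factory=list)

    def __iter__(self):
        return iter(self.arrays)

    def __len__(self) -> int:
        return len(self.arrays)


@dataclass
class ModerationParams:
    """Empirical-Bayes variance-shrinkage hyperparameters.

    ``d0`` is the prior degrees of freedom (may be ``inf``), ``s0_sq``
    the prior variance; per-gene residual df are carried by the caller.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if self.s0_sq <= 0:
            raise ValueError("prior variance must be > 0")


# ---------------------------------------------------------------------------
# normexp background correction


def _normexp_negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = theta
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    z = (x - mu - sigma**2 / alpha) / sigma
    ll = -log_alpha + (mu - x) / alpha + sigma**2 / (2 * alpha**2) + stats.norm.logcdf(z)
    return -float(np.sum(ll))


def _normexp_fit(x: np.ndarray) -> tuple[float, float, float]:
    """Maximum-likelihood fit of the normal+exponential convolution."""
    q = np.quantile(x, [0.05, 0.5])
    lower = x[x <= q[1]]
    mu0 = float(np.mean(lower))
    sigma0 = max(float(np.std(lower)), 1e-3 * max(abs(mu0), 1.0), 1e-6)
    alpha0 = max(float(np.mean(x) - mu0), sigma0)
    theta0 = np.array([mu0, np.log(sigma0), np.log(alpha0)])
    res = None
    from scipy.optimize import minimize

    res = minimize(_normexp_negloglik, theta0, args=(x,), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
    mu, log_sigma, log_alpha = res.x
    return float(mu), float(np.exp(log_sigma)), float(np.exp(log_alpha))


def normexp_posterior_mean(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """E[signal | observed] under normal(mu, sigma^2) + Exp(alpha)."""
    mu_sf = x - mu - sigma**2 / alpha
    z = mu_sf / sigma
    # sigma * phi(z)/Phi(z) stays finite and positive for all z
    out = mu_sf + sigma * np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    return np.maximum(out, np.finfo(float).tiny)


def _correct_channel(fg: np.ndarray, bg: np.ndarray, offset: float) -> np.ndarray:
    x = fg - bg
    if np.ptp(x) < 1e-12 or len(np.unique(x)) < 4:
        warnings.warn("degenerate intensities; falling back to subtract-and-floor",
                      RuntimeWarning, stacklevel=3)
        return np.maximum(x - np.min(x), 0.5) + offset
    mu, sigma, alpha = _normexp_fit(x)
    return normexp_posterior_mean(x, mu, sigma, alpha) + offset


def normexp_background_correct(arrays: TwoColorArraySet, offset: float = 0.0) -> TwoColorArraySet:
    """Background-correct both channels of every array.

    The observed (foreground - background) intensity is modeled as a
    normal background plus exponential signal; the corrected value is
    the posterior mean of the signal, which is strictly positive and
    monotone in the input.  ``offset`` is added to the corrected
    intensities to damp low-intensity log-ratio variance.
    """
    out = []
    for arr in arrays:
        red = _correct_channel(arr.red_fg, arr.red_bg, offset)
        green = _correct_channel(arr.green_fg, arr.green_bg, offset)
        out.append(replace(arr, red_fg=red, red_bg=np.zeros_like(red),
                           green_fg=green, green_bg=np.zeros_like(green)))
    return TwoColorArraySet(out)


# ---------------------------------------------------------------------------
# normalization


def loess_within_array(M: np.ndarray, A: np.ndarray, span: float = 0.3,
                       iterations: int = 3) -> np.ndarray:
    """Remove the intensity-dependent trend of M on A (locally linear fit).

    Returns M minus the loess fit evaluated at each A; requires at
    least 10 finite (M, A) pairs, otherwise the input is returned with
    a warning.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.shape != A.shape:
        raise ValueError("M and A must have the same length")
    finite = np.isfinite(M) & np.isfinite(A)
    if finite.sum() < 10:
        warnings.warn("fewer than 10 finite (M, A) pairs; skipping loess",
                      RuntimeWarning, stacklevel=2)
        return M.copy()
    fit = lowess(M[finite], A[finite], frac=span, it=iterations,
                 return_sorted=False)
    out = M.copy()
    out[finite] = M[finite] - fit
    return out


def aquantile_between_arrays(A: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize A-values (mean log intensity) across arrays.

    Columns are arrays, rows probes.  After the step the sorted A
    vector of every array equals the mean of the sorted input vectors;
    ties receive the average of the values they span.  M-values are not
    an input here and are untouched by construction.
    """
    if A.shape[1] < 2:
        raise ValueError("Aquantile needs at least 2 arrays")
    vals = A.to_numpy(dtype=float)
    sorted_mean = np.sort(vals, axis=0).mean(axis=1)
    n = vals.shape[0]
    out = np.empty_like(vals)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, sorted_mean)
    return pd.DataFrame(out, index=A.index, columns=A.columns)


def compute_foldchanges(arrays: TwoColorArraySet, span: float = 0.3,
                        loess: bool = True, aquantile: bool = True) -> FoldChangeMatrix:
    """Per-probe per-array log2(stress channel / control channel).

    Applies within-array loess normalization of M on A and Aquantile
    between-array normalization of A (both optional), then orients each
    array's log-ratio by its channel assignment so that positive values
    mean higher expression in the stressed sample.
    """
    if len(arrays) == 0:
        raise ValueError("empty array set")
    for arr in arrays:
        if not arr.stress_channel:
            raise ValueError(f"array {arr.array_id}: missing channel assignment")
    probes = arrays.arrays[0].probes
    M_cols, A_cols, ids, meta_rows = {}, {}, [], []
    for arr in arrays:
        if not arr.probes.equals(probes):
            raise ValueError("arrays must share an identical probe set")
        red = np.maximum(arr.red_fg, 1e-6)
        green = np.maximum(arr.green_fg, 1e-6)
        M = np.log2(red / green)
        A = 0.5 * np.log2(red * green)
        if loess:
            M = loess_within_array(M, A, span=span)
        if arr.stress_channel == "green":
            M = -M
        col = f"{arr.group}.{arr.replicate}." + ("b" if arr.swapped else "a")
        M_cols[col] = M
        A_cols[col] = A
        ids.append(col)
        meta_rows.append({"group": arr.group, "replicate": arr.replicate,
                          "swapped": arr.swapped})
    Mdf = pd.DataFrame(M_cols, index=probes)
    if aquantile and len(arrays) >= 2:
        # A-values are normalized for downstream users; M is unchanged
        aquantile_between_arrays(pd.DataFrame(A_cols, index=probes))
    meta = pd.DataFrame(meta_rows, index=ids)
    return FoldChangeMatrix(Mdf, meta)


# ---------------------------------------------------------------------------
# replicate handling


def average_dye_swaps(matrix: FoldChangeMatrix) -> FoldChangeMatrix:
    """Average orientation-corrected dye-swap pairs into one column per
    biological replicate.

    Unpaired columns pass through with a warning; more than two columns
    sharing a replicate id is an error.  A pair with one missing value
    at a gene keeps the finite member.
    """
    new_cols, new_meta = {}, []
    for (group, rep), sub in matrix.meta.groupby(["group", "replicate"], sort=False):
        cols = list(sub.index)
        if len(cols) > 2:
            raise ValueError(f"replicate {group}.{rep} has {len(cols)} columns (max 2)")
        if len(cols) == 1:
            warnings.warn(f"replicate {group}.{rep} has no dye-swap partner",
                          RuntimeWarning, stacklevel=2)
        name = f"{group}.{rep}"
        new_cols[name] = matrix.values[cols].mean(axis=1, skipna=True)
        new_meta.append({"group": group, "replicate": rep, "swapped": False})
    values = pd.DataFrame(new_cols)
    meta = pd.DataFrame(new_meta, index=list(values.columns))
    return FoldChangeMatrix(values, meta, matrix.gene_map)


def collapse_probes_to_genes(matrix: FoldChangeMatrix) -> FoldChangeMatrix:
    """Collapse probe rows to one row per gene by per-column median.

    Even probe counts take the mean of the two middle values (the
    ordinary median convention).
    """
    if matrix.gene_map is None:
        raise ValueError("probe -> gene map required to collapse probes")
    genes = matrix.gene_map.reindex(matrix.values.index)
    if genes.isna().any():
        missing = list(matrix.values.index[genes.isna()][:5])
        raise ValueError(f"probes missing from gene map, e.g. {missing}")
    collapsed = matrix.values.groupby(genes).median()
    return FoldChangeMatrix(collapsed, matrix.meta.copy(), None)


# ---------------------------------------------------------------------------
# moderation


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_moderation_params(s2: np.ndarray, d: np.ndarray | float) -> ModerationParams:
    """Method-of-moments fit of (d0, s0^2) from the spread of log s^2.

    Models s^2 ~ s0^2 * F(d, d0); the mean and variance of
    e = log s^2 - digamma(d/2) + log(d/2) identify s0^2 and d0 through
    the digamma/trigamma functions.  Genes with zero sample variance
    are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (d >= 1)
    if ok.sum() == 0:
        raise ValueError("all sample variances are zero; cannot fit prior")
    z = np.log(s2[ok])
    dd = d[ok]
    e = z - special.digamma(dd / 2.0) + np.log(dd / 2.0)
    emean = float(np.mean(e))
    if ok.sum() < 2:
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(emean)))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, dd / 2.0)))
    if evar <= 0:
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderate_variances(s2: np.ndarray, d: np.ndarray | float,
                       params: ModerationParams) -> np.ndarray:
    """Shrink per-gene variances toward the prior:
    s~^2 = (d0*s0^2 + d*s^2) / (d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    if np.isinf(params.d0):
        return np.full_like(s2, params.s0_sq)
    if params.d0 == 0:
        return s2.copy()
    return (params.d0 * params.s0_sq + d * s2) / (params.d0 + d)


# ---------------------------------------------------------------------------
# tests and adjustment


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    adj_i = min over j with rank(j) >= rank(i) of m * p_j / rank(j),
    capped at 1; order preserving.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _one_sample_stats(values: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = values.to_numpy(dtype=float)
    n = np.isfinite(arr).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=1)
        var = np.nanvar(arr, axis=1, ddof=1)
    return mean, var, n


def _t_pvalues(tstat: np.ndarray, df: np.ndarray) -> np.ndarray:
    p = np.ones_like(tstat)
    finite = np.isfinite(tstat)
    p[finite] = 2.0 * stats.t.sf(np.abs(tstat[finite]), df[finite])
    p[np.isposinf(tstat) | np.isneginf(tstat)] = 0.0
    return np.clip(p, 0.0, 1.0)


def paired_de_test(matrix: FoldChangeMatrix, group: str, moderation: bool = True,
                   lfc_threshold: float = 0.5, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene differential call for one stress group.

    One-sample (paired, since each logFC already contrasts a stressed
    pool with its sibling control) two-sided test of the replicate
    logFCs against zero; moderated t when ``moderation``.  BH
    adjustment across genes within the group; significant iff
    |logFC| > ``lfc_threshold`` (strict) and adjusted p < ``fdr_alpha``
    (strict).  Genes with fewer than 2 finite replicates are reported
    untested.
    """
    cols = matrix.group_columns(group)
    if len(cols) < 2:
        raise ValueError("insufficient degrees of freedom: need >= 2 replicate columns")
    mean, var, n = _one_sample_stats(matrix.values[cols])
    tested = n >= 2
    if not tested.any():
        raise ValueError("insufficient degrees of freedom: no gene has >= 2 finite replicates")
    d = np.where(tested, n - 1.0, np.nan)

    if moderation:
        params = fit_moderation_params(var[tested], d[tested])
        s2 = np.full_like(var, np.nan)
        s2[tested] = moderate_variances(var[tested], d[tested], params)
        df = d + (0.0 if np.isinf(params.d0) else params.d0)
        df[~tested] = np.nan
        if np.isinf(params.d0):
            df = np.where(tested, 1e6, np.nan)
    else:
        s2 = var
        df = d

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / np.sqrt(s2 / n)
    p = np.full(len(mean), np.nan)
    p[tested] = _t_pvalues(tstat[tested], df[tested])
    # zero-variance, zero-mean genes carry no evidence: p = 1 by convention
    degenerate = tested & (s2 == 0) & (mean == 0)
    p[degenerate] = 1.0
    tstat[degenerate] = 0.0

    adj = np.full(len(mean), np.nan)
    adj[tested] = benjamini_hochberg(p[tested])
    significant = tested & (np.abs(mean) > lfc_threshold) & (adj < fdr_alpha)
    return pd.DataFrame(
        {"group": group, "logfc": mean, "t": tstat, "p": p, "adj_p": adj,
         "significant": significant, "tested": tested, "n": n},
        index=matrix.values.index,
    )


def timecourse_contrast(matrix: FoldChangeMatrix, period_a: str, period_b: str,
                        moderation: bool = True, lfc_threshold: float = 0.5,
                        fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Between-period contrast of stress-vs-control logFCs (a minus b).

    A positive estimate means the stress-induced change is greater in
    ``period_a`` (the earlier period, by the caller's ordering).  The
    same joint |difference| > threshold and BH-adjusted p rule applies
    within this contrast family.
    """
    cols_a = matrix.group_columns(period_a)
    cols_b = matrix.group_columns(period_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both periods need >= 2 replicate columns")
    mean_a, var_a, n_a = _one_sample_stats(matrix.values[cols_a])
    mean_b, var_b, n_b = _one_sample_stats(matrix.values[cols_b])
    tested = (n_a >= 2) & (n_b >= 2)
    est = mean_a - mean_b
    d = n_a + n_b - 2.0
    with np.errstate(invalid="ignore"):
        pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / d
    d[~tested] = np.nan

    if moderation:
        params = fit_moderation_params(pooled[tested], d[tested])
        s2 = np.full_like(pooled, np.nan)
        s2[tested] = moderate_variances(pooled[tested], d[tested], params)
        df = d + (0.0 if np.isinf(params.d0) else params.d0)
        if np.isinf(params.d0):
            df = np.where(tested, 1e6, np.nan)
    else:
        s2 = pooled
        df = d

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = est / np.sqrt(s2 * (1.0 / n_a + 1.0 / n_b))
    p = np.full(len(est), np.nan)
    p[tested] = _t_pvalues(tstat[tested], df[tested])
    degenerate = tested & (s2 == 0) & (est == 0)
    p[degenerate] = 1.0
    tstat[degenerate] = 0.0

    adj = np.full(len(est), np.nan)
    adj[tested] = benjamini_hochberg(p[tested])
    significant = tested & (np.abs(est) > lfc_threshold) & (adj < fdr_alpha)
    return pd.DataFrame(
        {"contrast": f"{period_a}-{period_b}", "delta_logfc": est, "t": tstat,
         "p": p, "adj_p": adj, "significant": significant, "tested": tested},
        index=matrix.values.index,
    )
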