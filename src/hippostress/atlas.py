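"""Regional expression scoring from color-coded expression-mask images.

Atlas-style in situ hybridization expression masks code transcript
level by color, from blue (low) through green (medium) to red (high).
The regional score is the weighted sum of per-channel means over a
region of interest: blue x 1 + green x 2 + red x 3 by default, with
black (zero-expression) pixels included in the means.  A gene is
flagged as a potential dissection artifact when some region adjacent
to the target (e.g. choroid plexus next to the hippocampus) scores
strictly higher than the target region; when enough of a cluster's
representative genes are flagged, the whole cluster is screened
gene by gene and marked suspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon
from skimage.draw import polygon_perimeter as _draw_perimeter

__all__ = [
    "ExpressionMaskImage",
    "RegionOfInterest",
    "ScoringWeights",
    "EnrichmentFlag",
    "ClusterScreenResult",
    "weighted_color_score",
    "regional_profile",
    "enrichment_flag",
    "select_representatives",
    "screen_cluster",
]


@dataclass
class ExpressionMaskImage:
    """8-bit RGB expression mask for one gene (one atlas slice)."""

    pixels: np.ndarray  # rows x cols x 3, uint8
    gene: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("expected a rows x cols x 3 RGB raster")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px


@dataclass
class RegionOfInterest:
    """Named pixel set, as a boolean mask or a polygon (0-based row/col,
    boundary pixels included)."""

    name: str
    mask: np.ndarray | None = None
    polygon: np.ndarray | None = None  # (k, 2) array of (row, col) vertices

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != shape:
                raise ValueError(f"ROI {self.name!r}: mask shape {m.shape} != image {shape}")
            if not m.any():
                raise ValueError(f"ROI {self.name!r} is empty")
            return m
        if self.polygon is None:
            raise ValueError(f"ROI {self.name!r} has neither mask nor polygon")
        poly = np.asarray(self.polygon, dtype=float)
        if poly.min() < 0 or poly[:, 0].max() >= shape[0] or poly[:, 1].max() >= shape[1]:
            raise ValueError(f"ROI {self.name!r} lies outside the image bounds")
        m = np.zeros(shape, dtype=bool)
        rr, cc = _draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
        m[rr, cc] = True
        rr, cc = _draw_perimeter(poly[:, 0].round().astype(int),
                                 poly[:, 1].round().astype(int), shape=shape)
        m[rr, cc] = True
        if not m.any():
            raise ValueError(f"ROI {self.name!r} is empty")
        return m


@dataclass
class ScoringWeights:
    """Per-channel weights of the color-coded expression levels."""

    blue: float = 1.0
    green: float = 2.0
    red: float = 3.0

    def __post_init__(self) -> None:
        if min(self.blue, self.green, self.red) < 0:
            raise ValueError("weights must be nonnegative")


def weighted_color_score(image: ExpressionMaskImage, roi: RegionOfInterest,
                         weights: ScoringWeights | None = None) -> float:
    """w_b * mean(B) + w_g * mean(G) + w_r * mean(R) over the ROI pixels.

    Zero-expression (black) pixels inside the ROI count toward the
    channel means.
    """
    weights = weights or ScoringWeights()
    mask = roi.pixel_mask(image.pixels.shape[:2])
    px = image.pixels[mask].astype(float)
    r, g, b = px[:, 0].mean(), px[:, 1].mean(), px[:, 2].mean()
    return float(weights.red * r + weights.green * g + weights.blue * b)


@dataclass
class RegionalProfile:
    """Per gene, the mean weighted color score in each named region."""

    scores: pd.DataFrame        # genes x regions; NaN where region unscored
    n_slices: pd.DataFrame      # genes x regions slice counts
    unavailable: list[str] = field(default_factory=list)

    def available(self, gene: str) -> bool:
        return gene in self.scores.index and gene not in self.unavailable


def regional_profile(gene_images: dict[str, list[tuple[ExpressionMaskImage,
                                                       dict[str, RegionOfInterest]]]],
                     weights: ScoringWeights | None = None,
                     all_genes: list[str] | None = None) -> RegionalProfile:
    """Score every gene's slices and average per region.

    ``gene_images`` maps gene -> list of (image, region ROIs); a gene's
    regional score is the mean of its per-slice scores over the slices
    containing that region.  Genes listed in ``all_genes`` but absent
    from the imagery are flagged unavailable (atlases do not cover
    every transcript).
    """
    weights = weights or ScoringWeights()
    rows: dict[str, dict[str, list[float]]] = {}
    for gene, slices in gene_images.items():
        per_region: dict[str, list[float]] = {}
        for image, rois in slices:
            for region, roi in rois.items():
                per_region.setdefault(region, []).append(
                    weighted_color_score(image, roi, weights))
        rows[gene] = per_region
    regions = sorted({r for pr in rows.values() for r in pr})
    genes = list(rows)
    scores = pd.DataFrame(np.nan, index=genes, columns=regions)
    counts = pd.DataFrame(0, index=genes, columns=regions)
    for gene, per_region in rows.items():
        for region, vals in per_region.items():
            scores.loc[gene, region] = float(np.mean(vals))
            counts.loc[gene, region] = len(vals)
    unavailable = []
    if all_genes is not None:
        unavailable = [g for g in all_genes if g not in rows]
        scores = scores.reindex(list(genes) + unavailable)
        counts = counts.reindex(list(genes) + unavailable, fill_value=0)
    return RegionalProfile(scores, counts, unavailable)


@dataclass
class EnrichmentFlag:
    gene: str
    flagged: bool
    status: str               # "scored" or "unscored"
    ratio: float = np.nan     # best adjacent score / target score
    region: str = ""          # adjacent region that drove the flag


def enrichment_flag(profile: RegionalProfile, gene: str, target_region: str,
                    adjacent_regions: list[str], margin: float = 1.0) -> EnrichmentFlag:
    """Flag a gene whose expression is enriched next to the target region.

    Flagged iff max over adjacent regions of score(adjacent) is
    strictly greater than margin * score(target).  Genes without
    imagery get status "unscored" and no flag.
    """
    if not profile.available(gene):
        return EnrichmentFlag(gene, False, "unscored")
    row = profile.scores.loc[gene]
    target = row.get(target_region, np.nan)
    adj = row.reindex(adjacent_regions).dropna()
    if not np.isfinite(target) or adj.empty:
        return EnrichmentFlag(gene, False, "unscored")
    best_region = adj.idxmax()
    best = float(adj.max())
    ratio = best / target if target > 0 else np.inf
    flagged = best > margin * target
    return EnrichmentFlag(gene, bool(flagged), "scored", float(ratio), str(best_region))


def select_representatives(cluster_genes: list[str], profiles: pd.DataFrame,
                           k: int = 4) -> list[str]:
    """The k most central genes of a cluster (medoid-like).

    Centrality is the mean absolute centered correlation of a gene's
    fold-change profile with every other cluster member; ties break
    alphabetically by gene symbol.  Clusters smaller than k return all
    members.
    """
    genes = [g for g in cluster_genes if g in profiles.index]
    if len(genes) == 0:
        raise ValueError("cluster has no genes with fold-change profiles")
    if len(genes) <= k:
        return sorted(genes)
    arr = profiles.loc[genes].to_numpy(dtype=float)
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.abs(centered @ centered.T) / np.outer(norms, norms)
    np.fill_diagonal(corr, np.nan)
    centrality = np.nanmean(corr, axis=1)
    order = sorted(range(len(genes)), key=lambda i: (-centrality[i], str(genes[i])))
    return [genes[i] for i in order[:k]]


@dataclass
class ClusterScreenResult:
    cluster: int
    status: str                               # "clean", "suspect", "insufficient imagery"
    representative_flags: list[EnrichmentFlag]
    gene_flags: dict[str, EnrichmentFlag] = field(default_factory=dict)

    @property
    def suspect(self) -> bool:
        return self.status == "suspect"


def screen_cluster(cluster: int, cluster_genes: list[str], profile: RegionalProfile,
                   foldchanges: pd.DataFrame, target_region: str,
                   adjacent_regions: list[str], k: int = 4, trigger: int = 3,
                   margin: float = 1.0) -> ClusterScreenResult:
    """Cluster-level contamination call from representative imagery.

    If at least ``trigger`` of the k representative genes are flagged
    as adjacent-tissue enriched, every cluster member is screened
    individually and the cluster is marked suspect.  Fewer than
    ``trigger`` scorable representatives yields "insufficient imagery".
    """
    reps = select_representatives(cluster_genes, foldchanges, k=k)
    rep_flags = [enrichment_flag(profile, g, target_region, adjacent_regions, margin)
                 for g in reps]
    scored = [f for f in rep_flags if f.status == "scored"]
    if len(scored) < trigger:
        return ClusterScreenResult(cluster, "insufficient imagery", rep_flags)
    n_flagged = sum(f.flagged for f in scored)
    if n_flagged >= trigger:
        gene_flags = {g: enrichment_flag(profile, g, target_region, adjacent_regions, margin)
                      for g in cluster_genes}
        return ClusterScreenResult(cluster, "suspect", rep_flags, gene_flags)
    return ClusterScreenResult(cluster, "clean", rep_flags)
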