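"""Synthetic data with known ground truth for every pipeline input.

The generator emulates a two-color array study of social stress: four
stress regimes (acute, 8 days, 13 days, 13 days + 5 days recovery),
three pooled biological replicates per regime, each hybridized twice
(original + dye swap) against a sibling control pool — 24 array
comparisons in all.  Genes carry planted cluster structure: each
stress cluster has a mean log2 fold-change profile over the regimes,
marker genes instead load on a per-sample tissue-contamination
fraction (choroid plexus carried over during dissection), and the
rest are null background.

Contamination enters additively on the log2 scale as
loading x (fraction - mean fraction).  On arrays the fractions have
group-level mean structure (pools dissected in batches share
contamination luck), which makes marker genes differentially
expressed in some regimes; the per-animal contamination used for the
validation branch is drawn independently of group and of the stress
physiology, so marker expression stays uncorrelated with the
organ-weight stress indices.

Default cluster/marker profile directions are four near-equiangular
lines in the centered regime space (pairwise |cos| = 1/sqrt(5)), so
the similarity threshold r = 0.55 of the clustering stage separates
the planted clusters under absolute centered correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hippostress.atlas import ExpressionMaskImage, RegionOfInterest
from hippostress.contamination import StressIndexTable
from hippostress.diffexpr import FoldChangeMatrix
from hippostress.qpcr import QpcrPlate

__all__ = [
    "DEFAULT_GROUPS",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_foldchange_dataset",
    "simulate_animal_expression",
    "simulate_organ_weights",
    "simulate_ish_image",
    "simulate_gene_images",
    "default_brain_layout",
    "simulate_qpcr_plate",
]

DEFAULT_GROUPS = ("acute", "stress_8d", "stress_13d", "recovery")

# Marker symbols used when naming simulated contamination genes
_PLEXUS_SYMBOLS = ["Ttr", "Igf2", "Igfbp2", "Prlr", "Enpp2", "Sostdc1",
                   "1500015O10Rik", "Kl", "Clic6", "Kcne2", "F5", "Slc4a5", "Aqp1"]


def _equiangular_directions() -> np.ndarray:
    """Four unit vectors in the centered 4-group space with pairwise
    |cos| = 1/sqrt(5) (an icosahedral line frame mapped through an
    orthonormal basis of the zero-sum subspace)."""
    e1 = np.array([1.0, -1.0, 1.0, -1.0]) / 2.0
    e2 = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
    e3 = np.array([1.0, -1.0, -1.0, 1.0]) / 2.0
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    frame3 = np.array([[0.0, 1.0, phi],
                       [0.0, -1.0, phi],
                       [1.0, phi, 0.0],
                       [-1.0, phi, 0.0]])
    basis = np.vstack([e1, e2, e3])
    dirs = frame3 @ basis
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def _default_profiles(groups: tuple[str, ...], amplitude: float = 1.3) -> pd.DataFrame:
    if len(groups) != 4:
        raise ValueError("default cluster profiles are defined for 4 groups; "
                         "supply cluster_profiles explicitly for other designs")
    dirs = _equiangular_directions()
    return pd.DataFrame(amplitude * dirs[:3], index=[1, 2, 3], columns=list(groups))


def _default_contamination_law(groups: tuple[str, ...]) -> dict:
    if len(groups) == 4:
        marker_dir = _equiangular_directions()[3]
        means = np.clip(0.3 + 0.3 * marker_dir, 0.0, 1.0)
    else:
        means = np.full(len(groups), 0.3)
    return {
        "name": "group_normal",
        "group_means": {g: float(m) for g, m in zip(groups, means)},
        "sd": 0.03,        # per-pool jitter around the batch mean
        "animal_sd": 0.15,  # iid per-animal spread in the validation branch
        "animal_mean": 0.3,
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the 4 x 3 x 2 design."""

    n_genes: int = 500
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    n_replicates_per_group: int = 3
    dye_swap: bool = True
    cluster_profiles: pd.DataFrame | None = None   # cluster id x group mean log2FC
    gene_cluster_sizes: dict[int, int] | None = None
    noise_sd: float = 0.1                          # technical noise, log2 units
    contamination_fraction_law: dict | None = None
    marker_loading: float = 3.5                    # log2 shift per unit fraction
    marker_gene_count: int = 12
    stress_index_model: dict = field(default_factory=lambda: {
        "group_intensity": {"acute": 0.5, "stress_8d": 1.0,
                            "stress_13d": 1.5, "recovery": 0.3},
        "animal_sd": 0.3,
        "thymus_base": 0.22, "thymus_slope": -0.04,   # % body weight per unit score
        "spleen_base": 0.40, "spleen_slope": 0.06,
        "organ_noise_sd": 0.01,
        "expression_noise_sd": 0.3,
    })
    n_animals_per_group: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates_per_group < 1 or self.marker_gene_count < 0:
            raise ValueError("counts must be >= 1 (markers >= 0)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.group_labels) < 2:
            raise ValueError("need at least 2 groups")
        if self.cluster_profiles is None:
            self.cluster_profiles = _default_profiles(self.group_labels)
        unknown = set(self.cluster_profiles.columns) - set(self.group_labels)
        if unknown:
            raise ValueError(f"cluster_profiles reference unknown groups: {sorted(unknown)}")
        if set(self.cluster_profiles.columns) != set(self.group_labels):
            raise ValueError("cluster_profiles must cover every group")
        self.cluster_profiles = self.cluster_profiles[list(self.group_labels)]
        if self.gene_cluster_sizes is None:
            self.gene_cluster_sizes = {int(c): 30 for c in self.cluster_profiles.index}
        if any(n < 1 for n in self.gene_cluster_sizes.values()):
            raise ValueError("cluster sizes must be >= 1")
        unknown = set(self.gene_cluster_sizes) - set(int(c) for c in self.cluster_profiles.index)
        if unknown:
            raise ValueError(f"gene_cluster_sizes reference unknown clusters: {sorted(unknown)}")
        planted = sum(self.gene_cluster_sizes.values()) + self.marker_gene_count
        if planted > self.n_genes:
            raise ValueError("planted clusters + markers exceed n_genes")
        if self.contamination_fraction_law is None:
            self.contamination_fraction_law = _default_contamination_law(self.group_labels)

    @property
    def marker_cluster_id(self) -> int:
        return int(max(self.cluster_profiles.index, default=0)) + 1


@dataclass
class SyntheticTruth:
    """Ground truth: one record per simulated gene, sample and animal."""

    gene_cluster: pd.Series      # gene -> cluster id (0 = background)
    marker_loading: pd.Series    # gene -> log2 shift per unit fraction
    profiles: pd.DataFrame       # cluster id x group mean log2FC (markers all 0)
    sample_fraction: pd.Series   # biological sample "group.rep" -> fraction
    animals: pd.DataFrame        # animal, group, latent, fraction

    @property
    def is_marker(self) -> pd.Series:
        return self.marker_loading != 0

    @property
    def marker_genes(self) -> list[str]:
        return list(self.marker_loading.index[self.marker_loading != 0])

    @property
    def stress_genes(self) -> list[str]:
        stress = (self.gene_cluster > 0) & (self.marker_loading == 0)
        return list(self.gene_cluster.index[stress])


def _draw_fractions(law: dict, groups: list[str], n_rep: int,
                    rng: np.random.Generator) -> pd.Series:
    name = law.get("name", "group_normal")
    idx = [f"{g}.{r + 1}" for g in groups for r in range(n_rep)]
    if name == "group_normal":
        means = np.repeat([law["group_means"][g] for g in groups], n_rep)
        vals = means + rng.normal(0.0, law.get("sd", 0.03), size=len(idx))
    elif name == "uniform":
        vals = rng.uniform(law.get("low", 0.0), law.get("high", 1.0), size=len(idx))
    elif name == "beta":
        vals = rng.beta(law["a"], law["b"], size=len(idx))
    elif name == "constant":
        vals = np.full(len(idx), law.get("value", 0.0))
    else:
        raise ValueError(f"unknown contamination law: {name!r}")
    return pd.Series(np.clip(vals, 0.0, 1.0), index=idx)


def _gene_names(config: SimulationConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    names, clusters, loadings = [], [], []
    for cid in sorted(config.gene_cluster_sizes):
        for i in range(config.gene_cluster_sizes[cid]):
            names.append(f"Stg{cid}_{i + 1:03d}")
            clusters.append(cid)
            loadings.append(0.0)
    for i in range(config.marker_gene_count):
        sym = _PLEXUS_SYMBOLS[i] if i < len(_PLEXUS_SYMBOLS) else f"Plex{i + 1}"
        names.append(sym)
        clusters.append(config.marker_cluster_id)
        loadings.append(config.marker_loading)
    n_bkg = config.n_genes - len(names)
    for i in range(n_bkg):
        names.append(f"Bkg{i + 1:04d}")
        clusters.append(0)
        loadings.append(0.0)
    return names, np.array(clusters), np.array(loadings)


def simulate_foldchange_dataset(config: SimulationConfig) -> tuple[FoldChangeMatrix, SyntheticTruth]:
    """Generate the fold-change matrix and its ground truth.

    value(g, s) = profile(cluster(g), group(s))
                + loading(g) * (fraction(s) - mean fraction)
                + Normal(0, noise_sd^2),
    with the dye-swap copy of a sample sharing the biological value and
    differing only by fresh technical noise.  Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    groups = list(config.group_labels)
    n_rep = config.n_replicates_per_group
    names, clusters, loadings = _gene_names(config)

    fractions = _draw_fractions(config.contamination_fraction_law, groups, n_rep, rng)
    centered = fractions - fractions.mean()

    profile_lookup = config.cluster_profiles
    bio = np.zeros((len(names), len(fractions)))
    for gi, (cid, loading) in enumerate(zip(clusters, loadings)):
        for si, sample in enumerate(fractions.index):
            group = sample.rsplit(".", 1)[0]
            base = float(profile_lookup.loc[cid, group]) if cid in profile_lookup.index else 0.0
            bio[gi, si] = base + loading * centered.iloc[si]

    cols, meta_rows, data = [], [], []
    for si, sample in enumerate(fractions.index):
        group, rep = sample.rsplit(".", 1)
        orientations = ["a", "b"] if config.dye_swap else ["a"]
        for orient in orientations:
            noise = rng.normal(0.0, config.noise_sd, size=len(names)) if config.noise_sd > 0 \
                else np.zeros(len(names))
            data.append(bio[:, si] + noise)
            cols.append(f"{sample}.{orient}")
            meta_rows.append({"group": group, "replicate": rep, "swapped": orient == "b"})
    values = pd.DataFrame(np.column_stack(data), index=names, columns=cols)
    meta = pd.DataFrame(meta_rows, index=cols)
    matrix = FoldChangeMatrix(values, meta, gene_map=pd.Series(names, index=names))

    law = config.contamination_fraction_law
    sim = config.stress_index_model
    animal_rows = []
    for group in groups:
        intensity = sim["group_intensity"].get(group, 0.0)
        for j in range(config.n_animals_per_group):
            animal_rows.append({
                "animal": f"{group}_a{j + 1}",
                "group": group,
                "latent": intensity + rng.normal(0.0, sim["animal_sd"]),
                "fraction": float(np.clip(
                    law.get("animal_mean", 0.3) + rng.normal(0.0, law.get("animal_sd", 0.15)),
                    0.0, 1.0)),
            })
    animals = pd.DataFrame(animal_rows)

    full_profiles = profile_lookup.copy()
    if config.marker_gene_count > 0:
        full_profiles.loc[config.marker_cluster_id] = 0.0
    truth = SyntheticTruth(
        gene_cluster=pd.Series(clusters, index=names),
        marker_loading=pd.Series(loadings, index=names),
        profiles=full_profiles,
        sample_fraction=fractions,
        animals=animals,
    )
    return matrix, truth


def _gene_coupling(truth: SyntheticTruth, gene: str) -> float:
    """Signed per-unit-stress expression slope: the largest-magnitude
    entry of the gene's cluster profile (0 for markers/background)."""
    cid = int(truth.gene_cluster[gene])
    if cid == 0 or truth.marker_loading[gene] != 0:
        return 0.0
    row = truth.profiles.loc[cid].to_numpy(dtype=float)
    return float(row[np.argmax(np.abs(row))])


def simulate_animal_expression(truth: SyntheticTruth, config: SimulationConfig,
                               genes: list[str] | None = None) -> pd.DataFrame:
    """Per-animal log2 expression for the validation branch.

    Stress genes track the animal's latent stress score; marker genes
    track the animal's (group-independent) contamination fraction;
    background genes are pure noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = list(truth.gene_cluster.index) if genes is None else list(genes)
    sim = config.stress_index_model
    latent = truth.animals["latent"].to_numpy()
    frac = truth.animals["fraction"].to_numpy()
    frac_centered = frac - frac.mean()
    data = {}
    for gene in genes:
        signal = _gene_coupling(truth, gene) * latent \
            + truth.marker_loading[gene] * frac_centered
        data[gene] = signal + rng.normal(0.0, sim["expression_noise_sd"], size=len(latent))
    return pd.DataFrame(data, index=truth.animals["animal"].to_list())


def simulate_organ_weights(truth: SyntheticTruth, config: SimulationConfig) -> StressIndexTable:
    """Thymus and spleen weights (% body weight) from the latent scores.

    Thymus shrinks and spleen grows with the stress score; weights are
    clamped strictly positive.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sim = config.stress_index_model
    latent = truth.animals["latent"].to_numpy()
    noise = sim["organ_noise_sd"]
    thymus = sim["thymus_base"] + sim["thymus_slope"] * latent
    spleen = sim["spleen_base"] + sim["spleen_slope"] * latent
    if noise > 0:
        thymus = thymus + rng.normal(0.0, noise, size=len(latent))
        spleen = spleen + rng.normal(0.0, noise, size=len(latent))
    table = pd.DataFrame({
        "animal": truth.animals["animal"],
        "group": truth.animals["group"],
        "thymus_pct": np.maximum(thymus, 0.01),
        "spleen_pct": np.maximum(spleen, 0.01),
    })
    return StressIndexTable(table)


# ---------------------------------------------------------------------------
# ISH-like expression-mask images

_LEVEL_COLORS = {
    "none": (0, 0, 0),
    "low": (0, 0, 220),      # blue
    "medium": (0, 220, 0),   # green
    "high": (220, 0, 0),     # red
}


def simulate_ish_image(region_layout: dict[str, np.ndarray],
                       expression_levels: dict[str, str],
                       image_size: tuple[int, int] = (96, 96),
                       speckle: float = 0.0,
                       seed: int = 0,
                       gene: str = "") -> tuple[ExpressionMaskImage, dict[str, RegionOfInterest]]:
    """Render a color-coded expression mask with matching ROIs.

    Each region's polygon is painted blue/green/red for low/medium/high
    expression and left black for none; ``speckle`` is the probability
    that a pixel is replaced by a random color.  Overlapping polygons
    or polygons outside the image are rejected.
    """
    rng = np.random.default_rng(seed)
    pixels = np.zeros((*image_size, 3), dtype=np.uint8)
    rois: dict[str, RegionOfInterest] = {}
    occupied = np.zeros(image_size, dtype=bool)
    for region, poly in region_layout.items():
        roi = RegionOfInterest(region, polygon=np.asarray(poly, dtype=float))
        mask = roi.pixel_mask(image_size)  # raises if outside bounds
        if (mask & occupied).any():
            raise ValueError(f"region {region!r} overlaps another region")
        occupied |= mask
        level = expression_levels.get(region, "none")
        if level not in _LEVEL_COLORS:
            raise ValueError(f"unknown expression level {level!r}")
        pixels[mask] = _LEVEL_COLORS[level]
        rois[region] = RegionOfInterest(region, mask=mask)
    if speckle > 0:
        noise_mask = rng.random(image_size) < speckle
        pixels[noise_mask] = rng.integers(0, 256, size=(int(noise_mask.sum()), 3),
                                          dtype=np.uint8)
    return ExpressionMaskImage(pixels, gene=gene), rois


def default_brain_layout(image_size: tuple[int, int] = (96, 96)) -> dict[str, np.ndarray]:
    """Non-overlapping schematic polygons for the four scored regions."""
    h, w = image_size

    def rect(r0, c0, r1, c1):
        return np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], dtype=float)

    return {
        "hippocampus": rect(0.15 * h, 0.10 * w, 0.80 * h, 0.45 * w),
        "choroid_plexus": rect(0.15 * h, 0.55 * w, 0.80 * h, 0.65 * w),
        "habenula": rect(0.10 * h, 0.75 * w, 0.40 * h, 0.90 * w),
        "septal_nuclei": rect(0.55 * h, 0.75 * w, 0.85 * h, 0.90 * w),
    }


def gene_expression_levels(gene: str, truth: SyntheticTruth) -> dict[str, str]:
    """Planted regional pattern: markers are plexus-dominant with weak
    hippocampal signal, stress genes hippocampus-dominant, background
    uniform and unremarkable."""
    if truth.marker_loading[gene] != 0:
        return {"hippocampus": "low", "choroid_plexus": "high",
                "habenula": "none", "septal_nuclei": "none"}
    if truth.gene_cluster[gene] > 0:
        return {"hippocampus": "high", "choroid_plexus": "low",
                "habenula": "low", "septal_nuclei": "low"}
    return {"hippocampus": "medium", "choroid_plexus": "low",
            "habenula": "low", "septal_nuclei": "low"}


def simulate_gene_images(genes: list[str], truth: SyntheticTruth,
                         config: SimulationConfig,
                         image_size: tuple[int, int] = (96, 96),
                         speckle: float = 0.0,
                         ) -> dict[str, list[tuple[ExpressionMaskImage, dict[str, RegionOfInterest]]]]:
    """One schematic slice per gene, driven by the planted truth."""
    layout = default_brain_layout(image_size)
    out = {}
    base = np.random.SeedSequence([config.seed, 3]).generate_state(1)[0]
    for i, gene in enumerate(sorted(genes)):
        image, rois = simulate_ish_image(
            layout, gene_expression_levels(gene, truth), image_size=image_size,
            speckle=speckle, seed=int((base + i) % (2**31)), gene=gene)
        out[gene] = [(image, rois)]
    return out


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr_plate(true_ratios: dict[str, float], efficiencies: dict[str, float],
                        n_pairs: int = 9, replicate_sd: float = 0.15,
                        reference_gene: str = "Gapdh",
                        dilution_points: int = 5, dilution_factor: float = 5.0,
                        n_replicate_wells: int = 3, seed: int = 0) -> QpcrPlate:
    """Generate a plate whose Ct values satisfy the Pfaffl relation in
    expectation.

    Each target gene's stressed-sample Ct is shifted by
    -log(ratio)/log(E) relative to its sibling control; the reference
    gene has ratio 1 by construction.  Every gene gets a
    ``dilution_points``-long ``dilution_factor``-fold dilution series
    (for efficiency estimation) and a negative-control well.
    """
    for gene, ratio in true_ratios.items():
        if ratio <= 0:
            raise ValueError(f"{gene}: true ratio must be positive")
    for gene, e in efficiencies.items():
        if not (1.0 < e <= 2.5):
            raise ValueError(f"{gene}: efficiency {e} outside (1, 2.5]")
    if reference_gene not in efficiencies:
        raise ValueError("reference gene needs an efficiency")
    rng = np.random.default_rng(seed)
    genes = dict(true_ratios)
    genes.setdefault(reference_gene, 1.0)
    rows = []

    def noise() -> float:
        return float(rng.normal(0.0, replicate_sd)) if replicate_sd > 0 else 0.0

    for gi, (gene, ratio) in enumerate(genes.items()):
        e = efficiencies[gene]
        base_ct = 20.0 + 2.0 * gi
        shift = np.log(ratio) / np.log(e)
        for p in range(1, n_pairs + 1):
            for arm, ct0 in (("control", base_ct), ("stress", base_ct - shift)):
                for rep in range(1, n_replicate_wells + 1):
                    rows.append({"sample": f"pair{p}_{arm}", "gene": gene,
                                 "ct": ct0 + noise(), "replicate": rep,
                                 "role": "unknown", "dilution": np.nan,
                                 "pair_id": f"pair{p}", "arm": arm})
        for j in range(dilution_points):
            conc = dilution_factor**(-j)
            ct = base_ct - np.log10(conc) / np.log10(e)
            rows.append({"sample": f"{gene}_std{j + 1}", "gene": gene,
                         "ct": ct + noise(), "replicate": 1, "role": "standard",
                         "dilution": conc, "pair_id": "", "arm": ""})
        rows.append({"sample": f"{gene}_ntc", "gene": gene, "ct": np.nan,
                     "replicate": 1, "role": "negative", "dilution": np.nan,
                     "pair_id": "", "arm": ""})
    return QpcrPlate(pd.DataFrame(rows))
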