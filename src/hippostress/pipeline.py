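"""End-to-end orchestration: simulate/load -> differential expression ->
time-course -> clustering -> atlas screen -> contamination report.

All run-level thresholds live in :class:`PipelineConfig` (single source
of truth) and are passed explicitly to each stage; the resolved config
is written into the report metadata so every verdict is reproducible
from the recorded evidence.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from hippostress import atlas as atlas_mod
from hippostress import cluster as cluster_mod
from hippostress import contamination as contam_mod
from hippostress import diffexpr, io, simulate
from hippostress.simulate import SimulationConfig

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_pipeline",
           "validate_inputs"]

ADJACENT_REGIONS = ["choroid_plexus", "habenula", "septal_nuclei"]


@dataclass
class PipelineConfig:
    """Run-level thresholds and stage toggles."""

    lfc_threshold: float = 0.5
    fdr_alpha: float = 0.05
    r_main: float = 0.55
    r_sub: float = 0.75
    color_weights: tuple[float, float, float] = (1.0, 2.0, 3.0)  # blue, green, red
    enrichment_margin: float = 1.0
    representatives_k: int = 4
    suspect_trigger: int = 3
    screen_alpha: float = 0.05
    moderation: bool = True
    target_region: str = "hippocampus"
    adjacent_regions: tuple[str, ...] = tuple(ADJACENT_REGIONS)
    cluster_on_technical_replicates: bool = True
    seed: int = 0
    simulation: SimulationConfig | None = None
    image_speckle: float = 0.0
    timecourse_pairs: tuple[tuple[str, str], ...] | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("lfc_threshold", "fdr_alpha", "r_main", "r_sub",
                     "enrichment_margin", "screen_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    def to_metadata(self) -> dict:
        meta = {k: v for k, v in asdict(self).items() if k != "simulation"}
        meta["color_weights"] = list(self.color_weights)
        meta["adjacent_regions"] = list(self.adjacent_regions)
        meta["timecourse_pairs"] = [list(p) for p in (self.timecourse_pairs or [])]
        meta["simulation_seed"] = self.simulation.seed
        meta["n_genes"] = self.simulation.n_genes
        return meta


@dataclass
class RunManifest:
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, str]) -> None:
        self.stages[stage] = {"outputs": outputs, "timestamp": time.time()}

    @staticmethod
    def checksum(payload: bytes | str) -> str:
        if isinstance(payload, str):
            payload = payload.encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class PipelineResult:
    matrix: diffexpr.FoldChangeMatrix
    truth: simulate.SyntheticTruth
    de_results: pd.DataFrame
    timecourse_results: pd.DataFrame
    assignment: cluster_mod.ClusterAssignment
    dendrogram: cluster_mod.Dendrogram
    atlas_screens: dict[int, atlas_mod.ClusterScreenResult]
    stress_screen: pd.DataFrame
    overlaps: pd.DataFrame
    report: contam_mod.ContaminationReport
    manifest: RunManifest


def _default_timecourse_pairs(groups: list[str]) -> list[tuple[str, str]]:
    # earlier period first; the recovery group is not a stress period
    periods = [g for g in groups if g != "recovery"]
    return [(periods[i], periods[j])
            for i in range(len(periods)) for j in range(i + 1, len(periods))]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on a synthetic dataset with known ground truth.

    Deterministic given ``config.seed``: the same seed yields a byte-
    identical report.
    """
    manifest = RunManifest()
    simcfg = config.simulation

    # 1. simulate
    matrix, truth = simulate.simulate_foldchange_dataset(simcfg)
    manifest.record("simulate", {"foldchange": RunManifest.checksum(
        matrix.values.to_csv())})

    # 2. differential expression on dye-swap-averaged replicates
    averaged = diffexpr.average_dye_swaps(matrix)
    de_frames = [
        diffexpr.paired_de_test(averaged, group, moderation=config.moderation,
                                lfc_threshold=config.lfc_threshold,
                                fdr_alpha=config.fdr_alpha)
        for group in averaged.groups
    ]
    de_results = pd.concat(de_frames)
    manifest.record("de", {"table": RunManifest.checksum(de_results.to_csv())})

    # 3. time-course contrasts between stress periods
    pairs = list(config.timecourse_pairs) if config.timecourse_pairs else \
        _default_timecourse_pairs(averaged.groups)
    tc_frames = [
        diffexpr.timecourse_contrast(averaged, a, b, moderation=config.moderation,
                                     lfc_threshold=config.lfc_threshold,
                                     fdr_alpha=config.fdr_alpha)
        for a, b in pairs
    ]
    timecourse_results = pd.concat(tc_frames) if tc_frames else pd.DataFrame()
    manifest.record("timecourse", {"table": RunManifest.checksum(
        timecourse_results.to_csv() if len(timecourse_results) else "")})

    # 4. cluster the significant genes (default: on the per-technical-replicate
    #    matrix, which doubles the profile length the correlation sees)
    significant = sorted(de_results.index[de_results["significant"]].unique())
    if len(significant) < 2:
        raise RuntimeError("stage 'cluster' failed: fewer than 2 significant genes")
    cluster_input = matrix if config.cluster_on_technical_replicates else averaged
    profiles = cluster_input.values.loc[significant]
    sim = cluster_mod.similarity_matrix(profiles)
    dend = cluster_mod.upgma(sim)
    assignment = cluster_mod.cut_clusters(dend, r_main=config.r_main, r_sub=config.r_sub)
    manifest.record("cluster", {"assignment": RunManifest.checksum(
        assignment.assignment.to_csv())})

    # 5. atlas screen per cluster
    blue, green, red = config.color_weights
    weights = atlas_mod.ScoringWeights(blue=blue, green=green, red=red)
    atlas_screens: dict[int, atlas_mod.ClusterScreenResult] = {}
    for cid in assignment.cluster_ids:
        members = assignment.members(cid)
        reps = atlas_mod.select_representatives(members, profiles,
                                                k=config.representatives_k)
        # image whatever the screen may touch: representatives now, the
        # full membership if the cluster turns suspect
        gene_images = simulate.simulate_gene_images(members, truth, simcfg,
                                                    speckle=config.image_speckle)
        prof = atlas_mod.regional_profile(gene_images, weights, all_genes=members)
        atlas_screens[cid] = atlas_mod.screen_cluster(
            cid, members, prof, profiles, config.target_region,
            list(config.adjacent_regions), k=config.representatives_k,
            trigger=config.suspect_trigger, margin=config.enrichment_margin)
    suspect_status = {int(cid): res.status for cid, res in atlas_screens.items()}
    manifest.record("atlas", {"status": RunManifest.checksum(
        json.dumps(suspect_status, sort_keys=True))})

    # 6. stress-index screen on per-animal expression
    expression = simulate.simulate_animal_expression(truth, simcfg, genes=significant)
    indices = simulate.simulate_organ_weights(truth, simcfg)
    stress_screen = contam_mod.stress_index_screen(expression, indices,
                                                   alpha=config.screen_alpha)
    manifest.record("stress_screen", {"table": RunManifest.checksum(
        stress_screen.to_csv())})

    # 7. marker-panel overlap per cluster (best panel by enrichment p)
    panels = contam_mod.default_panels()
    overlap_rows = {}
    for cid in assignment.cluster_ids:
        members = assignment.members(cid)
        best = None
        for name, panel in panels.items():
            count, p = contam_mod.marker_overlap(members, panel, simcfg.n_genes)
            if best is None or (p, name) < (best["overlap_p"], best["panel"]):
                best = {"panel": name, "overlap_count": count, "overlap_p": p}
        overlap_rows[cid] = best
    overlaps = pd.DataFrame.from_dict(overlap_rows, orient="index")

    # 8. report
    report = contam_mod.build_report(
        assignment.assignment, suspect_status, overlaps, stress_screen,
        de_results.groupby(level=0)["significant"].any().loc[significant],
        panels, config=config.to_metadata())
    manifest.record("report", {"json": RunManifest.checksum(report.to_json())})

    result = PipelineResult(matrix, truth, de_results, timecourse_results,
                            assignment, dend, atlas_screens, stress_screen,
                            overlaps, report, manifest)
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_foldchange_tsv(result.matrix, out_dir / "foldchanges.tsv")
    result.de_results.to_csv(out_dir / "de_results.tsv", sep="\t")
    if len(result.timecourse_results):
        result.timecourse_results.to_csv(out_dir / "timecourse_results.tsv", sep="\t")
    result.assignment.assignment.to_csv(out_dir / "clusters.tsv", sep="\t")
    (out_dir / "dendrogram.nwk").write_text(result.dendrogram.to_newick() + "\n")
    result.stress_screen.to_csv(out_dir / "stress_screen.tsv", sep="\t")
    (out_dir / "report.json").write_text(result.report.to_json() + "\n")
    manifest = {stage: rec for stage, rec in result.manifest.stages.items()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# input validation


@dataclass
class Diagnostic:
    file: str
    message: str
    line: int | None = None

    def __str__(self) -> str:
        loc = f"{self.file}:{self.line}" if self.line is not None else self.file
        return f"{loc}: {self.message}"


def validate_inputs(paths: dict[str, str | Path]) -> list[Diagnostic]:
    """Schema checks for the pipeline's input files.

    Keys of ``paths``: any of 'foldchange' (TSV), 'qpcr' (CSV),
    'stress_index' (TSV).  Returns diagnostics, not exceptions.
    """
    diags: list[Diagnostic] = []
    fc_path = paths.get("foldchange")
    if fc_path is not None:
        try:
            df = pd.read_csv(fc_path, sep="\t")
            for col in ("probe", "gene"):
                if col not in df.columns:
                    diags.append(Diagnostic(str(fc_path), f"missing required column {col!r}"))
            for c in df.columns:
                if c in ("probe", "gene"):
                    continue
                try:
                    io.parse_column_id(c)
                except ValueError as err:
                    diags.append(Diagnostic(str(fc_path), str(err)))
                if not pd.api.types.is_numeric_dtype(df[c]):
                    diags.append(Diagnostic(str(fc_path), f"column {c!r} is not numeric"))
        except Exception as err:  # unreadable file is itself a diagnostic
            diags.append(Diagnostic(str(fc_path), f"unreadable: {err}"))
    qpcr_path = paths.get("qpcr")
    if qpcr_path is not None:
        try:
            df = pd.read_csv(qpcr_path)
            from hippostress.qpcr import WELL_COLUMNS
            for col in WELL_COLUMNS:
                if col not in df.columns:
                    diags.append(Diagnostic(str(qpcr_path), f"missing required column {col!r}"))
            if {"pair_id", "sample", "role"} <= set(df.columns):
                unknowns = df[df["role"] == "unknown"]
                samples = set(unknowns["sample"])
                for i, row in unknowns.iterrows():
                    pid = row["pair_id"]
                    if not isinstance(pid, str) or not pid:
                        diags.append(Diagnostic(str(qpcr_path),
                                                "unknown well lacks a pair id", line=i + 2))
                    elif not any(s.startswith(str(pid)) for s in samples):
                        diags.append(Diagnostic(str(qpcr_path),
                                                f"pair id {pid!r} references no sample",
                                                line=i + 2))
        except Exception as err:
            diags.append(Diagnostic(str(qpcr_path), f"unreadable: {err}"))
    si_path = paths.get("stress_index")
    if si_path is not None:
        try:
            df = pd.read_csv(si_path, sep="\t")
            for col in ("animal", "group", "thymus_pct", "spleen_pct"):
                if col not in df.columns:
                    diags.append(Diagnostic(str(si_path), f"missing required column {col!r}"))
            for col in ("thymus_pct", "spleen_pct"):
                if col in df.columns:
                    bad = df.index[df[col] <= 0]
                    for i in bad:
                        diags.append(Diagnostic(str(si_path),
                                                f"nonpositive {col}", line=int(i) + 2))
        except Exception as err:
            diags.append(Diagnostic(str(si_path), f"unreadable: {err}"))
    return diags
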