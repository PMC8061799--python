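"""End-to-end orchestration: run stages in dependency order from one config,
with per-stage seeds derived from a master seed and a manifest of artifacts.

Every output TSV starts with a comment header carrying the package version,
the stage seed, and a hash of the configuration, so reruns with identical
config and seeds are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    GeneAnnotation,
    GenotypeMatrix,
    LinePanel,
    apply_gene_filters,
    apply_inbred_site_filters,
    read_depth_matrix,
    read_panel,
)
from .drive_qtl import lod_scan, read_f2_panel, write_f2_panel
from .drive_sim import SimConfig, run_simulation_grid
from .genome_scans import block_permutation_test, classify_coverage_ratio, standardize_depth
from .popgen import diversity_table, gene_pair_ld, region_summary
from .sweep_dating import count_derived_variants, thomson_age
from .synthetic import (
    CrossSimConfig,
    PanelSimConfig,
    simulate_f2_cross,
    simulate_inbred_panel,
    write_depth_tsv,
    write_panel_vcf,
)

STAGE_ORDER = ["simdata", "stats", "ld", "date_sweep", "simulate", "scan_blocks", "cnv", "qtl"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Structured run configuration; unset inputs default to synthetic data."""

    out_dir: str = "run"
    seed: int = 0
    # input paths (generated by the simdata stage when absent)
    vcf: str | None = None
    annotation: str | None = None
    lines: str | None = None
    depth: str | None = None
    f2_probs: str | None = None
    f2_counts: str | None = None
    f2_map: str | None = None
    # filter thresholds
    min_depth: int = 3
    min_lines: int = 10
    min_sites: int = 150
    # dating grids
    mu_grid: list = field(default_factory=lambda: [0.2e-8, 1.5e-8])
    kb_per_cM_grid: list = field(default_factory=lambda: [150.0, 1000.0])
    # simulation settings
    sim_mu: list = field(default_factory=lambda: [1.0e-8])
    sim_n_max: list = field(default_factory=lambda: [50_000])
    sim_reps: int = 5
    # scans
    block_size: int = 8
    n_perm: int = 500
    # synthetic-data settings
    panel_sim: dict = field(default_factory=dict)
    cross_sim: dict = field(default_factory=dict)
    # per-gene LD cost control
    ld_max_sites_per_gene: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    _PATH_FIELDS = (
        "out_dir", "vcf", "annotation", "lines", "depth",
        "f2_probs", "f2_counts", "f2_map",
    )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded, so runs in
        different directories with the same settings hash identically)."""
        data = {
            k: v for k, v in asdict(self).items() if k not in self._PATH_FIELDS
        }
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# centrodrive={__version__} stage={stage} seed={seed} "
            f"config_hash={cfg.config_hash()}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def _require(path: str | None, what: str, stage: str) -> str:
    if path is None or not Path(path).exists():
        raise PipelineError(f"stage {stage!r} requires missing input: {what} ({path})")
    return path


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the selected stages in dependency order; returns the run dir.

    The manifest (manifest.json) is append-only across invocations against
    the same run directory; no stage rewrites another stage's outputs.
    """
    requested = stages or STAGE_ORDER
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGE_ORDER if s in requested]
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else []
    )

    def record(stage: str, *paths: Path) -> None:
        for p in paths:
            manifest.append({"stage": stage, "path": str(p)})

    state: dict[str, object] = {}

    def load_panel_inputs(stage: str):
        if "matrix" in state:
            return
        ann = GeneAnnotation.from_tsv(_require(cfg.annotation, "annotation", stage))
        vcf = _require(cfg.vcf, "genotype VCF", stage)
        g = read_panel(vcf, ann, min_depth=cfg.min_depth)
        g = apply_inbred_site_filters(g, min_lines=cfg.min_lines)
        g, _ = apply_gene_filters(g, ann, min_sites=cfg.min_sites)
        state["matrix"] = g
        state["annotation"] = ann
        state["panel"] = LinePanel.from_tsv(_require(cfg.lines, "line classes", stage))

    for stage in ordered:
        seed = stage_seed(cfg.seed, stage)
        if stage == "simdata":
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            pcfg = PanelSimConfig(**{**cfg.panel_sim, "seed": seed})
            g, ann, depth, panel, _ = simulate_inbred_panel(pcfg)
            write_panel_vcf(g, inputs / "panel.vcf")
            ann.to_tsv(inputs / "annotation.tsv")
            write_depth_tsv(depth, inputs / "depth.tsv")
            panel.to_tsv(inputs / "lines.tsv")
            ccfg = CrossSimConfig(**{**cfg.cross_sim, "seed": seed + 1})
            f2, _ = simulate_f2_cross(ccfg)
            write_f2_panel(
                f2, inputs / "f2_probs.tsv", inputs / "f2_counts.tsv",
                inputs / "f2_map.tsv",
            )
            cfg.vcf = str(inputs / "panel.vcf")
            cfg.annotation = str(inputs / "annotation.tsv")
            cfg.depth = str(inputs / "depth.tsv")
            cfg.lines = str(inputs / "lines.tsv")
            cfg.f2_probs = str(inputs / "f2_probs.tsv")
            cfg.f2_counts = str(inputs / "f2_counts.tsv")
            cfg.f2_map = str(inputs / "f2_map.tsv")
            record(stage, *sorted(inputs.iterdir()))
        elif stage == "stats":
            load_panel_inputs(stage)
            g = state["matrix"]
            panel = state["panel"]
            classes = {
                c: [l for l in panel.lines_of_class(c) if l in g.line_ids]
                for c in ("D", "D_MINUS")
            }
            classes = {c: lines for c, lines in classes.items() if lines}
            table = diversity_table(g, state["annotation"], classes)
            summary = region_summary(table, seed=seed)
            p1, p2 = out / "gene_diversity.tsv", out / "region_summary.tsv"
            _write_tsv(table, p1, cfg, stage, seed)
            _write_tsv(summary, p2, cfg, stage, seed)
            state["diversity"] = table
            record(stage, p1, p2)
        elif stage == "ld":
            load_panel_inputs(stage)
            g = state["matrix"]
            g_ld = _downsample_sites(g, cfg.ld_max_sites_per_gene)
            pairs = gene_pair_ld(g_ld)
            df = pd.DataFrame(
                [(p.gene_a, p.gene_b, p.mean_r2, p.n_pairs) for p in pairs],
                columns=["gene_a", "gene_b", "mean_r2", "n_pairs"],
            )
            p1 = out / "gene_pair_ld.tsv"
            _write_tsv(df, p1, cfg, stage, seed)
            record(stage, p1)
        elif stage == "date_sweep":
            load_panel_inputs(stage)
            g = state["matrix"]
            panel = state["panel"]
            d_lines = [l for l in panel.lines_of_class("D") if l in g.line_ids]
            if not d_lines:
                raise PipelineError("date_sweep requires D-class lines")
            table = count_derived_variants(g.subset_lines(d_lines), state["annotation"])
            ests = thomson_age(table, n=len(d_lines), mu=np.asarray(cfg.mu_grid), L=table.L)
            df = pd.DataFrame(
                [(e.mu, e.sum_x, e.n, e.L, e.t_hat) for e in ests],
                columns=["mu", "sum_x", "n", "L", "t_generations"],
            )
            p1 = out / "thomson_ages.tsv"
            _write_tsv(df, p1, cfg, stage, seed)
            record(stage, p1)
        elif stage == "simulate":
            grid = run_simulation_grid(
                cfg.sim_mu, cfg.sim_n_max, reps=cfg.sim_reps, seed=seed,
                base_config=SimConfig(max_gen=5000),
            )
            p1 = out / "simulation_grid.tsv"
            _write_tsv(grid, p1, cfg, stage, seed)
            record(stage, p1)
        elif stage == "scan_blocks":
            if "diversity" not in state:
                raise PipelineError(
                    "stage 'scan_blocks' requires missing input: per-gene "
                    "diversity (run the 'stats' stage first)"
                )
            table = state["diversity"]
            ann = state["annotation"].genes
            rows = []
            for cls, sub in table.groupby("line_class"):
                sub = sub.merge(ann[["gene_id", "map_order"]], on="gene_id")
                sub = sub.sort_values("map_order").reset_index(drop=True)
                focal_start = int(sub["pi"].rolling(cfg.block_size).mean().idxmin()) - cfg.block_size + 1
                focal = np.arange(focal_start, focal_start + cfg.block_size)
                res = block_permutation_test(
                    sub["pi"].to_numpy(), focal, block_size=cfg.block_size,
                    n_perm=cfg.n_perm, side="LOWER", seed=seed,
                )
                rows.append(
                    dict(
                        line_class=cls,
                        focal_first_gene=sub["gene_id"].iloc[focal[0]],
                        observed_mean_pi=res.observed_mean, p_value=res.p_value,
                    )
                )
            p1 = out / "block_scan.tsv"
            _write_tsv(pd.DataFrame(rows), p1, cfg, stage, seed)
            record(stage, p1)
        elif stage == "cnv":
            ann = state.get("annotation")
            if ann is None:
                ann = GeneAnnotation.from_tsv(_require(cfg.annotation, "annotation", stage))
            depth = read_depth_matrix(_require(cfg.depth, "depth matrix", stage), ann)
            panel = state.get("panel") or LinePanel.from_tsv(
                _require(cfg.lines, "line classes", stage)
            )
            std = standardize_depth(depth)
            recs = classify_coverage_ratio(std, panel)
            df = pd.DataFrame(
                [
                    (r.gene_id, r.mean_std_depth_d, r.mean_std_depth_dminus,
                     np.nan if r.ratio is None else r.ratio, r.category)
                    for r in recs
                ],
                columns=["gene_id", "mean_std_d", "mean_std_dminus", "ratio", "category"],
            )
            p1 = out / "cnv_classification.tsv"
            _write_tsv(df, p1, cfg, stage, seed)
            record(stage, p1)
        elif stage == "qtl":
            f2 = read_f2_panel(
                _require(cfg.f2_probs, "F2 genotype probabilities", stage),
                _require(cfg.f2_counts, "F3 genotype counts", stage),
                _require(cfg.f2_map, "marker map", stage),
            )
            profile = lod_scan(f2)
            df = profile.markers.copy()
            df["lod"] = profile.lod
            df["smoothed"] = profile.smoothed
            p1 = out / "lod_profile.tsv"
            _write_tsv(df, p1, cfg, stage, seed)
            record(stage, p1)
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return out


def _downsample_sites(g: GenotypeMatrix, max_sites_per_gene: int) -> GenotypeMatrix:
    """Keep at most the first k polymorphic sites per gene (LD cost control)."""
    from .popgen import site_allele_counts

    ref, alt = site_allele_counts(g.calls)
    poly = (ref > 0) & (alt > 0)
    keep = np.zeros(g.n_sites, dtype=bool)
    for gid in pd.unique(g.sites["gene_id"]):
        cols = np.flatnonzero((g.sites["gene_id"] == gid).to_numpy() & poly)
        keep[cols[:max_sites_per_gene]] = True
    return g.subset_sites(keep)
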