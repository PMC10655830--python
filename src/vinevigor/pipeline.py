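"""End-to-end orchestration: simulate -> measure -> heritability -> QTL.

One run mirrors a two-season field campaign on a biparental progeny: a
summer canopy trait measured from LiDAR-like scenes (apparent canopy volume)
and from rendered row images (exposed leaf area), and a winter wood trait
measured from before/after-pruning scene pairs.  The measured phenotypes are
filtered to plots with at least 2 productive plants, summarised into
heritabilities (ANOVA and control-based estimators) and scanned for QTLs
with a permutation-calibrated stepwise model.

All randomness flows from one root seed via named substreams, so a rerun
with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, pointcloud, quantgen, qtl, synthetic_data
from .synthetic_data import (CANOPY_BASE, CONTROL_GENOTYPE, PLANTS_PER_PLOT,
                             SimConfig, default_study_config)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=default_study_config)
    wood_sim: SimConfig | None = None   # derived from `sim` when None
    measure: str = "lidar"              # "lidar" (scenes) or "direct" (truth)
    side_combine: str = "union"
    canopy_voxel_s: float = 0.010
    wood_voxel_s: float = 0.005
    points_per_liter: float = 80.0
    illumination_noise: float = 0.0
    min_productive_plants: int = 2
    n_permutations: int = 1000
    alpha: float = 0.05
    run_qtl: bool = True
    run_ela: bool = True

    def resolved_wood_sim(self) -> SimConfig:
        if self.wood_sim is not None:
            return self.wood_sim
        base = self.sim
        return dataclasses.replace(
            base, trait_name="wood_volume", trait_mean=3.6,
            sigma_g2=0.6, sigma_e2=0.45, block_effect_sd=0.05,
            seed=base.seed)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def add(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


@contextmanager
def _stage(name: str, input_path=None):
    """Abort with the failing stage's name (and input, when known)."""
    try:
        yield
    except Exception as exc:
        where = f" (input: {input_path})" if input_path else ""
        raise RuntimeError(f"pipeline stage {name!r} failed{where}: {exc}") \
            from exc


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plot_seed(root: int, stage: int, index: int) -> int:
    return int(np.random.SeedSequence((root, stage, index)).generate_state(1)[0]
               % (2**31))


def measure_canopy_plot(targets, geometry, seed, config: PipelineConfig
                        ) -> np.ndarray:
    """Scene-based apparent canopy volumes (L) for the plants of one plot."""
    cloud = synthetic_data.simulate_canopy_point_cloud(
        targets, geometry, seed, points_per_liter=config.points_per_liter)
    clean = pointcloud.filter_scene(cloud, sensor_heights=geometry.sensor_heights)
    grids = {key: pointcloud.voxelize(sub, config.canopy_voxel_s)
             for key, sub in clean.split_sensor_side().items()}
    extent = (0.0, len(targets) * geometry.plant_spacing)
    s3L = config.canopy_voxel_s**3 * 1000.0
    if config.side_combine == "union":
        _, merged = pointcloud.combine_sensor_side_grids(grids, "union")
        counts = pointcloud.split_plant_zones(merged, extent, len(targets))
        return counts * s3L
    # count-based side combination
    per_side = {}
    for (sensor, side), grid in grids.items():
        per_side[side] = grid if side not in per_side else per_side[side].union(grid)
    zone_counts = [pointcloud.split_plant_zones(g, extent, len(targets))
                   for g in per_side.values()]
    stacked = np.vstack(zone_counts)
    combined = stacked.sum(axis=0) if config.side_combine == "sum" \
        else stacked.mean(axis=0)
    return combined * s3L


def measure_wood_plot(targets, geometry, seed, config: PipelineConfig
                      ) -> np.ndarray:
    """Before/after-pruning subtraction wood volumes (L) for one plot."""
    before, after = synthetic_data.simulate_pruning_point_clouds(
        targets, geometry, seed, voxel_s=config.wood_voxel_s)
    extent = (0.0, len(targets) * geometry.plant_spacing)
    gb = pointcloud.voxelize(before, config.wood_voxel_s)
    ga = pointcloud.voxelize(after, config.wood_voxel_s)
    nb = pointcloud.split_plant_zones(gb, extent, len(targets))
    na = pointcloud.split_plant_zones(ga, extent, len(targets))
    return np.array([
        pointcloud.pruning_wood_volume_from_counts(b, a, config.wood_voxel_s)
        for b, a in zip(nb, na)])


def measure_ela_plot(targets, geometry, seed, config: PipelineConfig
                     ) -> np.ndarray:
    """Per-plant ELA (m²) from a rendered row image of the plot."""
    cloud = synthetic_data.simulate_canopy_point_cloud(
        targets, geometry, seed, points_per_liter=config.points_per_liter)
    image, info = synthetic_data.render_row_image(
        cloud, geometry, illumination_noise=config.illumination_noise,
        seed=seed, x_extent=(0.0, len(targets) * geometry.plant_spacing))
    mask = imaging.segment_green(image)
    nrows, ncols = info["shape"]
    px = info["pixel_size"]
    z0, z1 = info["z_extent"]
    r1 = nrows - int(np.floor((CANOPY_BASE - z0) / px))
    r0 = max(nrows - int(np.floor((CANOPY_BASE + geometry.canopy_height - z0) / px)), 0)
    geom = imaging.ElaGeometry(geometry.plant_spacing, geometry.canopy_width,
                               geometry.canopy_height)
    out = []
    for i in range(len(targets)):
        c0 = int(round(i * ncols / len(targets)))
        c1 = int(round((i + 1) * ncols / len(targets)))
        fc = imaging.foliage_cover(mask, (r0, r1, c0, c1))
        out.append(imaging.exposed_leaf_area(fc, geom))
    return np.array(out)


def filter_productive_plots(table: pd.DataFrame,
                            min_plants: int = 2) -> pd.DataFrame:
    """Keep plots with at least ``min_plants`` plants carrying a finite value.

    Idempotent: re-applying the filter changes nothing.
    """
    ok = table["value"].notna()
    n_per_plot = table[ok].groupby("plot")["plant"].nunique()
    keep = n_per_plot[n_per_plot >= min_plants].index
    dropped = table["plot"].nunique() - len(keep)
    if dropped:
        logger.info("dropped %d plots with < %d productive plants",
                    dropped, min_plants)
    return table[table["plot"].isin(keep) & ok].reset_index(drop=True)


def _measured_table(truth: pd.DataFrame, trait: str, measure_fn, config,
                    stage_idx: int) -> pd.DataFrame:
    geometry = config.sim.geometry
    rows = []
    for idx, (plot, sub) in enumerate(truth.groupby("plot", sort=False)):
        targets = np.clip(sub.sort_values("plant")["value"].to_numpy(float),
                          0.0, None)
        seed = _plot_seed(config.sim.seed, stage_idx, idx)
        measured = measure_fn(targets, geometry, seed, config)
        base = sub.sort_values("plant")
        for plant, value in zip(base["plant"], measured):
            rows.append((base["genotype"].iloc[0], base["block"].iloc[0],
                         plot, plant, trait, float(value)))
    return pd.DataFrame(
        rows, columns=["genotype", "block", "plot", "plant", "trait", "value"])


def _heritability_rows(table: pd.DataFrame, trait: str) -> list[dict]:
    rows = []
    progeny = table[table["genotype"] != CONTROL_GENOTYPE]
    control = table[table["genotype"] == CONTROL_GENOTYPE]
    b1 = progeny[progeny["block"] == progeny["block"].min()]
    c1 = control[control["block"] == control["block"].min()]
    prog_means = b1.groupby("genotype")["value"].mean()
    ctrl_means = c1.groupby("plot")["value"].mean()
    if len(prog_means) >= 2 and len(ctrl_means) >= 2:
        vc = quantgen.control_heritability(prog_means, ctrl_means)
        rows.append({"trait": trait, "estimator": "control", "H2": vc.H2,
                     "sigma_g2": vc.sigma_g2, "sigma_e2": vc.sigma_e2})
    if progeny["block"].nunique() >= 2:
        vc = quantgen.anova_heritability(progeny)
        rows.append({"trait": trait, "estimator": "anova", "H2": vc.H2,
                     "sigma_g2": vc.sigma_g2, "sigma_e2": vc.sigma_e2})
    return rows


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the full study and write per-stage CSV/JSON plus a manifest."""
    if config.measure not in ("lidar", "direct"):
        raise ValueError(f"unknown measure mode {config.measure!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_hash(config), config.sim.seed, __version__)

    with _stage("map"):
        gmap = synthetic_data.simulate_genetic_map(config.sim)
        gmap.to_csv(out / "map.csv")
    manifest.add("map", output="map.csv", n_rows=len(gmap))

    with _stage("genotypes", out / "map.csv"):
        geno = synthetic_data.simulate_progeny_genotypes(
            gmap, config.sim.n_progeny, config.sim.seed)
        geno.to_csv(out / "genotypes.csv")
    manifest.add("genotypes", output="genotypes.csv", n_rows=len(geno))

    with _stage("phenotypes", out / "genotypes.csv"):
        truth_canopy = synthetic_data.simulate_phenotypes(geno, gmap, config.sim)
        wood_cfg = config.resolved_wood_sim()
        truth_wood = synthetic_data.simulate_phenotypes(geno, gmap, wood_cfg)
        pd.concat([truth_canopy, truth_wood]).to_csv(
            out / "phenotypes_truth.csv", index=False)
    manifest.add("phenotypes", output="phenotypes_truth.csv",
                 n_rows=len(truth_canopy) + len(truth_wood))

    measured = []
    with _stage("measurement", out / "phenotypes_truth.csv"):
        if config.measure == "lidar":
            measured.append(_measured_table(
                truth_canopy, "canopy_volume", measure_canopy_plot, config, 1))
            measured.append(_measured_table(
                truth_wood, "wood_volume", measure_wood_plot, config, 2))
            if config.run_ela:
                measured.append(_measured_table(
                    truth_canopy, "ela", measure_ela_plot, config, 3))
        else:
            measured = [truth_canopy, truth_wood]

    h2_rows, means_by_trait = [], {}
    kept_rows = 0
    with _stage("heritability", out / "phenotypes_measured.csv"):
        for tab in measured:
            trait = tab["trait"].iloc[0]
            kept = filter_productive_plots(tab, config.min_productive_plants)
            kept_rows += len(kept)
            h2_rows.extend(_heritability_rows(kept, trait))
            progeny = kept[kept["genotype"] != CONTROL_GENOTYPE]
            means_by_trait[trait] = quantgen.block_adjusted_means(progeny)
    measured_all = pd.concat(measured)
    measured_all.to_csv(out / "phenotypes_measured.csv", index=False)
    manifest.add("measurement", output="phenotypes_measured.csv",
                 n_rows=len(measured_all), n_rows_kept=kept_rows)

    pd.DataFrame(h2_rows).to_csv(out / "heritability.csv", index=False)
    manifest.add("heritability", output="heritability.csv", n_rows=len(h2_rows))

    if config.run_qtl:
      with _stage("qtl", out / "phenotypes_measured.csv"):
        scanner = qtl.MarkerRegressionScanner(geno, gmap)
        models = {}
        for trait, means in means_by_trait.items():
            y = means.reindex(geno.index).dropna()
            if len(y) < 10 or float(np.var(y)) == 0:
                models[trait] = qtl.QtlModel(n=len(y)).to_dict()
                continue
            res = qtl.scan_lod(y, geno, gmap, scanner=scanner)
            res.to_csv(out / f"scan_{trait}.csv")
            thr = qtl.permutation_threshold(
                y, geno, gmap, n_perm=config.n_permutations,
                alpha=config.alpha, seed=config.sim.seed, scanner=scanner)
            model = qtl.stepwise_model_search(y, geno, gmap, thr,
                                              scanner=scanner)
            models[trait] = model.to_dict()
        with open(out / "qtl_models.json", "w") as fh:
            json.dump(models, fh, indent=2, default=str)
        manifest.add("qtl", output="qtl_models.json", n_traits=len(models))

    manifest.write(out / "manifest.json")
    return manifest
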