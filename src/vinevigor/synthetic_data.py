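"""Synthetic study generator: maps, progeny, phenotypes and field scenes.

Emulates a grapevine QTL-mapping field trial: a biparental F1 progeny of 209
genotypes plus a replicated control variety, laid out as a randomized
complete 2-block design with elementary plots of 3 plants, phenotyped for
vigor-related traits (apparent canopy volume, pruning-wood volume, exposed
leaf area, chlorophyll) whose genetic architecture is controlled by planted
QTLs on a dense marker map.  The physical layer generates per-plot LiDAR-like
point clouds (two stacked scanners, two row sides, soil and trellis wires)
and row-facing RGB images against a blue background, so the whole
measurement pipeline can be exercised without any real data.

The canopy generative model is deliberately simple: points are sampled
uniformly inside a per-plant box and the point count grows linearly with the
target volume, which makes voxel-recovered apparent volumes a monotone
function of the planted target.  Winter scenes build canes on a voxel-aligned
lattice so the planted wood volume is recovered by the before/after-pruning
subtraction essentially exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pointcloud import PointCloud
from .qtl import GENOTYPE_CLASSES, GeneticMap, haldane

CONTROL_GENOTYPE = "control"
PLANTS_PER_PLOT = 3

# scene layout constants (metres)
CANOPY_BASE = 0.5       # bottom of the foliage / cane band; also cordon height
TRUNK_BASE = 0.05
WIRE_HEIGHTS = (0.7, 1.2)
WIRE_Y = 0.18           # wires run beside the canopy mid-plane
LOWER_SENSOR_HEIGHT = 0.8

#: default class-effect pattern: additive contributions of the two parental
#: alleles (a vs b and c vs d each worth +/- 0.5), order (ac, ad, bc, bd)
DEFAULT_EFFECT_PATTERN = (1.0, 0.0, 0.0, -1.0)


@dataclass(frozen=True)
class QtlSpec:
    """A planted QTL: position and the share of phenotypic variance it explains."""

    chromosome: str
    position_cM: float
    fraction_variance: float
    effect_sizes: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_variance < 1:
            raise ValueError("fraction_variance must be in [0, 1)")


@dataclass(frozen=True)
class TrainingGeometry:
    """Vertical-shoot-positioning trellis geometry (metres)."""

    row_spacing: float = 1.7
    plant_spacing: float = 1.4   # D in the ELA formula
    canopy_width: float = 0.3    # W
    canopy_height: float = 1.4   # H
    sensor_gap: float = 0.7      # vertical distance between the two scanners
    trigger_offset: float = 0.25  # acquisition starts this far into the plot

    def __post_init__(self) -> None:
        for name in ("row_spacing", "plant_spacing", "canopy_width",
                     "canopy_height", "sensor_gap", "trigger_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sensor_heights(self) -> tuple[float, float]:
        return (LOWER_SENSOR_HEIGHT, LOWER_SENSOR_HEIGHT + self.sensor_gap)

    @property
    def sensor_split_z(self) -> float:
        return 0.5 * sum(self.sensor_heights)


def default_chromosomes() -> list[tuple[str, float, int]]:
    """19 linkage groups of ~53.5 cM (~1,017 cM genome), 0.5 Mb per cM."""
    return [(f"chr{i}", 53.5, 26_750_000) for i in range(1, 20)]


@dataclass
class SimConfig:
    seed: int = 0
    n_progeny: int = 209
    n_control_plots: int = 6
    n_blocks: int = 2
    chromosomes: list[tuple[str, float, int]] = field(
        default_factory=default_chromosomes)
    marker_spacing_cM: float = 0.25
    qtls: tuple[QtlSpec, ...] = ()
    trait_name: str = "canopy_volume"
    trait_mean: float = 365.0     # L/plant, a typical mid-vigor canopy
    sigma_g2: float = 1450.0      # total genetic variance (incl. planted QTLs)
    sigma_e2: float = 1200.0      # per-plant residual variance
    block_effect_sd: float = 20.0
    geometry: TrainingGeometry = field(default_factory=TrainingGeometry)

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0 or self.block_effect_sd < 0:
            raise ValueError("variances must be non-negative")
        if self.marker_spacing_cM <= 0:
            raise ValueError("marker_spacing_cM must be positive")
        if self.n_blocks < 1 or self.n_control_plots < 1:
            raise ValueError("need at least one block and one control plot")
        lengths = {name: l_cM for name, l_cM, _ in self.chromosomes}
        for q in self.qtls:
            if q.chromosome not in lengths:
                raise ValueError(f"QTL chromosome {q.chromosome!r} not declared")
            if not 0 <= q.position_cM <= lengths[q.chromosome]:
                raise ValueError(
                    f"QTL position {q.position_cM} cM off {q.chromosome}")
        if sum(q.fraction_variance for q in self.qtls) >= 1:
            raise ValueError("QTL variance fractions must sum to < 1")


def default_study_config(seed: int = 0) -> SimConfig:
    """The default study conditions: 209 progeny, 19 chromosomes, 3 QTLs whose
    variance shares mirror typical single-locus effects (8-16%)."""
    return SimConfig(
        seed=seed,
        qtls=(
            QtlSpec("chr1", 39.0, 0.16),
            QtlSpec("chr10", 38.5, 0.13),
            QtlSpec("chr5", 24.0, 0.08),
        ),
    )


# ---------------------------------------------------------------------------
# Genetics
# ---------------------------------------------------------------------------

def simulate_genetic_map(config: SimConfig) -> GeneticMap:
    """Uniformly spaced markers named "<chrom>_<bp>", bp proportional to cM."""
    if not config.chromosomes:
        raise ValueError("no chromosomes declared")
    rows = []
    for name, length_cM, length_bp in config.chromosomes:
        if length_cM <= 0 or length_bp <= 0:
            raise ValueError(f"chromosome {name!r} has zero length")
        pos = np.arange(0.0, length_cM, config.marker_spacing_cM)
        if pos[-1] < length_cM:
            pos = np.append(pos, length_cM)
        bp = np.round(pos / length_cM * length_bp).astype(np.int64)
        for p, b in zip(pos, bp):
            rows.append((f"{name}_{b}", name, float(p), int(b)))
    table = pd.DataFrame(rows, columns=GeneticMap.REQUIRED)
    return GeneticMap(table)


def simulate_progeny_genotypes(gmap: GeneticMap, n: int,
                               seed: int) -> pd.DataFrame:
    """F1 four-way-cross genotypes with Haldane recombination along each
    chromosome; classes in {ac, ad, bc, bd}."""
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    blocks = []
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_table(chrom)
        pos = sub["position_cM"].to_numpy(float)
        r = haldane(np.diff(pos))
        alleles = []
        for _parent in range(2):
            start = rng.integers(0, 2, size=(n, 1))
            if len(pos) > 1:
                switches = rng.random((n, len(pos) - 1)) < r
                cum = np.cumsum(switches, axis=1)
                a = (start + np.concatenate(
                    [np.zeros((n, 1), dtype=int), cum], axis=1)) % 2
            else:
                a = start
            alleles.append(a)
        p1 = np.where(alleles[0] == 0, "a", "b")
        p2 = np.where(alleles[1] == 0, "c", "d")
        blocks.append(pd.DataFrame(np.char.add(p1, p2),
                                   columns=list(sub["marker"])))
    geno = pd.concat(blocks, axis=1)
    geno.index = [f"ind{i:04d}" for i in range(n)]
    return geno


def _nearest_marker(gmap: GeneticMap, chromosome: str, position_cM: float) -> str:
    sub = gmap.chrom_table(chromosome)
    idx = (sub["position_cM"] - position_cM).abs().idxmin()
    return str(sub.loc[idx, "marker"])


def qtl_class_effects(spec: QtlSpec, total_variance: float) -> np.ndarray:
    """Centered per-class effects scaled so the QTL explains
    ``fraction_variance`` of ``total_variance`` at equal class frequencies."""
    pattern = np.asarray(spec.effect_sizes if spec.effect_sizes is not None
                         else DEFAULT_EFFECT_PATTERN, dtype=float)
    centered = pattern - pattern.mean()
    ms = float(np.mean(centered**2))
    if ms == 0:
        raise ValueError("QTL effect pattern has no contrast")
    return centered * np.sqrt(spec.fraction_variance * total_variance / ms)


def simulate_phenotypes(genotypes: pd.DataFrame, gmap: GeneticMap,
                        config: SimConfig) -> pd.DataFrame:
    """Per-plant trait values for the progeny and the replicated control.

    plant value = trait mean + sum of QTL class effects (at the marker nearest
    each planted QTL) + genotype polygenic deviation + block effect + plant
    noise.  The control genotype carries no genetic term and is replicated in
    ``n_control_plots`` plots of 3 plants per block, so its between-plot
    variance is pure environment.
    """
    sp2 = config.sigma_g2 + config.sigma_e2
    qtl_var = sum(q.fraction_variance for q in config.qtls) * sp2
    resid_g2 = config.sigma_g2 - qtl_var
    if resid_g2 < -1e-9:
        raise ValueError(
            "planted QTL variance exceeds the total genetic variance")
    resid_g2 = max(resid_g2, 0.0)

    rng_g = np.random.default_rng((config.seed, 101))
    rng_b = np.random.default_rng((config.seed, 102))
    rng_e = np.random.default_rng((config.seed, 103))

    ids = list(genotypes.index)
    g = rng_g.normal(0.0, np.sqrt(resid_g2), size=len(ids))
    for spec in config.qtls:
        marker = _nearest_marker(gmap, spec.chromosome, spec.position_cM)
        if marker not in genotypes.columns:
            raise ValueError(f"marker {marker!r} absent from genotype matrix")
        effects = qtl_class_effects(spec, sp2)
        class_idx = {c: i for i, c in enumerate(GENOTYPE_CLASSES)}
        idx = genotypes[marker].map(class_idx).to_numpy()
        g = g + effects[idx]

    block_eff = rng_b.normal(0.0, config.block_effect_sd, size=config.n_blocks)
    sigma_e = np.sqrt(config.sigma_e2)
    rows = []
    for b in range(1, config.n_blocks + 1):
        for gid, gv in zip(ids, g):
            plot = f"B{b}_{gid}"
            noise = rng_e.normal(0.0, sigma_e, PLANTS_PER_PLOT)
            for p in range(PLANTS_PER_PLOT):
                rows.append((gid, b, plot, p + 1, config.trait_name,
                             config.trait_mean + gv + block_eff[b - 1]
                             + noise[p]))
        for k in range(1, config.n_control_plots + 1):
            plot = f"B{b}_{CONTROL_GENOTYPE}_{k}"
            noise = rng_e.normal(0.0, sigma_e, PLANTS_PER_PLOT)
            for p in range(PLANTS_PER_PLOT):
                rows.append((CONTROL_GENOTYPE, b, plot, p + 1,
                             config.trait_name,
                             config.trait_mean + block_eff[b - 1] + noise[p]))
    return pd.DataFrame(
        rows, columns=["genotype", "block", "plot", "plant", "trait", "value"])


# ---------------------------------------------------------------------------
# Physical scenes
# ---------------------------------------------------------------------------

def _as_targets(plot_phenotypes) -> np.ndarray:
    if isinstance(plot_phenotypes, pd.DataFrame):
        targets = plot_phenotypes.sort_values("plant")["value"].to_numpy(float)
    else:
        targets = np.asarray(plot_phenotypes, dtype=float)
    if targets.ndim != 1 or not 1 <= len(targets) <= PLANTS_PER_PLOT:
        raise ValueError("expected 1-3 per-plant target volumes")
    if np.any(targets < 0):
        raise ValueError("target volumes must be non-negative")
    return targets


def _plant_box_x(i: int, geometry: TrainingGeometry) -> tuple[float, float]:
    """Along-row extent of plant i's canopy box, kept clear of the trigger cut
    and of the neighbouring plant's box."""
    center = (i + 0.5) * geometry.plant_spacing
    half = 0.5 * geometry.plant_spacing - geometry.trigger_offset
    return center - half, center + half


def _wire_points(x_start: float, x_end: float) -> np.ndarray:
    xs = np.arange(x_start, x_end, 0.005)
    pts = []
    for z in WIRE_HEIGHTS:
        pts.append(np.column_stack([xs, np.full_like(xs, WIRE_Y),
                                    np.full_like(xs, z)]))
    return np.vstack(pts)


def _annotate(points: np.ndarray, labels: np.ndarray,
              geometry: TrainingGeometry, rng: np.random.Generator,
              plot_id: str | None) -> PointCloud:
    sensor = np.where(points[:, 2] < geometry.sensor_split_z, "lower", "upper")
    side = np.where(rng.random(len(points)) < 0.5, "north", "south")
    return PointCloud(points, sensor, side, labels, plot_id)


def simulate_canopy_point_cloud(
    plot_phenotypes,
    geometry: TrainingGeometry = TrainingGeometry(),
    seed: int = 0,
    points_per_liter: float = 80.0,
    n_soil_points: int = 500,
    occlusion: float = 0.0,
    plot_id: str | None = None,
) -> PointCloud:
    """Summer scene of one elementary plot: canopy boxes, soil plane, wires.

    Canopy points are sampled uniformly inside each plant's box (width W,
    height H) with a count proportional to the plant's target volume, so
    voxel-recovered apparent volume increases monotonically with the target.
    ``occlusion`` thins interior point density (no ray casting).  The scene
    starts ``trigger_offset`` into the plot.
    """
    targets = _as_targets(plot_phenotypes)
    if not 0 <= occlusion < 1:
        raise ValueError("occlusion must be in [0, 1)")
    rng = np.random.default_rng(seed)
    geom = geometry
    x_end = len(targets) * geom.plant_spacing
    pts, labels = [], []
    for i, target in enumerate(targets):
        n_pts = int(round(points_per_liter * target * (1.0 - occlusion)))
        if n_pts == 0:
            continue
        x0, x1 = _plant_box_x(i, geom)
        box = np.column_stack([
            rng.uniform(x0, x1, n_pts),
            rng.uniform(-geom.canopy_width / 2, geom.canopy_width / 2, n_pts),
            rng.uniform(CANOPY_BASE, CANOPY_BASE + geom.canopy_height, n_pts),
        ])
        pts.append(box)
        labels.append(np.full(n_pts, "canopy"))
    if n_soil_points:
        soil = np.column_stack([
            rng.uniform(geom.trigger_offset, x_end, n_soil_points),
            rng.uniform(-0.85, 0.85, n_soil_points),
            rng.uniform(0.0, 0.02, n_soil_points),
        ])
        pts.append(soil)
        labels.append(np.full(n_soil_points, "soil"))
    wires = _wire_points(geom.trigger_offset, x_end)
    pts.append(wires)
    labels.append(np.full(len(wires), "wire"))
    points = np.vstack(pts)
    labels = np.concatenate(labels)
    keep = points[:, 0] >= geom.trigger_offset
    return _annotate(points[keep], labels[keep], geom, rng, plot_id)


def _perennial_points(n_plants: int, geometry: TrainingGeometry,
                      rng: np.random.Generator):
    """Trunk and cordon points shared by the before/after winter scenes."""
    pts, labels = [], []
    for i in range(n_plants):
        center = (i + 0.5) * geometry.plant_spacing
        zs = np.arange(TRUNK_BASE, CANOPY_BASE, 0.004)
        trunk = np.column_stack([
            center + rng.uniform(-0.002, 0.002, len(zs)),
            rng.uniform(-0.002, 0.002, len(zs)),
            zs,
        ])
        x0, x1 = _plant_box_x(i, geometry)
        xs = np.arange(x0, x1, 0.004)
        cordon = np.column_stack([
            xs,
            rng.uniform(-0.002, 0.002, len(xs)),
            CANOPY_BASE + rng.uniform(-0.002, 0.002, len(xs)),
        ])
        pts.extend([trunk, cordon])
        labels.extend([np.full(len(trunk), "trunk"), np.full(len(cordon), "cordon")])
    return pts, labels


def simulate_pruning_point_clouds(
    plot_phenotypes,
    geometry: TrainingGeometry = TrainingGeometry(),
    seed: int = 0,
    voxel_s: float = 0.005,
    plot_id: str | None = None,
) -> tuple[PointCloud, PointCloud]:
    """Winter scene pair (before pruning, after pruning) for one plot.

    The after scene holds only trunk, cordon and wires; the before scene adds
    one-year canes whose points sit on a ``voxel_s``-aligned lattice occupying
    exactly round(target / s^3) cells per plant, all above the cordon band, so
    the before-minus-after voxel subtraction returns the planted wood volume.
    """
    targets = _as_targets(plot_phenotypes)
    rng = np.random.default_rng(seed)
    geom = geometry
    x_end = len(targets) * geom.plant_spacing

    pts, labels = _perennial_points(len(targets), geom, rng)
    wires = _wire_points(geom.trigger_offset, x_end)
    pts.append(wires)
    labels.append(np.full(len(wires), "wire"))
    after_pts = np.vstack(pts)
    after_labels = np.concatenate(labels)

    cell_L = voxel_s**3 * 1000.0
    cane_pts = []
    z0_idx = int(np.floor(CANOPY_BASE / voxel_s)) + 3  # clear of the cordon band
    z_top_idx = int(np.floor((CANOPY_BASE + geom.canopy_height) / voxel_s))
    col_height = z_top_idx - z0_idx
    for i, target in enumerate(targets):
        n_cells = int(round(target / cell_L))
        if n_cells == 0:
            continue
        x0, x1 = _plant_box_x(i, geom)
        xi = np.arange(int(np.ceil(x0 / voxel_s)), int(np.floor(x1 / voxel_s)), 2)
        yi = np.arange(int(np.ceil(-geom.canopy_width / 2 / voxel_s)),
                       int(np.floor(geom.canopy_width / 2 / voxel_s)), 2)
        capacity = len(xi) * len(yi) * col_height
        if n_cells > capacity:
            raise ValueError(
                f"wood target {target:.1f} L exceeds the geometric capacity "
                f"({capacity * cell_L:.1f} L) of the canopy box")
        cols = [(x, y) for y in yi for x in xi]
        remaining = n_cells
        for (cx, cy) in cols:
            take = min(col_height, remaining)
            zi = z0_idx + np.arange(take)
            centers = np.column_stack([
                np.full(take, (cx + 0.5) * voxel_s),
                np.full(take, (cy + 0.5) * voxel_s),
                (zi + 0.5) * voxel_s,
            ])
            jitter = rng.uniform(-0.4 * voxel_s, 0.4 * voxel_s, (take, 3))
            cane_pts.append(centers + jitter)
            remaining -= take
            if remaining == 0:
                break

    if cane_pts:
        canes = np.vstack(cane_pts)
        before_pts = np.vstack([after_pts, canes])
        before_labels = np.concatenate([after_labels, np.full(len(canes), "cane")])
    else:
        before_pts, before_labels = after_pts, after_labels

    # shared annotations so common points are identical in both scenes
    rng_ann = np.random.default_rng((seed, 7))
    before = _annotate(before_pts, before_labels, geom, rng_ann, plot_id)
    after = PointCloud(after_pts, before.sensor[:len(after_pts)],
                       before.side[:len(after_pts)], after_labels, plot_id)
    return before, after


def render_row_image(
    cloud: PointCloud,
    geometry: TrainingGeometry = TrainingGeometry(),
    illumination_noise: float = 0.0,
    seed: int = 0,
    pixel_size: float = 0.005,
    x_extent: tuple[float, float] | None = None,
    z_extent: tuple[float, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Orthographic row-facing render: canopy green on a blue background.

    Canopy points are projected onto the x-z plane at a fixed pixel pitch;
    any pixel hit by a canopy point is foliage-green, the rest is
    curtain-blue.  ``illumination_noise`` applies multiplicative per-pixel
    brightness jitter (uncontrolled field lighting); 0 gives a bit-identical
    image for a given seed.  Returns (uint8 RGB image, bookkeeping dict with
    the exact canopy pixel count).
    """
    if illumination_noise < 0:
        raise ValueError("illumination_noise must be >= 0")
    if x_extent is None:
        x_extent = (0.0, PLANTS_PER_PLOT * geometry.plant_spacing)
    if z_extent is None:
        z_extent = (0.0, CANOPY_BASE + geometry.canopy_height + 0.1)
    ncols = int(np.ceil((x_extent[1] - x_extent[0]) / pixel_size))
    nrows = int(np.ceil((z_extent[1] - z_extent[0]) / pixel_size))
    green = np.array([40, 160, 40], dtype=float)
    blue = np.array([30, 60, 200], dtype=float)
    img = np.broadcast_to(blue, (nrows, ncols, 3)).copy()

    if len(cloud) > 0:
        if cloud.label is not None:
            mask = ~np.isin(cloud.label, ("soil", "wire"))
        else:
            mask = np.ones(len(cloud), dtype=bool)
        pts = cloud.points[mask]
        col = np.floor((pts[:, 0] - x_extent[0]) / pixel_size).astype(int)
        row = nrows - 1 - np.floor((pts[:, 2] - z_extent[0]) / pixel_size).astype(int)
        ok = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        img[row[ok], col[ok]] = green
        canopy_pixels = int(len(np.unique(row[ok] * ncols + col[ok])))
    else:
        canopy_pixels = 0

    if illumination_noise > 0:
        rng = np.random.default_rng(seed)
        factor = np.clip(rng.normal(1.0, illumination_noise, (nrows, ncols)),
                         0.0, 2.0)
        img = img * factor[..., None]
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    info = {
        "canopy_pixel_count": canopy_pixels,
        "pixel_size": pixel_size,
        "x_extent": x_extent,
        "z_extent": z_extent,
        "shape": (nrows, ncols),
    }
    return image, info
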