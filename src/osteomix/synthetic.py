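"""Synthetic two-channel bone-imaging scenes with full ground truth.

Emulates intravital multiphoton acquisitions of Col2.3-ECFP (cyan,
osteoblast) / TRAP-tdTomato (red, osteoclast) reporters: tiled 512×512
fields stitched into a mosaic, z-stacks at 5-µm steps, and coculture-style
time-lapse sequences. Spatial intermingling of the two cell populations is
controlled by a single ``mixing_lambda`` in [0, 1]: cells of both colors are
drawn around paired cluster centers whose displacement shrinks linearly as
lambda rises, sweeping fully segregated (0) to fully co-clustered (1).

Every generator returns the raster(s) plus a :class:`SyntheticSceneTruth`
carrying binary masks, an object table, per-tile color areas, and (for
time-lapses / scripted volumes) the contact ground truth, so that each
downstream stage of the pipeline can be validated without real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    ConfigurationError,
    DataError,
    TimeLapse,
    TwoChannelImage,
    TwoChannelVolume,
)

__all__ = [
    "SceneConfig",
    "SyntheticSceneTruth",
    "ContactEpisode",
    "generate_field",
    "generate_volume",
    "generate_timelapse",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic two-channel scene.

    Defaults mirror the acquisition geometry of the intravital skull imaging
    this generator emulates: 16 contiguous 512×512 fields stitched 4×4, and
    z-stacks at 5-µm vertical steps spanning ~150 µm of depth. Cell counts,
    radii and the cluster process are free parameters (the acquisitions do
    not pin them); defaults are chosen to resemble the published mosaics —
    many small osteoblast patches, fewer and larger osteoclasts.
    """

    field_shape: tuple[int, int] = (512, 512)
    field_grid: tuple[int, int] = (4, 4)
    pixel_size_um: float = 1.0
    n_z: int = 31
    z_step_um: float = 5.0
    n_blue_cells: int = 240
    n_red_cells: int = 120
    r_blue_um: float = 7.0
    r_red_um: float = 18.0
    mixing_lambda: float = 0.5
    cluster_count: int = 8
    cluster_sd_um: float = 40.0
    snr: float = 8.0
    noise_sd: float = 0.02
    background: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fs, fg = self.field_shape, self.field_grid
        if len(fs) != 2 or any(int(s) <= 0 for s in fs):
            raise ConfigurationError("field_shape must be two positive integers")
        if len(fg) != 2 or any(int(s) <= 0 for s in fg):
            raise ConfigurationError("field_grid must be two positive integers")
        if not self.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.n_z < 1:
            raise ConfigurationError("n_z must be >= 1")
        if not self.z_step_um > 0:
            raise ConfigurationError("z_step_um must be > 0")
        if self.n_blue_cells < 0 or self.n_red_cells < 0:
            raise ConfigurationError("n_blue_cells and n_red_cells must be >= 0")
        if not (self.r_blue_um > 0 and self.r_red_um > 0):
            raise ConfigurationError("r_blue_um and r_red_um must be > 0")
        if not 0.0 <= self.mixing_lambda <= 1.0:
            raise ConfigurationError("mixing_lambda must lie in [0, 1]")
        if self.cluster_count < 1:
            raise ConfigurationError("cluster_count must be >= 1")
        if not self.cluster_sd_um > 0:
            raise ConfigurationError("cluster_sd_um must be > 0")
        if not self.snr > 1:
            raise ConfigurationError("snr must be > 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 < self.background < 1:
            raise ConfigurationError("background must lie in (0, 1)")

    @property
    def n_fields(self) -> int:
        return self.field_grid[0] * self.field_grid[1]

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        return (
            self.field_grid[0] * self.field_shape[0],
            self.field_grid[1] * self.field_shape[1],
        )


@dataclass(frozen=True)
class ContactEpisode:
    """A scripted contact between one blue and one red object.

    Frames ``start``..``end`` (inclusive) force the pair to overlap; all
    other frames leave the pair to its repelled random walk.
    """

    blue_id: int
    red_id: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(f"episode start {self.start} > end {self.end}")

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntheticSceneTruth:
    """Ground truth accompanying a generated scene.

    ``masks`` maps channel name to the boolean truth raster (2-D field, 3-D
    volume, or (T, H, W) time-lapse stack). ``objects`` has one row per
    rendered blob; for time-lapses it is long-format with one row per
    (frame, object). ``tile_areas`` gives true per-tile foreground areas for
    mosaics; ``contacts`` the scripted blue/red overlap pairs of a volume;
    ``episodes`` the scripted contact table of a time-lapse.
    """

    masks: dict[str, np.ndarray]
    objects: pd.DataFrame
    tile_areas: pd.DataFrame | None = None
    contacts: pd.DataFrame | None = None
    episodes: pd.DataFrame | None = None
    cluster_centers: pd.DataFrame | None = None
    pixel_size_um: float = 1.0
    voxel_size_um: tuple[float, float, float] | None = None

    def rasterize(self) -> dict[str, np.ndarray]:
        """Re-render the truth masks from the object table alone.

        Used to assert truth consistency: the union of per-object footprints
        must reproduce ``masks`` exactly.
        """
        out = {ch: np.zeros_like(m, dtype=bool) for ch, m in self.masks.items()}
        obj = self.objects
        if obj.empty:
            return out
        if "frame" in obj.columns:  # time-lapse: masks are (T, H, W)
            for row in obj.itertuples(index=False):
                m = out[row.channel][int(row.frame)]
                _paint_disk(m, (row.row, row.col), row.radius_px)
        elif "voxel_count" in obj.columns:  # volume: exact-count ellipsoids
            for row in obj.itertuples(index=False):
                vox = _blob_voxels(
                    (row.centroid_z, row.centroid_y, row.centroid_x),
                    (row.rz_vox, row.ry_vox, row.rx_vox),
                    int(row.voxel_count),
                    out[row.channel].shape,
                )
                out[row.channel][vox] = True
        else:
            for row in obj.itertuples(index=False):
                _paint_disk(out[row.channel], (row.centroid_row, row.centroid_col), row.radius_px)
        return out


# ---------------------------------------------------------------------------
# Rasterization primitives
# ---------------------------------------------------------------------------

def _paint_disk(mask: np.ndarray, center: tuple[float, float], radius: float) -> None:
    """Set mask pixels whose center lies within ``radius`` of ``center``."""
    cr, cc = center
    r0 = max(0, int(np.floor(cr - radius)))
    r1 = min(mask.shape[0], int(np.ceil(cr + radius)) + 1)
    c0 = max(0, int(np.floor(cc - radius)))
    c1 = min(mask.shape[1], int(np.ceil(cc + radius)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc_ = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    mask[r0:r1, c0:c1] |= (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius**2


def _disk_area(shape: tuple[int, int], center: tuple[float, float], radius: float) -> int:
    tmp = np.zeros(shape, dtype=bool)
    _paint_disk(tmp, center, radius)
    return int(tmp.sum())


def _add_soft_blob(img: np.ndarray, center, radius: float, amplitude: float) -> None:
    """Add a logistic radial-falloff intensity profile (flat core, soft edge).

    The edge width scales with the radius but stays sub-pixel-to-pixel so a
    threshold near the half-maximum recovers the nominal disk closely."""
    cr, cc = center
    w = max(0.5, radius / 12.0)
    pad = radius + 6 * w
    r0 = max(0, int(np.floor(cr - pad)))
    r1 = min(img.shape[0], int(np.ceil(cr + pad)) + 1)
    c0 = max(0, int(np.floor(cc - pad)))
    c1 = min(img.shape[1], int(np.ceil(cc + pad)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc_ = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d = np.sqrt((rr - cr) ** 2 + (cc_ - cc) ** 2)
    img[r0:r1, c0:c1] += amplitude / (1.0 + np.exp((d - radius) / w))


def _add_soft_blob_3d(
    img: np.ndarray,
    center: tuple[float, float, float],
    radii_vox: tuple[float, float, float],
    amplitude: float,
    edge_width: float = 0.06,
) -> None:
    """Add a logistic falloff in the normalized ellipsoid metric.

    The half-maximum contour sits on the nominal ellipsoid surface and the
    edge is sharp (``edge_width`` in units of the normalized radius), so a
    threshold near the half-maximum recovers the truth footprint closely
    even for blobs only a few voxels across.
    """
    cz, cy, cx = center
    az, ay, ax = (max(r, 1e-6) for r in radii_vox)
    pad = 1.0 + 8.0 * edge_width
    z0 = max(0, int(np.floor(cz - az * pad)) - 1)
    z1 = min(img.shape[0], int(np.ceil(cz + az * pad)) + 2)
    y0 = max(0, int(np.floor(cy - ay * pad)) - 1)
    y1 = min(img.shape[1], int(np.ceil(cy + ay * pad)) + 2)
    x0 = max(0, int(np.floor(cx - ax * pad)) - 1)
    x1 = min(img.shape[2], int(np.ceil(cx + ax * pad)) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    rho = np.sqrt(
        ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    )
    blob = amplitude / (1.0 + np.exp((rho - 1.0) / edge_width))
    region = img[z0:z1, y0:y1, x0:x1]
    img[z0:z1, y0:y1, x0:x1] = region + blob


def _blob_voxels(
    center: tuple[float, float, float],
    radii_vox: tuple[float, float, float],
    count: int,
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The ``count`` voxels closest to ``center`` in normalized ellipsoid metric.

    Ties in the metric are broken lexicographically on (z, y, x), making the
    footprint a pure function of (center, radii, count) — the generator and
    :meth:`SyntheticSceneTruth.rasterize` share it, so truth volumes are
    voxel-count-exact by construction.
    """
    cz, cy, cx = center
    az, ay, ax = (max(r, 1e-6) for r in radii_vox)
    # bounding box generous enough to always contain `count` voxels
    scale = 1.0 + 2.5 * (count ** (1 / 3)) / max(min(az, ay, ax), 1.0)
    z0 = max(0, int(np.floor(cz - az * scale)) - 2)
    z1 = min(shape[0], int(np.ceil(cz + az * scale)) + 3)
    y0 = max(0, int(np.floor(cy - ay * scale)) - 2)
    y1 = min(shape[1], int(np.ceil(cy + ay * scale)) + 3)
    x0 = max(0, int(np.floor(cx - ax * scale)) - 2)
    x1 = min(shape[2], int(np.ceil(cx + ax * scale)) + 3)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    zz, yy, xx = zz.ravel(), yy.ravel(), xx.ravel()
    d = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    if count > d.size:
        raise DataError(
            f"blob of {count} voxels does not fit in volume of shape {shape}"
        )
    order = np.lexsort((xx, yy, zz, d))[:count]
    return zz[order], yy[order], xx[order]


def _render_intensity_2d(
    shape: tuple[int, int],
    objects: list[tuple[tuple[float, float], float]],
    config: SceneConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.full(shape, config.background, dtype=np.float64)
    amp = config.snr * config.background
    for center, radius in objects:
        _add_soft_blob(img, center, radius, amp)
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Cluster process (shared by 2-D fields)
# ---------------------------------------------------------------------------

#: cell scatter around its cluster center is truncated at this many cluster SDs,
#: which (with the 8-SD minimum spacing of blue cluster centers) guarantees at
#: mixing_lambda=0 that no red cell lies within 2 SD of any blue cluster center
#: whenever the mosaic is roomy enough to honor spacing and margins.
_JITTER_TRUNC_SD = 1.9
_BLUE_SPACING_SD = 8.0


def _draw_cluster_centers(
    config: SceneConfig, shape_px: tuple[int, int], rng: np.random.Generator
):
    """Paired blue/red cluster centers; displacement D·(1−λ), D = 4·cluster_sd."""
    h, w = shape_px
    sd_px = config.cluster_sd_um / config.pixel_size_um
    r_max_px = max(config.r_blue_um, config.r_red_um) / config.pixel_size_um
    # margin keeps red centers + truncated jitter + cell radius inside the
    # mosaic without clipping; cramped configs fall back to a smaller margin
    margin = (4.0 + _JITTER_TRUNC_SD) * sd_px + r_max_px + 1.0
    if 2 * margin >= min(h, w):
        margin = min(h, w) / 4.0
    spacing = _BLUE_SPACING_SD * sd_px
    blue = np.zeros((config.cluster_count, 2))
    for k in range(config.cluster_count):
        pos = None
        for _ in range(2000):
            cand = np.array(
                [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
            )
            if all(np.linalg.norm(cand - blue[j]) >= spacing for j in range(k)):
                pos = cand
                break
        if pos is None:  # field too cramped for the spacing; accept the draw
            pos = cand
        blue[k] = pos
    theta = rng.uniform(0.0, 2 * np.pi, size=config.cluster_count)
    disp = 4.0 * sd_px * (1.0 - config.mixing_lambda)
    red = blue + disp * np.column_stack([np.sin(theta), np.cos(theta)])
    # guard against out-of-bounds only; in a roomy mosaic the margin already
    # keeps red centers inside, so segregation distances are preserved
    guard = r_max_px + 1.0
    red[:, 0] = np.clip(red[:, 0], guard, h - guard)
    red[:, 1] = np.clip(red[:, 1], guard, w - guard)
    return blue, red, sd_px


def _draw_cells(
    centers: np.ndarray,
    n_cells: int,
    r_mean_px: float,
    sd_px: float,
    shape_px: tuple[int, int],
    rng: np.random.Generator,
):
    """Cell centers scattered around cluster centers (truncated Gaussian),
    clipped so each disk fits inside the mosaic."""
    h, w = shape_px
    out = []
    for _ in range(n_cells):
        k = int(rng.integers(len(centers)))
        jitter = rng.normal(0.0, sd_px, size=2)
        norm = float(np.hypot(*jitter))
        cap = _JITTER_TRUNC_SD * sd_px
        if norm > cap:
            jitter *= cap / norm
        pos = centers[k] + jitter
        radius = max(2.0, rng.normal(r_mean_px, 0.15 * r_mean_px))
        pos[0] = np.clip(pos[0], radius, h - 1 - radius)
        pos[1] = np.clip(pos[1], radius, w - 1 - radius)
        out.append(((pos[0], pos[1]), radius, k))
    return out


# ---------------------------------------------------------------------------
# 2-D mosaic fields
# ---------------------------------------------------------------------------

def generate_field(config: SceneConfig) -> tuple[TwoChannelImage, SyntheticSceneTruth]:
    """Generate one stitched mosaic of ``n_fields`` tiles plus ground truth.

    Blue (cyan) and red blob centers follow a two-type clustered point
    process over the whole mosaic; ``mixing_lambda`` sets how far each red
    cluster center sits from its paired blue center. Intensities are soft
    blobs over a constant background plus clipped Gaussian noise.
    """
    shape = config.mosaic_shape
    rng = np.random.default_rng(config.seed)

    blue_centers, red_centers, sd_px = _draw_cluster_centers(config, shape, rng)
    r_blue_px = config.r_blue_um / config.pixel_size_um
    r_red_px = config.r_red_um / config.pixel_size_um
    blue_cells = _draw_cells(blue_centers, config.n_blue_cells, r_blue_px, sd_px, shape, rng)
    red_cells = _draw_cells(red_centers, config.n_red_cells, r_red_px, sd_px, shape, rng)

    masks = {ch: np.zeros(shape, dtype=bool) for ch in ("cyan", "red")}
    rows = []
    px_area = config.pixel_size_um**2
    oid = 0
    for channel, cells in (("cyan", blue_cells), ("red", red_cells)):
        for (cr, cc), radius, k in cells:
            _paint_disk(masks[channel], (cr, cc), radius)
            area = _disk_area(shape, (cr, cc), radius)
            rows.append(
                {
                    "id": oid,
                    "channel": channel,
                    "centroid_row": cr,
                    "centroid_col": cc,
                    "radius_px": radius,
                    "cluster": k,
                    "area_px": area,
                    "area_um2": area * px_area,
                }
            )
            oid += 1
    objects = pd.DataFrame(
        rows,
        columns=[
            "id",
            "channel",
            "centroid_row",
            "centroid_col",
            "radius_px",
            "cluster",
            "area_px",
            "area_um2",
        ],
    )

    cyan_img = _render_intensity_2d(shape, [(c, r) for c, r, _ in blue_cells], config, rng)
    red_img = _render_intensity_2d(shape, [(c, r) for c, r, _ in red_cells], config, rng)
    image = TwoChannelImage(cyan=cyan_img, red=red_img, pixel_size_um=config.pixel_size_um)

    tile_rows = []
    fh, fw = config.field_shape
    for i in range(config.field_grid[0]):
        for j in range(config.field_grid[1]):
            sl = np.s_[i * fh : (i + 1) * fh, j * fw : (j + 1) * fw]
            tile_rows.append(
                {
                    "tile_row": i,
                    "tile_col": j,
                    "cyan_area_px": int(masks["cyan"][sl].sum()),
                    "red_area_px": int(masks["red"][sl].sum()),
                }
            )
    centers_df = pd.DataFrame(
        [
            {"channel": ch, "cluster": k, "row": c[0], "col": c[1]}
            for ch, centers in (("cyan", blue_centers), ("red", red_centers))
            for k, c in enumerate(centers)
        ]
    )
    truth = SyntheticSceneTruth(
        masks=masks,
        objects=objects,
        tile_areas=pd.DataFrame(tile_rows),
        cluster_centers=centers_df,
        pixel_size_um=config.pixel_size_um,
    )
    return image, truth


# ---------------------------------------------------------------------------
# 3-D volumes
# ---------------------------------------------------------------------------

#: z/y/x aspect of ellipsoidal cells (slightly flattened along the optical axis)
_ASPECT = (0.7, 1.0, 1.0)

#: placement gap between non-contacting objects, generous enough that their
#: feathered intensity profiles stay separable after thresholding
_VOLUME_GAP_UM = 6.0


def _place_separated(
    rng: np.random.Generator,
    existing: list[tuple[np.ndarray, float]],
    radius_um: float,
    bounds_um: np.ndarray,
    min_gap_um: float,
    max_tries: int = 500,
    margin_um: np.ndarray | None = None,
) -> np.ndarray:
    """Uniform center with at least radius_i + radius_j + gap to all existing.

    ``margin_um`` optionally overrides the per-axis boundary margin (the
    separation radius is still ``radius_um``).
    """
    lo = np.broadcast_to(margin_um if margin_um is not None else radius_um,
                         bounds_um.shape).astype(float)
    hi = bounds_um - lo
    if np.any(hi <= lo):
        raise DataError("objects too large for the volume bounds")
    for _ in range(max_tries):
        pos = rng.uniform(lo, hi)
        ok = all(
            np.linalg.norm(pos - p) >= radius_um + r + min_gap_um for p, r in existing
        )
        if ok:
            return pos
    raise DataError("could not place non-overlapping objects; reduce counts or radii")


def generate_volume(
    config: SceneConfig,
    *,
    blue_volumes_um3: list[float] | None = None,
    red_volumes_um3: list[float] | None = None,
    n_scripted_contacts: int = 0,
    contact_overlap_um: float = 3.0,
) -> tuple[TwoChannelVolume, SyntheticSceneTruth]:
    """Generate a two-channel z-stack of ellipsoidal cells plus ground truth.

    Object volumes may be pinned explicitly per channel (``*_volumes_um3``);
    otherwise they are drawn around the configured mean radii. Truth volumes
    are exact: each blob is rasterized to ``round(V / voxel_volume)`` voxels.
    ``n_scripted_contacts`` blue/red pairs are placed to overlap by
    ``contact_overlap_um`` along one axis; all remaining objects are kept
    separated, so the truth contact table is exhaustive.
    """
    if config.n_z < 2:
        raise ConfigurationError("n_z must be >= 2 for a volume")
    rng = np.random.default_rng(config.seed)
    shape = (config.n_z, *config.field_shape)
    voxel_size = (config.z_step_um, config.pixel_size_um, config.pixel_size_um)
    vv = float(np.prod(voxel_size))
    bounds_um = np.array([s * d for s, d in zip(shape, voxel_size)])

    def volumes_for(n: int, r_mean: float, given) -> list[float]:
        if given is not None:
            return [float(v) for v in given]
        base = 4.0 / 3.0 * np.pi * r_mean**3
        return list(base * rng.lognormal(0.0, 0.25, size=n))

    blue_vols = volumes_for(config.n_blue_cells, config.r_blue_um, blue_volumes_um3)
    red_vols = volumes_for(config.n_red_cells, config.r_red_um, red_volumes_um3)
    if n_scripted_contacts > min(len(blue_vols), len(red_vols)):
        raise ConfigurationError(
            "n_scripted_contacts exceeds available blue/red object count"
        )
    for name, vols in (("blue_volumes_um3", blue_vols), ("red_volumes_um3", red_vols)):
        if any(v <= 0 for v in vols):
            raise ConfigurationError(f"{name} must be positive")

    def eq_radius(v: float) -> float:  # equivalent-sphere radius in µm
        return (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)

    # Place scripted pairs first, then the remaining separated objects.
    placed: list[tuple[np.ndarray, float]] = []
    blue_pos: list[np.ndarray] = []
    red_pos: list[np.ndarray] = []
    contact_rows = []
    for k in range(n_scripted_contacts):
        rb, rr = eq_radius(blue_vols[k]), eq_radius(red_vols[k])
        pair_extent = rb + 2 * rr  # in-plane extent; the pair lies in one z-plane
        z_margin = max(rb, rr) * _ASPECT[0] + voxel_size[0]
        margins = np.array([z_margin, pair_extent, pair_extent])
        center = _place_separated(rng, placed, pair_extent, bounds_um, _VOLUME_GAP_UM,
                                  margin_um=margins)
        axis = np.zeros(3)
        axis[1 + int(rng.integers(2))] = 1.0  # overlap along y or x (in-plane)
        gap = max(rb + rr - contact_overlap_um, 0.0)
        bpos = center - axis * gap / 2.0
        rpos = center + axis * gap / 2.0
        blue_pos.append(bpos)
        red_pos.append(rpos)
        placed.append((center, pair_extent))
        contact_rows.append({"blue_id": k, "red_id": len(blue_vols) + k})
    for k in range(n_scripted_contacts, len(blue_vols)):
        r = eq_radius(blue_vols[k])
        pos = _place_separated(rng, placed, r, bounds_um, _VOLUME_GAP_UM)
        blue_pos.append(pos)
        placed.append((pos, r))
    for k in range(n_scripted_contacts, len(red_vols)):
        r = eq_radius(red_vols[k])
        pos = _place_separated(rng, placed, r, bounds_um, _VOLUME_GAP_UM)
        red_pos.append(pos)
        placed.append((pos, r))

    masks = {ch: np.zeros(shape, dtype=bool) for ch in ("cyan", "red")}
    intensity = {
        ch: np.full(shape, config.background, dtype=np.float64) for ch in ("cyan", "red")
    }
    amp = config.snr * config.background
    rows = []
    oid = 0
    geom_norm = float(np.prod(_ASPECT)) ** (1.0 / 3.0)
    for channel, positions, vols in (
        ("cyan", blue_pos, blue_vols),
        ("red", red_pos, red_vols),
    ):
        for pos_um, vol in zip(positions, vols):
            count = max(1, int(round(vol / vv)))
            r_um = eq_radius(vol) / geom_norm  # semi-axis scale: az*ay*ax = r_eq^3
            center_vox = tuple(p / d for p, d in zip(pos_um, voxel_size))
            radii_vox = tuple(
                a * r_um / d for a, d in zip(_ASPECT, voxel_size)
            )
            vox = _blob_voxels(center_vox, radii_vox, count, shape)
            masks[channel][vox] = True
            _add_soft_blob_3d(intensity[channel], center_vox, radii_vox, amp)
            rows.append(
                {
                    "id": oid,
                    "channel": channel,
                    "centroid_z": center_vox[0],
                    "centroid_y": center_vox[1],
                    "centroid_x": center_vox[2],
                    "rz_vox": radii_vox[0],
                    "ry_vox": radii_vox[1],
                    "rx_vox": radii_vox[2],
                    "voxel_count": count,
                    "volume_um3": count * vv,
                }
            )
            oid += 1
    objects = pd.DataFrame(
        rows,
        columns=[
            "id",
            "channel",
            "centroid_z",
            "centroid_y",
            "centroid_x",
            "rz_vox",
            "ry_vox",
            "rx_vox",
            "voxel_count",
            "volume_um3",
        ],
    )

    for ch in ("cyan", "red"):
        if config.noise_sd > 0:
            intensity[ch] += rng.normal(0.0, config.noise_sd, size=shape)
        intensity[ch] = np.clip(intensity[ch], 0.0, 1.0)

    volume = TwoChannelVolume(
        cyan=intensity["cyan"], red=intensity["red"], voxel_size_um=voxel_size
    )
    contacts = pd.DataFrame(contact_rows, columns=["blue_id", "red_id"])
    if not contacts.empty:
        overlap_counts = []
        for row in contacts.itertuples(index=False):
            b = objects.loc[objects["id"] == row.blue_id].iloc[0]
            r = objects.loc[objects["id"] == row.red_id].iloc[0]
            bset = set(zip(*_blob_voxels(
                (b.centroid_z, b.centroid_y, b.centroid_x),
                (b.rz_vox, b.ry_vox, b.rx_vox), int(b.voxel_count), shape)))
            rset = set(zip(*_blob_voxels(
                (r.centroid_z, r.centroid_y, r.centroid_x),
                (r.rz_vox, r.ry_vox, r.rx_vox), int(r.voxel_count), shape)))
            overlap_counts.append(len(bset & rset))
        contacts["overlap_voxels"] = overlap_counts
    truth = SyntheticSceneTruth(
        masks=masks,
        objects=objects,
        contacts=contacts,
        pixel_size_um=config.pixel_size_um,
        voxel_size_um=voxel_size,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Time-lapse sequences
# ---------------------------------------------------------------------------

def _validate_episodes(
    episodes: list[ContactEpisode], n_blue: int, n_red: int, n_frames: int
) -> None:
    for ep in episodes:
        if not 0 <= ep.blue_id < n_blue:
            raise ConfigurationError(f"episode references invalid blue_id {ep.blue_id}")
        if not 0 <= ep.red_id < n_red:
            raise ConfigurationError(f"episode references invalid red_id {ep.red_id}")
        if ep.start < 0 or ep.end >= n_frames:
            raise ConfigurationError(
                f"episode frames {ep.start}-{ep.end} outside sequence of {n_frames} frames"
            )
    # contradictory scripts: one red object cannot satisfy two partners, and
    # one pair cannot hold two overlapping episodes
    for i, a in enumerate(episodes):
        for b in episodes[i + 1 :]:
            frames_overlap = a.start <= b.end and b.start <= a.end
            if not frames_overlap:
                continue
            same_pair = (a.blue_id, a.red_id) == (b.blue_id, b.red_id)
            shared_red = a.red_id == b.red_id
            if same_pair or shared_red:
                raise ConfigurationError(
                    f"contradictory episodes for red object {a.red_id} "
                    f"in overlapping frame ranges"
                )


def generate_timelapse(
    config: SceneConfig,
    n_frames: int,
    frame_interval_min: float,
    scripted_contacts: list[ContactEpisode] | list[tuple] | None = None,
    *,
    step_sd_um: float = 2.0,
    contact_overlap_um: float = 3.0,
    separation_um: float = 16.0,
) -> tuple[TimeLapse, SyntheticSceneTruth]:
    """Generate a 2-D time-lapse with scripted contact episodes.

    Objects follow a seeded random walk. During a scripted episode the red
    partner is pinned against its blue partner so their disks overlap by
    ``contact_overlap_um``; outside episodes every blue/red pair is kept at
    least ``separation_um`` apart (repulsion), so truth overlap exists in
    exactly the scripted frames.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    if not frame_interval_min > 0:
        raise ConfigurationError("frame_interval_min must be > 0")
    episodes = [
        ep if isinstance(ep, ContactEpisode) else ContactEpisode(*ep)
        for ep in (scripted_contacts or [])
    ]
    _validate_episodes(episodes, config.n_blue_cells, config.n_red_cells, n_frames)

    rng = np.random.default_rng(config.seed)
    shape = config.field_shape
    px = config.pixel_size_um
    h, w = shape
    r_blue = config.r_blue_um / px
    r_red = config.r_red_um / px
    sep = separation_um / px
    step_sd = step_sd_um / px

    # initial placement: all objects mutually separated
    placed: list[tuple[np.ndarray, float]] = []
    bounds = np.array([h - 1.0, w - 1.0])
    blue = np.zeros((config.n_blue_cells, 2))
    red = np.zeros((config.n_red_cells, 2))
    for i in range(config.n_blue_cells):
        pos = _place_separated(rng, placed, r_blue, bounds, sep)
        blue[i] = pos
        placed.append((pos, r_blue))
    for i in range(config.n_red_cells):
        pos = _place_separated(rng, placed, r_red, bounds, sep)
        red[i] = pos
        placed.append((pos, r_red))

    ep_theta = rng.uniform(0.0, 2 * np.pi, size=len(episodes))
    active_by_frame: list[list[int]] = [[] for _ in range(n_frames)]
    for k, ep in enumerate(episodes):
        for t in range(ep.start, ep.end + 1):
            active_by_frame[t].append(k)

    frames: list[TwoChannelImage] = []
    masks = {ch: np.zeros((n_frames, h, w), dtype=bool) for ch in ("cyan", "red")}
    rows = []
    contact_gap = r_blue + r_red - contact_overlap_um / px
    for t in range(n_frames):
        if t > 0:
            blue += rng.normal(0.0, step_sd, size=blue.shape)
            red += rng.normal(0.0, step_sd, size=red.shape)
        np.clip(blue[:, 0], r_blue, h - 1 - r_blue, out=blue[:, 0])
        np.clip(blue[:, 1], r_blue, w - 1 - r_blue, out=blue[:, 1])
        np.clip(red[:, 0], r_red, h - 1 - r_red, out=red[:, 0])
        np.clip(red[:, 1], r_red, w - 1 - r_red, out=red[:, 1])
        pinned_red = {episodes[k].red_id for k in active_by_frame[t]}
        for k in active_by_frame[t]:
            ep = episodes[k]
            u = np.array([np.sin(ep_theta[k]), np.cos(ep_theta[k])])
            red[ep.red_id] = blue[ep.blue_id] + u * contact_gap
            # translate the whole pair back inside so neither disk is clipped
            # by the frame border (which would shrink its area)
            shift = (
                np.clip(red[ep.red_id], r_red, [h - 1 - r_red, w - 1 - r_red])
                - red[ep.red_id]
            )
            red[ep.red_id] += shift
            blue[ep.blue_id] += shift
            shift = (
                np.clip(blue[ep.blue_id], r_blue, [h - 1 - r_blue, w - 1 - r_blue])
                - blue[ep.blue_id]
            )
            red[ep.red_id] += shift
            blue[ep.blue_id] += shift
        # relax all pairs (both channels) to their separation targets; pinned
        # episode partners are immovable, so the other object yields
        pinned_blue = {episodes[k].blue_id for k in active_by_frame[t]}

        def _repel(anchor: np.ndarray, obj: np.ndarray, target: float, r_obj: float):
            d = obj - anchor
            dist = float(np.hypot(*d))
            if dist >= target:
                return None
            # overshoot slightly so chains of repulsions converge instead of
            # re-triggering each other at exactly the target distance
            push = target + 2.0
            u = d / dist if dist > 1e-9 else np.array([1.0, 0.0])
            for direction in (u, -u):
                cand = anchor + direction * push
                cand = np.clip(cand, r_obj, [h - 1 - r_obj, w - 1 - r_obj])
                if float(np.hypot(*(cand - anchor))) >= target - 1e-9:
                    return cand
            return cand  # cramped frame: accept the best effort

        all_objs = [("b", i) for i in range(config.n_blue_cells)] + [
            ("r", j) for j in range(config.n_red_cells)
        ]
        episode_pairs = {
            (episodes[k].blue_id, episodes[k].red_id) for k in active_by_frame[t]
        }
        def _pair_state(ai, bi):
            (ca, ia), (cb, ib) = all_objs[ai], all_objs[bi]
            pa = blue[ia] if ca == "b" else red[ia]
            pb = blue[ib] if cb == "b" else red[ib]
            ra = r_blue if ca == "b" else r_red
            rb_ = r_blue if cb == "b" else r_red
            a_pinned = (ca == "b" and ia in pinned_blue) or (ca == "r" and ia in pinned_red)
            b_pinned = (cb == "b" and ib in pinned_blue) or (cb == "r" and ib in pinned_red)
            scripted = ca == "b" and cb == "r" and (ia, ib) in episode_pairs
            return (ca, ia, pa, ra, a_pinned), (cb, ib, pb, rb_, b_pinned), scripted

        for _ in range(25):
            moved = False
            for ai in range(len(all_objs)):
                for bi in range(ai + 1, len(all_objs)):
                    a, b, scripted = _pair_state(ai, bi)
                    if scripted or (a[4] and b[4]):
                        continue
                    (ca, ia, pa, ra, _), (cb, ib, pb, rb_, b_pinned) = a, b
                    target = ra + rb_ + sep
                    if b_pinned:  # move a instead
                        new = _repel(pb, pa, target, ra)
                        if new is not None:
                            (blue if ca == "b" else red)[ia] = new
                            moved = True
                    else:
                        new = _repel(pa, pb, target, rb_)
                        if new is not None:
                            (blue if cb == "b" else red)[ib] = new
                            moved = True
            if not moved:
                break
        else:
            # relaxation did not converge: re-place each still-violating
            # movable object at a fresh position clear of everything
            for ai in range(len(all_objs)):
                for bi in range(ai + 1, len(all_objs)):
                    a, b, scripted = _pair_state(ai, bi)
                    if scripted or (a[4] and b[4]):
                        continue
                    (ca, ia, pa, ra, _), (cb, ib, pb, rb_, b_pinned) = a, b
                    if float(np.hypot(*(pa - pb))) >= ra + rb_ + sep - 1e-9:
                        continue
                    mv = (ca, ia, ra) if b_pinned else (cb, ib, rb_)
                    others = [
                        (blue[j] if c == "b" else red[j], r_blue if c == "b" else r_red)
                        for c, j in all_objs
                        if (c, j) != (mv[0], mv[1])
                    ]
                    pos = _place_separated(
                        rng, others, mv[2], np.array([h - 1.0, w - 1.0]), sep
                    )
                    (blue if mv[0] == "b" else red)[mv[1]] = pos

        cyan_obj = [((p[0], p[1]), r_blue) for p in blue]
        red_obj = [((p[0], p[1]), r_red) for p in red]
        for ch, objs, ids in (
            ("cyan", cyan_obj, range(config.n_blue_cells)),
            ("red", red_obj, range(config.n_red_cells)),
        ):
            for oid, (center, radius) in zip(ids, objs):
                _paint_disk(masks[ch][t], center, radius)
                rows.append(
                    {
                        "frame": t,
                        "id": oid,
                        "channel": ch,
                        "row": center[0],
                        "col": center[1],
                        "radius_px": radius,
                    }
                )
        cyan_img = _render_intensity_2d(shape, cyan_obj, config, rng)
        red_img = _render_intensity_2d(shape, red_obj, config, rng)
        frames.append(TwoChannelImage(cyan=cyan_img, red=red_img, pixel_size_um=px))

    episodes_df = pd.DataFrame(
        [
            {
                "blue_id": ep.blue_id,
                "red_id": ep.red_id,
                "start_frame": ep.start,
                "end_frame": ep.end,
                "duration_min": ep.n_frames * frame_interval_min,
            }
            for ep in episodes
        ],
        columns=["blue_id", "red_id", "start_frame", "end_frame", "duration_min"],
    )
    truth = SyntheticSceneTruth(
        masks=masks,
        objects=pd.DataFrame(rows, columns=["frame", "id", "channel", "row", "col", "radius_px"]),
        episodes=episodes_df,
        pixel_size_um=px,
    )
    return TimeLapse(frames=frames, frame_interval_min=frame_interval_min), truth


def pair_overlap_pixels(truth: SyntheticSceneTruth, frame: int, blue_id: int, red_id: int) -> int:
    """Truth overlap (pixels) between one blue and one red object in a frame."""
    obj = truth.objects
    sel = obj[obj["frame"] == frame]
    b = sel[(sel["channel"] == "cyan") & (sel["id"] == blue_id)].iloc[0]
    r = sel[(sel["channel"] == "red") & (sel["id"] == red_id)].iloc[0]
    shape = truth.masks["cyan"].shape[1:]
    mb = np.zeros(shape, dtype=bool)
    mr = np.zeros(shape, dtype=bool)
    _paint_disk(mb, (b.row, b.col), b.radius_px)
    _paint_disk(mr, (r.row, r.col), r.radius_px)
    return int((mb & mr).sum())
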