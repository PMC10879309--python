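"""Render simulated ratio traces into synthetic two-channel FRET stacks.

The imaging scene emulates a confocal field of view containing the two
synergid cells (CFP and YFP channels of the ratiometric sensor) and a
red-fluorescent pollen tube approaching them.  Within each cell the CFP
expectation is ``cfp_gain * B(x, y)`` for a smooth within-cell expression
profile ``B``, and the YFP expectation is ``yfp_gain * B(x, y) * ratio(t)``,
so in the noiseless limit the per-pixel YFP/CFP ratio equals the input trace
everywhere inside the cell.  The pollen-tube blob lives in the RED channel
and bleeds a configurable fraction of its intensity into CFP and YFP.
Detector effects (Poisson shot noise, Gaussian read noise, salt-and-pepper
speckle) are applied after scene motion (cumulative frame drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .errors import ConfigError
from .rois import ROISet
from .simulate import GroundTruth
from .stack import CHANNEL_ORDER, ImageStack
from .trace import CalciumTrace

__all__ = ["SceneConfig", "render_stack", "default_polygons"]

#: Intensity written into "salt" speckle pixels (counts).
_SALT_VALUE = 10000.0


def default_polygons(height: int = 64, width: int = 96) -> dict[str, np.ndarray]:
    """Two side-by-side hexagonal synergid cells filling the mid-field."""
    def hexagon(cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
        ang = np.linspace(0, 2 * np.pi, 7)[:-1] + np.pi / 6
        return np.column_stack([cx + rx * np.cos(ang), cy + ry * np.sin(ang)])

    return {
        "left": hexagon(width * 0.32, height * 0.5, width * 0.14, height * 0.32),
        "right": hexagon(width * 0.68, height * 0.5, width * 0.14, height * 0.32),
    }


@dataclass
class SceneConfig:
    """Geometry, gains and noise of the synthetic imaging scene."""

    height: int = 64
    width: int = 96
    synergid_polygons: dict[str, np.ndarray] = field(default_factory=dict)
    cfp_gain: float = 300.0          # counts per unit concentration
    yfp_gain: float = 300.0
    red_peak_intensity: float = 800.0
    bleed_fraction: float = 0.1      # fraction of RED added to CFP and YFP
    drift_per_frame: tuple[float, float] = (0.0, 0.0)   # (dx, dy) px
    speckle_rate: float = 0.001      # fraction of pixels per frame
    read_noise_sd: float = 2.0       # counts
    photon_scaling: float = 1.0      # counts per expected photon; 0 = no shot noise
    red_sigma_px: float = 3.0
    red_path_start: tuple[float, float] | None = None   # (x, y)
    red_path_end: tuple[float, float] | None = None
    red_arrival_frac: float = 0.4    # fraction of the movie spent approaching
    roi_inset_px: float = 3.0        # measurement ROIs are inset from the cell edge

    def __post_init__(self) -> None:
        if not self.synergid_polygons:
            self.synergid_polygons = default_polygons(self.height, self.width)
        if set(self.synergid_polygons) != {"left", "right"}:
            raise ConfigError("synergid_polygons must be labelled left and right")
        if not 0.0 <= self.bleed_fraction < 1.0:
            raise ConfigError("bleed_fraction must lie in [0, 1)")
        if not 0.0 <= self.speckle_rate < 1.0:
            raise ConfigError("speckle_rate must lie in [0, 1)")
        if self.read_noise_sd < 0 or self.photon_scaling < 0:
            raise ConfigError("noise settings must be non-negative")
        polys = {k: Polygon(v) for k, v in self.synergid_polygons.items()}
        if polys["left"].intersects(polys["right"]):
            raise ConfigError("synergid polygons must not overlap")
        ROISet(regions=dict(self.synergid_polygons)).validate_bounds(
            self.height, self.width)

    def noiseless(self) -> "SceneConfig":
        """Copy with every stochastic imaging effect and drift disabled."""
        from dataclasses import replace
        return replace(self, bleed_fraction=0.0, drift_per_frame=(0.0, 0.0),
                       speckle_rate=0.0, read_noise_sd=0.0, photon_scaling=0.0,
                       synergid_polygons={k: v.copy() for k, v
                                          in self.synergid_polygons.items()})


def _expression_profile(mask: np.ndarray) -> np.ndarray:
    """Smooth within-cell brightness: brighter at the centre, dim at the wall.

    The distance-to-wall field is Gaussian-smoothed so the profile has no
    ridges, and the centre-to-wall contrast is mild — sensor expression in a
    cell is fairly uniform, and a gentle gradient keeps intensity curvature
    well below the bright-outlier threshold of the extraction defaults.
    """
    dist = ndimage.gaussian_filter(ndimage.distance_transform_edt(mask), 2.0)
    inside = dist[mask]
    if inside.size and inside.max() > inside.min():
        dist = (dist - inside.min()) / (inside.max() - inside.min())
    return np.where(mask, 0.6 + 0.4 * np.clip(dist, 0.0, 1.0), 0.0)


def _inset_polygon(verts: np.ndarray, inset: float) -> np.ndarray:
    poly = Polygon(verts).buffer(-inset)
    if poly.is_empty:
        raise ConfigError("roi_inset_px erases a synergid polygon entirely")
    coords = np.asarray(poly.exterior.coords[:-1], dtype=float)
    return coords


def _red_blob_track(scene: SceneConfig, n_frames: int) -> np.ndarray:
    """Per-frame (x, y) centre of the pollen-tube blob."""
    if scene.red_path_start is not None:
        start = np.asarray(scene.red_path_start, dtype=float)
    else:
        start = np.array([scene.width - 2.0, scene.height / 2.0])
    if scene.red_path_end is not None:
        end = np.asarray(scene.red_path_end, dtype=float)
    else:
        c_l = np.asarray(Polygon(scene.synergid_polygons["left"]).centroid.coords[0])
        c_r = np.asarray(Polygon(scene.synergid_polygons["right"]).centroid.coords[0])
        end = (c_l + c_r) / 2.0
    arrival = max(int(np.ceil(scene.red_arrival_frac * n_frames)), 1)
    frac = np.minimum(np.arange(n_frames) / arrival, 1.0)
    return start[None, :] + frac[:, None] * (end - start)[None, :]


def render_stack(
    left: CalciumTrace,
    right: CalciumTrace,
    scene: SceneConfig,
    seed: int,
) -> tuple[ImageStack, ROISet, GroundTruth]:
    """Render a left/right trace pair into a 3-channel image stack.

    Returns the stack, the undrifted ground-truth measurement ROIs (inset
    from the cell outline so that small median-filter footprints stay inside
    the cell), and a :class:`GroundTruth` carrying the input ratio traces and
    the cumulative per-frame drift track.
    """
    if len(left) != len(right):
        raise ConfigError(
            f"left and right traces must have equal frame counts "
            f"({len(left)} != {len(right)})")
    n_frames = len(left)
    h, w = scene.height, scene.width
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rois = ROISet(regions={
        label: _inset_polygon(verts, scene.roi_inset_px)
        for label, verts in scene.synergid_polygons.items()})

    cell_masks = {
        label: ROISet(regions={label: verts}).mask(label, h, w)
        for label, verts in scene.synergid_polygons.items()}
    profiles = {label: _expression_profile(mask)
                for label, mask in cell_masks.items()}

    track = _red_blob_track(scene, n_frames)
    cols, rows = np.meshgrid(np.arange(w, dtype=float),
                             np.arange(h, dtype=float))

    dx, dy = scene.drift_per_frame
    drift_track = np.column_stack([np.arange(n_frames) * dx,
                                   np.arange(n_frames) * dy])

    pixels = np.zeros((n_frames, 3, h, w))
    ratios = {"left": left.ratio, "right": right.ratio}
    for t in range(n_frames):
        cfp = np.zeros((h, w))
        yfp = np.zeros((h, w))
        for label in ("left", "right"):
            b = profiles[label]
            cfp += scene.cfp_gain * b
            yfp += scene.yfp_gain * b * ratios[label][t]
        bx, by = track[t]
        red = scene.red_peak_intensity * np.exp(
            -((cols - bx) ** 2 + (rows - by) ** 2) / (2 * scene.red_sigma_px ** 2))
        cfp = cfp + scene.bleed_fraction * red
        yfp = yfp + scene.bleed_fraction * red
        frame = np.stack([cfp, yfp, red])

        off_x, off_y = drift_track[t]
        if off_x or off_y:
            # scene motion: positive (dx, dy) moves content right/down
            frame = np.stack([
                ndimage.shift(ch, (off_y, off_x), order=1, mode="nearest")
                for ch in frame])

        if scene.photon_scaling > 0:
            frame = rng.poisson(frame / scene.photon_scaling) * scene.photon_scaling
        if scene.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, scene.read_noise_sd, frame.shape)
        if scene.speckle_rate > 0:
            hits = rng.random(frame.shape) < scene.speckle_rate
            salt = rng.random(frame.shape) < 0.5
            frame = np.where(hits & salt, _SALT_VALUE, frame)
            frame = np.where(hits & ~salt, 0.0, frame)
        pixels[t] = np.clip(frame, 0.0, None)

    stack = ImageStack(
        pixels=pixels,
        channel_roles={r: i for i, r in enumerate(CHANNEL_ORDER)},
        frame_interval_s=left.frame_interval_s if n_frames >= 2 else 10.0,
    )
    truth = GroundTruth(
        true_transient_times=np.array([]),
        true_amplitudes=np.array([]),
        true_ratio_trace=np.column_stack([left.ratio, right.ratio]),
        drift_track=drift_track,
    )
    return stack, rois, truth
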