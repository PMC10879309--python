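"""The in-memory fluorescence stack and its TIFF round-trip.

A stack is a T x C x H x W intensity grid with named channel roles (CFP and
YFP for the FRET sensor, RED for the pollen-expressed fluorophore) and a
frame interval.  On disk a stack is a multi-page TIFF in T -> C page order
plus a structured-text sidecar (``<file>.meta.yaml``) that records the
channel order and the frame interval, since plain TIFF carries neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import FormatError

__all__ = ["ImageStack", "read_stack", "write_stack", "CHANNEL_ORDER"]

CHANNEL_ORDER = ("CFP", "YFP", "RED")


@dataclass
class ImageStack:
    """A fluorescence time lapse with channel roles and a frame interval."""

    pixels: np.ndarray                              # (T, C, H, W), float
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {r: i for i, r in enumerate(CHANNEL_ORDER)})
    frame_interval_s: float = 10.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4:
            raise FormatError("pixels must be a 4-D (T, C, H, W) array")
        if self.pixels.shape[0] < 1:
            raise FormatError("stack must contain at least one frame")
        indices = sorted(self.channel_roles.values())
        if indices != list(range(self.pixels.shape[1])):
            raise FormatError(
                f"channel_roles {self.channel_roles} must map one role to each "
                f"of the {self.pixels.shape[1]} channels")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise FormatError("intensities must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.pixels.shape

    def channel(self, role: str) -> np.ndarray:
        """The (T, H, W) sub-stack for one channel role."""
        if role not in self.channel_roles:
            raise FormatError(f"stack has no {role!r} channel; roles: "
                              f"{sorted(self.channel_roles)}")
        return self.pixels[:, self.channel_roles[role]]

    def copy(self) -> "ImageStack":
        return ImageStack(self.pixels.copy(), dict(self.channel_roles),
                          self.frame_interval_s)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


def write_stack(stack: ImageStack, path: str | Path,
                dtype: str = "uint16") -> None:
    """Write a stack as multi-page TIFF plus a metadata sidecar.

    ``dtype='uint16'`` (the acquisition bit depth) rounds and clips to
    [0, 65535]; ``dtype='float32'`` preserves fractional intensities.
    """
    path = Path(path)
    data = stack.pixels
    if dtype == "uint16":
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = data.astype(np.float32)
    else:
        raise FormatError(f"unsupported dtype {dtype!r}")
    t, c, h, w = data.shape
    tifffile.imwrite(path, data.reshape(t * c, h, w),
                     photometric="minisblack")
    meta = {
        "n_frames": int(t),
        "n_channels": int(c),
        "channel_roles": {k: int(v) for k, v in stack.channel_roles.items()},
        "frame_interval_s": float(stack.frame_interval_s),
        "page_order": "T->C",
        "dtype": dtype,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack`."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"{path}: missing metadata sidecar {sidecar.name}")
    try:
        meta = yaml.safe_load(sidecar.read_text())
        t, c = int(meta["n_frames"]), int(meta["n_channels"])
        roles = {str(k): int(v) for k, v in meta["channel_roles"].items()}
        interval = float(meta["frame_interval_s"])
    except (yaml.YAMLError, KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{sidecar}: malformed metadata: {exc}") from exc
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"{path}: cannot read TIFF: {exc}") from exc
    pages = np.atleast_3d(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != t * c:
        raise FormatError(
            f"{path}: expected {t * c} pages ({t} frames x {c} channels), "
            f"found {pages.shape[0]}")
    if len(roles) != c or sorted(roles.values()) != list(range(c)):
        raise FormatError(
            f"{path}: {len(roles)} channel roles declared for {c} channels")
    pixels = pages.reshape(t, c, pages.shape[1], pages.shape[2])
    return ImageStack(pixels=pixels, channel_roles=roles,
                      frame_interval_s=interval)
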