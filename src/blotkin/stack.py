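"""Image stack loading and normalization.

An :class:`ImageStack` holds the ordered frames of one membrane recorded at
increasing exposure times.  Gray values are internally scaled to ``[0, 1]``:
integer inputs are divided by their dtype maximum, float inputs are clipped.
Exposure times come from a sidecar table (``file, exposure_s``) or are passed
directly; frames are sorted by exposure time on load.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "StackError",
    "load_stack",
    "from_frames",
    "split_membranes",
    "read_sidecar",
]

#: Gray level at or above which a pixel is treated as saturated.
SATURATION_LEVEL = 1.0 - 1e-4

#: A spot-frame is excluded from fitting when more than this fraction of its
#: spot-box pixels is saturated: clipping starts biasing the cumulative
#: signal the moment any pixel hits the ceiling, so the threshold is one
#: pixel of a default 30-px box.
MAX_SATURATED_FRACTION = 0.001


class StackError(ValueError):
    """Raised for malformed image stacks or metadata."""


@dataclass
class ImageStack:
    """Ordered gray-value frames of one membrane.

    ``frames`` has shape ``(n_frames, height, width)`` with values in
    ``[0, 1]``; ``exposure_times`` (seconds) is strictly increasing.  When the
    source carried no exposure metadata, placeholder times ``1..n`` are used
    and ``times_known`` is False; the kinetic mode refuses such stacks.
    """

    frames: np.ndarray
    exposure_times: np.ndarray
    source_depth: int | None = None
    name: str = ""
    times_known: bool = True

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise StackError(f"frames must be 3-D (n, h, w), got shape "
                             f"{frames.shape}")
        times = np.asarray(self.exposure_times, dtype=np.float64)
        if times.ndim != 1 or times.size != frames.shape[0]:
            raise StackError(
                f"need one exposure time per frame: {times.size} times for "
                f"{frames.shape[0]} frames")
        if frames.size and (frames.min() < 0.0 or frames.max() > 1.0):
            raise StackError("frame values must lie within [0, 1]; "
                             "use load_stack/from_frames to normalize")
        if np.any(times <= 0):
            raise StackError("exposure times must all be positive")
        if np.any(np.diff(times) <= 0):
            raise StackError("exposure times must be strictly increasing "
                             f"(got {times.tolist()})")
        self.frames = frames
        self.exposure_times = times

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def saturation_fraction(self) -> np.ndarray:
        """Per-frame fraction of pixels at the saturation level."""
        return (self.frames >= SATURATION_LEVEL).mean(axis=(1, 2))

    def with_frames(self, frames: np.ndarray, **kwargs) -> "ImageStack":
        """Copy with replaced frames (and optionally other fields)."""
        return replace(self, frames=frames, **kwargs)


def from_frames(frames: np.ndarray | Sequence[np.ndarray],
                times: Sequence[float] | None = None,
                *, name: str = "",
                source_depth: int | None = None) -> ImageStack:
    """Build a normalized stack from in-memory frames.

    Integer arrays are scaled by ``1 / (2**depth - 1)``; float arrays are
    clipped to ``[0, 1]`` (idempotent for data already in range).  Frames are
    sorted by exposure time.
    """
    arr = np.stack([np.asarray(f) for f in frames])
    if arr.ndim != 3:
        raise StackError(f"expected 2-D frames, got stacked shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        depth = info.bits if source_depth is None else source_depth
        arr = arr.astype(np.float64) / float(2 ** depth - 1)
        arr = np.clip(arr, 0.0, 1.0)
    else:
        depth = source_depth
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    times_known = times is not None
    if times is None:
        t = np.arange(1.0, arr.shape[0] + 1.0)
    else:
        t = np.asarray(list(times), dtype=np.float64)
        if t.size != arr.shape[0]:
            raise StackError(f"{t.size} exposure times for {arr.shape[0]} frames")
        if np.unique(t).size != t.size:
            raise StackError(f"duplicate exposure times: {sorted(t.tolist())}")
        order = np.argsort(t)
        arr, t = arr[order], t[order]
    return ImageStack(frames=arr, exposure_times=t, source_depth=depth,
                      name=name, times_known=times_known)


def read_sidecar(path: str | Path) -> dict[str, float]:
    """Read a sidecar CSV with columns ``file, exposure_s``."""
    path = Path(path)
    out: dict[str, float] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"file", "exposure_s"} <= set(
                reader.fieldnames):
            raise StackError(
                f"sidecar {path} must have columns 'file' and 'exposure_s'")
        for row in reader:
            key = row["file"].strip()
            if key in out:
                raise StackError(f"sidecar {path}: duplicate entry for {key!r}")
            out[key] = float(row["exposure_s"])
    return out


def _read_image(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            return tifffile.imread(path)
        return np.asarray(iio.imread(path))
    except Exception as exc:  # undecodable file
        raise StackError(f"could not decode image {path}: {exc}") from exc


def load_stack(paths: str | Path | Sequence[str | Path],
               times: Sequence[float] | None = None,
               sidecar: str | Path | None = None,
               *, name: str = "") -> ImageStack:
    """Load an image series or multi-page TIFF into an :class:`ImageStack`.

    Parameters
    ----------
    paths : path or sequence of paths
        A single multi-page TIFF, or an ordered series of single-frame images
        (TIFF/PNG).
    times : sequence of float, optional
        Exposure time in seconds per frame, in the given frame order.
    sidecar : path, optional
        CSV with columns ``file, exposure_s`` mapping file names to exposure
        times (single-frame series only).  Ignored when ``times`` is given.
    """
    if isinstance(paths, (str, Path)):
        path = Path(paths)
        arr = _read_image(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise StackError(f"{path}: unsupported image dimensionality "
                             f"{arr.ndim}")
        return from_frames(arr, times, name=name or path.stem)

    path_list = [Path(p) for p in paths]
    frames = []
    for p in path_list:
        img = _read_image(p)
        if img.ndim != 2:
            raise StackError(f"{p}: expected a single-frame 2-D image, got "
                             f"shape {img.shape}")
        frames.append(img)
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise StackError(f"frames have mixed dimensions: {sorted(shapes)}")
    dtypes = {f.dtype for f in frames}
    if len(dtypes) > 1:
        raise StackError(f"frames have mixed dtypes: {sorted(map(str, dtypes))}")
    if times is None and sidecar is not None:
        table = read_sidecar(sidecar)
        try:
            times = [table[p.name] for p in path_list]
        except KeyError as exc:
            raise StackError(f"sidecar {sidecar} has no exposure time for "
                             f"{exc.args[0]!r}") from exc
    return from_frames(np.stack(frames), times,
                       name=name or path_list[0].stem)


def split_membranes(stack: ImageStack,
                    regions: Sequence[tuple[int, int, int, int]]
                    ) -> list[ImageStack]:
    """Split a stack holding several membranes into per-region sub-stacks.

    ``regions`` are ``(row_start, row_stop, col_start, col_stop)`` rectangles
    in pixel coordinates (half-open).  Exposure times are preserved.
    """
    h, w = stack.frame_shape
    out = []
    for i, (r0, r1, c0, c1) in enumerate(regions):
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise StackError(
                f"region {(r0, r1, c0, c1)} is degenerate or exceeds the "
                f"frame bounds {(h, w)}")
        out.append(ImageStack(
            frames=stack.frames[:, r0:r1, c0:c1].copy(),
            exposure_times=stack.exposure_times.copy(),
            source_depth=stack.source_depth,
            name=f"{stack.name}-m{i}" if stack.name else f"membrane-{i}",
            times_known=stack.times_known,
        ))
    return out
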