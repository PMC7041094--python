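"""Fallback evaluation modes for stacks without exposure-time metadata.

When exposure times are unavailable the kinetic model cannot be fitted; the
signals can still be ranked.  Three spot-level summaries are provided:

raw
    Per spot and frame, the mean gray value of the spot square on the
    original (aligned) images, with the histogram background ``b`` exported
    alongside for optional deduction.
local_bg
    Mean over frames of the ratio between a spot's average on the raw image
    and its average on a morphologically extracted background (grayscale
    opening with a disc larger than any spot).
correlation
    Per spot, the ordinary-least-squares slope of the spot average against
    the frame's histogram background value -- a unitless relative brightness
    growth measure (the Pearson correlation is reported alongside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import morphology

from .background import BIN_WIDTH, estimate_background
from .layout import ArrayLayout
from .stack import ImageStack

__all__ = [
    "ModeResult",
    "ModeError",
    "raw_mode",
    "morphological_background",
    "local_bg_mode",
    "correlation_mode",
    "evaluate_mode",
    "MODES",
]


class ModeError(RuntimeError):
    """Raised for invalid inputs to an evaluation mode."""


@dataclass
class ModeResult:
    """Per-spot values of one evaluation mode.

    ``values`` has one row per grid spot (row-major): shape
    ``(n_spots, n_frames)`` for raw mode, ``(n_spots,)`` otherwise.  Missing
    or degenerate spots are NaN and flagged in ``flags``.
    """

    mode: str
    spots: list[tuple[int, int]]
    values: np.ndarray
    flags: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    extras: dict = field(default_factory=dict)

    def scalar_per_spot(self) -> np.ndarray:
        """One scalar per spot: the final-frame value for raw mode, the
        values themselves otherwise."""
        if self.values.ndim == 2:
            return self.values[:, -1]
        return self.values

    def as_dict(self) -> dict[tuple[int, int], float]:
        return {rc: float(v) for rc, v in zip(self.spots,
                                              self.scalar_per_spot())}


def _spot_means(frames: np.ndarray, layout: ArrayLayout) -> np.ndarray:
    """(n_spots, n_frames) mean gray value per spot square."""
    sb = layout.spot_box
    expected = layout.grid_shape
    if frames.shape[1:] != expected:
        raise ModeError(f"stack shape {frames.shape[1:]} does not match the "
                        f"layout's aligned geometry {expected}")
    n_r, n_c = layout.n_rows, layout.n_cols
    # reshape to (frames, rows, sb, cols, sb) and average the box axes
    boxed = frames.reshape(frames.shape[0], n_r, sb, n_c, sb)
    means = boxed.mean(axis=(2, 4))            # (frames, rows, cols)
    return means.reshape(frames.shape[0], -1).T


def raw_mode(aligned: ImageStack, layout: ArrayLayout) -> ModeResult:
    """Averaged gray values per spot on every original image in the stack.

    No background subtraction is applied; the histogram background ``b`` of
    every frame is exported in ``extras['background_b']`` so deduction
    remains possible downstream.
    """
    if aligned.n_frames == 0:
        raise ModeError("empty stack")
    values = _spot_means(aligned.frames, layout)
    b = np.array([estimate_background(f).b for f in aligned.frames])
    return ModeResult(mode="raw", spots=layout.grid_spots, values=values,
                      flags=np.zeros(values.shape[0], dtype=bool),
                      extras={"background_b": b,
                              "exposure_times": aligned.exposure_times.copy()})


def morphological_background(frame: np.ndarray, spot_box: int,
                             footprint_scale: float = 1.5
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Split a frame into foreground and background by grayscale opening.

    The structuring element is a disc of diameter ``footprint_scale *
    spot_box`` -- larger than any spot, so opening removes the spots and
    leaves the smooth background.  Returns ``(foreground, background)`` with
    ``foreground = frame - background`` clipped at 0.  Spots wider than the
    disc leak into the background (inherent to the operator).
    """
    frame = np.asarray(frame, dtype=np.float64)
    radius = max(1, int(round(footprint_scale * spot_box / 2.0)))
    if min(frame.shape) < 2 * radius + 1:
        raise ModeError(f"frame {frame.shape} is smaller than the "
                        f"structuring element (radius {radius} px)")
    bg = morphology.opening(frame, morphology.disk(radius))
    fg = np.clip(frame - bg, 0.0, None)
    return fg, bg


def local_bg_mode(aligned: ImageStack, layout: ArrayLayout,
                  footprint_scale: float = 1.5) -> ModeResult:
    """Mean over frames of the spot-average ratio raw / morphological
    background.  Frames where a spot's background average falls below one
    histogram bin width (1/2048) are skipped; spots with no usable frame are
    flagged NaN."""
    if aligned.n_frames == 0:
        raise ModeError("empty stack")
    raw_means = _spot_means(aligned.frames, layout)
    bg_frames = np.stack([
        morphological_background(f, layout.spot_box, footprint_scale)[1]
        for f in aligned.frames])
    bg_means = _spot_means(bg_frames, layout)

    usable = bg_means >= BIN_WIDTH
    ratios = np.divide(raw_means, bg_means,
                       out=np.full_like(raw_means, np.nan), where=usable)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN spots
        values = np.nanmean(np.where(usable, ratios, np.nan), axis=1)
    flags = ~usable.any(axis=1)
    values[flags] = np.nan
    return ModeResult(mode="local_bg", spots=layout.grid_spots, values=values,
                      flags=flags,
                      extras={"n_skipped": (~usable).sum(axis=1)})


def correlation_mode(aligned: ImageStack, layout: ArrayLayout) -> ModeResult:
    """OLS slope of each spot's average against the frame background ``b``.

    Requires at least 3 frames.  A degenerate background series (no spread)
    leaves every spot flagged.  The Pearson correlation coefficient per spot
    is reported in ``extras['pearson_r']``.
    """
    if aligned.n_frames < 3:
        raise ModeError(f"correlation mode needs >= 3 frames, got "
                        f"{aligned.n_frames}")
    means = _spot_means(aligned.frames, layout)
    b = np.array([estimate_background(f).b for f in aligned.frames])
    var_b = float(np.var(b))
    n_spots = means.shape[0]
    if var_b == 0.0:
        values = np.full(n_spots, np.nan)
        return ModeResult(mode="correlation", spots=layout.grid_spots,
                          values=values,
                          flags=np.ones(n_spots, dtype=bool),
                          extras={"background_b": b, "degenerate_b": True,
                                  "pearson_r": np.full(n_spots, np.nan)})
    centered_b = b - b.mean()
    centered_m = means - means.mean(axis=1, keepdims=True)
    cov = centered_m @ centered_b / b.size
    slopes = cov / var_b
    std_m = centered_m.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.where(std_m > 0, cov / (std_m * np.sqrt(var_b)), np.nan)
    return ModeResult(mode="correlation", spots=layout.grid_spots,
                      values=slopes,
                      flags=np.zeros(n_spots, dtype=bool),
                      extras={"background_b": b, "degenerate_b": False,
                              "pearson_r": pearson})


MODES = {
    "raw": raw_mode,
    "local_bg": local_bg_mode,
    "correlation": correlation_mode,
}


def evaluate_mode(aligned: ImageStack, layout: ArrayLayout,
                  mode: str, **kwargs) -> ModeResult:
    """Dispatch to an evaluation mode by name (raw | local_bg |
    correlation)."""
    try:
        fn = MODES[mode]
    except KeyError:
        raise ModeError(f"unknown mode {mode!r}; available: "
                        f"{', '.join(sorted(MODES))}") from None
    return fn(aligned, layout, **kwargs)
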