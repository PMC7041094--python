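"""Landmark-based membrane alignment.

The bright reference spots at the membrane edges serve as landmarks.  Their
outlines are extracted with the marching-squares iso-contour algorithm at 60%
of the frame's maximum gray value; each contour's vertex centroid is a
candidate anchor.  Three initial guesses are formed from the componentwise
extremes of the candidate centers,

    G1 = (min Cx, min Cy),   G2 = (min Cx, max Cy),   G3 = (max Cx, min Cy),

the nearest center to each guess becomes an anchor, and the anchor triple is
validated against the layout's expected side ratios, corner angle and
guess-to-anchor distance before the frame is warped (affine, bilinear) so
that every spot sits centered in its ``spot_box`` square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, transform

from .layout import ArrayLayout, canonical_anchor_positions, triangle_geometry
from .stack import ImageStack

__all__ = [
    "ContourCenter",
    "AnchorCheck",
    "AnchorSet",
    "AlignmentError",
    "detect_contour_centers",
    "initial_guesses",
    "select_anchors",
    "warp_and_trim",
    "align_stack",
]

CONTOUR_LEVEL_FRACTION = 0.6


class AlignmentError(RuntimeError):
    """Raised when anchors cannot be found or fail validation."""


@dataclass(frozen=True)
class ContourCenter:
    """Centroid of one closed iso-contour. ``x`` is the column coordinate,
    ``y`` the row coordinate; ``contour_area`` the enclosed area in px^2."""

    x: float
    y: float
    contour_area: float

    @property
    def point(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class AnchorCheck:
    name: str
    passed: bool
    measured: float
    expected: float
    tolerance: float

    def __str__(self) -> str:
        state = "ok" if self.passed else "FAILED"
        return (f"{self.name}: measured {self.measured:.4g}, expected "
                f"{self.expected:.4g} (tol {self.tolerance:.4g}) -> {state}")


@dataclass
class AnchorSet:
    """Initial guesses, selected anchors and validation-check outcomes."""

    guesses: np.ndarray                  # (3, 2) of (x, y)
    anchors: list[ContourCenter]
    checks: dict[str, AnchorCheck] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks.values())

    @property
    def anchor_points(self) -> np.ndarray:
        """Anchor coordinates as an ``(3, 2)`` array of ``(x, y)``."""
        return np.array([[a.x, a.y] for a in self.anchors])

    def failed_checks(self) -> list[AnchorCheck]:
        return [c for c in self.checks.values() if not c.passed]


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (row, col) vertices."""
    y, x = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def detect_contour_centers(frame: np.ndarray,
                           level_fraction: float = CONTOUR_LEVEL_FRACTION
                           ) -> list[ContourCenter]:
    """Find iso-contour centers at ``level_fraction`` of the frame maximum.

    The frame is padded with its minimum value so contours touching the
    border close along it.  Each center is the arithmetic mean of its contour
    vertices; centers are returned sorted by descending enclosed area.
    """
    frame = np.asarray(frame, dtype=np.float64)
    vmax, vmin = float(frame.max()), float(frame.min())
    if vmax <= vmin:
        raise AlignmentError("cannot detect contours on a constant frame")
    level = level_fraction * vmax
    padded = np.pad(frame, 1, mode="constant", constant_values=vmin)
    centers = []
    for contour in measure.find_contours(padded, level):
        verts = contour - 1.0  # undo padding offset
        if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
            closed = verts
            verts = verts[:-1]  # centroid must not double-count the seam
        else:
            closed = np.vstack([verts, verts[:1]])
        area = _polygon_area(closed[:-1])
        if area <= 0:
            continue
        cy, cx = verts.mean(axis=0)
        h, w = frame.shape
        centers.append(ContourCenter(x=float(np.clip(cx, 0, w - 1)),
                                     y=float(np.clip(cy, 0, h - 1)),
                                     contour_area=area))
    if not centers:
        raise AlignmentError(
            f"no closed contours found at level {level:.4g} "
            f"({level_fraction:.0%} of max {vmax:.4g})")
    centers.sort(key=lambda c: (-c.contour_area, c.y, c.x))
    return centers


def initial_guesses(centers: list[ContourCenter]) -> np.ndarray:
    """First-guess anchor positions from the componentwise extremes of the
    contour centers: rows are G1, G2, G3 as ``(x, y)``."""
    if len(centers) < 3:
        raise AlignmentError(
            f"need at least 3 contour centers for initial guesses, got "
            f"{len(centers)}")
    xs = np.array([c.x for c in centers])
    ys = np.array([c.y for c in centers])
    return np.array([
        [xs.min(), ys.min()],   # G1: top-left
        [xs.min(), ys.max()],   # G2: bottom-left
        [xs.max(), ys.min()],   # G3: top-right
    ])


def _nearest_center(centers: list[ContourCenter],
                    guess: np.ndarray) -> ContourCenter:
    # Tie-break equidistant candidates by larger area, then lower (y, x).
    best = min(centers, key=lambda c: (np.hypot(c.x - guess[0], c.y - guess[1]),
                                       -c.contour_area, c.y, c.x))
    return best


def select_anchors(centers: list[ContourCenter],
                   guesses: np.ndarray,
                   layout: ArrayLayout,
                   frame_shape: tuple[int, int],
                   *, strict: bool = True) -> AnchorSet:
    """Select the nearest center to each guess and run the three validity
    checks: pairwise side ratios, corner angle, and guess-anchor distance.

    With ``strict`` (default) a failed check raises :class:`AlignmentError`
    carrying the measured values; otherwise the failures are only recorded in
    the returned :class:`AnchorSet`.
    """
    if len(centers) < 3:
        raise AlignmentError(f"need at least 3 contour centers, got "
                             f"{len(centers)}")
    anchors = [_nearest_center(centers, g) for g in np.asarray(guesses, float)]
    pts = {(a.x, a.y) for a in anchors}
    if len(pts) != 3:
        raise AlignmentError(
            "ambiguous anchors: two initial guesses selected the same "
            f"contour center (anchors at {sorted(pts)})")

    anchor_set = AnchorSet(guesses=np.asarray(guesses, float), anchors=anchors)
    # (row, col) points, A1 first so the angle is measured at the corner.
    tri = np.array([[a.y, a.x] for a in anchors])
    ratios, angle = triangle_geometry(tri)
    exp_ratios, exp_angle = layout.expected_geometry()
    exp_sorted = sorted(exp_ratios)

    for i, (meas, exp) in enumerate(zip(ratios, exp_sorted), start=1):
        rel = abs(meas - exp) / exp
        anchor_set.checks[f"side_ratio_{i}"] = AnchorCheck(
            name=f"side_ratio_{i}", passed=rel <= layout.ratio_tol,
            measured=meas, expected=exp, tolerance=layout.ratio_tol)
    anchor_set.checks["angle"] = AnchorCheck(
        name="angle", passed=abs(angle - exp_angle) <= layout.angle_tol,
        measured=angle, expected=exp_angle, tolerance=layout.angle_tol)
    diag = float(np.hypot(*frame_shape))
    max_dist = max(float(np.hypot(a.x - g[0], a.y - g[1]))
                   for a, g in zip(anchors, anchor_set.guesses))
    anchor_set.checks["guess_distance"] = AnchorCheck(
        name="guess_distance",
        passed=max_dist <= layout.guess_dist_tol * diag,
        measured=max_dist, expected=layout.guess_dist_tol * diag,
        tolerance=layout.guess_dist_tol * diag)

    if strict and not anchor_set.passed:
        failed = "; ".join(str(c) for c in anchor_set.failed_checks())
        raise AlignmentError(f"anchor validation rejected the alignment: "
                             f"{failed}")
    return anchor_set


def warp_and_trim(frame: np.ndarray,
                  anchors: AnchorSet,
                  layout: ArrayLayout) -> np.ndarray:
    """Warp the frame with the affine transform mapping the anchors onto
    their canonical positions and trim to ``layout.grid_shape``.

    Bilinear interpolation; pixels outside the source are filled with 0.
    """
    dst_rc = canonical_anchor_positions(layout)
    dst_xy = dst_rc[:, ::-1]
    src_xy = anchors.anchor_points
    # tform maps canonical (output) coordinates to source coordinates, which
    # is the inverse map skimage.transform.warp expects.
    tform = transform.AffineTransform.from_estimate(dst_xy, src_xy)
    if not tform or not np.all(np.isfinite(tform.params)) or \
            abs(np.linalg.det(tform.params[:2, :2])) < 1e-12:
        raise AlignmentError(
            f"anchor triple is degenerate (collinear?): {src_xy.tolist()}")
    return transform.warp(np.asarray(frame, dtype=np.float64), tform,
                          output_shape=layout.grid_shape, order=1,
                          mode="constant", cval=0.0, preserve_range=True)


def _has_contrast(frame: np.ndarray, n_mads: float = 10.0) -> bool:
    """Whether the contour level clears the background value distribution.

    Anchor centroids on frames whose spots barely exceed the noise floor
    jitter by several pixels; such frames are better served by anchors
    borrowed from a high-contrast exposure.
    """
    level = CONTOUR_LEVEL_FRACTION * float(frame.max())
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    return level > med + n_mads * mad


def _detect_and_select(frame: np.ndarray, layout: ArrayLayout) -> AnchorSet:
    centers = detect_contour_centers(frame)
    guesses = initial_guesses(centers)
    return select_anchors(centers, guesses, layout, frame.shape)


def align_stack(stack: ImageStack, layout: ArrayLayout,
                *, return_anchors: bool = False):
    """Align every frame of a stack to the layout's canonical geometry.

    Anchors are detected and validated per frame (the membrane may drift
    between exposures).  Frames where detection or validation fails borrow
    the anchors of the nearest exposure with a valid anchor set: early
    frames may be too dim for contours, while on long exposures fast
    (high-``C_E``) reference spots can fall below the contour level because
    their luminol is depleted.  Exposure times are preserved.

    Returns the aligned stack, or ``(aligned, anchor_sets)`` when
    ``return_anchors`` is set.
    """
    frames = stack.frames
    k = (layout.rotation_hint // 90) % 4
    if k:
        frames = np.stack([np.rot90(f, k=-k) for f in frames])

    detected: list[AnchorSet | None] = []
    errors: list[str] = []
    for i, frame in enumerate(frames):
        try:
            if not _has_contrast(frame):
                raise AlignmentError(
                    "contour level does not stand clear of the background "
                    "distribution (low-contrast frame)")
            detected.append(_detect_and_select(frame, layout))
        except AlignmentError as exc:
            detected.append(None)
            errors.append(f"frame {i}: {exc}")
    valid = [i for i, a in enumerate(detected) if a is not None]
    if not valid:
        raise AlignmentError(
            "no frame yields a valid anchor set; per-frame failures: "
            + "; ".join(errors[:3]))

    # Cross-frame consistency guard: the three per-frame checks cannot catch
    # an anchor that slipped by one grid pitch (the triangle changes by only
    # a few percent), so anchors far from the across-frame median position
    # are treated as failed detections too.
    if len(valid) >= 3:
        pts = np.stack([detected[i].anchor_points for i in valid])
        med = np.median(pts, axis=0)
        tol = layout.spot_box / 3.0
        keep = [i for i, p in zip(valid, pts)
                if np.abs(p - med).max() <= tol]
        if keep and len(keep) < len(valid):
            for i in set(valid) - set(keep):
                warnings.warn(
                    f"frame {i}: anchors deviate from the cross-frame "
                    f"median by more than {tol:.0f} px, discarding",
                    stacklevel=2)
                detected[i] = None
            valid = keep

    aligned = np.empty((stack.n_frames, *layout.grid_shape))
    anchor_sets: list[AnchorSet] = []
    for i, frame in enumerate(frames):
        anchor_set = detected[i]
        if anchor_set is None:
            j = min(valid, key=lambda v: (abs(v - i), v))
            warnings.warn(
                f"frame {i} (t={stack.exposure_times[i]:g} s): anchor "
                f"detection failed, reusing anchors of frame {j}",
                stacklevel=2)
            anchor_set = detected[j]
        aligned[i] = warp_and_trim(frame, anchor_set, layout)
        anchor_sets.append(anchor_set)

    out = ImageStack(frames=np.clip(aligned, 0.0, 1.0),
                     exposure_times=stack.exposure_times.copy(),
                     source_depth=stack.source_depth,
                     name=stack.name, times_known=stack.times_known)
    if return_anchors:
        return out, anchor_sets
    return out
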