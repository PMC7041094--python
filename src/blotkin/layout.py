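"""Membrane array layouts.

An :class:`ArrayLayout` describes the geometry of one membrane type: the spot
grid, the always-bright reference spots used as alignment landmarks, the map
from grid coordinates to analyte names, and the expectations (side ratios,
corner angle, guess distance) against which a detected anchor triple is
validated before the image is warped.

Coordinate convention used throughout the package: grid coordinates are
``(row, col)``, 0-based, origin top-left.  In pixel space ``X`` is the column
index and ``Y`` the row index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ArrayLayout",
    "LayoutError",
    "load_layout",
    "save_layout",
    "builtin_layouts",
    "get_layout",
    "canonical_anchor_positions",
]

DEFAULT_SPOT_BOX = 30


class LayoutError(ValueError):
    """Raised when a layout file or layout definition is invalid."""


@dataclass(frozen=True)
class ArrayLayout:
    """Geometry and naming of a membrane array.

    Parameters
    ----------
    name : str
        Human-readable layout identifier.
    n_rows, n_cols : int
        Shape of the spot grid.
    spot_box : int
        Side length in pixels of the square each spot is centered in after
        alignment (default 30).
    reference_spots : tuple of (row, col)
        Grid coordinates of the always-bright reference spots; at least three
        are required for a full alignment.
    analytes : dict
        Map ``(row, col) -> analyte name``.  Spots that share a name are
        treated as duplicates and averaged in reports.  Unlisted spots get an
        auto-generated name; unlisted reference spots are named ``"REF"``.
    expected_side_ratios : tuple of two floats, optional
        Expected pairwise anchor-distance ratios relative to the longest side.
        ``None`` means "compute from the reference-spot geometry".
    expected_angle : float
        Expected angle (degrees) at the corner anchor; default 90.
    ratio_tol, angle_tol, guess_dist_tol : float
        Tolerances of the three anchor-validation checks: relative tolerance
        on each side ratio, absolute tolerance in degrees on the angle, and
        the maximum allowed guess-to-anchor distance as a fraction of the
        image diagonal.
    rotation_hint : int
        Coarse rotation in multiples of 90 degrees applied before detection.
    """

    name: str
    n_rows: int
    n_cols: int
    reference_spots: tuple[tuple[int, int], ...]
    spot_box: int = DEFAULT_SPOT_BOX
    analytes: dict[tuple[int, int], str] = field(default_factory=dict)
    expected_side_ratios: tuple[float, float] | None = None
    expected_angle: float = 90.0
    ratio_tol: float = 0.15
    angle_tol: float = 10.0
    guess_dist_tol: float = 0.10
    rotation_hint: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise LayoutError(f"layout {self.name!r}: grid must be positive, "
                              f"got {self.n_rows}x{self.n_cols}")
        if self.spot_box < 3:
            raise LayoutError(f"layout {self.name!r}: spot_box must be >= 3, "
                              f"got {self.spot_box}")
        refs = tuple(tuple(int(v) for v in rc) for rc in self.reference_spots)
        object.__setattr__(self, "reference_spots", refs)
        if len(refs) < 3:
            raise LayoutError(
                f"layout {self.name!r}: at least 3 reference spots are "
                f"required for alignment, got {len(refs)}")
        for rc in refs:
            self._check_coord(rc, "reference_spots")
        analytes = {tuple(int(v) for v in rc): str(name)
                    for rc, name in self.analytes.items()}
        for rc in analytes:
            self._check_coord(rc, "analytes")
        object.__setattr__(self, "analytes", analytes)
        for fname in ("ratio_tol", "angle_tol", "guess_dist_tol"):
            if getattr(self, fname) <= 0:
                raise LayoutError(f"layout {self.name!r}: {fname} must be "
                                  f"strictly positive")
        if not 0.0 < self.expected_angle < 180.0:
            raise LayoutError(f"layout {self.name!r}: expected_angle must lie "
                              f"in (0, 180) degrees, got {self.expected_angle}")
        if self.expected_side_ratios is not None:
            ratios = tuple(float(r) for r in self.expected_side_ratios)
            if len(ratios) != 2 or any(r <= 0 for r in ratios):
                raise LayoutError(f"layout {self.name!r}: expected_side_ratios "
                                  f"must be two positive reals, got {ratios}")
            object.__setattr__(self, "expected_side_ratios", ratios)
        if self.rotation_hint % 90 != 0:
            raise LayoutError(f"layout {self.name!r}: rotation_hint must be a "
                              f"multiple of 90 degrees")

    def _check_coord(self, rc: tuple[int, int], where: str) -> None:
        r, c = rc
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise LayoutError(
                f"layout {self.name!r}: {where} coordinate {rc} outside the "
                f"{self.n_rows}x{self.n_cols} grid")

    # -- derived geometry ---------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int]:
        """Pixel shape of the aligned, trimmed frame."""
        return (self.n_rows * self.spot_box, self.n_cols * self.spot_box)

    @property
    def grid_spots(self) -> list[tuple[int, int]]:
        """All grid coordinates, row-major."""
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def analyte_name(self, spot: tuple[int, int]) -> str:
        """Analyte name of a spot (auto-generated when not configured)."""
        rc = (int(spot[0]), int(spot[1]))
        if rc in self.analytes:
            return self.analytes[rc]
        if rc in self.reference_spots:
            return "REF"
        return f"spot-r{rc[0]}c{rc[1]}"

    def spot_center(self, spot: tuple[int, int]) -> tuple[float, float]:
        """Pixel center ``(row, col)`` of a spot in the aligned frame."""
        r, c = spot
        return ((r + 0.5) * self.spot_box, (c + 0.5) * self.spot_box)

    def alignment_reference_spots(self) -> tuple[tuple[int, int], ...]:
        """The three reference spots used as alignment anchors.

        Chosen to match the initial-guess pattern in pixel space: the
        reference spots closest to the top-left, bottom-left and top-right
        corners of the reference bounding box, in that order.
        """
        refs = np.asarray(self.reference_spots, dtype=float)
        r_min, c_min = refs.min(axis=0)
        r_max, c_max = refs.max(axis=0)
        targets = [(r_min, c_min), (r_max, c_min), (r_min, c_max)]
        chosen: list[tuple[int, int]] = []
        for tr, tc in targets:
            d = np.hypot(refs[:, 0] - tr, refs[:, 1] - tc)
            order = np.lexsort((refs[:, 1], refs[:, 0], d))
            chosen.append(tuple(int(v) for v in refs[order[0]]))
        if len(set(chosen)) != 3:
            raise LayoutError(
                f"layout {self.name!r}: reference spots {self.reference_spots} "
                f"do not provide three distinct alignment corners")
        return tuple(chosen)

    def expected_geometry(self) -> tuple[tuple[float, float], float]:
        """Expected (side ratios, corner angle) for anchor validation.

        When ``expected_side_ratios`` is not configured it is derived from the
        canonical positions of the three alignment reference spots.
        """
        if self.expected_side_ratios is not None:
            return self.expected_side_ratios, self.expected_angle
        pts = canonical_anchor_positions(self)
        ratios, _ = triangle_geometry(pts)
        return ratios, self.expected_angle


def triangle_geometry(points: np.ndarray) -> tuple[tuple[float, float], float]:
    """Side ratios (sorted, relative to the longest side) and angle at the
    first point, for a triple of ``(row, col)`` points."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in points)
    d12 = float(np.hypot(*(p1 - p2)))
    d13 = float(np.hypot(*(p1 - p3)))
    d23 = float(np.hypot(*(p2 - p3)))
    dists = sorted([d12, d13, d23])
    if dists[0] <= 0 or dists[2] <= 0:
        raise LayoutError("degenerate anchor triangle (coincident points)")
    ratios = (dists[0] / dists[2], dists[1] / dists[2])
    v2, v3 = p2 - p1, p3 - p1
    cosang = float(np.dot(v2, v3) / (np.hypot(*v2) * np.hypot(*v3)))
    angle = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
    return ratios, angle


def canonical_anchor_positions(layout: ArrayLayout) -> np.ndarray:
    """Pixel centers ``(row, col)`` of the three alignment reference spots in
    the trimmed output frame.

    Spot ``(r, c)`` is centered at ``((r + 0.5) * spot_box,
    (c + 0.5) * spot_box)``.  Deterministic and independent of image content.
    """
    spots = layout.alignment_reference_spots()
    return np.array([layout.spot_center(rc) for rc in spots], dtype=float)


# -- config file I/O --------------------------------------------------------

def load_layout(path: str | Path) -> ArrayLayout:
    """Load an :class:`ArrayLayout` from a YAML config file.

    Schema (keys at top level)::

        name: my-membrane          # optional, defaults to file stem
        n_rows: 8
        n_cols: 10
        spot_box: 30               # optional, default 30
        reference_spots: [[0, 0], [0, 9], [7, 0], [7, 9]]
        analytes:                  # optional, list of [row, col, name]
          - [1, 1, "VEGF"]
          - [1, 2, "VEGF"]
        expected_side_ratios: null # optional, derived from geometry
        expected_angle: 90.0       # optional
        ratio_tol: 0.15            # optional
        angle_tol: 10.0            # optional
        guess_dist_tol: 0.10       # optional
        rotation_hint: 0           # optional, multiples of 90 degrees
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise LayoutError(f"could not parse layout file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise LayoutError(f"layout file {path} must contain a mapping")
    return _layout_from_dict(raw, default_name=path.stem)


def _layout_from_dict(raw: dict, default_name: str = "layout") -> ArrayLayout:
    for key in ("n_rows", "n_cols", "reference_spots"):
        if key not in raw:
            raise LayoutError(f"layout is missing required field {key!r}")
    analytes_raw = raw.get("analytes") or []
    analytes: dict[tuple[int, int], str] = {}
    for entry in analytes_raw:
        if len(entry) != 3:
            raise LayoutError(f"analytes entries must be [row, col, name], "
                              f"got {entry!r}")
        r, c, name = entry
        analytes[(int(r), int(c))] = str(name)
    ratios = raw.get("expected_side_ratios")
    kwargs = dict(
        name=str(raw.get("name", default_name)),
        n_rows=int(raw["n_rows"]),
        n_cols=int(raw["n_cols"]),
        spot_box=int(raw.get("spot_box", DEFAULT_SPOT_BOX)),
        reference_spots=tuple(tuple(rc) for rc in raw["reference_spots"]),
        analytes=analytes,
        expected_side_ratios=tuple(ratios) if ratios is not None else None,
        rotation_hint=int(raw.get("rotation_hint", 0)),
    )
    for key in ("expected_angle", "ratio_tol", "angle_tol", "guess_dist_tol"):
        if raw.get(key) is not None:
            kwargs[key] = float(raw[key])
    return ArrayLayout(**kwargs)


def save_layout(layout: ArrayLayout, path: str | Path) -> Path:
    """Write a layout back to its YAML representation (round-trips with
    :func:`load_layout`)."""
    path = Path(path)
    data = {
        "name": layout.name,
        "n_rows": layout.n_rows,
        "n_cols": layout.n_cols,
        "spot_box": layout.spot_box,
        "reference_spots": [list(rc) for rc in layout.reference_spots],
        "analytes": [[r, c, name]
                     for (r, c), name in sorted(layout.analytes.items())],
        "expected_side_ratios": (list(layout.expected_side_ratios)
                                 if layout.expected_side_ratios else None),
        "expected_angle": layout.expected_angle,
        "ratio_tol": layout.ratio_tol,
        "angle_tol": layout.angle_tol,
        "guess_dist_tol": layout.guess_dist_tol,
        "rotation_hint": layout.rotation_hint,
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def builtin_layouts() -> list[str]:
    """Names of the layout configs shipped with the package."""
    pkg = resources.files("blotkin") / "layouts"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def get_layout(name: str) -> ArrayLayout:
    """Load a shipped layout by name (see :func:`builtin_layouts`)."""
    pkg = resources.files("blotkin") / "layouts" / f"{name}.yaml"
    if not pkg.is_file():
        raise LayoutError(
            f"unknown layout {name!r}; available: {', '.join(builtin_layouts())}")
    raw = yaml.safe_load(pkg.read_text())
    return _layout_from_dict(raw, default_name=name)


def with_rotation_hint(layout: ArrayLayout, hint: int) -> ArrayLayout:
    """Copy of ``layout`` with a different coarse rotation hint."""
    return replace(layout, rotation_hint=int(hint))
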