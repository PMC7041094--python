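"""Synthetic membrane stacks with known ground truth.

The generator is the forward model of the whole pipeline: spots are
isotropic Gaussian profiles truncated at their spot box, normalized so the
box mean equals the kinetic light flux ``L(t)`` exactly (recovery targets
are therefore profile-independent); the background mean and spread grow
linearly with exposure time; the membrane can be rotated and translated
against the camera frame.  The rendered canvas includes a dark margin around
the membrane, emulating the recording tray that real acquisitions show and
that feeds the histogram background estimator.

Background light and sensor noise live in the camera frame, so they are
added after the membrane (signal) is misaligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from skimage import transform

from .kinetics import KineticConstants, light_flux_model
from .layout import ArrayLayout
from .stack import ImageStack

__all__ = [
    "GroundTruth",
    "SimulationError",
    "default_truth",
    "generate_stack",
    "default_times",
    "write_simulation",
]

#: Reference spots must outshine every analyte; this is their C_E (mol/L).
REFERENCE_CE = 2e-8

DEFAULT_CE_RANGE = (1e-10, 1e-8)


class SimulationError(RuntimeError):
    """Raised for physically meaningless simulation parameters."""


@dataclass
class GroundTruth:
    """Parameters (and, after generation, derived data) of one synthetic
    stack.  Same seed, same parameters -> bit-identical stack."""

    ce_map: dict[tuple[int, int], float]
    kappa: float = 1.0
    constants: KineticConstants = field(default_factory=KineticConstants)
    bg_intercept: float = 0.01          # background mean at t=0, gray value
    bg_slope: float = 1e-4              # background mean growth, gray/s
    sigma_intercept: float = 0.002      # background spread at t=0
    sigma_slope: float = (0.01 - 0.002) / 600.0   # spread growth, gray/s
    rotation_deg: float = 2.0           # membrane rotation vs camera frame
    translation_px: tuple[float, float] = (4.0, 7.0)   # (rows, cols)
    spot_sigma: float = 4.2             # Gaussian spot width, px
    margin_px: int = 120                # dark tray border around the membrane
    seed: int = 0
    # filled in by generate_stack:
    times: np.ndarray | None = None
    true_anchor_px: np.ndarray | None = None     # (3, 2) of (row, col)
    per_spot_L: dict | None = None
    saturated_fraction: np.ndarray | None = None

    def background_mean(self, t: np.ndarray) -> np.ndarray:
        return self.bg_intercept + self.bg_slope * np.asarray(t, float)

    def background_sigma(self, t: np.ndarray) -> np.ndarray:
        return self.sigma_intercept + self.sigma_slope * np.asarray(t, float)


def default_times(n: int = 20, t_min: float = 5.0,
                  t_max: float = 600.0) -> np.ndarray:
    """Geometric exposure series: dense early frames resolve the fast-decay
    spots, late frames pin the asymptote."""
    return np.geomspace(t_min, t_max, n)


def default_truth(layout: ArrayLayout, seed: int = 0,
                  ce_range: tuple[float, float] = DEFAULT_CE_RANGE,
                  **overrides) -> GroundTruth:
    """Ground truth with analyte concentrations log-spaced over ``ce_range``
    and assigned to non-reference spots in seeded random order; reference
    spots receive the largest concentration so they stay the brightest
    landmarks."""
    rng = np.random.default_rng(seed)
    refs = set(layout.reference_spots)
    analyte_spots = [rc for rc in layout.grid_spots if rc not in refs]
    values = np.geomspace(ce_range[0], ce_range[1], len(analyte_spots))
    order = rng.permutation(len(analyte_spots))
    ce_map = {rc: float(values[i]) for rc, i in zip(analyte_spots, order)}
    for rc in refs:
        ce_map[rc] = max(REFERENCE_CE, float(values.max()))
    return GroundTruth(ce_map=ce_map, seed=seed, **overrides)


def _spot_profile(spot_box: int, sigma: float) -> np.ndarray:
    """Unit-box-mean Gaussian profile truncated at the spot box."""
    idx = np.arange(spot_box, dtype=float)
    center = spot_box / 2.0
    g = np.exp(-((idx - center) ** 2) / (2.0 * sigma ** 2))
    prof = np.outer(g, g)
    return prof * (spot_box ** 2 / prof.sum())


def _misalignment_matrix(truth: GroundTruth,
                         shape: tuple[int, int]) -> np.ndarray | None:
    """Forward affine map (x, y homogeneous) of the membrane misalignment:
    rotation about the canvas center plus translation."""
    if truth.rotation_deg == 0 and tuple(truth.translation_px) == (0.0, 0.0):
        return None
    theta = np.deg2rad(truth.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    dy, dx = truth.translation_px
    shift = c - rot @ c + np.array([dx, dy])
    m = np.eye(3)
    m[:2, :2] = rot
    m[:2, 2] = shift
    return m


def generate_stack(layout: ArrayLayout, truth: GroundTruth,
                   times: np.ndarray | None = None
                   ) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic exposure stack for ``layout`` and ``truth``.

    Returns the stack together with a copy of ``truth`` whose derived fields
    (per-spot fluxes, true anchor pixel positions, saturation fractions) are
    filled in.
    """
    t = default_times() if times is None else np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0) or np.any(t <= 0):
        raise SimulationError("exposure times must be positive and strictly "
                              "increasing")
    missing = [rc for rc in layout.grid_spots if rc not in truth.ce_map]
    if missing:
        raise SimulationError(f"ce_map is missing spots: {missing[:5]} ...")

    rng = np.random.default_rng(truth.seed)
    sb, m = layout.spot_box, truth.margin_px
    h = layout.n_rows * sb + 2 * m
    w = layout.n_cols * sb + 2 * m
    prof = _spot_profile(sb, truth.spot_sigma)

    spots = layout.grid_spots
    flux = {rc: light_flux_model(t, truth.kappa, truth.ce_map[rc],
                                 truth.constants)
            for rc in spots}

    fwd = _misalignment_matrix(truth, (h, w))
    inv_tform = (transform.AffineTransform(matrix=np.linalg.inv(fwd))
                 if fwd is not None else None)

    frames = np.empty((t.size, h, w))
    for k, tk in enumerate(t):
        signal = np.zeros((h, w))
        for (r, c) in spots:
            lv = flux[(r, c)][k]
            if lv <= 0:
                continue
            signal[m + r * sb:m + (r + 1) * sb,
                   m + c * sb:m + (c + 1) * sb] += lv * prof
        if inv_tform is not None:
            signal = transform.warp(signal, inv_tform, order=1,
                                    mode="constant", cval=0.0,
                                    preserve_range=True)
        frame = signal + truth.background_mean(tk)
        sigma = truth.background_sigma(tk)
        if sigma > 0:
            frame = frame + rng.normal(0.0, sigma, size=(h, w))
        frames[k] = np.clip(frame, 0.0, 1.0)

    sat = (frames >= 1.0).mean(axis=(1, 2))
    if np.any(sat > 0.5):
        worst = int(np.argmax(sat))
        raise SimulationError(
            f"frame {worst} (t={t[worst]:g} s) has {sat[worst]:.0%} saturated "
            f"pixels; the chosen kappa/C_E/background are unphysical")

    anchors_rc = np.array([layout.spot_center(rc)
                           for rc in layout.alignment_reference_spots()])
    anchors_rc = anchors_rc + m
    if fwd is not None:
        xy = np.column_stack([anchors_rc[:, 1], anchors_rc[:, 0],
                              np.ones(len(anchors_rc))])
        mapped = (fwd @ xy.T).T
        anchors_rc = np.column_stack([mapped[:, 1], mapped[:, 0]])

    out_truth = replace(truth, times=t.copy(), true_anchor_px=anchors_rc,
                        per_spot_L=flux,
                        saturated_fraction=sat)
    stack = ImageStack(frames=frames, exposure_times=t.copy(),
                       source_depth=None,
                       name=f"sim-{layout.name}-seed{truth.seed}")
    return stack, out_truth


def write_simulation(outdir: str | Path, layout: ArrayLayout,
                     truth: GroundTruth,
                     times: np.ndarray | None = None) -> dict[str, Path]:
    """Generate a stack and write it as a 16-bit TIFF plus exposure sidecar
    CSV and ground-truth JSON.  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, full = generate_stack(layout, truth, times)

    tif = outdir / "stack.tif"
    tifffile.imwrite(tif, (stack.frames * 65535.0).round().astype(np.uint16),
                     photometric="minisblack")
    sidecar = outdir / "exposures.csv"
    lines = ["file,exposure_s"]
    lines += [f"stack.tif#{i},{float(tt)!r}" for i, tt in
              enumerate(stack.exposure_times)]
    sidecar.write_text("\n".join(lines) + "\n")

    truth_json = outdir / "truth.json"
    payload = {
        "layout": layout.name,
        "kappa": full.kappa,
        "k_r": full.constants.k_r,
        "t0": full.constants.t0,
        "seed": full.seed,
        "rotation_deg": full.rotation_deg,
        "translation_px": list(full.translation_px),
        "spot_sigma": full.spot_sigma,
        "margin_px": full.margin_px,
        "background": {
            "b_intercept": full.bg_intercept, "b_slope": full.bg_slope,
            "sigma_intercept": full.sigma_intercept,
            "sigma_slope": full.sigma_slope,
        },
        "exposure_times_s": stack.exposure_times.tolist(),
        "ce_map": {f"{r},{c}": v for (r, c), v in
                   sorted(full.ce_map.items())},
    }
    truth_json.write_text(json.dumps(payload, indent=2))
    return {"stack": tif, "sidecar": sidecar, "truth": truth_json}
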