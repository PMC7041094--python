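"""Histogram-based background light estimation.

The membrane is mostly dark, so the gray-value histogram of a whole frame is
dominated by background pixels.  The estimator reduces the frame to a
2048-bin histogram over ``[0, 1]``, takes the highest bin's center as the
first guess ``b_G``, discards every value above ``2 * b_G`` (so spot light
cannot inflate the estimate), and fits a normal distribution to the retained
sample; its mean is the background level ``b`` and its standard deviation
``sigma_b``.  Across an exposure series both ``b`` and ``sigma_b`` grow
linearly with exposure time, which :func:`background_series` quantifies with
ordinary least-squares lines.

Background estimation operates on unaligned frames: it is a histogram-only
statistic, so warping (and its interpolation bias) is unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import ImageStack

__all__ = [
    "BackgroundEstimate",
    "BackgroundSeries",
    "estimate_background",
    "background_series",
    "N_BINS",
]

N_BINS = 2048
BIN_WIDTH = 1.0 / N_BINS


@dataclass(frozen=True)
class BackgroundEstimate:
    """Background statistics of one frame (gray values in [0, 1])."""

    b: float            # background mean
    sigma_b: float      # background spread
    b_g: float          # histogram-mode first guess
    n_retained: int     # pixels kept after the 2*b_G cutoff


@dataclass
class BackgroundSeries:
    """Per-frame background estimates with linear trends over exposure time.

    ``b_slope``/``b_intercept`` describe the OLS line of ``b`` against ``t``;
    ``sigma_slope``/``sigma_intercept`` the line for ``sigma_b``.  With fewer
    than two frames no trend can be fitted and ``trend_defined`` is False
    (slopes are NaN).
    """

    estimates: list[BackgroundEstimate]
    times: np.ndarray
    b_slope: float
    b_intercept: float
    sigma_slope: float
    sigma_intercept: float
    trend_defined: bool

    @property
    def b(self) -> np.ndarray:
        return np.array([e.b for e in self.estimates])

    @property
    def sigma_b(self) -> np.ndarray:
        return np.array([e.sigma_b for e in self.estimates])

    def __len__(self) -> int:
        return len(self.estimates)


def estimate_background(frame: np.ndarray) -> BackgroundEstimate:
    """Estimate the background level of a single frame.

    The histogram uses 2048 equal bins over ``[0, 1]`` regardless of the
    source bit depth (internal data is always scaled to that range).  The
    cutoff discards values strictly greater than ``2 * b_G``.  When the mode
    falls in the zero bin the cutoff would be pathological, so the lowest two
    bins are retained and the estimate degrades gracefully to ~0 instead of
    failing.
    """
    vals = np.asarray(frame, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("cannot estimate background of an empty frame")
    if vals.min() < 0.0 or vals.max() > 1.0:
        raise ValueError("frame values must lie within [0, 1]")
    counts, edges = np.histogram(vals, bins=N_BINS, range=(0.0, 1.0))
    # The top bin collects saturated pixels, which are reaction light by
    # definition; on long exposures their spike can outgrow the background
    # peak, so it is excluded from the mode search.
    mode_bin = int(np.argmax(counts[:-1]))  # ties resolve to the lowest bin
    b_g = (edges[mode_bin] + edges[mode_bin + 1]) / 2.0
    if mode_bin == 0:
        retained = vals[vals < edges[2]]
    else:
        retained = vals[vals <= 2.0 * b_g]
    if retained.size == 0:  # unreachable for valid frames; keep a safe path
        return BackgroundEstimate(b=0.0, sigma_b=0.0, b_g=b_g, n_retained=0)
    b, sigma = _fit_normal(retained, counts, edges, mode_bin, b_g)
    return BackgroundEstimate(b=b, sigma_b=sigma, b_g=float(b_g),
                              n_retained=int(retained.size))


def _fit_normal(retained: np.ndarray, counts: np.ndarray, edges: np.ndarray,
                mode_bin: int, b_g: float) -> tuple[float, float]:
    """Fit the normal distribution to the retained sample.

    The fit is a least-squares Gaussian fit to the retained histogram bins:
    it locks onto the symmetric background peak, so the faint spot skirts
    that survive the cutoff (a small right tail) barely perturb it, unlike
    the plain sample mean.  Degenerate histograms (fewer than four occupied
    bins) fall back to the sample moments.
    """
    mu0, sd0 = float(retained.mean()), float(retained.std())
    centers = (edges[:-1] + edges[1:]) / 2.0
    sel = centers <= 2.0 * b_g
    x, y = centers[sel], counts[sel].astype(float)
    # Quasi-degenerate histograms (most retained mass in one bin, or hardly
    # any occupied bins) carry no peak shape to fit; sample moments are the
    # better estimator there.
    if np.count_nonzero(y) < 4 or sd0 <= 0 or \
            counts[mode_bin] > 0.5 * retained.size:
        return mu0, sd0
    from scipy.optimize import curve_fit

    def gauss(x, amp, mu, sd):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sd ** 2))

    try:
        popt, _ = curve_fit(gauss, x, y,
                            p0=[float(counts[mode_bin]), b_g, max(sd0, BIN_WIDTH)],
                            maxfev=2000)
    except (RuntimeError, ValueError):
        return mu0, sd0
    mu, sd = float(popt[1]), abs(float(popt[2]))
    if not (0.0 <= mu <= 2.0 * b_g) or not np.isfinite(sd):
        return mu0, sd0
    return mu, sd


def background_series(stack: ImageStack) -> BackgroundSeries:
    """Estimate the background of every frame and fit its linear growth."""
    estimates = [estimate_background(f) for f in stack.frames]
    t = stack.exposure_times
    if len(estimates) >= 2:
        b_slope, b_intercept = np.polyfit(t, [e.b for e in estimates], 1)
        s_slope, s_intercept = np.polyfit(t, [e.sigma_b for e in estimates], 1)
        trend = True
    else:
        b_slope = s_slope = float("nan")
        b_intercept = estimates[0].b if estimates else float("nan")
        s_intercept = estimates[0].sigma_b if estimates else float("nan")
        trend = False
    return BackgroundSeries(
        estimates=estimates,
        times=t.copy(),
        b_slope=float(b_slope),
        b_intercept=float(b_intercept),
        sigma_slope=float(s_slope),
        sigma_intercept=float(s_intercept),
        trend_defined=trend,
    )
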