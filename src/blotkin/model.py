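"""Model / results interface over the analysis pipeline.

``MembraneArrayModel`` binds an exposure stack to a membrane layout; its
``fit`` method runs the requested evaluation and returns a results object
carrying the estimates, diagnostics and a ``summary()`` table.  The
underlying stage functions (alignment, background, kinetics, modes) remain
available as plain functions for custom workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import align_stack
from .background import BackgroundSeries
from .kinetics import (KineticConstants, KineticFit, SpotTrace,
                       light_flux_model, quantify)
from .layout import ArrayLayout, get_layout, load_layout
from .modes import ModeResult, evaluate_mode
from .report import Report, build_report, write_report
from .stack import ImageStack, load_stack

__all__ = ["MembraneArrayModel", "KineticResults", "ModeResults"]


class MembraneArrayModel:
    """A membrane exposure stack bound to its array layout.

    Parameters
    ----------
    stack : ImageStack
        Normalized exposure series of one membrane.
    layout : ArrayLayout or str
        Layout object, shipped layout name, or path to a layout config.
    constants : KineticConstants, optional
        Rate-law constants (``k_r``, preparation time ``t0``).
    """

    def __init__(self, stack: ImageStack, layout: ArrayLayout | str,
                 constants: KineticConstants | None = None):
        if isinstance(layout, (str, Path)):
            p = Path(layout)
            layout = load_layout(p) if p.suffix else get_layout(str(layout))
        self.stack = stack
        self.layout = layout
        self.constants = constants or KineticConstants()

    @classmethod
    def from_files(cls, images, layout: ArrayLayout | str,
                   times: Sequence[float] | None = None,
                   sidecar: str | Path | None = None,
                   constants: KineticConstants | None = None,
                   name: str = "") -> "MembraneArrayModel":
        """Build a model straight from image files (see
        :func:`blotkin.stack.load_stack`)."""
        stack = load_stack(images, times=times, sidecar=sidecar, name=name)
        return cls(stack, layout, constants=constants)

    def fit(self, mode: str = "kinetic", *, n_bright: int = 10, **kwargs):
        """Run an evaluation and return its results object.

        ``mode`` is ``"kinetic"`` (the reaction-based model, needs exposure
        times) or one of the fallback modes ``"raw"``, ``"local_bg"``,
        ``"correlation"``.
        """
        if mode == "kinetic":
            fit, aligned, traces = quantify(
                self.stack, self.layout, self.constants,
                n_bright=n_bright, return_details=True)
            return KineticResults(model=self, fit=fit, aligned=aligned,
                                  traces=traces)
        aligned = align_stack(self.stack, self.layout)
        result = evaluate_mode(aligned, self.layout, mode, **kwargs)
        return ModeResults(model=self, result=result, aligned=aligned)


@dataclass
class _ResultsBase:
    model: MembraneArrayModel
    aligned: ImageStack

    @property
    def layout(self) -> ArrayLayout:
        return self.model.layout

    def _report(self, result, **kwargs) -> Report:
        kwargs.setdefault("membrane_name",
                          self.model.stack.name or "membrane")
        return build_report(result, self.layout, **kwargs)

    def save_alignment_check(self, path: str | Path) -> Path:
        """Write the final aligned frame with the spot grid overlaid, as the
        visual alignment check that reports embed."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        path = Path(path)
        sb = self.layout.spot_box
        fig, ax = plt.subplots(figsize=(6, 6 * self.aligned.frame_shape[0]
                                        / self.aligned.frame_shape[1]))
        ax.imshow(self.aligned.frames[-1], cmap="gray_r", vmin=0, vmax=None)
        for r in range(self.layout.n_rows + 1):
            ax.axhline(r * sb - 0.5, color="tab:orange", lw=0.4)
        for c in range(self.layout.n_cols + 1):
            ax.axvline(c * sb - 0.5, color="tab:orange", lw=0.4)
        ax.set_title("alignment check (final exposure)")
        ax.set_axis_off()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path


@dataclass
class KineticResults(_ResultsBase):
    """Results of the kinetic quantification.

    Attributes
    ----------
    kappa : float
        Shared prefactor of the image set.
    ce : pandas.Series
        Per-spot enzyme concentration ``C_E`` in mol/L, indexed by
        ``(row, col)``.
    analyte_ce : pandas.Series
        Analyte-level values: mean over duplicate spots.
    """

    fit: KineticFit = None
    traces: list[SpotTrace] = field(default_factory=list)

    @property
    def kappa(self) -> float:
        return self.fit.kappa

    @property
    def background(self) -> BackgroundSeries:
        return self.fit.background

    @property
    def ce(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(self.fit.ce_per_spot.keys(),
                                        names=["row", "col"])
        return pd.Series(list(self.fit.ce_per_spot.values()), index=idx,
                         name="C_E [mol/L]")

    @property
    def residuals(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(self.fit.residuals.keys(),
                                        names=["row", "col"])
        return pd.Series(list(self.fit.residuals.values()), index=idx,
                         name="rms residual")

    @property
    def analyte_ce(self) -> pd.Series:
        groups: dict[str, list[float]] = {}
        for rc, v in self.fit.ce_per_spot.items():
            groups.setdefault(self.layout.analyte_name(rc), []).append(v)
        return pd.Series({k: float(np.mean(v))
                          for k, v in sorted(groups.items())},
                         name="C_E [mol/L]")

    def predicted_trace(self, spot: tuple[int, int]) -> np.ndarray:
        """Model light flux of a spot at the measured exposure times."""
        return light_flux_model(self.aligned.exposure_times, self.fit.kappa,
                                self.fit.ce_per_spot[tuple(spot)],
                                self.fit.constants)

    def summary(self) -> str:
        lay = self.layout
        st = self.model.stack
        bg = self.fit.background
        lines = []
        lines.append("   Membrane array kinetic quantification")
        lines.append("=" * 58)
        lines.append(f"membrane:            {st.name or '-'}")
        lines.append(f"layout:              {lay.name} "
                     f"({lay.n_rows}x{lay.n_cols}, spot box {lay.spot_box} px)")
        lines.append(f"frames:              {st.n_frames} "
                     f"({st.exposure_times[0]:g}-{st.exposure_times[-1]:g} s)")
        lines.append(f"kappa:               {self.fit.kappa:.6g}")
        lines.append(f"k_r:                 {self.fit.constants.k_r:.3g} "
                     f"(M s)^-1")
        lines.append(f"t0:                  {self.fit.constants.t0:g} s")
        if bg is not None and bg.trend_defined:
            lines.append(f"background b(t):     {bg.b_intercept:.4g} + "
                         f"{bg.b_slope:.4g} t")
            lines.append(f"background sigma(t): {bg.sigma_intercept:.4g} + "
                         f"{bg.sigma_slope:.4g} t")
        lines.append("-" * 58)
        lines.append(f"{'analyte':<22}{'C_E [mol/L]':>14}{'n spots':>10}")
        counts: dict[str, int] = {}
        for rc in lay.grid_spots:
            counts[lay.analyte_name(rc)] = counts.get(lay.analyte_name(rc),
                                                      0) + 1
        for name, val in self.analyte_ce.items():
            lines.append(f"{name:<22}{val:>14.4g}{counts.get(name, 0):>10}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_report(self, **kwargs) -> Report:
        return self._report(self.fit, **kwargs)

    def write_reports(self, outdir: str | Path,
                      formats: Sequence[str] = ("json", "csv"),
                      **kwargs) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        img = self.save_alignment_check(outdir / "alignment-check.png")
        rep = self.to_report(alignment_image=img, **kwargs)
        ext = {"json": "json", "csv": "csv", "excel": "xlsx", "latex": "tex"}
        return [write_report(rep, f, outdir / f"report.{ext[f]}")
                for f in formats]


@dataclass
class ModeResults(_ResultsBase):
    """Results of a fallback evaluation mode."""

    result: ModeResult = None

    @property
    def values(self) -> pd.Series | pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.result.spots,
                                        names=["row", "col"])
        if self.result.values.ndim == 2:
            return pd.DataFrame(self.result.values, index=idx,
                                columns=self.aligned.exposure_times)
        return pd.Series(self.result.values, index=idx,
                         name=self.result.mode)

    def summary(self) -> str:
        lay = self.layout
        lines = []
        lines.append(f"   Membrane array evaluation: {self.result.mode} mode")
        lines.append("=" * 58)
        lines.append(f"membrane:  {self.model.stack.name or '-'}")
        lines.append(f"layout:    {lay.name} ({lay.n_rows}x{lay.n_cols})")
        lines.append("-" * 58)
        lines.append(f"{'analyte':<22}{'value':>14}")
        rep = self.to_report()
        for name, val in rep.analytes.items():
            lines.append(f"{name:<22}{val:>14.4g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_report(self, **kwargs) -> Report:
        return self._report(self.result, **kwargs)

    def write_reports(self, outdir: str | Path,
                      formats: Sequence[str] = ("json", "csv"),
                      **kwargs) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        img = self.save_alignment_check(outdir / "alignment-check.png")
        rep = self.to_report(alignment_image=img, **kwargs)
        ext = {"json": "json", "csv": "csv", "excel": "xlsx", "latex": "tex"}
        return [write_report(rep, f, outdir / f"report.{ext[f]}")
                for f in formats]
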