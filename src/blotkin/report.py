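"""Result reports in json, csv, excel and LaTeX form.

A :class:`Report` aggregates per-spot values to analyte level (duplicate
spots share a name and are averaged), lists the strongest signals and
carries naming/version metadata.  The machine formats (json, csv) keep full
numeric precision and round-trip losslessly; the human-facing formats
(xlsx, LaTeX) round to three significant digits and embed a top-signal
chart plus, when available, the aligned membrane image as an alignment
check.
"""

from __future__ import annotations

import csv as _csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .kinetics import KineticFit
from .layout import ArrayLayout
from .modes import ModeResult

__all__ = ["Report", "ReportError", "build_report", "write_report",
           "REPORT_FORMATS"]

REPORT_FORMATS = ("json", "csv", "excel", "latex")


class ReportError(ValueError):
    """Raised when a result does not cover the layout or a format is bad."""


@dataclass
class Report:
    dataset_name: str
    membrane_name: str
    software_version: str
    mode: str
    analytes: dict[str, float]              # analyte -> averaged value
    spot_values: dict[str, float]           # "r,c" -> per-spot value
    top_signals: list[tuple[str, float]]
    value_unit: str = ""
    alignment_image: str | None = None
    metadata: dict = field(default_factory=dict)


def _spot_values_of(result, layout: ArrayLayout) -> dict[tuple[int, int], float]:
    if isinstance(result, KineticFit):
        return dict(result.ce_per_spot)
    if isinstance(result, ModeResult):
        return result.as_dict()
    raise ReportError(f"cannot report a {type(result).__name__}")


def build_report(result, layout: ArrayLayout, *,
                 dataset_name: str = "", membrane_name: str = "",
                 top_n: int = 10,
                 alignment_image: str | Path | None = None,
                 metadata: dict | None = None) -> Report:
    """Aggregate a kinetic fit or mode result into a :class:`Report`.

    Every grid spot of the layout must be covered by the result.  Analyte
    values are the mean over duplicate spots; the ``top_n`` strongest
    analytes are listed with ties broken by analyte name.
    """
    per_spot = _spot_values_of(result, layout)
    missing = [rc for rc in layout.grid_spots if rc not in per_spot]
    if missing:
        raise ReportError(f"result does not cover the layout grid; missing "
                          f"spots: {missing[:5]}")

    grouped: dict[str, list[float]] = {}
    for rc in layout.grid_spots:
        grouped.setdefault(layout.analyte_name(rc), []).append(per_spot[rc])
    analytes = {}
    for name in sorted(grouped):
        vals = np.asarray(grouped[name], dtype=float)
        finite = vals[np.isfinite(vals)]
        analytes[name] = float(finite.mean()) if finite.size else float("nan")

    ranked = sorted(
        ((name, val) for name, val in analytes.items() if np.isfinite(val)),
        key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:top_n]

    if isinstance(result, KineticFit):
        mode = "kinetic"
        unit = "mol/L"
        meta = {"kappa": result.kappa, "k_r": result.constants.k_r,
                "t0_s": result.constants.t0}
    else:
        mode = result.mode
        unit = "gray value" if mode == "raw" else "ratio" \
            if mode == "local_bg" else "slope"
        meta = {}
    meta.update(metadata or {})

    return Report(
        dataset_name=dataset_name,
        membrane_name=membrane_name,
        software_version=__version__,
        mode=mode,
        analytes=analytes,
        spot_values={f"{r},{c}": float(per_spot[(r, c)])
                     for r, c in layout.grid_spots},
        top_signals=top,
        value_unit=unit,
        alignment_image=str(alignment_image) if alignment_image else None,
        metadata=meta,
    )


def write_report(report: Report, fmt: str, path: str | Path) -> Path:
    """Write a report in one of the four formats: json, csv, excel, latex."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        return _write_json(report, path)
    if fmt == "csv":
        return _write_csv(report, path)
    if fmt == "excel":
        return _write_excel(report, path)
    if fmt == "latex":
        return _write_latex(report, path)
    raise ReportError(f"unsupported report format {fmt!r}; choose from "
                      f"{', '.join(REPORT_FORMATS)}")


def _write_json(report: Report, path: Path) -> Path:
    payload = {
        "dataset": report.dataset_name,
        "membrane": report.membrane_name,
        "software_version": report.software_version,
        "mode": report.mode,
        "value_unit": report.value_unit,
        "analytes": report.analytes,
        "top_signals": [[n, v] for n, v in report.top_signals],
        "spots": report.spot_values,
        # only the file name: the json must not depend on where it was run
        "alignment_image": (Path(report.alignment_image).name
                            if report.alignment_image else None),
        "metadata": report.metadata,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def _write_csv(report: Report, path: Path) -> Path:
    with path.open("w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["analyte", "value"])
        for name, val in report.analytes.items():
            writer.writerow([name, repr(val)])
    return path


def _sig3(v: float) -> str:
    return "n/a" if not np.isfinite(v) else f"{v:.3g}"


def _top_signal_chart(report: Report, path: Path) -> Path | None:
    if not report.top_signals:
        return None
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [n for n, _ in report.top_signals][::-1]
    vals = [v for _, v in report.top_signals][::-1]
    fig, ax = plt.subplots(figsize=(5, 0.4 * len(names) + 1))
    ax.barh(names, vals, color="#356a9b")
    ax.set_xlabel(f"value [{report.value_unit}]" if report.value_unit
                  else "value")
    ax.set_title("Strongest signals")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _write_excel(report: Report, path: Path) -> Path:
    from openpyxl import Workbook
    from openpyxl.chart import BarChart, Reference

    wb = Workbook()
    ws = wb.active
    ws.title = "Analytes"
    ws.append(["dataset", report.dataset_name])
    ws.append(["membrane", report.membrane_name])
    ws.append(["software version", report.software_version])
    ws.append(["mode", report.mode])
    ws.append([])
    header_row = ws.max_row + 1
    ws.append(["analyte", f"value [{report.value_unit}]"])
    for name, val in report.analytes.items():
        ws.append([name, val if np.isfinite(val) else None])

    ts = wb.create_sheet("Top signals")
    ts.append(["analyte", "value"])
    for name, val in report.top_signals:
        ts.append([name, val])
    if report.top_signals:
        chart = BarChart()
        chart.type = "bar"
        chart.title = "Strongest signals"
        data = Reference(ts, min_col=2, min_row=1,
                         max_row=1 + len(report.top_signals))
        cats = Reference(ts, min_col=1, min_row=2,
                         max_row=1 + len(report.top_signals))
        chart.add_data(data, titles_from_data=True)
        chart.set_categories(cats)
        ts.add_chart(chart, "D2")

    if report.alignment_image and Path(report.alignment_image).is_file():
        from openpyxl.drawing.image import Image as XlImage
        ai = wb.create_sheet("Alignment check")
        ai.add_image(XlImage(report.alignment_image), "A1")

    wb.save(path)
    return path


_LATEX_HEADER = r"""\documentclass{article}
\usepackage{graphicx}
\usepackage{booktabs}
\begin{document}
"""


def _latex_escape(s: str) -> str:
    for ch in "&%$#_{}":
        s = s.replace(ch, "\\" + ch)
    return s


def _write_latex(report: Report, path: Path) -> Path:
    chart = _top_signal_chart(report, path.with_suffix(".top-signals.png"))
    lines = [_LATEX_HEADER]
    lines.append(r"\section*{Membrane array report}")
    lines.append(r"\begin{tabular}{ll}")
    lines.append(r"\toprule")
    lines.append(f"dataset & {_latex_escape(report.dataset_name)} \\\\")
    lines.append(f"membrane & {_latex_escape(report.membrane_name)} \\\\")
    lines.append(f"software version & {report.software_version} \\\\")
    lines.append(f"mode & {_latex_escape(report.mode)} \\\\")
    lines.append(r"\bottomrule")
    lines.append(r"\end{tabular}")
    lines.append("")
    lines.append(r"\subsection*{Analyte values}")
    lines.append(r"\begin{tabular}{lr}")
    lines.append(r"\toprule")
    unit = _latex_escape(report.value_unit)
    lines.append(f"analyte & value [{unit}] \\\\")
    lines.append(r"\midrule")
    for name, val in report.analytes.items():
        lines.append(f"{_latex_escape(name)} & {_sig3(val)} \\\\")
    lines.append(r"\bottomrule")
    lines.append(r"\end{tabular}")
    if chart is not None:
        lines.append("")
        lines.append(r"\subsection*{Strongest signals}")
        lines.append(r"\includegraphics[width=0.8\linewidth]{%s}"
                     % chart.name)
    if report.alignment_image and Path(report.alignment_image).is_file():
        lines.append("")
        lines.append(r"\subsection*{Alignment check}")
        lines.append(r"\includegraphics[width=0.8\linewidth]{%s}"
                     % Path(report.alignment_image).name)
    lines.append(r"\end{document}")
    path.write_text("\n".join(lines) + "\n")
    return path
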