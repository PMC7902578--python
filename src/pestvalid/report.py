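"""Deterministic report rendering for validation runs.

Floating-point statistics are printed at one decimal (the precision of the
published validation tables); LOQs keep full precision since sub-0.01 mg/kg
limits are meaningful.  Rendering is pure string formatting so reruns on
identical inputs are byte-identical.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .validate import CompoundValidation, PanelSummary, summarize_panel

__all__ = ["compound_report_lines", "summary_lines", "write_reports"]


def _f1(x: float | None) -> str:
    return "" if x is None else f"{x:.1f}"


def _loq(x: float | None) -> str:
    return "" if x is None else f"{x:g}"


def compound_report_lines(validations: Sequence[CompoundValidation]) -> list[str]:
    """Delimited per-compound/per-level report (one header + data lines)."""
    lines = ["compound,level_fraction,recovery_mean,recovery_rsd,"
             "linearity_dev_solvent,linearity_dev_matrix,ion_ratio_pass,"
             "rt_pass,level_pass,loq_mg_kg,quantifiable,first_failing"]
    for v in validations:
        for lr in v.levels:
            lines.append(",".join([
                f'"{v.analyte}"' if "," in v.analyte else v.analyte,
                f"{lr.level_fraction:.2f}",
                _f1(lr.recovery_mean_pct), _f1(lr.recovery_rsd_pct),
                _f1(lr.linearity_dev_solvent_pct),
                _f1(lr.linearity_dev_matrix_pct),
                str(lr.ion_ratio_pass).lower(), str(lr.rt_pass).lower(),
                str(lr.level_pass).lower(), _loq(v.loq_mg_kg),
                str(v.quantifiable).lower(), v.first_failing or "",
            ]))
    return lines


def summary_lines(validations: Sequence[CompoundValidation]) -> list[str]:
    """Human-readable panel summary."""
    s: PanelSummary = summarize_panel(validations)
    lines = [
        "Validation panel summary",
        "========================",
        f"analytes evaluated : {s.n_analytes}",
        f"quantifiable       : {s.n_quantifiable}",
        f"not quantifiable   : {s.n_analytes - s.n_quantifiable}",
    ]
    if s.failing:
        lines.append("")
        lines.append("failing compounds (first failing criterion):")
        for name, crit in s.failing:
            lines.append(f"  - {name}: {crit}")
    return lines


def write_reports(validations: Sequence[CompoundValidation],
                  outdir: str | Path) -> tuple[Path, Path]:
    """Write compound_report.csv and panel_summary.txt under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = outdir / "compound_report.csv"
    summary = outdir / "panel_summary.txt"
    report.write_text("\n".join(compound_report_lines(validations)) + "\n",
                      encoding="utf-8")
    summary.write_text("\n".join(summary_lines(validations)) + "\n",
                       encoding="utf-8")
    return report, summary
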