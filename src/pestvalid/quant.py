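"""Per-injection computations: calibration, back-calculation, confirmation.

Calibration is ordinary unweighted least squares of detector response on
nominal concentration across the seven standard levels (10–150% of the
analytical concentration), fitted separately for the solvent arm and the
matrix-matched arm.  Linearity is judged on the signed percent deviation of
the back-calculated concentration from nominal.  Identity confirmation uses
the qualifier/quantifier ion ratio (relative tolerance against the
standard's ratio, boundary inclusive) and the retention time (strict
window against the standard's retention time).
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

__all__ = [
    "NO_SIGNAL",
    "PeakRecord",
    "CalibrationFit",
    "QuantError",
    "fit_calibration",
    "back_calc_deviation",
    "ion_ratio",
    "confirm_ion_ratio",
    "confirm_rt",
    "reference_ion_ratio",
    "reference_rt",
    "load_batch",
    "write_batch",
]

STANDARD_LEVELS = (0.10, 0.20, 0.50, 0.75, 1.00, 1.25, 1.50)
SPIKE_LEVELS = (0.10, 0.20, 0.50, 1.00, 1.50)
SOLUTION_TYPES = ("solvent_standard", "matrix_standard", "spiked_sample", "blank")

BATCH_COLUMNS = ["compound", "solution_type", "level_fraction", "replicate",
                 "quant_area", "qual_area", "rt_min"]


class QuantError(ValueError):
    """Raised for unusable calibration or confirmation inputs."""


class _NoSignal:
    """Sentinel for a qualifier transition that produced no signal."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_SIGNAL"


#: Typed "no signal" outcome: confirmation involving it automatically fails.
NO_SIGNAL = _NoSignal()


@dataclass(frozen=True)
class PeakRecord:
    """One injection's integrated peaks for one analyte."""

    analyte: str
    solution_type: str
    level_fraction: float
    replicate: int
    quant_area: float
    qual_area: float | None  # None encodes "no signal" on the qualifier
    rt: float                # minutes

    def __post_init__(self) -> None:
        if self.solution_type not in SOLUTION_TYPES:
            raise QuantError(f"unknown solution type {self.solution_type!r}")
        allowed = (SPIKE_LEVELS if self.solution_type == "spiked_sample"
                   else STANDARD_LEVELS)
        if self.solution_type != "blank" and not any(
                math.isclose(self.level_fraction, l) for l in allowed):
            raise QuantError(
                f"{self.analyte}: level fraction {self.level_fraction} not in "
                f"the permitted set for {self.solution_type}"
            )
        if self.quant_area < 0:
            raise QuantError(f"{self.analyte}: negative quantifier area")
        if self.rt <= 0:
            raise QuantError(f"{self.analyte}: retention time must be > 0")
        if self.replicate < 1:
            raise QuantError(f"{self.analyte}: replicate must be >= 1")


@dataclass
class CalibrationFit:
    """Least-squares line (response = slope*conc + intercept) for one arm."""

    analyte: str
    slope: float
    intercept: float
    arm: str  # "solvent" or "matrix"
    level_deviations: dict[float, float] = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        return self.slope > 0


def fit_calibration(
    points: Sequence[tuple[float, float]],
    *,
    analyte: str = "",
    arm: str = "solvent",
    weighting: str = "none",
) -> CalibrationFit:
    """Fit an unweighted least-squares calibration line.

    ``points`` are (nominal concentration, response) pairs; at least three
    distinct concentrations are required.  Every input point's back-
    calculated deviation is recorded in ``level_deviations`` keyed by its
    nominal concentration (mean deviation when a level repeats).
    """
    if weighting != "none":
        raise QuantError(f"unsupported weighting {weighting!r}")
    if len({c for c, _ in points}) < 3:
        raise QuantError(
            f"{analyte or 'calibration'}: need >= 3 distinct levels, "
            f"got {len({c for c, _ in points})}"
        )
    responses = [r for _, r in points]
    if len(set(responses)) == 1:
        raise QuantError(f"{analyte or 'calibration'}: all responses identical")
    concs = [c for c, _ in points]
    res = stats.linregress(concs, responses)
    fit = CalibrationFit(analyte=analyte, slope=float(res.slope),
                         intercept=float(res.intercept), arm=arm)
    if fit.slope == 0:
        raise QuantError(f"{analyte or 'calibration'}: zero calibration slope")
    devs: dict[float, list[float]] = {}
    for conc, resp in points:
        devs.setdefault(conc, []).append(back_calc_deviation(fit, resp, conc))
    fit.level_deviations = {c: sum(v) / len(v) for c, v in devs.items()}
    return fit


def back_calc_deviation(fit: CalibrationFit, response: float,
                        nominal: float) -> float:
    """Signed percent deviation of the back-calculated concentration.

    ((response − intercept)/slope − nominal)/nominal × 100.
    """
    if fit.slope == 0:
        raise QuantError(f"{fit.analyte}: zero slope, cannot back-calculate")
    if nominal <= 0:
        raise QuantError("nominal concentration must be > 0")
    back = (response - fit.intercept) / fit.slope
    return (back - nominal) / nominal * 100.0


def ion_ratio(record: PeakRecord) -> float | _NoSignal:
    """Qualifier/quantifier peak-area ratio, or NO_SIGNAL."""
    if record.qual_area is None:
        return NO_SIGNAL
    if record.quant_area == 0:
        raise QuantError(f"{record.analyte}: zero quantifier area")
    return record.qual_area / record.quant_area


def confirm_ion_ratio(sample_ratio: float | _NoSignal, standard_ratio: float,
                      tolerance_pct: float = 30.0) -> bool:
    """Identity confirmation: sample ratio within ±tolerance% of the
    standard's ratio (relative, boundary inclusive).  NO_SIGNAL fails."""
    if isinstance(sample_ratio, _NoSignal):
        return False
    if standard_ratio <= 0:
        raise QuantError("standard ion ratio must be > 0")
    return abs(sample_ratio - standard_ratio) / standard_ratio * 100.0 \
        <= tolerance_pct + 1e-12


def confirm_rt(sample_rt: float, standard_rt: float,
               window_min: float = 0.1) -> bool:
    """Retention-time confirmation: |Δ| strictly inside the window.

    A shift exactly at the window width fails; the comparison carries a
    1 ns guard so representation error cannot smuggle a boundary shift in.
    """
    if sample_rt <= 0 or standard_rt <= 0:
        raise QuantError("retention times must be > 0")
    return abs(sample_rt - standard_rt) < window_min - 1e-9


def _solvent_standards(records: Iterable[PeakRecord],
                       analyte: str) -> list[PeakRecord]:
    return [r for r in records
            if r.analyte == analyte and r.solution_type == "solvent_standard"]


def reference_ion_ratio(records: Iterable[PeakRecord],
                        analyte: str) -> float | _NoSignal:
    """Reference ion ratio: mean over solvent standards (all levels) whose
    qualifier transition gave a detectable signal."""
    ratios = [r.qual_area / r.quant_area
              for r in _solvent_standards(records, analyte)
              if r.qual_area is not None and r.quant_area > 0]
    if not ratios:
        return NO_SIGNAL
    return sum(ratios) / len(ratios)


def reference_rt(records: Iterable[PeakRecord], analyte: str) -> float:
    """Reference retention time: mean over solvent standards."""
    rts = [r.rt for r in _solvent_standards(records, analyte)]
    if not rts:
        raise QuantError(f"{analyte}: no solvent standards for reference RT")
    return sum(rts) / len(rts)


def load_batch(path: str | Path) -> list[PeakRecord]:
    """Read a measurement-batch file (empty qual_area field = no signal)."""
    out: list[PeakRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(BATCH_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise QuantError(f"batch file missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                qual = row["qual_area"].strip()
                out.append(PeakRecord(
                    analyte=row["compound"].strip(),
                    solution_type=row["solution_type"].strip(),
                    level_fraction=float(row["level_fraction"]),
                    replicate=int(row["replicate"]),
                    quant_area=float(row["quant_area"]),
                    qual_area=float(qual) if qual else None,
                    rt=float(row["rt_min"]),
                ))
            except (QuantError, ValueError) as exc:
                raise QuantError(f"batch row {i}: {exc}") from exc
    return out


def write_batch(records: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(BATCH_COLUMNS)
        for r in records:
            w.writerow([
                r.analyte, r.solution_type, f"{r.level_fraction:.2f}",
                r.replicate, repr(r.quant_area),
                "" if r.qual_area is None else repr(r.qual_area),
                repr(r.rt),
            ])
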