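"""Criteria engine: recovery, precision, matrix effect, LOQ, classification.

The validation criteria applied per fortification level are:

====================  ==========================================
linearity             back-calculated deviation within ±20% (both
                      the solvent and the matrix-matched arm)
recovery              mean of n=3 replicates within 70–120%
precision             RSD (n=3) <= 20%
ion ratio             within ±30% of the standard's ratio
retention time        strictly within ±0.1 min of the standard
====================  ==========================================

A fortification level passes when every criterion passes.  The limit of
quantification (LOQ) is the lowest fortification level such that that
level *and every higher level* passes (the monotone rule); a compound is
quantifiable when its LOQ exists and does not exceed its MRL (inclusive).

``comparison_mode="paper_repro"`` relaxes the recovery band by 0.5
percentage points, absorbing round-before-compare ambiguity in printed
one-decimal tables; ``"strict"`` is the default for new data.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel import Analyte, Panel
from .quant import (
    NO_SIGNAL,
    PeakRecord,
    QuantError,
    SPIKE_LEVELS,
    STANDARD_LEVELS,
    back_calc_deviation,
    confirm_ion_ratio,
    confirm_rt,
    fit_calibration,
    ion_ratio,
    reference_ion_ratio,
    reference_rt,
)

__all__ = [
    "CriteriaConfig",
    "LevelStats",
    "LevelResult",
    "CompoundValidation",
    "PanelSummary",
    "ValidationError",
    "recovery",
    "rsd",
    "matrix_effect",
    "evaluate_levels",
    "determine_loq",
    "classify_compound",
    "summarize_panel",
    "classify_recoveries",
    "load_validation_summary",
    "load_matrix_effect_table",
    "bundled_validation_summary",
    "bundled_matrix_effect",
    "bundled_printed_loq",
    "validate_summary",
    "validate_batch",
]

#: Fixed reporting order for the first-failing criterion.
CRITERION_ORDER = ("ion_ratio", "rt", "linearity", "recovery", "precision")


class ValidationError(ValueError):
    """Raised for malformed or incomplete validation inputs."""


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds of the validation criteria, with comparison-mode switch."""

    linearity_tol_pct: float = 20.0
    recovery_low_pct: float = 70.0
    recovery_high_pct: float = 120.0
    rsd_max_pct: float = 20.0
    ion_ratio_tol_pct: float = 30.0
    rt_window_min: float = 0.1
    recovery_levels: tuple[float, ...] = SPIKE_LEVELS
    comparison_mode: str = "strict"  # or "paper_repro"

    def __post_init__(self) -> None:
        if not self.recovery_low_pct < self.recovery_high_pct:
            raise ValidationError("recovery_low_pct must be < recovery_high_pct")
        for name in ("linearity_tol_pct", "rsd_max_pct", "ion_ratio_tol_pct",
                     "rt_window_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.comparison_mode not in ("strict", "paper_repro"):
            raise ValidationError(
                f"unknown comparison mode {self.comparison_mode!r}")

    @property
    def recovery_slack_pct(self) -> float:
        return 0.5 if self.comparison_mode == "paper_repro" else 0.0


@dataclass(frozen=True)
class LevelStats:
    """Computed statistics for one analyte at one fortification level.

    ``None`` encodes a statistic that could not be measured (e.g. recovery
    suppressed because the confirmation failed); a missing statistic fails
    its criterion.
    """

    level_fraction: float
    linearity_dev_solvent_pct: float | None = None
    linearity_dev_matrix_pct: float | None = None
    recovery_mean_pct: float | None = None
    recovery_rsd_pct: float | None = None
    ion_ratio_ok: bool = True
    rt_ok: bool = True


@dataclass(frozen=True)
class LevelResult:
    level_fraction: float
    recovery_mean_pct: float | None
    recovery_rsd_pct: float | None
    linearity_dev_solvent_pct: float | None
    linearity_dev_matrix_pct: float | None
    ion_ratio_pass: bool
    rt_pass: bool
    linearity_pass: bool
    recovery_pass: bool
    precision_pass: bool

    @property
    def level_pass(self) -> bool:
        return (self.ion_ratio_pass and self.rt_pass and self.linearity_pass
                and self.recovery_pass and self.precision_pass)

    @property
    def failed_criteria(self) -> tuple[str, ...]:
        flags = {
            "ion_ratio": self.ion_ratio_pass,
            "rt": self.rt_pass,
            "linearity": self.linearity_pass,
            "recovery": self.recovery_pass,
            "precision": self.precision_pass,
        }
        return tuple(c for c in CRITERION_ORDER if not flags[c])


@dataclass
class CompoundValidation:
    """All per-level results and the derived classification for one analyte."""

    analyte: str
    mrl: float
    levels: list[LevelResult]
    matrix_effect_pct: dict[float, float] = field(default_factory=dict)
    loq_mg_kg: float | None = None
    quantifiable: bool = False

    @property
    def first_failing(self) -> str | None:
        """First failed criterion at the lowest failing level (fixed order)."""
        for lr in sorted(self.levels, key=lambda l: l.level_fraction):
            if not lr.level_pass:
                return lr.failed_criteria[0]
        return None


@dataclass
class PanelSummary:
    n_analytes: int
    n_quantifiable: int
    failing: list[tuple[str, str]]  # (analyte, first-failing criterion)


# --------------------------------------------------------------- elementary ops

def recovery(measured_conc: float, spiked_conc: float) -> float:
    """Recovery percent: measured/spiked × 100."""
    if spiked_conc <= 0:
        raise ValidationError("spiked concentration must be > 0")
    # back-calculated concentrations may be slightly negative near zero
    # signal; the signed recovery is meaningful and is not clamped
    return measured_conc / spiked_conc * 100.0


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation percent (sample SD, n−1 denominator)."""
    if len(values) < 2:
        raise ValidationError("RSD requires at least 2 values")
    mean = float(np.mean(values))
    if mean == 0:
        raise ValidationError("RSD undefined for zero mean")
    return float(np.std(values, ddof=1)) / abs(mean) * 100.0


def matrix_effect(matrix_vs_solvent_recovery_pct: float) -> float:
    """Percent deviation from 100% of the matrix/solvent response ratio.

    Negative = suppression, positive = enhancement.
    """
    if matrix_vs_solvent_recovery_pct < 0:
        raise ValidationError("response ratio percent must be >= 0")
    return matrix_vs_solvent_recovery_pct - 100.0


# ------------------------------------------------------------- criteria engine

def _within(value: float | None, low: float, high: float) -> bool:
    return value is not None and low <= value <= high


def evaluate_levels(
    analyte: str,
    stats: Mapping[float, LevelStats],
    criteria: CriteriaConfig = CriteriaConfig(),
) -> list[LevelResult]:
    """Apply every criterion at each recovery level; missing level is an error.

    Returns results ordered by level fraction.
    """
    results: list[LevelResult] = []
    for lvl in sorted(criteria.recovery_levels):
        st = _lookup_level(stats, lvl)
        if st is None:
            raise ValidationError(f"{analyte}: no statistics for level {lvl:g}")
        tol = criteria.linearity_tol_pct
        lin_ok = (_within(st.linearity_dev_solvent_pct, -tol, tol)
                  and _within(st.linearity_dev_matrix_pct, -tol, tol))
        slack = criteria.recovery_slack_pct
        rec_ok = _within(st.recovery_mean_pct,
                         criteria.recovery_low_pct - slack,
                         criteria.recovery_high_pct + slack)
        prec_ok = (st.recovery_rsd_pct is not None
                   and st.recovery_rsd_pct <= criteria.rsd_max_pct)
        results.append(LevelResult(
            level_fraction=lvl,
            recovery_mean_pct=st.recovery_mean_pct,
            recovery_rsd_pct=st.recovery_rsd_pct,
            linearity_dev_solvent_pct=st.linearity_dev_solvent_pct,
            linearity_dev_matrix_pct=st.linearity_dev_matrix_pct,
            ion_ratio_pass=st.ion_ratio_ok,
            rt_pass=st.rt_ok,
            linearity_pass=lin_ok,
            recovery_pass=rec_ok,
            precision_pass=prec_ok,
        ))
    return results


def _lookup_level(stats: Mapping[float, LevelStats],
                  lvl: float) -> LevelStats | None:
    for k, v in stats.items():
        if math.isclose(k, lvl):
            return v
    return None


def determine_loq(levels: Sequence[LevelResult],
                  mrl: float) -> float | None:
    """Monotone LOQ rule: the lowest fortification level L such that L and
    every *higher* level passes; None when no such level exists.

    The rule is deliberately stronger than "first passing level": a compound
    that passes only at low levels but fails at the MRL cannot be credited
    with an LOQ below it.
    """
    ordered = sorted(levels, key=lambda l: l.level_fraction)
    loq = None
    for lr in reversed(ordered):
        if lr.level_pass:
            loq = lr.level_fraction * mrl
        else:
            break
    return loq


def classify_compound(validation: CompoundValidation,
                      mrl: float | None = None) -> bool:
    """Quantifiable iff an LOQ exists and LOQ <= MRL (boundary inclusive)."""
    mrl = validation.mrl if mrl is None else mrl
    return (validation.loq_mg_kg is not None
            and validation.loq_mg_kg <= mrl * (1 + 1e-9))


def summarize_panel(validations: Sequence[CompoundValidation]) -> PanelSummary:
    names = [v.analyte for v in validations]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate analyte in validations")
    failing = [(v.analyte, v.first_failing or "loq") for v in validations
               if not v.quantifiable]
    return PanelSummary(
        n_analytes=len(validations),
        n_quantifiable=sum(v.quantifiable for v in validations),
        failing=failing,
    )


def classify_recoveries(recoveries: Mapping[str, float], low: float,
                        high: float = math.inf) -> dict[str, list[str]]:
    """Partition recovery rates into below/within/above by inclusive bounds.

    Used for screening individual pretreatment steps (e.g. >= 80% for a
    single purification step run without matrix, 70–120% for the full
    matrix recovery test).
    """
    if not low < high:
        raise ValidationError("low bound must be < high bound")
    out: dict[str, list[str]] = {"below": [], "within": [], "above": []}
    for name in recoveries:  # preserve caller order
        v = recoveries[name]
        bucket = "below" if v < low else ("above" if v > high else "within")
        out[bucket].append(name)
    return out


# ------------------------------------------------------------------- table I/O

SUMMARY_COLUMNS = ["compound", "level_fraction", "linearity_dev_solvent",
                   "linearity_dev_matrix", "recovery_mean", "recovery_rsd",
                   "ion_ratio_ok", "rt_ok"]


def _opt_float(s: str) -> float | None:
    s = s.strip()
    return float(s) if s else None


def load_validation_summary(
        path: str | Path) -> dict[str, dict[float, LevelStats]]:
    """Read a summarized per-level validation table (long format)."""
    out: dict[str, dict[float, LevelStats]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(SUMMARY_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(
                f"summary table missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                name = row["compound"].strip()
                lvl = float(row["level_fraction"])
                st = LevelStats(
                    level_fraction=lvl,
                    linearity_dev_solvent_pct=_opt_float(row["linearity_dev_solvent"]),
                    linearity_dev_matrix_pct=_opt_float(row["linearity_dev_matrix"]),
                    recovery_mean_pct=_opt_float(row["recovery_mean"]),
                    recovery_rsd_pct=_opt_float(row["recovery_rsd"]),
                    ion_ratio_ok=row["ion_ratio_ok"].strip().lower() == "true",
                    rt_ok=row["rt_ok"].strip().lower() == "true",
                )
            except ValueError as exc:
                raise ValidationError(f"summary row {i}: {exc}") from exc
            out.setdefault(name, {})[lvl] = st
    return out


def load_matrix_effect_table(path: str | Path) -> dict[str, dict[float, float]]:
    """Read a per-level matrix-effect table (percent deviations from 100%)."""
    out: dict[str, dict[float, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            name = row["compound"].strip()
            lvl = float(row["level_fraction"])
            val = _opt_float(row["matrix_effect_pct"])
            out.setdefault(name, {})
            if val is not None:
                out[name][lvl] = val
    return out


def bundled_validation_summary() -> dict[str, dict[float, LevelStats]]:
    return load_validation_summary(
        Path(resources.files("pestvalid.data") / "validation_summary.csv"))


def bundled_matrix_effect() -> dict[str, dict[float, float]]:
    return load_matrix_effect_table(
        Path(resources.files("pestvalid.data") / "matrix_effect.csv"))


def bundled_printed_loq() -> dict[str, float | None]:
    """Published LOQ column, for cross-checking reproduced values."""
    out: dict[str, float | None] = {}
    path = Path(resources.files("pestvalid.data") / "printed_loq.csv")
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[row["compound"].strip()] = _opt_float(row["loq_mg_kg"])
    return out


# -------------------------------------------------------------- full pipelines

def validate_summary(
    panel: Panel,
    summary: Mapping[str, Mapping[float, LevelStats]],
    criteria: CriteriaConfig = CriteriaConfig(),
    matrix_effects: Mapping[str, Mapping[float, float]] | None = None,
) -> list[CompoundValidation]:
    """Apply the criteria engine to pre-summarized per-level statistics."""
    unknown = sorted(set(summary) - set(panel.names))
    if unknown:
        raise ValidationError(f"compounds absent from panel: {unknown}")
    out: list[CompoundValidation] = []
    for analyte in panel:
        if analyte.name not in summary:
            raise ValidationError(f"no statistics for {analyte.name}")
        levels = evaluate_levels(analyte.name, summary[analyte.name], criteria)
        cv = CompoundValidation(
            analyte=analyte.name, mrl=analyte.mrl, levels=levels,
            matrix_effect_pct=dict((matrix_effects or {}).get(analyte.name, {})),
        )
        cv.loq_mg_kg = determine_loq(levels, analyte.mrl)
        cv.quantifiable = classify_compound(cv)
        out.append(cv)
    return out


def validate_batch(
    panel: Panel,
    records: Sequence[PeakRecord],
    criteria: CriteriaConfig = CriteriaConfig(),
    calibration_arm: str = "solvent",
) -> list[CompoundValidation]:
    """Full raw-batch pipeline: calibration of both arms, back-calculation,
    confirmation against solvent-standard references, recovery/RSD of spiked
    replicates, per-level matrix effect, criteria, LOQ, classification.

    Spiked samples are quantified against the ``calibration_arm`` fit
    (default: solvent standards).
    """
    if calibration_arm not in ("solvent", "matrix"):
        raise ValidationError(f"unknown calibration arm {calibration_arm!r}")
    unknown = sorted({r.analyte for r in records} - set(panel.names))
    if unknown:
        raise ValidationError(f"compounds absent from panel: {unknown}")
    out: list[CompoundValidation] = []
    for analyte in panel:
        recs = [r for r in records if r.analyte == analyte.name]
        if not recs:
            raise ValidationError(f"no measurements for {analyte.name}")
        out.append(_validate_one(analyte, recs, criteria, calibration_arm))
    return out


def _arm_points(recs: list[PeakRecord], sol_type: str,
                conc0: float) -> list[tuple[float, float]]:
    return [(r.level_fraction * conc0, r.quant_area)
            for r in recs if r.solution_type == sol_type]


def _validate_one(analyte: Analyte, recs: list[PeakRecord],
                  criteria: CriteriaConfig,
                  calibration_arm: str) -> CompoundValidation:
    conc0 = analyte.analytical_concentration
    fits = {
        "solvent": fit_calibration(
            _arm_points(recs, "solvent_standard", conc0),
            analyte=analyte.name, arm="solvent"),
        "matrix": fit_calibration(
            _arm_points(recs, "matrix_standard", conc0),
            analyte=analyte.name, arm="matrix"),
    }
    ref_ratio = reference_ion_ratio(recs, analyte.name)
    ref_rt = reference_rt(recs, analyte.name)

    # matrix effect per level: matrix/solvent quantifier response ratio
    me: dict[float, float] = {}
    for lvl in STANDARD_LEVELS:
        sol = [r.quant_area for r in recs
               if r.solution_type == "solvent_standard"
               and math.isclose(r.level_fraction, lvl)]
        mat = [r.quant_area for r in recs
               if r.solution_type == "matrix_standard"
               and math.isclose(r.level_fraction, lvl)]
        if sol and mat and sum(sol) > 0:
            ratio_pct = (sum(mat) / len(mat)) / (sum(sol) / len(sol)) * 100.0
            me[lvl] = matrix_effect(ratio_pct)

    stats: dict[float, LevelStats] = {}
    quant_fit = fits[calibration_arm]
    for lvl in criteria.recovery_levels:
        spikes = [r for r in recs if r.solution_type == "spiked_sample"
                  and math.isclose(r.level_fraction, lvl)]
        if not spikes:
            raise ValidationError(
                f"{analyte.name}: no spiked samples at level {lvl:g}")
        ion_ok = all(
            confirm_ion_ratio(ion_ratio(r), ref_ratio,
                              criteria.ion_ratio_tol_pct)
            if not isinstance(ref_ratio, type(NO_SIGNAL)) else False
            for r in spikes)
        rt_ok = all(confirm_rt(r.rt, ref_rt, criteria.rt_window_min)
                    for r in spikes)
        spiked_conc = lvl * conc0
        recoveries = [
            recovery((r.quant_area - quant_fit.intercept) / quant_fit.slope,
                     spiked_conc)
            for r in spikes]
        mean_rec = float(np.mean(recoveries))
        rsd_pct = rsd(recoveries) if len(recoveries) >= 2 else None
        if not (ion_ok and rt_ok):
            mean_rec, rsd_pct = None, None  # reported only when confirmed
        stats[lvl] = LevelStats(
            level_fraction=lvl,
            linearity_dev_solvent_pct=fits["solvent"].level_deviations.get(
                lvl * conc0),
            linearity_dev_matrix_pct=fits["matrix"].level_deviations.get(
                lvl * conc0),
            recovery_mean_pct=mean_rec,
            recovery_rsd_pct=rsd_pct,
            ion_ratio_ok=ion_ok,
            rt_ok=rt_ok,
        )
    levels = evaluate_levels(analyte.name, stats, criteria)
    cv = CompoundValidation(analyte=analyte.name, mrl=analyte.mrl,
                            levels=levels, matrix_effect_pct=me)
    cv.loq_mg_kg = determine_loq(levels, analyte.mrl)
    cv.quantifiable = classify_compound(cv)
    return cv
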