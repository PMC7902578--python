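"""Seeded generator of synthetic MRM validation batches.

The generator reproduces the study design the criteria engine expects:
seven calibration levels (10, 20, 50, 75, 100, 125, 150% of the analytical
concentration) injected in a solvent arm and a matrix-matched arm, plus
five fortification levels (10, 20, 50, 100, 150% of the MRL) with three
replicate spiked samples each.

Generative model per analyte (all draws from one seeded PCG64 stream, in a
fixed analyte/solution/level/replicate order, so equal seeds give
bit-identical batches):

* quantifier area  = (response_factor · conc + intercept) · m · ε,
  ε ~ lognormal with mean 1 and coefficient of variation ``noise_cv``,
  m = ``matrix_multiplier`` in the matrix arm and in spiked samples, 1 in
  the solvent arm;
* qualifier area   = quantifier area · true_ion_ratio · ε′ (independent ε′),
  absent below ``qualifier_dropout_level``;
* retention time   = rt_center + N(0, rt_jitter_sd).

Matrix suppression/enhancement is a level-independent multiplier: the
pipeline's estimated matrix effect should recover 100·(m − 1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Panel
from .quant import (NO_SIGNAL, PeakRecord, SPIKE_LEVELS, STANDARD_LEVELS,
                    reference_ion_ratio)
from .validate import matrix_effect

__all__ = [
    "AnalyteParams",
    "SimulationParams",
    "SimulationError",
    "simulate_validation_batch",
    "parameter_recovery_report",
    "load_params",
]


class SimulationError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass(frozen=True)
class AnalyteParams:
    """Generative parameters for one analyte."""

    response_factor: float = 1e6     # counts per (µg/mL)
    intercept: float = 0.0           # counts
    noise_cv: float = 0.0            # CV of multiplicative response noise
    matrix_multiplier: float = 1.0   # response scaling in the matrix arm
    true_ion_ratio: float = 0.5
    rt_center: float = 10.0          # minutes
    rt_jitter_sd: float = 0.0        # minutes
    qualifier_dropout_level: float | None = None

    def __post_init__(self) -> None:
        if self.response_factor <= 0:
            raise SimulationError("response_factor must be > 0")
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be >= 0")
        if self.matrix_multiplier <= 0:
            raise SimulationError("matrix_multiplier must be > 0")
        if self.rt_jitter_sd < 0:
            raise SimulationError("rt_jitter_sd must be >= 0")
        if self.true_ion_ratio <= 0:
            raise SimulationError("true_ion_ratio must be > 0")
        if self.rt_center <= 0:
            raise SimulationError("rt_center must be > 0")


@dataclass(frozen=True)
class SimulationParams:
    """Global simulation configuration plus optional per-analyte overrides."""

    seed: int = 0
    replicates: int = 3
    default: AnalyteParams = field(default_factory=AnalyteParams)
    per_analyte: Mapping[str, AnalyteParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise SimulationError("replicates must be >= 1")

    def for_analyte(self, name: str) -> AnalyteParams:
        return self.per_analyte.get(name, self.default)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def simulate_validation_batch(panel: Panel,
                              params: SimulationParams) -> list[PeakRecord]:
    """Generate one full validation batch for every panel analyte.

    Identical ``params.seed`` values yield bit-identical record lists.
    """
    if len(panel) == 0:
        raise SimulationError("panel is empty")
    for name in params.per_analyte:
        if name not in panel:
            raise SimulationError(f"unknown analyte in params: {name!r}")
    rng = np.random.default_rng(params.seed)
    records: list[PeakRecord] = []
    for analyte in panel:
        p = params.for_analyte(analyte.name)
        conc0 = analyte.analytical_concentration
        for sol_type, levels, n_rep, mult in (
                ("solvent_standard", STANDARD_LEVELS, 1, 1.0),
                ("matrix_standard", STANDARD_LEVELS, 1, p.matrix_multiplier),
                ("spiked_sample", SPIKE_LEVELS, params.replicates,
                 p.matrix_multiplier)):
            for lvl in levels:
                conc = lvl * conc0
                for rep in range(1, n_rep + 1):
                    quant = ((p.response_factor * conc + p.intercept) * mult
                             * _lognormal_factor(rng, p.noise_cv))
                    qual_noise = _lognormal_factor(rng, p.noise_cv)
                    rt_jit = (float(rng.normal(0.0, p.rt_jitter_sd))
                              if p.rt_jitter_sd > 0 else 0.0)
                    dropout = (p.qualifier_dropout_level is not None
                               and lvl < p.qualifier_dropout_level - 1e-12)
                    qual = None if dropout else quant * p.true_ion_ratio * qual_noise
                    records.append(PeakRecord(
                        analyte=analyte.name,
                        solution_type=sol_type,
                        level_fraction=lvl,
                        replicate=rep,
                        quant_area=quant,
                        qual_area=qual,
                        rt=p.rt_center + rt_jit,
                    ))
    return records


def parameter_recovery_report(batch: Sequence[PeakRecord],
                              truth: SimulationParams,
                              panel: Panel) -> pd.DataFrame:
    """Compare pipeline estimates against the generating parameters.

    For each analyte the matrix effect is estimated as the mean over the
    seven standard levels of the matrix/solvent response-ratio deviation,
    and the ion ratio as the solvent-standard reference ratio.  Returns a
    tidy table with one row per (analyte, parameter).
    """
    batch_names = {r.analyte for r in batch}
    if batch_names != set(panel.names):
        raise SimulationError(
            "analyte mismatch between batch and panel: "
            f"{sorted(batch_names ^ set(panel.names))}")
    rows = []
    for analyte in panel:
        p = truth.for_analyte(analyte.name)
        recs = [r for r in batch if r.analyte == analyte.name]
        me_per_level = []
        for lvl in STANDARD_LEVELS:
            sol = [r.quant_area for r in recs
                   if r.solution_type == "solvent_standard"
                   and math.isclose(r.level_fraction, lvl)]
            mat = [r.quant_area for r in recs
                   if r.solution_type == "matrix_standard"
                   and math.isclose(r.level_fraction, lvl)]
            if sol and mat:
                me_per_level.append(matrix_effect(
                    (sum(mat) / len(mat)) / (sum(sol) / len(sol)) * 100.0))
        est_me = float(np.mean(me_per_level))
        true_me = 100.0 * (p.matrix_multiplier - 1.0)
        ref = reference_ion_ratio(recs, analyte.name)
        est_ratio = float("nan") if ref is NO_SIGNAL else float(ref)
        rows.append((analyte.name, "matrix_effect_pct", true_me, est_me,
                     est_me - true_me))
        rows.append((analyte.name, "ion_ratio", p.true_ion_ratio, est_ratio,
                     est_ratio - p.true_ion_ratio))
    return pd.DataFrame(
        rows, columns=["analyte", "parameter", "true", "estimate", "error"])


# ---------------------------------------------------------------- param files

_GLOBAL_KEYS = {"seed", "replicates"}
_ANALYTE_KEYS = {"response_factor", "intercept", "noise_cv",
                 "matrix_multiplier", "true_ion_ratio", "rt_center",
                 "rt_jitter_sd", "qualifier_dropout_level"}


def load_params(path: str | Path) -> SimulationParams:
    """Read a flat ``key = value`` parameter file.

    Global keys: ``seed``, ``replicates``.  Analyte-model keys (applied to
    every analyte): the :class:`AnalyteParams` field names.  Per-analyte
    overrides use ``<analyte>.<key> = value``.
    """
    glob: dict[str, float] = {}
    default: dict[str, float] = {}
    per: dict[str, dict[str, float]] = {}
    for i, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SimulationError(f"params line {i}: expected key = value")
        key, val = (s.strip() for s in line.split("=", 1))
        value = float(val)
        if key in _GLOBAL_KEYS:
            glob[key] = value
        elif key in _ANALYTE_KEYS:
            default[key] = value
        elif "." in key:
            name, sub = key.rsplit(".", 1)
            if sub not in _ANALYTE_KEYS:
                raise SimulationError(f"params line {i}: unknown key {sub!r}")
            per.setdefault(name, {})[sub] = value
        else:
            raise SimulationError(f"params line {i}: unknown key {key!r}")
    base = AnalyteParams(**default)
    return SimulationParams(
        seed=int(glob.get("seed", 0)),
        replicates=int(glob.get("replicates", 3)),
        default=base,
        per_analyte={n: replace(base, **kv) for n, kv in per.items()},
    )
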