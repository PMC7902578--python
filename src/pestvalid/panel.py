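"""Analyte panel: compounds, regulatory limits and MRM transitions.

A *panel* is the ordered list of compounds a multi-residue method targets.
Each analyte carries its maximum residue limit (MRL, mg/kg), the working
analytical concentration (µg/mL) and a pair of MRM transitions: the
quantifier (used for quantitation via its peak area) and the qualifier
(used for identity confirmation via the qualifier/quantifier area ratio).

Several regulatory entries are "sum of" residue definitions: one MRL
applies to the summed concentration of a parent compound and its named
isomers/metabolites.  Such entries are modelled as *groups* sharing an MRL.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Transition",
    "Analyte",
    "Group",
    "Panel",
    "GroupComparison",
    "PanelError",
    "load_panel",
    "bundled_panel_path",
    "evaluate_residue_definition",
]

PANEL_COLUMNS = [
    "compound", "group", "mrl_mg_kg", "analytical_conc_ug_ml",
    "quant_precursor", "quant_product", "quant_ce",
    "qual_precursor", "qual_product", "qual_ce", "supplier",
]


class PanelError(ValueError):
    """Raised when a panel table cannot be loaded or validated."""


@dataclass(frozen=True)
class Transition:
    """One precursor → product MRM transition."""

    precursor_mz: float
    product_mz: float
    collision_energy: float
    role: str  # "quantifier" or "qualifier"

    def __post_init__(self) -> None:
        if not (self.precursor_mz > self.product_mz > 0):
            raise PanelError(
                f"transition must satisfy precursor > product > 0, got "
                f"{self.precursor_mz} -> {self.product_mz}"
            )
        if self.collision_energy < 0:
            raise PanelError("collision energy must be >= 0")
        if self.role not in ("quantifier", "qualifier"):
            raise PanelError(f"unknown transition role {self.role!r}")


@dataclass(frozen=True)
class Analyte:
    """One panel compound with its limits and transitions."""

    name: str
    group_name: str
    mrl: float                       # mg/kg
    analytical_concentration: float  # µg/mL
    quantifier: Transition
    qualifier: Transition
    supplier_code: str = ""          # opaque provenance tag, never interpreted

    def __post_init__(self) -> None:
        if self.mrl <= 0:
            raise PanelError(f"{self.name}: MRL must be > 0, got {self.mrl}")
        if self.analytical_concentration <= 0:
            raise PanelError(
                f"{self.name}: analytical concentration must be > 0, "
                f"got {self.analytical_concentration}"
            )
        if self.quantifier.role != "quantifier" or self.qualifier.role != "qualifier":
            raise PanelError(f"{self.name}: transitions have wrong roles")


@dataclass(frozen=True)
class Group:
    """A residue-definition entry: member analytes sharing one MRL."""

    name: str
    members: tuple[str, ...]
    mrl: float


@dataclass
class Panel:
    analytes: list[Analyte] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.analytes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate compound names: {sorted(dupes)}")
        for g, members in self._members_by_group().items():
            mrls = {a.mrl for a in members}
            if len(mrls) > 1:
                raise PanelError(
                    f"group {g!r} members disagree on MRL: {sorted(mrls)}"
                )

    def _members_by_group(self) -> dict[str, list[Analyte]]:
        out: dict[str, list[Analyte]] = {}
        for a in self.analytes:
            out.setdefault(a.group_name, []).append(a)
        return out

    @property
    def groups(self) -> dict[str, Group]:
        return {
            g: Group(g, tuple(a.name for a in members), members[0].mrl)
            for g, members in self._members_by_group().items()
        }

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    def __len__(self) -> int:
        return len(self.analytes)

    def __iter__(self):
        return iter(self.analytes)

    def __getitem__(self, name: str) -> Analyte:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(a.name == name for a in self.analytes)

    def to_csv(self, path: str | Path) -> None:
        """Serialize back to the delimited panel-table format (round-trips)."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(PANEL_COLUMNS)
            for a in self.analytes:
                q, l = a.quantifier, a.qualifier
                w.writerow([
                    a.name, a.group_name, f"{a.mrl:g}",
                    f"{a.analytical_concentration:g}",
                    f"{q.precursor_mz:g}", f"{q.product_mz:g}",
                    f"{q.collision_energy:g}",
                    f"{l.precursor_mz:g}", f"{l.product_mz:g}",
                    f"{l.collision_energy:g}", a.supplier_code,
                ])


def bundled_panel_path() -> Path:
    """Path of the bundled 91-compound panel table."""
    return Path(resources.files("pestvalid.data") / "panel.csv")


def load_panel(path: str | Path | None = None) -> Panel:
    """Load a panel from a delimited table; ``None`` loads the bundled panel.

    Raises :class:`PanelError` naming the offending row for malformed input.
    """
    path = bundled_panel_path() if path is None else Path(path)
    analytes: list[Analyte] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(PANEL_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise PanelError(f"panel table missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                analytes.append(Analyte(
                    name=row["compound"].strip(),
                    group_name=row["group"].strip(),
                    mrl=float(row["mrl_mg_kg"]),
                    analytical_concentration=float(row["analytical_conc_ug_ml"]),
                    quantifier=Transition(
                        float(row["quant_precursor"]), float(row["quant_product"]),
                        float(row["quant_ce"]), "quantifier"),
                    qualifier=Transition(
                        float(row["qual_precursor"]), float(row["qual_product"]),
                        float(row["qual_ce"]), "qualifier"),
                    supplier_code=row["supplier"].strip(),
                ))
            except (PanelError, ValueError, KeyError) as exc:
                raise PanelError(f"panel row {i}: {exc}") from exc
    if not analytes:
        raise PanelError(f"panel table {path} contains no data rows")
    return Panel(analytes)


@dataclass(frozen=True)
class GroupComparison:
    """Result of comparing summed member concentrations to a group MRL."""

    group: str
    summed_mg_kg: float
    mrl_mg_kg: float
    exceeds: bool


def evaluate_residue_definition(
    concentrations: Mapping[str, float],
    group: Group,
    *,
    missing_as_zero: bool = False,
) -> GroupComparison:
    """Compare the summed member concentrations of a residue definition
    against the group's shared MRL.

    Exceedance is strict (> MRL); a summed concentration exactly at the MRL
    complies, consistent with LOQ <= MRL being acceptable.
    """
    total = 0.0
    for member in group.members:
        if member not in concentrations:
            if missing_as_zero:
                continue
            raise ValueError(
                f"group {group.name!r}: no concentration for member {member!r}"
            )
        c = concentrations[member]
        if c < 0:
            raise ValueError(f"negative concentration for {member!r}: {c}")
        total += c
    return GroupComparison(group.name, total, group.mrl, total > group.mrl)
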