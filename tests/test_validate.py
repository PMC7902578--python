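"""Criteria engine: recovery, precision, matrix effect, LOQ, classification."""
import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestvalid.validate import (CompoundValidation, CriteriaConfig,
                                LevelResult, LevelStats, ValidationError,
                                classify_compound, classify_recoveries,
                                determine_loq, evaluate_levels, matrix_effect,
                                recovery, rsd, summarize_panel,
                                validate_summary)

RECOVERY_LEVELS = (0.10, 0.20, 0.50, 1.00, 1.50)


def make_levels(passes):
    """LevelResults with the given pass pattern at the recovery levels."""
    out = []
    for lvl, ok in zip(RECOVERY_LEVELS, passes):
        out.append(LevelResult(
            level_fraction=lvl, recovery_mean_pct=100.0, recovery_rsd_pct=1.0,
            linearity_dev_solvent_pct=0.0, linearity_dev_matrix_pct=0.0,
            ion_ratio_pass=True, rt_pass=True, linearity_pass=True,
            recovery_pass=ok, precision_pass=True))
    return out


def loq_oracle(passes, mrl):
    """Exhaustive enumeration over suffixes of the level ladder."""
    candidates = [lvl for i, lvl in enumerate(RECOVERY_LEVELS)
                  if all(passes[i:])]
    return min(candidates) * mrl if candidates else None


class TestElementaryStats:
    def test_recovery_identity_and_zero(self):
        assert recovery(0.05, 0.05) == pytest.approx(100.0)
        assert recovery(0.0, 0.05) == pytest.approx(0.0)

    def test_recovery_zero_spike_fails(self):
        with pytest.raises(ValidationError):
            recovery(0.05, 0.0)

    def test_rsd_constant_and_forced(self):
        assert rsd([100.0, 100.0, 100.0]) == pytest.approx(0.0)
        assert rsd([90.0, 100.0, 110.0]) == pytest.approx(10.0)

    @given(st.lists(st.floats(1.0, 200.0), min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None)
    def test_rsd_matches_two_pass_oracle(self, values):
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        expected = math.sqrt(var) / mean * 100.0
        assert rsd(values) == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_rsd_preconditions(self):
        with pytest.raises(ValidationError):
            rsd([100.0])
        with pytest.raises(ValidationError):
            rsd([1.0, -1.0])

    def test_matrix_effect_formula(self):
        assert matrix_effect(100.0) == pytest.approx(0.0)
        assert matrix_effect(41.1) == pytest.approx(-58.9)

    @given(st.floats(-99.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_matrix_effect_inverts_its_construction(self, me):
        assert matrix_effect(me + 100.0) == pytest.approx(me, abs=1e-9)

    def test_matrix_effect_negative_ratio_fails(self):
        with pytest.raises(ValidationError):
            matrix_effect(-1.0)


class TestEvaluateLevels:
    """Per-level verdicts on the transcribed validation statistics."""

    @pytest.mark.parametrize("compound,level,criterion", [
        ("Azinphos-methyl", 0.10, "linearity"),   # solvent deviation 93.9
        ("Deltamethrin", 0.20, "recovery"),       # mean recovery 134.2
        ("Dicofol", 0.10, "precision"),           # RSD 22.2
        ("Alachlor", 0.10, "ion_ratio"),          # qualifier gave no signal
    ])
    def test_failing_level_and_criterion(self, summary, compound, level,
                                         criterion):
        results = evaluate_levels(compound, summary[compound])
        by_level = {r.level_fraction: r for r in results}
        assert by_level[level].level_pass is False
        assert criterion in by_level[level].failed_criteria

    def test_missing_level_names_analyte(self):
        stats = {0.10: LevelStats(0.10, 0.0, 0.0, 100.0, 1.0)}
        with pytest.raises(ValidationError, match="Azinphos.*0.2"):
            evaluate_levels("Azinphos-methyl", stats)

    def test_paper_repro_mode_gives_half_point_slack(self):
        stats = {lvl: LevelStats(lvl, 0.0, 0.0, 120.4, 1.0)
                 for lvl in RECOVERY_LEVELS}
        strict = evaluate_levels("x", stats, CriteriaConfig())
        repro = evaluate_levels(
            "x", stats, CriteriaConfig(comparison_mode="paper_repro"))
        assert not any(r.level_pass for r in strict)
        assert all(r.level_pass for r in repro)


class TestDetermineLoq:
    def test_all_pass_gives_lowest_level(self):
        assert determine_loq(make_levels([1] * 5), mrl=1.0) == \
            pytest.approx(0.10)

    def test_all_fail_gives_none(self):
        assert determine_loq(make_levels([0] * 5), mrl=1.0) is None

    def test_azinphos_methyl_row(self, panel, summary):
        levels = evaluate_levels("Azinphos-methyl", summary["Azinphos-methyl"])
        assert determine_loq(levels, panel["Azinphos-methyl"].mrl) == \
            pytest.approx(0.2)

    def test_pass_only_below_mrl_is_not_credited(self):
        # passes at 10-50% but fails at 100/150% -> no LOQ at all
        assert determine_loq(make_levels([1, 1, 1, 0, 0]), mrl=0.1) is None

    @given(st.lists(st.booleans(), min_size=5, max_size=5),
           st.floats(0.01, 4.0))
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_suffix_oracle(self, passes, mrl):
        got = determine_loq(make_levels(passes), mrl)
        want = loq_oracle(passes, mrl)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want)


class TestClassification:
    def test_profenophos_not_quantifiable(self, panel, summary):
        vals = validate_summary(panel, summary)
        by_name = {v.analyte: v for v in vals}
        assert by_name["Profenophos"].quantifiable is False
        assert by_name["Profenophos"].loq_mg_kg is None

    def test_loq_equal_to_mrl_is_quantifiable(self, panel, summary):
        vals = validate_summary(panel, summary)
        delta = {v.analyte: v for v in vals}["Deltamethrin"]
        assert delta.loq_mg_kg == pytest.approx(0.5)
        assert delta.loq_mg_kg == pytest.approx(panel["Deltamethrin"].mrl)
        assert delta.quantifiable is True  # inclusive boundary

    def test_absent_loq_never_quantifiable(self):
        cv = CompoundValidation("x", mrl=1.0, levels=make_levels([0] * 5))
        assert classify_compound(cv) is False


class TestSummarizePanel:
    def test_bundled_tables_give_88_of_91(self, panel, summary):
        s = summarize_panel(validate_summary(panel, summary))
        assert (s.n_analytes, s.n_quantifiable) == (91, 88)
        assert {name for name, _ in s.failing} == \
            {"Fenchlorphos oxon", "Paraoxon-methyl", "Profenophos"}

    def test_removing_failures_gives_full_count(self, panel, summary):
        from pestvalid.panel import Panel
        failing = {"Fenchlorphos oxon", "Paraoxon-methyl", "Profenophos"}
        reduced = Panel([a for a in panel if a.name not in failing])
        trimmed = {k: v for k, v in summary.items() if k not in failing}
        s = summarize_panel(validate_summary(reduced, trimmed))
        assert s.n_quantifiable == s.n_analytes == 88
        assert s.failing == []

    def test_empty_input_gives_zeros(self):
        s = summarize_panel([])
        assert (s.n_analytes, s.n_quantifiable, s.failing) == (0, 0, [])

    def test_duplicate_analyte_fails(self):
        cv = CompoundValidation("x", 1.0, make_levels([1] * 5))
        with pytest.raises(ValidationError, match="duplicate"):
            summarize_panel([cv, cv])


class TestCriterionMonotonicity:
    """Tightening any tolerance never lowers an LOQ or adds a quantifiable
    compound."""

    def _counts(self, panel, summary, criteria):
        vals = validate_summary(panel, summary, criteria)
        loqs = {v.analyte: (math.inf if v.loq_mg_kg is None else v.loq_mg_kg)
                for v in vals}
        return loqs, sum(v.quantifiable for v in vals)

    @pytest.mark.parametrize("tight", [
        dict(linearity_tol_pct=10.0),
        dict(recovery_low_pct=80.0, recovery_high_pct=110.0),
        dict(rsd_max_pct=5.0),
    ])
    def test_tightening_on_bundled_tables(self, panel, summary, tight):
        base_loqs, base_n = self._counts(panel, summary, CriteriaConfig())
        tight_loqs, tight_n = self._counts(panel, summary,
                                           CriteriaConfig(**tight))
        assert tight_n <= base_n
        assert all(tight_loqs[a] >= base_loqs[a] for a in base_loqs)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_tightening_on_randomized_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        stats = {lvl: LevelStats(
            lvl,
            float(rng.normal(0, 15)), float(rng.normal(0, 15)),
            float(rng.normal(100, 20)), float(abs(rng.normal(5, 8))))
            for lvl in RECOVERY_LEVELS}
        loose = evaluate_levels("x", stats, CriteriaConfig())
        tight = evaluate_levels("x", stats, CriteriaConfig(
            linearity_tol_pct=10.0, recovery_low_pct=80.0,
            recovery_high_pct=110.0, rsd_max_pct=10.0))
        l_loose = determine_loq(loose, 1.0)
        l_tight = determine_loq(tight, 1.0)
        assert (math.inf if l_tight is None else l_tight) >= \
            (math.inf if l_loose is None else l_loose)


class TestProcessStepClassification:
    def test_single_step_screen_at_80(self):
        buckets = classify_recoveries({"Fenchlorphos oxon": 79.5,
                                       "Fenchlorphos": 95.0}, low=80.0)
        assert buckets["below"] == ["Fenchlorphos oxon"]
        assert buckets["within"] == ["Fenchlorphos"]

    def test_matrix_recovery_band(self):
        buckets = classify_recoveries(
            {"Profenophos": 44.7, "Dicofol": 122.1, "Fenthion": 90.0},
            low=70.0, high=120.0)
        assert buckets == {"below": ["Profenophos"], "within": ["Fenthion"],
                           "above": ["Dicofol"]}

    def test_bounds_inclusive(self):
        buckets = classify_recoveries({"a": 70.0, "b": 120.0}, 70.0, 120.0)
        assert buckets["within"] == ["a", "b"]

    def test_bad_bounds_fail(self):
        with pytest.raises(ValidationError):
            classify_recoveries({"a": 1.0}, 120.0, 70.0)


class TestLoqColumnReproduction:
    def test_paper_repro_mode_reproduces_printed_loq_column(
            self, panel, summary, printed_loq):
        """Every printed LOQ (alachlor's ambiguous row aside) is recomputed
        from the per-level statistics by the monotone rule."""
        vals = validate_summary(
            panel, summary, CriteriaConfig(comparison_mode="paper_repro"))
        for v in vals:
            if v.analyte == "Alachlor":
                continue
            want = printed_loq[v.analyte]
            if want is None:
                assert v.loq_mg_kg is None, v.analyte
            else:
                assert v.loq_mg_kg == pytest.approx(want), v.analyte

    def test_strict_mode_differs_only_on_azinphos_ethyl(
            self, panel, summary, printed_loq):
        vals = validate_summary(panel, summary, CriteriaConfig())
        mismatches = []
        for v in vals:
            if v.analyte == "Alachlor":
                continue
            want = printed_loq[v.analyte]
            same = ((v.loq_mg_kg is None and want is None)
                    or (v.loq_mg_kg is not None and want is not None
                        and math.isclose(v.loq_mg_kg, want)))
            if not same:
                mismatches.append(v.analyte)
        assert mismatches == ["Azinphos-ethyl"]
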