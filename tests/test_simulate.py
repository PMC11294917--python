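"""Acquisition simulator: scheduler rules, reproducibility, closed forms."""

import math

import numpy as np
import pytest

from prmquant.extract import extract_ms1_area
from prmquant.msdata import InclusionEntry
from prmquant.simulate import (
    AcquisitionConfig,
    SimTarget,
    default_panel,
    glycone_aglycone_surface,
    inclusion_list_from_targets,
    insource_fraction,
    simulate_calibration_series,
    simulate_dda_run,
    simulate_mrm_traces,
    simulate_prm_run,
)

from _oracles import dda_schedule_oracle
from conftest import flat_target


def _ms2_per_cycle(run):
    counts = {}
    for s in run.ms2_spectra():
        cycle = s.scan_id.split("_")[0]
        counts[cycle] = counts.get(cycle, 0) + 1
    return counts


class TestPrmScheduler:
    def test_ms2_count_matches_cycle_grid_arithmetic(self):
        """Closed form: one always-eligible target fragments once per cycle
        whose MS2 event time falls inside the 1-min window."""
        target = flat_target(rt_apex=1.0, intensity=1000.0)
        cfg = AcquisitionConfig(gradient_length=2.0, noise_cv=0.0, seed=0)
        entries = inclusion_list_from_targets([target], cfg.rt_window)
        run, truth = simulate_prm_run([target], entries, cfg)
        cyc = cfg.cycle_time / 60.0
        offset = cfg.ms1_accumulation / 60000.0
        expected = sum(
            1
            for k in range(int(2.0 * 60.0 / cfg.cycle_time))
            if abs(k * cyc + offset - 1.0) <= 0.5
        )
        assert len(truth.targets["flat"].ms2_scan_ids) == expected
        assert len(run.ms2_spectra()) == expected

    def test_candidate_cap_of_eight(self):
        """20 co-eluting eligible precursors produce exactly 8 MS2 per cycle."""
        targets = [
            flat_target(f"t{i}", 1000.0 + 10 * i, rt_apex=1.0, mz_mass=400.0 + i)
            for i in range(20)
        ]
        cfg = AcquisitionConfig(gradient_length=1.5, noise_cv=0.0, seed=0)
        run, _ = simulate_prm_run(targets, inclusion_list_from_targets(targets), cfg)
        per_cycle = _ms2_per_cycle(run)
        assert max(per_cycle.values()) == 8
        # every cycle overlapping the shared window hits the cap
        assert all(v == 8 for v in per_cycle.values())

    def test_threshold_is_strict(self):
        """A precursor at exactly the 50 cps threshold is never fragmented."""
        at = flat_target("at50", 50.0, rt_apex=1.0)
        cfg = AcquisitionConfig(gradient_length=2.0, noise_cv=0.0, seed=0)
        run, truth = simulate_prm_run([at], inclusion_list_from_targets([at]), cfg)
        assert len(run.ms2_spectra()) == 0
        just_above = flat_target("t", 50.0 + 1e-6, rt_apex=1.0)
        run2, _ = simulate_prm_run([just_above], inclusion_list_from_targets([just_above]), cfg)
        assert len(run2.ms2_spectra()) > 0

    def test_never_fragments_outside_window(self):
        target = flat_target(rt_apex=1.0)
        cfg = AcquisitionConfig(gradient_length=3.0, noise_cv=0.0, seed=0)
        entries = inclusion_list_from_targets([target], cfg.rt_window)
        run, _ = simulate_prm_run([target], entries, cfg)
        for s in run.ms2_spectra():
            assert abs(s.rt - 1.0) <= 0.5 + 1e-12

    def test_cycle_budget_invariant_enforced(self):
        with pytest.raises(ValueError, match="cannot hold"):
            AcquisitionConfig(cycle_time=1.0, max_candidates_per_cycle=8)

    def test_reproducibility_bit_identical(self):
        panel = default_panel()
        cfg = AcquisitionConfig(gradient_length=2.0, noise_cv=0.1, seed=42)
        entries = inclusion_list_from_targets(panel)
        run1, truth1 = simulate_prm_run(panel, entries, cfg)
        run2, truth2 = simulate_prm_run(panel, entries, cfg)
        assert [s.scan_id for s in run1.spectra] == [s.scan_id for s in run2.spectra]
        for a, b in zip(run1.spectra, run2.spectra):
            np.testing.assert_array_equal(a.intensity, b.intensity)
        for tid in truth1.targets:
            assert truth1.targets[tid].ms2_scan_ids == truth2.targets[tid].ms2_scan_ids
            assert truth1.targets[tid].ms1_area == truth2.targets[tid].ms1_area


class TestDdaScheduler:
    def test_single_target_schedule_matches_hand_simulation(self):
        """3 acquisitions, 30 s exclusion, re-selection — against an
        independent re-simulation of the timeline."""
        target = flat_target(rt_apex=1.0, intensity=1000.0)
        cfg = AcquisitionConfig.for_dda(gradient_length=2.0, noise_cv=0.0, seed=0)
        run, truth = simulate_dda_run([target], cfg)
        got_cycles = [
            int(sid.split("_")[0].removeprefix("cycle"))
            for sid in truth.targets["flat"].ms2_scan_ids
        ]
        expected = dda_schedule_oracle(
            cfg.cycle_time, cfg.gradient_length, cfg.dda_exclusion_after, cfg.dda_exclusion_s
        )
        assert got_cycles == expected

    def test_top_four_rule(self):
        targets = [
            flat_target(f"t{i}", 500.0 + 10 * i, rt_apex=1.0, mz_mass=400.0 + i)
            for i in range(5)
        ]
        cfg = AcquisitionConfig.for_dda(gradient_length=0.05, noise_cv=0.0, seed=0)
        run, _ = simulate_dda_run(targets, cfg)
        per_cycle = _ms2_per_cycle(run)
        assert max(per_cycle.values()) == 4
        # the least intense precursor is the one left out
        first_cycle_ids = {s.scan_id for s in run.ms2_spectra() if s.scan_id.startswith("cycle0_")}
        assert "cycle0_ms2_t0" not in first_cycle_ids

    def test_zero_targets_gives_ms1_only_run(self):
        cfg = AcquisitionConfig.for_dda(gradient_length=0.1, seed=0)
        run, truth = simulate_dda_run([], cfg)
        assert len(run.ms2_spectra()) == 0
        assert len(run.ms1_spectra()) > 0


class TestMrmTraces:
    def test_noiseless_apex_closed_form(self):
        target = SimTarget("t", 470.2668, "M+H", 1.0, 0.05, 120.0, 10.0, ((281.19, 1.0),))
        cfg = AcquisitionConfig(gradient_length=2.0, noise_cv=0.0, seed=0)
        (trace,) = simulate_mrm_traces([target], cfg)
        assert trace.intensity.max() == pytest.approx(120.0 * 10.0, rel=1e-4)

    def test_glycoside_apex_attenuated_by_insource_loss(self):
        glyco = SimTarget(
            "g", 782.4089, "M+NH4", 1.0, 0.05, 120.0, 10.0, ((621.36, 1.0),), is_glycoside=True
        )
        apex = {}
        for temp in (400.0, 550.0):
            cfg = AcquisitionConfig(
                gradient_length=2.0, noise_cv=0.0, desolvation_temperature=temp, seed=0
            )
            (trace,) = simulate_mrm_traces([glyco], cfg)
            apex[temp] = trace.intensity.max()
            assert apex[temp] == pytest.approx(
                1200.0 * (1.0 - insource_fraction(temp)), rel=1e-4
            )
        assert apex[550.0] < apex[400.0]

    def test_non_glycoside_invariant_to_temperature(self):
        target = SimTarget("t", 470.2668, "M+H", 1.0, 0.05, 120.0, 10.0, ((281.19, 1.0),))
        traces = []
        for temp in (400.0, 550.0):
            cfg = AcquisitionConfig(
                gradient_length=2.0, noise_cv=0.02, desolvation_temperature=temp, seed=5
            )
            traces.append(simulate_mrm_traces([target], cfg)[0])
        np.testing.assert_array_equal(traces[0].intensity, traces[1].intensity)


class TestInsourceModel:
    def test_half_conversion_at_midpoint(self):
        assert insource_fraction(450.0) == pytest.approx(0.5)

    def test_monotone_in_temperature(self):
        temps = np.linspace(300, 600, 31)
        fracs = [insource_fraction(t) for t in temps]
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_ratio_surface_table(self):
        table = glycone_aglycone_surface([400.0, 500.0], [2.0, 3.0])
        assert len(table) == 4
        r400 = table.loc[table["desolvation_temperature"] == 400.0, "glycone_aglycone_ratio"]
        r500 = table.loc[table["desolvation_temperature"] == 500.0, "glycone_aglycone_ratio"]
        assert r400.min() > r500.max()
        # voltage is a pass-through label: ratio identical across voltages
        assert r400.nunique() == 1


class TestNoiselessAnalyticArea:
    def test_extracted_area_matches_gaussian_closed_form(self):
        target = SimTarget("g", 470.2668, "M+H", 1.0, 0.05, 150.0, 20.0, ((281.19, 1.0),))
        cfg = AcquisitionConfig(gradient_length=2.0, noise_cv=0.0, seed=0)
        run, truth = simulate_prm_run([target], [], cfg)
        area = extract_ms1_area(run, target.precursor_mz, 1.0, 1.0)
        analytic = 150.0 * 20.0 * 0.05 * math.sqrt(2 * math.pi)
        assert truth.targets["g"].ms1_area == pytest.approx(analytic, rel=1e-12)
        assert area.area == pytest.approx(analytic, rel=0.02)


class TestCalibrationSeries:
    def test_paper_design_30_runs(self):
        panel = default_panel()[:2] + default_panel()[-1:]
        levels = [0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0, 5000.0, 10000.0]
        cfg = AcquisitionConfig(gradient_length=0.05, noise_cv=0.0, seed=0)
        acqs, design = simulate_calibration_series(
            panel, levels, 3, cfg, mode="mrm", internal_standard_id="digoxin_d3"
        )
        assert len(acqs) == 30
        assert design.groupby("sample_id").ngroups == 30
        is_rows = design[design["target_id"] == "digoxin_d3"]
        assert is_rows["concentration_ng_ml"].nunique() == 1

    def test_noiseless_single_replicate_recovers_slope(self):
        target = SimTarget("t", 470.2668, "M+H", 1.0, 0.05, 120.0, 1.0, ((281.19, 1.0),))
        cfg = AcquisitionConfig(gradient_length=2.0, noise_cv=0.0, seed=0)
        acqs, design = simulate_calibration_series(
            [target], [1.0, 10.0, 100.0], 1, cfg, mode="mrm"
        )
        from prmquant.extract import integrate_transition

        areas = {
            sid: integrate_transition(traces[0], 1.0, 1.0).area
            for sid, traces, _ in acqs
        }
        xs = design.set_index("sample_id")["concentration_ng_ml"]
        ratios = [(xs[sid], area) for sid, area in areas.items()]
        slope = np.polyfit([x for x, _ in ratios], [a for _, a in ratios], 1)[0]
        expected = 120.0 * 0.05 * math.sqrt(2 * math.pi)  # area per unit conc
        assert slope == pytest.approx(expected, rel=1e-3)

    def test_invalid_inputs_rejected(self):
        cfg = AcquisitionConfig(seed=0)
        target = flat_target()
        with pytest.raises(ValueError):
            simulate_calibration_series([target], [0.0, 1.0], 1, cfg)
        with pytest.raises(ValueError):
            simulate_calibration_series([target], [1.0], 0, cfg)
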