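"""Extraction and integration: scan matching, fragment traces, areas, adducts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prmquant.extract import (
    FragmentTrace,
    assign_ms2_scans,
    compute_adduct_mz,
    extract_fragment_traces,
    extract_ms1_area,
    integrate_target,
    integrate_transition,
    match_ms2_scans,
    quantify_prm,
    select_top_fragments,
)
from prmquant.msdata import InclusionEntry, ReferenceSpectrum, Run, TransitionTrace
from prmquant.simulate import (
    AcquisitionConfig,
    SimTarget,
    inclusion_list_from_targets,
    reference_spectra_from_targets,
    simulate_prm_run,
)

from _oracles import PROTON_MASS, formula_mass
from conftest import make_ms1, make_ms2


class TestMatchMs2Scans:
    def test_exact_hit_inside_window(self, small_run, entry_471):
        scans = match_ms2_scans(small_run, entry_471, 20.0)
        assert [s.scan_id for s in scans] == ["s2", "s3", "s4"]

    def test_outside_window_empty(self, small_run):
        entry = InclusionEntry("wfa", 471.2740, 6.0, 1.0)
        assert match_ms2_scans(small_run, entry, 20.0) == []

    def test_ppm_tolerance_excludes_distant_precursor(self, small_run):
        entry = InclusionEntry("other", 471.2940, 5.0, 1.0)  # ~42 ppm away
        assert match_ms2_scans(small_run, entry, 20.0) == []

    def test_matches_simulator_truth_log(self):
        """Extraction recovers exactly the scans the scheduler emitted."""
        targets = [
            SimTarget("a", 470.2668, "M+H", 0.6, 0.04, 300.0, 10.0, ((281.19, 1.0),)),
            SimTarget("b", 500.2700, "M+H", 1.3, 0.04, 250.0, 10.0, ((311.20, 1.0),)),
        ]
        cfg = AcquisitionConfig(gradient_length=2.0, noise_cv=0.0, seed=0)
        run, truth = simulate_prm_run(targets, inclusion_list_from_targets(targets), cfg)
        for target in targets:
            entry = next(
                e for e in inclusion_list_from_targets(targets) if e.target_id == target.target_id
            )
            matched = [s.scan_id for s in match_ms2_scans(run, entry, 25.0)]
            assert matched == truth.targets[target.target_id].ms2_scan_ids
            assert len(matched) > 0

    def test_exclusive_assignment_tie_rule(self):
        """A scan matching two entries goes to the nearer one only."""
        scan = make_ms2("x", 5.05, 471.2740, [(281.19, 1.0)])
        run = Run("r", [make_ms1("m", 5.0, [(471.2740, 10.0)]), scan])
        near = InclusionEntry("near", 471.2740, 5.0, 1.0)
        far = InclusionEntry("far", 471.2740, 5.4, 1.0)
        assigned = assign_ms2_scans(run, [far, near], 25.0)
        assert [s.scan_id for s in assigned["near"]] == ["x"]
        assert assigned["far"] == []


class TestSelectTopFragments:
    @pytest.mark.parametrize(
        "n,expected",
        [(2, [281.19, 263.18]), (1, [281.19]), (10, [281.19, 263.18, 109.06])],
    )
    def test_top_n_by_intensity(self, n, expected):
        ref = ReferenceSpectrum("t", ((281.19, 1.0), (263.18, 0.6), (109.06, 0.3)))
        assert select_top_fragments(ref, n) == pytest.approx(expected)

    def test_tie_broken_by_lower_mz(self):
        ref = ReferenceSpectrum("t", ((281.19, 1.0), (263.18, 0.6), (300.20, 0.6)))
        assert select_top_fragments(ref, 2) == [281.19, 263.18]


class TestFragmentTraces:
    def test_direct_lookup(self, small_run, entry_471):
        scans = match_ms2_scans(small_run, entry_471, 20.0)
        (trace,) = extract_fragment_traces(scans, [281.19], 20.0)
        np.testing.assert_allclose(trace.intensity, [10.0, 100.0, 10.0])

    def test_absent_fragment_all_zero(self, small_run, entry_471):
        scans = match_ms2_scans(small_run, entry_471, 20.0)
        (trace,) = extract_fragment_traces(scans, [999.99], 20.0)
        np.testing.assert_array_equal(trace.intensity, 0.0)

    def test_two_centroids_within_tolerance_summed(self):
        # 20 ppm of 281.19 is ~0.0056 Th, so both centroids fall in-window
        scan = make_ms2("x", 1.0, 471.27, [(281.1900, 40.0), (281.1925, 10.0)])
        (trace,) = extract_fragment_traces([scan], [281.19], 20.0)
        assert trace.intensity[0] == pytest.approx(50.0)


class TestIntegrateTarget:
    def test_rectangular_trapezoid(self):
        tr = FragmentTrace("t", 281.19, [0.0, 1.0, 2.0, 3.0], [0.0, 100.0, 100.0, 0.0])
        area = integrate_target([tr])
        assert area.area == pytest.approx(200.0)
        assert area.n_scans == 4

    def test_all_zero_traces(self):
        tr = FragmentTrace("t", 281.19, [0.0, 1.0], [0.0, 0.0])
        assert integrate_target([tr]).area == 0.0

    def test_linearity_two_identical_traces(self):
        rt = [0.0, 0.5, 1.0]
        inten = [0.0, 60.0, 0.0]
        one = integrate_target([FragmentTrace("t", 281.19, rt, inten)])
        two = integrate_target(
            [FragmentTrace("t", 281.19, rt, inten), FragmentTrace("t", 263.18, rt, inten)]
        )
        assert two.area == pytest.approx(2.0 * one.area)

    def test_mismatched_grids_rejected(self):
        a = FragmentTrace("t", 281.19, [0.0, 1.0], [1.0, 1.0])
        b = FragmentTrace("t", 263.18, [0.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="mismatched"):
            integrate_target([a, b])

    def test_single_scan_yields_zero_area_with_warning(self):
        tr = FragmentTrace("t", 281.19, [1.0], [50.0])
        with pytest.warns(UserWarning):
            area = integrate_target([tr])
        assert area.area == 0.0 and area.n_scans == 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        intensities=st.lists(
            st.lists(st.floats(0, 1e6), min_size=4, max_size=4), min_size=1, max_size=4
        ),
        scale=st.floats(1e-3, 1e3),
    )
    def test_sum_then_integrate_equals_integrate_then_sum(self, intensities, scale):
        """The two readings of 'integrate the top ions' coincide, and areas
        scale linearly with intensity."""
        rt = [0.0, 0.4, 0.8, 1.2]
        traces = [
            FragmentTrace("t", 100.0 + i, rt, np.array(vals))
            for i, vals in enumerate(intensities)
        ]
        combined = integrate_target(traces).area
        separate = sum(integrate_target([t]).area for t in traces)
        assert combined == pytest.approx(separate, rel=1e-9, abs=1e-9)
        scaled = integrate_target(
            [FragmentTrace(t.target_id, t.fragment_mz, t.rt, t.intensity * scale) for t in traces]
        ).area
        assert scaled == pytest.approx(combined * scale, rel=1e-9, abs=1e-12)


class TestMs1Area:
    def test_triangle_peak(self):
        run = Run(
            "r",
            [
                make_ms1("a", 4.5, [(471.2740, 0.0)]),
                make_ms1("b", 5.0, [(471.2740, 100.0)]),
                make_ms1("c", 5.5, [(471.2740, 0.0)]),
            ],
        )
        area = extract_ms1_area(run, 471.2740, 5.0, 1.0, 20.0)
        assert area.area == pytest.approx(50.0)
        assert area.mode == "dda_ms1"

    def test_absent_mz_zero_area(self):
        run = Run("r", [make_ms1("a", 4.9, [(100.0, 5.0)]), make_ms1("b", 5.1, [(100.0, 5.0)])])
        assert extract_ms1_area(run, 471.2740, 5.0, 1.0, 20.0).area == 0.0

    def test_no_scans_in_window_warns(self):
        run = Run("r", [make_ms1("a", 1.0, [(100.0, 5.0)])])
        with pytest.warns(UserWarning, match="no MS1 scans"):
            area = extract_ms1_area(run, 100.0, 9.0, 1.0, 20.0)
        assert area.area == 0.0 and area.n_scans == 0

    def test_simulated_gaussian_matches_closed_form(self):
        target = SimTarget("g", 470.2668, "M+H", 1.0, 0.05, 200.0, 10.0, ((281.19, 1.0),))
        cfg = AcquisitionConfig(gradient_length=2.0, noise_cv=0.0, seed=0)
        run, truth = simulate_prm_run([target], [], cfg)
        area = extract_ms1_area(run, target.precursor_mz, 1.0, 1.0, 25.0)
        assert area.area == pytest.approx(truth.targets["g"].ms1_area, rel=0.02)


class TestIntegrateTransition:
    def test_rectangular(self):
        tr = TransitionTrace("t", 471.27, 281.19, [0.0, 1.0, 2.0, 3.0], [0.0, 100.0, 100.0, 0.0])
        assert integrate_transition(tr, 1.5, 3.0).area == pytest.approx(200.0)

    def test_window_excluding_all_points(self):
        tr = TransitionTrace("t", 471.27, 281.19, [0.0, 1.0], [10.0, 10.0])
        assert integrate_transition(tr, 9.0, 1.0).area == 0.0

    def test_split_at_shared_boundary_is_additive(self):
        rt = np.linspace(0.0, 2.0, 21)
        inten = np.exp(-0.5 * ((rt - 1.0) / 0.2) ** 2) * 100.0
        tr = TransitionTrace("t", 471.27, 281.19, rt, inten)
        full = integrate_transition(tr, 1.0, 2.0).area
        left = integrate_transition(tr, 0.5, 1.0).area
        right = integrate_transition(tr, 1.5, 1.0).area
        assert left + right == pytest.approx(full, rel=1e-9)

    def test_empty_trace_rejected(self):
        tr = TransitionTrace("t", 471.27, 281.19, [], [])
        with pytest.raises(ValueError, match="empty"):
            integrate_transition(tr, 1.0, 1.0)


class TestAdducts:
    def test_offset_definition(self):
        assert compute_adduct_mz(1e-12, "M+H") == pytest.approx(1.007276, abs=1e-6)

    def test_withaferin_a_protonated(self):
        """Independent oracle: sum of atomic masses for C28H38O6 plus a proton."""
        mass = formula_mass({"C": 28, "H": 38, "O": 6})
        assert mass == pytest.approx(470.2668, abs=5e-4)
        assert compute_adduct_mz(mass, "M+H") == pytest.approx(mass + PROTON_MASS, abs=1e-6)
        assert compute_adduct_mz(470.2668, "M+H") == pytest.approx(471.2741, abs=5e-4)

    def test_water_loss_identity(self):
        m = 470.2668
        assert compute_adduct_mz(m, "M-H2O+H") == pytest.approx(
            compute_adduct_mz(m, "M+H") - 18.010565, abs=1e-9
        )

    def test_unknown_adduct_rejected(self):
        with pytest.raises(ValueError, match="unknown adduct"):
            compute_adduct_mz(470.0, "M+K")


class TestPrmQuantitation:
    def test_area_monotone_in_concentration(self):
        areas = []
        for conc in (1.0, 10.0, 100.0):
            target = SimTarget(
                "a", 470.2668, "M+H", 1.0, 0.05, 200.0, conc, ((281.19, 1.0), (263.18, 0.5))
            )
            cfg = AcquisitionConfig(gradient_length=2.0, noise_cv=0.0, seed=0)
            entries = inclusion_list_from_targets([target])
            run, _ = simulate_prm_run([target], entries, cfg)
            (area,) = quantify_prm(run, entries, reference_spectra_from_targets([target]))
            areas.append(area.area)
        assert areas[0] < areas[1] < areas[2]
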