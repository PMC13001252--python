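"""Deconvolution: axis profiles, thresholding rules, triangulation, oracle."""

import math

import numpy as np
import pytest

import tnarray as tn
from tnarray.deconvolve import (
    AMBIGUOUS,
    AUTO,
    MULTILOCATED,
    TRIANGULATED,
    UNRESOLVED,
    AxisProfile,
    DeconvolutionConfig,
)

from conftest import matrix_from_rows


class TestAxisProfiles:
    def test_partition_sizes_follow_design(self):
        d = tn.build_design(19, 19, 8, 12)
        profiles = tn.axis_profiles(np.zeros(58, dtype=int), d)
        sizes = {a: len(p.counts) for a, p in profiles.items()}
        assert sizes == {"WELL_COL": 12, "WELL_ROW": 8, "PLATE_COL": 19, "PLATE_ROW": 19}

    def test_all_zero_row(self, small_design):
        profiles = tn.axis_profiles(np.zeros(small_design.n_pools, dtype=int), small_design)
        assert all(p.top == 0 and p.snr == 0.0 for p in profiles.values())

    def test_top_second_snr_arithmetic(self):
        p = AxisProfile("WELL_COL", (450, 30, 0, 0, 0, 0))
        assert p.top_coord == 1 and p.top == 450 and p.second == 30
        assert p.snr == pytest.approx(15.0)

    def test_length_mismatch_rejected(self, small_design):
        with pytest.raises(ValueError):
            tn.axis_profiles(np.zeros(5), small_design)


class TestResolveAxis:
    config = DeconvolutionConfig()  # thresholds 50 and 9

    def resolve(self, counts):
        return tn.resolve_axis(AxisProfile("WELL_COL", tuple(counts)), self.config)

    def test_clear_peak_resolves(self):
        r = self.resolve([450, 30, 0, 0])
        assert r.resolved and r.coord == 1 and r.snr == pytest.approx(15.0)

    def test_low_snr_keeps_both_candidates(self):
        r = self.resolve([450, 60, 0, 0])
        assert not r.resolved
        assert r.candidates == {1, 2}  # 60 >= max(10, 450/9) = 50

    def test_below_primary_threshold(self):
        r = self.resolve([40, 3, 0, 0])
        assert not r.resolved
        assert r.candidates == {1}  # floor max(10, 40/9) = 10

    def test_zero_second_is_infinite_snr(self):
        r = self.resolve([500, 0, 0, 0])
        assert r.resolved and r.snr == math.inf

    def test_exact_tie_unresolved(self):
        r = self.resolve([500, 500, 0, 0])
        assert not r.resolved and r.candidates == {1, 2}

    def test_raising_snr_threshold_never_resolves_more(self):
        counts = [450, 30, 12, 0]
        resolved = [
            tn.resolve_axis(
                AxisProfile("WELL_COL", tuple(counts)),
                DeconvolutionConfig(snr_threshold=s),
            ).resolved
            for s in (2, 9, 15, 16, 40)
        ]
        assert resolved == sorted(resolved, reverse=True)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DeconvolutionConfig(primary_threshold=0)
        with pytest.raises(ValueError):
            DeconvolutionConfig(snr_threshold=1.0)
        with pytest.raises(ValueError):
            DeconvolutionConfig(candidate_floor=100, primary_threshold=50)


class TestFirstPass:
    def test_noise_free_round_trip(self, reference, small_design):
        pl = tn.simulate_picking(reference, small_design, 50, duplicate_rate=0.0, seed=5)
        m = tn.simulate_pool_counts(pl, small_design, tn.NoiseModel.noise_free())
        a = tn.assign_first_pass(m, small_design)
        assert all(x.status == AUTO for x in a.values())
        assert all(a[s].well == pl.wells_of(s)[0] for s in a)

    def test_duplicate_clone_is_multilocated(self, small_design):
        # one clone in two wells differing on every axis: two peaks per axis
        m = matrix_from_rows(small_design, {
            "S1": {"WC01": 400, "WC02": 380, "WRA": 400, "WRB": 380,
                   "PC01": 400, "PC02": 380, "PR01": 400, "PR02": 380},
        })
        a = tn.assign_first_pass(m, small_design)
        assert a["S1"].status == MULTILOCATED

    def test_auto_conflict_demoted_to_ambiguous(self, small_design):
        peaks = {"WC01": 500, "WRA": 500, "PC01": 500, "PR01": 500}
        m = matrix_from_rows(small_design, {"S1": peaks, "S2": peaks})
        a = tn.assign_first_pass(m, small_design)
        assert a["S1"].status == AMBIGUOUS and a["S2"].status == AMBIGUOUS
        assert a["S1"].well is None

    def test_empty_matrix(self, small_design):
        m = matrix_from_rows(small_design, {})
        assert tn.assign_first_pass(m, small_design) == {}


class TestTriangulate:
    def test_recovers_site_blocked_by_auto(self, small_design):
        m = matrix_from_rows(small_design, {
            "X": {"WC01": 500, "WRA": 500, "PC01": 500, "PR01": 500},
            "Y": {"WC01": 450, "WC02": 60, "WRA": 500, "PC01": 500, "PR01": 500},
        })
        first = tn.assign_first_pass(m, small_design)
        assert first["Y"].status == UNRESOLVED
        final = tn.triangulate(first, small_design)
        assert final["X"].status == AUTO
        assert final["Y"].status == TRIANGULATED
        assert final["Y"].well == tn.WellAddress(1, 1, 1, 2)

    def test_fixpoint_with_nothing_unresolved(self, reference, small_design):
        pl = tn.simulate_picking(reference, small_design, 30, duplicate_rate=0.0, seed=5)
        m = tn.simulate_pool_counts(pl, small_design, tn.NoiseModel.noise_free())
        first = tn.assign_first_pass(m, small_design)
        snapshot = {s: (a.status, a.well) for s, a in first.items()}
        final = tn.triangulate(first, small_design)
        assert {s: (a.status, a.well) for s, a in final.items()} == snapshot

    def test_symmetric_candidates_stay_ambiguous(self, small_design):
        shared = {"WC01": 300, "WC02": 300, "WRA": 500, "PC01": 500, "PR01": 500}
        m = matrix_from_rows(small_design, {"Y1": shared, "Y2": dict(shared)})
        final = tn.deconvolve(m, small_design)
        assert final["Y1"].status == AMBIGUOUS
        assert final["Y2"].status == AMBIGUOUS

    def test_assigned_wells_stay_distinct(self, reference, small_design):
        pl = tn.simulate_picking(reference, small_design, 70, duplicate_rate=0.3, seed=2)
        m = tn.simulate_pool_counts(pl, small_design, tn.NoiseModel(seed=4))
        final = tn.deconvolve(m, small_design)
        wells = [a.well for a in final.values() if a.status in (AUTO, TRIANGULATED)]
        assert len(wells) == len(set(wells))

    def test_triangulation_never_unassigns_autos(self, reference, small_design):
        pl = tn.simulate_picking(reference, small_design, 70, duplicate_rate=0.3, seed=2)
        m = tn.simulate_pool_counts(pl, small_design, tn.NoiseModel(seed=4))
        first = tn.assign_first_pass(m, small_design)
        autos = {s: a.well for s, a in first.items() if a.status == AUTO}
        final = tn.triangulate(first, small_design)
        for s, well in autos.items():
            assert final[s].status == AUTO and final[s].well == well


class TestOracle:
    @staticmethod
    def outcomes(assignments):
        return {s: (a.status, a.well) for s, a in assignments.items()}

    def test_equivalent_on_noise_free_instance(self, reference, small_design):
        pl = tn.simulate_picking(reference, small_design, 40, duplicate_rate=0.0, seed=8)
        m = tn.simulate_pool_counts(pl, small_design, tn.NoiseModel.noise_free())
        assert self.outcomes(tn.deconvolve(m, small_design)) == self.outcomes(
            tn.brute_force_oracle(m, small_design)
        )

    def test_equivalent_on_triangulation_fixture(self, small_design):
        m = matrix_from_rows(small_design, {
            "X": {"WC01": 500, "WRA": 500, "PC01": 500, "PR01": 500},
            "Y": {"WC01": 450, "WC02": 60, "WRA": 500, "PC01": 500, "PR01": 500},
        })
        assert self.outcomes(tn.deconvolve(m, small_design)) == self.outcomes(
            tn.brute_force_oracle(m, small_design)
        )

    def test_all_zero_matrix_fully_unresolved(self, small_design):
        m = matrix_from_rows(small_design, {"S1": {}, "S2": {}})
        o = tn.brute_force_oracle(m, small_design)
        assert all(a.status == UNRESOLVED for a in o.values())
        assert self.outcomes(tn.deconvolve(m, small_design)) == self.outcomes(o)

    def test_refuses_large_designs(self, reference):
        big = tn.build_design(5, 5, 8, 12)
        pl = tn.simulate_picking(reference, big, 10, duplicate_rate=0.0, seed=1)
        m = tn.simulate_pool_counts(pl, big, tn.NoiseModel.noise_free())
        with pytest.raises(ValueError):
            tn.brute_force_oracle(m, big)


def test_snr_config_monotonicity_on_noisy_instance(reference, small_design):
    """Raising the SNR threshold never increases the number of auto calls."""
    pl = tn.simulate_picking(reference, small_design, 60, duplicate_rate=0.1, seed=6)
    m = tn.simulate_pool_counts(pl, small_design, tn.NoiseModel(seed=7))
    n_auto = []
    for snr in (2.0, 5.0, 9.0, 20.0, 100.0):
        a = tn.assign_first_pass(m, small_design, DeconvolutionConfig(snr_threshold=snr))
        n_auto.append(sum(x.status == AUTO for x in a.values()))
    assert n_auto == sorted(n_auto, reverse=True)


def test_assignments_frame_columns(reference, small_design):
    pl = tn.simulate_picking(reference, small_design, 20, duplicate_rate=0.0, seed=5)
    m = tn.simulate_pool_counts(pl, small_design, tn.NoiseModel.noise_free())
    frame = tn.assignments_frame(tn.deconvolve(m, small_design), m)
    assert {"position", "strand", "status", "plate_row", "well_row"} <= set(frame.columns)
    assert len(frame) == pl.n_sites
    assert (frame["status"] == AUTO).all()
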