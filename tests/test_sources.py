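"""Singularity detection vs the Poincare-index oracle; tracking and SAC."""

import numpy as np
import pytest

from conftest import radial_source_field, smooth_random_field, vortex_field
from egflow.flow import FlowConfig, build_summary_map
from egflow.geometry import GridLocation
from egflow.preprocess import PixelGrid
from egflow.sources import (
    ACTIVE_DIVERGENT,
    PASSIVE_CONVERGENT,
    PASSIVE_ROTATIONAL,
    Detection,
    _detect_mask,
    _noise_floor,
    detect_singularities,
    match_location,
    poincare_index,
    run_detection_experiment,
    track_sources,
)
from egflow.synth import WaveScenario, simulate


class TestDetector:
    def test_radial_outflow_active_divergent_at_center(self):
        """Ideal centrifugal field: active divergent point exactly at the
        centre.  (On the wrapped spline axis the same field also carries a
        convergent point at the opposite side, where wavefronts collide.)"""
        u, v = radial_source_field(center=(16, 14))
        dets = detect_singularities((u, v))
        divergent = [d for d in dets if d.type == ACTIVE_DIVERGENT]
        assert len(divergent) == 1
        assert (divergent[0].row_px, divergent[0].col_px) == (16, 14)
        assert divergent[0].radial > 0
        for other in dets:
            if other.type != ACTIVE_DIVERGENT:
                assert other.type == PASSIVE_CONVERGENT
                assert other.row_px in (0, 1, 31)  # wrap antipode of row 16

    def test_radial_inflow_passive_convergent(self):
        u, v = radial_source_field(center=(10, 10))
        dets = [d for d in detect_singularities((-u, -v)) if d.type == PASSIVE_CONVERGENT]
        assert len(dets) == 1
        assert (dets[0].row_px, dets[0].col_px) == (10, 10)

    def test_vortex_passive_rotational_with_winding_oracle(self):
        u, v = vortex_field(center=(12, 12))
        dets = detect_singularities((u, v))
        at_center = [d for d in dets if (d.row_px, d.col_px) == (12, 12)]
        assert len(at_center) == 1
        det = at_center[0]
        assert det.type == PASSIVE_ROTATIONAL
        assert abs(det.tangential) > abs(det.radial)
        assert abs(poincare_index(u, v, det.row_px, det.col_px)) == 1

    def test_uniform_flow_no_detection(self):
        u = np.ones((32, 29))
        v = 0.3 * np.ones((32, 29))
        assert detect_singularities((u, v)) == []

    def test_sector_coverage_equals_winding_number_on_random_fields(self):
        """Oracle equivalence: on >= 500 smooth random fields, the detector's
        coverage mask matches |Poincare index| = 1 at every pixel above the
        noise floor."""
        rng = np.random.default_rng(2024)
        n_fields = 500
        checked = 0
        disagreements = 0
        for _ in range(n_fields):
            u, v = smooth_random_field(rng, shape=(16, 16), n_modes=3)
            floor = _noise_floor(u, v, 0.05)
            mask, _rad, _tan = _detect_mask(u, v, floor)
            for r in range(16):
                for c in range(1, 15):
                    idx = poincare_index(u, v, r, c, noise_floor=floor)
                    if idx is None:
                        assert not mask[r, c]  # sub-floor ring never detects
                        continue
                    checked += 1
                    if mask[r, c] != (abs(idx) == 1):
                        disagreements += 1
        assert checked > 50_000
        assert disagreements == 0

    def test_noise_floor_suppresses_jitter(self):
        rng = np.random.default_rng(0)
        u = 1e-9 * rng.normal(size=(32, 29))
        v = 1e-9 * rng.normal(size=(32, 29))
        u[:16] += 1.0  # strong coherent flow sets the floor
        dets = detect_singularities((u, v))
        # tiny-jitter region cannot vote its way to 360-deg coverage
        assert all(d.row_px < 17 for d in dets)


class TestMatchLocation:
    @pytest.mark.parametrize(
        "src,site,expected",
        [("E6", "E6", True), ("E7", "E6", True), ("B3", "E6", False), ("A4", "H4", True)],
    )
    def test_examples(self, src, site, expected):
        from egflow.geometry import label_to_grid

        assert match_location(label_to_grid(src), site) is expected


class _FakeSegmentMap:
    """Minimal stand-in segment map carrying scripted detections."""

    def __init__(self, index, detections, grid, n_frame_pairs=104):
        self.segment_index = index
        self.detections = detections
        self.grid = grid
        self.n_frame_pairs = n_frame_pairs


def _active_det(row_px, col_px):
    return Detection(row_px, col_px, ACTIVE_DIVERGENT, radial=0.5, tangential=0.0)


@pytest.fixture
def grid(geometry):
    return PixelGrid(geometry)


class TestTracking:
    def test_always_on_source_sac_100(self, grid):
        maps = [
            _FakeSegmentMap(s, [[_active_det(16, 16)] for _ in range(104)], grid)
            for s in range(3)
        ]
        summary, everything = track_sources(maps)
        assert len(everything) == 1
        src = everything[0]
        assert src.summary_sac == pytest.approx(100.0)
        assert src.label == "E5"
        assert summary == everything

    def test_never_detected_absent(self, grid):
        maps = [_FakeSegmentMap(s, [[] for _ in range(104)], grid) for s in range(3)]
        summary, everything = track_sources(maps)
        assert summary == [] and everything == []

    def test_half_on_schedule_gives_50pct_sac(self, grid):
        """Source active in all frames of 15 of 30 segments -> SAC 50%."""
        maps = []
        for s in range(30):
            dets = [[_active_det(16, 16)] if s < 15 else [] for _ in range(104)]
            maps.append(_FakeSegmentMap(s, dets, grid))
        _, everything = track_sources(maps)
        assert everything[0].summary_sac == pytest.approx(50.0)
        assert everything[0].first_segment_active == 0
        assert everything[0].last_segment_active == 14

    def test_sub_threshold_source_kept_in_diagnostics_only(self, grid):
        maps = []
        for s in range(30):
            dets = [[_active_det(16, 16)] if (s == 0 and f < 50) else [] for f in range(104)]
            maps.append(_FakeSegmentMap(s, dets, grid))
        summary, everything = track_sources(maps)
        assert summary == []
        assert len(everything) == 1
        assert everything[0].summary_sac == pytest.approx(100 * 50 / 104 / 30)

    def test_nearby_detections_cluster_to_one_source(self, grid):
        maps = [
            _FakeSegmentMap(
                0,
                [[_active_det(16 + (f % 2), 16 - (f % 3))] for f in range(104)],
                grid,
            )
        ]
        _, everything = track_sources(maps)
        assert len(everything) == 1

    def test_passive_detections_never_contribute_sac(self, grid):
        dets = [
            [Detection(16, 16, PASSIVE_ROTATIONAL, radial=0.0, tangential=0.6)]
            for _ in range(104)
        ]
        maps = [_FakeSegmentMap(0, dets, grid)]
        _, everything = track_sources(maps)
        assert everything[0].summary_sac == 0.0
        assert everything[0].type == PASSIVE_ROTATIONAL

    def test_low_contact_flag_propagates(self, grid):
        from egflow.preprocess import ContactReport

        maps = [_FakeSegmentMap(0, [[_active_det(16, 16)] for _ in range(104)], grid)]
        contact = ContactReport(near_field_score={"E5": 0.2}, low_contact_flags={"E5"})
        summary, _ = track_sources(maps, contact=contact)
        assert summary[0].unreliable_contact is True


class TestEndToEndDetection:
    def test_source_vanishes_when_pacing_stops(self):
        """No source outlives its field: activity gated off after segment 1
        yields zero SAC in the off segments."""
        scn = WaveScenario(
            kind="fibrillatory",
            origin=GridLocation(4, 4),
            cycle_length_ms=100.0,
            activity_schedule=(1.0, 1.0, 0.0, 0.0),
            seed=6,
        )
        rec, _ = simulate(scn, duration=8.0)
        summary = build_summary_map(rec)
        src = next(s for s in summary.all_sources if match_location(s, GridLocation(4, 4)))
        on = src.per_segment_activity[:2].mean()
        off = src.per_segment_activity[2:].mean()
        assert on > 15.0
        assert off < on / 5.0

    def test_schedule_fraction_recovered_in_sac(self):
        """15 of 30 segments on -> summary SAC near 50% of the always-on SAC."""
        sched = tuple(1.0 if s < 8 else 0.0 for s in range(16))
        scn = WaveScenario(
            kind="fibrillatory",
            origin=GridLocation(4, 4),
            cycle_length_ms=100.0,
            activity_schedule=sched,
            seed=7,
        )
        rec, _ = simulate(scn, duration=32.0)
        summary = build_summary_map(rec)
        src = next(s for s in summary.all_sources if match_location(s, GridLocation(4, 4)))
        act = src.per_segment_activity
        assert act[:8].mean() > 5 * max(act[8:].mean(), 1e-9)

    def test_experiment_report_shapes(self):
        scenarios = [
            WaveScenario(kind="focal_paced", origin=GridLocation(4, 3), seed=1),
            WaveScenario(kind="subthreshold_artifact", origin=GridLocation(2, 5), seed=2),
        ]
        table, report = run_detection_experiment(scenarios, duration=8.0)
        assert len(table) == 2
        assert set(report) == {"focal_paced", "subthreshold_artifact"}
        assert (table["error"] == "").all()
        for r in report.values():
            assert 0.0 <= r["detection_rate_pct"] <= 100.0
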