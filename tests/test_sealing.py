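"""Sealing analysis: distances, classification, area bookkeeping, 2D map."""

import numpy as np
import pytest

from tavrseal import anatomy, sealing
from tavrseal.frame import FrameParams, build_frame
from tavrseal.sealing import (
    SealingSummary,
    SkirtElementRecord,
    classify,
    element_distance,
    project_2d,
    pvl_surrogate,
    skirt_records,
    summarize,
)

from conftest import make_tube


def make_records(specs):
    """specs: list of (area, distance, region) -> classified records."""
    recs = []
    for i, (area, dist, region) in enumerate(specs):
        th = 2 * np.pi * i / len(specs)
        recs.append(SkirtElementRecord(
            i, np.array([10 * np.cos(th), 10 * np.sin(th), 5.0]),
            area, region, dist))
    return classify(recs)


class TestElementDistance:
    def test_concentric_cylinders(self):
        tube = make_tube(12.0, 0.0, 10.0)
        for th in np.linspace(0, 2 * np.pi, 17):
            c = np.array([10 * np.cos(th), 10 * np.sin(th), 5.0])
            n = np.array([np.cos(th), np.sin(th), 0.0])
            dist, region, _, fb = element_distance(c, n, tube)
            assert dist == pytest.approx(2.0, abs=1e-6)
            assert region == anatomy.LVOT
            assert not fb

    def test_touching_surfaces_give_zero(self):
        tube = make_tube(10.0, 0.0, 10.0)
        c = np.array([10.0, 0.0, 5.0])
        dist, _, _, _ = element_distance(c, np.array([1.0, 0, 0]), tube)
        assert dist == pytest.approx(0.0, abs=1e-9)

    def test_fallback_and_unresolved(self):
        tube = make_tube(12.0, 0.0, 10.0)
        # element above the tube: the outward ray misses, nearest point works
        c = np.array([10.0, 0.0, 12.0])
        dist, region, _, fb = element_distance(c, np.array([1.0, 0, 0]), tube)
        assert fb and np.isfinite(dist)
        assert region == anatomy.LVOT
        # far away: unresolved
        c = np.array([10.0, 0.0, 200.0])
        dist, region, _, fb = element_distance(c, np.array([1.0, 0, 0]), tube)
        assert region == sealing.UNRESOLVED and np.isinf(dist)

    def test_degenerate_normal_rejected(self):
        tube = make_tube(12.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            element_distance(np.zeros(3), np.zeros(3), tube)


class TestClassify:
    def test_strict_threshold_semantics(self):
        recs = make_records([(1.0, 0.99, anatomy.LVOT),
                             (1.0, 1.00, anatomy.LVOT),
                             (1.0, 1.01, anatomy.LVOT)])
        assert [r.apposed for r in recs] == [True, False, False]

    def test_zero_threshold_malapposes_everything(self):
        recs = make_records([(1.0, 0.0, anatomy.LVOT), (1.0, 0.5, anatomy.LVOT)])
        classify(recs, threshold=0.0)
        assert not any(r.apposed for r in recs)


class TestSummarize:
    def test_all_apposed(self):
        recs = make_records([(2.0, 0.1, r) for r in sealing.CORE_REGIONS])
        s = summarize(recs)
        assert s.malapposition_total_pct == 0.0
        assert s.total_skirt_area == pytest.approx(6.0)

    def test_half_and_half(self):
        specs = []
        for i in range(40):
            region = sealing.CORE_REGIONS[i % 3]
            specs.append((1.0, 0.5 if i % 2 == 0 else 1.5, region))
        s = summarize(make_records(specs))
        assert s.malapposition_total_pct == pytest.approx(50.0, abs=0.5)

    def test_area_conservation_and_percentage_identities(self):
        rng = np.random.default_rng(5)
        specs = [(float(rng.uniform(0.5, 2.0)), float(rng.uniform(0, 3)),
                  sealing.CORE_REGIONS[int(rng.integers(3))]) for _ in range(60)]
        s = summarize(make_records(specs))
        total = sum(a for a, _, _ in specs)
        assert s.total_skirt_area == pytest.approx(total)
        per_region = sum(s.malapposition_pct(r) for r in sealing.CORE_REGIONS)
        assert per_region == pytest.approx(s.malapposition_total_pct, abs=0.1)
        contrib = sum(s.apposition_contribution_pct(r)
                      for r in sealing.CORE_REGIONS)
        assert contrib == pytest.approx(100.0, abs=0.1)

    def test_published_tav_column_arithmetic(self):
        s = SealingSummary.from_areas(
            apposed={"LVOT": 157.4, "INTERLEAFLET_TRIANGLE": 175.1,
                     "LEAFLET": 611.5},
            malapposed={"LVOT": 52.0, "INTERLEAFLET_TRIANGLE": 65.5,
                        "LEAFLET": 56.8},
        )
        assert s.total_skirt_area == pytest.approx(1118.3)
        assert s.malapposition_total_pct == pytest.approx(174.3 / 1118.3 * 100,
                                                          abs=1e-9)
        assert round(s.malapposition_total_pct, 1) == 15.6

    def test_unresolved_reassigned_by_angular_proximity(self):
        recs = make_records([(1.0, 0.5, anatomy.LVOT),
                             (1.0, 2.0, anatomy.LEAFLET)])
        orphan = SkirtElementRecord(99, np.array([10.0, 0.1, 5.0]), 3.0,
                                    sealing.UNRESOLVED, np.inf)
        classify([orphan])
        s = summarize(recs + [orphan])
        assert s.n_unresolved == 1
        assert s.unresolved_fraction == pytest.approx(1 / 3)
        # nearest by angle is the LVOT record at theta=0
        assert s.malapposed_area[anatomy.LVOT] == pytest.approx(3.0)

    def test_ascending_excluded_from_totals(self):
        recs = make_records([(1.0, 0.5, anatomy.LVOT),
                             (5.0, 2.0, anatomy.ASCENDING_AORTA)])
        s = summarize(recs)
        assert s.total_skirt_area == pytest.approx(1.0)
        assert s.ascending_malapposed_area == pytest.approx(5.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestThresholdMonotonicity:
    def test_malapposition_nonincreasing_in_threshold(self, deployed_tav):
        records = skirt_records(deployed_tav)
        pcts = []
        for thr in np.linspace(0.0, 3.0, 7):
            s = summarize(classify(records, thr))
            pcts.append(s.malapposition_total_pct)
        assert all(b <= a + 1e-9 for a, b in zip(pcts, pcts[1:]))


class TestProject2D:
    def test_cylindrical_skirt_unrolls_to_rectangle(self):
        p = FrameParams(size_label=26, nominal_profile=((0.0, 10.0), (50.0, 10.0)),
                        n_levels=26, n_sectors=24, skirt_height=10.0)
        fr = build_frame(p)

        class FakeState:
            frame = fr

        state = FakeState()
        records = [SkirtElementRecord(i, np.zeros(3), 1.0, anatomy.LVOT, 0.0)
                   for i in range(len(fr.skirt_elements))]
        polys, r_ref = project_2d(state, records)
        assert len(polys) == len(fr.skirt_elements)
        assert r_ref == pytest.approx(10.0)
        xs = np.concatenate([q[:, 0] for q in polys])
        assert xs.max() - xs.min() == pytest.approx(2 * np.pi * 10, rel=0.05)
        area_2d = sum(
            abs(np.dot(q[:, 0], np.roll(q[:, 1], -1))
                - np.dot(q[:, 1], np.roll(q[:, 0], -1))) / 2 for q in polys)
        nodes = fr.nodes.reshape(-1, 3)
        skirt_top = nodes[np.unique(fr.skirt_elements.ravel()), 2].max()
        assert area_2d == pytest.approx(2 * np.pi * 10 * skirt_top, rel=0.05)

    def test_unrolled_area_close_to_3d_for_deployed_state(self, deployed_tav):
        records = skirt_records(deployed_tav)
        polys, _ = project_2d(deployed_tav, records)
        area_2d = sum(
            abs(np.dot(q[:, 0], np.roll(q[:, 1], -1))
                - np.dot(q[:, 1], np.roll(q[:, 0], -1))) / 2 for q in polys)
        area_3d = sum(r.area for r in records)
        assert area_2d == pytest.approx(area_3d, rel=0.05)


class TestPVLSurrogate:
    @pytest.mark.parametrize("pct,grade", [
        (4.4, "none_or_trace"),   # representative well-sealed case
        (20.9, "mild"),           # representative bicuspid case
        (0.0, "none_or_trace"),
        (30.0, "moderate"),
    ])
    def test_grades(self, pct, grade):
        assert pvl_surrogate(pct) == grade

    def test_summary_input_and_bad_thresholds(self):
        s = SealingSummary.from_areas({"LVOT": 99.0}, {"LVOT": 1.0})
        assert pvl_surrogate(s) == "none_or_trace"
        with pytest.raises(ValueError):
            pvl_surrogate(5.0, (25.0, 10.0))
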