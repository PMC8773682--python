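import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record
from netscan.classification import (
    BIMODALITY_CUTOFF,
    CellClass,
    EstimationError,
    ReferenceLevels,
    between_class_split,
    bimodality_coefficient,
    classify_four_channel,
    classify_two_channel,
    estimate_reference_levels,
)

REFS = ReferenceLevels(intensity_ref=200.0, area_ref_um2=80.0)


def truth_table_oracle(intensity, area, refs):
    """Exhaustive boolean evaluation of the event definitions."""
    green = intensity >= refs.intensity_ref
    big = area >= refs.area_ref_um2
    if green and big:
        return CellClass.TYPE1_NET
    if green and not big:
        return CellClass.TYPE2_OTHER_DEATH
    return CellClass.TYPE3_LIVE


class TestTwoChannelGates:
    @pytest.mark.parametrize(
        "intensity_mult,area_mult,expected",
        [
            (2.0, 3.0, CellClass.TYPE1_NET),
            (2.0, 0.5, CellClass.TYPE2_OTHER_DEATH),
            (0.5, 10.0, CellClass.TYPE3_LIVE),   # intensity gate dominates
            (1.0, 1.0, CellClass.TYPE1_NET),     # boundary: >= is a responder
        ],
    )
    def test_event_definitions(self, intensity_mult, area_mult, expected):
        rec = make_record(
            avg_intensity_ch2=intensity_mult * REFS.intensity_ref,
            target_area_ch2_um2=area_mult * REFS.area_ref_um2,
        )
        assert classify_two_channel(rec, REFS) is expected

    def test_matches_truth_table_on_all_gate_combinations(self):
        for i_mult in (0.5, 1.5):
            for a_mult in (0.5, 1.5):
                rec = make_record(
                    avg_intensity_ch2=i_mult * REFS.intensity_ref,
                    target_area_ch2_um2=a_mult * REFS.area_ref_um2,
                )
                assert classify_two_channel(rec, REFS) is truth_table_oracle(
                    rec.avg_intensity_ch2, rec.target_area_ch2_um2, REFS)

    def test_matches_truth_table_on_random_records(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            rec = make_record(
                avg_intensity_ch2=float(rng.uniform(0, 500)),
                target_area_ch2_um2=float(rng.uniform(0, 300)),
            )
            assert classify_two_channel(rec, REFS) is truth_table_oracle(
                rec.avg_intensity_ch2, rec.target_area_ch2_um2, REFS)

    @given(
        intensity=st.floats(0, 1e4, allow_nan=False),
        area=st.floats(0, 1e4, allow_nan=False),
        d_area=st.floats(0, 100, allow_nan=False),
        d_int=st.floats(0, 100, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_gate_monotonicity(self, intensity, area, d_area, d_int):
        """Raising A* only moves NET -> other death; raising I* only grows
        the live class."""
        rec = make_record(avg_intensity_ch2=intensity, target_area_ch2_um2=area)
        base = classify_two_channel(rec, REFS)
        up_area = ReferenceLevels(REFS.intensity_ref, REFS.area_ref_um2 + d_area)
        after = classify_two_channel(rec, up_area)
        if base is CellClass.TYPE3_LIVE:
            assert after is CellClass.TYPE3_LIVE
        if after is CellClass.TYPE1_NET:
            assert base is CellClass.TYPE1_NET
        up_int = ReferenceLevels(REFS.intensity_ref + d_int, REFS.area_ref_um2)
        after_i = classify_two_channel(rec, up_int)
        if base is CellClass.TYPE3_LIVE:
            assert after_i is CellClass.TYPE3_LIVE


class TestFourChannelGates:
    def test_pi_positive_large_punctate_is_net(self):
        rec = make_record(
            avg_intensity_ch2=2 * REFS.intensity_ref,
            target_area_ch2_um2=4 * REFS.area_ref_um2,
            annexin_ring_ratio=1.0, annexin_cv=1.5,
        )
        assert classify_four_channel(rec, REFS) is CellClass.NET

    def test_pi_positive_small_no_surface_annexin_is_necrotic(self):
        rec = make_record(
            avg_intensity_ch2=2 * REFS.intensity_ref,
            target_area_ch2_um2=0.4 * REFS.area_ref_um2,
            annexin_ring_ratio=0.9, annexin_cv=0.2,
        )
        assert classify_four_channel(rec, REFS) is CellClass.NECROTIC

    def test_surface_annexin_without_pi_is_early_apoptotic(self):
        rec = make_record(
            avg_intensity_ch2=0.3 * REFS.intensity_ref,
            target_area_ch2_um2=0.3 * REFS.area_ref_um2,
            annexin_ring_ratio=3.5, annexin_cv=0.2,
        )
        assert classify_four_channel(rec, REFS) is CellClass.APOPTOTIC

    def test_surface_annexin_with_pi_is_late_apoptotic(self):
        rec = make_record(
            avg_intensity_ch2=2 * REFS.intensity_ref,
            target_area_ch2_um2=0.5 * REFS.area_ref_um2,
            annexin_ring_ratio=3.0, annexin_cv=0.2,
        )
        assert classify_four_channel(rec, REFS) is CellClass.APOPTOTIC

    def test_nothing_gated_is_live(self):
        rec = make_record(
            avg_intensity_ch2=0.2 * REFS.intensity_ref,
            target_area_ch2_um2=0.3 * REFS.area_ref_um2,
            annexin_ring_ratio=1.0, annexin_cv=0.1,
        )
        assert classify_four_channel(rec, REFS) is CellClass.LIVE

    def test_missing_annexin_features_raise(self):
        rec = make_record(avg_intensity_ch2=500.0)
        with pytest.raises(ValueError):
            classify_four_channel(rec, REFS)

    def test_partition_exactly_one_class(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            rec = make_record(
                avg_intensity_ch2=float(rng.uniform(0, 600)),
                target_area_ch2_um2=float(rng.uniform(0, 400)),
                annexin_ring_ratio=float(rng.uniform(0, 5)),
                annexin_cv=float(rng.uniform(0, 2)),
            )
            got = classify_four_channel(rec, REFS)
            assert got in {CellClass.NET, CellClass.NECROTIC,
                           CellClass.APOPTOTIC, CellClass.LIVE}


def brute_force_split(values):
    """Independent O(n^2)-ish oracle for the between-class-variance cut."""
    x = np.sort(np.asarray(values, float))
    best, best_cut = -np.inf, None
    for i in range(1, len(x)):
        if x[i] == x[i - 1]:
            continue
        lo, hi = x[:i], x[i:]
        bcv = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
        if bcv > best:
            best, best_cut = bcv, 0.5 * (x[i - 1] + x[i])
    return best_cut


class TestReferenceEstimation:
    def _mixture(self, rng, n=1000):
        n_hi = int(0.3 * n)
        return np.concatenate([
            rng.normal(100, 10, n - n_hi), rng.normal(1000, 100, n_hi)
        ])

    def test_bimodal_mixture_split_lands_between_modes(self):
        rng = np.random.default_rng(2)
        intensities = self._mixture(rng)
        areas = rng.normal(40, 4, len(intensities))
        control = [
            make_record(avg_intensity_ch2=float(v), area_ch1_um2=float(a))
            for v, a in zip(intensities[:300], areas[:300])
            if v < 300
        ]
        everything = [
            make_record(avg_intensity_ch2=float(v), area_ch1_um2=float(a))
            for v, a in zip(intensities, areas)
        ]
        refs = estimate_reference_levels(control, everything)
        assert 200 < refs.intensity_ref < 800
        assert refs.provenance == "AUTO"
        assert refs.intensity_ref == pytest.approx(
            brute_force_split(intensities), rel=1e-9)

    def test_area_reference_is_multiplier_times_median(self):
        rng = np.random.default_rng(3)
        control = [
            make_record(avg_intensity_ch2=5.0, area_ch1_um2=a)
            for a in rng.normal(40, 5, 200)
        ]
        everything = control + [
            make_record(avg_intensity_ch2=1000.0, area_ch1_um2=40.0)
            for _ in range(100)
        ]
        refs = estimate_reference_levels(control, everything,
                                         area_multiplier=2.0)
        median_area = np.median([r.area_ch1_um2 for r in control])
        assert refs.area_ref_um2 == pytest.approx(2.0 * median_area)

    def test_unimodal_plate_falls_back_to_median_mad(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(100, 10, 500)
        control = [
            make_record(avg_intensity_ch2=float(v), area_ch1_um2=40.0)
            for v in vals
        ]
        assert bimodality_coefficient(vals) <= BIMODALITY_CUTOFF
        refs = estimate_reference_levels(control, control)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        assert refs.intensity_ref == pytest.approx(med + 5 * mad)

    def test_too_few_control_objects_raise(self):
        recs = [make_record(avg_intensity_ch2=5.0) for _ in range(10)]
        with pytest.raises(EstimationError, match="MANUAL"):
            estimate_reference_levels(recs, recs, min_control_objects=50)

    def test_border_objects_excluded_from_estimation(self):
        interior = [make_record(avg_intensity_ch2=5.0, area_ch1_um2=40.0)
                    for _ in range(60)]
        border = [make_record(avg_intensity_ch2=5000.0, area_ch1_um2=900.0,
                              border=True) for _ in range(60)]
        hi = [make_record(avg_intensity_ch2=1000.0) for _ in range(40)]
        refs = estimate_reference_levels(interior + border,
                                         interior + border + hi)
        assert refs.area_ref_um2 == pytest.approx(80.0)


def test_between_class_split_matches_brute_force_on_random_samples():
    rng = np.random.default_rng(5)
    for _ in range(10):
        x = np.concatenate([
            rng.normal(0, 1, 50), rng.normal(rng.uniform(3, 8), 1, 50)])
        assert between_class_split(x) == pytest.approx(
            brute_force_split(x), rel=1e-12)
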