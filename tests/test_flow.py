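"""Flow-cytometry ratios: gating, normalization, simulation recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trapfish import (
    CompetitionTimecourse,
    FlowEventTable,
    chop_neon_ratio,
    competition_normalize,
    growth_ratio,
    marker_threshold_from_control,
    simulate_flow_events,
)


def table(marker, reporter):
    return FlowEventTable(
        sample_id="t", events=pd.DataFrame({"mCherry": marker, "mNeon": reporter})
    )


def constructed_table(n_neg=900, n_pos=100, neg_reporter=100.0, top_reporter=500.0,
                      other_reporter=200.0, top_frac=0.10):
    """Negatives at marker 1; positives ranked by marker so the top fraction
    has a known reporter mean."""
    n_top = int(n_pos * top_frac)
    marker = np.concatenate([
        np.ones(n_neg),
        np.linspace(10, 20, n_pos - n_top),
        np.linspace(100, 200, n_top),
    ])
    reporter = np.concatenate([
        np.full(n_neg, neg_reporter),
        np.full(n_pos - n_top, other_reporter),
        np.full(n_top, top_reporter),
    ])
    return table(marker, reporter)


class TestChopNeonRatio:
    def test_identical_reporter_everywhere_gives_one(self):
        t = table(np.concatenate([np.ones(50), np.full(50, 100.0)]), np.full(100, 7.0))
        assert chop_neon_ratio(t, "mNeon", "mCherry", positive_threshold=10) == 1.0

    def test_constructed_five_fold(self):
        t = constructed_table()
        assert chop_neon_ratio(t, "mNeon", "mCherry", positive_threshold=5) == pytest.approx(5.0)

    def test_background_subtraction(self):
        t = constructed_table(neg_reporter=150.0, top_reporter=600.0)
        r = chop_neon_ratio(t, "mNeon", "mCherry", positive_threshold=5,
                            subtract_background=100.0)
        assert r == pytest.approx((600 - 100) / (150 - 100))  # 10.0

    def test_empty_gates_error(self):
        t = table(np.full(10, 100.0), np.full(10, 1.0))
        with pytest.raises(ValueError, match="negative"):
            chop_neon_ratio(t, "mNeon", "mCherry", positive_threshold=5)
        with pytest.raises(ValueError, match="positive"):
            chop_neon_ratio(t, "mNeon", "mCherry", positive_threshold=1e6)

    def test_nonpositive_denominator_after_background_error(self):
        t = constructed_table(neg_reporter=50.0)
        with pytest.raises(ValueError, match="background"):
            chop_neon_ratio(t, "mNeon", "mCherry", positive_threshold=5,
                            subtract_background=50.0)

    @given(c=st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance_of_reporter(self, c):
        t = constructed_table()
        base = chop_neon_ratio(t, "mNeon", "mCherry", positive_threshold=5)
        scaled = table(t.events["mCherry"].to_numpy(),
                       t.events["mNeon"].to_numpy() * c)
        assert chop_neon_ratio(scaled, "mNeon", "mCherry", positive_threshold=5) == \
            pytest.approx(base, rel=1e-12)

    def test_top_frac_one_uses_all_positives(self):
        t = constructed_table()
        r_all = chop_neon_ratio(t, "mNeon", "mCherry", positive_threshold=5, top_frac=1.0)
        mean_pos = (90 * 200.0 + 10 * 500.0) / 100
        assert r_all == pytest.approx(mean_pos / 100.0)

    def test_numerator_monotone_toward_positive_mean(self):
        t = constructed_table()
        fracs = [0.1, 0.3, 0.6, 1.0]
        ratios = [chop_neon_ratio(t, "mNeon", "mCherry", positive_threshold=5, top_frac=f)
                  for f in fracs]
        assert ratios == sorted(ratios, reverse=True)  # widening the gate dilutes the top


class TestCompetitionNormalize:
    def test_ntc_maps_to_one(self):
        norm = competition_normalize(CompetitionTimecourse(
            pd.DataFrame({7.0: [50, 50], 14.0: [40, 30], 21.0: [30, 10]},
                         index=["NTC", "sgX"])), reference_day=7.0)
        assert np.allclose(norm.loc["NTC"], 1.0)

    def test_worked_example(self):
        tc = CompetitionTimecourse(
            pd.DataFrame({7.0: [50.0, 40.0], 14.0: [50.0, 20.0]}, index=["NTC", "sg"])
        )
        norm = competition_normalize(tc, reference_day=7.0)
        assert norm.loc["sg", 7.0] == pytest.approx(1.0)
        assert norm.loc["sg", 14.0] == pytest.approx(0.5)

    def test_single_day_all_ones(self):
        tc = CompetitionTimecourse(pd.DataFrame({7.0: [30.0, 60.0]}, index=["NTC", "sg"]))
        norm = competition_normalize(tc, reference_day=7.0)
        assert np.allclose(norm, 1.0)

    def test_per_day_rescaling_cancels(self):
        base = pd.DataFrame({7.0: [50.0, 40.0], 14.0: [50.0, 20.0]}, index=["NTC", "sg"])
        norm_a = competition_normalize(CompetitionTimecourse(base), 7.0)
        rescaled = base.copy()
        rescaled[14.0] *= 0.5  # same day, both labels
        norm_b = competition_normalize(CompetitionTimecourse(rescaled), 7.0)
        assert np.allclose(norm_a, norm_b)

    def test_missing_ntc_rejected(self):
        with pytest.raises(ValueError, match="NTC"):
            CompetitionTimecourse(pd.DataFrame({7.0: [40.0]}, index=["sg"]))

    def test_zero_ntc_errors(self):
        tc = CompetitionTimecourse(
            pd.DataFrame({7.0: [50.0, 40.0], 14.0: [0.0, 20.0]}, index=["NTC", "sg"])
        )
        with pytest.raises(ValueError, match="zero"):
            competition_normalize(tc, 7.0)

    def test_missing_reference_day_errors(self):
        tc = CompetitionTimecourse(pd.DataFrame({14.0: [50.0, 20.0]}, index=["NTC", "sg"]))
        with pytest.raises(ValueError, match="reference day"):
            competition_normalize(tc, 7.0)


class TestGrowthRatio:
    def test_identical_series_all_ones(self):
        assert np.allclose(growth_ratio([10, 20, 30], [10, 20, 30]), 1.0)

    def test_worked_example(self):
        assert growth_ratio([100, 50], [100, 100]).tolist() == [1.0, 0.5]

    def test_zero_control_errors(self):
        with pytest.raises(ValueError, match="positive"):
            growth_ratio([100, 50], [100, 0])

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError, match="matching"):
            growth_ratio([1, 2], [1, 2, 3])


class TestSimulateFlowEvents:
    def test_deterministic_per_seed(self):
        a = simulate_flow_events(seed=5, n_events=500)
        b = simulate_flow_events(seed=5, n_events=500)
        assert a.events.equals(b.events)

    def test_untransfected_sample_has_few_events_above_control_gate(self):
        control = simulate_flow_events(seed=1, n_events=5000, transfected_frac=0.0)
        thr = marker_threshold_from_control(control, "mCherry")
        other = simulate_flow_events(seed=2, n_events=5000, transfected_frac=0.0)
        assert (other.events["mCherry"] > thr).mean() < 0.01

    def test_planted_reporter_shift_recovered(self):
        """A x5 reporter shift in transfected cells is recovered by the gated
        ratio within 10% on average over seeds."""
        ratios = []
        for seed in range(50):
            control = simulate_flow_events(seed=10_000 + seed, n_events=4000,
                                           transfected_frac=0.0)
            thr = marker_threshold_from_control(control, "mCherry")
            events = simulate_flow_events(seed=seed, n_events=4000,
                                          transfected_frac=0.3, reporter_shift=5.0)
            ratios.append(chop_neon_ratio(events, "mNeon", "mCherry",
                                          positive_threshold=thr))
        assert abs(np.mean(ratios) - 5.0) / 5.0 < 0.10
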