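"""Tests of spike binning, MUA pooling and feature assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statebmi import (
    BinningSchedule,
    TrialCountMatrices,
    assemble_dataset,
    bin_spikes,
    build_activity_vector,
    make_default_schedule,
    pool_mua,
)
from statebmi.binning import POST_BIN_WIDTH, Variant
from statebmi.neural_sim import SpikeSession, Trial


def _trial(spike_lists, index=0, stimulus=1):
    return Trial(index, stimulus, tuple(np.asarray(s, float) for s in spike_lists))


class TestSchedule:
    def test_default_has_39_adaptive_pre_bins(self):
        sch = make_default_schedule(0.75, 0.05, 0.030)
        assert sch.t_theta == 39
        widths = np.diff(sch.pre_edges)
        # coarse -> fine toward onset, summing to the full 0.75 s window
        assert np.all(np.diff(widths) <= 1e-12)
        assert widths.sum() == pytest.approx(0.75)
        assert sch.pre_edges[-1] == 0.0

    @pytest.mark.parametrize("post_span,n_bins", [(0.05, 10), (0.15, 30), (0.005, 1)])
    def test_post_bins_are_uniform_5ms(self, post_span, n_bins):
        sch = make_default_schedule(0.75, post_span, 0.030)
        assert sch.t_r == n_bins
        np.testing.assert_allclose(np.diff(sch.post_edges), POST_BIN_WIDTH)
        assert sch.post_edges[0] == pytest.approx(0.030)

    def test_invalid_spans_rejected(self):
        with pytest.raises(ValueError):
            make_default_schedule(0.5, 0.05)  # pre window too short
        with pytest.raises(ValueError):
            make_default_schedule(0.75, 0.052)  # not a multiple of 5 ms

    def test_truncate_keeps_bins_closest_to_onset(self):
        sch = make_default_schedule(0.75, 0.05, 0.030)
        sub = sch.truncate(t_theta=13, t_r=5)
        assert sub.t_theta == 13 and sub.t_r == 5
        assert sub.pre_edges[-1] == 0.0
        np.testing.assert_allclose(np.diff(sub.pre_edges), 0.005)
        assert sub.post_edges[0] == sch.post_edges[0]

    def test_increasing_widths_toward_onset_rejected(self):
        with pytest.raises(ValueError):
            BinningSchedule(
                pre_edges=np.array([-0.1, -0.095, -0.05, 0.0]),
                post_edges=np.array([0.03, 0.035]),
            )


class TestBinSpikes:
    def test_empty_trial_gives_zero_matrices(self, default_schedule):
        m = bin_spikes(_trial([[], []]), default_schedule)
        assert m.theta.sum() == 0 and m.r.sum() == 0
        assert m.theta.shape == (2, 39) and m.r.shape == (2, 10)

    def test_spike_just_after_blank_lands_in_first_post_bin(self, default_schedule):
        m = bin_spikes(_trial([[0.032]]), default_schedule)
        assert m.r[0, 0] == 1 and m.r.sum() == 1 and m.theta.sum() == 0

    def test_matches_brute_force_histogram(self, default_schedule, rng):
        for _ in range(25):
            spikes = rng.uniform(-0.75, 0.08, size=500)
            m = bin_spikes(_trial([spikes]), default_schedule, warn_out_of_span=False)
            for edges, counts in [
                (default_schedule.pre_edges, m.theta[0]),
                (default_schedule.post_edges, m.r[0]),
            ]:
                brute = [
                    sum(1 for t in spikes if lo <= t < hi)
                    for lo, hi in zip(edges[:-1], edges[1:])
                ]
                np.testing.assert_array_equal(counts, brute)

    def test_out_of_span_spikes_dropped_with_warning(self, default_schedule, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="statebmi.binning"):
            m = bin_spikes(_trial([[-2.0, 0.01, 0.032]]), default_schedule)
        assert m.r.sum() + m.theta.sum() == 1
        assert any("ignored" in rec.message for rec in caplog.records)

    @given(
        st.lists(
            st.floats(min_value=-0.75, max_value=0.0799, exclude_max=False),
            max_size=80,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_counts_conserved_for_in_window_spikes(self, spikes):
        sch = make_default_schedule(0.75, 0.05, 0.030)
        inside = [
            t
            for t in spikes
            if (-0.75 <= t < 0.0) or (0.030 <= t < 0.080)
        ]
        m = bin_spikes(_trial([spikes]), sch, warn_out_of_span=False)
        assert m.theta.sum() + m.r.sum() == len(inside)


class TestPoolMua:
    def test_single_unit_is_identity(self):
        m = TrialCountMatrices(theta=np.array([[1, 2]]), r=np.array([[0, 3]]))
        pooled = pool_mua(m)
        np.testing.assert_array_equal(pooled.theta, m.theta)
        np.testing.assert_array_equal(pooled.r, m.r)

    def test_pooling_sums_units_and_conserves_totals(self):
        m = TrialCountMatrices(
            theta=np.array([[1, 0], [2, 3]]), r=np.array([[1, 1], [0, 2]])
        )
        pooled = pool_mua(m)
        np.testing.assert_array_equal(pooled.theta, [[3, 3]])
        np.testing.assert_array_equal(pooled.r, [[1, 3]])
        assert pooled.theta.sum() + pooled.r.sum() == m.theta.sum() + m.r.sum()


class TestActivityVectors:
    matrices = TrialCountMatrices(
        theta=np.array([[0, 3, 3], [1, 1, 1]]), r=np.array([[4, 5], [6, 7]])
    )

    def test_sd_td_concatenates_unit_major(self):
        v = build_activity_vector(self.matrices, "SD-TD")
        np.testing.assert_array_equal(v, [0, 3, 3, 4, 5, 1, 1, 1, 6, 7])

    def test_si_equals_flattened_response(self):
        v = build_activity_vector(self.matrices, "SI")
        np.testing.assert_array_equal(v, [4, 5, 6, 7])

    def test_sd_ta_uses_mean_pre_count(self):
        v = build_activity_vector(self.matrices, "SD-TA")
        np.testing.assert_array_equal(v, [2.0, 4, 5, 1.0, 6, 7])

    @pytest.mark.parametrize(
        "variant,length", [("SI", 4), ("SD-TA", 6), ("SD-TD", 10)]
    )
    def test_feature_count_formulas(self, variant, length):
        assert build_activity_vector(self.matrices, variant).size == length

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_activity_vector(self.matrices, "SD-XX")

    def test_state_only_drops_response(self):
        v = build_activity_vector(self.matrices, "SD-TD", state_only=True)
        np.testing.assert_array_equal(v, [0, 3, 3, 1, 1, 1])
        with pytest.raises(ValueError):
            build_activity_vector(self.matrices, "SI", state_only=True)


class TestAssembleDataset:
    def test_shapes_and_feature_formulas(self, small_session, small_schedule):
        n, tt, tr = small_session.n_units, small_schedule.t_theta, small_schedule.t_r
        for variant, f in [
            ("SI", n * tr),
            ("SD-TA", n * (1 + tr)),
            ("SD-TD", n * (tt + tr)),
        ]:
            ds = assemble_dataset(small_session, small_schedule, variant, "SUA")
            assert ds.matrix.shape == (small_session.n_trials, f)
        mua = assemble_dataset(small_session, small_schedule, "SD-TD", "MUA")
        assert mua.matrix.shape == (small_session.n_trials, tt + tr)
        assert mua.n_units == 1

    def test_rows_match_per_trial_vectors(self, small_session, small_schedule):
        ds = assemble_dataset(small_session, small_schedule, "SD-TD", "SUA")
        for m in (0, 7, 31):
            counts = bin_spikes(small_session.trials[m], small_schedule)
            np.testing.assert_array_equal(
                ds.matrix[m], build_activity_vector(counts, Variant.SD_TD)
            )

    def test_permuting_trials_permutes_rows_and_labels(
        self, small_session, small_schedule, rng
    ):
        perm = rng.permutation(small_session.n_trials)
        shuffled = SpikeSession(
            trials=tuple(small_session.trials[i] for i in perm),
            n_units=small_session.n_units,
            pre_span=small_session.pre_span,
            post_span=small_session.post_span,
            artifact_blank=small_session.artifact_blank,
            seed=small_session.seed,
        )
        a = assemble_dataset(small_session, small_schedule, "SI", "SUA")
        b = assemble_dataset(shuffled, small_schedule, "SI", "SUA")
        np.testing.assert_array_equal(b.matrix, a.matrix[perm])
        np.testing.assert_array_equal(b.labels, a.labels[perm])

    def test_count_conservation_against_raw_spikes(self, small_session, small_schedule):
        ds = assemble_dataset(small_session, small_schedule, "SD-TD", "SUA")
        for m, trial in enumerate(small_session.trials):
            in_window = sum(
                int(
                    np.sum(
                        ((st >= small_schedule.pre_edges[0]) & (st < 0))
                        | (
                            (st >= small_schedule.post_edges[0])
                            & (st < small_schedule.post_edges[-1])
                        )
                    )
                )
                for st in trial.spikes
            )
            assert ds.matrix[m].sum() == in_window
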