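"""Pacing protocols: bookkeeping, determinism, chaining, S1-S2 consistency."""

import numpy as np
import pytest

from canatrial import cell_model as cm
from canatrial.pacing import (dynamic_pacing_scan, pace_fixed_pcl,
                              s1s2_restitution)


class TestFixedPCL:
    def test_single_beat_trace_spans_one_pcl(self, control_params,
                                             control_stimulus):
        trace, final = pace_fixed_pcl(control_params, 400.0, 1, record_last=1,
                                      stimulus=control_stimulus)
        assert trace.t[0] == 0.0
        assert trace.t[-1] == pytest.approx(400.0 - 0.1, abs=1e-9)
        assert trace.stim_onsets == (0.0,)
        assert isinstance(final, cm.CellState)

    def test_identical_inputs_bit_identical_traces(self, control_params,
                                                   control_stimulus):
        a, _ = pace_fixed_pcl(control_params, 300.0, 3, record_last=2,
                              stimulus=control_stimulus)
        b, _ = pace_fixed_pcl(control_params, 300.0, 3, record_last=2,
                              stimulus=control_stimulus)
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.ca_i, b.ca_i)

    def test_validates_beat_counts(self, control_params, control_stimulus):
        with pytest.raises(ValueError):
            pace_fixed_pcl(control_params, 300.0, 1, record_last=2,
                           stimulus=control_stimulus)


class TestDynamicScan:
    def test_degenerate_ladder_equals_fixed_pacing(self, control_params,
                                                   control_stimulus):
        df, _ = dynamic_pacing_scan(control_params, [400.0], beats_per_pcl=3,
                                    stimulus=control_stimulus)
        trace, _ = pace_fixed_pcl(control_params, 400.0, 3, record_last=2,
                                  stimulus=control_stimulus)
        table = trace.biomarkers()
        assert df["apd90_ms"].tolist() == pytest.approx(
            table["apd90_ms"].tolist(), abs=1e-9)

    def test_checkpoint_restart_reproduces_scan(self, control_params,
                                                control_stimulus):
        ladder = [400.0, 380.0, 360.0, 340.0]
        full, _ = dynamic_pacing_scan(control_params, ladder, beats_per_pcl=3,
                                      stimulus=control_stimulus)
        head, state = dynamic_pacing_scan(control_params, ladder[:2],
                                          beats_per_pcl=3,
                                          stimulus=control_stimulus)
        tail, _ = dynamic_pacing_scan(control_params, ladder[2:],
                                      beats_per_pcl=3, state=state,
                                      stimulus=control_stimulus)
        rejoined = np.concatenate([head["apd90_ms"], tail["apd90_ms"]])
        assert np.array_equal(rejoined, full["apd90_ms"].to_numpy())

    def test_ladder_must_descend(self, control_params, control_stimulus):
        with pytest.raises(ValueError):
            dynamic_pacing_scan(control_params, [300.0, 400.0],
                                beats_per_pcl=3, stimulus=control_stimulus)


class TestS1S2:
    def test_s2_equal_to_s1_reproduces_steady_point(self, control_params,
                                                    control_stimulus):
        """The degenerate S2 = S1 pair lies on the fixed-pacing point."""
        s1 = 500.0
        df = s1s2_restitution(control_params, s1_pcl=s1, n_s1=8,
                              s2_list=[s1], stimulus=control_stimulus)
        trace, _ = pace_fixed_pcl(control_params, s1, 9, record_last=2,
                                  stimulus=control_stimulus)
        steady = trace.biomarkers().iloc[-1]["apd90_ms"]
        assert len(df) == 1
        assert df.iloc[0]["apd90_ms"] == pytest.approx(steady, abs=0.5)

    def test_failed_capture_pairs_excluded(self, control_params,
                                           control_stimulus):
        df = s1s2_restitution(control_params, s1_pcl=500.0, n_s1=5,
                              s2_list=[500.0, 5.0],  # 5 ms is refractory
                              stimulus=control_stimulus)
        assert df["s2_ms"].tolist() == [500.0]

    def test_di_is_positive_and_below_s2(self, control_params,
                                         control_stimulus):
        df = s1s2_restitution(control_params, s1_pcl=500.0, n_s1=5,
                              s2_list=[450.0, 350.0],
                              stimulus=control_stimulus)
        assert (df["di_ms"] > 0).all()
        assert (df["di_ms"] < df["s2_ms"]).all()


class TestQuasiSteadyState:
    def test_apd_converged_after_100_beats_at_1hz(self, control_params,
                                                  control_stimulus):
        """Beats 100 and 101 differ by < 0.5 ms at PCL 1000 ms."""
        trace, _ = pace_fixed_pcl(control_params, 1000.0, 101, record_last=2,
                                  stimulus=control_stimulus)
        t = trace.biomarkers()
        assert abs(t.iloc[-1]["apd90_ms"] - t.iloc[-2]["apd90_ms"]) < 0.5
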