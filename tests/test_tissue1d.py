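"""1D cable: decoupled limit, symmetry, CV measurement, nodes, patterns."""

import numpy as np
import pytest

from canatrial import cell_model as cm
from canatrial.synthetic import make_apd_map
from canatrial.tissue1d import (CableConfig, CableResult, classify_pattern,
                                detect_nodes, measure_cv, simulate_cable)


def small_cfg(**kw):
    base = dict(n_cells=24, n_prep_beats=0, n_test_beats=2, test_pcl=300.0,
                keep_beats=2, init_beats=1, prep_pcl=300.0)
    base.update(kw)
    return CableConfig(**base)


class TestConfig:
    def test_stability_bound_enforced(self):
        with pytest.raises(ValueError):
            CableConfig(diffusion=0.167, dx=0.05, dt=0.02)  # D*dt/dx^2 > 0.5

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            CableConfig(n_cells=4)


class TestDecoupledLimit:
    def test_d_zero_matches_single_cell_bitwise(self, control_params,
                                                control_stimulus):
        """With D = 0 every stimulated cell integrates the single-cell path."""
        state = cm.default_state(control_params)
        cfg = small_cfg(diffusion=0.0, record_stride=0.5)
        res = simulate_cable(cfg, control_params, state=state,
                             stimulus=control_stimulus)
        stim = cm.Stimulus(control_stimulus.amplitude,
                           control_stimulus.duration, onsets=(0.0, 300.0))
        _, t, rec = cm.integrate(state.copy(), control_params, 600.0,
                                 stimulus=stim, record_stride=0.5)
        assert np.array_equal(res.v_map[:, 0], rec[:len(res.t_map), cm.S_V])
        assert np.array_equal(res.ca_map[:, 2], rec[:len(res.t_map), cm.S_CAI])
        # unstimulated cells stay at rest
        assert np.all(np.abs(res.v_map[:, 10] - state.v) < 1.0)

    def test_mirrored_stimulation_mirrors_solution(self, control_params,
                                                   control_stimulus):
        cfg_l = small_cfg(diffusion=0.167, n_test_beats=1, record_stride=0.5)
        cfg_r = cfg_l.replace(stim_at_end=True)
        state = cm.default_state(control_params)
        res_l = simulate_cable(cfg_l, control_params, state=state,
                               stimulus=control_stimulus)
        res_r = simulate_cable(cfg_r, control_params, state=state,
                               stimulus=control_stimulus)
        assert np.allclose(res_l.v_map, res_r.v_map[:, ::-1], atol=1e-6)


class TestCV:
    def _plane_wave_result(self, cv=0.6, n_cells=300, dx=0.167):
        cfg = CableConfig(n_cells=n_cells, dx=dx, n_prep_beats=0,
                          n_test_beats=1, keep_beats=1)
        x = cfg.x_mm
        act = (x / cv)[None, :]
        return CableResult(
            config=cfg, t_map=np.arange(0.0, 200.0, 1.0),
            v_map=np.zeros((200, n_cells)), ca_map=np.zeros((200, n_cells)),
            stim_onsets=np.array([0.0]), activation=act,
            max_dvdt=np.full_like(act, 100.0),
            apd_matrix=np.zeros((1, n_cells)),
            cat_matrix=np.zeros((1, n_cells)),
            kept_beats=np.array([0]), conducted=np.array([True]),
        )

    def test_constructed_plane_wave(self):
        res = self._plane_wave_result(cv=0.6)
        assert measure_cv(res, 0) == pytest.approx(0.6, rel=1e-6)

    def test_nonconducted_beat_is_missing(self):
        res = self._plane_wave_result()
        res.conducted[0] = False
        assert np.isnan(measure_cv(res, 0))


class TestNodes:
    def test_single_planted_node(self):
        mat, x = make_apd_map(300, 4, [25.0])
        nodes = detect_nodes(mat, 0, x)
        assert len(nodes) == 1
        assert nodes[0] == pytest.approx(25.0, abs=0.167 / 2)

    def test_uniform_sign_yields_no_node(self):
        mat, x = make_apd_map(300, 4, [])
        assert detect_nodes(mat, 0, x).size == 0

    def test_drifting_nodes_recovered_per_pair(self):
        drift = [[40.0], [34.0], [28.0]]
        mat, x = make_apd_map(300, 4, drift)
        got = [detect_nodes(mat, b, x)[0] for b in range(3)]
        assert got == pytest.approx([40.0, 34.0, 28.0], abs=0.167 / 2)

    def test_multiple_nodes_sorted(self):
        mat, x = make_apd_map(300, 4, [12.0, 30.0, 44.0])
        nodes = detect_nodes(mat, 0, x)
        assert list(nodes) == sorted(nodes)
        assert nodes == pytest.approx([12.0, 30.0, 44.0], abs=0.167 / 2)


class TestPatternClassification:
    def _result_from(self, apd_matrix, x, conducted):
        n_beats, n_cells = apd_matrix.shape
        cfg = CableConfig(n_cells=n_cells, n_prep_beats=0,
                          n_test_beats=n_beats, keep_beats=n_beats)
        return CableResult(
            config=cfg, t_map=np.arange(10.0),
            v_map=np.zeros((10, n_cells)), ca_map=np.zeros((10, n_cells)),
            stim_onsets=np.arange(n_beats, dtype=float),
            activation=np.zeros((n_beats, n_cells)),
            max_dvdt=np.full((n_beats, n_cells), 100.0),
            apd_matrix=apd_matrix, cat_matrix=np.zeros_like(apd_matrix),
            kept_beats=np.arange(n_beats),
            conducted=np.asarray(conducted),
        )

    def test_uniform_conduction_is_normal(self):
        mat, x = make_apd_map(60, 10, [], magnitude=0.0)
        res = self._result_from(mat, x, [True] * 10)
        assert classify_pattern(res) == "normal"

    def test_opposite_phase_regions_are_discordant(self):
        mat, x = make_apd_map(60, 10, [5.0], magnitude=15.0)
        res = self._result_from(mat, x, [True] * 10)
        assert classify_pattern(res) == "discordant_alternans"

    def test_alternating_conduction_failure_is_2to1_block(self):
        mat, x = make_apd_map(60, 10, [], magnitude=0.0)
        res = self._result_from(mat, x, [True, False] * 5)
        assert classify_pattern(res) == "block_2to1"

    def test_irregular_conduction_is_other(self):
        mat, x = make_apd_map(60, 10, [], magnitude=0.0)
        res = self._result_from(mat, x,
                                [True, True, False, True, True,
                                 False, False, True, True, True])
        assert classify_pattern(res) == "other"
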