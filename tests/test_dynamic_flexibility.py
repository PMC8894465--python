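import numpy as np
import pytest
from scipy.stats import spearmanr

from commarch import dynamic_flexibility as dyn
from commarch.synthetic_data import generate_switch_panel


class TestWindowCount:
    def test_resting_state_case(self):
        # 30 s window at 0.72 s sampling = 42 samples; 4800-sample scan
        w = dyn.window_samples_from_seconds(30.0, 0.72)
        assert w == 42
        assert dyn.window_count(4800, w, 1) == 4759

    def test_window_equals_series(self):
        assert dyn.window_count(10, 10, 1) == 1

    def test_strided(self):
        assert dyn.window_count(100, 30, 10) == 8

    def test_overlong_window_rejected(self):
        with pytest.raises(ValueError):
            dyn.window_count(10, 11, 1)


class TestSlidingWindowFC:
    def test_identical_rows_correlate_fully(self):
        base = np.random.default_rng(0).standard_normal(120)
        panel = dyn.TimeSeriesPanel(np.vstack([base, base, base]), sampling_interval=1.0)
        dc = dyn.sliding_window_fc(panel, window_seconds=20, step_seconds=10)
        assert np.allclose(dc.tensor, 1.0)

    def test_sign_flip_gives_minus_one(self):
        base = np.random.default_rng(1).standard_normal(100)
        panel = dyn.TimeSeriesPanel(np.vstack([base, -base]), sampling_interval=1.0)
        dc = dyn.sliding_window_fc(panel, window_seconds=10, step_seconds=5)
        off = dc.tensor[0, 1, :]
        assert np.allclose(off, -1.0)

    def test_window_tally_matches_formula(self):
        rng = np.random.default_rng(2)
        panel = dyn.TimeSeriesPanel(rng.standard_normal((4, 200)), sampling_interval=0.72)
        dc = dyn.sliding_window_fc(panel, window_seconds=30.0)
        assert dc.window_samples == 42
        assert dc.n_windows == dyn.window_count(200, 42, 1)

    def test_zero_variance_node_set_to_zero(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((3, 60))
        values[2] = 5.0  # constant node
        panel = dyn.TimeSeriesPanel(values, sampling_interval=1.0)
        dc = dyn.sliding_window_fc(panel, window_seconds=20, step_seconds=20)
        assert np.all(dc.tensor[2, :2, :] == 0)
        assert np.all(np.diagonal(dc.tensor, axis1=0, axis2=1) == 1.0)


class TestDynamicCommunities:
    def _static_panel(self, seed=0, n=20, t=400):
        return generate_switch_panel(
            N=n, T=t, sampling_interval=1.0, switch_times=[], M=2, noise_sd=0.3, seed=seed
        )

    def test_static_structure_constant_labels(self):
        panel = self._static_panel()
        dc = dyn.sliding_window_fc(panel, window_seconds=50, step_seconds=25)
        labels = dyn.dynamic_communities(dc, seed=0)
        assert (labels == labels[:, [0]]).all()

    def test_single_switch_confined_to_transition(self):
        t, switch = 600, 300
        panel = generate_switch_panel(
            N=20, T=t, sampling_interval=1.0, switch_times=[switch], M=2, noise_sd=0.3, seed=4
        )
        win, step = 50, 25
        dc = dyn.sliding_window_fc(panel, window_seconds=win, step_seconds=step)
        labels = dyn.dynamic_communities(dc, seed=1)
        changes = (labels[:, 1:] != labels[:, :-1]).any(axis=0)
        changing = set(np.flatnonzero(changes))
        # transitions may only occur where one of the two windows straddles
        # the switch point
        contains = [k * step < switch < k * step + win for k in range(dc.n_windows)]
        allowed = {k for k in range(dc.n_windows - 1) if contains[k] or contains[k + 1]}
        assert changing
        assert changing <= allowed

    def test_two_identical_windows_no_transitions(self):
        rng = np.random.default_rng(5)
        slice_ = np.corrcoef(rng.standard_normal((10, 50)))
        tensor = np.dstack([slice_, slice_])
        dc = dyn.DynamicConnectivity(tensor=tensor, window_samples=50, step_samples=1)
        labels = dyn.dynamic_communities(dc, seed=2)
        assert (labels[:, 0] == labels[:, 1]).all()


class TestFlexibility:
    def test_constant_labels_zero(self):
        labels = np.zeros((5, 10), dtype=int)
        res = dyn.flexibility(labels)
        assert res.mean_flexibility == 0.0

    def test_alternating_labels_one(self):
        labels = np.tile([0, 1], (4, 5))
        assert dyn.flexibility(labels).mean_flexibility == 1.0

    def test_single_change_fraction(self):
        labels = np.array([[0, 0, 1, 1, 1]])
        assert dyn.flexibility(labels).per_node_flexibility[0] == pytest.approx(0.25)

    def test_invariant_under_label_permutation(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 4, size=(8, 20))
        perm = np.array([3, 0, 2, 1])
        assert dyn.flexibility(perm[labels]).mean_flexibility == pytest.approx(
            dyn.flexibility(labels).mean_flexibility
        )

    def test_flexibility_tracks_planted_switch_rate(self):
        # more latent switches -> higher measured flexibility
        rates = [0, 2, 4, 8, 12]
        t = 800
        means = []
        rng = np.random.default_rng(7)
        for n_switch in rates:
            times = sorted(rng.choice(np.arange(50, t - 50), size=n_switch, replace=False))
            panel = generate_switch_panel(
                N=20, T=t, sampling_interval=1.0, switch_times=times, M=2, noise_sd=0.3,
                seed=int(rng.integers(1 << 30)),
            )
            dc = dyn.sliding_window_fc(panel, window_seconds=40, step_seconds=20)
            labels = dyn.dynamic_communities(dc, seed=3)
            means.append(dyn.flexibility(labels).mean_flexibility)
        rho, _ = spearmanr(rates, means)
        assert rho > 0.9
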