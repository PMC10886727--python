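"""PLV / wPLI estimators, phase extraction, and the windowed computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetaconn import (
    DEFAULT_WINDOWS,
    EpochedRecording,
    PlantedCoupling,
    SimulationConfig,
    bandpass_theta,
    generate_epochs,
    instantaneous_phase,
    plv,
    windowed_connectivity,
    wpli,
)

FS = 100.0
T = np.arange(250) / FS


class TestInstantaneousPhase:
    def test_cosine_phase_slope(self):
        # 4.8 Hz is bin-centred over the 2.5 s epoch (12 full cycles), so the
        # circular analytic signal is leakage-free
        phi = instantaneous_phase(np.cos(2 * np.pi * 4.8 * T), FS)
        slope = np.diff(np.unwrap(phi))[25:-25] * FS  # rad/s, away from epoch edges
        np.testing.assert_allclose(slope, 2 * np.pi * 4.8, rtol=0.01)

    def test_quadrature_offset(self):
        cos = instantaneous_phase(np.cos(2 * np.pi * 4.8 * T), FS)
        sin = instantaneous_phase(np.sin(2 * np.pi * 4.8 * T), FS)
        diff = np.angle(np.exp(1j * (cos - sin)))[25:-25]
        np.testing.assert_allclose(diff, np.pi / 2, atol=0.02)

    def test_matches_fft_analytic_oracle(self, rng):
        """Sample-wise agreement with a hand-built FFT analytic signal."""
        x = rng.standard_normal(250)
        spec = np.fft.fft(x)
        h = np.zeros(250)
        h[0] = 1
        h[1:125] = 2
        h[125] = 1  # even length: Nyquist kept once
        oracle = np.angle(np.fft.ifft(spec * h))
        np.testing.assert_allclose(instantaneous_phase(x, FS), oracle, atol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            instantaneous_phase(np.zeros(100), FS)

    def test_window_slicing(self):
        phi = instantaneous_phase(np.cos(2 * np.pi * 5 * T), FS, DEFAULT_WINDOWS[2])
        assert phi.shape[-1] == 100


class TestPlv:
    def test_constant_difference_is_one(self):
        assert plv(np.full(64, 0.7)) == pytest.approx(1.0)

    def test_antipodal_phasors_cancel(self):
        assert plv(np.array([0.0, np.pi] * 32)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phase_rayleigh_mean(self, rng):
        """Mean null PLV follows the Rayleigh statistic, ~ sqrt(pi/T)/2."""
        t = 10_000
        vals = [plv(rng.uniform(0, 2 * np.pi, t)) for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(0.5 * np.sqrt(np.pi / t), rel=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            plv(np.array([]))


class TestWpli:
    def test_direct_evaluation(self):
        value, degenerate = wpli(np.array([3j, 1j, -1j]))
        assert value == pytest.approx(0.6)
        assert not degenerate

    def test_consistent_sign_is_one(self):
        value, _ = wpli(np.array([0.5j, 2j, 1j, 3j]))
        assert value == pytest.approx(1.0)

    def test_zero_lag_degenerate(self):
        # purely real cross-spectrum (identical zero-lag signals)
        value, degenerate = wpli(np.array([1.0 + 0j, 2.0 + 0j, 3.0 + 0j]))
        assert value == 0.0
        assert degenerate

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wpli(np.array([]))


class TestWindowedConnectivity:
    def test_perfect_lagged_locking(self):
        cfg = SimulationConfig(n_trials_per_cell=6, snr=np.inf, seed=5)
        coup = [PlantedCoupling((("C5", "F3"),), kappa=1.0, lag=np.pi / 2)]
        rec = bandpass_theta(generate_epochs(cfg, coup, "Sleep", "L"))
        for metric in ("plv", "wpli"):
            t = windowed_connectivity(rec, metric)
            assert t.values[t.pair_index("C5", "F3")].min() >= 0.99

    def test_duplicated_channel_zero_lag(self, rng):
        x = rng.standard_normal((1, 4, 250))
        rec = EpochedRecording(
            np.concatenate([x, x]), FS, ("a", "b"), metadata={"band": (3, 8)}
        )
        with pytest.warns(UserWarning, match="channels"):
            p = windowed_connectivity(rec, "plv")
            w = windowed_connectivity(rec, "wpli")
        np.testing.assert_allclose(p.values, 1.0)
        np.testing.assert_allclose(w.values, 0.0)
        assert w.degenerate.all()

    def test_matches_straight_line_reference(self, coupled_recording):
        """Vectorised tensor equals an unoptimised per-pair/window/trial loop."""
        rec = coupled_recording
        for metric in ("plv", "wpli"):
            tensor = windowed_connectivity(rec, metric)
            z = {
                lab: np.apply_along_axis(lambda s: s, -1, rec.data[i])
                for i, lab in enumerate(rec.channel_labels)
            }
            from scipy.signal import hilbert

            for pi, (a, b) in enumerate(tensor.pairs):
                ia = rec.channel_labels.index(a)
                ib = rec.channel_labels.index(b)
                for wi, win in enumerate(tensor.windows):
                    for tr in range(rec.n_trials):
                        za = hilbert(rec.data[ia, tr])[win.slice(rec.fs, rec.time0)]
                        zb = hilbert(rec.data[ib, tr])[win.slice(rec.fs, rec.time0)]
                        if metric == "plv":
                            ref = plv(np.angle(za) - np.angle(zb))
                        else:
                            ref, _ = wpli(za * np.conj(zb))
                        assert tensor.values[pi, wi, tr] == pytest.approx(ref, abs=1e-9)

    def test_window_consistency_for_late_coupling(self):
        """A coupling confined to [1, 2] s shows in w3, partly w2, not w1."""
        cfg = SimulationConfig(n_trials_per_cell=40, snr=np.inf, seed=11)
        coup = [PlantedCoupling((("C5", "F3"),), kappa=1.0, lag=np.pi / 3, support=(1.0, 2.0))]
        rec = bandpass_theta(generate_epochs(cfg, coup, "Sleep", "L"))
        t = windowed_connectivity(rec, "plv")
        w1, w2, w3 = t.values[t.pair_index("C5", "F3")].mean(axis=1)
        assert w3 > 0.9
        assert w3 > w2 > w1
        assert w1 < 0.6

    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.1, max_value=100.0),
    )
    @settings(max_examples=15, deadline=None)
    def test_bounds_symmetry_amplitude_invariance(self, seed, scale):
        """Values in [0,1]; symmetric in pair order; invariant to channel gain."""
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((3, 2, 250))
        rec = EpochedRecording(data, FS, ("a", "b", "c"))
        scaled = EpochedRecording(data * np.array([scale, 1.0, 1.0])[:, None, None], FS, ("a", "b", "c"))
        for metric in ("plv", "wpli"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = windowed_connectivity(rec, metric)
                ts = windowed_connectivity(scaled, metric)
            assert (t.values >= 0).all() and (t.values <= 1).all()
            np.testing.assert_allclose(t.values, ts.values, atol=1e-9)
            # symmetry is structural: reversing channel order permutes pairs only
            rev = EpochedRecording(data[::-1], FS, ("c", "b", "a"))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tr = windowed_connectivity(rev, metric)
            np.testing.assert_allclose(
                tr.values[tr.pair_index("a", "b")], t.values[t.pair_index("a", "b")], atol=1e-9
            )
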