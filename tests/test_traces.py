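import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import odorfusion as of
from odorfusion.traces import DriftModelError


@pytest.fixture
def protocol():
    return of.StimulusProtocol()


def make_trace(values, **kw):
    return of.ImagingTrace(values=np.asarray(values, dtype=float), **kw)


class TestDeltaFOverF:
    def test_constant_trace_is_zero(self, protocol):
        tr = make_trace(np.full(80, 100.0))
        assert np.allclose(of.delta_f_over_f(tr).values, 0.0)

    def test_twenty_percent_rise(self, protocol):
        vals = np.full(80, 100.0)
        vals[40] = 120.0  # outside the F0 window, so F0 stays 100
        out = of.delta_f_over_f(make_trace(vals))
        assert out.values[40] == pytest.approx(20.0)
        assert out.values[0] == pytest.approx(0.0)

    def test_inhibition_is_negative(self):
        vals = np.full(80, 100.0)
        vals[40] = 90.0
        out = of.delta_f_over_f(make_trace(vals))
        assert out.values[40] == pytest.approx(-10.0, abs=0.5)

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError):
            of.delta_f_over_f(make_trace(np.zeros(80)))


class TestWindows:
    def test_frame_indices_at_4hz(self, protocol):
        # onset 6.75 s: response window frames 28-47, baseline 18-27 (1-based)
        post = protocol.window_frames(6.75, 11.75)
        base = protocol.window_frames(4.25, 6.75)
        assert post[0] + 1 == 28 and post[-1] + 1 == 47 and len(post) == 20
        assert base[0] + 1 == 18 and base[-1] + 1 == 27 and len(base) == 10

    def test_f0_window_is_twenty_frames(self, protocol):
        f0 = protocol.window_frames(1.75, 6.75)
        assert len(f0) == 20

    def test_fit_weights_shape(self, protocol):
        w = protocol.fit_weights()
        t = protocol.frame_times()
        assert np.all(w[t < 0.75] == 0.0)  # initial exclusion
        assert np.all(w[(t >= 0.75) & (t < 6.75)] == 100.0)  # pre-stimulus
        assert np.all(w[(t >= 6.75) & (t <= 17.75)] == 0.0)  # post-stimulus exclusion


class TestDecayEstimation:
    def _decay_trace(self, a=10.0, b=8.0, c=1.0, noise=0.0, seed=0):
        proto = of.StimulusProtocol()
        t = proto.frame_times()
        rng = np.random.default_rng(seed)
        vals = a * np.exp(-t / b) + c + rng.normal(0, noise, t.size)
        return make_trace(vals, is_solvent_control=True)

    def test_noiseless_b_recovered_within_one_percent(self):
        model = of.estimate_decay([self._decay_trace()])
        assert model.B == pytest.approx(8.0, rel=0.01)
        assert model.A == pytest.approx(10.0, rel=0.01)

    def test_median_is_robust_to_one_corrupted_trace(self):
        good = self._decay_trace()
        bad = make_trace(good.values + 50.0, is_solvent_control=True)
        model = of.estimate_decay([good, make_trace(good.values, is_solvent_control=True), bad])
        assert model.B == pytest.approx(8.0, rel=0.01)

    def test_no_controls_is_error(self):
        with pytest.raises(ValueError):
            of.estimate_decay([])


class TestBleachCorrect:
    def test_decay_only_trace_corrects_to_zero(self):
        proto = of.StimulusProtocol()
        t = proto.frame_times()
        a = 10.0
        tr = make_trace(a * np.exp(-t / 8.0) + 1.0)
        corrected, model = of.bleach_correct(tr, b_fixed=8.0)
        assert model is not None
        assert np.max(np.abs(corrected.values)) < 1e-6 * a

    def test_boxcar_response_preserved(self):
        proto = of.StimulusProtocol()
        t = proto.frame_times()
        box = np.zeros_like(t)
        box[proto.window_frames(6.75, 11.75)] = 12.0
        tr = make_trace(10.0 * np.exp(-t / 8.0) + box)
        corrected, _ = of.bleach_correct(tr, b_fixed=8.0)
        mag = of.response_magnitude(corrected)
        assert mag == pytest.approx(12.0, rel=0.05)

    def test_zero_weight_windows_do_not_influence_fit(self):
        proto = of.StimulusProtocol()
        t = proto.frame_times()
        base = 10.0 * np.exp(-t / 8.0) + 1.0
        tr1 = make_trace(base.copy())
        perturbed = base.copy()
        w = proto.fit_weights()
        perturbed[w == 0] += 37.0  # only excluded frames change
        tr2 = make_trace(perturbed)
        _, m1 = of.bleach_correct(tr1, 8.0)
        _, m2 = of.bleach_correct(tr2, 8.0)
        assert m1.A == pytest.approx(m2.A, abs=1e-9)
        assert m1.C == pytest.approx(m2.C, abs=1e-9)

    def test_flat_trace_correction_skipped(self):
        rng = np.random.default_rng(0)
        tr = make_trace(rng.normal(0, 0.3, 80))
        corrected, model = of.bleach_correct(tr, 8.0)
        assert model is None
        assert np.allclose(corrected.values, tr.values)


class TestResponseMagnitude:
    def test_flat_trace(self):
        assert of.response_magnitude(make_trace(np.full(80, 3.0))) == 0.0

    def test_exact_boxcar(self):
        proto = of.StimulusProtocol()
        vals = np.zeros(80)
        vals[proto.window_frames(6.75, 11.75)] = 10.0
        assert of.response_magnitude(make_trace(vals)) == pytest.approx(10.0)

    def test_invariant_under_global_offset(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 80)
        m1 = of.response_magnitude(make_trace(vals))
        m2 = of.response_magnitude(make_trace(vals + 42.0))
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_second_onset(self):
        proto = of.StimulusProtocol()
        vals = np.zeros(80)
        vals[proto.window_frames(9.75, 14.75)] = 5.0
        assert of.response_magnitude(make_trace(vals), onset_index=2) > 4.0


class TestDriftCorrect:
    def test_constant_references_give_unit_factors(self):
        resp = pd.Series([1.0, 2.0, 3.0], index=[0.0, 1.0, 2.0])
        refs = pd.Series([5.0, 5.0], index=[0.0, 2.0])
        out = of.drift_correct(resp, refs)
        pd.testing.assert_series_equal(out, resp)

    def test_linear_decline_doubles_final_factor(self):
        # references decline 10 -> 5: the last measurement is scaled by 2
        refs = pd.Series([10.0, 5.0], index=[0.0, 10.0])
        resp = pd.Series([1.0, 1.0], index=[0.0, 10.0])
        out = of.drift_correct(resp, refs)
        assert out.iloc[0] == pytest.approx(1.0)
        assert out.iloc[1] == pytest.approx(2.0)

    def test_references_self_correct_to_first(self):
        refs = pd.Series([8.0, 6.0, 4.0], index=[0.0, 5.0, 10.0])
        out = of.drift_correct(refs, refs)
        assert np.allclose(out, 8.0)

    def test_zero_crossing_is_invalid(self):
        refs = pd.Series([4.0, 1.0], index=[0.0, 5.0])
        resp = pd.Series([1.0], index=[10.0])  # L(10) < 0
        with pytest.raises(DriftModelError):
            of.drift_correct(resp, refs)


class TestFullPipeline:
    def test_magnitude_rank_recovery_under_noise(self):
        rhos = []
        for animal in range(8):
            cfg = of.TraceSimulationConfig(
                magnitudes=(0.0, 2.0, 5.0, 10.0, 20.0), seed=animal
            )
            traces, truth = of.simulate_traces(cfg)
            result = of.process_animal(traces, drift=False)
            merged = result.set_index("stimulus_id")["response"]
            rhos.append(spearmanr(merged[truth.index], truth).statistic)
        assert np.median(rhos) >= 0.98

    def test_zero_magnitude_recovers_near_zero(self):
        cfg = of.TraceSimulationConfig(magnitudes=(0.0,), noise_sd=0.0, seed=1)
        traces, _ = of.simulate_traces(cfg)
        result = of.process_animal(traces, drift=False)
        assert abs(result["response"].iloc[0]) < 1e-6

    def test_round_trip_traces_file(self, tmp_path):
        cfg = of.TraceSimulationConfig(seed=3)
        traces, _ = of.simulate_traces(cfg)
        path = tmp_path / "traces.tsv"
        of.write_traces(traces, path)
        back = of.load_traces(path)
        assert len(back) == len(traces)
        assert np.allclose(back[0].values, traces[0].values, atol=1e-5)
        assert back[0].is_solvent_control


def test_protocol_from_file(tmp_path):
    path = tmp_path / "protocol.cfg"
    path.write_text(
        "frame_rate = 4\nduration = 20\nonsets = 6.75, 9.75\n"
        "response_window = 5\nbaseline_window = 2.5\nprestim_weight = 100\n"
    )
    proto = of.StimulusProtocol.from_file(path)
    assert proto.onsets == (6.75, 9.75)
    assert proto.n_frames == 80
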