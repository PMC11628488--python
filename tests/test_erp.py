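"""Epoching arithmetic, signed-r² properties and the bootstrap estimators."""

import numpy as np
import pandas as pd
import pytest

from asmebci.erp import (
    EmptySelectionError,
    InsufficientDataError,
    estimate_onset_latency,
    estimate_peak_amplitude,
    grand_average,
    make_epochs,
    signed_r2_map,
)
from asmebci.paradigm import ParadigmConfig, TrialPlan, build_sequence
from asmebci.preprocessing import ContinuousData, highpass_and_concatenate
from asmebci.synthetic import NoiseSpec, simulate_recording

from conftest import build_epochset


@pytest.fixture(scope="module")
def noiseless_cont():
    """One noiseless 4-stream trial at 1000 Hz with the preset components."""
    from asmebci.synthetic import component_preset

    cfg = ParadigmConfig.asme4stream().with_n_stimuli(40)
    seq = build_sequence(cfg, seed=2)
    rec = simulate_recording(
        seq, TrialPlan(1, "D1"), component_preset("asme4stream"),
        NoiseSpec.silent(), fs=1000.0, seed=0,
    )
    return highpass_and_concatenate([rec])


class TestMakeEpochs:
    def test_sample_arithmetic_1000_to_250(self, noiseless_cont):
        eps = make_epochs(noiseless_cont, fs_out=250.0)
        assert eps.epochs.shape == (40, 64, 325)
        assert eps.times[0] == pytest.approx(-0.1)
        assert eps.times[-1] == pytest.approx(-0.1 + 324 / 250)
        assert eps.sampling_rate == 250.0

    def test_full_trial_yields_one_epoch_per_stimulus(self):
        cfg = ParadigmConfig.asme4stream()
        seq = build_sequence(cfg, seed=0)
        rec = simulate_recording(
            seq, TrialPlan(1, "D1"), [], NoiseSpec.silent(), fs=250.0, seed=0
        )
        cont = highpass_and_concatenate([rec])
        eps = make_epochs(cont, fs_out=250.0)
        assert len(eps) == 600
        assert eps.n_dropped == 0

    def test_constant_zero_input_gives_zero_epochs(self):
        from asmebci.synthetic import ALL_CHANNELS

        events = pd.DataFrame(
            {"sample": [500, 900], "stimulus_id": ["S1", "S1"],
             "label": ["nontarget"] * 2, "role": ["standard"] * 2,
             "stream": [1, 1], "trial": [0, 0], "run": [0, 0],
             "onset_s": [2.0, 3.6], "frequency_hz": [110.0] * 2, "tag": [""] * 2}
        )
        cont = ContinuousData(
            data=np.zeros((66, 2000)), sampling_rate=250.0,
            channel_names=ALL_CHANNELS, events=events,
        )
        eps = make_epochs(cont, fs_out=250.0)
        assert not eps.epochs.any()

    def test_edge_events_dropped_and_counted(self, noiseless_cont):
        cont = noiseless_cont
        ev = cont.events.copy()
        ev.loc[0, "sample"] = 3  # window starts before the recording
        shifted = ContinuousData(
            data=cont.data, sampling_rate=cont.sampling_rate,
            channel_names=cont.channel_names, events=ev,
        )
        eps = make_epochs(shifted, fs_out=250.0)
        assert eps.n_dropped == 1
        assert len(eps) == len(ev) - 1


class TestGrandAverage:
    def test_single_epoch_is_identity(self):
        x = np.random.default_rng(0).standard_normal((1, 3, 50))
        eps = build_epochset(x)
        assert np.allclose(grand_average(eps), x[0])

    def test_opposite_epochs_cancel(self):
        x = np.random.default_rng(1).standard_normal((1, 3, 50))
        eps = build_epochset(np.concatenate([x, -x]))
        assert np.allclose(grand_average(eps), 0.0)

    def test_empty_selection_raises(self):
        eps = build_epochset(np.zeros((4, 2, 10)))
        with pytest.raises(EmptySelectionError):
            grand_average(eps, np.zeros(4, dtype=bool))

    def test_query_selector(self):
        labels = pd.DataFrame(
            {"label": ["target", "nontarget"], "role": ["deviant", "standard"]}
        )
        x = np.stack([np.ones((2, 10)), 3 * np.ones((2, 10))])
        eps = build_epochset(x, labels=labels)
        assert np.allclose(grand_average(eps, "label == 'target'"), 1.0)


class TestSignedR2:
    @staticmethod
    def _labeled(x, y):
        labels = pd.DataFrame(
            {"label": ["target" if v else "nontarget" for v in y],
             "role": ["deviant" if v else "standard" for v in y]}
        )
        return build_epochset(x, labels=labels)

    def test_bounds_on_random_data(self):
        rng = np.random.default_rng(0)
        eps = self._labeled(rng.standard_normal((60, 4, 30)), rng.integers(0, 2, 60))
        r2 = signed_r2_map(eps).values
        assert np.all(np.abs(r2) <= 1.0)

    def test_perfect_separation_is_one(self):
        y = np.array([1] * 5 + [0] * 5)
        x = y[:, None, None] * np.ones((10, 2, 8))
        r2 = signed_r2_map(self._labeled(x, y)).values
        assert np.allclose(r2, 1.0)

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((40, 3, 20))
        y = rng.integers(0, 2, 40)
        a = signed_r2_map(self._labeled(x, y)).values
        b = signed_r2_map(self._labeled(x, 1 - y)).values
        assert np.allclose(a, -b, atol=1e-12)

    def test_permuted_labels_shrink_with_n(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((400, 2, 10))
        small = np.abs(
            signed_r2_map(self._labeled(x[:40], rng.integers(0, 2, 40))).values
        ).mean()
        large = np.abs(
            signed_r2_map(self._labeled(x, rng.integers(0, 2, 400))).values
        ).mean()
        assert large < small

    def test_zero_variance_maps_to_zero(self):
        y = np.array([1, 1, 0, 0])
        x = np.zeros((4, 1, 5))
        assert np.all(signed_r2_map(self._labeled(x, y)).values == 0.0)


def kernel_epochs(n, amplitude=4.0, peak_t=0.3, fs=250.0, n_t=325, noise=0.0, seed=0):
    """Epochs holding a half-cosine bump peaking at ``peak_t`` on channel 0."""
    rng = np.random.default_rng(seed)
    times = -0.1 + np.arange(n_t) / fs
    width = 0.2
    shape = np.where(
        np.abs(times - peak_t) < width / 2,
        0.5 * (1 + np.cos(2 * np.pi * (times - peak_t) / width)),
        0.0,
    )
    x = np.tile(shape * amplitude, (n, 5, 1))
    x += noise * rng.standard_normal(x.shape)
    return build_epochset(x, channels=("Fz", "FCz", "Cz", "CPz", "Pz"))


class TestBootstrapAmplitude:
    def test_noiseless_recovery_is_exact_for_every_replicate(self):
        eps = kernel_epochs(30, amplitude=3.7)
        res = estimate_peak_amplitude(
            eps, channels=eps.channels, n_boot=50, seed=1
        )
        assert np.all(res.samples == pytest.approx(3.7))
        assert res.estimate == pytest.approx(3.7)

    def test_peak_outside_window_uses_window_max(self):
        eps = kernel_epochs(20, amplitude=5.0, peak_t=0.6)
        res = estimate_peak_amplitude(eps, channels=eps.channels, n_boot=20, seed=0)
        times = eps.times
        win = (times >= 0.2) & (times <= 0.5)
        expected = eps.epochs[:, :, win].mean(0).max()
        assert res.estimate == pytest.approx(expected)
        assert res.estimate < 5.0

    def test_monotone_in_injected_amplitude(self):
        ests = [
            estimate_peak_amplitude(
                kernel_epochs(40, amplitude=a, noise=1.0, seed=9),
                channels=("Fz", "FCz", "Cz", "CPz", "Pz"),
                n_boot=100, seed=2,
            ).estimate
            for a in (1.0, 3.0, 5.0)
        ]
        assert ests[0] < ests[1] < ests[2]

    def test_deterministic_given_seed_and_counts(self):
        eps = kernel_epochs(25, noise=0.5, seed=4)
        r1 = estimate_peak_amplitude(eps, channels=eps.channels, n_boot=64, seed=7)
        r2 = estimate_peak_amplitude(eps, channels=eps.channels, n_boot=64, seed=7)
        assert np.array_equal(r1.samples, r2.samples)
        assert len(r1.samples) == 64

    def test_too_few_epochs_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_peak_amplitude(
                kernel_epochs(1), channels=("Fz", "FCz", "Cz", "CPz", "Pz")
            )


class TestBootstrapLatency:
    def test_identical_conditions_never_significant(self):
        eps = kernel_epochs(20, noise=0.0)  # every epoch identical
        res = estimate_onset_latency(
            eps, eps, channels=eps.channels, n_boot=30, seed=0
        )
        assert res.n_failed == 30
        assert not res.defined
        assert np.isnan(res.estimate)

    def test_noiseless_step_detected_at_first_grid_time(self):
        # target exceeds standard from 0.25 s on; grid step puts the first
        # sampled time at 0.252 s
        times_n = 325
        fs = 250.0
        times = -0.1 + np.arange(times_n) / fs
        base = np.zeros((12, 5, times_n))
        step = base.copy()
        step[:, :, times >= 0.25] = 1.0
        rng = np.random.default_rng(0)
        jitter = 1e-6 * rng.standard_normal(base.shape)  # break exact ties
        t_eps = build_epochset(step + jitter, channels=("a", "b", "c", "d", "e"))
        s_eps = build_epochset(base + jitter[::-1], channels=("a", "b", "c", "d", "e"))
        res = estimate_onset_latency(
            t_eps, s_eps, channels=t_eps.channels, n_boot=20, seed=3
        )
        assert res.n_failed == 0
        assert res.estimate == pytest.approx(0.252, abs=1e-9)

    def test_latency_always_inside_window(self):
        eps_t = kernel_epochs(30, amplitude=3.0, noise=1.0, seed=6)
        eps_s = kernel_epochs(30, amplitude=0.0, noise=1.0, seed=7)
        res = estimate_onset_latency(
            eps_t, eps_s, channels=eps_t.channels, n_boot=60, seed=1
        )
        assert res.defined
        assert np.all((res.samples >= 0.2) & (res.samples <= 0.5))
        assert len(res.samples) == 60 - res.n_failed
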