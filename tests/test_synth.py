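import dataclasses

import numpy as np
import pytest

from erpwp import synth
from erpwp.io_core import CONDITIONS
from erpwp.stimuli import build_inventory, generate_list, schedule_onsets, to_event_list


def quiet_spec(**overrides):
    """CohortSpec with noise, drift, artifacts and variability switched off
    unless overridden."""
    base = dict(noise_sd_uv=0.0, drift_sd_uv=0.0, blink_rate_hz=0.0,
                movement_rate_hz=0.0, subject_amplitude_sd=0.0)
    base.update(overrides)
    return dataclasses.replace(synth.CohortSpec(), **base)


def session_events(seed=0, fs=1000.0):
    lst = generate_list(build_inventory(), seed)
    onsets = schedule_onsets(lst, seed)
    return to_event_list(lst, onsets, fs)


class TestSubjectSimulation:
    def test_zero_amplitudes_and_noise_give_flat_recording(self):
        spec = quiet_spec(components=tuple(
            synth.ComponentSpec(c.center_ms, c.width_ms,
                                {k: 0.0 for k in c.amplitude_uv})
            for c in synth.CohortSpec().components))
        rec, _, anns = synth.simulate_subject(spec, 4.8, session_events(), 0)
        assert np.abs(rec.data).max() == 0.0
        assert len(anns) == 0

    def test_single_component_reproduced_at_peak(self):
        comp = synth.ComponentSpec(100.0, 25.0,
                                   {c: -5.0 for c in CONDITIONS},
                                   channel_gains={"Fz": 1.0})
        spec = quiet_spec(components=(comp,))
        events = session_events()
        rec, _, _ = synth.simulate_subject(spec, 4.8, events, 0)
        from erpwp.preprocess import epoch_recording
        ep = epoch_recording(rec, events)
        avg = ep.data.mean(axis=0)[ep.channel_index("Fz")]
        t_peak = ep.times_ms[np.argmin(avg)]
        assert avg.min() == pytest.approx(-5.0, abs=1e-6)
        assert t_peak == pytest.approx(100.0, abs=1.0)

    def test_window_mean_contrast_within_closed_form_bound(self):
        """An injected +3 µV late contrast is recovered in the 650-800 ms
        window means to within twice the trial-averaging standard error."""
        comp = synth.ComponentSpec(
            725.0, 200.0,  # broad bump ≈ flat over the window
            {"WORDS": 1.5, "SIMILAR": 1.5, "NONSENSE": -1.5},
            channel_gains={"Fz": 1.0})
        spec = quiet_spec(components=(comp,), noise_sd_uv=10.0)
        events = session_events(3)
        rec, _, _ = synth.simulate_subject(spec, 4.8, events, 7)
        from erpwp.preprocess import epoch_recording
        ep = epoch_recording(rec, events)
        sl = ep.time_slice(650, 800)
        means = {c: ep.data[ep.conditions == c].mean(axis=0)[0, sl].mean()
                 for c in CONDITIONS}
        diff = means["WORDS"] - means["NONSENSE"]
        injected = 3.0 * np.exp(
            -0.5 * ((np.arange(650, 801) - 725) / 200.0) ** 2).mean()
        se_bound = 2 * (10.0 / np.sqrt(80)) * np.sqrt(2)
        assert abs(diff - injected) < se_bound

    def test_blinks_large_on_eog_attenuated_on_scalp(self):
        spec = quiet_spec(blink_rate_hz=0.1, components=())
        rec, _, anns = synth.simulate_subject(spec, 4.8, session_events(), 5)
        assert len(anns) > 0
        assert all(a.label == "blink" for a in anns)
        f7 = np.abs(rec.get("F7")).max()
        fz = np.abs(rec.get("Fz")).max()
        assert f7 == pytest.approx(spec.blink_amplitude_uv, rel=0.05)
        assert fz == pytest.approx(
            spec.blink_amplitude_uv * spec.blink_propagation, rel=0.05)

    def test_artifact_ground_truth_covers_large_samples(self):
        """Every sample driven beyond 5× noise_sd by injected artifacts
        falls inside a logged annotation interval."""
        spec = dataclasses.replace(synth.CohortSpec(), noise_sd_uv=1.0,
                                   drift_sd_uv=0.0, subject_amplitude_sd=0.0,
                                   components=(), blink_rate_hz=0.1,
                                   movement_rate_hz=0.05)
        rec, _, anns = synth.simulate_subject(spec, 4.8, session_events(), 11)
        fs = rec.sampling_rate
        covered = np.zeros(rec.n_samples, dtype=bool)
        for a in anns:
            covered[int(a.start_s * fs):int(np.ceil(a.end_s * fs)) + 1] = True
        big = np.abs(rec.data).max(axis=0) > 5.0 * 5  # 5×sd plus headroom
        assert big.any()
        assert covered[big].all()

    def test_pink_noise_spectral_slope(self):
        x = synth._pink_noise(np.random.default_rng(0), (60,), 4096, 1.0,
                              1000.0)
        freqs = np.fft.rfftfreq(4096, 1e-3)
        psd = (np.abs(np.fft.rfft(x, axis=-1)) ** 2).mean(axis=0)
        band = (freqs >= 1.0) & (freqs <= 40.0)
        slope = np.polyfit(np.log(freqs[band]), np.log(psd[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)


class TestCohortSimulation:
    def test_subject_count_and_determinism(self, tmp_path):
        spec = dataclasses.replace(quiet_spec(noise_sd_uv=2.0),
                                   n_subjects=3, seed=9)
        cov = synth.default_covariates(3, seed=9)
        out_a = tmp_path / "a"
        out_b = tmp_path / "b"
        subs_a = synth.simulate_cohort(spec, cov, out_dir=out_a)
        subs_b = synth.simulate_cohort(spec, cov, out_dir=out_b)
        assert len(subs_a) == 3
        for f in sorted(out_a.iterdir()):
            assert (out_b / f.name).read_bytes() == f.read_bytes()

    def test_covariate_table_size_mismatch_rejected(self):
        spec = dataclasses.replace(quiet_spec(), n_subjects=3)
        with pytest.raises(ValueError, match="covariate"):
            synth.simulate_cohort(spec, synth.default_covariates(5))

    def test_usage_frequency_scales_injected_contrast(self):
        """High-usage subjects carry a larger true late WORDS−NONSENSE
        contrast than low-usage subjects (covariate moderation)."""
        spec = quiet_spec()
        events = session_events()
        from erpwp.preprocess import epoch_recording

        def contrast(usage):
            rec, _, _ = synth.simulate_subject(spec, usage, events, 0)
            ep = epoch_recording(rec, events)
            sl = ep.time_slice(650, 800)
            m = {c: ep.data[ep.conditions == c].mean(axis=0)[0, sl].mean()
                 for c in CONDITIONS}
            return m["WORDS"] - m["NONSENSE"]

        assert contrast(5.0) > contrast(4.8) > contrast(4.5) >= 0.0

    def test_default_covariates_show_ceiling_effect(self):
        cov = synth.default_covariates(17, seed=1)
        usage = cov.values("usage_frequency")
        assert ((1 <= usage) & (usage <= 5)).all()
        assert (usage == 5.0).sum() >= 4


def test_simulate_epochs_matches_design_shape():
    ep = synth.simulate_epochs(quiet_spec(noise_sd_uv=1.0), 4.8, seed=0)
    assert ep.data.shape == (240, 2, 1201)
    for c in CONDITIONS:
        assert (ep.conditions == c).sum() == 80
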