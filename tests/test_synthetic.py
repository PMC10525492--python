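"""Synthetic cohort generator: background, signatures, injection, cohorts,
and the band-power template-matching oracle."""


import numpy as np
import pytest

from ictalkit.io_formats import (
    AnnotationSet, SEIZURE_LABELS, STANDARD_21, parse_tse, read_recording,
)
from ictalkit.synthetic import (
    CohortConfig,
    background_eeg,
    default_signatures,
    generate_cohort,
    inject_seizure,
    oracle_classify,
    simulate_record,
    tile_background,
)


def _bandpower(x, sr, lo, hi):
    f = np.fft.rfftfreq(x.size, 1 / sr)
    p = np.abs(np.fft.rfft(x)) ** 2
    return p[(f >= lo) & (f < hi)].sum()


class TestBackground:
    def test_deterministic_for_seed(self):
        a = background_eeg(5.0, seed=42)
        b = background_eeg(5.0, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_amplitudes_give_silence(self):
        cfg = CohortConfig(noise_uv=0.0, background_alpha_uv=0.0)
        rec = background_eeg(2.0, cfg=cfg, seed=1)
        assert np.abs(rec.data).max() == 0.0

    def test_posterior_dominant_alpha(self):
        rec = background_eeg(60.0, seed=3)
        o1 = rec.data[rec.channel_names.index("O1")]
        fp1 = rec.data[rec.channel_names.index("Fp1")]
        assert _bandpower(o1, 250, 9, 11) > _bandpower(fp1, 250, 9, 11)

    def test_rms_near_requested_noise_level(self):
        cfg = CohortConfig(noise_uv=15.0, background_alpha_uv=0.0)
        rec = background_eeg(20.0, cfg=cfg, seed=4)
        rms = np.sqrt((rec.data**2).mean(axis=1))
        assert np.all(rms > 10) and np.all(rms < 20)


class TestSignatures:
    sigs = default_signatures()
    by_label = {s.label: s for s in sigs}

    def test_one_signature_per_type(self):
        assert sorted(s.label for s in self.sigs) == sorted(SEIZURE_LABELS)

    def test_absence_midline_emphasis(self):
        absz = self.by_label["absz"]
        assert absz.spatial_profile["Fz"] >= absz.spatial_profile["T3"]
        assert absz.spatial_profile["Pz"] >= absz.spatial_profile["T4"]

    def test_focal_types_have_focus(self):
        for lab in ("fnsz", "spsz", "cpsz"):
            sig = self.by_label[lab]
            assert sig.focal and sig.focus_electrode in STANDARD_21.names
            assert sig.spatial_profile[sig.focus_electrode] == pytest.approx(1.0)

    def test_focal_gain_decays_with_scalp_distance(self):
        fnsz = self.by_label["fnsz"]
        d = {n: STANDARD_21.scalp_distance(n, "T3") for n in STANDARD_21.names}
        near, far = min(d, key=d.get), max(d, key=d.get)
        assert fnsz.spatial_profile[near] > fnsz.spatial_profile[far]

    def test_generalized_gains_at_least_07(self):
        for lab in ("gnsz", "absz", "tnsz", "tcsz", "mysz"):
            assert min(self.by_label[lab].spatial_profile.values()) >= 0.7

    def test_pairwise_distinguishable(self):
        keys = [
            (s.waveform, round(s.base_freq_hz, 1),
             s.focus_electrode or tuple(sorted(s.spatial_profile.items())))
            for s in self.sigs
        ]
        assert len(set(keys)) == len(keys)


class TestInjectSeizure:
    def setup_method(self):
        self.cfg = CohortConfig()
        self.rec = background_eeg(30.0, cfg=self.cfg, seed=5)
        self.ann = tile_background(
            AnnotationSet([]), 30.0
        )
        self.sigs = {s.label: s for s in default_signatures()}

    def test_annotation_event_added(self):
        _, ann2 = inject_seizure(self.rec, self.ann, self.sigs["absz"], 10.0, 4.0)
        ev = ann2.seizure_events()
        assert len(ev) == 1
        assert (ev[0].start_s, ev[0].stop_s, ev[0].label) == (10.0, 14.0, "absz")

    def test_zero_amplitude_leaves_data(self):
        from dataclasses import replace

        sig = replace(self.sigs["gnsz"], amplitude_uv=0.0)
        rec2, ann2 = inject_seizure(self.rec, self.ann, sig, 10.0, 4.0)
        np.testing.assert_array_equal(rec2.data, self.rec.data)
        assert len(ann2.seizure_events()) == 1

    def test_overlap_with_existing_seizure_rejected(self):
        _, ann2 = inject_seizure(self.rec, self.ann, self.sigs["absz"], 10.0, 4.0)
        with pytest.raises(ValueError, match="overlap"):
            inject_seizure(self.rec, ann2, self.sigs["gnsz"], 12.0, 4.0)

    def test_outside_record_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            inject_seizure(self.rec, self.ann, self.sigs["absz"], 28.0, 5.0)

    def test_focal_power_peaks_at_focus(self):
        rec2, _ = inject_seizure(self.rec, self.ann, self.sigs["fnsz"], 5.0, 8.0)
        sl = slice(int(5 * 250), int(13 * 250))
        added = rec2.data[:, sl] - self.rec.data[:, sl]
        p_t3 = _bandpower(added[self.rec.channel_names.index("T3")], 250, 4, 8)
        p_o2 = _bandpower(added[self.rec.channel_names.index("O2")], 250, 4, 8)
        assert p_t3 > p_o2

    def test_background_untouched_elsewhere(self):
        rec2, _ = inject_seizure(self.rec, self.ann, self.sigs["gnsz"], 10.0, 4.0)
        np.testing.assert_array_equal(rec2.data[:, : 10 * 250],
                                      self.rec.data[:, : 10 * 250])

    def test_injected_sine_peaks_in_nearest_bin(self):
        cfg = CohortConfig(noise_uv=1.0, background_alpha_uv=0.0)
        rec = background_eeg(30.0, cfg=cfg, seed=6)
        ann = tile_background(AnnotationSet([]), 30.0)
        sig = self.sigs["gnsz"]  # 4 Hz rhythmic sine, amplitude >> noise
        rec2, _ = inject_seizure(rec, ann, sig, 10.0, 8.0)
        seg = rec2.data[0, int(12 * 250) : int(13 * 250)]
        f = np.fft.rfftfreq(250, 1 / 250)
        peak = f[np.abs(np.fft.rfft(seg - seg.mean())).argmax()]
        assert abs(peak - sig.base_freq_hz) <= 1.0


class TestCohort:
    def test_record_structure_and_tiling(self):
        cfg = CohortConfig(n_subjects=2, record_duration_s=60,
                           seizures_per_record=3, seed=9)
        rec, ann = simulate_record(cfg, 0)
        assert rec.n_channels == 21 and rec.sampling_rate_hz == 250.0
        assert len(ann.seizure_events()) == 3
        # events tile [0, 60) with no gaps
        cursor = 0.0
        for ev in ann:
            assert ev.start_s == pytest.approx(cursor, abs=1e-6)
            cursor = ev.stop_s
        assert cursor == pytest.approx(60.0)

    def test_class_mix_concentration(self):
        cfg = CohortConfig(n_subjects=2, record_duration_s=60,
                           seizures_per_record=3, class_mix={"gnsz": 1.0}, seed=2)
        for i in range(2):
            _, ann = simulate_record(cfg, i)
            assert {e.label for e in ann.seizure_events()} == {"gnsz"}

    def test_generate_cohort_files_and_determinism(self, tmp_path):
        cfg = CohortConfig(n_subjects=2, record_duration_s=60,
                           seizures_per_record=3, seed=4)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = generate_cohort(cfg, d1)
        m2 = generate_cohort(cfg, d2)
        assert (d1 / "manifest.json").read_bytes() == (d2 / "manifest.json").read_bytes()
        assert len(m1["records"]) == 2
        for row in m1["records"]:
            rec = read_recording(d1 / row["recording"])
            ann = parse_tse(d1 / row["annotation"])
            assert rec.n_channels == 21
            assert len(ann.seizure_events()) == row["n_seizures"] == 3

    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums"):
            CohortConfig(class_mix={"gnsz": 0.5})


class TestOracle:
    def test_class_separability(self, small_cohort):
        """Template-matching oracle solves the 8-class task at >= 95%."""
        _, cohort = small_cohort
        x, y = [], []
        for rec, ann in cohort:
            for ev in ann.seizure_events():
                t = ev.start_s
                while t + 1.0 <= ev.stop_s:
                    i0 = int(round(t * 250))
                    x.append(rec.data[:, i0 : i0 + 250])
                    y.append(ev.label)
                    t += 1.0
        pred = oracle_classify(np.array(x), 250.0)
        acc = np.mean([p == t for p, t in zip(pred, y)])
        assert acc >= 0.95
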