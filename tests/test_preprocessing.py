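"""Filtering, resampling, windowing, STFT tensors, splits, class weights."""

import warnings

import numpy as np
import pytest

from ictalkit.io_formats import AnnotationEvent, AnnotationSet, Recording
from ictalkit.preprocessing import (
    LabeledWindow,
    SplitSpec,
    class_weights,
    extract_windows,
    fir_lowpass,
    kfold_indices,
    make_splits,
    resample,
    save_tensors,
    load_tensors,
    stft_tensor,
    tapered_segments,
)


def _sine_rec(freq, sr=250.0, dur=10.0, channels=("Cz",)):
    t = np.arange(int(dur * sr)) / sr
    data = np.tile(np.sin(2 * np.pi * freq * t), (len(channels), 1))
    return Recording("s", "r", list(channels), sr, data)


class TestFilter:
    def test_passband_gain_within_one_percent(self):
        out = fir_lowpass(_sine_rec(10.0))
        mid = out.data[0, 500:-500]
        assert abs(np.abs(mid).max() - 1.0) < 0.01

    def test_stopband_attenuation_40db(self):
        out = fir_lowpass(_sine_rec(60.0))
        mid = np.abs(out.data[0, 500:-500]).max()
        assert 20 * np.log10(mid) < -40

    def test_dc_unchanged(self):
        rec = Recording("s", "r", ["Cz"], 250.0, np.full((1, 1000), 7.5))
        out = fir_lowpass(rec)
        np.testing.assert_allclose(out.data, 7.5, rtol=1e-6)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fir_lowpass(_sine_rec(10.0), cutoff_hz=125.0)

    def test_length_preserved(self):
        rec = _sine_rec(10.0, dur=3.3)
        assert fir_lowpass(rec).n_samples == rec.n_samples


class TestResample:
    def test_downsample_sample_count(self):
        rec = _sine_rec(10.0, sr=500.0, dur=10.0)
        assert resample(rec, 250.0).n_samples == 2500

    def test_identity(self):
        rec = _sine_rec(10.0)
        out = resample(rec, 250.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_matches_analytic_sinusoid(self):
        rec = _sine_rec(5.0, sr=250.0, dur=10.0)
        out = resample(rec, 50.0)
        ref = np.sin(2 * np.pi * 5.0 * np.arange(500) / 50.0)
        c = np.corrcoef(out.data[0, 25:-25], ref[25:-25])[0, 1]
        assert c > 0.99
        assert out.sampling_rate_hz == 50.0


class TestWindows:
    def test_floor_window_count(self):
        rec = Recording("s", "r", ["Cz"], 250.0, np.zeros((1, int(10.7 * 250))))
        ann = AnnotationSet([AnnotationEvent(0, 10.7, "bckg")])
        assert len(extract_windows(rec, ann)) == 10

    def test_all_background(self):
        rec = Recording("s", "r", ["Cz"], 250.0, np.zeros((1, 2500)))
        ann = AnnotationSet([AnnotationEvent(0, 10, "bckg")])
        assert {w.label for w in extract_windows(rec, ann)} == {"bckg"}

    def test_boundary_label_tiling(self):
        rec = Recording("s", "r", ["Cz"], 250.0, np.zeros((1, 2500)))
        ann = AnnotationSet(
            [AnnotationEvent(0, 5, "bckg"), AnnotationEvent(5, 8, "fnsz"),
             AnnotationEvent(8, 10, "bckg")]
        )
        labels = [w.label for w in extract_windows(rec, ann)]
        assert labels == ["bckg"] * 5 + ["fnsz"] * 3 + ["bckg"] * 2

    def test_windows_disjoint_and_conserving(self):
        rng = np.random.default_rng(0)
        rec = Recording("s", "r", ["Cz", "Pz"], 100.0, rng.normal(size=(2, 1034)))
        ann = AnnotationSet([AnnotationEvent(0, 10.34, "bckg")])
        ws = extract_windows(rec, ann)
        stitched = np.concatenate([w.data for w in ws], axis=1)
        np.testing.assert_array_equal(stitched, rec.data[:, : 10 * 100])


class TestSTFT:
    def test_printed_tensor_shape(self):
        w = LabeledWindow(np.zeros((21, 250)), "bckg", "s", 0)
        assert stft_tensor(w).values.shape == (21, 33, 8)

    def test_zero_window_zero_tensor(self):
        w = LabeledWindow(np.zeros((3, 250)), "bckg", "s", 0)
        assert np.abs(stft_tensor(w).values).max() == 0.0

    def test_pure_tone_hits_its_bin(self):
        # 7.8125 Hz = bin 2 of the 64-point grid at 250 Hz
        t = np.arange(250) / 250.0
        for phase in (0.0, 1.0, 2.5):
            w = LabeledWindow(np.sin(2 * np.pi * 7.8125 * t + phase)[None],
                              "bckg", "s", 0)
            st = stft_tensor(w)
            assert list(st.values[0].argmax(axis=0)) == [2] * 8

    def test_parseval_per_segment(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 250))
        segs = tapered_segments(data, nfft=64)
        st = stft_tensor(LabeledWindow(data, "bckg", "s", 0)).values
        two_sided = (
            st[:, 0, :] ** 2 + st[:, -1, :] ** 2 + 2 * (st[:, 1:-1, :] ** 2).sum(1)
        )
        energy = (segs**2).sum(-1)  # (C, 8)
        np.testing.assert_allclose(two_sided, 64 * energy, rtol=1e-6)

    def test_commutes_with_channel_subset(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(5, 250))
        full = stft_tensor(LabeledWindow(data, "bckg", "s", 0)).values
        sub = stft_tensor(LabeledWindow(data[[1, 3]], "bckg", "s", 0)).values
        np.testing.assert_allclose(sub, full[[1, 3]])

    def test_odd_nfft_rejected(self):
        w = LabeledWindow(np.zeros((1, 250)), "bckg", "s", 0)
        with pytest.raises(ValueError, match="even"):
            stft_tensor(w, nfft=63)

    def test_timesteps_fixed_across_sampling_rates(self):
        for sr in (50, 100, 150, 200, 250):
            w = LabeledWindow(np.zeros((4, sr)), "bckg", "s", 0)
            assert stft_tensor(w).values.shape == (4, 33, 8)

    def test_tensor_persistence_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        tensors = [
            stft_tensor(LabeledWindow(rng.normal(size=(3, 250)), "fnsz", "s", i))
            for i in range(4)
        ]
        path = tmp_path / "t.npz"
        save_tensors(tensors, path, meta={"sr": 250})
        back, meta = load_tensors(path)
        assert meta == {"sr": 250}
        assert [t.label for t in back] == ["fnsz"] * 4
        np.testing.assert_allclose(back[2].values, tensors[2].values)


def _singleton_windows(n, label="bckg"):
    return [
        LabeledWindow(np.zeros((1, 10)), label, f"s{i}", i, record_id=f"r{i}")
        for i in range(n)
    ]


class TestSplits:
    def test_fraction_sizes_with_singleton_events(self):
        ws = _singleton_windows(100)
        tr, va, te = make_splits(ws, SplitSpec(0.7, 0.15, 0.15, seed=0))
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_event_grouping_keeps_event_whole(self):
        ws = [LabeledWindow(np.zeros((1, 10)), "fnsz", "s0", 5, record_id="r")
              for _ in range(50)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            parts = make_splits(ws, SplitSpec(seed=1))
        sizes = sorted(len(p) for p in parts)
        assert sizes == [0, 0, 50]

    def test_partition_disjoint_exhaustive(self, small_windows):
        windows, _, _ = small_windows
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr, va, te = make_splits(windows, SplitSpec(seed=3))
        all_idx = sorted(tr + va + te)
        assert all_idx == list(range(len(windows)))
        assert not (set(tr) & set(va)) and not (set(tr) & set(te))

    def test_no_event_leaks_across_splits(self, small_windows):
        windows, _, _ = small_windows
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr, va, te = make_splits(windows, SplitSpec(seed=3))
        groups = [set(windows[i].group_key for i in part) for part in (tr, va, te)]
        assert not (groups[0] & groups[1]) and not (groups[0] & groups[2])
        assert not (groups[1] & groups[2])

    def test_seed_determinism_and_variation(self):
        ws = _singleton_windows(60)
        a = make_splits(ws, SplitSpec(seed=5))
        b = make_splits(ws, SplitSpec(seed=5))
        c = make_splits(ws, SplitSpec(seed=6))
        assert a == b and a != c

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(0.5, 0.5, 0.5)


class TestKFold:
    def test_singleton_events_balanced_folds(self):
        ws = _singleton_windows(50)
        folds = kfold_indices(ws, k=5, seed=0)
        assert [len(va) for _, va in folds] == [10] * 5

    def test_validation_folds_partition_everything(self, small_windows):
        windows, _, _ = small_windows
        folds = kfold_indices(windows, k=5, seed=0)
        union = sorted(i for _, va in folds for i in va)
        assert union == list(range(len(windows)))

    def test_every_class_in_every_training_fold(self, default_cohort_data):
        # needs the full cohort: every class there has several events
        _, _, windows, _, labels = default_cohort_data
        folds = kfold_indices(windows, k=5, seed=0)
        present = set(labels)
        for tr, _ in folds:
            assert set(labels[i] for i in tr) == present

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(_singleton_windows(10), k=1)


class TestClassWeights:
    def test_formula(self):
        w = class_weights(["A"] * 3 + ["B"])
        assert w["A"] == pytest.approx(4 / 6)
        assert w["B"] == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "labels",
        [["A"] * 5 + ["B"] * 5, ["x"] * 7, ["a", "b", "b", "c", "c", "c"]],
    )
    def test_conservation(self, labels):
        w = class_weights(labels)
        total = sum(w[l] for l in labels)
        assert total == pytest.approx(len(labels))

    def test_balanced_and_single(self):
        assert class_weights(["A", "B"]) == {"A": 1.0, "B": 1.0}
        assert class_weights(["A"]) == {"A": 1.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_weights([])
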