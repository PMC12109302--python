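"""Label mapping, wake trimming, segmentation, and the EDF round trip
(write with the package's own writer, read back through MNE)."""

import numpy as np
import pytest

from sleepssm.data import EPOCH_SAMPLES, StageLabel
from sleepssm.edfwrite import read_edf_header, write_edf, write_hypnogram_edf
from sleepssm.signal_io import (RawRecording, expand_annotations,
                                load_recording, map_stage_labels,
                                pair_sleep_edf_files, prepare_recording,
                                export_recording_edf, segment_epochs,
                                trim_wake_margin)
from sleepssm.synthetic import GeneratorConfig, synth_dataset

S = StageLabel


# ---------------------------------------------------------------------------
# label mapping


def test_rk_to_aasm_mapping():
    assert map_stage_labels(["3", "4"]) == [S.N3, S.N3]
    assert map_stage_labels(["MOVEMENT", "?"]) == [None, None]
    assert map_stage_labels(["W", "1", "2", "R"]) == [S.W, S.N1, S.N2, S.REM]
    # EDF+ long form and AASM names are accepted and idempotent
    assert map_stage_labels(["Sleep stage 4", "Sleep stage W"]) == [S.N3, S.W]
    assert map_stage_labels(["N3", "REM"]) == [S.N3, S.REM]


def test_unknown_label_is_named_in_error():
    with pytest.raises(ValueError, match="'Sleep stage X'"):
        map_stage_labels(["W", "Sleep stage X"])


# ---------------------------------------------------------------------------
# wake trimming


def test_trim_keeps_half_hour_margin():
    labels = [S.W] * 100 + [S.N2] * 50 + [S.W] * 100
    assert trim_wake_margin(labels, 60) == (40, 210)


def test_trim_degenerate_cases():
    assert trim_wake_margin([S.N2] * 30, 60) == (0, 30)
    assert trim_wake_margin(
        map_stage_labels(["W", "W", "1", "W", "W"]), 0) == (2, 3)
    with pytest.warns(UserWarning, match="no sleep"):
        assert trim_wake_margin([S.W] * 10, 60) == (0, 10)
    # excluded epochs never count as sleep onset
    labels = [None] * 5 + [S.W] * 5 + [S.N1] * 2 + [S.W] * 5
    assert trim_wake_margin(labels, 2) == (8, 14)
    with pytest.raises(ValueError):
        trim_wake_margin([], 60)


# ---------------------------------------------------------------------------
# segmentation


def _raw_from_labels(raw_labels, sfreq=100.0, extra_samples=0):
    n = len(raw_labels) * EPOCH_SAMPLES + extra_samples
    rng = np.random.default_rng(0)
    sig = rng.normal(size=(2, n))
    anns = [(i * 30.0, 30.0, f"Sleep stage {lab}")
            for i, lab in enumerate(raw_labels)]
    return RawRecording(subject_id="T", night_id="0",
                        channels={"EEG Fpz-Cz": sig[0],
                                  "EOG horizontal": sig[1]},
                        sampling_rate=sfreq, annotations=anns)


def test_segment_drops_excluded_and_counts():
    raw = _raw_from_labels(["W", "1", "2", "M", "2", "3", "?", "R", "W", "2"])
    rec = segment_epochs(raw, margin_epochs=60)
    assert len(rec) == 8  # 10 windows, 2 excluded
    labels = [e.label for e in rec.epochs]
    assert S.N3 in labels and None not in labels


def test_segment_slicing_identity():
    """Epoch k's EEG equals raw samples [3000k, 3000(k+1)) when
    z-scoring is off."""
    raw = _raw_from_labels(["2"] * 5)
    rec = segment_epochs(raw, zscore=False)
    eeg = raw.channels["EEG Fpz-Cz"]
    for k, ep in enumerate(rec.epochs):
        np.testing.assert_allclose(
            ep.eeg, eeg[k * EPOCH_SAMPLES:(k + 1) * EPOCH_SAMPLES],
            atol=1e-6)


def test_segment_applies_wake_trim():
    raw = _raw_from_labels(["W"] * 8 + ["2"] * 4 + ["W"] * 8)
    rec = segment_epochs(raw, margin_epochs=2)
    assert len(rec) == 2 + 4 + 2
    assert rec.epochs[0].index_in_night == 6


def test_segment_errors_on_short_signal():
    raw = _raw_from_labels(["2"] * 5)
    for name in raw.channels:
        raw.channels[name] = raw.channels[name][:-EPOCH_SAMPLES]
    with pytest.raises(ValueError, match="exceeds signal length"):
        segment_epochs(raw)


def test_expand_annotations_drops_partial_window():
    onsets, labels = expand_annotations([(0.0, 75.0, "Sleep stage 2")])
    assert onsets == [0.0, 30.0]
    assert labels == ["Sleep stage 2", "Sleep stage 2"]


def test_segment_histogram_matches_generator(default_dataset):
    """Round-tripping a synthetic recording through segmentation keeps
    the generator's label histogram (no exclusions present)."""
    rec = default_dataset[0]
    x, y = rec.to_arrays()
    names = ["W", "1", "2", "3", "R"]
    raw = RawRecording(
        subject_id=rec.subject_id, night_id="0",
        channels={"EEG Fpz-Cz": x[:, 0, :].ravel(),
                  "EOG horizontal": x[:, 1, :].ravel()},
        sampling_rate=100.0,
        annotations=[(i * 30.0, 30.0, f"Sleep stage {names[int(v)]}")
                     for i, v in enumerate(y)])
    out = segment_epochs(raw, margin_epochs=10**6, zscore=False)
    np.testing.assert_array_equal(out.to_arrays()[1], y)


# ---------------------------------------------------------------------------
# EDF round trip


@pytest.fixture()
def edf_pair(tmp_path):
    recs = synth_dataset(GeneratorConfig(n_subjects=1, epochs_per_subject=10,
                                         seed=3))
    psg = tmp_path / "S000-PSG.edf"
    hyp = tmp_path / "S000-Hypnogram.edf"
    export_recording_edf(recs[0], psg, hyp)
    return recs[0], psg, hyp


def test_edf_round_trip_within_quantisation(edf_pair):
    """Write-then-read identity within the 16-bit EDF quantisation step."""
    rec, psg, hyp = edf_pair
    raw = load_recording(psg, hyp)
    assert list(raw.channels) == ["EEG Fpz-Cz", "EOG horizontal"]
    assert raw.sampling_rate == 100.0
    x, y = rec.to_arrays()
    for i, name in enumerate(raw.channels):
        orig = x[:, i, :].ravel()
        got = raw.channels[name]
        step = 2 * np.abs(orig).max() / 65534
        assert np.abs(orig - got).max() <= step
    # labels survive the EDF+ annotation round trip
    rt = segment_epochs(raw, zscore=False)
    np.testing.assert_array_equal(rt.to_arrays()[1], y)


def test_missing_channel_is_named(edf_pair):
    _, psg, hyp = edf_pair
    with pytest.raises(ValueError, match="channel not found: 'EEG Pz-Oz'"):
        load_recording(psg, hyp, ["EEG Pz-Oz"])


def test_off_spec_sampling_rate_is_rejected(tmp_path):
    """A 50 Hz channel raises instead of being silently resampled."""
    sig = np.random.default_rng(0).normal(size=1500)
    psg = tmp_path / "slow-PSG.edf"
    write_edf(psg, {"EEG Fpz-Cz": sig, "EOG horizontal": sig}, sfreq=50.0)
    hyp = tmp_path / "slow-Hypnogram.edf"
    write_hypnogram_edf(hyp, [(0.0, 30.0, "Sleep stage W")])
    with pytest.raises(ValueError, match="50 Hz, expected 100"):
        load_recording(psg, hyp)


def test_edf_header_fields(edf_pair):
    _, psg, _ = edf_pair
    header = read_edf_header(psg)
    assert header.channel_names == ["EEG Fpz-Cz", "EOG horizontal"]
    assert header.sampling_rate("EEG Fpz-Cz") == 100.0
    assert header.n_records * header.record_seconds == 10 * 30


def test_pairing_helper(tmp_path, edf_pair):
    _, psg, hyp = edf_pair
    pairs = pair_sleep_edf_files(psg.parent)
    assert pairs == [(psg, hyp)]
    # Sleep-EDF style names pair on the subject-night prefix even though
    # the trailing scorer characters differ
    sc_psg = psg.parent / "SC4001E0-PSG.edf"
    sc_hyp = psg.parent / "SC4001EC-Hypnogram.edf"
    sc_psg.write_bytes(psg.read_bytes())
    sc_hyp.write_bytes(hyp.read_bytes())
    assert (sc_psg, sc_hyp) in pair_sleep_edf_files(psg.parent)
    (psg.parent / "S001-PSG.edf").write_bytes(psg.read_bytes())
    with pytest.warns(UserWarning, match="no hypnogram"):
        pairs = pair_sleep_edf_files(psg.parent)
    assert len(pairs) == 2


def test_prepare_recording_full_path(edf_pair):
    rec, psg, hyp = edf_pair
    out = prepare_recording(psg, hyp, margin_epochs=60, zscore=True)
    assert len(out) == len(rec)
    x, _ = out.to_arrays()
    np.testing.assert_allclose(x.mean(axis=-1), 0.0, atol=1e-4)
    np.testing.assert_allclose(x.std(axis=-1), 1.0, atol=1e-3)
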