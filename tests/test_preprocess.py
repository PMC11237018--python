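"""Preprocessing contracts: notch, re-referencing, ocular regression,
baseline, amplitude rejection and the surface Laplacian."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_recording
from eightart.montage import EOG_CHANNELS, FULL_SCALP, MASTOID_CHANNELS, REDUCED_SCALP, scalp_positions
from eightart.preprocess import (
    ConfigurationError,
    InsufficientDataError,
    PreprocConfig,
    csd_of_map,
    csd_transform,
    epoch_and_clean,
    preprocess_continuous,
)

CHANNELS = tuple(REDUCED_SCALP) + MASTOID_CHANNELS + EOG_CHANNELS
N_CH = len(CHANNELS)
SFREQ = 500.0


def events_every(n_events, step_s=2.0, start_s=1.0):
    samples = (start_s + step_s * np.arange(n_events)) * SFREQ
    return pd.DataFrame(
        {"sample": samples.astype(int), "kind": "stimulus",
         "trial_index": np.arange(n_events)}
    )


def test_notch_removes_line_component():
    t = np.arange(int(20 * SFREQ)) / SFREQ
    line = 10.0 * np.sin(2 * np.pi * 50.0 * t)
    data = np.tile(line, (N_CH, 1))
    rec = make_recording(data, CHANNELS)
    out = preprocess_continuous(rec, PreprocConfig())
    scalp_idx = [CHANNELS.index(c) for c in REDUCED_SCALP]
    core = out.data[scalp_idx, 1000:-1000]  # ignore filter edges
    assert np.sqrt((core**2).mean()) < 0.01 * np.sqrt((line**2).mean())


def test_mastoid_rereference_arithmetic():
    data = np.zeros((N_CH, 1000))
    data[CHANNELS.index("Pz")] = 7.0
    data[CHANNELS.index("M1")] = 3.0
    data[CHANNELS.index("M2")] = 5.0
    rec = make_recording(data, CHANNELS)
    out = preprocess_continuous(rec, PreprocConfig(notch_hz=0.0))
    assert out.data[CHANNELS.index("Pz")] == pytest.approx(7.0 - 4.0)


def test_eog_regression_recovers_planted_propagation(rng):
    n = int(60 * SFREQ)
    eog = rng.standard_normal(n).cumsum()  # slow, blink-like drift
    eog -= eog.mean()
    signal = np.sin(2 * np.pi * 7.0 * np.arange(n) / SFREQ)
    data = np.zeros((N_CH, n))
    data[CHANNELS.index("VEOGU")] = eog
    i_fcz = CHANNELS.index("FCz")
    data[i_fcz] = 0.3 * eog + signal
    rec = make_recording(data, CHANNELS)
    out = preprocess_continuous(rec, PreprocConfig(notch_hz=0.0))
    corrected = out.data[i_fcz].astype(float)
    r = np.corrcoef(corrected, eog)[0, 1]
    assert abs(r) < 0.05
    assert np.corrcoef(corrected, signal)[0, 1] > 0.95


def test_missing_reference_channel_raises():
    rec = make_recording(np.zeros((len(REDUCED_SCALP), 100)), REDUCED_SCALP)
    with pytest.raises(ConfigurationError):
        preprocess_continuous(rec, PreprocConfig())


class TestEpoching:
    def test_constant_offset_zero_after_baseline(self):
        data = np.full((N_CH, 4000), 13.0)
        rec = make_recording(data, CHANNELS, events=events_every(3))
        eps = epoch_and_clean(rec, PreprocConfig(), "stimulus")
        assert np.allclose(eps.epochs, 0.0)

    def test_baseline_idempotent(self):
        rng = np.random.default_rng(3)
        rec = make_recording(rng.normal(0, 5, (N_CH, 6000)), CHANNELS,
                             events=events_every(4))
        eps = epoch_and_clean(rec, PreprocConfig(), "stimulus")
        b0 = np.flatnonzero(eps.times_ms >= -100.0)[0]
        b1 = np.flatnonzero(eps.times_ms >= 0.0)[0]
        again = eps.epochs - eps.epochs[:, :, b0:b1].mean(axis=2, keepdims=True)
        assert np.allclose(again, eps.epochs, atol=1e-10)

    def test_threshold_rule_and_reason(self):
        data = np.zeros((N_CH, 6000))
        ev = events_every(4)
        data[0, int(ev["sample"][1]) + 50] = 101.0  # one sample over threshold
        rec = make_recording(data, CHANNELS, events=ev)
        eps = epoch_and_clean(rec, PreprocConfig(), "stimulus")
        assert eps.n_epochs == 3
        assert list(eps.rejection_log.reason) == ["amplitude"]
        assert list(eps.rejection_log.trial_index) == [1]
        # at 99 µV the epoch survives
        data[0, int(ev["sample"][1]) + 50] = 99.0
        eps2 = epoch_and_clean(make_recording(data, CHANNELS, events=ev),
                               PreprocConfig(), "stimulus")
        assert eps2.n_epochs == 4

    def test_rejection_monotone_in_threshold(self, rng):
        data = rng.normal(0, 20, (N_CH, 40000))
        rec = make_recording(data, CHANNELS, events=events_every(30, step_s=2.5))
        kept = {}
        for thr in (80.0, 100.0, 120.0):
            eps = epoch_and_clean(rec, PreprocConfig(artifact_threshold_uV=thr),
                                  "stimulus")
            kept[thr] = set(eps.labels.trial_index)
        assert kept[80.0] <= kept[100.0] <= kept[120.0]

    def test_planted_artifact_fraction_recovered(self, rng):
        n_trials = 300
        step = 1.5
        ev = events_every(n_trials, step_s=step)
        n = int((n_trials + 2) * step * SFREQ)
        data = rng.normal(0, 5, (N_CH, n))
        bad = rng.choice(n_trials, size=15, replace=False)  # 5 %
        for b in bad:
            s = int(ev["sample"][b]) + 100
            data[2, s : s + 50] += 150.0
        rec = make_recording(data, CHANNELS, events=ev)
        eps = epoch_and_clean(rec, PreprocConfig(), "stimulus")
        frac = len(eps.rejection_log) / n_trials
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_empty_required_cell_raises_with_counts(self):
        data = np.zeros((N_CH, 6000))
        labels = pd.DataFrame({"trial_index": range(4), "response_type": "MI_SUCCESS"})
        rec = make_recording(data, CHANNELS, events=events_every(4))
        with pytest.raises(InsufficientDataError) as exc:
            epoch_and_clean(rec, PreprocConfig(), "stimulus", labels,
                            required_cells=["MI_ERROR"])
        assert exc.value.cell_counts.get("MI_SUCCESS") == 4


class TestCSD:
    def test_constant_map_gives_zero(self):
        out = csd_of_map(np.full(len(FULL_SCALP), 5.0), FULL_SCALP)
        assert np.abs(out).max() < 1e-6

    def test_reference_invariance(self, rng):
        m = rng.normal(0, 3, len(FULL_SCALP))
        a = csd_of_map(m, FULL_SCALP)
        b = csd_of_map(m + 10.0, FULL_SCALP)
        assert np.allclose(a, b, atol=1e-6 * max(np.abs(a).max(), 1.0))

    def test_linearity(self, rng):
        x = rng.normal(0, 2, len(FULL_SCALP))
        y = rng.normal(0, 2, len(FULL_SCALP))
        assert np.allclose(
            csd_of_map(x + y, FULL_SCALP),
            csd_of_map(x, FULL_SCALP) + csd_of_map(y, FULL_SCALP),
            atol=1e-8,
        )

    def test_focal_source_peaks_under_its_electrode(self):
        pos = scalp_positions(FULL_SCALP)
        center = pos["FCz"]
        m = np.array(
            [np.exp(-np.sum((pos[c] - center) ** 2) / (2 * 0.04**2))
             for c in FULL_SCALP]
        )
        out = csd_of_map(m, FULL_SCALP)
        assert FULL_SCALP[int(np.argmax(out))] == "FCz"
        assert out.min() < 0  # surrounding sign inversion

    def test_csd_epochset_units_and_shape(self, rng):
        from eightart.preprocess import EpochSet

        eps = EpochSet(
            lock="stimulus", ch_names=tuple(REDUCED_SCALP),
            epochs=rng.normal(0, 5, (3, len(REDUCED_SCALP), 50)),
            times_ms=np.arange(50) * 2.0, sfreq=SFREQ,
            labels=pd.DataFrame({"trial_index": range(3)}),
            rejection_log=pd.DataFrame(columns=["trial_index", "reason"]),
        )
        out = csd_transform(eps)
        assert out.unit == "uV/cm2"
        assert out.epochs.shape == eps.epochs.shape
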