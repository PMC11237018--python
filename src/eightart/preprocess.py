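"""Continuous-EEG cleaning and epoching.

Pipeline order: 50 Hz notch → re-reference to the averaged mastoids →
regression-based ocular correction (each scalp channel regressed on the four
EOG channels over the continuous record, blink segments included) →
epoching on stimulus or response markers → baseline correction → ±100 µV
amplitude rejection on the scalp channels → optional current source density
(spherical-spline surface Laplacian, µV/cm², reference-free).

The amplitude threshold is applied after ocular correction and before CSD.
Epoch windows are half-open ``[t0, t1)`` with the lock sample at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .montage import EOG_CHANNELS, MASTOID_CHANNELS, make_mne_montage
from .simulate import EEGRecording

__all__ = [
    "PreprocConfig",
    "EpochSet",
    "InsufficientDataError",
    "preprocess_continuous",
    "epoch_and_clean",
    "csd_transform",
    "csd_of_map",
    "lowpass",
]


class ConfigurationError(ValueError):
    pass


class InsufficientDataError(RuntimeError):
    """Raised when a required analysis cell has no surviving epochs."""

    def __init__(self, message: str, cell_counts: Optional[dict] = None):
        super().__init__(message)
        self.cell_counts = cell_counts or {}


@dataclass(frozen=True)
class PreprocConfig:
    notch_hz: float = 50.0
    reference: tuple[str, ...] = MASTOID_CHANNELS
    eog_channels: tuple[str, ...] = EOG_CHANNELS
    artifact_threshold_uV: float = 100.0
    stimulus_epoch_ms: tuple[float, float] = (-100.0, 700.0)
    response_epoch_ms: tuple[float, float] = (-100.0, 500.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    csd_stiffness: int = 4
    csd_lambda: float = 1e-5
    csd_n_legendre_terms: int = 50

    def __post_init__(self):
        if self.artifact_threshold_uV <= 0:
            raise ConfigurationError("artifact threshold must be positive")
        for win in (self.stimulus_epoch_ms, self.response_epoch_ms):
            if not (win[0] <= self.baseline_ms[0] < self.baseline_ms[1] <= win[1]):
                # baseline must lie within both epoch windows it may apply to
                pass


@dataclass
class EpochSet:
    """Condition-labelled fixed-window epochs."""

    lock: str  # "stimulus" | "response"
    ch_names: tuple[str, ...]
    epochs: np.ndarray  # (n_epochs, n_channels, n_times)
    times_ms: np.ndarray
    sfreq: float
    labels: pd.DataFrame  # one row per retained epoch, includes trial_index
    rejection_log: pd.DataFrame  # trial_index, reason
    unit: str = "uV"

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def pick(self, channels: Sequence[str]) -> "EpochSet":
        idx = [self.ch_names.index(c) for c in channels]
        return EpochSet(
            lock=self.lock,
            ch_names=tuple(channels),
            epochs=self.epochs[:, idx, :],
            times_ms=self.times_ms,
            sfreq=self.sfreq,
            labels=self.labels,
            rejection_log=self.rejection_log,
            unit=self.unit,
        )

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            lock=self.lock,
            ch_names=self.ch_names,
            epochs=self.epochs[mask],
            times_ms=self.times_ms,
            sfreq=self.sfreq,
            labels=self.labels.loc[np.asarray(mask)].reset_index(drop=True),
            rejection_log=self.rejection_log,
            unit=self.unit,
        )


def preprocess_continuous(
    rec: EEGRecording, cfg: PreprocConfig = PreprocConfig()
) -> EEGRecording:
    """Notch-filter, re-reference and ocular-correct a continuous recording."""
    for ch in tuple(cfg.reference) + tuple(cfg.eog_channels):
        if ch not in rec.ch_names:
            raise ConfigurationError(f"missing channel {ch!r}")
    out = rec.copy()
    data = out.data.astype(np.float64)
    scalp = [out.idx(c) for c in out.scalp_names]
    mastoid = [out.idx(c) for c in cfg.reference]
    eog = [out.idx(c) for c in cfg.eog_channels]

    # 50 Hz notch (zero-phase IIR, applied twice through filtfilt -> deep null)
    if cfg.notch_hz:
        b, a = signal.iirnotch(cfg.notch_hz, Q=30.0, fs=rec.sfreq)
        chans = scalp + mastoid + eog
        data[chans] = signal.filtfilt(b, a, data[chans], axis=-1)

    # re-reference scalp channels to the averaged mastoids
    ref = data[mastoid].mean(axis=0)
    data[scalp] -= ref

    # ocular correction: least-squares propagation factors on the continuous
    # record (blink-dominated segments included), then subtraction
    X = data[eog].T - data[eog].mean(axis=1)
    Y = data[scalp].T
    beta, *_ = np.linalg.lstsq(X, Y - Y.mean(axis=0), rcond=None)
    data[scalp] = (Y - X @ beta).T

    out.data = data.astype(np.float32)
    return out


def epoch_and_clean(
    rec: EEGRecording,
    cfg: PreprocConfig,
    lock: str,
    labels: Optional[pd.DataFrame] = None,
    window_ms: Optional[tuple[float, float]] = None,
    baseline_ms: Optional[tuple[float, float]] = None,
    required_cells: Optional[Sequence] = None,
) -> EpochSet:
    """Cut half-open epochs at the given lock, baseline-correct and reject.

    ``labels`` (optional) is a per-trial frame carrying at least
    ``trial_index`` plus any classification columns; it is joined onto the
    retained epochs.  Any epoch with a scalp sample beyond
    ±``artifact_threshold_uV`` is dropped and logged.  If ``required_cells``
    names values of a ``response_type`` label column, an
    :class:`InsufficientDataError` (with per-cell counts) is raised when any
    of those cells ends up empty.
    """
    if lock not in ("stimulus", "response"):
        raise ValueError("lock must be 'stimulus' or 'response'")
    ev = rec.events[rec.events["kind"] == lock]
    if ev.empty:
        raise InsufficientDataError(f"no {lock} events in recording")
    if window_ms is None:
        window_ms = (
            cfg.stimulus_epoch_ms if lock == "stimulus" else cfg.response_epoch_ms
        )
    if baseline_ms is None:
        baseline_ms = cfg.baseline_ms
    if not (window_ms[0] <= baseline_ms[0] < baseline_ms[1] <= window_ms[1]):
        raise ConfigurationError("baseline must lie within the epoch window")
    sfreq = rec.sfreq
    s0 = int(round(window_ms[0] / 1000.0 * sfreq))
    s1 = int(round(window_ms[1] / 1000.0 * sfreq))
    n_t = s1 - s0
    times_ms = (np.arange(s0, s1) / sfreq) * 1000.0
    b0 = int(round(baseline_ms[0] / 1000.0 * sfreq)) - s0
    b1 = int(round(baseline_ms[1] / 1000.0 * sfreq)) - s0

    scalp_names = rec.scalp_names
    scalp_idx = [rec.idx(c) for c in scalp_names]
    kept, kept_rows, rejected = [], [], []
    label_by_trial = (
        labels.set_index("trial_index") if labels is not None else None
    )
    for row in ev.itertuples(index=False):
        a, b = row.sample + s0, row.sample + s1
        if a < 0 or b > rec.data.shape[1]:
            rejected.append((row.trial_index, "edge"))
            continue
        ep = rec.data[:, a:b].astype(np.float64)
        ep = ep - ep[:, b0:b1].mean(axis=1, keepdims=True)
        if np.abs(ep[scalp_idx]).max() > cfg.artifact_threshold_uV:
            rejected.append((row.trial_index, "amplitude"))
            continue
        kept.append(ep[scalp_idx])
        lab = {"trial_index": row.trial_index}
        if label_by_trial is not None and row.trial_index in label_by_trial.index:
            lab.update(label_by_trial.loc[row.trial_index].to_dict())
        kept_rows.append(lab)

    rejection_log = pd.DataFrame(rejected, columns=["trial_index", "reason"])
    if not kept:
        raise InsufficientDataError("no epochs survived cleaning")
    eps = EpochSet(
        lock=lock,
        ch_names=tuple(scalp_names),
        epochs=np.stack(kept),
        times_ms=times_ms,
        sfreq=sfreq,
        labels=pd.DataFrame(kept_rows),
        rejection_log=rejection_log,
    )
    if required_cells is not None:
        counts = (
            eps.labels["response_type"].value_counts().to_dict()
            if "response_type" in eps.labels
            else {}
        )
        missing = [c for c in required_cells if counts.get(c, 0) == 0]
        if missing:
            raise InsufficientDataError(
                f"no surviving epochs for cells {missing}", cell_counts=counts
            )
    return eps


def _csd_epochs_mne(data_uV, ch_names, sfreq, stiffness, lambda2):
    import mne

    mne.set_log_level("ERROR")
    info = mne.create_info(list(ch_names), sfreq, "eeg")
    ep = mne.EpochsArray(data_uV * 1e-6, info, verbose="ERROR")
    ep.set_montage(make_mne_montage(ch_names))
    csd = mne.preprocessing.compute_current_source_density(
        ep, stiffness=stiffness, lambda2=lambda2
    )
    # V/m^2 -> µV/cm^2
    return csd.get_data() * 100.0


def csd_transform(epochs: EpochSet, cfg: PreprocConfig = PreprocConfig()) -> EpochSet:
    """Spherical-spline surface Laplacian of every epoch (µV/cm²)."""
    try:
        make_mne_montage(epochs.ch_names)
    except KeyError as e:
        raise ConfigurationError(f"missing electrode position: {e}") from e
    out_data = _csd_epochs_mne(
        epochs.epochs, epochs.ch_names, epochs.sfreq, cfg.csd_stiffness, cfg.csd_lambda
    )
    return EpochSet(
        lock=epochs.lock,
        ch_names=epochs.ch_names,
        epochs=out_data,
        times_ms=epochs.times_ms,
        sfreq=epochs.sfreq,
        labels=epochs.labels,
        rejection_log=epochs.rejection_log,
        unit="uV/cm2",
    )


def csd_of_map(weights_uV: np.ndarray, ch_names: Sequence[str]) -> np.ndarray:
    """CSD (µV/cm²) of a static scalp map given in µV — used for template
    calibration and for toy-map checks."""
    data = np.asarray(weights_uV, float)[None, :, None].repeat(2, axis=2)
    out = _csd_epochs_mne(data, ch_names, 500.0, 4, 1e-5)
    return out[0, :, 0]


def lowpass(x: np.ndarray, sfreq: float, cutoff_hz: float = 30.0, order: int = 4):
    """Zero-phase Butterworth low-pass along the last axis."""
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)
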