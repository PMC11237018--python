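"""Lateralised readiness potential: derivation and jackknife onset estimation.

The LRP is the average of the two hand-wise differences
``C4'(t) − C3'(t)`` (left hand) and ``C3'(t) − C4'(t)`` (right hand); for
error trials the hand that actually executed the response defines the
laterality.  Motor activation is negative-going by this construction.

Onsets are estimated with a 50 % fractional-peak criterion — the first time
point at which the LRP magnitude exceeds half the peak amplitude for at
least five consecutive samples — on leave-one-participant-out grand
averages, and individual onsets are retrieved with the Smulders
transformation ``o_i = n·J̄ − (n−1)·J_i``.  A 30 Hz low-pass is applied to
the LRP waveform at the end of the processing pipeline, before onset
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import EpochSet, InsufficientDataError, lowpass

__all__ = [
    "LrpConfig",
    "LrpWaveform",
    "JackknifeOnsetSet",
    "derive_lrp",
    "onset_fractional",
    "smulders_retrieve",
    "jackknife_onsets",
]


@dataclass(frozen=True)
class LrpConfig:
    electrodes: tuple[str, str] = ("C3'", "C4'")
    lowpass_hz: float = 30.0
    criterion_fraction: float = 0.5
    persistence_samples: int = 5
    min_trials_per_hand: int = 6
    stimulus_window_ms: tuple[float, float] = (-100.0, 800.0)
    response_window_ms: tuple[float, float] = (-500.0, 200.0)

    def __post_init__(self):
        if not 0.0 < self.criterion_fraction < 1.0:
            raise ValueError("criterion fraction must lie in (0, 1)")
        if self.persistence_samples < 1:
            raise ValueError("persistence must be >= 1")


@dataclass
class LrpWaveform:
    cell: str
    lock: str
    times_ms: np.ndarray
    amplitude_uV: np.ndarray
    n_trials_left: int
    n_trials_right: int
    sfreq: float


@dataclass
class JackknifeOnsetSet:
    cell: str
    lock: str
    participants: list
    subsample_onsets_ms: list[Optional[float]]
    retrieved_onsets_ms: list[Optional[float]]
    grand_onset_ms: Optional[float]

    @property
    def complete(self) -> bool:
        return all(o is not None for o in self.subsample_onsets_ms)


def derive_lrp(
    epochs: EpochSet,
    cell: str,
    cfg: LrpConfig = LrpConfig(),
    apply_lowpass: bool = True,
) -> LrpWaveform:
    """Hand-balanced contralateral-minus-ipsilateral average for one cell.

    ``epochs.labels`` must carry ``response_type`` and ``hand``
    ("left"/"right", the executed hand).  Participants whose hand counts fall
    below ``min_trials_per_hand`` raise :class:`InsufficientDataError` and
    are excluded from LRP analyses by the caller.
    """
    i3 = epochs.ch_names.index(cfg.electrodes[0])
    i4 = epochs.ch_names.index(cfg.electrodes[1])
    lab = epochs.labels
    sel = (lab["response_type"] == cell).to_numpy()
    hands = lab["hand"].to_numpy()
    left = sel & (hands == "left")
    right = sel & (hands == "right")
    n_l, n_r = int(left.sum()), int(right.sum())
    if n_l < cfg.min_trials_per_hand or n_r < cfg.min_trials_per_hand:
        raise InsufficientDataError(
            f"cell {cell!r}: {n_l} left / {n_r} right trials "
            f"(minimum {cfg.min_trials_per_hand} per hand)",
            cell_counts={"left": n_l, "right": n_r},
        )
    # left hand: C4' − C3'; right hand: C3' − C4'
    lrp_left = (epochs.epochs[left, i4, :] - epochs.epochs[left, i3, :]).mean(axis=0)
    lrp_right = (epochs.epochs[right, i3, :] - epochs.epochs[right, i4, :]).mean(axis=0)
    wave = 0.5 * (lrp_left + lrp_right)
    if apply_lowpass and cfg.lowpass_hz:
        wave = lowpass(wave, epochs.sfreq, cfg.lowpass_hz)
    return LrpWaveform(
        cell=cell,
        lock=epochs.lock,
        times_ms=epochs.times_ms,
        amplitude_uV=wave,
        n_trials_left=n_l,
        n_trials_right=n_r,
        sfreq=epochs.sfreq,
    )


def onset_fractional(
    lrp: LrpWaveform | np.ndarray,
    cfg: LrpConfig = LrpConfig(),
    times_ms: Optional[np.ndarray] = None,
) -> Optional[float]:
    """First sustained crossing of the fractional-peak criterion, in ms.

    The peak is the largest negative-going excursion in the analysis window
    (motor activation is negative by construction; positive excursions are
    ignored).  The onset is the first sample whose magnitude reaches
    ``criterion_fraction`` × |peak| and stays there for
    ``persistence_samples`` consecutive samples.  Returns ``None`` when the
    criterion is never met (e.g. a flat waveform, or the unstable
    motor-inhibition error pattern without a single sustained deflection).
    """
    if isinstance(lrp, LrpWaveform):
        wave, times = lrp.amplitude_uV, lrp.times_ms
    else:
        wave, times = np.asarray(lrp, float), np.asarray(times_ms, float)
    peak = wave.min()
    if not np.isfinite(peak) or peak >= 0.0:
        return None
    level = cfg.criterion_fraction * (-peak)
    exceed = (-wave) >= level
    run = 0
    for i, e in enumerate(exceed):
        run = run + 1 if e else 0
        if run >= cfg.persistence_samples:
            return float(times[i - cfg.persistence_samples + 1])
    return None


def smulders_retrieve(subsample_onsets: Sequence[float]) -> list[float]:
    """Individual onsets from leave-one-out onsets: ``o_i = n·J̄ − (n−1)·J_i``.

    The transformation inverts the smoothing of the jackknife so the
    retrieved values can enter ordinary repeated-measures statistics; their
    mean equals the mean of the subsample onsets exactly.
    """
    j = np.asarray(subsample_onsets, float)
    n = len(j)
    return list(n * j.mean() - (n - 1) * j)


def jackknife_onsets(
    waveforms: Sequence[LrpWaveform],
    cfg: LrpConfig = LrpConfig(),
    participants: Optional[Sequence] = None,
) -> JackknifeOnsetSet:
    """Leave-one-out onsets plus Smulders-retrieved individual onsets.

    For each participant i the onset J_i of the grand average excluding i is
    estimated; the retrieved individual onset is ``o_i = n·J̄ − (n−1)·J_i``,
    so that ``mean(o) = mean(J)`` exactly.  If any subsample onset is absent
    the retrieval is undefined and the cell is flagged (all retrieved values
    ``None``).
    """
    n = len(waveforms)
    if n < 3:
        raise ValueError("jackknife needs at least 3 participants")
    if participants is None:
        participants = list(range(n))
    stack = np.stack([w.amplitude_uV for w in waveforms])
    times = waveforms[0].times_ms
    total = stack.sum(axis=0)
    sub_onsets: list[Optional[float]] = []
    for i in range(n):
        loo = (total - stack[i]) / (n - 1)
        sub_onsets.append(onset_fractional(loo, cfg, times))
    grand = onset_fractional(total / n, cfg, times)
    if any(o is None for o in sub_onsets):
        retrieved: list[Optional[float]] = [None] * n
    else:
        retrieved = smulders_retrieve(sub_onsets)
    return JackknifeOnsetSet(
        cell=waveforms[0].cell,
        lock=waveforms[0].lock,
        participants=list(participants),
        subsample_onsets_ms=sub_onsets,
        retrieved_onsets_ms=retrieved,
        grand_onset_ms=grand,
    )
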