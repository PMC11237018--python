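"""Synthetic behaviour and EEG with the statistical structure the analysis assumes.

The generator produces, per simulated participant, (a) per-trial 8-key force
traces and response times with the condition × accuracy cell structure of the
task's behavioural measures, and (b) continuous multichannel EEG containing
condition-specific ERP components, a hand-lateralised motor potential at the
primed channels C3'/C4', 1/f background noise, 50 Hz line noise and eye
blinks mirrored into the EOG channels.

Defaults encode the group-level cell means of the behavioural and
electrophysiological measures, so that running the full analysis pipeline on
default synthetic data recovers the generating values ("parameter
recovery").  Three conventions matter:

* RT distributions are lognormal, calibrated on the *median*, because the
  pipeline summarises RT as the participant median.
* Multiple-response / correction probabilities are per-trial probabilities
  within a cell, derived from cell percentages that are expressed relative to
  all included trials of the condition (see :mod:`eightart.behaviour`).
* The response-locked motor ramp is parameterised by the time at which it
  reaches half its peak amplitude, which is exactly what the 50 % fractional
  onset criterion measures; with zero noise the quantification therefore
  returns the generating onset.

All participants share the same generating parameters: the generator models
within-participant trial noise, not between-participant heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .montage import (
    EOG_CHANNELS,
    MASTOID_CHANNELS,
    REDUCED_SCALP,
    scalp_positions,
)
from .task import TrialSpec, ShapeSet

__all__ = [
    "CellParams",
    "ConditionParams",
    "BehaviourParams",
    "SimulatedBehaviour",
    "ErpTemplate",
    "LrpGenParams",
    "EegParams",
    "EEGRecording",
    "simulate_behaviour",
    "simulate_eeg",
    "default_behaviour_params",
    "default_erp_templates",
    "default_eeg_params",
    "default_params",
    "CELLS",
]

CELLS = (("MI", "success"), ("MI", "error"), ("IS", "success"), ("IS", "error"))

Cell = tuple[str, str]


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellParams:
    """Trial-level generating parameters of one condition × accuracy cell."""

    rt_median_ms: float
    rt_sigma: float  # sd of log-RT
    force_mean_cN: float
    force_sd_cN: float
    multiple_rate: float  # P(second key crosses threshold | trial in cell)
    correction_rate: float = 0.0  # P(second key is the correct key), error cells


@dataclass(frozen=True)
class ConditionParams:
    """Condition-level rates and sequential RT shifts."""

    error_rate: float  # P(cell error | trial included)
    other_error_rate: float  # P(response neither correct nor location/distractor)
    too_slow_rate: float
    no_response_rate: float
    pes_shift_ms: float  # added to the RT of the trial after a cell error
    pre_error_drift_ms: float  # added to the RT of the trial before a cell error


@dataclass(frozen=True)
class BehaviourParams:
    cells: dict[Cell, CellParams]
    congruent: CellParams  # MI congruent trials (analysed only sequentially)
    conditions: dict[str, ConditionParams]
    rt_limit_ms: float = 1000.0
    force_threshold_cN: float = 40.0

    def __post_init__(self):
        for cond in self.conditions.values():
            for p in (
                cond.error_rate,
                cond.other_error_rate,
                cond.too_slow_rate,
                cond.no_response_rate,
            ):
                if not 0.0 <= p <= 1.0:
                    raise ValueError("probabilities must lie in [0, 1]")
        for c in list(self.cells.values()) + [self.congruent]:
            if c.rt_sigma <= 0 or c.force_sd_cN <= 0:
                raise ValueError("spreads must be positive")


def default_behaviour_params() -> BehaviourParams:
    """Defaults whose group-level cell summaries equal the reference values.

    Cell response rates (MI 73.3/26.7, IS 81.9/18.1 % of included trials),
    median RTs, mean peak forces, multiple-response and correction
    percentages, PES and pre-error speeding are encoded directly.  Cell
    multiple/correction percentages are stated relative to included condition
    trials, so the per-trial probability within a cell is the cell percentage
    divided by the cell's response rate.  Exclusion rates are chosen so that
    overall accuracy matches the post-response accuracy level of each
    condition (~94 % for MI where most trials are congruent, ~59 % for IS
    where non-distractor errors are common).
    """
    sigma = 0.2
    cells = {
        ("MI", "success"): CellParams(754.6, sigma, 164.9, 25.0, 0.028 / 0.733),
        ("MI", "error"): CellParams(
            538.7, sigma, 111.9, 25.0, 0.032 / 0.267, 0.013 / 0.267
        ),
        ("IS", "success"): CellParams(765.8, sigma, 189.8, 25.0, 0.039 / 0.819),
        ("IS", "error"): CellParams(
            788.3, sigma, 159.2, 25.0, 0.050 / 0.181, 0.032 / 0.181
        ),
    }
    congruent = CellParams(680.0, sigma, 170.0, 25.0, 0.03)
    conditions = {
        "MI": ConditionParams(
            error_rate=0.267,
            other_error_rate=0.02,
            too_slow_rate=0.025,
            no_response_rate=0.002,
            pes_shift_ms=11.5,
            pre_error_drift_ms=-18.0,
        ),
        "IS": ConditionParams(
            error_rate=0.181,
            other_error_rate=0.284,
            too_slow_rate=0.04,
            no_response_rate=0.002,
            pes_shift_ms=29.4,
            pre_error_drift_ms=-7.3,
        ),
    }
    return BehaviourParams(cells=cells, congruent=congruent, conditions=conditions)


# rates on congruent MI trials (an error there is not a cell error); the
# other-error rate is pinned by the post-response accuracy level of the MI
# condition (the trial after an included MI trial is always congruent)
_CONGRUENT_OTHER_ERROR = 0.061
_CONGRUENT_TOO_SLOW = 0.025
_CONGRUENT_NO_RESPONSE = 0.002


def _calibrated_log_median(
    median_ms: float, sigma: float, limit_ms: float
) -> tuple[float, float]:
    """Log-median µ and admissible CDF mass F(limit) of a lognormal RT cell.

    Cell RTs are drawn conditionally on the response deadline, so µ is solved
    such that the *conditional* (post-deadline) median equals the stated cell
    median — the printed medians are themselves deadline-limited quantities.
    """
    from scipy.special import ndtr, ndtri

    log_m, log_l = math.log(median_ms), math.log(limit_ms)
    mu = log_m
    for _ in range(40):
        f_l = ndtr((log_l - mu) / sigma)
        mu = log_m - sigma * ndtri(f_l / 2.0)
    return mu, float(ndtr((log_l - mu) / sigma))


@dataclass
class SimulatedBehaviour:
    """Per-trial ground truth plus the raw force traces."""

    trials: list[TrialSpec]
    table: pd.DataFrame  # trial_index, condition, block, planted_type, rt_ms,
    #                      key, second_key, stim_onset_ms, response_onset_ms,
    #                      is_multiple, is_correction
    forces: np.ndarray  # (n_trials, 8, n_samples) cN, aligned to stimulus onset
    sfreq: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)


_GAMMA_SHAPE = 3.0
_RISE_MS = 150.0  # onset-to-peak time of a force pulse


def _pulse_shape(sfreq: float, n: int) -> np.ndarray:
    """Gamma-density force pulse, unit peak at _RISE_MS."""
    t = np.arange(n) / sfreq * 1000.0
    tau = _RISE_MS / (_GAMMA_SHAPE - 1.0)
    s = (t / _RISE_MS) ** (_GAMMA_SHAPE - 1.0) * np.exp(
        (_GAMMA_SHAPE - 1.0) * (1.0 - t / _RISE_MS)
    )
    s[t <= 0] = 0.0
    return s


def _rise_inverse() -> tuple[np.ndarray, np.ndarray]:
    """Dense (fraction, time_ms) table of the rising limb, for crossings."""
    t = np.linspace(1e-3, _RISE_MS, 2000)
    s = (t / _RISE_MS) ** (_GAMMA_SHAPE - 1.0) * np.exp(
        (_GAMMA_SHAPE - 1.0) * (1.0 - t / _RISE_MS)
    )
    return s, t


_RISE_S, _RISE_T = _rise_inverse()


def _crossing_offset_ms(fraction: np.ndarray) -> np.ndarray:
    """Time from pulse onset to the point where it reaches ``fraction`` of peak."""
    return np.interp(fraction, _RISE_S, _RISE_T)


def simulate_behaviour(
    trials: Sequence[TrialSpec],
    params: BehaviourParams,
    seed: int,
    shapes: Optional[ShapeSet] = None,
    force_sfreq: float = 500.0,
    block_break_ms: float = 4000.0,
) -> SimulatedBehaviour:
    """Simulate choices, RTs and force traces for a trial sequence.

    Each responded trial receives a gamma-shaped force pulse on the pressed
    key that crosses the 40 cN threshold exactly at the drawn RT and peaks at
    the cell's force level; multiple responses and corrections add a second
    supra-threshold pulse.  Sequential structure: the trial after a cell
    error gets ``pes_shift_ms`` added to its RT, the trial before a cell
    error gets ``pre_error_drift_ms`` (block boundaries break adjacency).
    """
    if not trials:
        raise ValueError("empty trial list")
    shapes = shapes or ShapeSet()
    rng = np.random.default_rng(seed)
    n = len(trials)
    threshold = params.force_threshold_cN

    # --- 1. planted response category per trial -------------------------
    planted: list[str] = []
    for t in trials:
        cond = params.conditions[t.condition]
        if t.condition == "MI" and t.congruent:
            u = rng.random()
            if u < _CONGRUENT_NO_RESPONSE:
                planted.append("EXCL_NO_RESPONSE")
            elif u < _CONGRUENT_NO_RESPONSE + _CONGRUENT_TOO_SLOW:
                planted.append("EXCL_TOO_SLOW")
            elif u < (
                _CONGRUENT_NO_RESPONSE + _CONGRUENT_TOO_SLOW + _CONGRUENT_OTHER_ERROR
            ):
                planted.append("EXCL_MI_OTHER_ERROR")
            else:
                planted.append("EXCL_MI_CONGRUENT")
            continue
        u = rng.random()
        if u < cond.no_response_rate:
            planted.append("EXCL_NO_RESPONSE")
        elif u < cond.no_response_rate + cond.too_slow_rate:
            planted.append("EXCL_TOO_SLOW")
        elif u < cond.no_response_rate + cond.too_slow_rate + cond.other_error_rate:
            planted.append(f"EXCL_{t.condition}_OTHER_ERROR")
        elif rng.random() < cond.error_rate:
            planted.append(f"{t.condition}_ERROR")
        else:
            planted.append(f"{t.condition}_SUCCESS")

    # --- 2. base RTs ----------------------------------------------------
    from scipy.special import ndtri

    mu_cache: dict[tuple[float, float], tuple[float, float]] = {}

    def draw_rt(cell: CellParams) -> float:
        key = (cell.rt_median_ms, cell.rt_sigma)
        if key not in mu_cache:
            mu_cache[key] = _calibrated_log_median(
                cell.rt_median_ms, cell.rt_sigma, params.rt_limit_ms
            )
        mu, f_l = mu_cache[key]
        u = rng.random() * f_l  # conditional on beating the deadline
        return math.exp(mu + cell.rt_sigma * ndtri(u))

    rts = np.full(n, np.nan)
    for i, (t, p) in enumerate(zip(trials, planted)):
        if p == "EXCL_NO_RESPONSE":
            continue
        if p == "EXCL_TOO_SLOW":
            rts[i] = params.rt_limit_ms + rng.uniform(60.0, 360.0)
            continue
        if p == "EXCL_MI_CONGRUENT" or p == "EXCL_MI_OTHER_ERROR" and t.congruent:
            cell = params.congruent
        elif p.endswith("OTHER_ERROR"):
            cell = params.cells[(t.condition, "success")]
        elif p.endswith("ERROR"):
            cell = params.cells[(t.condition, "error")]
        else:
            cell = params.cells[(t.condition, "success")]
        rts[i] = draw_rt(cell)

    # --- 3. sequential shifts -------------------------------------------
    for i in range(n):
        same_block = (
            lambda j: trials[j].condition == trials[i].condition
            and trials[j].block == trials[i].block
        )
        cond = params.conditions[trials[i].condition]
        if i > 0 and same_block(i - 1) and planted[i - 1].endswith("_ERROR") and not planted[i - 1].startswith("EXCL"):
            if np.isfinite(rts[i]):
                rts[i] += cond.pes_shift_ms
        if (
            i + 1 < n
            and same_block(i + 1)
            and planted[i + 1].endswith("_ERROR")
            and not planted[i + 1].startswith("EXCL")
        ):
            if np.isfinite(rts[i]):
                rts[i] += cond.pre_error_drift_ms
    rts = np.clip(rts, 150.0, None)

    # --- 4. response keys, multiples, corrections ------------------------
    keys = np.full(n, -1)
    second_keys = np.full(n, -1)
    second_dt = np.full(n, np.nan)
    is_multiple = np.zeros(n, bool)
    is_correction = np.zeros(n, bool)
    for i, (t, p) in enumerate(zip(trials, planted)):
        if p == "EXCL_NO_RESPONSE":
            continue
        correct = shapes.home_location[t.target_shape]
        if p in ("MI_ERROR", "IS_ERROR"):
            keys[i] = t.location
        elif p.endswith("OTHER_ERROR"):
            banned = {correct, t.location}
            choices = [k for k in range(8) if k not in banned]
            keys[i] = int(choices[rng.integers(len(choices))])
        else:  # success / congruent correct / too slow
            keys[i] = correct
        # second key
        if p in ("MI_ERROR", "IS_ERROR"):
            cellp = params.cells[(t.condition, "error")]
            u = rng.random()
            if u < cellp.correction_rate:
                is_multiple[i] = is_correction[i] = True
                second_keys[i] = correct
            elif u < cellp.multiple_rate:
                is_multiple[i] = True
                choices = [k for k in range(8) if k not in (keys[i], correct)]
                second_keys[i] = int(choices[rng.integers(len(choices))])
        else:
            if t.condition == "MI" and t.congruent:
                mrate = params.congruent.multiple_rate
            else:
                mrate = params.cells[(t.condition, "success")].multiple_rate
            if rng.random() < mrate:
                is_multiple[i] = True
                choices = [k for k in range(8) if k != keys[i]]
                second_keys[i] = int(choices[rng.integers(len(choices))])
        if is_multiple[i]:
            second_dt[i] = float(np.clip(rng.normal(180.0, 40.0), 80.0, 300.0))

    # --- 5. force traces -------------------------------------------------
    n_samples = int(round((params.rt_limit_ms + 600.0) / 1000.0 * force_sfreq))
    forces = np.zeros((n, 8, n_samples), np.float32)
    shape_len = int(round((_RISE_MS + 900.0) / 1000.0 * force_sfreq))
    base_shape = _pulse_shape(force_sfreq, shape_len)

    def add_pulse(i: int, key: int, cross_ms: float, peak: float) -> None:
        frac = min(threshold / peak, 0.999)
        onset_ms = cross_ms - _crossing_offset_ms(np.array([frac]))[0]
        start = int(round(onset_ms / 1000.0 * force_sfreq))
        # resample the shape so that the threshold crossing lands on cross_ms
        t_rel = (np.arange(n_samples) - start) / force_sfreq * 1000.0
        seg = np.interp(
            t_rel, np.arange(shape_len) / force_sfreq * 1000.0, base_shape,
            left=0.0, right=0.0,
        )
        forces[i, key] += (peak * seg).astype(np.float32)

    for i, (t, p) in enumerate(zip(trials, planted)):
        if keys[i] < 0:
            continue
        if p == "EXCL_MI_CONGRUENT" or (t.condition == "MI" and t.congruent):
            cellp = params.congruent
        elif p.endswith("_ERROR") and not p.startswith("EXCL"):
            cellp = params.cells[(t.condition, "error")]
        else:
            cellp = params.cells[(t.condition, "success")]
        peak = float(
            np.clip(rng.normal(cellp.force_mean_cN, cellp.force_sd_cN), 45.0, None)
        )
        add_pulse(i, keys[i], rts[i], peak)
        if is_multiple[i]:
            add_pulse(i, second_keys[i], rts[i] + second_dt[i], rng.uniform(55.0, 95.0))
    forces += rng.normal(0.0, 0.3, forces.shape).astype(np.float32)

    # --- 6. session timeline ---------------------------------------------
    stim_onsets = np.zeros(n)
    t_cursor = 1000.0
    for i, t in enumerate(trials):
        if i > 0 and (
            trials[i - 1].block != t.block
            or trials[i - 1].condition != t.condition
        ):
            t_cursor += block_break_ms
        stim_onsets[i] = t_cursor
        trial_dur = rts[i] if np.isfinite(rts[i]) else params.rt_limit_ms
        t_cursor += trial_dur + t.iti_ms

    table = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in trials],
            "condition": [t.condition for t in trials],
            "block": [t.block for t in trials],
            "planted_type": planted,
            "rt_ms": rts,
            "key": keys,
            "second_key": second_keys,
            "stim_onset_ms": stim_onsets,
            "response_onset_ms": np.where(np.isfinite(rts), stim_onsets + rts, np.nan),
            "is_multiple": is_multiple,
            "is_correction": is_correction,
        }
    )
    return SimulatedBehaviour(
        trials=list(trials), table=table, forces=forces, sfreq=force_sfreq
    )


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

@dataclass
class ErpTemplate:
    """One ERP component's generating template.

    ``amplitude`` holds the target cell values in ``unit``; for CSD-quantified
    components (µV/cm²) ``source_scale_uV`` converts one target unit into the
    µV amplitude of the scalp source map (calibrated empirically through the
    pipeline's own spline Laplacian, since no analytic mapping exists for an
    arbitrary montage).  The temporal kernel is a half-period cosine bump of
    ``width_ms`` peaking at ``latency_ms``.
    """

    name: str
    lock: str  # "stimulus" | "response"
    electrodes: tuple[str, ...]
    amplitude: dict[Cell, float]
    latency_ms: dict[Cell, float]
    unit: str = "uV"  # "uV" | "uV/cm2"
    width_ms: float = 150.0
    latency_jitter_sd_ms: float = 10.0
    spatial_sigma_m: float = 0.04
    source_scale_uV: float = 1.0

    def spatial_weights(self, ch_names: Sequence[str]) -> np.ndarray:
        """Gaussian scalp map centred on the component's electrodes.

        Normalised so the mean weight over the measurement electrodes is 1.
        The primed motor channels carry no ERP-template activity.
        """
        pos = scalp_positions([c for c in ch_names if c not in ("C3'", "C4'")])
        centers = [pos[e] for e in self.electrodes]
        w = np.zeros(len(ch_names))
        for i, ch in enumerate(ch_names):
            if ch not in pos:
                continue
            d2 = min(float(np.sum((pos[ch] - c) ** 2)) for c in centers)
            w[i] = math.exp(-d2 / (2.0 * self.spatial_sigma_m**2))
        ref = np.mean([w[list(ch_names).index(e)] for e in self.electrodes])
        return w / ref


@dataclass
class LrpGenParams:
    """Generating parameters of the lateralised motor potential.

    ``onset_ms`` is the response-locked time at which the contralateral ramp
    reaches half its peak (negative) amplitude — the quantity the 50 %
    fractional criterion estimates.  In the instability scenario,
    motor-inhibition error trials receive several brief low-amplitude
    impulses near the response instead of a single sustained ramp.
    """

    amplitude_uV: float = 4.0
    rise_ms: float = 150.0
    onset_ms: dict[Cell, float] = field(
        default_factory=lambda: {
            ("MI", "success"): -140.2,
            ("MI", "error"): -223.8,
            ("IS", "success"): -114.3,
            ("IS", "error"): -139.3,
        }
    )
    jitter_sd_ms: float = 10.0
    hold_after_response_ms: float = 50.0
    decay_ms: float = 200.0
    mi_error_instability: bool = False
    instability_n_impulses: int = 3
    instability_window_ms: tuple[float, float] = (-180.0, 40.0)
    instability_width_ms: float = 120.0
    instability_amp_uV: tuple[float, float] = (0.8, 1.6)


@dataclass
class EegParams:
    sfreq: float = 500.0
    scalp: tuple[str, ...] = REDUCED_SCALP
    noise_rms_uV: float = 4.0
    noise_exponent: float = 1.0
    eog_noise_rms_uV: float = 3.0
    line_freq_hz: float = 50.0
    line_amp_uV: float = 3.0
    blink_rate_per_min: float = 8.0
    blink_amp_uV: float = 120.0
    blink_duration_ms: float = 400.0
    lrp: LrpGenParams = field(default_factory=LrpGenParams)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.scalp) + MASTOID_CHANNELS + EOG_CHANNELS

    def __post_init__(self):
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG (µV) with an event stream."""

    ch_names: tuple[str, ...]
    data: np.ndarray  # (n_channels, n_samples), µV
    sfreq: float
    events: pd.DataFrame  # columns: sample, kind ("stimulus"|"response"), trial_index
    ch_types: dict[str, str] = field(default_factory=dict)  # name -> eeg|eog|misc

    def __post_init__(self):
        ev = self.events
        if len(ev) and (
            not ev["sample"].is_monotonic_increasing
            or ev["sample"].max() >= self.data.shape[1]
            or ev["sample"].min() < 0
        ):
            raise ValueError("events must be sorted and within the recording")
        if not self.ch_types:
            self.ch_types = {
                ch: (
                    "eog"
                    if ch in EOG_CHANNELS
                    else "misc" if ch in MASTOID_CHANNELS else "eeg"
                )
                for ch in self.ch_names
            }

    def idx(self, name: str) -> int:
        return self.ch_names.index(name)

    @property
    def scalp_names(self) -> list[str]:
        return [c for c in self.ch_names if self.ch_types[c] == "eeg"]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            ch_names=self.ch_names,
            data=self.data.copy(),
            sfreq=self.sfreq,
            events=self.events.copy(),
            ch_types=dict(self.ch_types),
        )


_BLINK_EOG = {"VEOGU": 1.0, "VEOGD": -0.4, "HEOGL": 0.08, "HEOGR": 0.08}


def _blink_scalp_weights(ch_names: Sequence[str]) -> np.ndarray:
    """Frontal-gradient blink propagation map (fraction of the VEOGU blink)."""
    pos = scalp_positions(ch_names)
    y = np.array([pos[c][1] for c in ch_names])
    y_front = max(y.max(), 1e-3)
    return 0.45 * np.clip(y, 0.0, None) / y_front


def _one_over_f_noise(
    rng: np.random.Generator, n: int, sfreq: float, exponent: float, rms: float
) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x * (rms / max(x.std(), 1e-12))


def _half_cosine(width_samples: int) -> np.ndarray:
    # half-period cosine bump: 0 -> 1 -> 0 over the width, peak at the centre
    return np.sin(np.linspace(0.0, np.pi, width_samples, endpoint=False))


_CELL_FALLBACK = {
    "MI_SUCCESS": ("MI", "success"),
    "MI_ERROR": ("MI", "error"),
    "IS_SUCCESS": ("IS", "success"),
    "IS_ERROR": ("IS", "error"),
    "EXCL_MI_CONGRUENT": ("MI", "success"),
    "EXCL_MI_OTHER_ERROR": ("MI", "success"),
    "EXCL_IS_OTHER_ERROR": ("IS", "success"),
}


def _cell_of(planted: str, condition: str) -> Cell:
    return _CELL_FALLBACK.get(planted, (condition, "success"))


def simulate_eeg(
    trials: Sequence[TrialSpec],
    behaviour: SimulatedBehaviour,
    templates: Sequence[ErpTemplate],
    eeg: EegParams,
    seed: int,
) -> EEGRecording:
    """Render continuous EEG for one participant's session.

    Component templates are placed at stimulus or response onsets with the
    amplitude of each trial's condition × accuracy cell; the lateralised
    motor ramp is added at C3'/C4' with the sign determined by the responding
    hand (keys 0–3 left, 4–7 right; the contralateral channel goes negative).
    """
    if len(trials) != behaviour.n_trials:
        raise ValueError("trials/behaviour length mismatch")
    rng = np.random.default_rng(seed)
    sfreq = eeg.sfreq
    tab = behaviour.table
    ch_names = eeg.channels
    n_ch = len(ch_names)
    t_end = float(np.nanmax(tab["stim_onset_ms"])) + 2500.0
    n = int(round(t_end / 1000.0 * sfreq))
    data = np.zeros((n_ch, n), np.float64)

    scalp_idx = [i for i, c in enumerate(ch_names) if c in eeg.scalp]
    mastoid_idx = [i for i, c in enumerate(ch_names) if c in MASTOID_CHANNELS]
    eog_idx = [i for i, c in enumerate(ch_names) if c in EOG_CHANNELS]

    # background noise
    for i in range(n_ch):
        rms = eeg.eog_noise_rms_uV if i in eog_idx else eeg.noise_rms_uV
        data[i] += _one_over_f_noise(rng, n, sfreq, eeg.noise_exponent, rms)

    # line noise on scalp + mastoids
    if eeg.line_amp_uV > 0:
        t = np.arange(n) / sfreq
        for i in scalp_idx + mastoid_idx:
            data[i] += eeg.line_amp_uV * np.sin(
                2.0 * np.pi * eeg.line_freq_hz * t + rng.uniform(0, 2 * np.pi)
            )

    # blinks
    if eeg.blink_rate_per_min > 0:
        n_blinks = rng.poisson(eeg.blink_rate_per_min * (t_end / 60000.0))
        blink_len = int(round(eeg.blink_duration_ms / 1000.0 * sfreq))
        kernel = np.sin(np.linspace(0, np.pi, blink_len)) ** 2
        scalp_w = _blink_scalp_weights(list(eeg.scalp))
        starts = rng.integers(0, max(n - blink_len, 1), n_blinks)
        for s0 in np.sort(starts):
            amp = rng.normal(eeg.blink_amp_uV, 15.0)
            seg = amp * kernel
            for j, i in enumerate(scalp_idx):
                data[i, s0 : s0 + blink_len] += scalp_w[j] * seg
            for i in eog_idx:
                data[i, s0 : s0 + blink_len] += _BLINK_EOG[ch_names[i]] * seg

    # ERP component templates
    scalp_names = list(eeg.scalp)
    for tpl in templates:
        w = tpl.spatial_weights(scalp_names) * tpl.source_scale_uV
        width = max(int(round(tpl.width_ms / 1000.0 * sfreq)), 2)
        kernel = _half_cosine(width)
        for row in tab.itertuples(index=False):
            cell = _cell_of(row.planted_type, row.condition)
            if tpl.lock == "response":
                if not np.isfinite(row.response_onset_ms):
                    continue
                lock_ms = row.response_onset_ms
            else:
                lock_ms = row.stim_onset_ms
            lat = tpl.latency_ms[cell] + rng.normal(0.0, tpl.latency_jitter_sd_ms)
            start = int(round((lock_ms + lat - tpl.width_ms / 2.0) / 1000.0 * sfreq))
            if start < 0 or start + width > n:
                continue
            amp = tpl.amplitude[cell]
            seg = amp * kernel
            for j, i in enumerate(scalp_idx):
                if w[j] != 0.0:
                    data[i, start : start + width] += w[j] * seg

    # lateralised motor potential at C3'/C4'
    _add_motor_potential(data, ch_names, tab, eeg, rng, n)

    # event stream
    ev_rows = []
    for row in tab.itertuples(index=False):
        ev_rows.append(
            dict(
                sample=int(round(row.stim_onset_ms / 1000.0 * sfreq)),
                kind="stimulus",
                trial_index=int(row.trial_index),
            )
        )
        if np.isfinite(row.response_onset_ms):
            ev_rows.append(
                dict(
                    sample=int(round(row.response_onset_ms / 1000.0 * sfreq)),
                    kind="response",
                    trial_index=int(row.trial_index),
                )
            )
    events = (
        pd.DataFrame(ev_rows).sort_values("sample", kind="stable").reset_index(drop=True)
    )
    return EEGRecording(
        ch_names=ch_names, data=data.astype(np.float32), sfreq=sfreq, events=events
    )


def _ramp_profile(
    t_ms: np.ndarray, center_ms: float, rise: float, hold_until: float, decay: float
) -> np.ndarray:
    """Unit-amplitude motor ramp: half-cosine rise (half-max at ``center_ms``),
    plateau, then raised-cosine decay."""
    y = np.zeros_like(t_ms)
    r0, r1 = center_ms - rise / 2.0, center_ms + rise / 2.0
    rising = (t_ms >= r0) & (t_ms < r1)
    y[rising] = 0.5 * (1.0 - np.cos(np.pi * (t_ms[rising] - r0) / rise))
    hold_until = max(hold_until, r1)
    y[(t_ms >= r1) & (t_ms < hold_until)] = 1.0
    decaying = (t_ms >= hold_until) & (t_ms < hold_until + decay)
    y[decaying] = 0.5 * (1.0 + np.cos(np.pi * (t_ms[decaying] - hold_until) / decay))
    return y


def _add_motor_potential(data, ch_names, tab, eeg: EegParams, rng, n) -> None:
    p = eeg.lrp
    sfreq = eeg.sfreq
    i_c3 = ch_names.index("C3'")
    i_c4 = ch_names.index("C4'")
    for row in tab.itertuples(index=False):
        if not np.isfinite(row.response_onset_ms) or row.key < 0:
            continue
        contra = i_c4 if row.key < 4 else i_c3  # left hand -> right hemisphere
        cell = _cell_of(row.planted_type, row.condition)
        resp = row.response_onset_ms
        if (
            p.mi_error_instability
            and row.planted_type == "MI_ERROR"
        ):
            # several brief, low-amplitude impulses near the response:
            # response preparation repeatedly interrupted by inhibition attempts
            for _ in range(p.instability_n_impulses):
                c = resp + rng.uniform(*p.instability_window_ms)
                a = rng.uniform(*p.instability_amp_uV)
                w = int(round(p.instability_width_ms / 1000.0 * sfreq))
                start = int(round((c - p.instability_width_ms / 2.0) / 1000.0 * sfreq))
                if start < 0 or start + w > n:
                    continue
                data[contra, start : start + w] += -a * _half_cosine(w)
            continue
        center = resp + p.onset_ms[cell] + rng.normal(0.0, p.jitter_sd_ms)
        t0 = center - p.rise_ms / 2.0 - 10.0
        t1 = resp + p.hold_after_response_ms + p.decay_ms + 10.0
        s0, s1 = int(round(t0 / 1000.0 * sfreq)), int(round(t1 / 1000.0 * sfreq))
        if s0 < 0 or s1 > n:
            continue
        t_ms = np.arange(s0, s1) / sfreq * 1000.0
        prof = _ramp_profile(
            t_ms, center, p.rise_ms, resp + p.hold_after_response_ms, p.decay_ms
        )
        data[contra, s0:s1] += -p.amplitude_uV * prof


# ---------------------------------------------------------------------------
# defaults (reference cell means)
# ---------------------------------------------------------------------------

_P3_LATENCY = {
    ("MI", "success"): 306.3,
    ("MI", "error"): 303.5,
    ("IS", "success"): 331.5,
    ("IS", "error"): 315.3,
}


def _flat_latency(v: float) -> dict[Cell, float]:
    return {c: v for c in CELLS}


def default_erp_templates(calibrate_on: Optional[Sequence[str]] = None) -> list[ErpTemplate]:
    """Component templates whose cell amplitudes encode the reference means.

    CSD-quantified components state their amplitudes in µV/cm²; call with
    ``calibrate_on`` (a scalp channel list) to compute the per-template
    ``source_scale_uV`` through the pipeline's spline Laplacian so that CSD
    quantification on that montage recovers the stated values.
    """
    tpls = [
        ErpTemplate(
            "P1", "stimulus", ("PO7", "PO8"),
            {("MI", "success"): 0.21, ("MI", "error"): 0.21,
             ("IS", "success"): 0.19, ("IS", "error"): 0.21},
            _flat_latency(125.0), unit="uV/cm2", width_ms=120.0,
        ),
        ErpTemplate(
            "N1", "stimulus", ("P1", "P2"),
            {("MI", "success"): -0.05, ("MI", "error"): -0.03,
             ("IS", "success"): -0.03, ("IS", "error"): -0.04},
            _flat_latency(180.0), unit="uV/cm2", width_ms=120.0,
        ),
        ErpTemplate(
            "P2", "stimulus", ("PO9", "PO10"),
            {("MI", "success"): 0.20, ("MI", "error"): 0.22,
             ("IS", "success"): 0.18, ("IS", "error"): 0.19},
            _flat_latency(200.0), unit="uV/cm2", width_ms=120.0,
        ),
        ErpTemplate(
            "N2", "stimulus", ("FCz",),
            {("MI", "success"): -0.10, ("MI", "error"): -0.10,
             ("IS", "success"): -0.08, ("IS", "error"): -0.10},
            _flat_latency(225.0), unit="uV/cm2", width_ms=150.0,
        ),
        ErpTemplate(
            "P3_frontal", "stimulus", ("FCz",),
            {("MI", "success"): 2.3, ("MI", "error"): 3.7,
             ("IS", "success"): 3.1, ("IS", "error"): 3.5},
            dict(_P3_LATENCY), unit="uV", width_ms=200.0,
        ),
        ErpTemplate(
            "P3_parietal", "stimulus", ("Pz",),
            {("MI", "success"): 7.0, ("MI", "error"): 9.1,
             ("IS", "success"): 8.2, ("IS", "error"): 8.5},
            dict(_P3_LATENCY), unit="uV", width_ms=200.0,
        ),
        ErpTemplate(
            "Ne", "response", ("FCz",),
            {("MI", "success"): -0.12, ("MI", "error"): -0.14,
             ("IS", "success"): -0.10, ("IS", "error"): -0.14},
            _flat_latency(75.0), unit="uV/cm2", width_ms=120.0,
        ),
        ErpTemplate(
            "Pe", "response", ("Cz",),
            {("MI", "success"): 0.07, ("MI", "error"): 0.19,
             ("IS", "success"): 0.04, ("IS", "error"): 0.11},
            _flat_latency(225.0), unit="uV/cm2", width_ms=150.0,
        ),
    ]
    if calibrate_on is not None:
        calibrate_csd_templates(tpls, calibrate_on)
    return tpls


def calibrate_csd_templates(
    templates: Sequence[ErpTemplate], scalp: Sequence[str]
) -> None:
    """Set ``source_scale_uV`` of µV/cm² templates for the given montage.

    Pushes each template's unit-amplitude scalp map through the spline
    Laplacian and reads the resulting µV/cm² value at the measurement
    electrodes; the inverse of that gain converts target amplitudes into
    source µV.
    """
    from .preprocess import csd_of_map

    scalp = [c for c in scalp]
    for tpl in templates:
        if tpl.unit != "uV/cm2":
            tpl.source_scale_uV = 1.0
            continue
        missing = [e for e in tpl.electrodes if e not in scalp]
        if missing:
            raise ValueError(f"montage lacks electrodes {missing} for {tpl.name}")
        w = tpl.spatial_weights(scalp)
        csd_map = csd_of_map(w, scalp)
        gain = float(
            np.mean([csd_map[scalp.index(e)] for e in tpl.electrodes])
        )
        if abs(gain) < 1e-9:
            raise ValueError(f"degenerate CSD gain for template {tpl.name}")
        tpl.source_scale_uV = 1.0 / gain


def default_eeg_params(scalp: Sequence[str] = REDUCED_SCALP) -> EegParams:
    return EegParams(scalp=tuple(scalp))


def default_params(
    scalp: Sequence[str] = REDUCED_SCALP,
) -> tuple[BehaviourParams, list[ErpTemplate], EegParams]:
    """Behaviour parameters, ERP templates and EEG parameters at the
    reference cell means.

    CSD-quantified templates are always calibrated on the full 63-channel
    montage: the spline-Laplacian gain is a property of the generating scalp
    topography, while ``scalp`` merely selects which channels are recorded.
    """
    from .montage import FULL_SCALP

    templates = default_erp_templates(calibrate_on=FULL_SCALP)
    return default_behaviour_params(), templates, default_eeg_params(scalp)
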