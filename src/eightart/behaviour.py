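"""Response detection, trial classification and behavioural measures.

Responses are registered from eight force-key traces: the first exceedance of
40 cN on any key defines the responding key and the response time (RT).
Trials are then classified into the four analysed response types (motor
inhibition error/success, interference suppression error/success) or one of
the exclusion categories, and summarised per participant into the cell
measures of the behavioural analysis (response rates, median RT, multiple
responses, response corrections, peak force) plus the sequential measures
(post-error slowing, pre-error speeding, post-response accuracy).

Percentage conventions
----------------------
Response rates, multiple-response percentages and correction percentages are
all expressed relative to the *included* trials of a condition (MI: the
incongruent success+error trials; IS: the distractor-error + correct trials).
Under this convention the two accuracy cells of a condition sum to the
condition-level percentage, and the success/error response rates sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import ShapeSet, TrialSpec

__all__ = [
    "ResponseEvent",
    "ResponseType",
    "detect_responses",
    "classify_trial",
    "classify_all",
    "summarize_behaviour",
    "compute_sequential_effects",
    "INCLUDED_TYPES",
]

FORCE_THRESHOLD_CN = 40.0


class ResponseType(Enum):
    MI_ERROR = "MI_ERROR"
    MI_SUCCESS = "MI_SUCCESS"
    IS_ERROR = "IS_ERROR"
    IS_SUCCESS = "IS_SUCCESS"
    EXCL_TOO_SLOW = "EXCL_TOO_SLOW"
    EXCL_NO_RESPONSE = "EXCL_NO_RESPONSE"
    EXCL_IS_OTHER_ERROR = "EXCL_IS_OTHER_ERROR"
    EXCL_MI_CONGRUENT = "EXCL_MI_CONGRUENT"
    EXCL_MI_OTHER_ERROR = "EXCL_MI_OTHER_ERROR"


INCLUDED_TYPES = {
    ResponseType.MI_ERROR,
    ResponseType.MI_SUCCESS,
    ResponseType.IS_ERROR,
    ResponseType.IS_SUCCESS,
}


@dataclass
class ResponseEvent:
    """Force-derived response of one trial (times in ms from stimulus onset)."""

    trial_index: int
    first_key: Optional[int]
    rt_ms: Optional[float]
    peak_force_cN: Optional[float]
    keys_crossed: frozenset[int]
    is_multiple: bool
    is_correction: bool  # filled in by classify_all (needs the correct key)
    too_slow: bool
    crossing_ms: dict[int, float]  # first-crossing time per crossed key


def detect_responses(
    forces: np.ndarray,
    sfreq: float,
    threshold_cN: float = FORCE_THRESHOLD_CN,
    rt_limit_ms: float = 1000.0,
    trial_indices: Optional[Sequence[int]] = None,
) -> list[ResponseEvent]:
    """Detect responses from per-trial 8-key force traces.

    Parameters
    ----------
    forces : array (n_trials, 8, n_samples)
        Force in cN, sample 0 aligned to stimulus onset.
    sfreq : float
        Sampling rate of the force traces in Hz.
    threshold_cN : float
        Crossing level that registers a keypress (40 cN by default).
    rt_limit_ms : float
        Responses later than this are flagged ``too_slow``.

    The first threshold crossing defines the responding key and the RT.  If
    two keys cross within the same sample, the key with the larger
    instantaneous force wins; remaining ties go to the lower key index.
    """
    forces = np.asarray(forces)
    if not np.isfinite(forces).all():
        raise ValueError("non-finite force trace values")
    n_trials = forces.shape[0]
    if trial_indices is None:
        trial_indices = range(n_trials)
    events: list[ResponseEvent] = []
    over = forces >= threshold_cN
    for t, tid in zip(range(n_trials), trial_indices):
        crossing: dict[int, float] = {}
        first_sample: dict[int, int] = {}
        for k in range(forces.shape[1]):
            idx = np.flatnonzero(over[t, k])
            if idx.size:
                first_sample[k] = int(idx[0])
                crossing[k] = idx[0] / sfreq * 1000.0
        if not crossing:
            events.append(
                ResponseEvent(
                    trial_index=tid,
                    first_key=None,
                    rt_ms=None,
                    peak_force_cN=None,
                    keys_crossed=frozenset(),
                    is_multiple=False,
                    is_correction=False,
                    too_slow=True,
                    crossing_ms={},
                )
            )
            continue
        smin = min(first_sample.values())
        simultaneous = [k for k, s in first_sample.items() if s == smin]
        if len(simultaneous) > 1:
            # larger instantaneous force first, then lower key index
            simultaneous.sort(key=lambda k: (-forces[t, k, smin], k))
        first_key = simultaneous[0]
        rt = crossing[first_key]
        events.append(
            ResponseEvent(
                trial_index=tid,
                first_key=first_key,
                rt_ms=rt,
                peak_force_cN=float(forces[t, first_key].max()),
                keys_crossed=frozenset(crossing),
                is_multiple=len(crossing) > 1,
                is_correction=False,
                too_slow=rt > rt_limit_ms,
                crossing_ms=crossing,
            )
        )
    return events


def classify_trial(
    spec: TrialSpec, ev: ResponseEvent, shapes: ShapeSet
) -> ResponseType:
    """Assign one of the nine response types to a trial.

    The correct key is the target shape's home-square key.  A motor-inhibition
    error is a press of the key beneath the presentation location on an
    incongruent trial; an interference-suppression error is a press of the
    distractor shape's key (which, by construction, is also the location key).
    """
    if spec.trial_index != ev.trial_index:
        raise ValueError("trial/event index mismatch")
    if ev.first_key is None:
        return ResponseType.EXCL_NO_RESPONSE
    if ev.too_slow:
        return ResponseType.EXCL_TOO_SLOW
    correct_key = shapes.home_location[spec.target_shape]
    if spec.condition == "MI":
        if spec.congruent:
            return (
                ResponseType.EXCL_MI_CONGRUENT
                if ev.first_key == correct_key
                else ResponseType.EXCL_MI_OTHER_ERROR
            )
        if ev.first_key == correct_key:
            return ResponseType.MI_SUCCESS
        if ev.first_key == spec.location:
            return ResponseType.MI_ERROR
        return ResponseType.EXCL_MI_OTHER_ERROR
    # IS
    if ev.first_key == correct_key:
        return ResponseType.IS_SUCCESS
    distractor_key = shapes.home_location[spec.distractor_shape]
    if ev.first_key == distractor_key:
        return ResponseType.IS_ERROR
    return ResponseType.EXCL_IS_OTHER_ERROR


def classify_all(
    specs: Sequence[TrialSpec],
    events: Sequence[ResponseEvent],
    shapes: ShapeSet,
) -> list[ResponseType]:
    """Classify every trial and resolve response corrections.

    A correction is an error trial (of either condition) on which the correct
    key also crosses the force threshold *after* the erroneous first key.
    """
    if len(specs) != len(events):
        raise ValueError("specs/events length mismatch")
    types: list[ResponseType] = []
    for spec, ev in zip(specs, events):
        rtype = classify_trial(spec, ev, shapes)
        if rtype in (ResponseType.MI_ERROR, ResponseType.IS_ERROR):
            correct_key = shapes.home_location[spec.target_shape]
            tc = ev.crossing_ms.get(correct_key)
            if tc is not None and tc > ev.rt_ms:
                ev.is_correction = True
        types.append(rtype)
    return types


_CELL_OF = {
    ResponseType.MI_SUCCESS: ("MI", "success"),
    ResponseType.MI_ERROR: ("MI", "error"),
    ResponseType.IS_SUCCESS: ("IS", "success"),
    ResponseType.IS_ERROR: ("IS", "error"),
}


def summarize_behaviour(
    specs: Sequence[TrialSpec],
    events: Sequence[ResponseEvent],
    types: Sequence[ResponseType],
    participant: object = 0,
) -> pd.DataFrame:
    """Per-cell behavioural summary for one participant.

    Returns a long-format frame with one row per (condition, accuracy) cell:
    ``response_rate_pct`` (within included condition trials), ``median_rt_ms``,
    ``multiple_pct`` and ``correction_pct`` (both relative to included
    condition trials, see module docstring), ``mean_peak_force_cN`` and
    ``n_trials``.  Empty cells yield NaN values rather than silent zeros.
    """
    rows = []
    df = pd.DataFrame(
        {
            "type": list(types),
            "rt": [ev.rt_ms for ev in events],
            "multiple": [ev.is_multiple for ev in events],
            "correction": [ev.is_correction for ev in events],
            "force": [ev.peak_force_cN for ev in events],
        }
    )
    for condition in ("MI", "IS"):
        included = df[
            df["type"].isin(
                [t for t, (c, _) in _CELL_OF.items() if c == condition]
            )
        ]
        n_inc = len(included)
        for accuracy in ("success", "error"):
            rtype = next(
                t for t, cell in _CELL_OF.items() if cell == (condition, accuracy)
            )
            cell = df[df["type"] == rtype]
            n = len(cell)
            if n == 0 or n_inc == 0:
                rows.append(
                    dict(
                        participant=participant,
                        condition=condition,
                        accuracy=accuracy,
                        response_rate_pct=np.nan,
                        median_rt_ms=np.nan,
                        multiple_pct=np.nan,
                        correction_pct=np.nan,
                        mean_peak_force_cN=np.nan,
                        n_trials=n,
                    )
                )
                continue
            rows.append(
                dict(
                    participant=participant,
                    condition=condition,
                    accuracy=accuracy,
                    response_rate_pct=100.0 * n / n_inc,
                    median_rt_ms=float(np.median(cell["rt"])),
                    multiple_pct=100.0 * cell["multiple"].sum() / n_inc,
                    correction_pct=100.0 * cell["correction"].sum() / n_inc,
                    mean_peak_force_cN=float(np.mean(cell["force"])),
                    n_trials=n,
                )
            )
    return pd.DataFrame(rows)


def compute_sequential_effects(
    specs: Sequence[TrialSpec],
    events: Sequence[ResponseEvent],
    types: Sequence[ResponseType],
    shapes: ShapeSet,
    rt_limit_ms: float = 1000.0,
    participant: object = 0,
) -> pd.DataFrame:
    """Post-error slowing, pre-error speeding and post-response accuracy.

    Per condition, PES is the mean RT of trials following an included error
    minus the mean RT of trials following an included success; pre-error
    speeding applies the same subtraction to the trials immediately preceding
    errors versus successes.  Adjacent trials contribute their RT whenever a
    response was registered, regardless of their own classification (after a
    motor-inhibition error the next trial is, by task design, always
    congruent; exclusion criteria apply to the analysed trial, not to its
    neighbours, so a late neighbouring response still contributes its RT).
    Block boundaries break adjacency.
    Post-response accuracy is the proportion of correct responses (any trial
    type) on the following trials.
    """
    rows = []
    # specs are assumed in presentation order within each condition run
    by_condition: dict[str, list[int]] = {"MI": [], "IS": []}
    for i, s in enumerate(specs):
        by_condition[s.condition].append(i)

    def rt_ok(i: int) -> Optional[float]:
        ev = events[i]
        return ev.rt_ms  # None when no response was registered

    def is_correct(i: int) -> Optional[bool]:
        ev = events[i]
        if ev.first_key is None:
            return None
        return ev.first_key == shapes.home_location[specs[i].target_shape]

    for condition in ("MI", "IS"):
        idx = by_condition[condition]
        err_t = ResponseType[f"{condition}_ERROR"]
        suc_t = ResponseType[f"{condition}_SUCCESS"]
        post: dict[ResponseType, list[float]] = {err_t: [], suc_t: []}
        pre: dict[ResponseType, list[float]] = {err_t: [], suc_t: []}
        post_acc: dict[ResponseType, list[bool]] = {err_t: [], suc_t: []}
        for pos, i in enumerate(idx):
            if types[i] not in (err_t, suc_t):
                continue
            if pos + 1 < len(idx):
                j = idx[pos + 1]
                if specs[j].block == specs[i].block:
                    rt = rt_ok(j)
                    if rt is not None:
                        post[types[i]].append(rt)
                    corr = is_correct(j)
                    if corr is not None:
                        post_acc[types[i]].append(corr)
            if pos > 0:
                j = idx[pos - 1]
                if specs[j].block == specs[i].block:
                    rt = rt_ok(j)
                    if rt is not None:
                        pre[types[i]].append(rt)

        def diff(d):
            if not d[err_t] or not d[suc_t]:
                return np.nan
            return float(np.mean(d[err_t]) - np.mean(d[suc_t]))

        rows.append(
            dict(
                participant=participant,
                condition=condition,
                pes_ms=diff(post),
                pre_error_speeding_ms=diff(pre),
                post_error_accuracy_pct=(
                    100.0 * np.mean(post_acc[err_t]) if post_acc[err_t] else np.nan
                ),
                post_correct_accuracy_pct=(
                    100.0 * np.mean(post_acc[suc_t]) if post_acc[suc_t] else np.nan
                ),
                n_post_error=len(post[err_t]),
                n_post_success=len(post[suc_t]),
            )
        )
    return pd.DataFrame(rows)
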