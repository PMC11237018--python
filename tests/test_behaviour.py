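"""Force-based response detection, trial classification and behavioural
measures."""

import numpy as np
import pandas as pd
import pytest

from eightart.behaviour import (
    ResponseEvent,
    ResponseType,
    classify_all,
    classify_trial,
    compute_sequential_effects,
    detect_responses,
    summarize_behaviour,
)
from eightart.pipeline import analyze_behaviour, make_session
from eightart.simulate import default_behaviour_params, simulate_behaviour
from eightart.task import TrialSpec

SFREQ = 500.0


def pulse_trace(crossings, n_samples=800, peak=120.0):
    """8-key traces with a piecewise-linear pulse reaching exactly 40 cN at
    the stated crossing times (ms) per key."""
    tr = np.zeros((1, 8, n_samples))
    t = np.arange(n_samples) / SFREQ * 1000.0
    for key, c in crossings.items():
        tr[0, key] += np.interp(
            t,
            [c - 50.0, c, c + 50.0, c + 150.0, c + 250.0],
            [0.0, 40.0, peak, peak, 0.0],
            left=0.0,
            right=0.0,
        )
    return tr


def mk_trial(condition="MI", congruent=False, location=5, target="shape3",
             distractor=None, index=0):
    return TrialSpec(
        condition=condition, block=0, trial_index=index, target_shape=target,
        location=location, congruent=congruent if condition == "MI" else None,
        distractor_shape=distractor, iti_ms=600,
    )


def test_single_pulse_detection():
    ev = detect_responses(pulse_trace({3: 512.0}), SFREQ)[0]
    assert ev.first_key == 3
    assert abs(ev.rt_ms - 512.0) <= 1000.0 / SFREQ
    assert not ev.is_multiple and not ev.too_slow


def test_multiple_key_detection():
    ev = detect_responses(pulse_trace({3: 500.0, 5: 700.0}), SFREQ)[0]
    assert ev.is_multiple and ev.keys_crossed == frozenset({3, 5})
    assert ev.first_key == 3


def test_no_crossing_and_too_slow():
    ev = detect_responses(np.zeros((1, 8, 800)), SFREQ)[0]
    assert ev.first_key is None and ev.too_slow
    ev = detect_responses(pulse_trace({2: 1100.0}), SFREQ, rt_limit_ms=1000.0)[0]
    assert ev.too_slow and ev.first_key == 2


def test_nonfinite_trace_rejected():
    tr = np.zeros((1, 8, 10))
    tr[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        detect_responses(tr, SFREQ)


def test_simultaneous_crossing_tiebreak():
    # both keys cross in the same sample; larger instantaneous force wins
    tr = np.zeros((1, 8, 20))
    tr[0, 4, 5:] = 50.0
    tr[0, 2, 5:] = 60.0
    assert detect_responses(tr, SFREQ)[0].first_key == 2
    # exact tie -> lower key index
    tr[0, 2, 5:] = 50.0
    assert detect_responses(tr, SFREQ)[0].first_key == 2


def ev_for(key, rt=500.0, crossing=None, index=0):
    crossing = crossing or {key: rt}
    return ResponseEvent(
        trial_index=index, first_key=key, rt_ms=rt,
        peak_force_cN=120.0, keys_crossed=frozenset(crossing),
        is_multiple=len(crossing) > 1, is_correction=False,
        too_slow=rt > 1000.0, crossing_ms=crossing,
    )


class TestClassification:
    def test_mi_location_press_is_error(self, shapes):
        # target shape3 (home key 3) shown at square 5; pressing key 5
        # follows the induced location tendency -> motor inhibition error
        spec = mk_trial(location=5)
        assert classify_trial(spec, ev_for(5), shapes) is ResponseType.MI_ERROR
        assert classify_trial(spec, ev_for(3), shapes) is ResponseType.MI_SUCCESS
        assert (
            classify_trial(spec, ev_for(7), shapes) is ResponseType.EXCL_MI_OTHER_ERROR
        )

    def test_mi_congruent_correct_is_excluded(self, shapes):
        spec = mk_trial(congruent=True, location=3)
        assert (
            classify_trial(spec, ev_for(3), shapes) is ResponseType.EXCL_MI_CONGRUENT
        )

    def test_is_distractor_press_is_error(self, shapes):
        spec = mk_trial("IS", location=5, distractor="shape5")
        assert classify_trial(spec, ev_for(3), shapes) is ResponseType.IS_SUCCESS
        assert classify_trial(spec, ev_for(5), shapes) is ResponseType.IS_ERROR
        assert (
            classify_trial(spec, ev_for(6), shapes) is ResponseType.EXCL_IS_OTHER_ERROR
        )

    def test_too_slow_and_no_response(self, shapes):
        spec = mk_trial()
        assert (
            classify_trial(spec, ev_for(3, rt=1200.0), shapes)
            is ResponseType.EXCL_TOO_SLOW
        )
        ev = ResponseEvent(0, None, None, None, frozenset(), False, False, True, {})
        assert classify_trial(spec, ev, shapes) is ResponseType.EXCL_NO_RESPONSE

    def test_correction_flagged_when_correct_key_follows(self, shapes):
        spec = mk_trial(location=5)
        ev = ev_for(5, rt=450.0, crossing={5: 450.0, 3: 650.0})
        types = classify_all([spec], [ev], shapes)
        assert types[0] is ResponseType.MI_ERROR and ev.is_correction
        # correct key crossing *before* the error key is not a correction
        ev2 = ev_for(5, rt=450.0, crossing={5: 450.0, 3: 400.0})
        classify_all([spec], [ev2], shapes)
        assert not ev2.is_correction


def test_every_trial_gets_exactly_one_type(shapes):
    _, specs = make_session(3)
    sim = simulate_behaviour(specs, default_behaviour_params(), 4, shapes=shapes)
    events, types, summary, _ = analyze_behaviour(shapes, specs, sim)
    assert len(types) == len(specs)
    counts = pd.Series([t.value for t in types]).value_counts()
    assert counts.sum() == len(specs)
    # response-rate complements per condition
    for cond in ("MI", "IS"):
        cells = summary[summary.condition == cond]
        assert cells.response_rate_pct.sum() == pytest.approx(100.0)


def test_summary_median_and_rates(shapes):
    specs = [mk_trial(index=i, location=5) for i in range(3)]
    events = [ev_for(3, rt, index=i) for i, rt in enumerate([400.0, 500.0, 900.0])]
    types = classify_all(specs, events, shapes)
    s = summarize_behaviour(specs, events, types)
    mi_succ = s.query("condition=='MI' and accuracy=='success'").iloc[0]
    assert mi_succ.median_rt_ms == 500.0
    assert mi_succ.response_rate_pct == 100.0
    assert s.query("condition=='IS'").n_trials.sum() == 0


def test_pes_arithmetic(shapes):
    # success(err-free), error, post-error, success, post-success trial
    specs = [mk_trial(index=i, location=5) for i in range(4)]
    keys = [5, 3, 3, 3]  # error then successes
    rts = [500.0, 780.0, 600.0, 750.0]
    events = [ev_for(k, r, index=i) for i, (k, r) in enumerate(zip(keys, rts))]
    types = classify_all(specs, events, shapes)
    seq = compute_sequential_effects(specs, events, types, shapes)
    mi = seq[seq.condition == "MI"].iloc[0]
    # post-error RT 780, post-success mean (600+750)/2 = 675 -> PES 105
    assert mi.pes_ms == pytest.approx(780.0 - 675.0)


def test_identical_rts_give_zero_sequential_effects(shapes):
    _, specs = make_session(5)
    sim = simulate_behaviour(specs, default_behaviour_params(), 6, shapes=shapes)
    events, types, _, _ = analyze_behaviour(shapes, specs, sim)
    for ev in events:
        if ev.rt_ms is not None:
            ev.rt_ms = 700.0
    seq = compute_sequential_effects(specs, events, types, shapes)
    assert (seq.pes_ms.dropna() == 0).all()
    assert (seq.pre_error_speeding_ms.dropna() == 0).all()


def test_shuffled_order_destroys_pes(shapes):
    """With trial order shuffled, sequential structure vanishes and the
    expected PES is zero."""
    _, specs = make_session(11)
    sim = simulate_behaviour(specs, default_behaviour_params(), 12, shapes=shapes)
    events, types, _, _ = analyze_behaviour(shapes, specs, sim)
    rng = np.random.default_rng(0)
    vals = []
    for _ in range(20):
        perm = rng.permutation(len(specs))
        ev_s = [events[i] for i in perm]
        ty_s = [types[i] for i in perm]
        sp_s = [specs[i] for i in perm]
        # keep per-trial (spec, event, type) triplets intact, shuffle order only
        seq = compute_sequential_effects(sp_s, ev_s, ty_s, shapes)
        vals.append(seq[seq.condition == "IS"].pes_ms.iloc[0])
    assert abs(np.nanmean(vals)) < 15.0
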