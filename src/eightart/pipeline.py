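"""End-to-end orchestration: simulate → preprocess → classify → quantify →
LRP → statistics.

`run_pipeline` drives a fully seeded multi-participant synthetic study and
writes tabular results (group behaviour and ERP cell summaries, ANOVA and
contrast reports, exclusion logs) plus a machine-readable JSON of all
statistics.  The lower-level group-study helpers are reusable entry points
for parameter-recovery work: `behaviour_group_study` runs the behaviour-only
chain (no EEG), `eeg_group_study` runs the EEG chain on a reduced montage
and recovers the parietal P3 and the response-locked LRP onsets.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import behaviour as bhv
from . import erp as erp_mod
from . import lrp as lrp_mod
from . import stats as stats_mod
from .montage import REDUCED_SCALP
from .preprocess import (
    InsufficientDataError,
    PreprocConfig,
    csd_transform,
    epoch_and_clean,
    preprocess_continuous,
)
from .simulate import (
    BehaviourParams,
    EegParams,
    ErpTemplate,
    default_behaviour_params,
    default_params,
    simulate_behaviour,
    simulate_eeg,
)
from .task import (
    ISDesign,
    MIDesign,
    ShapeSet,
    TrialSpec,
    generate_is_sequence,
    generate_mi_sequence,
)

__all__ = [
    "make_session",
    "analyze_behaviour",
    "behaviour_group_study",
    "eeg_group_study",
    "run_pipeline",
]

CELL_TYPES = ("MI_SUCCESS", "MI_ERROR", "IS_SUCCESS", "IS_ERROR")


def _child_seeds(base_seed: int, participant: int, n: int) -> list[int]:
    ss = np.random.SeedSequence([int(base_seed), int(participant)])
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def make_session(
    seed: int,
    shapes: Optional[ShapeSet] = None,
    mi_design: MIDesign = MIDesign(),
    is_design: ISDesign = ISDesign(),
) -> tuple[ShapeSet, list[TrialSpec]]:
    """One participant's full trial list (MI run then IS run) with globally
    unique trial indices."""
    shapes = shapes or ShapeSet()
    mi = generate_mi_sequence(mi_design, shapes, seed)
    is_ = generate_is_sequence(is_design, shapes, seed + 1)
    out: list[TrialSpec] = []
    for i, t in enumerate(mi + is_):
        out.append(replace(t, trial_index=i))
    return shapes, out


def analyze_behaviour(
    shapes: ShapeSet,
    specs: Sequence[TrialSpec],
    sim,
    participant: object = 0,
    rt_limit_ms: float = 1000.0,
):
    """Detection → classification → summaries for one participant."""
    events = bhv.detect_responses(
        sim.forces, sim.sfreq, rt_limit_ms=rt_limit_ms,
        trial_indices=[t.trial_index for t in specs],
    )
    types = bhv.classify_all(specs, events, shapes)
    summary = bhv.summarize_behaviour(specs, events, types, participant=participant)
    seq = bhv.compute_sequential_effects(
        specs, events, types, shapes, rt_limit_ms=rt_limit_ms, participant=participant
    )
    return events, types, summary, seq


def behaviour_group_study(
    n_participants: int = 30,
    base_seed: int = 1,
    params: Optional[BehaviourParams] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Behaviour-only simulation + analysis for a group of participants.

    Returns the per-participant cell summary (long format) and the
    sequential-effect table, both ready for the group-level statistics.
    """
    params = params or default_behaviour_params()
    cell_rows, seq_rows = [], []
    for pid in range(1, n_participants + 1):
        s_task, s_beh = _child_seeds(base_seed, pid, 2)
        shapes, specs = make_session(s_task)
        sim = simulate_behaviour(specs, params, s_beh, shapes=shapes)
        _, _, summary, seq = analyze_behaviour(
            shapes, specs, sim, participant=pid, rt_limit_ms=params.rt_limit_ms
        )
        cell_rows.append(summary)
        seq_rows.append(seq)
    return (
        pd.concat(cell_rows, ignore_index=True),
        pd.concat(seq_rows, ignore_index=True),
    )


_LRP_BASELINE = (-500.0, -400.0)  # pre-activation segment of the R-LRP window


def _participant_eeg(
    pid: int,
    base_seed: int,
    params: BehaviourParams,
    templates: Sequence[ErpTemplate],
    eeg_params: EegParams,
    cfg: PreprocConfig,
):
    s_task, s_beh, s_eeg = _child_seeds(base_seed, pid, 3)
    shapes, specs = make_session(s_task)
    sim = simulate_behaviour(specs, params, s_beh, shapes=shapes)
    rec = simulate_eeg(specs, sim, templates, eeg_params, s_eeg)
    clean = preprocess_continuous(rec, cfg)
    events, types, summary, seq = analyze_behaviour(
        shapes, specs, sim, participant=pid, rt_limit_ms=params.rt_limit_ms
    )
    labels = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in specs],
            "condition": [t.condition for t in specs],
            "response_type": [t.value for t in types],
            "hand": [
                ("left" if ev.first_key < 4 else "right")
                if ev.first_key is not None
                else "none"
                for ev in events
            ],
        }
    )
    return shapes, specs, sim, clean, labels, summary, seq


def eeg_group_study(
    n_participants: int = 12,
    base_seed: int = 1,
    scalp: Sequence[str] = REDUCED_SCALP,
    instability: bool = False,
    cfg: PreprocConfig = PreprocConfig(),
    lrp_cfg: lrp_mod.LrpConfig = lrp_mod.LrpConfig(),
) -> dict:
    """EEG recovery study on a reduced montage.

    Runs the full chain for each participant and returns the per-participant
    parietal P3 amplitudes (µV, untransformed, stimulus-locked) and the
    jackknifed response-locked LRP onset sets per cell.
    """
    params, templates, eeg_params = default_params(scalp)
    if instability:
        eeg_params = replace(
            eeg_params, lrp=replace(eeg_params.lrp, mi_error_instability=True)
        )
    p3_spec = next(s for s in erp_mod.DEFAULT_COMPONENTS if s.name == "P3_parietal")
    p3_rows = []
    lrp_waves: dict[str, list] = {c: [] for c in CELL_TYPES}
    lrp_participants: dict[str, list] = {c: [] for c in CELL_TYPES}
    lrp_exclusions = []
    for pid in range(1, n_participants + 1):
        _, _, _, clean, labels, _, _ = _participant_eeg(
            pid, base_seed, params, templates, eeg_params, cfg
        )
        stim_eps = epoch_and_clean(clean, cfg, "stimulus", labels)
        for cell in CELL_TYPES:
            n_cell = int((stim_eps.labels["response_type"] == cell).sum())
            if n_cell < erp_mod.DEFAULT_MIN_TRIALS["P3_parietal"]:
                continue
            wf = erp_mod.average_waveform(stim_eps, cell, p3_spec.electrodes)
            m = erp_mod.measure_component(
                wf, stim_eps.times_ms, p3_spec,
                participant=pid, response_type=cell, n_trials=n_cell,
            )
            p3_rows.append(vars(m))
        resp_eps = epoch_and_clean(
            clean, cfg, "response", labels,
            window_ms=lrp_cfg.response_window_ms, baseline_ms=_LRP_BASELINE,
        )
        for cell in CELL_TYPES:
            try:
                w = lrp_mod.derive_lrp(resp_eps, cell, lrp_cfg)
            except InsufficientDataError as e:
                lrp_exclusions.append(dict(participant=pid, cell=cell, reason=str(e)))
                continue
            lrp_waves[cell].append(w)
            lrp_participants[cell].append(pid)
    onset_sets = {}
    for cell in CELL_TYPES:
        if len(lrp_waves[cell]) >= 3:
            onset_sets[cell] = lrp_mod.jackknife_onsets(
                lrp_waves[cell], lrp_cfg, participants=lrp_participants[cell]
            )
        else:
            onset_sets[cell] = None
    return dict(
        p3=pd.DataFrame(p3_rows),
        lrp_onsets=onset_sets,
        lrp_waveforms=lrp_waves,
        lrp_exclusions=pd.DataFrame(lrp_exclusions),
        generating=dict(params=params, templates=templates, eeg=eeg_params),
    )


# ---------------------------------------------------------------------------
# full study driver
# ---------------------------------------------------------------------------

def _group_cell_stats(cells: pd.DataFrame, value: str) -> pd.DataFrame:
    g = cells.groupby(["condition", "accuracy"])[value]
    return g.agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(x.count())).reset_index()


def _anova_block(cells: pd.DataFrame, value: str) -> dict:
    long = cells.rename(columns={value: "value"})[
        ["participant", "condition", "accuracy", "value"]
    ]
    res = stats_mod.rm_anova_2x2(long)
    out = {
        "effects": {
            k: dict(F=e.F, df1=e.df1, df2=e.df2, p=e.p, partial_eta_sq=e.partial_eta_sq)
            for k, e in res.effects.items()
        },
        "cell_means": res.cell_means.to_dict(orient="records"),
        "n": res.n_complete,
    }
    if res.effects["interaction"].p < 0.05:
        out["tukey"] = [
            dict(a="/".join(c.cell_a), b="/".join(c.cell_b),
                 mean_diff=c.mean_diff, t=c.t, df=c.df, p=c.p, d=c.cohen_d)
            for c in stats_mod.posthoc_tukey(long)
        ]
    return out


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: Optional[int] = None,
) -> dict:
    """Run the configured synthetic study and write the results bundle.

    ``config`` is a dict or YAML path with keys ``n_participants`` (default
    12), ``seed``, ``eeg`` (bool, default False: behavioural outputs only)
    and ``instability`` (bool).  Returns the statistics bundle that is also
    written to ``results.json``.
    """
    import yaml

    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    n = int(config.get("n_participants", 12))
    base_seed = int(seed if seed is not None else config.get("seed", 1))
    with_eeg = bool(config.get("eeg", False))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cells, seq = behaviour_group_study(n, base_seed)
    cells.to_csv(out / "behaviour_cells.tsv", sep="\t", index=False)
    seq.to_csv(out / "sequential_effects.tsv", sep="\t", index=False)

    bundle: dict = {"config": dict(config, n_participants=n, seed=base_seed)}
    table1 = []
    for metric in ("response_rate_pct", "median_rt_ms", "multiple_pct",
                   "correction_pct", "mean_peak_force_cN"):
        stats = _group_cell_stats(cells, metric)
        stats.insert(0, "measure", metric)
        table1.append(stats)
    pd.concat(table1, ignore_index=True).to_csv(
        out / "table1_style.tsv", sep="\t", index=False
    )

    bundle["anova"] = {
        "median_rt_ms": _anova_block(cells, "median_rt_ms"),
        "multiple_pct": _anova_block(cells, "multiple_pct"),
        "mean_peak_force_cN": _anova_block(cells, "mean_peak_force_cN"),
    }
    pes, pre = {}, {}
    for cond in ("MI", "IS"):
        s = seq[seq["condition"] == cond]
        pes[cond] = vars(stats_mod.paired_t(s["pes_ms"].dropna(), sided="one"))
        pre[cond] = vars(
            stats_mod.paired_t(s["pre_error_speeding_ms"].dropna(), sided="one",
                               direction="less")
        )
    mi_corr = cells.query("condition=='MI' and accuracy=='error'").set_index(
        "participant"
    )["correction_pct"]
    is_corr = cells.query("condition=='IS' and accuracy=='error'").set_index(
        "participant"
    )["correction_pct"]
    common = mi_corr.index.intersection(is_corr.index)
    bundle["pes"] = pes
    bundle["pre_error_speeding"] = pre
    bundle["corrections_mi_vs_is"] = vars(
        stats_mod.paired_t(mi_corr.loc[common], is_corr.loc[common], sided="two")
    )

    if with_eeg:
        study = eeg_group_study(
            n, base_seed, instability=bool(config.get("instability", False))
        )
        study["p3"].to_csv(out / "p3_parietal.tsv", sep="\t", index=False)
        rows = []
        for cell, js in study["lrp_onsets"].items():
            if js is None:
                continue
            for p, sub, ret in zip(
                js.participants, js.subsample_onsets_ms, js.retrieved_onsets_ms
            ):
                rows.append(
                    dict(participant=p, cell=cell, lock=js.lock,
                         subsample_onset_ms=sub, retrieved_onset_ms=ret)
                )
        pd.DataFrame(rows).to_csv(out / "lrp_onsets.tsv", sep="\t", index=False)
        study["lrp_exclusions"].to_csv(out / "lrp_exclusions.tsv", sep="\t", index=False)
        p3 = study["p3"]
        bundle["p3_parietal_cells"] = (
            p3.groupby("response_type")["amplitude"].agg(["mean", "sem"]).to_dict()
        )
        bundle["r_lrp_grand_onsets_ms"] = {
            cell: (js.grand_onset_ms if js is not None else None)
            for cell, js in study["lrp_onsets"].items()
        }

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (tuple, set)):
            return list(o)
        return str(o)

    (out / "results.json").write_text(json.dumps(bundle, indent=2, default=_default))
    return bundle
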