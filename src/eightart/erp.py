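"""ERP component quantification: peak-anchored mean amplitudes and P3 latency.

Each component is defined by a search window, one or two electrodes (two are
averaged), a polarity and a lock.  The peak is the extremum of the stated
polarity inside the closed window; the amplitude is the mean of the five
samples centred on the peak (±2 data points, clamped to the epoch bounds when
the peak sits at an edge).  A wide 40-sample mode exists for the slow
components but is off by default.  The parietal P3's peak latency doubles as
the P3 latency measure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import EpochSet, InsufficientDataError

__all__ = [
    "ComponentSpec",
    "ComponentMeasure",
    "DEFAULT_COMPONENTS",
    "DEFAULT_MIN_TRIALS",
    "average_waveform",
    "measure_component",
    "build_component_table",
]

RESPONSE_TYPES_4 = ("MI_SUCCESS", "MI_ERROR", "IS_SUCCESS", "IS_ERROR")


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    window_ms: tuple[float, float]
    electrodes: tuple[str, ...]
    polarity: str  # "positive" | "negative"
    lock: str  # "stimulus" | "response"
    use_csd: bool
    halfwidth_samples: int = 2
    wide: bool = False  # 40-sample averaging mode

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        if not 1 <= len(self.electrodes) <= 2:
            raise ValueError("one or two electrodes")


#: Quantification table: window, pooled electrodes, lock and CSD use per
#: component.  The P3 is measured on untransformed data; everything else on
#: the current source density.
DEFAULT_COMPONENTS: tuple[ComponentSpec, ...] = (
    ComponentSpec("P1", (90.0, 160.0), ("PO7", "PO8"), "positive", "stimulus", True),
    ComponentSpec("N1", (150.0, 210.0), ("P1", "P2"), "negative", "stimulus", True),
    ComponentSpec("P2", (150.0, 250.0), ("PO9", "PO10"), "positive", "stimulus", True),
    ComponentSpec("N2", (150.0, 300.0), ("FCz",), "negative", "stimulus", True),
    ComponentSpec("P3_frontal", (200.0, 500.0), ("FCz",), "positive", "stimulus", False),
    ComponentSpec("P3_parietal", (200.0, 500.0), ("Pz",), "positive", "stimulus", False),
    ComponentSpec("Ne", (0.0, 150.0), ("FCz",), "negative", "response", True),
    ComponentSpec("Pe", (150.0, 300.0), ("Cz",), "positive", "response", True),
)

#: Minimum trial counts per cell for a participant to enter a component's
#: analysis (error-monitoring components need at least six error trials;
#: N2 and P3 need 20 and 14 trials for internal consistency).
DEFAULT_MIN_TRIALS: dict[str, int] = {
    "N2": 20,
    "P3_frontal": 14,
    "P3_parietal": 14,
    "Ne": 6,
    "Pe": 6,
}


@dataclass
class ComponentMeasure:
    participant: object
    component: str
    response_type: str
    amplitude: float
    unit: str
    peak_latency_ms: float
    n_trials: int
    excluded: bool = False


def average_waveform(
    epochs: EpochSet, cell: str, electrodes: Sequence[str]
) -> np.ndarray:
    """Per-cell average: pointwise mean over epochs, then over electrodes."""
    mask = (epochs.labels["response_type"] == cell).to_numpy()
    if not mask.any():
        raise InsufficientDataError(
            f"no epochs in cell {cell!r}", cell_counts={cell: 0}
        )
    idx = [epochs.ch_names.index(e) for e in electrodes]
    return epochs.epochs[mask][:, idx, :].mean(axis=(0, 1))


def measure_component(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    spec: ComponentSpec,
    participant: object = 0,
    response_type: str = "",
    unit: str = "uV",
    n_trials: int = 0,
) -> ComponentMeasure:
    """Peak-anchored mean amplitude (and peak latency) of one waveform."""
    in_win = (times_ms >= spec.window_ms[0]) & (times_ms <= spec.window_ms[1])
    if not in_win.any():
        raise ValueError("window outside the epoch")
    widx = np.flatnonzero(in_win)
    seg = waveform[widx]
    local = int(np.argmax(seg) if spec.polarity == "positive" else np.argmin(seg))
    peak = int(widx[local])
    if spec.wide:
        lo, hi = peak - 20, peak + 20
    else:
        lo, hi = peak - spec.halfwidth_samples, peak + spec.halfwidth_samples + 1
    lo, hi = max(lo, 0), min(hi, len(waveform))
    return ComponentMeasure(
        participant=participant,
        component=spec.name,
        response_type=response_type,
        amplitude=float(waveform[lo:hi].mean()),
        unit=unit,
        peak_latency_ms=float(times_ms[peak]),
        n_trials=n_trials,
    )


def build_component_table(
    epochsets: Mapping[tuple[str, bool], EpochSet],
    specs: Sequence[ComponentSpec] = DEFAULT_COMPONENTS,
    min_trials: Optional[Mapping[str, int]] = None,
    participant: object = 0,
    response_types: Sequence[str] = RESPONSE_TYPES_4,
) -> pd.DataFrame:
    """One amplitude/latency measure per component × response type.

    ``epochsets`` maps ``(lock, use_csd)`` to the matching :class:`EpochSet`
    (CSD epochs in µV/cm², untransformed in µV).  A participant failing a
    component's minimum per-cell trial count is flagged ``excluded`` for that
    component (amplitudes NaN) but retained elsewhere.
    """
    if min_trials is None:
        min_trials = DEFAULT_MIN_TRIALS
    rows = []
    for spec in specs:
        key = (spec.lock, spec.use_csd)
        if key not in epochsets:
            raise KeyError(f"no epoch set for lock={spec.lock}, csd={spec.use_csd}")
        eps = epochsets[key]
        counts = {
            rt: int((eps.labels["response_type"] == rt).sum())
            for rt in response_types
        }
        need = min_trials.get(spec.name, 1)
        excluded = any(c < need for c in counts.values())
        for rt in response_types:
            if excluded:
                rows.append(
                    ComponentMeasure(
                        participant, spec.name, rt, np.nan, eps.unit, np.nan,
                        counts[rt], excluded=True,
                    )
                )
                continue
            wf = average_waveform(eps, rt, spec.electrodes)
            m = measure_component(
                wf, eps.times_ms, spec,
                participant=participant, response_type=rt,
                unit=eps.unit, n_trials=counts[rt],
            )
            rows.append(m)
    return pd.DataFrame([vars(m) for m in rows])
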