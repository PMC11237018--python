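"""Inferential layer: 2×2 repeated-measures ANOVA, Tukey-adjusted post-hoc
contrasts and paired t-tests with Cohen's d.

The design is fully within-subject with two two-level factors (inhibition
type × accuracy), so every effect has one numerator degree of freedom, no
sphericity correction applies, and each effect's F equals the squared paired
t statistic of the corresponding difference scores.  Partial eta squared is
``SS_effect / (SS_effect + SS_error_effect)``.  No multiple-comparison alpha
adjustment is applied across the test battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "AnovaResult",
    "Contrast",
    "rm_anova_2x2",
    "posthoc_tukey",
    "paired_t",
]

FACTOR_A = "accuracy"  # success vs error
FACTOR_B = "condition"  # MI vs IS


@dataclass
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    cell_means: pd.DataFrame  # condition, accuracy, mean, sem, n
    n_complete: int
    dropped: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(effect=k, F=e.F, df1=e.df1, df2=e.df2, p=e.p,
                     partial_eta_sq=e.partial_eta_sq)
                for k, e in self.effects.items()
            ]
        )


@dataclass
class Contrast:
    cell_a: tuple
    cell_b: tuple
    mean_diff: float
    t: float
    df: int
    p: float
    cohen_d: float
    adjusted: bool  # True when Tukey-adjusted over the four cells
    sided: str = "two"


def _complete_cases(table: pd.DataFrame, value: str):
    """Pivot a long (participant × condition × accuracy) table to an
    n × 4 complete-case cell matrix."""
    wide = table.pivot_table(
        index="participant", columns=[FACTOR_B, FACTOR_A], values=value,
        aggfunc="first",
    )
    cells = [("MI", "success"), ("MI", "error"), ("IS", "success"), ("IS", "error")]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cells))
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        warnings.warn(f"dropping incomplete participants: {dropped}")
    return complete, cells, dropped


def rm_anova_2x2(table: pd.DataFrame, value: str = "value") -> AnovaResult:
    """Within-subject 2×2 ANOVA on a long table.

    Expects columns ``participant``, ``condition``, ``accuracy`` and the
    value column.  Participants missing any cell are dropped (complete-case).
    Sums of squares are computed explicitly with subject as a random factor;
    each effect is tested against its own effect × subject interaction.
    """
    complete, cells, dropped = _complete_cases(table, value)
    n = len(complete)
    if n < 3:
        raise ValueError(f"need >= 3 complete cases, have {n}")
    Y = complete.to_numpy(float)  # (n, 4) in cell order MI-s, MI-e, IS-s, IS-e
    a_level = np.array([0, 1, 0, 1])  # accuracy: success=0, error=1
    b_level = np.array([0, 0, 1, 1])  # condition: MI=0, IS=1

    grand = Y.mean()
    subj = Y.mean(axis=1)
    m_a = np.array([Y[:, a_level == a].mean() for a in (0, 1)])
    m_b = np.array([Y[:, b_level == b].mean() for b in (0, 1)])
    m_ab = np.array([[Y[:, (a_level == a) & (b_level == b)].mean()
                      for b in (0, 1)] for a in (0, 1)])
    m_ia = np.stack([Y[:, a_level == a].mean(axis=1) for a in (0, 1)], axis=1)
    m_ib = np.stack([Y[:, b_level == b].mean(axis=1) for b in (0, 1)], axis=1)

    ss_a = n * 2 * ((m_a - grand) ** 2).sum()
    ss_b = n * 2 * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = 2 * ((m_ia - m_a[None, :] - subj[:, None] + grand) ** 2).sum()
    ss_bs = 2 * ((m_ib - m_b[None, :] - subj[:, None] + grand) ** 2).sum()
    ss_abs = 0.0
    for i in range(n):
        for j in range(4):
            a, b = a_level[j], b_level[j]
            resid = (
                Y[i, j] - m_ab[a, b] - m_ia[i, a] - m_ib[i, b]
                + m_a[a] + m_b[b] + subj[i] - grand
            )
            ss_abs += resid**2

    df2 = n - 1
    effects = {}
    for name, ss_eff, ss_err in (
        ("accuracy", ss_a, ss_as),
        ("condition", ss_b, ss_bs),
        ("interaction", ss_ab, ss_abs),
    ):
        if ss_err <= 0:
            F = 0.0 if ss_eff == 0 else np.inf
        else:
            F = (ss_eff / 1.0) / (ss_err / df2)
        p = float(sps.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        effects[name] = EffectResult(
            F=float(F), df1=1, df2=df2, p=p, partial_eta_sq=float(eta),
            ss_effect=float(ss_eff), ss_error=float(ss_err),
        )

    cm = []
    for j, (cond, acc) in enumerate(cells):
        col = Y[:, j]
        cm.append(
            dict(condition=cond, accuracy=acc, mean=col.mean(),
                 sem=col.std(ddof=1) / np.sqrt(n), n=n)
        )
    return AnovaResult(
        effects=effects, cell_means=pd.DataFrame(cm), n_complete=n, dropped=dropped
    )


def posthoc_tukey(table: pd.DataFrame, value: str = "value") -> list[Contrast]:
    """All six pairwise cell contrasts with studentized-range adjustment.

    Within-subject analogue of Tukey's HSD: each pair is tested with a paired
    t statistic and referred to the studentized-range distribution with
    k = 4 means (q = √2·|t|), which keeps the family-wise error across the
    four cells controlled while respecting the pairing.
    """
    complete, cells, _ = _complete_cases(table, value)
    n = len(complete)
    if n < 3:
        raise ValueError(f"need >= 3 complete cases, have {n}")
    Y = complete.to_numpy(float)
    out = []
    for i, j in combinations(range(4), 2):
        d = Y[:, i] - Y[:, j]
        sd = d.std(ddof=1)
        md = d.mean()
        if sd == 0:
            t = 0.0 if md == 0 else np.inf * np.sign(md)
            warnings.warn("zero-variance contrast")
        else:
            t = md / (sd / np.sqrt(n))
        q = np.sqrt(2.0) * abs(t)
        p = float(sps.studentized_range.sf(q, k=4, df=n - 1)) if np.isfinite(q) else 0.0
        out.append(
            Contrast(
                cell_a=cells[i], cell_b=cells[j], mean_diff=float(md),
                t=float(t), df=n - 1, p=min(p, 1.0),
                cohen_d=float(md / sd) if sd > 0 else np.nan,
                adjusted=True,
            )
        )
    return out


def paired_t(
    a: Sequence[float],
    b: Optional[Sequence[float]] = None,
    sided: str = "two",
    direction: str = "greater",
) -> Contrast:
    """Paired t-test (against zero when ``b`` is omitted) with Cohen's d.

    ``sided='one'`` tests the stated ``direction`` of ``a − b``.  Cohen's d is
    mean(diff)/sd(diff).  Zero-variance differences yield p of 0 or 1 by the
    sign of the mean difference, with a warning.
    """
    a = np.asarray(a, float)
    d = a - np.asarray(b, float) if b is not None else a
    n = len(d)
    if b is not None and len(np.asarray(b)) != n:
        raise ValueError("paired samples must have equal length")
    md, sd = d.mean(), d.std(ddof=1)
    df = n - 1
    if sd == 0:
        warnings.warn("zero variance of differences")
        if md == 0:
            t, p = 0.0, 1.0
        else:
            t = np.inf * np.sign(md)
            good = (md > 0) == (direction == "greater") or sided == "two"
            p = 0.0 if good else 1.0
        return Contrast((), (), float(md), float(t), df, p, np.nan, False,
                        sided=sided)
    t = md / (sd / np.sqrt(n))
    if sided == "two":
        p = 2.0 * sps.t.sf(abs(t), df)
    else:
        p = sps.t.sf(t, df) if direction == "greater" else sps.t.cdf(t, df)
    return Contrast(
        cell_a=(), cell_b=(), mean_diff=float(md), t=float(t), df=df,
        p=float(p), cohen_d=float(md / sd), adjusted=False, sided=sided,
    )
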