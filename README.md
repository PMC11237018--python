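# eightart

Simulation and analysis pipeline for the **eight-alternative response task
(8ART)** — a speeded choice task in which eight shapes are mapped to eight
force-sensitive keys and two kinds of inhibition failure can be contrasted
directly:

* **Motor-inhibition (MI) errors** — the target usually appears beneath its
  matching shape, inducing a prepotent location-driven response; on the rare
  incongruent trials (every third to fifth trial) that tendency must be
  overridden, and pressing the *location* key instead of the target's key is
  an MI error.
* **Interference-suppression (IS) errors** — every shape has a mirrored
  counterpart; targets never appear beneath their own or their mirror's
  square, so each trial carries a perceptually similar distractor, and
  pressing the *distractor's* key is an IS error.

The package implements the complete analysis chain for this paradigm and a
synthetic-data generator that lets every stage be validated end to end by
**parameter recovery**: the generator's defaults encode known group-level
cell means, and the pipeline has to measure them back out of raw force
traces and continuous EEG.

## What is implemented

| stage | module | content |
| --- | --- | --- |
| trial design | `eightart.task` | MI/IS sequence generation under the gap and placement constraints, constraint validator, TSV round trip |
| synthesis | `eightart.simulate` | per-trial 8-key force traces (gamma pulses crossing 40 cN exactly at the drawn RT), lognormal RT cells with post-error slowing / pre-error speeding, continuous EEG (ERP templates, lateralised motor ramp at C3′/C4′, 1/f noise, 50 Hz line noise, blinks) |
| preprocessing | `eightart.preprocess` | 50 Hz notch, averaged-mastoid re-reference, regression-based ocular correction, half-open epoching with baseline correction, ±100 µV rejection, spherical-spline current source density (µV/cm²) |
| behaviour | `eightart.behaviour` | 40 cN response detection with tie-breaking, nine-way trial classification, per-cell summaries (response rates, median RT, multiple responses, corrections, peak force), PES / pre-error speeding / post-response accuracy |
| ERP | `eightart.erp` | peak-anchored mean amplitudes (±2 samples around the peak) for P1, N1, P2, N2, frontal/parietal P3, Ne/c, Pe/c with per-component minimum trial counts |
| LRP | `eightart.lrp` | hand-balanced C3′/C4′ difference waves, 30 Hz low-pass, 50 % fractional-peak onsets with 5-sample persistence, leave-one-out jackknife with Smulders retrieval `o_i = n·J̄ − (n−1)·J_i` |
| statistics | `eightart.stats` | 2×2 repeated-measures ANOVA (explicit sums of squares, partial η²), within-subject Tukey-adjusted contrasts, one/two-sided paired t with Cohen's d |
| orchestration | `eightart.pipeline`, `eightart.cli` | seeded multi-participant studies, results bundles, `eightart` command line |

File formats: trial/summary tables as TSV, generation parameters as YAML,
recordings and epoch sets as HDF5, continuous EEG also as a BrainVision
triplet (`.vhdr/.vmrk/.eeg`, read back through mne).

## Worked example

```python
from eightart.pipeline import behaviour_group_study
from eightart.stats import rm_anova_2x2, paired_t

cells, seq = behaviour_group_study(n_participants=30, base_seed=1)
print(cells.groupby(["condition", "accuracy"])["median_rt_ms"].mean().round(1))

rt = cells.rename(columns={"median_rt_ms": "value"})
print(rm_anova_2x2(rt).summary().to_string(index=False))

pes_is = seq[seq.condition == "IS"]["pes_ms"]
t = paired_t(pes_is, sided="one")
print(f"IS post-error slowing: {t.mean_diff:.1f} ms, "
      f"t({t.df}) = {t.t:.2f}, p = {t.p:.2g}")
```

Output:

```
condition  accuracy
IS         error       789.1
           success     768.1
MI         error       541.6
           success     757.4
Name: median_rt_ms, dtype: float64
     effect           F  df1  df2            p  partial_eta_sq
   accuracy 1619.664258    1   29 5.332793e-27        0.982410
  condition 1215.676162    1   29 3.149467e-25        0.976701
interaction 1409.017962    1   29 3.875452e-26        0.979833
IS post-error slowing: 30.2 ms, t(29) = 7.07, p = 4.5e-08
```

Reading: MI errors are fast impulsive location presses (median ≈ 539 ms),
IS errors are *slower* than correct responses (≈ 789 vs 766 ms) because the
distractor prolongs response selection — hence the strong accuracy ×
condition interaction — and errors are followed by measurable slowing on the
next trial.

An EEG example (12 participants, reduced 11-channel montage) is run by
`eightart.pipeline.eeg_group_study`, which returns the parietal P3 cell
amplitudes and the jackknifed response-locked LRP onsets per response type.

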