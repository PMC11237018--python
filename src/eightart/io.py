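"""File formats: TSV trial/summary tables, HDF5 containers for recordings and
epochs, YAML round-trips for generation parameters, and BrainVision export.

BrainVision triplets (.vhdr/.vmrk/.eeg) are written as IEEE float32
multiplexed µV with stimulus/response markers carrying the trial index, and
read back through mne.
"""

from __future__ import annotations

import io
import os
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocess import EpochSet
from .simulate import (
    BehaviourParams,
    CellParams,
    ConditionParams,
    EegParams,
    EEGRecording,
    LrpGenParams,
)

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_recording_h5",
    "read_recording_h5",
    "write_epochs_h5",
    "read_epochs_h5",
    "write_brainvision",
    "read_brainvision",
    "behaviour_params_to_yaml",
    "behaviour_params_from_yaml",
]


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def write_recording_h5(rec: EEGRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32), compression="gzip")
        f.attrs["sfreq"] = rec.sfreq
        f.attrs["ch_names"] = list(rec.ch_names)
        f.attrs["ch_types"] = [rec.ch_types[c] for c in rec.ch_names]
        g = f.create_group("events")
        for col in ("sample", "trial_index"):
            g.create_dataset(col, data=rec.events[col].to_numpy())
        g.create_dataset(
            "kind", data=np.array(rec.events["kind"], dtype=h5py.string_dtype())
        )


def read_recording_h5(path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        ch_names = tuple(str(c) for c in f.attrs["ch_names"])
        ch_types = {c: str(t) for c, t in zip(ch_names, f.attrs["ch_types"])}
        events = pd.DataFrame(
            {
                "sample": f["events/sample"][()],
                "kind": [k.decode() for k in f["events/kind"][()]],
                "trial_index": f["events/trial_index"][()],
            }
        )
        return EEGRecording(
            ch_names=ch_names,
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            events=events.sort_values("sample", kind="stable").reset_index(drop=True),
            ch_types=ch_types,
        )


def write_epochs_h5(eps: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=eps.epochs.astype(np.float32), compression="gzip")
        f.create_dataset("times_ms", data=eps.times_ms)
        f.attrs["lock"] = eps.lock
        f.attrs["sfreq"] = eps.sfreq
        f.attrs["unit"] = eps.unit
        f.attrs["ch_names"] = list(eps.ch_names)
        f.attrs["labels_json"] = eps.labels.to_json(orient="table")
        f.attrs["rejection_json"] = eps.rejection_log.to_json(orient="table")


def read_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            lock=str(f.attrs["lock"]),
            ch_names=tuple(str(c) for c in f.attrs["ch_names"]),
            epochs=f["epochs"][()],
            times_ms=f["times_ms"][()],
            sfreq=float(f.attrs["sfreq"]),
            labels=pd.read_json(io.StringIO(f.attrs["labels_json"]), orient="table"),
            rejection_log=pd.read_json(
                io.StringIO(f.attrs["rejection_json"]), orient="table"
            ),
            unit=str(f.attrs["unit"]),
        )


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def write_brainvision(rec: EEGRecording, basepath) -> Path:
    """Write a .vhdr/.vmrk/.eeg triplet (IEEE float32, multiplexed, µV)."""
    base = Path(basepath)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch = len(rec.ch_names)
    interval_us = 1e6 / rec.sfreq
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.ch_names, 1):
        lines.append(f"Ch{i}={ch},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    k = 2
    for row in rec.events.itertuples(index=False):
        mtype = "Stimulus" if row.kind == "stimulus" else "Response"
        code = ("S" if row.kind == "stimulus" else "R") + str(int(row.trial_index))
        mlines.append(f"Mk{k}={mtype},{code},{int(row.sample) + 1},1,0")
        k += 1
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major
    return vhdr


def read_brainvision(vhdr_path) -> EEGRecording:
    """Read a BrainVision triplet into an :class:`EEGRecording` (µV)."""
    import mne

    mne.set_log_level("ERROR")
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6
    rows = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        parts = desc.split("/")
        code = parts[-1].strip()
        if not code or code[0] not in "SR" or not code[1:].strip().isdigit():
            continue
        rows.append(
            dict(
                sample=int(round(onset * raw.info["sfreq"])),
                kind="stimulus" if code[0] == "S" else "response",
                trial_index=int(code[1:]),
            )
        )
    events = (
        pd.DataFrame(rows, columns=["sample", "kind", "trial_index"])
        .sort_values("sample", kind="stable")
        .reset_index(drop=True)
    )
    return EEGRecording(
        ch_names=tuple(raw.ch_names),
        data=data.astype(np.float32),
        sfreq=float(raw.info["sfreq"]),
        events=events,
    )


# ---------------------------------------------------------------------------
# YAML parameter round-trip
# ---------------------------------------------------------------------------

def _cellkey(cell) -> str:
    return f"{cell[0]}.{cell[1]}"


def behaviour_params_to_yaml(params: BehaviourParams, path=None) -> str:
    d = {
        "cells": {_cellkey(k): asdict(v) for k, v in params.cells.items()},
        "congruent": asdict(params.congruent),
        "conditions": {k: asdict(v) for k, v in params.conditions.items()},
        "rt_limit_ms": params.rt_limit_ms,
        "force_threshold_cN": params.force_threshold_cN,
    }
    text = yaml.safe_dump(d, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def behaviour_params_from_yaml(source) -> BehaviourParams:
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        source = Path(source).read_text()
    d = yaml.safe_load(source)
    return BehaviourParams(
        cells={
            tuple(k.split(".")): CellParams(**v) for k, v in d["cells"].items()
        },
        congruent=CellParams(**d["congruent"]),
        conditions={k: ConditionParams(**v) for k, v in d["conditions"].items()},
        rt_limit_ms=d["rt_limit_ms"],
        force_threshold_cN=d["force_threshold_cN"],
    )
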