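"""HDF5 containers for simulated studies, epochs and head models.

Study layout::

    /subject_00/data      channels x samples (uV)
    /subject_00/events    compound table (onset_sample, condition,
                          trial_type, rt_ms)
    /head/{sensor_positions,source_positions,gain}
    attrs: sfreq_hz, ch_names, config (JSON), ground_truth (JSON)

Epoch files store the trials x channels x samples tensor with its time axis,
labels, subject ids and rejection bookkeeping. Event tables can also be
exported as CSV.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .headmodel import HeadModel
from .preprocess import EpochSet
from .simulate import (EffectSpec, NoiseSpec, RTModel, StudyConfig,
                       SyntheticStudy)

__all__ = ["save_study", "load_study", "save_epochs", "load_epochs",
           "save_head", "load_head", "events_to_csv"]

_EVENT_DTYPE = np.dtype([("onset_sample", "i8"), ("condition", "S8"),
                         ("trial_type", "S8"), ("rt_ms", "f8")])


def _events_to_struct(df: pd.DataFrame) -> np.ndarray:
    arr = np.empty(len(df), dtype=_EVENT_DTYPE)
    arr["onset_sample"] = df["onset_sample"].to_numpy()
    arr["condition"] = df["condition"].astype("S8").to_numpy()
    arr["trial_type"] = df["trial_type"].astype("S8").to_numpy()
    arr["rt_ms"] = df.get("rt_ms", pd.Series(np.nan, index=df.index)).to_numpy()
    return arr


def _struct_to_events(arr: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "onset_sample": arr["onset_sample"].astype(int),
        "condition": arr["condition"].astype(str),
        "trial_type": arr["trial_type"].astype(str),
        "rt_ms": arr["rt_ms"].astype(float),
    })


def _write_head(grp: h5py.Group, head: HeadModel) -> None:
    grp.create_dataset("sensor_positions", data=head.sensor_positions)
    grp.create_dataset("source_positions", data=head.source_positions)
    grp.create_dataset("gain", data=head.gain)
    grp.attrs["spread"] = head.spread


def _read_head(grp: h5py.Group) -> HeadModel:
    return HeadModel(
        sensor_positions=grp["sensor_positions"][()],
        source_positions=grp["source_positions"][()],
        gain=grp["gain"][()],
        spread=float(grp.attrs.get("spread", 0.6)),
    )


def save_head(head: HeadModel, path: str) -> None:
    with h5py.File(path, "w") as f:
        _write_head(f.create_group("head"), head)


def load_head(path: str) -> HeadModel:
    with h5py.File(path, "r") as f:
        return _read_head(f["head"])


def save_study(study: SyntheticStudy, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sfreq_hz"] = study.sfreq_hz
        f.attrs["ch_names"] = json.dumps(study.ch_names)
        f.attrs["config"] = study.config.to_json()
        f.attrs["ground_truth"] = json.dumps(study.ground_truth)
        for k, subj in enumerate(study.subject_ids()):
            g = f.create_group(f"subject_{k:02d}")
            g.attrs["subject_id"] = subj
            g.create_dataset("data", data=study.recordings[k],
                             compression="gzip", compression_opts=1)
            g.create_dataset("events", data=_events_to_struct(study.events[k]))
        _write_head(f.create_group("head"), study.head)


def _config_from_json(blob: str) -> StudyConfig:
    d = json.loads(blob)
    d["noise"] = NoiseSpec(**d["noise"])
    d["rt_model"] = RTModel(**d["rt_model"])
    d["effects"] = [
        EffectSpec(**{**e,
                      "window_ms": tuple(e["window_ms"]),
                      "source_indices": (tuple(e["source_indices"])
                                         if e["source_indices"] is not None
                                         else None),
                      "anchor": (tuple(e["anchor"])
                                 if e["anchor"] is not None else None)})
        for e in d["effects"]
    ]
    d["epoch_ms"] = tuple(d["epoch_ms"])
    return StudyConfig(**d)


def load_study(path: str) -> SyntheticStudy:
    with h5py.File(path, "r") as f:
        keys = sorted(k for k in f if k.startswith("subject_"))
        recordings = [f[k]["data"][()] for k in keys]
        events = [_struct_to_events(f[k]["events"][()]) for k in keys]
        return SyntheticStudy(
            recordings=recordings,
            events=events,
            sfreq_hz=float(f.attrs["sfreq_hz"]),
            ch_names=json.loads(f.attrs["ch_names"]),
            head=_read_head(f["head"]),
            config=_config_from_json(f.attrs["config"]),
            ground_truth=json.loads(f.attrs["ground_truth"]),
        )


def save_epochs(ep: EpochSet, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data, compression="gzip",
                         compression_opts=1)
        f.create_dataset("times_ms", data=ep.times_ms)
        f.create_dataset("labels", data=ep.labels)
        f.create_dataset("subject_ids",
                         data=np.asarray(ep.subject_ids, dtype="S16"))
        if ep.rt_ms is not None:
            f.create_dataset("rt_ms", data=ep.rt_ms)
        f.attrs["sfreq_hz"] = ep.sfreq_hz
        f.attrs["ch_names"] = json.dumps(list(ep.ch_names))
        f.attrs["n_rejected"] = json.dumps(ep.n_rejected, default=str)


def load_epochs(path: str) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times_ms=f["times_ms"][()],
            labels=f["labels"][()].astype(int),
            subject_ids=f["subject_ids"][()].astype(str),
            sfreq_hz=float(f.attrs["sfreq_hz"]),
            ch_names=json.loads(f.attrs["ch_names"]),
            rt_ms=f["rt_ms"][()] if "rt_ms" in f else None,
            n_rejected=json.loads(f.attrs.get("n_rejected", "{}")),
        )


def events_to_csv(events: pd.DataFrame, path: str) -> None:
    events[["onset_sample", "condition", "trial_type", "rt_ms"]].to_csv(
        path, index=False)
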