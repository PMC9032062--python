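"""Persistence: HDF5 containers for signals/models, CSV for events/metrics."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import Acquisition, RotationalEvent

__all__ = [
    "save_cohort",
    "load_cohort",
    "events_to_frame",
    "save_events",
    "load_events",
    "save_model_weights",
    "load_model_weights",
]


def save_cohort(path, cohort) -> None:
    """Write acquisitions + ground-truth events, one HDF5 group each."""
    with h5py.File(path, "w") as f:
        for i, (acq, events) in enumerate(cohort):
            g = f.create_group(f"acq{i:05d}")
            g.create_dataset("signal", data=acq.signal, compression="gzip")
            g.attrs["fs"] = acq.fs
            g.attrs["kind"] = acq.kind
            g.attrs["patient_id"] = acq.patient_id
            g.attrs["acq_index"] = acq.acq_index
            ev = np.array(
                [
                    (e.t_start, e.t_end, e.chirality == "clockwise",
                     e.n_rotations, e.ring_index)
                    for e in events
                ],
                dtype=float,
            ).reshape(-1, 5)
            g.create_dataset("events", data=ev)


def load_cohort(path):
    cohort = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            acq = Acquisition(
                g["signal"][...],
                float(g.attrs["fs"]),
                str(g.attrs["kind"]),
                patient_id=str(g.attrs["patient_id"]),
                acq_index=int(g.attrs["acq_index"]),
            )
            events = [
                RotationalEvent(
                    row[0], row[1],
                    "clockwise" if row[2] else "counterclockwise",
                    int(row[3]), int(row[4]),
                )
                for row in g["events"][...]
            ]
            cohort.append((acq, events))
    return cohort


def events_to_frame(records) -> pd.DataFrame:
    """Columnar event table: (acquisition id, interval, chirality, ...)."""
    rows = []
    for acq_id, events in records:
        for e in events:
            rows.append(
                {
                    "acq_id": acq_id,
                    "t_start_ms": e.t_start,
                    "t_end_ms": e.t_end,
                    "chirality": e.chirality,
                    "n_rotations": e.n_rotations,
                    "ring_index": e.ring_index,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["acq_id", "t_start_ms", "t_end_ms", "chirality",
                 "n_rotations", "ring_index"],
    )


def save_events(path, records) -> None:
    events_to_frame(records).to_csv(path, index=False)


def load_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model_weights(path, model) -> None:
    np.savez(Path(path), *model.get_weights())


def load_model_weights(path, model) -> None:
    with np.load(Path(path)) as z:
        model.set_weights([z[k] for k in z.files])
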