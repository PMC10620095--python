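"""File-format helpers: tables as CSV/Parquet, spikes and embeddings as HDF5."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .selectivity import UnitRecording


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def save_units_h5(path, units: list[UnitRecording]) -> None:
    """One group per unit; per-trial event-time datasets in seconds."""
    with h5py.File(path, "w") as f:
        for u in units:
            g = f.create_group(f"unit_{u.unit_id:05d}")
            g.attrs["unit_id"] = u.unit_id
            g.attrs["unit_class"] = u.unit_class
            g.attrs["region"] = u.region or ""
            g.attrs["coords_um"] = np.asarray(u.coords_um, float)
            ss = g.create_group("ss")
            for tid, t in u.spikes.items():
                ss.create_dataset(str(tid), data=np.asarray(t, float))
            if u.cs_spikes is not None:
                cs = g.create_group("cs")
                for tid, t in u.cs_spikes.items():
                    cs.create_dataset(str(tid), data=np.asarray(t, float))


def load_units_h5(path) -> list[UnitRecording]:
    units = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            spikes = {int(k): g["ss"][k][()] for k in g["ss"]}
            cs = ({int(k): g["cs"][k][()] for k in g["cs"]}
                  if "cs" in g else None)
            units.append(UnitRecording(
                unit_id=int(g.attrs["unit_id"]),
                spikes=spikes, cs_spikes=cs,
                coords_um=tuple(g.attrs["coords_um"]),
                region=str(g.attrs["region"]) or None,
                unit_class=str(g.attrs["unit_class"]),
            ))
    return units


def save_embeddings_h5(path, session) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["step_s"] = session.step_s
        f.attrs["true_lag"] = session.true_lag
        f.create_dataset("frame_t", data=session.frame_t)
        f.create_dataset("trial_index", data=session.trial_index)
        f.create_dataset("trial_type",
                         data=np.asarray(session.trial_type, dtype="S"))
        f.create_dataset("embeddings", data=session.embeddings)
        f.create_dataset("counts", data=session.counts)
        f.create_dataset("true_weights", data=session.true_weights)


def load_embeddings_h5(path):
    from .synthetic import EmbeddingSession
    with h5py.File(path, "r") as f:
        return EmbeddingSession(
            step_s=float(f.attrs["step_s"]),
            frame_t=f["frame_t"][()],
            trial_index=f["trial_index"][()],
            trial_type=f["trial_type"][()].astype(str),
            embeddings=f["embeddings"][()],
            counts=f["counts"][()],
            true_weights=f["true_weights"][()],
            true_lag=int(f.attrs["true_lag"]),
        )
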