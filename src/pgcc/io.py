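"""File formats: list-mode events (TSV and HDF5), images, configs.

There is no community standard for Compton-camera list-mode data, so the
package defines one canonical record — per event: module index, crystal
indices, interaction count, per-interaction deposited energy [MeV] and
(x, y, z) position [cm], and the trigger timestamp [us from run start] —
carried by two containers:

* a plain-text TSV dialect (one event per row, fixed three interaction
  slots, label columns included when labels exist) for fixtures and
  interchange;
* an HDF5 layout (one dataset per field under ``/events`` and ``/labels``,
  provenance as JSON in a root attribute) for bulk data.

Both round-trip exactly through their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .events import EventLabels, ListModeDataset
from .recon import EnergyWindow, ImageGrid, PGImage

__all__ = [
    "write_listmode_tsv", "read_listmode_tsv",
    "write_listmode_h5", "read_listmode_h5",
    "write_listmode", "read_listmode",
    "save_image", "load_image",
    "load_yaml_config",
]

_EVENT_FIELDS = ["n_interactions", "module", "timestamp"]


def _to_frame(data: ListModeDataset) -> pd.DataFrame:
    cols = {
        "n_interactions": data.n_interactions,
        "module": data.module,
        "timestamp": data.timestamp,
    }
    for k in range(3):
        cols[f"e{k + 1}"] = data.energies[:, k]
        for a, ax in enumerate("xyz"):
            cols[f"{ax}{k + 1}"] = data.positions[:, k, a]
        cols[f"crystal{k + 1}"] = data.crystals[:, k]
    if data.labels is not None:
        lab = data.labels
        cols["label_category"] = lab.category
        for k in range(3):
            cols[f"label_order{k + 1}"] = lab.order[:, k]
        cols["label_pair1"] = lab.ds_pair[:, 0]
        cols["label_pair2"] = lab.ds_pair[:, 1]
    return pd.DataFrame(cols)


def _from_frame(df: pd.DataFrame, provenance: dict) -> ListModeDataset:
    n = len(df)
    energies = np.column_stack([df[f"e{k + 1}"] for k in range(3)])
    positions = np.stack(
        [np.column_stack([df[f"{ax}{k + 1}"] for ax in "xyz"]) for k in range(3)],
        axis=1,
    )
    crystals = np.column_stack([df[f"crystal{k + 1}"] for k in range(3)])
    labels = None
    if "label_category" in df.columns:
        labels = EventLabels(
            df["label_category"].to_numpy(),
            np.column_stack([df[f"label_order{k + 1}"] for k in range(3)]),
            np.column_stack([df["label_pair1"], df["label_pair2"]]),
        )
    return ListModeDataset(
        df["n_interactions"].to_numpy(), energies, positions,
        df["module"].to_numpy(), crystals, df["timestamp"].to_numpy(),
        labels=labels, provenance=provenance,
    )


def write_listmode_tsv(data: ListModeDataset, path) -> None:
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# provenance: {json.dumps(data.provenance, default=str)}\n")
        _to_frame(data).to_csv(f, sep="\t", index=False, float_format="%.6f")


def read_listmode_tsv(path) -> ListModeDataset:
    path = Path(path)
    provenance = {}
    with open(path) as f:
        first = f.readline()
        if first.startswith("# provenance:"):
            provenance = json.loads(first.split(":", 1)[1])
            df = pd.read_csv(f, sep="\t")
        else:
            f.seek(0)
            df = pd.read_csv(f, sep="\t")
    return _from_frame(df, provenance)


def write_listmode_h5(data: ListModeDataset, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("events")
        g.create_dataset("n_interactions", data=data.n_interactions)
        g.create_dataset("energies", data=data.energies)
        g.create_dataset("positions", data=data.positions)
        g.create_dataset("module", data=data.module)
        g.create_dataset("crystals", data=data.crystals)
        g.create_dataset("timestamp", data=data.timestamp)
        if data.labels is not None:
            l = f.create_group("labels")
            l.create_dataset("category", data=data.labels.category)
            l.create_dataset("order", data=data.labels.order)
            l.create_dataset("ds_pair", data=data.labels.ds_pair)
        f.attrs["provenance"] = json.dumps(data.provenance, default=str)


def read_listmode_h5(path) -> ListModeDataset:
    with h5py.File(path, "r") as f:
        g = f["events"]
        labels = None
        if "labels" in f:
            l = f["labels"]
            labels = EventLabels(l["category"][...], l["order"][...], l["ds_pair"][...])
        return ListModeDataset(
            g["n_interactions"][...], g["energies"][...], g["positions"][...],
            g["module"][...], g["crystals"][...], g["timestamp"][...],
            labels=labels,
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )


def write_listmode(data: ListModeDataset, path) -> None:
    """Dispatch on extension: .tsv/.txt for text, .h5/.hdf5 for HDF5."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tsv", ".txt"):
        write_listmode_tsv(data, path)
    elif suffix in (".h5", ".hdf5"):
        write_listmode_h5(data, path)
    else:
        raise ValueError(f"unsupported list-mode extension {suffix!r}")


def read_listmode(path) -> ListModeDataset:
    suffix = Path(path).suffix.lower()
    if suffix in (".tsv", ".txt"):
        return read_listmode_tsv(path)
    if suffix in (".h5", ".hdf5"):
        return read_listmode_h5(path)
    raise ValueError(f"unsupported list-mode extension {suffix!r}")


def save_image(image: PGImage, path) -> None:
    """Raw 3D array (.npy) plus a JSON sidecar with grid metadata."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), image.data)
    meta = {
        "grid": {k: getattr(image.grid, k)
                 for k in ("nx", "ny", "nz", "dx", "dy", "dz", "x0", "y0", "z0")},
        "n_events": image.n_events,
        "n_dropped": image.n_dropped,
        "window": [image.window.lo, image.window.hi] if image.window else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_image(path) -> PGImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npy"))
    window = EnergyWindow(*meta["window"]) if meta.get("window") else None
    return PGImage(grid=ImageGrid(**meta["grid"]), data=data,
                   n_events=meta.get("n_events", 0),
                   n_dropped=meta.get("n_dropped", 0), window=window)


def load_yaml_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}
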