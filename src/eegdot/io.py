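"""Serialization helpers: YAML geometry/layout schema, CSV exports, PLY
surfaces and an .npz container for forward matrices.

YAML schema (documented by example)::

    head:
      shell_radii: [80.0, 82.0, 87.0, 92.0]
      conductivities: [1.0, 5.0, 0.0125, 1.0]
      optical_props: {750: {mua: 0.0178, musp: 1.25}, ...}
    electrodes:            # optional
      labels: [...]
      positions: [[x, y, z], ...]
    optodes:               # optional
      source_positions: [[...]]
      detector_positions: [[...]]
      channels: [[si, di], ...]
      density: regular
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .phantom import ElectrodeArray, HeadModel, OptodeArray, default_patch_frame

__all__ = [
    "head_to_yaml",
    "head_from_yaml",
    "recordings_to_csv",
    "map_to_csv",
    "save_forward_npz",
    "export_ply",
]


def head_to_yaml(path, head: HeadModel, electrodes: ElectrodeArray | None = None,
                 optodes: OptodeArray | None = None):
    doc = {
        "head": {
            "shell_radii": [float(r) for r in head.shell_radii],
            "conductivities": [float(s) for s in head.conductivities],
            "optical_props": {
                float(wl): {k: float(v) for k, v in props.items()}
                for wl, props in head.optical_props.items()
            },
        }
    }
    if electrodes is not None:
        doc["electrodes"] = {
            "labels": list(electrodes.labels),
            "positions": electrodes.positions.tolist(),
        }
    if optodes is not None:
        doc["optodes"] = {
            "source_positions": optodes.source_positions.tolist(),
            "detector_positions": optodes.detector_positions.tolist(),
            "channels": [list(c) for c in optodes.channels],
            "density": optodes.density,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def head_from_yaml(path):
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    h = doc["head"]
    head = HeadModel(
        shell_radii=tuple(h["shell_radii"]),
        conductivities=tuple(h["conductivities"]),
        optical_props={float(k): v for k, v in h["optical_props"].items()},
    )
    out = {"head": head}
    if "electrodes" in doc:
        e = doc["electrodes"]
        out["electrodes"] = ElectrodeArray(
            positions=np.asarray(e["positions"], float), labels=tuple(e["labels"])
        )
    if "optodes" in doc:
        o = doc["optodes"]
        out["optodes"] = OptodeArray(
            source_positions=np.asarray(o["source_positions"], float),
            detector_positions=np.asarray(o["detector_positions"], float),
            channels=tuple(tuple(c) for c in o["channels"]),
            density=o["density"],
            frame=default_patch_frame(),
        )
    return out


def recordings_to_csv(path, data: np.ndarray, fs: float, channel_names=None):
    """Long-format (channel, time, value) CSV of a channels x time array."""
    C, T = data.shape
    names = channel_names or [f"ch{i}" for i in range(C)]
    t = np.arange(T) / fs
    df = pd.DataFrame(
        {
            "channel": np.repeat(names, T),
            "time": np.tile(t, C),
            "value": data.ravel(),
        }
    )
    df.to_csv(path, index=False)


def map_to_csv(path, rmap):
    """(voxel_id, x, y, z, value[, time]) CSV of a reconstruction map."""
    pos = rmap.positions
    if rmap.values.ndim == 1:
        df = pd.DataFrame(
            {"voxel_id": np.arange(pos.shape[0]), "x": pos[:, 0], "y": pos[:, 1],
             "z": pos[:, 2], "value": rmap.values}
        )
    else:
        frames = []
        for j, t in enumerate(rmap.times):
            frames.append(
                pd.DataFrame(
                    {"voxel_id": np.arange(pos.shape[0]), "x": pos[:, 0],
                     "y": pos[:, 1], "z": pos[:, 2],
                     "value": rmap.values[:, j], "time": t}
                )
            )
        df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False)


def save_forward_npz(path, leadfield=None, jacobian=None):
    """Forward matrices with shape/axis metadata in a .npz container."""
    arrays = {}
    if leadfield is not None:
        arrays["leadfield"] = leadfield.matrix
        arrays["leadfield_axes"] = np.array(["electrode", "voxel"])
        arrays["leadfield_n_terms"] = np.array([leadfield.n_terms])
    if jacobian is not None:
        arrays["jacobian"] = jacobian.matrix
        arrays["jacobian_axes"] = np.array(["channel_wavelength", "voxel_chromophore"])
        arrays["jacobian_wavelengths"] = np.asarray(jacobian.wavelengths)
        arrays["jacobian_n_channels"] = np.array([jacobian.n_channels])
    np.savez_compressed(path, **arrays)


def export_ply(path, points: np.ndarray, scalars: np.ndarray | None = None):
    """ASCII PLY point cloud, optionally with a per-vertex scalar."""
    points = np.asarray(points, float)
    n = points.shape[0]
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if scalars is not None:
            fh.write("property float quality\n")
        fh.write("end_header\n")
        for i in range(n):
            row = f"{points[i, 0]:.4f} {points[i, 1]:.4f} {points[i, 2]:.4f}"
            if scalars is not None:
                row += f" {float(scalars[i]):.6g}"
            fh.write(row + "\n")
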