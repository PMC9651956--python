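"""File formats: raster CSV, SHD-style HDF5 event files, cochleogram CSV.

Rasters are written as two-column CSV (id, t_ms) with the channel count
and duration in ``#``-comment header lines.  Batches of rasters with
labels use the Spiking-Heidelberg-Digits HDF5 layout: a ``spikes`` group
with variable-length ``units`` and ``times`` datasets (times in seconds)
plus a ``labels`` dataset.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .encoding import Cochleogram
from .simulate import SpikeRaster


def write_raster_csv(raster: SpikeRaster, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# n_sources={raster.n_sources}\n")
        fh.write(f"# duration_ms={raster.duration}\n")
        fh.write("id,t_ms\n")
        for s, t in zip(raster.sources, raster.times):
            fh.write(f"{s},{t}\n")


def read_raster_csv(path) -> SpikeRaster:
    path = Path(path)
    n_sources = duration = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "n_sources":
                n_sources = int(value)
            elif key.strip() == "duration_ms":
                duration = float(value)
    if n_sources is None or duration is None:
        raise ValueError(f"{path}: missing n_sources/duration_ms header comments")
    df = pd.read_csv(path, comment="#")
    return SpikeRaster(
        df["id"].to_numpy(), df["t_ms"].to_numpy(), n_sources, duration
    )


def write_shd_h5(
    path, rasters: Sequence[SpikeRaster], labels: Sequence[int]
) -> None:
    """Write a batch of rasters in the SHD event-file layout (times in s)."""
    if len(rasters) != len(labels):
        raise ValueError("rasters and labels disagree in length")
    n_channels = rasters[0].n_sources if rasters else 0
    duration = rasters[0].duration if rasters else 0.0
    with h5py.File(path, "w") as f:
        vlen_i = h5py.special_dtype(vlen=np.dtype("int64"))
        vlen_f = h5py.special_dtype(vlen=np.dtype("float64"))
        grp = f.create_group("spikes")
        units = grp.create_dataset("units", (len(rasters),), dtype=vlen_i)
        times = grp.create_dataset("times", (len(rasters),), dtype=vlen_f)
        for k, r in enumerate(rasters):
            units[k] = r.sources
            times[k] = r.times / 1000.0
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        f.attrs["n_channels"] = n_channels
        f.attrs["duration_ms"] = duration


def read_shd_h5(path) -> tuple[list[SpikeRaster], np.ndarray]:
    """Read an SHD-style event file into rasters (ms) and labels."""
    with h5py.File(path, "r") as f:
        units = f["spikes/units"]
        times = f["spikes/times"]
        labels = np.asarray(f["labels"], dtype=np.int64)
        all_units = [np.asarray(u, dtype=np.int64) for u in units]
        all_times = [np.asarray(t, dtype=float) * 1000.0 for t in times]
        n_channels = int(
            f.attrs.get(
                "n_channels",
                1 + max((u.max() for u in all_units if u.size), default=0),
            )
        )
        duration = float(
            f.attrs.get(
                "duration_ms",
                max((t.max() for t in all_times if t.size), default=0.0),
            )
        )
    rasters = [
        SpikeRaster(u, t, n_channels, duration)
        for u, t in zip(all_units, all_times)
    ]
    return rasters, labels


def write_cochleogram(coch: Cochleogram, path) -> None:
    """Matrix as CSV plus a JSON sidecar with the frame period."""
    path = Path(path)
    pd.DataFrame(coch.values).to_csv(path, index=False, header=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "frame_period_ms": coch.frame_period_ms,
                "n_channels": coch.n_channels,
                "n_frames": coch.n_frames,
            }
        )
    )


def read_cochleogram(path) -> Cochleogram:
    path = Path(path)
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Cochleogram(values, frame_period_ms=meta.get("frame_period_ms", 4.0))
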