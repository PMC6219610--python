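"""HDF5 / CSV / JSON containers shared by the pipeline stages.

IQ series are stored one HDF5 group per subject with one complex
dataset per block (timestamp, frame rate and pitch as attributes);
parametric maps live in a parallel layout with kind/units attributes.
Region time series and point clouds travel as CSV, reports as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd

from .doppler_maps import ParametricMap
from .synthetic_data import ExperimentSeries, IQBlock
from .regional_stats import RegionTimeSeries

__all__ = ["save_experiment", "load_experiment", "StoredSeries",
           "save_maps", "load_maps", "save_region_series",
           "load_region_series", "export_tiff", "write_json", "read_json"]


# ---------------------------------------------------------------- IQ series

def save_experiment(path: str | Path, series: list, include_blocks: bool = True,
                    dtype=np.complex64) -> None:
    """Write a cohort to HDF5 (one group per subject, one dataset per block).

    ``series`` elements may be :class:`ExperimentSeries` (blocks are then
    synthesized on the fly) or :class:`StoredSeries`.
    """
    with h5py.File(path, "w") as f:
        for s in series:
            g = f.create_group(f"subjects/{s.subject}")
            g.attrs["group"] = s.group
            g.create_dataset("block_times_min", data=s.block_times_min)
            g.create_dataset("artifact", data=np.asarray(s.artifact, bool))
            g.create_dataset("map_values", data=s.map_values)
            if getattr(s, "events", None):
                g.attrs["events"] = json.dumps(
                    {k: list(v) for k, v in s.events.items()}, sort_keys=True)
            if include_blocks:
                bg = g.create_group("blocks")
                for i, block in s.iter_blocks():
                    d = bg.create_dataset(f"{i:05d}",
                                          data=block.data.astype(dtype))
                    d.attrs["t0"] = block.t0
                    d.attrs["frame_rate"] = block.frame_rate
                    d.attrs["pixel_pitch_axial"] = block.pixel_pitch_axial
                    d.attrs["pixel_pitch_lateral"] = block.pixel_pitch_lateral
                    d.attrs["aliased"] = bool(block.aliased)


@dataclass
class StoredSeries:
    """Lazy reader for one subject of a saved cohort."""

    path: Path
    subject: str
    group: str
    block_times_min: np.ndarray
    artifact: np.ndarray
    map_values: np.ndarray
    events: dict

    @property
    def n_blocks(self) -> int:
        return self.block_times_min.size

    def block(self, i: int) -> IQBlock:
        with h5py.File(self.path, "r") as f:
            d = f[f"subjects/{self.subject}/blocks/{i:05d}"]
            return IQBlock(data=d[...], frame_rate=float(d.attrs["frame_rate"]),
                           t0=float(d.attrs["t0"]),
                           pixel_pitch_axial=float(d.attrs["pixel_pitch_axial"]),
                           pixel_pitch_lateral=float(
                               d.attrs["pixel_pitch_lateral"]),
                           aliased=bool(d.attrs.get("aliased", False)))

    def iter_blocks(self) -> Iterator[tuple[int, IQBlock]]:
        for i in range(self.n_blocks):
            yield i, self.block(i)


def load_experiment(path: str | Path) -> list[StoredSeries]:
    path = Path(path)
    out = []
    with h5py.File(path, "r") as f:
        for name, g in sorted(f["subjects"].items()):
            out.append(StoredSeries(
                path=path, subject=name, group=str(g.attrs["group"]),
                block_times_min=g["block_times_min"][...],
                artifact=g["artifact"][...].astype(bool),
                map_values=g["map_values"][...],
                events=json.loads(g.attrs.get("events", "{}"))))
    return out


# ------------------------------------------------------------------- maps

def save_maps(path: str | Path, maps_by_subject: dict[str, list[ParametricMap]]
              ) -> None:
    with h5py.File(path, "w") as f:
        for subject, maps in maps_by_subject.items():
            g = f.create_group(f"subjects/{subject}")
            for i, m in enumerate(maps):
                d = g.create_dataset(f"{m.kind}/{i:05d}",
                                     data=m.values.astype(np.float32))
                d.attrs["kind"] = m.kind
                d.attrs["units"] = m.units
                d.attrs["timestamp"] = m.timestamp


def load_maps(path: str | Path) -> dict[str, list[ParametricMap]]:
    out: dict[str, list[ParametricMap]] = {}
    with h5py.File(path, "r") as f:
        for subject, g in sorted(f["subjects"].items()):
            maps = []
            for kind, kg in sorted(g.items()):
                for _, d in sorted(kg.items()):
                    maps.append(ParametricMap(
                        values=d[...].astype(float), kind=str(d.attrs["kind"]),
                        timestamp=float(d.attrs["timestamp"]),
                        units=str(d.attrs["units"])))
            out[subject] = sorted(maps, key=lambda m: (m.kind, m.timestamp))
    return out


# --------------------------------------------------------------- tables

def save_region_series(path: str | Path,
                       series: list[RegionTimeSeries],
                       map_by_subject: dict[str, tuple[np.ndarray, np.ndarray]]
                       | None = None,
                       group_by_subject: dict[str, str] | None = None) -> None:
    """Per-subject regional time series as long-format CSV."""
    rows = []
    for s in series:
        mp = None
        if map_by_subject and s.subject in map_by_subject:
            mt, mv = map_by_subject[s.subject]
            mp = np.interp(s.times, mt, mv)
        for j, t in enumerate(s.times):
            rows.append({
                "subject": s.subject,
                "group": (group_by_subject or {}).get(s.subject, ""),
                "region": s.region,
                "time_min": t,
                "relative_ufd_pct": s.values[j],
                "artifact": bool(s.artifact[j]),
                "map_mmhg": (np.nan if mp is None else mp[j]),
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def load_region_series(path: str | Path
                       ) -> tuple[list[RegionTimeSeries], pd.DataFrame]:
    df = pd.read_csv(path)
    series = []
    for (subject, region), sub in df.groupby(["subject", "region"],
                                             sort=True):
        sub = sub.sort_values("time_min")
        series.append(RegionTimeSeries(
            region=region, times=sub["time_min"].to_numpy(),
            values=sub["relative_ufd_pct"].to_numpy(), subject=subject,
            artifact=sub["artifact"].to_numpy(dtype=bool)))
    return series, df


def export_tiff(path: str | Path, m: ParametricMap) -> None:
    """16-bit TIFF export for visualization (values min-max scaled)."""
    import tifffile
    v = m.values.astype(float)
    finite = np.isfinite(v)
    lo = float(v[finite].min()) if finite.any() else 0.0
    hi = float(v[finite].max()) if finite.any() else 1.0
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    img = np.zeros(v.shape, dtype=np.uint16)
    img[finite] = np.round((v[finite] - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, img)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
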