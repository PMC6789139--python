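"""Reading and writing the pipeline's file formats.

Images are 16-bit TIFF (one page per channel) with the um/px scale stored in
the TIFF description and a JSON sidecar; label maps are integer TIFF plus a
region-table CSV; ROIs, truth tables and specs travel as JSON; detection and
count tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .axonmap import ROI
from .cellcount import CellDetection, Section
from .ephys import SweepSet
from .inputmap import LabelMap

__all__ = [
    "write_section", "read_section",
    "write_labelmap", "read_labelmap",
    "write_rois", "read_rois",
    "write_sweeps_csv", "read_sweeps_csv",
    "detections_to_frame",
]

_U16 = np.iinfo(np.uint16).max


def write_section(path: str | Path, section: Section) -> None:
    """Multi-page 16-bit TIFF; intensities in [0,1] scale to the full range."""
    path = Path(path)
    names = list(section.channels)
    stack = np.stack([np.round(np.clip(section.channels[n], 0, 1) * _U16)
                      .astype(np.uint16) for n in names])
    meta = {"um_per_px": section.um_per_px, "channels": names,
            "bregma_mm": section.bregma_mm}
    tifffile.imwrite(path, stack, description=json.dumps(meta))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_section(path: str | Path) -> Section:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else json.loads(
        path.with_suffix(path.suffix + ".json").read_text())
    stack = np.atleast_3d(stack)
    if stack.shape[0] != len(meta["channels"]):
        stack = np.moveaxis(stack, -1, 0)
    channels = {name: stack[i].astype(np.float64) / _U16
                for i, name in enumerate(meta["channels"])}
    return Section(channels=channels, um_per_px=float(meta["um_per_px"]),
                   bregma_mm=meta.get("bregma_mm"))


def write_labelmap(path_tiff: str | Path, path_csv: str | Path, lm: LabelMap) -> None:
    tifffile.imwrite(path_tiff, lm.raster.astype(np.int32))
    lm.table.to_csv(path_csv, index=False)


def read_labelmap(path_tiff: str | Path, path_csv: str | Path) -> LabelMap:
    return LabelMap(raster=tifffile.imread(path_tiff).astype(np.int32),
                    table=pd.read_csv(path_csv))


def write_rois(path: str | Path, rois: list[ROI]) -> None:
    payload = [{"name": r.name, "box": r.box, "polygon": r.polygon,
                "section_id": r.section_id} for r in rois]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_rois(path: str | Path) -> list[ROI]:
    payload = json.loads(Path(path).read_text())
    return [ROI(name=d["name"],
                box=tuple(d["box"]) if d.get("box") else None,
                polygon=[tuple(p) for p in d["polygon"]] if d.get("polygon") else None,
                section_id=d.get("section_id", "")) for d in payload]


def write_sweeps_csv(path: str | Path, sweepsets: list[SweepSet]) -> None:
    """Long form: cell, condition, sweep, t_s, i_pa."""
    frames = []
    for ss in sweepsets:
        n_sw, n_t = ss.sweeps.shape
        t = np.arange(n_t) / ss.sampling_rate_hz
        frames.append(pd.DataFrame({
            "cell": np.repeat(ss.cell_id, n_sw * n_t),
            "condition": ss.condition,
            "sweep": np.repeat(np.arange(n_sw), n_t),
            "t_s": np.tile(t, n_sw),
            "i_pa": ss.sweeps.ravel(),
            "stim_onset_s": ss.stim_onset_s,
            "sampling_rate_hz": ss.sampling_rate_hz,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sweeps_csv(path: str | Path) -> list[SweepSet]:
    df = pd.read_csv(path)
    out = []
    for (cell, cond), grp in df.groupby(["cell", "condition"], sort=True):
        n_sw = int(grp["sweep"].max()) + 1
        sweeps = grp.sort_values(["sweep", "t_s"])["i_pa"].to_numpy().reshape(n_sw, -1)
        out.append(SweepSet(cell_id=str(cell), condition=str(cond), sweeps=sweeps,
                            sampling_rate_hz=float(grp["sampling_rate_hz"].iloc[0]),
                            stim_onset_s=float(grp["stim_onset_s"].iloc[0])))
    return out


def detections_to_frame(dets: list[CellDetection], um_per_px: float) -> pd.DataFrame:
    rows = []
    for d in dets:
        x_um, y_um = d.centroid_um(um_per_px)
        row = {"id": d.id, "channel": d.channel, "x_um": x_um, "y_um": y_um,
               "area_um2": d.area_um2, "subregion": d.subregion}
        for marker, flag in d.coexpress.items():
            row[f"coexpress_{marker}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)
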