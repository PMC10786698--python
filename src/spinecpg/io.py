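"""Plain-text readers/writers for the pipeline's tabular formats.

All formats are tidy CSV (plus GMT for gene sets and a YAML sidecar for
sEMG acquisition metadata) so every input and result is diffable text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .morpho import BodyAxis
from .neural import BilateralTraceSet
from .semg import SemgRecording


# -- calcium traces ---------------------------------------------------------

def write_traces_csv(ts: BilateralTraceSet, path) -> None:
    """Tidy trace table: time_s, roi_id, side, value."""
    ts.to_tidy().to_csv(path, index=False)


def read_traces_csv(path, fps: float | None = None) -> BilateralTraceSet:
    return BilateralTraceSet.from_tidy(pd.read_csv(path), fps=fps)


# -- midlines ---------------------------------------------------------------

def write_midlines_csv(axes: list[BodyAxis], path, metadata_path=None) -> None:
    """Midline coordinates (fish_id, point_index, x, y) and an optional
    per-fish metadata table (fish_id, genotype, treatment, age_dpf)."""
    coord_rows, meta_rows = [], []
    for axis in axes:
        if axis.fish_id is None:
            raise ParameterError("fish_id required to write midlines")
        for i, (x, y) in enumerate(axis.points):
            coord_rows.append({"fish_id": axis.fish_id, "point_index": i,
                               "x": x, "y": y})
        meta_rows.append({"fish_id": axis.fish_id, "genotype": axis.genotype,
                          "treatment": axis.treatment, "age_dpf": axis.age_dpf})
    pd.DataFrame(coord_rows).to_csv(path, index=False)
    if metadata_path is not None:
        pd.DataFrame(meta_rows).to_csv(metadata_path, index=False)


def read_midlines_csv(path, metadata_path=None) -> list[BodyAxis]:
    coords = pd.read_csv(path)
    meta = (pd.read_csv(metadata_path).set_index("fish_id")
            if metadata_path is not None else None)
    axes = []
    for fish_id, grp in coords.groupby("fish_id", sort=False):
        grp = grp.sort_values("point_index")
        info = meta.loc[fish_id] if meta is not None and fish_id in meta.index else None
        axes.append(BodyAxis(
            points=grp[["x", "y"]].to_numpy(dtype=float),
            fish_id=str(fish_id),
            genotype=None if info is None else _opt(info.get("genotype")),
            treatment=None if info is None else _opt(info.get("treatment")),
            age_dpf=None if info is None else _opt(info.get("age_dpf")),
        ))
    return axes


def _opt(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else v


# -- cohorts ----------------------------------------------------------------

def write_cohorts_csv(tables, path) -> None:
    pd.DataFrame([{"group": t.group, "variant_alleles": t.variant_alleles,
                   "total_alleles": t.total_alleles} for t in tables]).to_csv(
        path, index=False)


def read_cohorts_csv(path):
    from .cohort import CohortTable
    df = pd.read_csv(path)
    return [CohortTable(group=r.group, variant_alleles=int(r.variant_alleles),
                        total_alleles=int(r.total_alleles))
            for r in df.itertuples(index=False)]


# -- sEMG -------------------------------------------------------------------

def write_semg_csv(rec: SemgRecording, path, sidecar_path=None) -> None:
    """Long-form channel table (time_s, channel, value) plus a YAML sidecar
    with fs, gain, and posture."""
    t = np.arange(rec.n_samples) / rec.fs
    frames = [pd.DataFrame({"time_s": t, "channel": name, "value": x})
              for name, x in rec.channels.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else Path(path).with_suffix(".yaml")
    sidecar.write_text(yaml.safe_dump(
        {"fs": rec.fs, "gain": rec.gain, "posture": rec.posture}))


def read_semg_csv(path, sidecar_path=None) -> SemgRecording:
    df = pd.read_csv(path)
    sidecar = Path(sidecar_path) if sidecar_path else Path(path).with_suffix(".yaml")
    meta = yaml.safe_load(sidecar.read_text())
    channels = {name: grp.sort_values("time_s")["value"].to_numpy(dtype=float)
                for name, grp in df.groupby("channel", sort=False)}
    return SemgRecording(channels=channels, fs=float(meta["fs"]),
                         gain=float(meta.get("gain", 1000.0)),
                         posture=meta.get("posture", "standing"))


# -- uptake plates ----------------------------------------------------------

def write_plate_csv(plate, path) -> None:
    plate.wells.to_csv(path, index=False)


def read_plate_csv(path):
    from .uptake import UptakePlate
    return UptakePlate(pd.read_csv(path))


def write_membrane_csv(levels: Mapping[str, float], path) -> None:
    pd.DataFrame({"genotype": list(levels), "relative_level": list(levels.values())}
                 ).to_csv(path, index=False)


def read_membrane_csv(path) -> dict[str, float]:
    df = pd.read_csv(path)
    return dict(zip(df["genotype"], df["relative_level"].astype(float)))
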