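"""File formats: trace containers, ground-truth sidecars, configs, tables.

A simulated movie is stored as one CSV/TSV with columns
``(particle_id, frame, donor, acceptor)`` plus a JSON sidecar holding the
acquisition metadata and ground-truth segments, or as an HDF5 container
with ``/traces/<id>/donor`` and ``/acceptor`` datasets and movie-level
attributes.  Event tables are plain CSV/JSON; configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .events import DegradationEvent
from .params import EmissionParams, KineticParams
from .simulate import FluorescenceTrace, SimulationConfig
from .trajectory import StateTrajectory

PathLike = Union[str, Path]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_movie_csv(traces: Sequence[FluorescenceTrace], path: PathLike,
                   sep: str = ",") -> None:
    """Write one movie (CSV/TSV + JSON ground-truth sidecar)."""
    path = Path(path)
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "particle_id": tr.particle_id,
            "frame": np.arange(tr.n_frames),
            "donor": tr.donor,
            "acceptor": tr.acceptor,
        }))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.4f")
    meta = {
        "frame_period": traces[0].frame_period,
        "integration_time": traces[0].integration_time,
        "condition": traces[0].condition,
        "movie_id": traces[0].movie_id,
        "particles": {
            tr.particle_id: {
                "ground_truth": (tr.ground_truth.to_records()
                                 if tr.ground_truth is not None else None),
                "meta": tr.meta,
            }
            for tr in traces
        },
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_movie_csv(path: PathLike, sep: str = ",") -> List[FluorescenceTrace]:
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    traces = []
    for pid, grp in df.groupby("particle_id", sort=True):
        grp = grp.sort_values("frame")
        pmeta = meta.get("particles", {}).get(str(pid), {})
        gt = pmeta.get("ground_truth")
        traces.append(FluorescenceTrace(
            donor=grp["donor"].to_numpy(float),
            acceptor=grp["acceptor"].to_numpy(float),
            frame_period=float(meta.get("frame_period", 0.05)),
            integration_time=float(
                meta.get("integration_time", meta.get("frame_period", 0.05))),
            particle_id=str(pid),
            condition=str(meta.get("condition", "")),
            movie_id=str(meta.get("movie_id", "m0")),
            ground_truth=(StateTrajectory.from_records(gt) if gt else None),
            meta=pmeta.get("meta", {}),
        ))
    return traces


def save_movie_hdf5(traces: Sequence[FluorescenceTrace], path: PathLike) -> None:
    import h5py

    with h5py.File(Path(path), "w") as f:
        f.attrs["frame_period"] = traces[0].frame_period
        f.attrs["condition"] = traces[0].condition
        f.attrs["movie_id"] = traces[0].movie_id
        g = f.create_group("traces")
        for tr in traces:
            tg = g.create_group(tr.particle_id)
            tg.create_dataset("donor", data=tr.donor)
            tg.create_dataset("acceptor", data=tr.acceptor)
            if tr.ground_truth is not None:
                tg.attrs["ground_truth"] = json.dumps(
                    tr.ground_truth.to_records())


def load_movie_hdf5(path: PathLike) -> List[FluorescenceTrace]:
    import h5py

    traces = []
    with h5py.File(Path(path), "r") as f:
        dt = float(f.attrs["frame_period"])
        cond = str(f.attrs.get("condition", ""))
        movie = str(f.attrs.get("movie_id", "m0"))
        for pid in sorted(f["traces"]):
            tg = f["traces"][pid]
            gt = tg.attrs.get("ground_truth")
            traces.append(FluorescenceTrace(
                donor=tg["donor"][...],
                acceptor=tg["acceptor"][...],
                frame_period=dt, integration_time=dt,
                particle_id=pid, condition=cond, movie_id=movie,
                ground_truth=(StateTrajectory.from_records(json.loads(gt))
                              if gt else None)))
    return traces


def events_to_frame(events: Sequence[DegradationEvent]) -> pd.DataFrame:
    return pd.DataFrame([e.to_record() for e in events])


def save_events(events: Sequence[DegradationEvent], path: PathLike) -> None:
    """Events table as CSV (or JSON when the suffix is .json)."""
    path = Path(path)
    df = events_to_frame(events)
    if path.suffix == ".json":
        path.write_text(df.to_json(orient="records", indent=1))
    else:
        df.to_csv(path, index=False, float_format="%.5f")


def load_config(path: PathLike) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file.

    Recognized blocks: ``kinetics``, ``emission``, ``acquisition``
    (``frame_period``, ``duration``), ``ensemble`` (``n_particles``,
    ``n_movies``), plus top-level ``assay``/``condition``/``preset``.
    A ``preset`` name supplies defaults that explicit blocks override.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kin_kwargs = dict(raw.get("kinetics", {}))
    em_kwargs = dict(raw.get("emission", {}))
    acq = dict(raw.get("acquisition", {}))
    ens = dict(raw.get("ensemble", {}))
    assay = raw.get("assay")
    condition = raw.get("condition")
    if "preset" in raw:
        from .presets import get_preset

        pre = get_preset(raw["preset"])
        kin_kwargs = {**pre.kinetics.to_dict(), **kin_kwargs}
        em_kwargs = {**pre.emission.to_dict(), **em_kwargs}
        assay = assay or pre.assay
        condition = condition or pre.name
        acq.setdefault("frame_period", pre.frame_period)
    return SimulationConfig(
        kinetics=KineticParams(**kin_kwargs),
        emission=EmissionParams(**em_kwargs),
        assay=assay or "processing",
        condition=condition or "custom",
        n_particles=int(ens.get("n_particles", 50)),
        n_movies=int(ens.get("n_movies", 1)),
        duration=float(acq.get("duration", 300.0)),
        frame_period=float(acq.get("frame_period", 0.05)),
    )


def save_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))
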