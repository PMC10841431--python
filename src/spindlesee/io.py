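"""Trial file formats and dataset manifests.

A trial on disk is a column-oriented CSV (``time,mtu_length,mtu_force,
fascicle_length`` — or ``fascicle_voltage`` for uncalibrated sonomicrometry)
plus a JSON metadata sidecar (``<stem>.meta.json``) holding the spike
times, identifiers, protocol, units and provenance. An HDF5 twin with the
same content is supported for hierarchical storage. Round trips are
lossless: floats are written with 17 significant digits.

Units are fixed pipeline-wide (mm, N, s, pps) and checked at read time.
Native acquisition formats (Spike2 ``.smr``) are out of scope; external
datasets are imported through generic CSV exports.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .generator import GeneratorParams
from .protocols import ProtocolSpec
from .records import TrialRecord, UNITS

logger = logging.getLogger(__name__)

CHANNEL_COLUMNS = ("time", "mtu_length", "mtu_force")
FASCICLE_COLUMNS = ("fascicle_length", "fascicle_voltage")
FLOAT_FMT = "%.17g"


def _meta_dict(rec: TrialRecord) -> dict:
    return {
        "trial_id": rec.trial_id,
        "animal_id": rec.animal_id,
        "afferent_id": rec.afferent_id,
        "condition": rec.condition,
        "discriminable": bool(rec.discriminable),
        "protocol": rec.protocol.to_dict() if rec.protocol else None,
        "ground_truth": (rec.ground_truth.to_dict()
                         if isinstance(rec.ground_truth, GeneratorParams)
                         else None),
        "spike_times": rec.spike_times.tolist(),
        "units": dict(UNITS),
        "provenance": dict(rec.provenance),
    }


def _record_from_meta(meta: dict, channels: dict) -> TrialRecord:
    units = meta.get("units", {})
    for ch, unit in units.items():
        if ch in UNITS and unit != UNITS[ch]:
            raise ValueError(
                f"unit mismatch for {ch!r}: file says {unit!r}, pipeline "
                f"expects {UNITS[ch]!r}")
    proto = meta.get("protocol")
    gt = meta.get("ground_truth")
    return TrialRecord(
        time=channels["time"],
        mtu_length=channels["mtu_length"],
        mtu_force=channels["mtu_force"],
        fascicle_length=channels.get("fascicle_length"),
        fascicle_voltage=channels.get("fascicle_voltage"),
        spike_times=np.asarray(meta.get("spike_times", []), float),
        animal_id=meta.get("animal_id", ""),
        afferent_id=meta.get("afferent_id", ""),
        condition=meta.get("condition", "CTRL"),
        protocol=ProtocolSpec.from_dict(proto) if proto else None,
        trial_id=meta.get("trial_id", ""),
        discriminable=meta.get("discriminable", True),
        ground_truth=GeneratorParams.from_dict(gt) if gt else None,
        provenance=meta.get("provenance", {}),
    )


def write_trial(rec: TrialRecord, path) -> pathlib.Path:
    """Write one trial; format chosen by extension (``.csv`` or ``.h5``)."""
    path = pathlib.Path(path)
    if path.suffix == ".csv":
        cols = {"time": rec.time, "mtu_length": rec.mtu_length,
                "mtu_force": rec.mtu_force}
        if rec.fascicle_length is not None:
            cols["fascicle_length"] = rec.fascicle_length
        if rec.fascicle_voltage is not None:
            cols["fascicle_voltage"] = rec.fascicle_voltage
        pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(_meta_dict(rec), indent=1))
        return path
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "w") as f:
            g = f.create_group("channels")
            g.create_dataset("time", data=rec.time)
            g.create_dataset("mtu_length", data=rec.mtu_length)
            g.create_dataset("mtu_force", data=rec.mtu_force)
            if rec.fascicle_length is not None:
                g.create_dataset("fascicle_length", data=rec.fascicle_length)
            if rec.fascicle_voltage is not None:
                g.create_dataset("fascicle_voltage", data=rec.fascicle_voltage)
            f.create_dataset("spike_times", data=rec.spike_times)
            meta = _meta_dict(rec)
            meta.pop("spike_times")
            f.attrs["meta"] = json.dumps(meta)
        return path
    raise ValueError(f"unsupported trial format {path.suffix!r} "
                     "(expected .csv or .h5)")


def read_trial(path) -> TrialRecord:
    """Read one trial written by :func:`write_trial` (CSV+sidecar or HDF5)."""
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in CHANNEL_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"trial CSV {path} is missing required "
                                 f"column {col!r}")
        if not any(c in df.columns for c in FASCICLE_COLUMNS):
            raise ValueError(
                f"trial CSV {path} has neither 'fascicle_length' nor "
                "'fascicle_voltage'")
        sidecar = path.with_suffix(".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        channels = {c: df[c].to_numpy() for c in df.columns}
        return _record_from_meta(meta, channels)
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "r") as f:
            channels = {k: f["channels"][k][()] for k in f["channels"]}
            for col in CHANNEL_COLUMNS:
                if col not in channels:
                    raise ValueError(f"trial file {path} is missing required "
                                     f"channel {col!r}")
            meta = json.loads(f.attrs["meta"])
            meta["spike_times"] = f["spike_times"][()].tolist()
        return _record_from_meta(meta, channels)
    raise ValueError(f"unsupported trial format {path.suffix!r}")


@dataclass
class DatasetManifest:
    """List of trial files with their metadata and provenance."""

    trials: list = field(default_factory=list)   # dicts: path + metadata
    provenance: dict = field(default_factory=dict)

    def validate(self, root: Optional[pathlib.Path] = None) -> None:
        ids = [t["trial_id"] for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate trial IDs in manifest: {dupes}")
        for t in self.trials:
            p = pathlib.Path(t["path"])
            if root is not None and not p.is_absolute():
                p = root / p
            if not p.exists():
                raise FileNotFoundError(f"manifest lists missing file: {p}")


def write_dataset(
    records: Iterable[TrialRecord], outdir, fmt: str = "csv",
    provenance: Optional[dict] = None,
) -> pathlib.Path:
    """Write a dataset as one file per trial plus ``manifest.json``."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest(provenance=provenance or {})
    for i, rec in enumerate(records):
        name = rec.trial_id or f"trial{i:04d}"
        fname = f"{name.replace('/', '_')}.{fmt}"
        write_trial(rec, outdir / fname)
        manifest.trials.append({
            "path": fname, "trial_id": rec.trial_id,
            "animal_id": rec.animal_id, "afferent_id": rec.afferent_id,
            "condition": rec.condition,
            "protocol": rec.protocol.kind if rec.protocol else None})
    manifest.validate(root=outdir)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(
        {"trials": manifest.trials, "provenance": manifest.provenance},
        indent=1))
    logger.info("wrote %d trials to %s", len(manifest.trials), outdir)
    return mpath


def load_manifest(path) -> list[TrialRecord]:
    """Read every trial listed in a ``manifest.json``."""
    path = pathlib.Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    d = json.loads(path.read_text())
    manifest = DatasetManifest(trials=d.get("trials", []),
                               provenance=d.get("provenance", {}))
    manifest.validate(root=path.parent)
    out = []
    for t in manifest.trials:
        p = pathlib.Path(t["path"])
        if not p.is_absolute():
            p = path.parent / p
        out.append(read_trial(p))
    return out
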