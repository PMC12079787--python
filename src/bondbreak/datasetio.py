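"""Persistence of sampled conformers: HDF5 container + extended-XYZ export.

Every saved conformer is a :class:`DatasetRecord`: a geometry, its optional
property label (energy/forces/dipole/N_FOD-by-temperature), and schedule
metadata (target distance, stage, convergence flags).  Records round-trip
losslessly through the HDF5 container (coordinates to 1e-8 Å, energies to
1e-10 in the declared unit; float64 on disk, so in practice bit-exact).

Layout of the container: ``/molecules/<id>/bonds/<a-b>/steps/<step>/<frame>``
with a global ``order`` attribute preserving workflow order.  The flat
extended-XYZ export carries the provenance as ``key=value`` pairs on each
frame's comment line, making the dataset greppable and diffable.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np

from .electronic import ConformerLabel
from .structures import Geometry, Provenance

LENGTH_UNIT = "Angstrom"
DEFAULT_ENERGY_UNIT = "eV"


class DatasetError(RuntimeError):
    """Raised on malformed or unreadable dataset files."""


@dataclass
class DatasetRecord:
    """One sampled conformer plus its labels and workflow metadata."""

    geometry: Geometry
    label: Optional[ConformerLabel] = None
    target_distance: float = float("nan")
    stage_index: int = -1
    converged: bool = True
    discarded: bool = False


def records_from_trajectory(result, labels: Optional[Sequence[ConformerLabel]] = None) -> List[DatasetRecord]:
    """Flatten a sampler TrajectoryResult into dataset records.

    ``labels``, when given, must align with ``result.all_geometries()``.
    """
    geoms = result.all_geometries()
    if labels is not None and len(labels) != len(geoms):
        raise ValueError("labels do not align with the trajectory's geometries")
    step_meta = {s.step_index: s for s in result.steps}
    records = []
    for i, g in enumerate(geoms):
        meta = step_meta.get(g.provenance.step_index)
        records.append(
            DatasetRecord(
                geometry=g,
                label=labels[i] if labels is not None else None,
                target_distance=meta.target if meta else float("nan"),
                stage_index=meta.stage if meta else -1,
                converged=meta.opt_converged if meta else True,
            )
        )
    return records


# ---------------------------------------------------------------- HDF5 --


def write_dataset(
    records: Sequence[DatasetRecord],
    path: str | Path,
    energy_unit: str = DEFAULT_ENERGY_UNIT,
    discarded_count: int = 0,
    extxyz: bool = True,
) -> Dict:
    """Write records to ``<path>/records.h5`` (+ flat extxyz) with a manifest.

    Returns the manifest dict, which is also written to
    ``<path>/manifest.json``.  Counts are split by origin tag; discarded
    geometries (never materialized as records) are reported via
    ``discarded_count``.
    """
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DatasetError(f"cannot create dataset directory {path}: {exc}") from exc

    h5path = path / "records.h5"
    with h5py.File(h5path, "w") as fh:
        fh.attrs["length_unit"] = LENGTH_UNIT
        fh.attrs["energy_unit"] = energy_unit
        fh.attrs["n_records"] = len(records)
        for order, rec in enumerate(records):
            p = rec.geometry.provenance
            frame = f"{p.origin}{p.snapshot_index:04d}"
            grp = fh.create_group(
                f"molecules/{p.molecule_id}/bonds/{p.bond_id or 'none'}/"
                f"steps/{p.step_index:03d}/{frame}"
            )
            grp.attrs.update(
                {
                    "order": order,
                    "molecule_id": p.molecule_id,
                    "bond_id": p.bond_id,
                    "step_index": p.step_index,
                    "origin": p.origin,
                    "snapshot_index": p.snapshot_index,
                    "target_distance": rec.target_distance,
                    "stage_index": rec.stage_index,
                    "converged": rec.converged,
                    "discarded": rec.discarded,
                }
            )
            grp.create_dataset("elements", data=np.array(rec.geometry.elements, dtype="S4"))
            grp.create_dataset("coordinates", data=rec.geometry.coordinates)
            if rec.label is not None:
                lab = grp.create_group("label")
                lab.attrs["energy"] = rec.label.energy
                lab.create_dataset("forces", data=np.asarray(rec.label.forces))
                if rec.label.dipole is not None:
                    lab.create_dataset("dipole", data=np.asarray(rec.label.dipole))
                if rec.label.n_fod_by_temperature:
                    temps = sorted(rec.label.n_fod_by_temperature)
                    lab.create_dataset("nfod_temperatures", data=np.array(temps))
                    lab.create_dataset(
                        "nfod_values",
                        data=np.array([rec.label.n_fod_by_temperature[t] for t in temps]),
                    )

    manifest = {
        "total": len(records),
        "opt": sum(1 for r in records if r.geometry.provenance.origin == "opt"),
        "md": sum(1 for r in records if r.geometry.provenance.origin == "md"),
        "embed": sum(1 for r in records if r.geometry.provenance.origin == "embed"),
        "discarded": int(discarded_count),
        "length_unit": LENGTH_UNIT,
        "energy_unit": energy_unit,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if extxyz:
        write_extxyz(records, path / "records.extxyz")
    return manifest


def read_dataset(path: str | Path) -> List[DatasetRecord]:
    """Load records from a dataset directory, ``.h5`` file, or extxyz file."""
    path = Path(path)
    if path.is_dir():
        path = path / "records.h5"
    if not path.exists():
        raise DatasetError(f"no dataset at {path}")
    if path.suffix in (".xyz", ".extxyz"):
        return read_extxyz(path)
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise DatasetError(f"cannot open container {path}: {exc}") from exc
    with fh:
        found: List[tuple] = []

        def visit(_name, obj):
            if isinstance(obj, h5py.Group) and "coordinates" in obj:
                found.append((int(obj.attrs["order"]), obj.name))

        fh.visititems(visit)
        found.sort()
        records = []
        for order, name in found:
            grp = fh[name]
            try:
                elements = tuple(e.decode() for e in grp["elements"][()])
                coords = np.array(grp["coordinates"][()], dtype=float)
                prov = Provenance(
                    molecule_id=str(grp.attrs["molecule_id"]),
                    bond_id=str(grp.attrs["bond_id"]),
                    step_index=int(grp.attrs["step_index"]),
                    origin=str(grp.attrs["origin"]),
                    snapshot_index=int(grp.attrs["snapshot_index"]),
                )
                label = None
                if "label" in grp:
                    lab = grp["label"]
                    nfod: Dict[float, float] = {}
                    if "nfod_temperatures" in lab:
                        for t, v in zip(lab["nfod_temperatures"][()], lab["nfod_values"][()]):
                            nfod[float(t)] = float(v)
                    label = ConformerLabel(
                        energy=float(lab.attrs["energy"]),
                        forces=np.array(lab["forces"][()], dtype=float),
                        dipole=np.array(lab["dipole"][()], dtype=float) if "dipole" in lab else None,
                        n_fod_by_temperature=nfod,
                    )
                records.append(
                    DatasetRecord(
                        geometry=Geometry(elements, coords, prov),
                        label=label,
                        target_distance=float(grp.attrs["target_distance"]),
                        stage_index=int(grp.attrs["stage_index"]),
                        converged=bool(grp.attrs["converged"]),
                        discarded=bool(grp.attrs["discarded"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise DatasetError(f"malformed record #{order} at {name}: {exc}") from exc
    return records


# ------------------------------------------------------------- extxyz --


def _fmt_comment(rec: DatasetRecord) -> str:
    p = rec.geometry.provenance
    fields = {
        "Properties": "species:S:1:pos:R:3",
        "molecule_id": p.molecule_id,
        "bond_id": p.bond_id or "none",
        "step_index": p.step_index,
        "origin": p.origin,
        "snapshot_index": p.snapshot_index,
        "target_distance": f"{rec.target_distance:.8f}",
        "stage_index": rec.stage_index,
        "converged": str(rec.converged),
    }
    if rec.label is not None:
        fields["energy"] = f"{rec.label.energy:.12e}"
    return " ".join(f"{k}={v}" for k, v in fields.items())


def write_extxyz(records: Sequence[DatasetRecord], path: str | Path, mode: str = "w") -> None:
    """Write records as extended XYZ (append mode supports crash-safe streaming)."""
    with open(path, mode) as fh:
        for rec in records:
            fh.write(f"{rec.geometry.n_atoms}\n{_fmt_comment(rec)}\n")
            for el, (x, y, z) in zip(rec.geometry.elements, rec.geometry.coordinates):
                fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


_KV = re.compile(r'(\S+)=(?:"([^"]*)"|(\S+))')


def read_extxyz(path: str | Path) -> List[DatasetRecord]:
    """Parse a (conforming) extended-XYZ file back into records.

    Malformed or truncated frames raise :class:`DatasetError` naming the
    frame index.
    """
    records: List[DatasetRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise DatasetError(f"frame {frame}: bad atom-count line {lines[i]!r}") from exc
        if i + 2 + natoms > len(lines):
            raise DatasetError(f"frame {frame}: truncated (expected {natoms} atoms)")
        kv = {m.group(1): m.group(2) or m.group(3) for m in _KV.finditer(lines[i + 1])}
        elements, coords = [], []
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise DatasetError(f"frame {frame}: malformed atom line {j}")
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        bond_id = kv.get("bond_id", "")
        prov = Provenance(
            molecule_id=kv.get("molecule_id", "unknown"),
            bond_id="" if bond_id == "none" else bond_id,
            step_index=int(kv.get("step_index", -1)),
            origin=kv.get("origin", "embed"),
            snapshot_index=int(kv.get("snapshot_index", 0)),
        )
        label = None
        if "energy" in kv:
            label = ConformerLabel(energy=float(kv["energy"]), forces=np.zeros((natoms, 3)))
        records.append(
            DatasetRecord(
                geometry=Geometry(tuple(elements), np.array(coords), prov),
                label=label,
                target_distance=float(kv.get("target_distance", "nan")),
                stage_index=int(kv.get("stage_index", -1)),
                converged=kv.get("converged", "True") == "True",
            )
        )
        i += 2 + natoms
        frame += 1
    return records
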