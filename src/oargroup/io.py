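"""Reading and writing the package's on-disk artifacts.

Structure sets are stored as one NIfTI volume per mask plus a JSON manifest
naming each structure's role and recording the grid and provenance label.
Objective specs round-trip through YAML. Plans are stored as a weights CSV,
a dose NIfTI and a JSON metadata file carrying the objective trace.
Influence matrices are cached in scipy's sparse ``.npz`` container with a
JSON sidecar header describing the grid and beam configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import sparse

from .dose import BeamConfig, InfluenceMatrix
from .geometry import Grid, Role, StructureMask, StructureSet
from .objective import ObjectiveSpec

MANIFEST_VERSION = 1
INFLUENCE_FORMAT_VERSION = 1


def _affine(grid: Grid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_structure_set(structures: StructureSet, directory: str | Path) -> Path:
    """Write one NIfTI per mask plus ``structures.json``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in structures:
        fname = f"{s.name}.nii"
        img = nib.Nifti1Image(s.voxels.astype(np.uint8), _affine(structures.grid))
        nib.save(img, directory / fname)
        entries.append({"name": s.name, "role": s.role.value, "file": fname})
    manifest = {
        "manifest_version": MANIFEST_VERSION,
        "label": structures.label,
        "grid": {"shape": list(structures.grid.shape),
                 "spacing": list(structures.grid.spacing),
                 "origin": list(structures.grid.origin)},
        "structures": entries,
    }
    path = directory / "structures.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_structure_set(directory: str | Path) -> StructureSet:
    directory = Path(directory)
    manifest = json.loads((directory / "structures.json").read_text())
    g = manifest["grid"]
    grid = Grid(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
    masks = []
    for entry in manifest["structures"]:
        img = nib.load(directory / entry["file"])
        vox = np.asarray(img.dataobj).astype(bool)
        masks.append(StructureMask(grid, vox, entry["name"], Role(entry["role"])))
    return StructureSet(grid, masks, manifest.get("label", ""))


def export_structure_volumes(structures: StructureSet, path: str | Path) -> None:
    """CSV of per-structure volumes in cm^3."""
    from .geometry import mask_volume

    rows = [{"structure": s.name, "role": s.role.value,
             "volume_cm3": mask_volume(s)} for s in structures]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_objective_spec(spec: ObjectiveSpec, path: str | Path) -> None:
    Path(path).write_text(spec.to_yaml())


def load_objective_spec(path: str | Path) -> ObjectiveSpec:
    return ObjectiveSpec.from_yaml(Path(path).read_text())


def save_influence(influence: InfluenceMatrix, path_stem: str | Path) -> None:
    """Cache an influence matrix as ``<stem>.npz`` + ``<stem>.json`` header."""
    stem = Path(path_stem)
    sparse.save_npz(stem.with_suffix(".npz"), influence.entries)
    header = {
        "format_version": INFLUENCE_FORMAT_VERSION,
        "grid": {"shape": list(influence.grid.shape),
                 "spacing": list(influence.grid.spacing),
                 "origin": list(influence.grid.origin)},
        "beam_config": dataclasses.asdict(influence.beam_config),
        "beamlet_table": influence.beamlet_table.tolist(),
    }
    stem.with_suffix(".json").write_text(json.dumps(header, sort_keys=True))


def load_influence(path_stem: str | Path) -> InfluenceMatrix:
    stem = Path(path_stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    if header["format_version"] != INFLUENCE_FORMAT_VERSION:
        raise ValueError(f"unsupported influence cache version "
                         f"{header['format_version']}")
    g = header["grid"]
    grid = Grid(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
    bc = dict(header["beam_config"])
    bc["gantry_angles"] = tuple(bc["gantry_angles"])
    beams = BeamConfig(**bc)
    entries = sparse.load_npz(stem.with_suffix(".npz")).tocsr()
    return InfluenceMatrix(entries, grid, beams,
                           np.asarray(header["beamlet_table"], dtype=float))


def save_plan(results, directory: str | Path, stem: str = "plan") -> None:
    """Write a plan's weights (CSV), dose (NIfTI) and metadata+trace (JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"beamlet": np.arange(results.weights.size),
                  "weight": results.weights}).to_csv(
        directory / f"{stem}_weights.csv", index=False)
    img = nib.Nifti1Image(results.dose.astype(np.float32),
                          _affine(results.model.influence.grid))
    nib.save(img, directory / f"{stem}_dose.nii")
    meta = {
        "mode": results.spec.mode,
        "anatomy": results.structures.label,
        "converged": bool(results.converged),
        "iterations": int(results.iterations),
        "objective_trace": [float(v) for v in results.objective_trace],
        "total_beamlet_weight": results.total_beamlet_weight,
        "metadata": results.metadata,
    }
    (directory / f"{stem}_meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True))
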