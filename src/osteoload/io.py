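"""File interchange: legacy-VTK meshes, node-set sidecars, CSV, YAML.

Meshes and solution fields are written as ASCII legacy VTK unstructured
grids (cell type 24, quadratic tetrahedron — the node ordering used
in-package matches VTK's), readable by ParaView and friends.  Named node
sets travel in a JSON sidecar next to the mesh file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .meshing import Mesh
from .synthetic import CohortDesign, HandInfo, DEFAULT_HANDS

__all__ = [
    "write_mesh_vtk",
    "read_mesh_vtk",
    "write_node_sets",
    "read_node_sets",
    "write_trials_csv",
    "load_design_yaml",
    "save_design_yaml",
]

_VTK_QUADRATIC_TETRA = 24


def write_mesh_vtk(
    mesh: Mesh,
    path: str | Path,
    point_data: Mapping[str, np.ndarray] | None = None,
    node_sets: bool = True,
) -> None:
    """Write the mesh (plus optional nodal vector/scalar fields) as legacy
    ASCII VTK; node sets go to ``<path>.sets.json``."""
    path = Path(path)
    n, e = mesh.n_nodes, mesh.n_elements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("plate-fixed osteotomy construct\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.10g")
        fh.write(f"CELLS {e} {e * 11}\n")
        cells = np.hstack([np.full((e, 1), 10), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {e}\n")
        np.savetxt(fh, np.full(e, _VTK_QUADRATIC_TETRA), fmt="%d")
        fh.write(f"CELL_DATA {e}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.element_region, fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.10g")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr.reshape(-1, 1), fmt="%.10g")
    if node_sets and mesh.node_sets:
        write_node_sets(mesh.node_sets, path.with_suffix(path.suffix + ".sets.json"))


def read_mesh_vtk(path: str | Path) -> Mesh:
    """Read a mesh written by :func:`write_mesh_vtk` (restricted legacy-VTK
    subset: one unstructured grid of quadratic tetrahedra)."""
    path = Path(path)
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nodes = elements = region = None
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            flat = []
            i += 1
            while len(flat) < 3 * n:
                flat.extend(float(t) for t in lines[i].split())
                i += 1
            nodes = np.array(flat).reshape(n, 3)
            continue
        if line.startswith("CELLS"):
            e = int(line.split()[1])
            rows = []
            i += 1
            for _ in range(e):
                rows.append([int(t) for t in lines[i].split()][1:])
                i += 1
            elements = np.array(rows)
            continue
        if line.startswith("SCALARS region"):
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < len(elements):
                vals.extend(int(t) for t in lines[i].split())
                i += 1
            region = np.array(vals, dtype=np.int8)
            continue
        i += 1
    if nodes is None or elements is None:
        raise ValueError(f"{path} is not a recognized legacy-VTK unstructured grid")
    if region is None:
        region = np.zeros(len(elements), dtype=np.int8)
    mesh = Mesh(nodes=nodes, elements=elements, element_region=region)
    sets_path = path.with_suffix(path.suffix + ".sets.json")
    if sets_path.exists():
        mesh.node_sets = read_node_sets(sets_path)
    return mesh


def write_node_sets(node_sets: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: np.asarray(v).tolist() for k, v in node_sets.items()}, fh)


def read_node_sets(path: str | Path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        return {k: np.asarray(v, dtype=int) for k, v in json.load(fh).items()}


def write_trials_csv(records: Iterable, path: str | Path) -> pd.DataFrame:
    """Long-format trial curves: one row per sample with identity columns,
    machine travel, normalized distance, and the cut-plane moment."""
    rows = []
    for r in records:
        if r.normalized is None:
            r.process()
        k = len(r.normalized)  # analyzed window = leading samples
        for travel, mom, s in zip(r.travel[:k], r.moment[:k], r.normalized[:, 0]):
            rows.append(
                dict(hand=r.hand, digit=r.digit, test=r.test, trial=r.trial,
                     travel=travel, normalized_distance=s, Mz=mom)
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def save_design_yaml(design: CohortDesign, path: str | Path) -> None:
    data = {
        "hands": {
            h: dict(side=i.side, sex=i.sex, age=i.age, height_cm=i.height_cm,
                    weight_kg=i.weight_kg, bmi=i.bmi)
            for h, i in design.hands.items()
        },
        "digits": list(design.digits),
        "trials_per_digit": design.trials_per_digit,
        "retained_trials": list(design.retained_trials),
        "exclusions": [list(x) for x in design.exclusions],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_design_yaml(path: str | Path) -> CohortDesign:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    hands = {
        int(h): HandInfo(**info) for h, info in data.get("hands", {}).items()
    } or DEFAULT_HANDS
    return CohortDesign(
        hands=hands,
        digits=tuple(data.get("digits", (2, 3, 4))),
        trials_per_digit=int(data.get("trials_per_digit", 5)),
        retained_trials=tuple(data.get("retained_trials", (3, 4, 5))),
        exclusions=tuple(tuple(x) for x in data.get("exclusions", ())),
    )
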