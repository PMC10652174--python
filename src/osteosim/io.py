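"""Plain-text exports: legacy-ASCII VTK unstructured grids and CSV logs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geometry as geo

__all__ = ["write_vtk", "write_region_map_csv", "write_timecourse_csv"]

_VTK_HEXAHEDRON = 12


def write_vtk(path: str, mesh: geo.Mesh,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (and optional per-element scalar fields) as legacy VTK."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nosteosim field export\n"
                 "ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        np.savetxt(fh, mesh.nodes, fmt="%.6g")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {ne * 9}\n")
        np.savetxt(fh, np.hstack([np.full((ne, 1), 8), mesh.conn]), fmt="%d")
        fh.write(f"CELL_TYPES {ne}\n")
        np.savetxt(fh, np.full(ne, _VTK_HEXAHEDRON), fmt="%d")
        if cell_data:
            fh.write(f"CELL_DATA {ne}\n")
            for name, values in cell_data.items():
                v = np.asarray(values, dtype=float)
                if v.shape != (ne,):
                    raise ValueError(f"{name}: one value per element required")
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, v, fmt="%.6g")


def write_region_map_csv(path: str, mesh: geo.Mesh) -> None:
    """Element id, region label (dominant material), and footprint weight."""
    dominant = np.argmax(mesh.fractions, axis=1)
    df = pd.DataFrame({
        "element": np.arange(mesh.n_elements),
        "region": [geo.MATERIALS[m] for m in dominant],
        "footprint_weight": mesh.footprint_weight,
        "lateral": mesh.lateral,
    })
    df.to_csv(path, index=False)


def write_timecourse_csv(path: str, result) -> None:
    """Per-day BV/TV and phenotype counts of one simulation run."""
    df = result.cell_counts.copy()
    df.insert(0, "bvtv_percent", result.bvtv_timecourse)
    df.to_csv(path)
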