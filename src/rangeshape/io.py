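"""Plain-text I/O: CSV matrix rasters and long-format tables.

Rasters (elevation, climate, realms, richness maps) are stored as plain CSV
matrices; species occupancy as long-format CSV with columns
``species_id,row,col``; elevational limits as ``species_id,e_lo,e_hi``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import SpeciesRecord
from .grid import Cell, RichnessMap


def write_matrix_csv(path: str | Path, values: np.ndarray) -> None:
    np.savetxt(path, np.asarray(values), delimiter=",", fmt="%.10g")


def read_matrix_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_richness_csv(path: str | Path, rmap: RichnessMap) -> None:
    write_matrix_csv(path, rmap.values)


def read_richness_csv(path: str | Path, resolution: str) -> RichnessMap:
    return RichnessMap(resolution, read_matrix_csv(path))


def write_presence_csv(path: str | Path, ranges: dict[str, set[Cell]]) -> None:
    rows = [
        {"species_id": sid, "row": r, "col": c}
        for sid, cells in sorted(ranges.items())
        for r, c in sorted(cells)
    ]
    pd.DataFrame(rows, columns=["species_id", "row", "col"]).to_csv(path, index=False)


def read_presence_csv(path: str | Path) -> dict[str, set[Cell]]:
    df = pd.read_csv(path)
    out: dict[str, set[Cell]] = {}
    for sid, grp in df.groupby("species_id"):
        out[str(sid)] = {(int(r), int(c)) for r, c in zip(grp["row"], grp["col"])}
    return out


def write_limits_csv(path: str | Path, species: list[SpeciesRecord]) -> None:
    pd.DataFrame(
        [
            {"species_id": sp.species_id, "e_lo": sp.elev_limits[0],
             "e_hi": sp.elev_limits[1]}
            for sp in species
        ]
    ).to_csv(path, index=False)


def read_limits_csv(path: str | Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path)
    return {
        str(row.species_id): (float(row.e_lo), float(row.e_hi))
        for row in df.itertuples()
    }


def write_patch_assignments_csv(path: str | Path, assignments: pd.DataFrame) -> None:
    """Columns: species_id, row, col, patch_id, group_id."""
    cols = ["species_id", "row", "col", "patch_id", "group_id"]
    assignments[cols].to_csv(path, index=False)
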