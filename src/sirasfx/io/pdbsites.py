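"""Minimal PDB-subset files for heavy-atom sites.

Only CRYST1, ATOM/HETATM and END records are understood.  Coordinates are
orthogonal Angstrom; with the orthorhombic restriction the fractional <->
orthogonal conversion is the diagonal cell matrix.
"""

from __future__ import annotations

import numpy as np

from ..cell import UnitCell
from ..sfcalc import AtomSite
from ..symmetry import SpaceGroup, get_space_group

__all__ = ["write_pdb_sites", "read_pdb_sites"]

_SG_PDB = {"P1": "P 1", "P212121": "P 21 21 21"}


class PdbFormatError(ValueError):
    pass


def write_pdb_sites(path, sites, cell: UnitCell, sg: SpaceGroup) -> None:
    sites = list(sites)
    if len(sites) > 9999:
        raise ValueError("at most 9999 sites supported")
    with open(path, "w") as fh:
        fh.write(
            f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
            f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} "
            f"{_SG_PDB.get(sg.name, sg.name):<11s}{4:4d}\n"
        )
        for i, site in enumerate(sites, start=1):
            x, y, z = cell.orthogonalize(site.frac_xyz)
            name = (site.label or "X")[:4]
            fh.write(
                f"HETATM{i:5d} {name:<4s} UNK A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{site.occupancy:6.2f}{site.b_iso:6.2f}"
                f"          {name[:2]:>2s}\n"
            )
        fh.write("END\n")


def read_pdb_sites(path):
    """Returns (sites: list[AtomSite], cell, space group)."""
    cell = None
    sg = None
    sites = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    cell = UnitCell(
                        float(line[6:15]), float(line[15:24]), float(line[24:33]),
                        float(line[33:40]), float(line[40:47]), float(line[47:54]),
                    )
                except (ValueError, NotImplementedError) as exc:
                    raise PdbFormatError(f"malformed CRYST1 record: {line.rstrip()}") from exc
                sg_name = line[55:66].strip().replace(" ", "")
                sg = get_space_group(sg_name)
            elif rec in ("ATOM", "HETATM"):
                if cell is None:
                    raise PdbFormatError("coordinate record before CRYST1")
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
                b = float(line[60:66]) if line[60:66].strip() else 0.0
                label = line[12:16].strip() or "X"
                sites.append(
                    AtomSite(
                        label=label,
                        frac_xyz=tuple(np.mod(cell.fractionalize(xyz), 1.0)),
                        occupancy=occ,
                        b_iso=b,
                    )
                )
    if cell is None:
        raise PdbFormatError(f"{path}: no CRYST1 record found")
    return sites, cell, sg
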