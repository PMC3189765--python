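"""Volumetric grid writers/readers (Gaussian cube and OpenDX).

Grids are written in Ångström (noted in the header comment) with the
cube convention of z-fastest value ordering.  The readers exist for
round-tripping our own files; they are not general-purpose parsers of
third-party output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from fieldqsar.fields import Lattice

__all__ = ["write_cube", "read_cube", "write_dx", "read_dx"]


def write_cube(
    lattice: Lattice, values: np.ndarray, path: str | Path, comment: str = ""
) -> None:
    """Write a Gaussian-cube-format grid (units Å, z-fastest ordering)."""
    values = np.asarray(values, dtype=float)
    if values.size != lattice.n_points:
        raise ValueError("value count does not match lattice dims")
    nx, ny, nz = lattice.dims
    ox, oy, oz = lattice.origin
    s = lattice.spacing
    lines = [
        f"fieldqsar grid (units: Angstrom) {comment}".rstrip(),
        "values ordered z-fastest",
        f"{0:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}",
        f"{nx:5d}{s:12.6f}{0.0:12.6f}{0.0:12.6f}",
        f"{ny:5d}{0.0:12.6f}{s:12.6f}{0.0:12.6f}",
        f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{s:12.6f}",
    ]
    flat = values.ravel()
    for start in range(0, flat.size, 6):
        lines.append("".join(f"{v:13.5E}" for v in flat[start : start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> tuple[Lattice, np.ndarray, str]:
    lines = Path(path).read_text().splitlines()
    comment = lines[0]
    natoms_line = lines[2].split()
    natoms = int(natoms_line[0])
    origin = tuple(float(x) for x in natoms_line[1:4])
    dims = []
    spacing = None
    for axis, line in enumerate(lines[3:6]):
        parts = line.split()
        dims.append(int(parts[0]))
        step = float(parts[axis + 1])
        if spacing is None:
            spacing = step
    values = np.array(
        [float(tok) for line in lines[6 + abs(natoms) :] for tok in line.split()]
    )
    lattice = Lattice(origin=origin, spacing=float(spacing), dims=tuple(dims))
    return lattice, values, comment


def write_dx(
    lattice: Lattice, values: np.ndarray, path: str | Path, comment: str = ""
) -> None:
    """Write an OpenDX regular-grid file (units Å, z-fastest ordering)."""
    values = np.asarray(values, dtype=float)
    if values.size != lattice.n_points:
        raise ValueError("value count does not match lattice dims")
    nx, ny, nz = lattice.dims
    ox, oy, oz = lattice.origin
    s = lattice.spacing
    lines = [
        f"# fieldqsar grid (units: Angstrom) {comment}".rstrip(),
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    flat = values.ravel()
    for start in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6E}" for v in flat[start : start + 3]))
    lines.append('attribute "dep" string "positions"')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> tuple[Lattice, np.ndarray, str]:
    lines = Path(path).read_text().splitlines()
    comment = lines[0].lstrip("# ")
    dims = None
    origin = None
    spacing = None
    data: list[float] = []
    in_data = False
    for line in lines:
        if line.startswith("object 1"):
            dims = tuple(int(x) for x in line.split()[-3:])
        elif line.startswith("origin"):
            origin = tuple(float(x) for x in line.split()[1:4])
        elif line.startswith("delta") and spacing is None:
            spacing = float(line.split()[1])
        elif "data follows" in line:
            in_data = True
        elif line.startswith("attribute"):
            in_data = False
        elif in_data:
            data.extend(float(tok) for tok in line.split())
    if dims is None or origin is None or spacing is None:
        raise ValueError(f"malformed dx file: {path}")
    lattice = Lattice(origin=origin, spacing=spacing, dims=dims)
    return lattice, np.array(data), comment
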