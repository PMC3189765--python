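"""CoMFA and CoMSIA lattice fields.

CoMFA probes each lattice point with an sp3 carbon carrying unit
positive charge: the steric field is a Lennard-Jones 12-6 sum and the
electrostatic field a Coulomb sum with a distance-dependent dielectric
(D = r by default), both truncated to ±30 kcal/mol.  Points where the
untruncated steric energy reaches the cutoff are flagged as clashes so
the electrostatic value there can be replaced by the training-set
column mean downstream.

CoMSIA evaluates, for five physicochemical properties k (steric r³,
electrostatic charge, hydrophobic, H-bond donor and acceptor
indicators), the Gaussian similarity index

    A_k(q) = sum_i  w_probe,k * w_ik * exp(-alpha * r_iq^2)

with attenuation factor alpha = 0.3 and all probe property values +1.
The positive sign convention is used; a global sign flip is immaterial
to the PLS models built on these columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from fieldqsar.chemio import Molecule, MoleculeSet

__all__ = [
    "COMFA_FIELDS",
    "COMSIA_FIELDS",
    "ALL_FIELDS",
    "COULOMB_CONSTANT",
    "Lattice",
    "ProbeSpec",
    "FieldGrid",
    "build_lattice",
    "comfa_fields",
    "comsia_fields",
]

COMFA_FIELDS = ("comfa_steric", "comfa_elec")
COMSIA_FIELDS = (
    "comsia_steric",
    "comsia_elec",
    "comsia_hydrophobic",
    "comsia_donor",
    "comsia_acceptor",
)
ALL_FIELDS = COMFA_FIELDS + COMSIA_FIELDS
FieldName = Literal[
    "comfa_steric",
    "comfa_elec",
    "comsia_steric",
    "comsia_elec",
    "comsia_hydrophobic",
    "comsia_donor",
    "comsia_acceptor",
]

COULOMB_CONSTANT = 332.17  # kcal·Å/(mol·e²)


@dataclass(frozen=True)
class Lattice:
    """A regular axis-aligned 3D grid: origin, spacing, dims.

    Points are ordered C-style over (ix, iy, iz), i.e. z fastest — the
    ordering used by Gaussian cube files.
    """

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("lattice dims must be positive")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points as an (n_points, 3) array (z fastest)."""
        nx, ny, nz = self.dims
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
        return np.asarray(self.origin) + idx * self.spacing

    def index_of(self, ix: int, iy: int, iz: int) -> int:
        nx, ny, nz = self.dims
        if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
            raise IndexError(f"lattice index ({ix},{iy},{iz}) out of range {self.dims}")
        return (ix * ny + iy) * nz + iz

    def unravel(self, flat: int) -> tuple[int, int, int]:
        nx, ny, nz = self.dims
        if not 0 <= flat < self.n_points:
            raise IndexError(f"flat index {flat} out of range")
        ix, rem = divmod(flat, ny * nz)
        iy, iz = divmod(rem, nz)
        return ix, iy, iz


@dataclass(frozen=True)
class ProbeSpec:
    """Probe-atom parameters for both field families.

    The CoMFA probe is an sp3 carbon (LJ radius/epsilon) with +1 charge;
    the CoMSIA probe has radius 1 Å and +1 for every property.
    """

    lj_radius: float = 1.70
    lj_epsilon: float = 0.107
    charge: float = 1.0
    hydrophobicity: float = 1.0
    hbd: float = 1.0
    hba: float = 1.0
    comsia_radius: float = 1.0
    attenuation_alpha: float = 0.3
    truncation: float = 30.0
    dielectric: Literal["distance", "constant"] = "distance"

    def __post_init__(self) -> None:
        if self.attenuation_alpha <= 0:
            raise ValueError("attenuation_alpha must be positive")
        if self.truncation <= 0:
            raise ValueError("truncation must be positive")


@dataclass
class FieldGrid:
    """Per-molecule values of one field on a shared lattice."""

    molecule_id: str
    field: FieldName
    values: np.ndarray
    clash_mask: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.clash_mask is None:
            self.clash_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.clash_mask = np.asarray(self.clash_mask, dtype=bool)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite field values for {self.molecule_id}/{self.field}")


def build_lattice(mols: MoleculeSet, spacing: float = 2.0, margin: float = 4.0) -> Lattice:
    """Axis-aligned lattice enclosing all aligned molecules plus a margin."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if len(mols) == 0:
        raise ValueError("cannot build a lattice for an empty molecule set")
    all_xyz = np.vstack([m.coords for m in mols])
    lo = all_xyz.min(axis=0) - margin
    hi = all_xyz.max(axis=0) + margin
    extent = hi - lo
    dims = tuple(int(np.ceil(e / spacing)) + 1 for e in extent)
    return Lattice(origin=tuple(float(x) for x in lo), spacing=float(spacing), dims=dims)


def _distances(mol: Molecule, lattice: Lattice) -> np.ndarray:
    return cdist(lattice.points(), mol.coords)


def comfa_fields(
    mol: Molecule, lattice: Lattice, probe: ProbeSpec = ProbeSpec()
) -> tuple[FieldGrid, FieldGrid]:
    """Lennard-Jones steric and Coulomb electrostatic grids for one molecule.

    LJ combination rules: r_min = r_vdw,i + r_probe (arithmetic),
    eps = sqrt(eps_i * eps_probe) (geometric), so the pair minimum is
    exactly -eps at r = r_min.  Both grids are clamped to ±truncation;
    the clash mask marks points whose unclamped steric energy reached
    the cutoff (including probe-on-atom coincidences).
    """
    r = _distances(mol, lattice)
    eps_i = np.array([a.lj_epsilon for a in mol.atoms])
    rmin_i = np.array([a.vdw_radius for a in mol.atoms]) + probe.lj_radius
    q_i = np.array([a.partial_charge for a in mol.atoms])
    cut = probe.truncation

    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = np.where(r > 0, rmin_i / np.maximum(r, 1e-12), np.inf)
        s6 = inv**6
        eps_pair = np.sqrt(eps_i * probe.lj_epsilon)
        steric_terms = eps_pair * (s6 * s6 - 2.0 * s6)
        steric_raw = np.where(np.isfinite(steric_terms), steric_terms, cut).sum(axis=1)
        steric_raw = np.where(np.isfinite(steric_raw), steric_raw, cut)

        if probe.dielectric == "distance":
            denom = r * r  # D(r) = r  ->  1/(D*r) = 1/r^2
        else:
            denom = r
        coul_terms = COULOMB_CONSTANT * q_i * probe.charge / np.where(denom > 0, denom, np.inf)
        coul_raw = np.where(np.isfinite(coul_terms), coul_terms, 0.0).sum(axis=1)

    clash = steric_raw >= cut
    steric = np.clip(steric_raw, -cut, cut)
    elec = np.clip(coul_raw, -cut, cut)
    return (
        FieldGrid(mol.id, "comfa_steric", steric, clash),
        FieldGrid(mol.id, "comfa_elec", elec, clash),
    )


def comsia_fields(
    mol: Molecule, lattice: Lattice, probe: ProbeSpec = ProbeSpec()
) -> tuple[FieldGrid, ...]:
    """Gaussian similarity-index grids for the five CoMSIA properties."""
    if probe.attenuation_alpha <= 0:
        raise ValueError("attenuation_alpha must be positive")
    r2 = _distances(mol, lattice) ** 2
    g = np.exp(-probe.attenuation_alpha * r2)
    omegas = {
        "comsia_steric": np.array([a.vdw_radius**3 for a in mol.atoms]),
        "comsia_elec": np.array([a.partial_charge for a in mol.atoms]),
        "comsia_hydrophobic": np.array([a.hydrophobic_w for a in mol.atoms]),
        "comsia_donor": np.array([1.0 if a.is_hbd else 0.0 for a in mol.atoms]),
        "comsia_acceptor": np.array([1.0 if a.is_hba else 0.0 for a in mol.atoms]),
    }
    probe_w = {
        "comsia_steric": 1.0,
        "comsia_elec": probe.charge,
        "comsia_hydrophobic": probe.hydrophobicity,
        "comsia_donor": probe.hbd,
        "comsia_acceptor": probe.hba,
    }
    return tuple(
        FieldGrid(mol.id, name, probe_w[name] * (g * w).sum(axis=1))
        for name, w in omegas.items()
    )
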