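"""Molecular geometries: the ``Molecule`` container, XYZ I/O and the built-in
fixture set of small closed-shell molecules used throughout the test suite.

Coordinates are stored in Angstrom (the XYZ convention); ``coords_bohr``
converts to atomic units for the integral engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR, ELEMENT_Z


class GeometryError(ValueError):
    """Malformed molecular input (bad XYZ file, open-shell system, ...)."""


@dataclass(frozen=True)
class Molecule:
    """A molecule: element symbols, Cartesian coordinates (Angstrom), charge
    and spin multiplicity.  Only closed-shell singlets are supported."""

    atoms: tuple[str, ...]
    coordinates: np.ndarray  # (natom, 3), Angstrom
    charge: int = 0
    multiplicity: int = 1
    name: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coordinates", coords)
        if len(self.atoms) == 0:
            raise GeometryError("molecule must contain at least one atom")
        if len(self.atoms) != coords.shape[0]:
            raise GeometryError(
                f"{len(self.atoms)} element symbols but {coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        for sym in self.atoms:
            if sym not in ELEMENT_Z:
                raise GeometryError(f"unsupported element {sym!r}")
        if self.multiplicity != 1:
            raise GeometryError("only closed-shell singlets are supported")
        if self.n_electrons % 2 != 0:
            raise GeometryError(
                f"odd electron count ({self.n_electrons}) is not a closed shell"
            )

    @property
    def n_electrons(self) -> int:
        return sum(ELEMENT_Z[a] for a in self.atoms) - self.charge

    @property
    def nuclear_charges(self) -> np.ndarray:
        return np.array([ELEMENT_Z[a] for a in self.atoms], dtype=float)

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coordinates * ANGSTROM_TO_BOHR

    def nuclear_repulsion(self) -> float:
        """Nuclear repulsion energy in Hartree."""
        r = self.coords_bohr
        z = self.nuclear_charges
        e = 0.0
        for i in range(len(z)):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e

    def translated(self, shift_angstrom) -> "Molecule":
        return Molecule(self.atoms, self.coordinates + np.asarray(shift_angstrom),
                        self.charge, self.multiplicity, self.name)

    def rotated(self, rotation: np.ndarray) -> "Molecule":
        rotation = np.asarray(rotation, dtype=float)
        return Molecule(self.atoms, self.coordinates @ rotation.T,
                        self.charge, self.multiplicity, self.name)


def load_xyz(path) -> Molecule:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` rows
    in Angstrom)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GeometryError(f"{path}: empty file")
    try:
        natom = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise GeometryError(f"{path}: line 1: expected an atom count")
    if len(lines) < 2 + natom:
        raise GeometryError(
            f"{path}: header announces {natom} atoms but only "
            f"{max(0, len(lines) - 2)} coordinate lines follow"
        )
    atoms, coords = [], []
    for k in range(natom):
        ln = lines[2 + k].split()
        if len(ln) < 4:
            raise GeometryError(f"{path}: line {3 + k}: expected 'El x y z'")
        atoms.append(ln[0].capitalize())
        try:
            coords.append([float(x) for x in ln[1:4]])
        except ValueError:
            raise GeometryError(f"{path}: line {3 + k}: non-numeric coordinate")
    comment = lines[1].strip()
    return Molecule(tuple(atoms), np.array(coords), name=comment or "xyz")


def write_xyz(molecule: Molecule, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(molecule.atoms)}\n{molecule.name}\n")
        for sym, (x, y, z) in zip(molecule.atoms, molecule.coordinates):
            fh.write(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def _deg(x):
    return math.radians(x)


def _build_fixtures() -> dict[str, Molecule]:
    """Standard experimental equilibrium geometries (Angstrom)."""
    fx = {}

    # Water: r(OH) = 0.9572 A, HOH = 104.52 deg
    r, th = 0.9572, _deg(104.52)
    fx["h2o"] = Molecule(
        ("O", "H", "H"),
        np.array([
            [0.0, 0.0, 0.0],
            [r * math.sin(th / 2), 0.0, r * math.cos(th / 2)],
            [-r * math.sin(th / 2), 0.0, r * math.cos(th / 2)],
        ]),
        name="h2o",
    )

    # Ammonia: r(NH) = 1.0116 A, HNH = 106.7 deg
    r, hnh = 1.0116, _deg(106.7)
    # place N at origin, H atoms on a cone about z
    srho = math.sin(hnh / 2) / math.sin(_deg(120) / 2)  # sin of polar half-angle
    pol = math.asin(srho)
    hs = []
    for k in range(3):
        phi = 2 * math.pi * k / 3
        hs.append([r * math.sin(pol) * math.cos(phi),
                   r * math.sin(pol) * math.sin(phi),
                   r * math.cos(pol)])
    fx["nh3"] = Molecule(("N", "H", "H", "H"),
                         np.array([[0.0, 0.0, 0.0]] + hs), name="nh3")

    # Carbon monoxide: r = 1.1283 A
    fx["co"] = Molecule(("C", "O"),
                        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.1283]]),
                        name="co")

    # Hydrogen fluoride: r = 0.9168 A
    fx["hf"] = Molecule(("H", "F"),
                        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.9168]]),
                        name="hf")

    # Methane: r(CH) = 1.086 A, tetrahedral
    d = 1.086 / math.sqrt(3)
    fx["ch4"] = Molecule(
        ("C", "H", "H", "H", "H"),
        np.array([
            [0.0, 0.0, 0.0],
            [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d],
        ]),
        name="ch4",
    )

    # Ethylene (planar, D2h): r(CC) = 1.339, r(CH) = 1.086, HCC = 121.3 deg
    rcc, rch, hcc = 1.339, 1.086, _deg(121.3)
    x = rcc / 2
    dx, dy = rch * math.cos(math.pi - hcc), rch * math.sin(math.pi - hcc)
    fx["c2h4"] = Molecule(
        ("C", "C", "H", "H", "H", "H"),
        np.array([
            [x, 0.0, 0.0], [-x, 0.0, 0.0],
            [x + dx, dy, 0.0], [x + dx, -dy, 0.0],
            [-x - dx, dy, 0.0], [-x - dx, -dy, 0.0],
        ]),
        name="c2h4",
    )

    # Formaldehyde (C2v, planar): r(CO) = 1.205, r(CH) = 1.111, HCH = 116.3 deg
    rco, rch, hch = 1.205, 1.111, _deg(116.3)
    fx["h2co"] = Molecule(
        ("O", "C", "H", "H"),
        np.array([
            [0.0, 0.0, 0.0],
            [0.0, 0.0, rco],
            [rch * math.sin(hch / 2), 0.0, rco + rch * math.cos(hch / 2)],
            [-rch * math.sin(hch / 2), 0.0, rco + rch * math.cos(hch / 2)],
        ]),
        name="h2co",
    )

    # Dihydrogen: r = 0.7414 A
    fx["h2"] = Molecule(("H", "H"),
                        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.7414]]),
                        name="h2")

    fx["he"] = Molecule(("He",), np.array([[0.0, 0.0, 0.0]]), name="he")
    return fx


FIXTURES = _build_fixtures()


def fixture(name: str) -> Molecule:
    """Return a built-in fixture molecule by name (h2o, nh3, co, hf, ch4,
    c2h4, h2co, h2, he)."""
    try:
        return FIXTURES[name.lower()]
    except KeyError:
        raise GeometryError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
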