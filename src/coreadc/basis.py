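"""Gaussian basis sets.

A small built-in library carries the standard STO-3G minimal and 6-31G
split-valence (double-zeta) sets for H-Ne as published parameter tables.
Correlation/excitation density fitting uses an even-tempered auxiliary basis
generated per element from the orbital basis ("autoaux" style): for every
auxiliary angular momentum reachable by orbital products, a geometric
progression of exponents covers the full product-exponent range.  Because
the probed states are 1s core excitations, the steep core-product exponents
are deliberately kept.

Shells are Cartesian; the orbital sets contain only s and p functions, the
auxiliary sets go up to d.  Auxiliary d shells use the 6 Cartesian
components; the (near-)linear dependency this introduces with steep s
functions is handled by the eigenvalue cutoff of the Coulomb-metric inverse
square root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecule import Molecule

__all__ = ["Shell", "BasisSet", "build_basis", "build_auxiliary_basis",
           "BasisError", "AVAILABLE_BASES"]


class BasisError(ValueError):
    """Unknown basis name or element not covered by the library."""


# --------------------------------------------------------------------------
# Built-in basis data:  {basis: {element: [(l, [exp...], [coef...]), ...]}}
# Exponents in 1/bohr^2, contraction coefficients for normalized primitives.
# --------------------------------------------------------------------------

def _sto3g():
    # STO-3G: least-squares 3-Gaussian fits to Slater functions, scaled by
    # element-specific zeta.  Base exponents for zeta = 1 and fixed
    # contraction coefficients.
    a1s = [2.227660584, 0.405771156, 0.109818]
    c1s = [0.154328967, 0.535328142, 0.444634542]
    a2sp = [0.994203, 0.231031, 0.0751386]
    c2s = [-0.099967229, 0.399512826, 0.700115469]
    c2p = [0.155916275, 0.607683719, 0.391957393]
    zetas = {  # (zeta_1s, zeta_2sp)
        "H": (1.24, None), "He": (1.69, None),
        "Li": (2.69, 0.80), "Be": (3.68, 1.15), "B": (4.68, 1.45),
        "C": (5.67, 1.72), "N": (6.67, 1.95), "O": (7.66, 2.25),
        "F": (8.65, 2.55), "Ne": (9.64, 2.88),
    }
    data = {}
    for el, (z1, z2) in zetas.items():
        shells = [(0, [a * z1 ** 2 for a in a1s], list(c1s))]
        if z2 is not None:
            exps2 = [a * z2 ** 2 for a in a2sp]
            shells.append((0, exps2, list(c2s)))
            shells.append((1, list(exps2), list(c2p)))
        data[el] = shells
    return data


def _631g():
    # 6-31G split-valence set of Pople and co-workers (H-F).
    data = {
        "H": [
            (0, [18.7311370, 2.8253937, 0.6401217],
                [0.03349460, 0.23472695, 0.81375733]),
            (0, [0.1612778], [1.0]),
        ],
        "C": [
            (0, [3047.5249, 457.36951, 103.94869, 29.210155, 9.2866630,
                 3.1639270],
                [0.0018347, 0.0140373, 0.0688426, 0.2321844, 0.4679413,
                 0.3623120]),
            (0, [7.8682724, 1.8812885, 0.5442493],
                [-0.1193324, -0.1608542, 1.1434564]),
            (1, [7.8682724, 1.8812885, 0.5442493],
                [0.0689991, 0.3164240, 0.7443083]),
            (0, [0.1687144], [1.0]),
            (1, [0.1687144], [1.0]),
        ],
        "N": [
            (0, [4173.5110, 627.45790, 142.90210, 40.234330, 12.820210,
                 4.3904370],
                [0.00183480, 0.0139950, 0.0685870, 0.2322410, 0.4690700,
                 0.3604550]),
            (0, [11.626358, 2.7162800, 0.7722180],
                [-0.1149610, -0.1691180, 1.1458520]),
            (1, [11.626358, 2.7162800, 0.7722180],
                [0.0675800, 0.3239070, 0.7408950]),
            (0, [0.2120313], [1.0]),
            (1, [0.2120313], [1.0]),
        ],
        "O": [
            (0, [5484.6717, 825.23495, 188.04696, 52.964500, 16.897570,
                 5.7996353],
                [0.00183110, 0.0139501, 0.0684451, 0.2327143, 0.4701930,
                 0.3585209]),
            (0, [15.539616, 3.5999336, 1.0137618],
                [-0.1107775, -0.1480263, 1.1307670]),
            (1, [15.539616, 3.5999336, 1.0137618],
                [0.0708743, 0.3397528, 0.7271586]),
            (0, [0.2700058], [1.0]),
            (1, [0.2700058], [1.0]),
        ],
        "F": [
            (0, [7001.7131, 1051.3660, 239.28569, 67.397445, 21.519957,
                 7.4031013],
                [0.0018196169, 0.0139160796, 0.0684053245, 0.2331857600,
                 0.4712674390, 0.3566185460]),
            (0, [20.847952, 4.8083083, 1.3440699],
                [-0.1085069750, -0.1464516580, 1.1286885800]),
            (1, [20.847952, 4.8083083, 1.3440699],
                [0.0716287243, 0.3459121030, 0.7224699570]),
            (0, [0.3581513930], [1.0]),
            (1, [0.3581513930], [1.0]),
        ],
    }
    return data


_BASIS_LIBRARY = {"sto-3g": _sto3g(), "6-31g": _631g()}
AVAILABLE_BASES = tuple(sorted(_BASIS_LIBRARY))

_DOUBLE_FACT = {0: 1.0, 1: 1.0, 2: 3.0, 3: 15.0, 4: 105.0, 5: 945.0,
                6: 10395.0}


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian powers (lx, ly, lz) of an l-shell, lexicographic order."""
    return [(lx, ly, l - lx - ly)
            for lx in range(l, -1, -1)
            for ly in range(l - lx, -1, -1)]


def primitive_norm(alpha: float, lx: int, ly: int, lz: int) -> float:
    """Self-overlap normalization of a Cartesian primitive x^lx y^ly z^lz
    exp(-alpha r^2)."""
    l = lx + ly + lz
    num = (2 * alpha / np.pi) ** 1.5 * (4 * alpha) ** l
    den = (_odd_double_factorial(lx) * _odd_double_factorial(ly)
           * _odd_double_factorial(lz))
    return float(np.sqrt(num / den))


def _odd_double_factorial(m: int) -> float:
    """(2m-1)!! with (−1)!! = 1."""
    out = 1.0
    for k in range(2 * m - 1, 0, -2):
        out *= k
    return out


@dataclass(frozen=True)
class Shell:
    """One contracted Cartesian shell on a center."""

    l: int
    exponents: np.ndarray
    coefficients: np.ndarray  # for unit-normalized primitives, then rescaled
    center: np.ndarray        # bohr
    atom_index: int
    element: str

    @property
    def n_functions(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2

    def normalized_coefficients(self, lx: int, ly: int, lz: int) -> np.ndarray:
        """Contraction coefficients including primitive norms for one
        Cartesian component, rescaled so the contracted function has unit
        self-overlap."""
        norms = np.array([primitive_norm(a, lx, ly, lz)
                          for a in self.exponents])
        c = self.coefficients * norms
        # contracted self-overlap from the 1D moment integrals
        # int x^{2m} e^{-p x^2} dx = (2m-1)!!/(2p)^m sqrt(pi/p)
        l = lx + ly + lz
        aa = self.exponents[:, None] + self.exponents[None, :]
        dfp = (_odd_double_factorial(lx) * _odd_double_factorial(ly)
               * _odd_double_factorial(lz))
        s = dfp / (2 * aa) ** l * (np.pi / aa) ** 1.5
        norm2 = c @ s @ c
        return c / np.sqrt(norm2)


class BasisSet:
    """A list of shells for a molecule, with AO indexing metadata."""

    def __init__(self, shells: list[Shell], name: str = ""):
        self.shells = shells
        self.name = name
        self.offsets = np.cumsum([0] + [sh.n_functions for sh in shells])

    @property
    def n_functions(self) -> int:
        return int(self.offsets[-1])

    def __len__(self):
        return len(self.shells)

    def function_labels(self) -> list[str]:
        lab = []
        lname = "spdfgh"
        for sh in self.shells:
            for (lx, ly, lz) in cartesian_components(sh.l):
                comp = "x" * lx + "y" * ly + "z" * lz
                lab.append(f"{sh.element}{sh.atom_index}:{lname[sh.l]}{comp}")
        return lab

    def ao_atom_indices(self) -> np.ndarray:
        return np.concatenate([
            np.full(sh.n_functions, sh.atom_index) for sh in self.shells
        ])


def build_basis(molecule: Molecule, basis_name: str) -> BasisSet:
    """Instantiate a named orbital basis on a molecule."""
    key = basis_name.lower()
    if key not in _BASIS_LIBRARY:
        raise BasisError(
            f"unknown basis {basis_name!r}; available: {AVAILABLE_BASES}")
    table = _BASIS_LIBRARY[key]
    shells = []
    coords = molecule.coords_bohr
    for iat, el in enumerate(molecule.atoms):
        if el not in table:
            raise BasisError(f"basis {basis_name!r} has no data for {el}")
        for (l, exps, coefs) in table[el]:
            shells.append(Shell(l, np.array(exps, float),
                                np.array(coefs, float), coords[iat], iat, el))
    return BasisSet(shells, name=key)


def build_auxiliary_basis(molecule: Molecule, orbital_basis: BasisSet,
                          beta: float = 2.0,
                          l_inc: int = 1,
                          l_max_cap: int = 2) -> BasisSet:
    """Even-tempered fitting basis generated from the orbital basis.

    For each element, the primitive exponents are grouped by angular
    momentum; every pair (l1, l2) of orbital shells produces candidate
    auxiliary momenta |l1-l2| ... l1+l2+l_inc with exponents
    alpha1+alpha2.  The auxiliary set for momentum L is a geometric ladder
    with ratio ``beta`` spanning the product-exponent range.  ``l_inc``
    raises the angular coverage beyond the strict on-center product rule
    (off-center products carry higher multipoles - without it, hydrogen
    would get an s-only fitting set); ``l_max_cap`` bounds the auxiliary
    angular momentum (d suffices for s/p orbital bases)."""
    per_element: dict[str, list[tuple[int, float]]] = {}
    for sh in orbital_basis.shells:
        per_element.setdefault(sh.element, [])
    # exponent lists per element per l
    el_l_exps: dict[str, dict[int, list[float]]] = {}
    for sh in orbital_basis.shells:
        el_l_exps.setdefault(sh.element, {}).setdefault(sh.l, []).extend(
            float(a) for a in sh.exponents)

    aux_table: dict[str, list[tuple[int, list[float]]]] = {}
    for el, lmap in el_l_exps.items():
        bounds: dict[int, list[float]] = {}
        for l1, e1 in lmap.items():
            for l2, e2 in lmap.items():
                lo = min(e1) + min(e2)
                hi = max(e1) + max(e2)
                for L in range(abs(l1 - l2),
                               min(l1 + l2 + l_inc, l_max_cap) + 1):
                    if L in bounds:
                        bounds[L][0] = min(bounds[L][0], lo)
                        bounds[L][1] = max(bounds[L][1], hi)
                    else:
                        bounds[L] = [lo, hi]
        shells = []
        for L in sorted(bounds):
            lo, hi = bounds[L]
            n = max(1, int(np.ceil(np.log(hi / lo) / np.log(beta))) + 1)
            exps = lo * beta ** np.arange(n)
            for a in exps:
                shells.append((L, [float(a)]))
        aux_table[el] = shells

    shells = []
    coords = molecule.coords_bohr
    for iat, el in enumerate(molecule.atoms):
        for (L, exps) in aux_table[el]:
            shells.append(Shell(L, np.array(exps), np.ones(len(exps)),
                                coords[iat], iat, el))
    return BasisSet(shells, name=f"etb-aux(beta={beta})")
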