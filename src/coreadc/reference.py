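"""Hartree-Fock reference and the core-valence-separated orbital partition.

``compute_reference`` produces a converged closed-shell RHF reference with
its basis/auxiliary-basis metadata.  ``partition_orbitals`` splits the
canonical MOs into the four CVS classes used by every correlated module:

* ``active_core``       (labels I, J) - the probed 1s core orbitals,
* ``inactive_occupied`` (labels i, j) - remaining correlated occupieds,
* ``frozen_core``       - deep 1s orbitals of other heavy atoms, dropped
  from all correlated sums,
* ``virtual``           (labels a, b).

Active cores are identified by Mulliken population on the 1s atomic
functions of the selected element rather than by energy order, which keeps
the selection stable for equivalent atoms with near-degenerate core levels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import integrals
from .basis import BasisSet, build_basis, build_auxiliary_basis
from .constants import FIRST_ROW_CORE_ELEMENTS
from .molecule import Molecule
from .scf import ScfResult, restricted_hartree_fock


class CvsSelectionError(ValueError):
    """The CVS selector matched no suitable occupied orbital."""


@dataclass
class ScfReference:
    """Converged RHF reference plus basis metadata."""

    molecule: Molecule
    basis: BasisSet
    aux_basis: BasisSet
    mo_coefficients: np.ndarray   # (nao, nmo)
    orbital_energies: np.ndarray  # Hartree
    n_occupied: int
    hf_energy: float
    overlap: np.ndarray
    _ao_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_mo(self) -> int:
        return self.mo_coefficients.shape[1]

    @property
    def n_virtual(self) -> int:
        return self.n_mo - self.n_occupied

    # --- cached AO-basis integral helpers -------------------------------
    def ao_three_center(self) -> np.ndarray:
        if "3c" not in self._ao_cache:
            self._ao_cache["3c"] = integrals.three_center(
                self.basis, self.aux_basis)
        return self._ao_cache["3c"]

    def ao_metric(self) -> np.ndarray:
        if "2c" not in self._ao_cache:
            self._ao_cache["2c"] = integrals.two_center_coulomb(self.aux_basis)
        return self._ao_cache["2c"]

    def ao_dipole(self, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
        return integrals.dipole(self.basis, origin)


@dataclass(frozen=True)
class OrbitalSpace:
    """The CVS partition of the canonical MO list."""

    frozen_core: tuple[int, ...]
    active_core: tuple[int, ...]
    inactive_occupied: tuple[int, ...]
    virtual: tuple[int, ...]
    orbital_energies: np.ndarray
    freeze_in_doubles: bool = True  # frozen cores also excluded from the
    #                                 excited-state doubles space

    def __post_init__(self):
        groups = [set(self.frozen_core), set(self.active_core),
                  set(self.inactive_occupied), set(self.virtual)]
        total = set()
        for g in groups:
            if g & total:
                raise ValueError("orbital classes overlap")
            total |= g
        if total != set(range(len(self.orbital_energies))):
            raise ValueError("orbital classes do not cover all MOs")
        if not self.active_core:
            raise CvsSelectionError("no active core orbital selected")

    @property
    def n_core(self) -> int:
        return len(self.active_core)

    @property
    def n_occ(self) -> int:
        return len(self.inactive_occupied)

    @property
    def n_virt(self) -> int:
        return len(self.virtual)

    @property
    def eps_core(self) -> np.ndarray:
        return self.orbital_energies[list(self.active_core)]

    @property
    def eps_occ(self) -> np.ndarray:
        return self.orbital_energies[list(self.inactive_occupied)]

    @property
    def eps_virt(self) -> np.ndarray:
        return self.orbital_energies[list(self.virtual)]

    @property
    def correlated_occupied(self) -> tuple[int, ...]:
        """Occupied MOs entering the ground-state MP2 amplitudes:
        active core + inactive occupied (frozen cores excluded)."""
        return tuple(self.active_core) + tuple(self.inactive_occupied)

    def with_virtual_subset(self, eps_virt_new: np.ndarray) -> "OrbitalSpace":
        """A copy whose virtual space has been replaced by a (truncated,
        semicanonical) set with energies ``eps_virt_new``.  Virtual MO
        indices are renumbered to follow the occupied block."""
        nocc_all = (len(self.frozen_core) + len(self.active_core)
                    + len(self.inactive_occupied))
        nv = len(eps_virt_new)
        energies = np.concatenate([
            self.orbital_energies[:nocc_all], np.asarray(eps_virt_new)])
        return OrbitalSpace(self.frozen_core, self.active_core,
                            self.inactive_occupied,
                            tuple(range(nocc_all, nocc_all + nv)),
                            energies, self.freeze_in_doubles)


def _cache_key(molecule: Molecule, basis: str, beta: float) -> str:
    import hashlib
    h = hashlib.sha256()
    h.update(basis.lower().encode())
    h.update(f"beta={beta:.6f}".encode())
    for sym, xyz in zip(molecule.atoms, molecule.coordinates):
        h.update(sym.encode())
        h.update(np.round(xyz, 8).tobytes())
    h.update(str(molecule.charge).encode())
    return h.hexdigest()[:24]


def compute_reference(molecule: Molecule, basis: str,
                      aux_basis: str = "auto",
                      scf_convergence: float = 1.0e-10,
                      cache_dir: str | None = None) -> ScfReference:
    """Run closed-shell RHF and return the reference.

    ``aux_basis='auto'`` builds the even-tempered fitting basis from the
    orbital basis; ``'auto/<beta>'`` overrides the progression ratio.
    The SCF Fock matrices are built from DF-reconstructed integrals, so the
    reference is itself a density-fitted one (matching the correlated
    treatment).  ``cache_dir`` enables an on-disk store of the AO
    three-center integrals and metric, keyed by geometry and basis."""
    bs = build_basis(molecule, basis)
    if aux_basis in (None, "auto") or str(aux_basis).startswith("auto"):
        beta = 2.0
        if isinstance(aux_basis, str) and "/" in aux_basis:
            beta = float(aux_basis.split("/", 1)[1])
        aux = build_auxiliary_basis(molecule, bs, beta=beta)
    else:
        raise ValueError(
            f"unknown auxiliary basis {aux_basis!r}; use 'auto' or "
            "'auto/<beta>'")

    p3 = v2 = None
    cache_file = None
    if cache_dir is not None:
        import h5py
        import os
        os.makedirs(cache_dir, exist_ok=True)
        cache_file = os.path.join(
            cache_dir, f"df-{_cache_key(molecule, basis, beta)}.h5")
        if os.path.exists(cache_file):
            with h5py.File(cache_file, "r") as fh:
                p3 = fh["three_center"][...]
                v2 = fh["metric"][...]
    if p3 is None:
        p3 = integrals.three_center(bs, aux)
        v2 = integrals.two_center_coulomb(aux)
        if cache_file is not None:
            import h5py
            with h5py.File(cache_file, "w") as fh:
                fh.create_dataset("three_center", data=p3)
                fh.create_dataset("metric", data=v2)
    w, u = np.linalg.eigh(v2)
    keep = w > 1.0e-10
    vih = (u[:, keep] * w[keep] ** -0.5) @ u[:, keep].T
    bfac = p3 @ vih
    eri = np.einsum("mnP,rsP->mnrs", bfac, bfac, optimize=True)
    res: ScfResult = restricted_hartree_fock(
        molecule, bs, eri, convergence=scf_convergence)
    if res.n_occupied >= res.mo_coefficients.shape[1]:
        raise ValueError("no virtual orbitals in this basis")
    ref = ScfReference(molecule, bs, aux, res.mo_coefficients,
                       res.orbital_energies, res.n_occupied, res.energy,
                       res.overlap)
    ref._ao_cache["3c"] = p3
    ref._ao_cache["2c"] = v2
    return ref


_CVS_RE = re.compile(r"^([A-Z][a-z]?)\s*1s$")


def _core_1s_ao_indices(ref: ScfReference, element: str) -> np.ndarray:
    """AO indices of the steepest (1s-like) contracted s function on each
    atom of the given element."""
    idx = []
    by_atom: dict[int, tuple[float, int]] = {}
    for ish, sh in enumerate(ref.basis.shells):
        if sh.element != element or sh.l != 0:
            continue
        steep = float(np.max(sh.exponents))
        off = int(ref.basis.offsets[ish])
        cur = by_atom.get(sh.atom_index)
        if cur is None or steep > cur[0]:
            by_atom[sh.atom_index] = (steep, off)
    idx = [off for (_, off) in by_atom.values()]
    return np.array(sorted(idx), dtype=int)


def mulliken_populations(ref: ScfReference, ao_indices: np.ndarray
                         ) -> np.ndarray:
    """Per-MO summed Mulliken population on a set of AOs."""
    c = ref.mo_coefficients
    sc = ref.overlap @ c
    return np.einsum("mp,mp->p", c[ao_indices], sc[ao_indices])


def partition_orbitals(ref: ScfReference, cvs_spec: str,
                       frozen_policy: str = "freeze-other-cores",
                       population_threshold: float = 0.5) -> OrbitalSpace:
    """Build the CVS orbital partition.

    ``cvs_spec`` is an element/shell selector such as ``"O 1s"`` or
    ``"C1s"``.  Occupied canonical MOs whose summed Mulliken population on
    the selected element's 1s atomic functions exceeds
    ``population_threshold`` become the active cores.  ``frozen_policy``:

    * ``"freeze-other-cores"`` (default): 1s orbitals of other first-row
      heavy atoms are frozen everywhere (ground-state amplitudes and the
      excited-state doubles space),
    * ``"mp2-only"``: frozen in the ground-state amplitudes only,
    * ``"none"``: nothing frozen.
    """
    # normalize e.g. "o 1s" -> "O1s"
    spec = (cvs_spec or "").replace(" ", "").replace("_", "")
    if not spec:
        raise CvsSelectionError("empty CVS selector")
    spec = (spec[0].upper() + spec[1:]).replace("1S", "1s")
    m = _CVS_RE.match(spec)
    if not m:
        raise CvsSelectionError(
            f"cannot parse CVS selector {cvs_spec!r}; expected '<El> 1s'")
    element = m.group(1)
    if element not in {a for a in ref.molecule.atoms}:
        raise CvsSelectionError(
            f"element {element} not present in the molecule")
    if element not in FIRST_ROW_CORE_ELEMENTS:
        raise CvsSelectionError(
            f"{element} has no 1s core shell treatable by this CVS setup")

    ao_1s = _core_1s_ao_indices(ref, element)
    pops = mulliken_populations(ref, ao_1s)
    nocc = ref.n_occupied
    active = [p for p in range(nocc) if pops[p] >= population_threshold]
    if not active:
        raise CvsSelectionError(
            f"no occupied MO carries >= {population_threshold} Mulliken "
            f"population on the {element} 1s functions")
    virt_hits = [p for p in range(nocc, ref.n_mo)
                 if pops[p] >= population_threshold]
    if virt_hits:
        raise CvsSelectionError(
            f"CVS selector matched virtual orbitals {virt_hits}")

    frozen: list[int] = []
    if frozen_policy in ("freeze-other-cores", "mp2-only"):
        for other in sorted(set(ref.molecule.atoms)
                            & FIRST_ROW_CORE_ELEMENTS - {element}):
            ao_o = _core_1s_ao_indices(ref, other)
            pop_o = mulliken_populations(ref, ao_o)
            frozen.extend(p for p in range(nocc)
                          if pop_o[p] >= population_threshold
                          and p not in active)
    elif frozen_policy != "none":
        raise ValueError(f"unknown frozen_policy {frozen_policy!r}")

    inactive = [p for p in range(nocc) if p not in active and p not in frozen]
    return OrbitalSpace(tuple(sorted(frozen)), tuple(sorted(active)),
                        tuple(sorted(inactive)),
                        tuple(range(nocc, ref.n_mo)),
                        ref.orbital_energies.copy(),
                        freeze_in_doubles=(frozen_policy != "mp2-only"))
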