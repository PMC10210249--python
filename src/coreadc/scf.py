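"""Restricted Hartree-Fock with DIIS convergence acceleration.

The Fock build works from an in-memory four-index ERI tensor.  The
production path reconstructs that tensor from the density-fitting factors
(the systems this package targets are small enough for an O(N^4) store);
an exact dense-integral route is kept for validation work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .basis import BasisSet
from . import integrals
from .molecule import Molecule


class ScfConvergenceError(RuntimeError):
    def __init__(self, n_iter, error, energy_trace):
        super().__init__(
            f"SCF failed to converge in {n_iter} iterations "
            f"(last DIIS error {error:.3e}); energy trace: "
            + ", ".join(f"{e:.8f}" for e in energy_trace[-5:]))
        self.n_iter = n_iter
        self.error = error
        self.energy_trace = energy_trace


@dataclass
class ScfResult:
    energy: float                 # total HF energy, Hartree
    mo_coefficients: np.ndarray   # (nao, nmo)
    orbital_energies: np.ndarray  # (nmo,), Hartree
    n_occupied: int
    overlap: np.ndarray
    core_hamiltonian: np.ndarray
    n_iterations: int


def restricted_hartree_fock(molecule: Molecule, basis: BasisSet,
                            eri: np.ndarray,
                            max_iterations: int = 100,
                            convergence: float = 1.0e-10,
                            diis_depth: int = 8) -> ScfResult:
    """Solve the closed-shell RHF equations.

    ``eri`` is the four-index (mu nu | rho sigma) tensor (exact or
    DF-reconstructed).  Convergence is measured on the orbital-rotation
    gradient FDS - SDF; DIIS extrapolation starts from the second
    iteration, seeded by the core-Hamiltonian guess.
    """
    nel = molecule.n_electrons
    nocc = nel // 2
    s = integrals.overlap(basis)
    t = integrals.kinetic(basis)
    v = integrals.nuclear_attraction(
        basis, molecule.nuclear_charges, molecule.coords_bohr)
    hcore = t + v
    if nocc > basis.n_functions:
        raise ValueError("basis too small for the electron count")

    # symmetric orthogonalizer
    w, u = np.linalg.eigh(s)
    if w.min() < 1.0e-10:
        raise ValueError("orbital basis is numerically linearly dependent")
    x = u @ np.diag(w ** -0.5) @ u.T

    def fock(dm):
        j = np.einsum("mnrs,rs->mn", eri, dm, optimize=True)
        k = np.einsum("mrns,rs->mn", eri, dm, optimize=True)
        return hcore + j - 0.5 * k

    def density(c):
        cocc = c[:, :nocc]
        return 2.0 * cocc @ cocc.T

    # core guess
    e_mo, c = sla.eigh(hcore, s)
    dm = density(c)
    enuc = molecule.nuclear_repulsion()
    energies = []
    diis_f, diis_e = [], []
    err_norm = np.inf
    for it in range(1, max_iterations + 1):
        f = fock(dm)
        err = f @ dm @ s - s @ dm @ f
        err = x.T @ err @ x
        err_norm = np.abs(err).max()
        e_tot = 0.5 * np.einsum("mn,mn->", dm, hcore + f) + enuc
        energies.append(e_tot)
        if err_norm < convergence and it > 1:
            return ScfResult(e_tot, c, e_mo, nocc, s, hcore, it)
        diis_f.append(f)
        diis_e.append(err.ravel())
        if len(diis_f) > diis_depth:
            diis_f.pop(0)
            diis_e.pop(0)
        if len(diis_f) > 1:
            nd = len(diis_f)
            bmat = -np.ones((nd + 1, nd + 1))
            bmat[-1, -1] = 0.0
            for i in range(nd):
                for j in range(nd):
                    bmat[i, j] = diis_e[i] @ diis_e[j]
            rhs = np.zeros(nd + 1)
            rhs[-1] = -1.0
            try:
                coef = np.linalg.solve(bmat, rhs)[:nd]
                f = sum(ci * fi for ci, fi in zip(coef, diis_f))
            except np.linalg.LinAlgError:
                pass
        e_mo, c = sla.eigh(f, s)
        dm = density(c)
    raise ScfConvergenceError(max_iterations, err_norm, energies)
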