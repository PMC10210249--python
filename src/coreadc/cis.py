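"""CVS-CIS: configuration-interaction singles restricted to core holes.

Provides the spin-adapted singlet sigma vector built from DF integrals, a
block-Davidson eigensolver for the lowest core-excited CIS states, and the
dense CVS-CIS matrix helper used for small-space diagnostics and
preconditioning.  CIS states seed the CVS-ADC(2) solver and enter the
CIS(D) density of the compression pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .df import DfTensor
from .reference import OrbitalSpace


class CisError(RuntimeError):
    pass


@dataclass
class SinglesVector:
    """Singles amplitudes r_{Ia} over (active core) x (virtual)."""

    amplitudes: np.ndarray  # (n_core, n_virt)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def normalized(self) -> "SinglesVector":
        n = self.norm
        if n == 0.0:
            raise CisError("cannot normalize a zero singles vector")
        return SinglesVector(self.amplitudes / n)


def cis_sigma(r: np.ndarray, j: DfTensor, space: OrbitalSpace,
              coupling: bool = True) -> np.ndarray:
    """Singlet CVS-CIS sigma:  sigma_Ia = (eps_a - eps_I) r_Ia
    + sum_Jb [2 (Ia|Jb) - (IJ|ab)] r_Jb  (DF-reconstructed ERIs).

    ``coupling=False`` keeps only the orbital-energy diagonal."""
    nc, nv = space.n_core, space.n_virt
    if r.shape != (nc, nv):
        raise CisError(f"singles vector shape {r.shape} does not match "
                       f"the CVS space ({nc}, {nv})")
    de = space.eps_virt[None, :] - space.eps_core[:, None]
    sigma = de * r
    if coupling:
        jcv = j.block("cv")
        jcc = j.block("cc")
        jvv = j.block("vv")
        w = np.einsum("QJb,Jb->Q", jcv, r, optimize=True)
        sigma += 2.0 * np.einsum("QIa,Q->Ia", jcv, w, optimize=True)
        sigma -= np.einsum("QIJ,Qab,Jb->Ia", jcc, jvv, r, optimize=True)
    return sigma


def dense_cis_matrix(j: DfTensor, space: OrbitalSpace) -> np.ndarray:
    """Explicit (n_core*n_virt)^2 singlet CVS-CIS matrix (small spaces)."""
    nc, nv = space.n_core, space.n_virt
    dim = nc * nv
    m = np.empty((dim, dim))
    for col in range(dim):
        unit = np.zeros(dim)
        unit[col] = 1.0
        m[:, col] = cis_sigma(unit.reshape(nc, nv), j, space).ravel()
    return 0.5 * (m + m.T)


def solve_cis(n_states: int, j: DfTensor, space: OrbitalSpace,
              tol: float = 1.0e-7, max_iterations: int = 120,
              dense_cutoff: int | None = None
              ) -> list[tuple[float, SinglesVector]]:
    """Lowest singlet CVS-CIS eigenpairs by block Davidson.

    Diagonal preconditioner eps_a - eps_I - omega; the subspace collapses
    to the current Ritz vectors when it exceeds 20 x n_states.  Problems
    up to ``dense_cutoff`` (default max(60, 4 n_states)) are diagonalized
    densely instead."""
    nc, nv = space.n_core, space.n_virt
    dim = nc * nv
    if n_states < 1 or n_states > dim:
        raise CisError(
            f"requested {n_states} states from a singles space of size {dim}")
    diag = (space.eps_virt[None, :] - space.eps_core[:, None]).ravel()

    if dense_cutoff is None:
        dense_cutoff = max(60, 4 * n_states)
    if dim <= dense_cutoff:
        # small space: dense diagonalization is both faster and exact
        m = dense_cis_matrix(j, space)
        w, v = np.linalg.eigh(m)
        return [(float(w[k]), SinglesVector(v[:, k].reshape(nc, nv)))
                for k in range(n_states)]

    # padded guess block guards against root skipping
    n_guess = min(dim, n_states + 3)
    order = np.argsort(diag)
    bvec = np.zeros((dim, n_guess))
    for k in range(n_guess):
        bvec[order[k], k] = 1.0
    vs = [bvec[:, k] for k in range(n_guess)]
    max_sub = 20 * n_states
    sigmas: list[np.ndarray] = []
    for _ in range(max_iterations):
        for k in range(len(sigmas), len(vs)):
            sigmas.append(cis_sigma(vs[k].reshape(nc, nv), j, space).ravel())
        vmat = np.column_stack(vs)
        smat = np.column_stack(sigmas)
        hsub = vmat.T @ smat
        hsub = 0.5 * (hsub + hsub.T)
        w, c = np.linalg.eigh(hsub)
        ritz_v = vmat @ c[:, :n_states]
        ritz_s = smat @ c[:, :n_states]
        resid = ritz_s - ritz_v * w[:n_states]
        rnorm = np.linalg.norm(resid, axis=0)
        if np.all(rnorm < tol):
            return [(float(w[k]), SinglesVector(
                ritz_v[:, k].reshape(nc, nv))) for k in range(n_states)]
        if len(vs) + n_states > max_sub:
            vs = [ritz_v[:, k] for k in range(n_states)]
            sigmas = [ritz_s[:, k] for k in range(n_states)]
            vmat = np.column_stack(vs)
        for k in range(n_states):
            if rnorm[k] < tol:
                continue
            denom = diag - w[k]
            denom = np.where(np.abs(denom) < 1e-8, 1e-8, denom)
            new = resid[:, k] / denom
            basis = np.column_stack(vs)
            new -= basis @ (basis.T @ new)
            new -= basis @ (basis.T @ new)
            nn = np.linalg.norm(new)
            if nn > 1e-8:
                vs.append(new / nn)
    raise CisError(
        f"CVS-CIS Davidson did not converge below {tol} in "
        f"{max_iterations} iterations (residuals {rnorm})")
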