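"""Cost-reduction core: natural auxiliary functions (NAFs) and state-
specific frozen virtual natural orbitals (VNOs).

NAFs are eigenvectors of W = sum_pq J_pq (x) J_pq over the auxiliary index;
the eigenvalues are squared singular values of the unfolded three-center
matrix and measure each fitting function's importance.  Functions whose
singular value falls below eps_naf are dropped (a global truncation on the
canonical integral list, and a second, much stronger one per state in the
truncated VNO basis - both with the same cutoff).

VNOs diagonalize a state-averaged virtual-virtual one-particle density
D = (D_MP2 + D_CVS-CIS(D))/2 so that ground- and excited-state equations
share one reduced subspace; eigenvectors with |occupation| below eps_vno
are dropped and the kept block is semicanonicalized (the virtual-virtual
Fock rediagonalized) so orbital-energy denominators stay valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adc2 import doubles_amplitudes
from .cis import SinglesVector
from .df import DfTensor
from .reference import OrbitalSpace

DEFAULT_EPS_NAF = 0.1      # au, on the singular-value scale
DEFAULT_EPS_VNO = 7.5e-5   # occupation-number scale


class CompressionError(RuntimeError):
    pass


@dataclass
class NafBasis:
    """Retained natural-auxiliary-function rotation."""

    rotation: np.ndarray      # (n_Q, n_kept), orthonormal columns
    importance: np.ndarray    # all W eigenvalues, descending
    n_kept: int

    @property
    def n_total(self) -> int:
        return self.rotation.shape[0]

    @property
    def kept_fraction(self) -> float:
        return self.n_kept / self.n_total

    @property
    def singular_values(self) -> np.ndarray:
        return np.sqrt(np.clip(self.importance, 0.0, None))

    @property
    def discarded_frobenius(self) -> float:
        """Frobenius norm of the discarded part of J:
        sqrt(sum of dropped W eigenvalues)."""
        return float(np.sqrt(max(0.0, self.importance[self.n_kept:].sum())))


@dataclass
class StateDensity:
    """State-averaged virtual-virtual density with its components."""

    d_vv: np.ndarray
    d_mp2: np.ndarray
    d_cisd: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.d_vv, self.d_vv.T, atol=1e-12):
            raise CompressionError("state density is not symmetric")


@dataclass
class SubspaceMap:
    """State-specific reduced problem: VNO rotation + final NAF rotation."""

    vno_rotation: np.ndarray          # (n_virt, n_kept)
    semicanonical_energies: np.ndarray
    naf_final: NafBasis
    reduced_j: DfTensor
    reduced_space: OrbitalSpace
    retained_vno_fraction: float
    retained_naf_fraction: float      # after the second truncation
    bookkeeping: dict = field(default_factory=dict)

    def project_singles(self, r: np.ndarray) -> np.ndarray:
        """Map a singles vector into the reduced virtual space."""
        return r @ self.vno_rotation


def build_naf(j: DfTensor, eps_naf: float = DEFAULT_EPS_NAF) -> NafBasis:
    """Diagonalize W = sum_pq J_pq (x) J_pq and keep NAFs whose singular
    value (sqrt of the W eigenvalue, in au) is >= eps_naf.

    Off-diagonal MO-group blocks enter twice, representing both (p,q) and
    (q,p) entries of the full integral list."""
    if eps_naf < 0:
        raise ValueError("eps_naf must be non-negative")
    nq = j.n_aux
    w = np.zeros((nq, nq))
    for key, block in j.blocks.items():
        flat = block.reshape(nq, -1)
        contrib = flat @ flat.T
        w += contrib if key[0] == key[1] else 2.0 * contrib
    if not np.allclose(w, w.T, atol=1e-10):
        raise CompressionError("NAF matrix W is not symmetric")
    evals, evecs = np.linalg.eigh(w)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    sv = np.sqrt(np.clip(evals, 0.0, None))
    n_kept = int(np.sum(sv >= eps_naf)) if eps_naf > 0 else nq
    n_kept = max(n_kept, 1)
    return NafBasis(evecs[:, :n_kept], evals, n_kept)


def mp2_vv_density(j: DfTensor, space: OrbitalSpace) -> np.ndarray:
    """Unrelaxed MP2 virtual-virtual density (frozen-core amplitudes):

    D_ab = 2 sum_ijc t[i,a,j,c] (2 t[i,b,j,c] - t[i,c,j,b]),
    accumulated pair-wise without storing the full amplitude tensor."""
    from .adc2 import _occ_blocks, _eps_all_occ
    if space.n_virt == 0:
        raise CompressionError("no virtual orbitals to correlate")
    jkv, _ = _occ_blocks(j)
    eps_k = _eps_all_occ(space)
    eps_v = space.eps_virt
    nk, nv = len(eps_k), len(eps_v)
    d = np.zeros((nv, nv))
    for k in range(nk):
        for l in range(nk):
            kint = jkv[:, k, :].T @ jkv[:, l, :]
            den = eps_k[k] + eps_k[l] - eps_v[:, None] - eps_v[None, :]
            t_kl = kint / den
            d += 2.0 * t_kl @ (2.0 * t_kl - t_kl.T).T
    return 0.5 * (d + d.T)


def cisd_vv_density(j: DfTensor, cis_state: tuple[float, SinglesVector],
                    space: OrbitalSpace,
                    include_doubles: bool = True) -> np.ndarray:
    """Virtual-virtual density of the CVS-CIS(D) wave function.

    CIS term sum_I r_Ia r_Ib plus the doubles term built from the
    omega-dependent doubles coefficients evaluated at omega_CIS."""
    omega_cis, vec = cis_state
    r = vec.amplitudes
    if abs(np.linalg.norm(r) - 1.0) > 1e-8:
        raise CompressionError(
            f"CIS vector is not normalized (|r| = {np.linalg.norm(r):.6f})")
    d = r.T @ r
    if include_doubles:
        b1 = doubles_amplitudes(r, omega_cis, j, space)  # B[I,c,j,d]
        d += 2.0 * (np.einsum("Iajc,Ibjc->ab", b1, b1, optimize=True)
                    + np.einsum("Icja,Icjb->ab", b1, b1, optimize=True))
        d -= (np.einsum("Iajc,Icjb->ab", b1, b1, optimize=True)
              + np.einsum("Icja,Ibjc->ab", b1, b1, optimize=True))
    return 0.5 * (d + d.T)


def state_averaged_density(d_mp2: np.ndarray,
                           d_cisd: np.ndarray) -> StateDensity:
    """Equal-weight average D = (D_MP2 + D_CIS(D)) / 2."""
    d_mp2 = np.asarray(d_mp2, float)
    d_cisd = np.asarray(d_cisd, float)
    if d_mp2.shape != d_cisd.shape:
        raise CompressionError(
            f"density dimension mismatch: {d_mp2.shape} vs {d_cisd.shape}")
    return StateDensity(0.5 * (d_mp2 + d_cisd), d_mp2, d_cisd)


def build_vno(density: StateDensity, space: OrbitalSpace,
              eps_vno: float = DEFAULT_EPS_VNO):
    """VNO rotation from the state-averaged density.

    Eigenvectors with |eigenvalue| >= eps_vno are kept (magnitude ranking:
    CIS(D) densities may carry slightly negative eigenvalues); the kept
    block is semicanonicalized against the diagonal virtual Fock.

    Returns (rotation, semicanonical_energies, occupations_descending)."""
    if eps_vno < 0:
        raise ValueError("eps_vno must be non-negative")
    evals, evecs = np.linalg.eigh(density.d_vv)
    order = np.argsort(np.abs(evals))[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = np.abs(evals) >= eps_vno
    if eps_vno == 0.0:
        keep[:] = True
    if not np.any(keep):
        raise CompressionError(
            f"eps_vno = {eps_vno:g} discards every virtual natural orbital")
    u = evecs[:, keep]
    # semicanonicalize: rediagonalize the (diagonal) virtual-virtual Fock
    f_red = (u * space.eps_virt[:, None]).T @ u
    w, c = np.linalg.eigh(0.5 * (f_red + f_red.T))
    return u @ c, w, evals


def reduce_state(j: DfTensor, cis_state: tuple[float, SinglesVector],
                 space: OrbitalSpace,
                 eps_naf: float = DEFAULT_EPS_NAF,
                 eps_vno: float = DEFAULT_EPS_VNO,
                 naf_total_aux: int | None = None) -> SubspaceMap:
    """State-specific reduction: state-averaged density -> VNO truncation
    -> J in the kept semicanonical VNO basis -> second NAF truncation with
    the same eps_naf.

    ``j`` must already carry the global NAF truncation;
    ``naf_total_aux`` is the pre-truncation auxiliary dimension used for
    bookkeeping (defaults to the current one)."""
    d_mp2 = mp2_vv_density(j, space)
    d_cisd = cisd_vv_density(j, cis_state, space)
    density = state_averaged_density(d_mp2, d_cisd)
    vno_rot, eps_tilde, occupations = build_vno(density, space, eps_vno)

    reduced_space = space.with_virtual_subset(eps_tilde)
    j_vno = j.rotate_virtual(vno_rot, reduced_space)
    naf2 = build_naf(j_vno, eps_naf)
    j_red = j_vno.rotate_auxiliary(naf2.rotation)

    n_total_aux = naf_total_aux or j.n_aux
    return SubspaceMap(
        vno_rotation=vno_rot,
        semicanonical_energies=eps_tilde,
        naf_final=naf2,
        reduced_j=j_red,
        reduced_space=reduced_space,
        retained_vno_fraction=vno_rot.shape[1] / space.n_virt,
        retained_naf_fraction=naf2.n_kept / n_total_aux,
        bookkeeping={
            "n_vno_kept": vno_rot.shape[1],
            "n_virt": space.n_virt,
            "n_naf_kept": naf2.n_kept,
            "n_aux_total": n_total_aux,
            "n_aux_stage1": j.n_aux,
            "occupations": occupations,
        },
    )
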