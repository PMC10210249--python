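"""Brute-force validation references (test-only; never reachable from the
CLI).

Three layers, in increasing specialization:

1. A second-quantized determinant engine: Slater determinants are occupied
   spin-orbital tuples; the Hamiltonian and the total-spin operator S^2 are
   applied operator by operator, with phases from explicit creation /
   annihilation bookkeeping.  This gives full CI and arbitrary CI blocks
   with no transcribed matrix-element formulas at all.

2. ``DenseAdcMatrix``: the explicit CVS-ADC(2) secular matrix in the
   spin-orbital basis.  The singles-singles first-order block and the
   singles-doubles coupling are exact CI matrix elements from layer 1 (for
   canonical HF orbitals the CI coupling *is* the strict second-order
   coupling); the doubles-doubles block is the zeroth-order orbital-energy
   diagonal; only the second-order singles-singles term is written as a
   formula -- and that term is validated by the perturbation-order test
   against full CI (the poles of the second-order secular matrix must agree
   with exact excitation energies through second order in the fluctuation
   potential).

3. Closed-form two-level (one occupied / one virtual) MP2 and singlet CIS
   expressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "spin_orbital_integrals", "Determinant", "build_hamiltonian",
    "s_squared_matrix", "hartree_fock_determinant", "fci_states",
    "DenseAdcMatrix", "build_dense_adc_matrix", "two_level_closed_forms",
]

Determinant = tuple[int, ...]  # sorted occupied spin-orbital indices


# ---------------------------------------------------------------------------
# layer 1: determinant engine
# ---------------------------------------------------------------------------

def spin_orbital_integrals(eps: np.ndarray, eri_mo: np.ndarray):
    """Expand spatial quantities to spin orbitals (even index = alpha,
    odd = beta).  Returns the spin-orbital orbital energies and the
    antisymmetrized two-electron integrals <pq||rs> in physicists'
    notation."""
    n = len(eps)
    nso = 2 * n
    g = np.zeros((nso, nso, nso, nso))
    # <pq|rs> = (pr|qs) with spin deltas p~r, q~s
    for sp in (0, 1):
        for sq in (0, 1):
            g[sp::2][:, sq::2][:, :, sp::2][:, :, :, sq::2] += \
                eri_mo.transpose(0, 2, 1, 3)
    g_anti = g - g.transpose(0, 1, 3, 2)
    eps_so = np.repeat(eps, 2)
    return eps_so, g_anti


def _annihilate(det: Determinant, p: int):
    if p not in det:
        return None, 0
    pos = det.index(p)
    return det[:pos] + det[pos + 1:], (-1) ** pos


def _create(det: Determinant, p: int):
    if p in det:
        return None, 0
    pos = 0
    while pos < len(det) and det[pos] < p:
        pos += 1
    return det[:pos] + (p,) + det[pos:], (-1) ** pos


def apply_excitation(det: Determinant, a: int, b: int, j: int, i: int):
    """a+_a a+_b a_j a_i |det> -> (det', phase) or (None, 0)."""
    d, s1 = _annihilate(det, i)
    if d is None:
        return None, 0
    d, s2 = _annihilate(d, j)
    if d is None:
        return None, 0
    d, s3 = _create(d, b)
    if d is None:
        return None, 0
    d, s4 = _create(d, a)
    if d is None:
        return None, 0
    return d, s1 * s2 * s3 * s4


def apply_single(det: Determinant, p: int, q: int):
    """a+_p a_q |det>."""
    d, s1 = _annihilate(det, q)
    if d is None:
        return None, 0
    d, s2 = _create(d, p)
    if d is None:
        return None, 0
    return d, s1 * s2


def build_hamiltonian(dets: list[Determinant], h_so: np.ndarray,
                      g_anti: np.ndarray) -> np.ndarray:
    """Dense Hamiltonian matrix over a determinant list.

    ``h_so`` is the one-body matrix in spin orbitals, ``g_anti`` the
    antisymmetrized two-electron integrals <pq||rs>.  Built by operator
    application: H = sum h_pq p+q + 1/4 sum <pq||rs> p+q+ s r."""
    index = {d: k for k, d in enumerate(dets)}
    n = len(dets)
    nso = h_so.shape[0]
    ham = np.zeros((n, n))
    nz_h = [(p, q) for p in range(nso) for q in range(nso)
            if abs(h_so[p, q]) > 1e-300]
    for kd, det in enumerate(dets):
        # one body
        for p, q in nz_h:
            d, ph = apply_single(det, p, q)
            if d is not None and d in index:
                ham[index[d], kd] += ph * h_so[p, q]
        # two body: 1/4 free sum = sum over i<j annihilated, p<q created
        occ = det
        for jj in range(len(occ)):
            for ii in range(jj):
                i, j = occ[ii], occ[jj]
                for q in range(nso):
                    for p in range(q):
                        val = g_anti[p, q, i, j]
                        if val == 0.0:
                            continue
                        d, ph = apply_excitation(det, p, q, j, i)
                        if d is not None and d in index:
                            ham[index[d], kd] += ph * val
    return ham


def s_squared_matrix(dets: list[Determinant], n_spatial: int) -> np.ndarray:
    """Total-spin S^2 matrix over a determinant list (even so = alpha)."""
    index = {d: k for k, d in enumerate(dets)}
    n = len(dets)
    out = np.zeros((n, n))
    for kd, det in enumerate(dets):
        na = sum(1 for p in det if p % 2 == 0)
        nb = len(det) - na
        ms = 0.5 * (na - nb)
        out[kd, kd] += ms * (ms + 1.0)
        # S-S+ = sum_pq a+_{p beta} a_{p alpha} a+_{q alpha} a_{q beta}
        for q in range(n_spatial):
            d1, ph1 = apply_single(det, 2 * q, 2 * q + 1)  # S+ piece q
            if d1 is None:
                continue
            for p in range(n_spatial):
                d2, ph2 = apply_single(d1, 2 * p + 1, 2 * p)  # S- piece p
                if d2 is not None and d2 in index:
                    out[index[d2], kd] += ph1 * ph2
    return out


def hartree_fock_determinant(n_occ_spatial: int) -> Determinant:
    return tuple(range(2 * n_occ_spatial))


def fci_states(eps: np.ndarray, eri_mo: np.ndarray, h_mo: np.ndarray,
               n_occ: int):
    """All FCI eigenstates of a (tiny) system, with <S^2> diagnostics.

    ``h_mo`` is the true one-electron (core) Hamiltonian in the MO basis;
    ``eps`` is unused here beyond sizing.  Returns (energies, vectors,
    s2_expectations, dets)."""
    n = len(eps)
    nso = 2 * n
    nel = 2 * n_occ
    from itertools import combinations
    dets = [tuple(sorted(c)) for c in combinations(range(nso), nel)]
    # keep only Ms = 0 determinants (sufficient for singlets and triplets)
    dets = [d for d in dets
            if sum(1 for p in d if p % 2 == 0) == nel // 2]
    h_so = np.zeros((nso, nso))
    h_so[0::2, 0::2] = h_mo
    h_so[1::2, 1::2] = h_mo
    _, g_anti = spin_orbital_integrals(np.zeros(n), eri_mo)
    ham = build_hamiltonian(dets, h_so, g_anti)
    s2 = s_squared_matrix(dets, n)
    w, v = np.linalg.eigh(ham)
    s2exp = np.einsum("ik,ij,jk->k", v, s2, v)
    return w, v, s2exp, dets


# ---------------------------------------------------------------------------
# layer 2: dense CVS-ADC(2) matrix
# ---------------------------------------------------------------------------

@dataclass
class DenseAdcMatrix:
    """Explicit CVS-ADC(2) secular matrix in a spin-orbital configuration
    basis (singles then doubles)."""

    matrix: np.ndarray
    singles: list[tuple[int, int]]            # (i_so, a_so)
    doubles: list[tuple[int, int, int, int]]  # (k_so, l_so, c_so, d_so)
    dets: list[Determinant]                   # configuration determinants
    s2: np.ndarray                            # S^2 over the same basis
    e_hf: float

    @property
    def n_singles(self) -> int:
        return len(self.singles)

    def m11(self) -> np.ndarray:
        n1 = self.n_singles
        return self.matrix[:n1, :n1]

    def m12(self) -> np.ndarray:
        n1 = self.n_singles
        return self.matrix[:n1, n1:]

    def m22_diagonal(self) -> np.ndarray:
        n1 = self.n_singles
        return np.diag(self.matrix)[n1:]

    def singlet_eigenstates(self, s2_tol: float = 1.0e-6):
        """Eigenvalues/vectors with <S^2> ~ 0."""
        w, v = np.linalg.eigh(self.matrix)
        s2exp = np.einsum("ik,ij,jk->k", v, self.s2, v)
        mask = np.abs(s2exp) < max(s2_tol, 1e-6)
        return w[mask], v[:, mask]

    def folded_singles_matrix(self, omega: float) -> np.ndarray:
        """Effective (omega-dependent) singles-only matrix
        M11 + M12 (omega - M22)^{-1} M21."""
        n1 = self.n_singles
        m12 = self.m12()
        d22 = self.m22_diagonal()
        return self.m11() + m12 @ ((1.0 / (omega - d22))[:, None] * m12.T)


def _mp2_amplitudes_so(eps_so, g_anti, occ_so, virt_so):
    no, nv = len(occ_so), len(virt_so)
    t = np.zeros((no, no, nv, nv))
    for ii, i in enumerate(occ_so):
        for jj, j in enumerate(occ_so):
            for aa, a in enumerate(virt_so):
                for bb, b in enumerate(virt_so):
                    denom = eps_so[i] + eps_so[j] - eps_so[a] - eps_so[b]
                    t[ii, jj, aa, bb] = g_anti[i, j, a, b] / denom
    return t


def build_dense_adc_matrix(eps: np.ndarray, eri_mo: np.ndarray,
                           n_occ: int, active_core: list[int],
                           frozen_core: list[int] = (),
                           include_second_order: bool = True,
                           include_coupling: bool = True,
                           cvs: bool = True,
                           max_doubles: int = 4000) -> DenseAdcMatrix:
    """Assemble the explicit CVS-ADC(2) matrix.

    CVS: singles have the occupied index in ``active_core``; doubles carry
    exactly one active-core occupied index.  ``frozen_core`` orbitals are
    excluded from every configuration and from the MP2 amplitudes."""
    n = len(eps)
    eps_so, g_anti = spin_orbital_integrals(eps, eri_mo)
    nso = 2 * n
    core_so = {2 * p + s for p in active_core for s in (0, 1)}
    frozen_so = {2 * p + s for p in frozen_core for s in (0, 1)}
    occ_so = [p for p in range(2 * n_occ) if p not in frozen_so]
    val_so = [p for p in occ_so if p not in core_so]
    virt_so = list(range(2 * n_occ, nso))

    hf = hartree_fock_determinant(n_occ)
    singles = [(i, a) for i in sorted(core_so) for a in virt_so]
    doubles = []
    for kk in range(len(occ_so)):
        for ll in range(kk):
            k, l = occ_so[ll], occ_so[kk]  # k < l
            if cvs and (k in core_so) + (l in core_so) != 1:
                continue
            for cc in range(len(virt_so)):
                for dd in range(cc):
                    c, d = virt_so[dd], virt_so[cc]  # c < d
                    doubles.append((k, l, c, d))
    if len(doubles) > max_doubles:
        raise ValueError(
            f"doubles space of {len(doubles)} configurations exceeds the "
            f"dense-oracle limit {max_doubles}")

    # Configurations are defined operatorially: Phi_ia = a+_a a_i |HF>,
    # Phi_klcd = a+_c a+_d a_l a_k |HF>.  Each is a sorted determinant times
    # a phase; the phases must be carried so the CI blocks and the
    # amplitude-convention second-order block share one sign convention.
    dets: list[Determinant] = []
    phases: list[int] = []
    for (i, a) in singles:
        dd, ph = apply_single(hf, a, i)
        dets.append(dd)
        phases.append(ph)
    for (k, l, c, d) in doubles:
        dd, ph = apply_excitation(hf, c, d, l, k)
        dets.append(dd)
        phases.append(ph)

    # true one-electron Hamiltonian recovered from the canonical orbital
    # energies: h_pq = eps_p delta_pq - sum_{k in HF} <pk||qk>
    h_so = np.diag(eps_so).astype(float)
    hf_occ = list(hf)
    for p in range(nso):
        for q in range(nso):
            h_so[p, q] -= sum(g_anti[p, k, q, k] for k in hf_occ)

    pvec = np.array(phases, dtype=float)
    ham = pvec[:, None] * build_hamiltonian(dets, h_so, g_anti) * pvec[None, :]
    e_ref = build_hamiltonian([hf], h_so, g_anti)[0, 0]
    n1, n2 = len(singles), len(doubles)
    m = np.zeros((n1 + n2, n1 + n2))
    if include_coupling:
        m[:n1, n1:] = ham[:n1, n1:]
        m[n1:, :n1] = ham[n1:, :n1]
    m[:n1, :n1] = ham[:n1, :n1] - e_ref * np.eye(n1)
    for kk, (k, l, c, d) in enumerate(doubles):
        m[n1 + kk, n1 + kk] = (eps_so[c] + eps_so[d]
                               - eps_so[k] - eps_so[l])

    if include_second_order:
        t = _mp2_amplitudes_so(eps_so, g_anti, occ_so, virt_so)
        iocc = {p: k for k, p in enumerate(occ_so)}
        ivir = {p: k for k, p in enumerate(virt_so)}
        for s1, (i, a) in enumerate(singles):
            for s2_, (j, b) in enumerate(singles):
                if s2_ > s1:
                    continue
                val = 0.0
                ii, jj = iocc[i], iocc[j]
                aa, bb = ivir[a], ivir[b]
                if i == j:
                    for kk_ in range(len(occ_so)):
                        for ll in range(len(occ_so)):
                            for cc in range(len(virt_so)):
                                val -= 0.25 * (
                                    t[kk_, ll, aa, cc]
                                    * g_anti[occ_so[kk_], occ_so[ll],
                                             b, virt_so[cc]]
                                    + g_anti[occ_so[kk_], occ_so[ll],
                                             a, virt_so[cc]]
                                    * t[kk_, ll, bb, cc])
                if a == b:
                    for kk_ in range(len(occ_so)):
                        for cc in range(len(virt_so)):
                            for dd in range(len(virt_so)):
                                val -= 0.25 * (
                                    t[ii, kk_, cc, dd]
                                    * g_anti[j, occ_so[kk_],
                                             virt_so[cc], virt_so[dd]]
                                    + g_anti[i, occ_so[kk_],
                                             virt_so[cc], virt_so[dd]]
                                    * t[jj, kk_, cc, dd])
                for kk_ in range(len(occ_so)):
                    for cc in range(len(virt_so)):
                        val += 0.5 * (
                            t[ii, kk_, aa, cc]
                            * g_anti[j, occ_so[kk_], b, virt_so[cc]]
                            + g_anti[i, occ_so[kk_], a, virt_so[cc]]
                            * t[jj, kk_, bb, cc])
                m[s1, s2_] += val
                if s1 != s2_:
                    m[s2_, s1] += val

    s2mat = pvec[:, None] * s_squared_matrix(dets, n) * pvec[None, :]
    return DenseAdcMatrix(m, singles, doubles, dets, s2mat, e_ref)


def dense_adc2_eigenvalues(eps, eri_mo, n_occ, active_core,
                           frozen_core=(), n_states=3):
    """Lowest singlet CVS-ADC(2) excitation energies from the explicit
    matrix."""
    adc = build_dense_adc_matrix(eps, eri_mo, n_occ, list(active_core),
                                 list(frozen_core))
    w, _ = adc.singlet_eigenstates()
    return np.sort(w)[:n_states]


# ---------------------------------------------------------------------------
# layer 3: two-level closed forms
# ---------------------------------------------------------------------------

def two_level_closed_forms(eps_i: float, eps_a: float, g_iaia: float,
                           g_iiaa: float, g_aaaa: float = 0.0,
                           g_iiii: float = 0.0):
    """Closed forms for a one-occupied / one-virtual closed-shell model.

    Returns (E_MP2, omega_CIS_singlet, t_amplitude) with
    E_MP2 = -(ia|ia)^2 / (2(eps_a - eps_i) - ... ) for the two-electron
    pair: the only amplitude is t = (ia|ia)/(2 eps_i - 2 eps_a) and
    E_MP2 = (ia|ia) t; the singlet CIS energy is
    Delta-eps + 2 (ia|ia) - (ii|aa)."""
    if abs(eps_a - eps_i) < 1.0e-12:
        raise ZeroDivisionError("degenerate two-level model")
    t = g_iaia / (2.0 * (eps_i - eps_a))
    e_mp2 = g_iaia * t
    omega_cis = (eps_a - eps_i) + 2.0 * g_iaia - g_iiaa
    return e_mp2, omega_cis, t
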