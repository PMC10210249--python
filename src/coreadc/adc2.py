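"""Strict CVS-ADC(2) with density fitting and on-the-fly doubles.

The secular problem is folded into the singles space: the effective
(omega-dependent) Jacobian acts on a core-hole singles vector r_{Ia} as

    sigma(r, omega) = sigma_CIS(r) + sigma_GS(r) + sigma_D(r, omega)

where sigma_CIS is the singlet CVS-CIS part, sigma_GS collects the
second-order ground-state (MP2) amplitude terms, and sigma_D is the
contribution of the double-excitation coefficients, whose denominators
contain omega (the source of the nonlinearity).  Doubles carry exactly one
active-core occupied index (CVS) and are contracted on the fly - the full
doubles tensor is never stored.

The nonlinear eigenproblem omega = <r|sigma(r, omega)|r> is solved state by
state with a modified Davidson iteration (subspace rebuilt at the current
omega) accelerated by DIIS extrapolation, with root homing on the CVS-CIS
guess vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cis import SinglesVector, cis_sigma
from .df import DfTensor
from .reference import OrbitalSpace

log = logging.getLogger(__name__)


class Adc2Error(RuntimeError):
    pass


class DegenerateDenominatorError(Adc2Error):
    pass


@dataclass
class SolverSettings:
    n_states: int = 3
    energy_tolerance: float = 1.0e-6     # Hartree
    residual_tolerance: float = 1.0e-5
    max_iterations: int = 60
    diis_depth: int = 6
    guess_source: str = "cis"

    def __post_init__(self):
        if self.energy_tolerance <= 0 or self.residual_tolerance <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ExcitedState:
    omega: float                  # Hartree
    vector: SinglesVector
    oscillator_strength: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))


# ---------------------------------------------------------------------------
# combined occupied-group helpers (active core first, then inactive occupied)
# ---------------------------------------------------------------------------

def _occ_blocks(j: DfTensor):
    """J blocks with a combined correlated-occupied index k = (core,occ)."""
    jcv, jov = j.block("cv"), j.block("ov")
    jkv = np.concatenate([jcv, jov], axis=1)            # (Q, k, a)
    jcc, jco = j.block("cc"), j.block("co")
    jck = np.concatenate([jcc, jco], axis=2)            # (Q, I, k)
    return jkv, jck


def _eps_all_occ(space: OrbitalSpace) -> np.ndarray:
    return np.concatenate([space.eps_core, space.eps_occ])


# ---------------------------------------------------------------------------
# MP2 ground state
# ---------------------------------------------------------------------------

@dataclass
class Mp2Intermediates:
    """Frozen-core MP2 quantities entering sigma_GS.

    ``x_vv``/``y_cc`` are the symmetrized second-order virtual-virtual and
    (active-core) occupied-occupied intermediates; ``t_core`` is the slice
    of ground-state amplitudes with one active-core index, needed by the
    non-diagonal second-order terms.  The full amplitude tensor is built
    pairwise and contracted immediately, never stored."""

    x_vv: np.ndarray       # (nv, nv), symmetric
    y_cc: np.ndarray       # (nc, nc), symmetric
    t_core: np.ndarray     # (nc, nv, nk, nv): t[I,a,k,c]
    energy: float          # MP2 correlation energy (Hartree)

    def __post_init__(self):
        if not np.allclose(self.x_vv, self.x_vv.T, atol=1e-10):
            raise Adc2Error("X_ab intermediate is not symmetric")


def mp2_intermediates(j: DfTensor, space: OrbitalSpace,
                      denominator_floor: float = 1.0e-6) -> Mp2Intermediates:
    """Batch-wise MP2: loop over occupied pairs, form the pair amplitude
    block from DF integrals, contract into X/Y intermediates and the
    correlation energy on the fly."""
    jkv, _ = _occ_blocks(j)
    eps_k = _eps_all_occ(space)
    eps_v = space.eps_virt
    nk, nv = len(eps_k), len(eps_v)
    nc = space.n_core
    if nv == 0:
        raise Adc2Error("no virtual orbitals")

    x2 = np.zeros((nv, nv))
    energy = 0.0
    kmats = [jkv[:, k, :] for k in range(nk)]  # (Q, a) slices
    for k in range(nk):
        for l in range(nk):
            kint = kmats[k].T @ kmats[l]       # (ka|lb) -> [a, b]
            den = eps_k[k] + eps_k[l] - eps_v[:, None] - eps_v[None, :]
            bad = np.abs(den) < denominator_floor
            if np.any(bad):
                a, b = np.argwhere(bad)[0]
                raise DegenerateDenominatorError(
                    f"vanishing MP2 denominator for occupied pair "
                    f"({k},{l}) and virtuals ({a},{b})")
            t_kl = kint / den                  # t[k,a,l,b] block
            energy += float(np.sum(t_kl * (2.0 * kint - kint.T)))
            # X[a,b] = sum_{klc} (2 t[k,a,l,c] - t[k,c,l,a]) (kb|lc):
            # per-pair contribution sum_c (2 t_kl - t_kl^T)[a,c] kint[b,c]
            x2 += (2.0 * t_kl - t_kl.T) @ kint.T

    # amplitude slice with one active-core index (k index runs over all)
    jc_v = jkv[:, :nc, :]
    kint_c = np.einsum("QIa,Qkc->Iakc", jc_v, jkv, optimize=True)
    den_c = (eps_k[:nc, None, None, None] + eps_k[None, None, :, None]
             - eps_v[None, :, None, None] - eps_v[None, None, None, :])
    t_core = kint_c / den_c

    # Y[I,J] = sum_{kcd} (2 t[I,c,k,d] - t[I,d,k,c]) (Jc|kd)
    kint_cv = np.einsum("QJc,Qkd->Jckd", jc_v, jkv, optimize=True)
    y_cc = np.einsum("Ickd,Jckd->IJ",
                     2.0 * t_core - t_core.transpose(0, 3, 2, 1),
                     kint_cv, optimize=True)

    xs = 0.5 * (x2 + x2.T)
    ys = 0.5 * (y_cc + y_cc.T)
    return Mp2Intermediates(xs, ys, t_core, energy)


# ---------------------------------------------------------------------------
# sigma vector pieces
# ---------------------------------------------------------------------------

def sigma_gs(r: np.ndarray, j: DfTensor, space: OrbitalSpace,
             mp2: Mp2Intermediates) -> np.ndarray:
    """Ground-state-amplitude (second-order, omega-independent) terms:

    sigma_GS = -(X r + Y r) + 1/2 [ t~ . K~(r) + K~ . t~(r) ]

    with the spin-adapted combinations t~ = 2t - t(swap) over the
    core-amplitude slice and K~ = 2(Ia|kc) - (Ic|ka)."""
    jkv, _ = _occ_blocks(j)
    jcv = j.block("cv")
    sigma = -r @ mp2.x_vv - mp2.y_cc @ r
    t_c = mp2.t_core
    tt = 2.0 * t_c - t_c.transpose(0, 3, 2, 1)     # t~[I,a,k,c]
    # K~-weighted r:  w~[k,c] = sum_Jb [2(Jb|kc) - (Jc|kb)] r_Jb
    wq = np.einsum("QJb,Jb->Q", jcv, r, optimize=True)
    w = np.einsum("Q,Qkc->kc", wq, jkv, optimize=True)
    mm = np.einsum("QJc,Qkb,Jb->kc", jcv, jkv, r, optimize=True)
    wt = 2.0 * w - mm
    sigma += 0.5 * np.einsum("Iakc,kc->Ia", tt, wt, optimize=True)
    # t~-weighted r:  u~[k,c] = sum_Jb t~[J,b,k,c] r_Jb, contracted with K~
    ut = np.einsum("Jbkc,Jb->kc", tt, r, optimize=True)
    uq = np.einsum("Qkc,kc->Q", jkv, ut, optimize=True)
    sigma += np.einsum("QIa,Q->Ia", jcv, uq, optimize=True)
    sigma -= 0.5 * np.einsum("QIc,Qka,kc->Ia", jcv, jkv, ut, optimize=True)
    return sigma


def doubles_amplitudes(r: np.ndarray, omega: float, j: DfTensor,
                       space: OrbitalSpace,
                       pole_floor: float = 1.0e-8) -> np.ndarray:
    """CVS doubles coefficients B[I,c,j,d] (one active-core index I, one
    inactive occupied j) at the given omega.

    B = [sum_a r_Ia (ac|jd) - sum_I' r_I'c (II'|jd) - sum_I' r_I'd (jI'|Ic)]
        / (omega + eps_I + eps_j - eps_c - eps_d)
    """
    jcv, jov = j.block("cv"), j.block("ov")
    jcc, jco = j.block("cc"), j.block("co")
    joc = jco.transpose(0, 2, 1)
    num = np.einsum("Qac,Qjd,Ia->Icjd", j.block("vv"), jov, r,
                    optimize=True)
    num -= np.einsum("QIi,Qjd,ic->Icjd", jcc, jov, r, optimize=True)
    num -= np.einsum("Qji,QIc,id->Icjd", joc, jcv, r, optimize=True)
    den = (omega + space.eps_core[:, None, None, None]
           + space.eps_occ[None, None, :, None]
           - space.eps_virt[None, :, None, None]
           - space.eps_virt[None, None, None, :])
    bad = np.abs(den) < pole_floor
    if np.any(bad):
        idx = tuple(np.argwhere(bad)[0])
        raise DegenerateDenominatorError(
            f"omega = {omega:.8f} hits a doubles pole at (I,c,j,d) = {idx}")
    return num / den


def sigma_doubles(r: np.ndarray, omega: float, j: DfTensor,
                  space: OrbitalSpace) -> np.ndarray:
    """Fold of the doubles block at fixed omega (on-the-fly contraction)."""
    b1 = doubles_amplitudes(r, omega, j, space)
    jcv, jov = j.block("cv"), j.block("ov")
    jcc, jco = j.block("cc"), j.block("co")
    joc = jco.transpose(0, 2, 1)
    bt = 2.0 * b1 - b1.transpose(0, 3, 2, 1)   # 2B[J,a,j,d]-B[J,d,j,a]
    sigma = -np.einsum("QJI,Qjd,Jajd->Ia", jcc, jov, bt, optimize=True)
    # pairs in (inactive, core) order: B[j,c,J,d] = B1[J,d,j,c]
    bt2 = 2.0 * b1.transpose(0, 3, 2, 1) - b1   # bt2[J,a,j,d]=2B1[J,d,j,a]-B1[J,a,j,d]
    sigma -= np.einsum("QjI,QJd,Jajd->Ia", joc, jcv, bt2, optimize=True)
    sigma += np.einsum("Qac,Qjd,Icjd->Ia", j.block("vv"), jov, bt,
                       optimize=True)
    return sigma


def sigma_vector(r: np.ndarray, omega: float, j: DfTensor,
                 space: OrbitalSpace, mp2: Mp2Intermediates,
                 include_second_order: bool = True) -> np.ndarray:
    """Full effective-Jacobian action sigma(r, omega)."""
    sigma = cis_sigma(r, j, space)
    if include_second_order:
        sigma += sigma_gs(r, j, space, mp2)
        sigma += sigma_doubles(r, omega, j, space)
    return sigma


# ---------------------------------------------------------------------------
# nonlinear (state-specific) solver
# ---------------------------------------------------------------------------

def solve_adc2(settings: SolverSettings, j: DfTensor, space: OrbitalSpace,
               mp2: Mp2Intermediates,
               guesses: list[tuple[float, SinglesVector]],
               include_second_order: bool = True) -> list[ExcitedState]:
    """Solve the omega-dependent eigenproblem for each guess state.

    Each state is converged in its own Davidson subspace, rebuilt at the
    current omega every macro-iteration; omega is updated from the Rayleigh
    quotient and the iteration is DIIS-accelerated on the residual
    vectors.  Root homing follows maximal overlap with the CVS-CIS guess."""
    if len(guesses) < settings.n_states:
        raise Adc2Error(
            f"{settings.n_states} states requested but only "
            f"{len(guesses)} CIS guesses supplied")
    states = []
    for istate in range(settings.n_states):
        omega_cis, rvec = guesses[istate]
        state = _solve_single_state(settings, j, space, mp2,
                                    omega_cis, rvec.amplitudes,
                                    include_second_order)
        state.diagnostics["state_index"] = istate
        states.append(state)
    _check_root_collapse(states)
    return states


def _solve_single_state(settings, j, space, mp2, omega_cis, r0,
                        include_second_order) -> ExcitedState:
    nc, nv = r0.shape
    dim = nc * nv
    guess = r0.ravel() / np.linalg.norm(r0)
    omega = float(omega_cis)
    vs = [guess]
    diis_r: list[np.ndarray] = []
    diis_e: list[np.ndarray] = []
    history = []
    for it in range(1, settings.max_iterations + 1):
        smat = np.column_stack([
            sigma_vector(v.reshape(nc, nv), omega, j, space, mp2,
                         include_second_order).ravel() for v in vs])
        vmat = np.column_stack(vs)
        hsub = vmat.T @ smat
        hsub = 0.5 * (hsub + hsub.T)
        w, c = np.linalg.eigh(hsub)
        overlaps = np.abs(c.T @ (vmat.T @ guess))
        root = int(np.argmax(overlaps))
        theta = float(w[root])
        x = vmat @ c[:, root]
        sx = smat @ c[:, root]
        resid = sx - theta * x
        rnorm = float(np.linalg.norm(resid))
        de = abs(theta - omega)
        history.append((omega, theta, rnorm))
        log.debug("adc2 it=%d omega=%.8f theta=%.8f |r|=%.2e",
                  it, omega, theta, rnorm)
        if de < settings.energy_tolerance and \
                rnorm < settings.residual_tolerance:
            cis_ovl = float(abs(x @ guess))
            if cis_ovl < 0.5:
                log.warning(
                    "low CVS-CIS overlap (%.3f) for converged state at "
                    "omega=%.6f Ha: the singles character differs "
                    "strongly from the CIS guess", cis_ovl, theta)
            return ExcitedState(
                theta, SinglesVector(x.reshape(nc, nv) / np.linalg.norm(x)),
                diagnostics={
                    "converged": True, "iterations": it,
                    "residual_norm": rnorm, "cis_overlap": cis_ovl,
                    "omega_cis": omega_cis,
                    "dominant_amplitude": float(np.abs(x).max()),
                })
        # DIIS on (ritz vector, residual) pairs
        diis_r.append(x)
        diis_e.append(resid)
        if len(diis_r) > settings.diis_depth:
            diis_r.pop(0)
            diis_e.pop(0)
        x_diis = x
        if len(diis_r) > 1:
            nd = len(diis_r)
            bmat = -np.ones((nd + 1, nd + 1))
            bmat[-1, -1] = 0.0
            for p in range(nd):
                for q in range(nd):
                    bmat[p, q] = diis_e[p] @ diis_e[q]
            rhs = np.zeros(nd + 1)
            rhs[-1] = -1.0
            try:
                coef = np.linalg.solve(bmat, rhs)[:nd]
                x_diis = sum(ci * xi for ci, xi in zip(coef, diis_r))
                x_diis = x_diis / np.linalg.norm(x_diis)
            except np.linalg.LinAlgError:
                pass
        # preconditioned residual expansion
        diag = (space.eps_virt[None, :] - space.eps_core[:, None]).ravel()
        denom = diag - theta
        denom = np.where(np.abs(denom) < 1e-8, 1e-8, denom)
        new = resid / denom
        # collapse subspace: current solution estimate + correction
        basis = [x_diis]
        for cand in (new, x):
            q = cand - sum((b @ cand) * b for b in basis)
            q = q - sum((b @ q) * b for b in basis)
            nn = np.linalg.norm(q)
            if nn > 1e-10:
                basis.append(q / nn)
        vs = basis
        omega = theta
    raise Adc2Error(
        "CVS-ADC(2) state did not converge; trajectory (omega, theta, |r|): "
        + "; ".join(f"({o:.6f}, {t:.6f}, {rn:.1e})"
                    for o, t, rn in history[-6:]))


def _check_root_collapse(states: list[ExcitedState]) -> None:
    for a in range(len(states)):
        for b in range(a):
            ra = states[a].vector.amplitudes
            rb = states[b].vector.amplitudes
            if ra.shape != rb.shape:
                continue  # state-specific reduced spaces differ
            ovl = abs(float(np.sum(ra * rb)))
            dw = abs(states[a].omega - states[b].omega)
            if ovl > 0.98 and dw < 1e-6:
                raise Adc2Error(
                    f"root collapse: states {b} and {a} converged to the "
                    f"same vector (overlap {ovl:.4f})")
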