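"""Ground-to-core-excited transition moments and oscillator strengths in
the dipole-length gauge.

The transition moment couples the MP2-correlated ground state with the
(singles + on-the-fly doubles) core-excited state:

* zeroth order: sqrt(2) sum_Ia r_Ia mu_Ia;
* first order:  the MP1 doubles contracted against the singles vector
  (intensity borrowing into valence occupied -> virtual dipole elements);
* second order: (a) MP2-density renormalization of the singles amplitudes,
  (b) the omega-dependent CVS doubles coefficients contracted with the MP1
  doubles, entering through occupied-occupied and virtual-virtual dipole
  blocks, with the ground-state-dipole overlap correction that keeps the
  moment origin-independent.

Every contraction was validated against a brute-force determinant
evaluation of <Psi_0 | mu | Psi_exc>; the second-order singles terms beyond
the density renormalization are omitted (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adc2 import ExcitedState, doubles_amplitudes, _occ_blocks, _eps_all_occ
from .df import DfTensor
from .reference import OrbitalSpace


class PropertiesError(RuntimeError):
    pass


@dataclass
class TransitionMoment:
    dipole: np.ndarray      # (3,) au
    omega: float            # Hartree
    f: float                # dimensionless

    def __post_init__(self):
        if self.f < -1e-12:
            raise PropertiesError("negative oscillator strength")


# statistics convention: oscillator strengths enter error statistics only
# above this value
F_STATISTICS_THRESHOLD = 0.015


def _full_amplitudes(j: DfTensor, space: OrbitalSpace) -> np.ndarray:
    """Ground-state MP2 amplitudes t[k,c,l,d] over the combined correlated
    occupied index (used only by the property contractions; sizes here are
    modest)."""
    jkv, _ = _occ_blocks(j)
    eps_k = _eps_all_occ(space)
    eps_v = space.eps_virt
    kint = np.einsum("Qkc,Qld->kcld", jkv, jkv, optimize=True)
    den = (eps_k[:, None, None, None] + eps_k[None, None, :, None]
           - eps_v[None, :, None, None] - eps_v[None, None, None, :])
    return kint / den


def _embed_doubles(b1: np.ndarray, space: OrbitalSpace) -> np.ndarray:
    """Embed B[I,c,j,d] into the combined occupied index with the CVS pair
    structure (both orderings; zero elsewhere)."""
    nc, nv = space.n_core, space.n_virt
    nk = nc + space.n_occ
    b = np.zeros((nk, nv, nk, nv))
    b[:nc, :, nc:, :] = b1
    b[nc:, :, :nc, :] = b1.transpose(2, 3, 0, 1)
    return b


def transition_moment(state: ExcitedState, j: DfTensor,
                      space: OrbitalSpace,
                      mu_ov: np.ndarray, mu_oo: np.ndarray,
                      mu_vv: np.ndarray,
                      include_second_order: bool = True) -> TransitionMoment:
    """Dipole transition moment for a converged core-excited state.

    ``mu_ov``/``mu_oo``/``mu_vv`` are MO dipole blocks (3, nk, nv),
    (3, nk, nk), (3, nv, nv) over the combined correlated-occupied index
    (active core first) and the current virtual space."""
    if not state.converged:
        raise PropertiesError(
            "transition moment requested for an unconverged state")
    r = state.vector.amplitudes
    nc, nv = space.n_core, space.n_virt
    sq2 = np.sqrt(2.0)

    # zeroth order
    tvec = sq2 * np.einsum("xIa,Ia->x", mu_ov[:, :nc, :], r, optimize=True)

    if include_second_order:
        t = _full_amplitudes(j, space)
        tp = t.transpose(0, 3, 2, 1)

        # first order: intensity borrowing  u~[k,c] = (2 t - t') . r
        u = (2.0 * np.einsum("kcId,Id->kc", t[:, :, :nc, :], r,
                             optimize=True)
             - np.einsum("kdIc,Id->kc", t[:, :, :nc, :], r, optimize=True))
        tvec += sq2 * np.einsum("xkc,kc->x", mu_ov, u, optimize=True)

        # second order (a): MP2-density renormalization of the singles
        rho_vv = 2.0 * np.einsum("kcla,kclb->ab", t, 2.0 * t - tp,
                                 optimize=True)
        rho_cc = 2.0 * np.einsum("Ickd,Jckd->IJ",
                                 t[:nc], (2.0 * t - tp)[:nc], optimize=True)
        f_ren = -0.5 * (rho_cc @ r + r @ rho_vv)
        tvec += sq2 * np.einsum("xIa,Ia->x", mu_ov[:, :nc, :], f_ren,
                                optimize=True)

        # second order (b): doubles coefficients against MP1 amplitudes
        b1 = doubles_amplitudes(r, state.omega, j, space)
        b = _embed_doubles(b1, space)
        bp = b.transpose(0, 3, 2, 1)
        pref = 1.0 / sq2
        gvv = pref * (np.einsum("kcld,kcle->de", t - tp, b - bp,
                                optimize=True)
                      + np.einsum("kdlc,kelc->de", t, b, optimize=True)
                      + np.einsum("kcld,kcle->de", t, b, optimize=True))
        goo = -pref * (np.einsum("kcld,kcmd->lm", t - tp, b - bp,
                                 optimize=True)
                       + np.einsum("kcld,kcmd->lm", t, b, optimize=True)
                       + np.einsum("kdlc,kdmc->lm", t, b, optimize=True))
        tvec += np.einsum("xde,de->x", mu_vv, gvv, optimize=True)
        tvec += np.einsum("xlm,lm->x", mu_oo, goo, optimize=True)

    f = (2.0 / 3.0) * state.omega * float(tvec @ tvec)
    return TransitionMoment(tvec, state.omega, f)


def oscillator_strength(state: ExcitedState, j: DfTensor,
                        space: OrbitalSpace, mu_ov, mu_oo, mu_vv,
                        include_second_order: bool = True) -> float:
    return transition_moment(state, j, space, mu_ov, mu_oo, mu_vv,
                             include_second_order).f
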