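"""Density-fitting factors in the molecular-orbital basis.

Four-center ERIs are approximated as (pq|rs) = sum_Q J^Q_pq J^Q_rs where
J = I V^{-1/2}: the three-center Coulomb integrals dressed with the inverse
square root of the two-center metric.  ``DfTensor`` stores J in the MO-block
layout required by the CVS-ADC(2) sigma vector: active core (c), inactive
occupied (o) and virtual (v) groups, with the auxiliary index leading so a
NAF rotation is a single matrix product per block.  Frozen-core orbitals are
never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import OrbitalSpace, ScfReference


class DfIndexError(IndexError):
    """MO index outside the blocks held by a DfTensor."""


BLOCK_KEYS = ("cc", "co", "cv", "oo", "ov", "vv")


def metric_inverse_sqrt(v: np.ndarray, cutoff: float = 1.0e-10) -> np.ndarray:
    """V^{-1/2} of the (symmetric, positive semidefinite) Coulomb metric by
    eigendecomposition; eigenvalues below ``cutoff`` are discarded, which
    projects out numerically linearly dependent fitting directions."""
    v = np.asarray(v, float)
    if not np.allclose(v, v.T, atol=1.0e-10):
        raise ValueError("Coulomb metric is not symmetric")
    w, u = np.linalg.eigh(v)
    keep = w > cutoff
    if not np.any(keep):
        raise ValueError(
            f"all metric eigenvalues below cutoff {cutoff:g}: degenerate "
            "auxiliary basis")
    return (u[:, keep] * w[keep] ** -0.5) @ u[:, keep].T


@dataclass
class DfTensor:
    """Metric-dressed three-center MO integrals J^Q_pq, blocked by MO group.

    ``blocks[gh]`` has shape (n_aux, n_g, n_h) for group pair gh in
    cc, co, cv, oo, ov, vv.  ``index_map`` translates a global MO index to
    (group letter, local index)."""

    blocks: dict[str, np.ndarray]
    index_map: dict[int, tuple[str, int]]
    space: OrbitalSpace

    @property
    def n_aux(self) -> int:
        return self.blocks["cv"].shape[0]

    def block(self, key: str) -> np.ndarray:
        """Block by group pair; transposed blocks are served on the fly."""
        if key in self.blocks:
            return self.blocks[key]
        rkey = key[::-1]
        if rkey in self.blocks:
            return self.blocks[rkey].transpose(0, 2, 1)
        raise DfIndexError(f"no DF block {key!r}")

    def reconstruct_block(self, bra: str, ket: str) -> np.ndarray:
        """(pq|rs) tensor for bra/ket group pairs, from sum_Q J J."""
        return np.einsum("Qpq,Qrs->pqrs", self.block(bra), self.block(ket),
                         optimize=True)

    def reconstruct_eri(self, p: int, q: int, r: int, s: int) -> float:
        """Single DF ERI (pq|rs) by global MO indices."""
        try:
            (gp, lp), (gq, lq) = self.index_map[p], self.index_map[q]
            (gr, lr), (gs, ls) = self.index_map[r], self.index_map[s]
        except KeyError as exc:
            raise DfIndexError(
                f"MO index {exc.args[0]} is not held by this DF tensor "
                "(frozen or out of range)") from None
        jb = self.block(gp + gq)[:, lp, lq]
        jk = self.block(gr + gs)[:, lr, ls]
        return float(jb @ jk)

    def rotate_auxiliary(self, u: np.ndarray) -> "DfTensor":
        """Apply an auxiliary-space rotation/truncation (n_aux x n_kept)."""
        new = {k: np.einsum("QR,Qpq->Rpq", u, b, optimize=True)
               for k, b in self.blocks.items()}
        return DfTensor(new, dict(self.index_map), self.space)

    def rotate_virtual(self, vmat: np.ndarray,
                       space: OrbitalSpace) -> "DfTensor":
        """Apply a virtual-space rotation/truncation (n_virt x n_kept); the
        caller supplies the matching (semicanonicalized) orbital space."""
        new = {}
        for k, b in self.blocks.items():
            if k == "vv":
                new[k] = np.einsum("Qab,ac,bd->Qcd", b, vmat, vmat,
                                   optimize=True)
            elif k.endswith("v"):
                new[k] = np.einsum("Qpa,ab->Qpb", b, vmat, optimize=True)
            else:
                new[k] = b.copy()
        index_map = {p: gl for p, gl in self.index_map.items()
                     if gl[0] != "v"}
        for loc, p in enumerate(space.virtual):
            index_map[p] = ("v", loc)
        return DfTensor(new, index_map, space)


def assemble_J(three_center_ao: np.ndarray, vinvhalf: np.ndarray,
               ref: ScfReference, space: OrbitalSpace) -> DfTensor:
    """MO-transform and metric-dress the AO three-center integrals.

    Produces all group-pair blocks needed by the CVS-CIS/CVS-ADC(2) sigma
    vectors and the compression pipeline."""
    nao = ref.mo_coefficients.shape[0]
    if three_center_ao.shape[:2] != (nao, nao) or \
            three_center_ao.shape[2] != vinvhalf.shape[0]:
        raise ValueError(
            f"AO tensor shape {three_center_ao.shape} inconsistent with "
            f"{nao} AOs / metric dimension {vinvhalf.shape[0]}")
    c = ref.mo_coefficients
    groups = {
        "c": c[:, list(space.active_core)],
        "o": c[:, list(space.inactive_occupied)],
        "v": c[:, list(space.virtual)],
    }
    dressed = np.einsum("mnP,PQ->Qmn", three_center_ao, vinvhalf,
                        optimize=True)
    blocks = {}
    for key in BLOCK_KEYS:
        c1, c2 = groups[key[0]], groups[key[1]]
        blocks[key] = np.einsum("Qmn,mp,nq->Qpq", dressed, c1, c2,
                                optimize=True)
    index_map: dict[int, tuple[str, int]] = {}
    for loc, p in enumerate(space.active_core):
        index_map[p] = ("c", loc)
    for loc, p in enumerate(space.inactive_occupied):
        index_map[p] = ("o", loc)
    for loc, p in enumerate(space.virtual):
        index_map[p] = ("v", loc)
    return DfTensor(blocks, index_map, space)


def build_df_tensor(ref: ScfReference, space: OrbitalSpace,
                    metric_cutoff: float = 1.0e-10) -> DfTensor:
    """Convenience wrapper: AO integrals -> metric inverse sqrt -> J."""
    vih = metric_inverse_sqrt(ref.ao_metric(), metric_cutoff)
    return assemble_J(ref.ao_three_center(), vih, ref, space)
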