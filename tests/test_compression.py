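"""NAF and VNO compression: exact algebraic properties of the truncations
and the thresholds->0 recovery of the canonical result."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coreadc import adc2, compression, oracle
from coreadc.cis import SinglesVector, solve_cis
from coreadc.df import DfTensor, build_df_tensor
from coreadc.molecule import fixture
from coreadc.reference import OrbitalSpace, compute_reference
from conftest import df_eri_mo


def _random_df_tensor(rng, nq=8, nc=1, no=2, nv=3):
    blocks = {}
    for key, (n1, n2) in {"cc": (nc, nc), "co": (nc, no), "cv": (nc, nv),
                          "oo": (no, no), "ov": (no, nv),
                          "vv": (nv, nv)}.items():
        b = rng.normal(size=(nq, n1, n2))
        if key in ("cc", "oo", "vv"):
            b = 0.5 * (b + b.transpose(0, 2, 1))
        blocks[key] = b
    eps = np.concatenate([[-20.0], np.sort(rng.uniform(-2, -0.5, no)),
                          np.sort(rng.uniform(0.5, 2.0, nv))])
    space = OrbitalSpace((), (0,), tuple(range(1, 1 + no)),
                         tuple(range(1 + no, 1 + no + nv)), eps)
    index_map = {0: ("c", 0)}
    for k in range(no):
        index_map[1 + k] = ("o", k)
    for k in range(nv):
        index_map[1 + no + k] = ("v", k)
    return DfTensor(blocks, index_map, space)


# ---------------------------------------------------------------------------
# NAF
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=10, derandomize=True)
@given(st.integers(0, 10_000))
def test_naf_eigenvalues_are_squared_singular_values(seed):
    """sqrt(W eigenvalues) equals the singular values of J unfolded to
    n_Q x (n_p n_q), with off-diagonal group blocks double-weighted."""
    rng = np.random.default_rng(seed)
    j = _random_df_tensor(rng)
    naf = compression.build_naf(j, 0.0)
    flat = np.concatenate(
        [(1.0 if k[0] == k[1] else np.sqrt(2.0)) * b.reshape(j.n_aux, -1)
         for k, b in j.blocks.items()], axis=1)
    sv = np.sort(np.linalg.svd(flat, compute_uv=False))[::-1]
    assert np.abs(naf.singular_values[:len(sv)] - sv).max() < 1e-11


@settings(deadline=None, max_examples=10, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.05, 2.0))
def test_naf_discarded_frobenius_bound(seed, eps_naf):
    """||discarded part of J||_F = sqrt(sum of dropped W eigenvalues)."""
    rng = np.random.default_rng(seed)
    j = _random_df_tensor(rng)
    naf = compression.build_naf(j, eps_naf)
    u = naf.rotation
    proj = u @ u.T
    disc2 = 0.0
    for key, b in j.blocks.items():
        flat = b.reshape(j.n_aux, -1)
        w = 1.0 if key[0] == key[1] else 2.0
        disc2 += w * np.linalg.norm(flat - proj @ flat) ** 2
    assert np.sqrt(disc2) == pytest.approx(naf.discarded_frobenius,
                                           abs=1e-10)


def test_naf_zero_threshold_preserves_eris(h2o_sto3g):
    j = h2o_sto3g.j
    naf = compression.build_naf(j, 0.0)
    assert naf.n_kept == j.n_aux
    j2 = j.rotate_auxiliary(naf.rotation)
    for key in ("cv", "vv"):
        a = np.einsum("Qpq,Qrs->pqrs", j.block(key), j.block(key))
        b = np.einsum("Qpq,Qrs->pqrs", j2.block(key), j2.block(key))
        assert np.abs(a - b).max() < 1e-12


def test_rank_one_j_keeps_single_naf():
    rng = np.random.default_rng(0)
    j = _random_df_tensor(rng)
    # make every auxiliary slice proportional to the first
    weights = rng.normal(size=j.n_aux)
    weights[0] = 1.0
    for key, b in j.blocks.items():
        j.blocks[key] = weights[:, None, None] * b[0][None, :, :]
    # threshold far below the one true singular value but above the
    # numerical-noise floor of the rank-one W spectrum
    naf = compression.build_naf(j, 1e-4)
    assert naf.n_kept == 1


# ---------------------------------------------------------------------------
# densities and VNOs
# ---------------------------------------------------------------------------

def test_mp2_density_h2_closed_form():
    """One occupied / one virtual: the density is the squared amplitude
    (times 2 for spin summation)."""
    ref = compute_reference(fixture("h2"), "sto-3g")
    sp = OrbitalSpace((), (0,), (), (1,), ref.orbital_energies)
    j = build_df_tensor(ref, sp)
    _, _, t = oracle.two_level_closed_forms(
        ref.orbital_energies[0], ref.orbital_energies[1],
        j.reconstruct_eri(0, 1, 0, 1), j.reconstruct_eri(0, 0, 1, 1))
    d = compression.mp2_vv_density(j, sp)
    assert d.shape == (1, 1)
    assert d[0, 0] == pytest.approx(2.0 * t * t, abs=1e-12)


def test_mp2_density_vs_spin_orbital_oracle(h2o_631g):
    ref = h2o_631g.ref
    eri_mo = df_eri_mo(ref)
    eps_so, g_anti = oracle.spin_orbital_integrals(
        ref.orbital_energies, eri_mo)
    occ = list(range(2 * ref.n_occupied))
    vir = list(range(2 * ref.n_occupied, 2 * ref.n_mo))
    t = oracle._mp2_amplitudes_so(eps_so, g_anti, occ, vir)
    d_so = 0.5 * np.einsum("ijac,ijbc->ab", t, t)
    d_ref = d_so[0::2, 0::2] + d_so[1::2, 1::2]
    d = compression.mp2_vv_density(h2o_631g.j, h2o_631g.space)
    assert np.abs(d - d_ref).max() < 1e-12
    assert np.all(np.linalg.eigvalsh(d) > -1e-10)   # PSD
    assert np.trace(d) > 0


def test_mp2_density_trace_shrinks_with_gap(h2o_631g):
    """Shifting every virtual upward weakens correlation: trace(D)
    decreases monotonically."""
    sp = h2o_631g.space
    traces = []
    for shift in (0.0, 0.5, 1.0):
        e = sp.orbital_energies.copy()
        e[list(sp.virtual)] += shift
        sp2 = OrbitalSpace(sp.frozen_core, sp.active_core,
                           sp.inactive_occupied, sp.virtual, e)
        traces.append(np.trace(compression.mp2_vv_density(
            h2o_631g.j, sp2)))
    assert traces[0] > traces[1] > traces[2] > 0


def test_cisd_density_cis_term_only(h2o_631g):
    sp, j = h2o_631g.space, h2o_631g.j
    (w, vec), = solve_cis(1, j, sp)
    d = compression.cisd_vv_density(j, (w, vec), sp,
                                    include_doubles=False)
    r = vec.amplitudes
    assert np.abs(d - r.T @ r).max() < 1e-14
    assert np.trace(d) == pytest.approx(1.0, abs=1e-10)


def test_cisd_density_symmetric_and_normalization_guard(h2o_631g):
    sp, j = h2o_631g.space, h2o_631g.j
    (w, vec), = solve_cis(1, j, sp)
    d = compression.cisd_vv_density(j, (w, vec), sp)
    assert np.abs(d - d.T).max() < 1e-12
    with pytest.raises(compression.CompressionError, match="normalized"):
        compression.cisd_vv_density(
            j, (w, SinglesVector(2.0 * vec.amplitudes)), sp)


def test_state_averaged_density():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(4, 4))
    a = a @ a.T
    sd = compression.state_averaged_density(a, a)
    assert np.abs(sd.d_vv - a).max() == 0.0
    sd = compression.state_averaged_density(np.zeros_like(a), a)
    assert np.abs(sd.d_vv - 0.5 * a).max() == 0.0
    with pytest.raises(compression.CompressionError, match="mismatch"):
        compression.state_averaged_density(a, np.zeros((3, 3)))
    # eigenvalue interlacing sanity for the average of two symmetrics
    b = rng.normal(size=(4, 4))
    b = b @ b.T
    sd = compression.state_averaged_density(a, b)
    lam = np.linalg.eigvalsh(sd.d_vv).max()
    bound = 0.5 * (np.linalg.eigvalsh(a).max()
                   + np.linalg.eigvalsh(b).max())
    assert lam <= bound + 1e-12


def test_build_vno_threshold_examples(h2o_631g):
    sp = h2o_631g.space
    d = compression.StateDensity(np.diag([1e-3, 1e-6]),
                                 np.diag([1e-3, 1e-6]),
                                 np.diag([1e-3, 1e-6]))
    sp2 = OrbitalSpace((), (0,), (1, 2, 3, 4),
                       (5, 6), sp.orbital_energies[:7])
    rot, eps_t, occs = compression.build_vno(d, sp2, eps_vno=7.5e-5)
    assert rot.shape == (2, 1)
    with pytest.raises(compression.CompressionError, match="eps_vno"):
        compression.build_vno(d, sp2, eps_vno=1.0)


def test_vno_semicanonical_fock_is_diagonal(h2o_631g, h2co_631g):
    for bundle in (h2o_631g, h2co_631g):
        sp, j = bundle.space, bundle.j
        (w, vec), = solve_cis(1, j, sp)
        sm = compression.reduce_state(j, (w, vec), sp, eps_naf=0.1)
        u = sm.vno_rotation
        assert np.abs(u.T @ u - np.eye(u.shape[1])).max() < 1e-12
        f = (u * sp.eps_virt[:, None]).T @ u
        off = f - np.diag(sm.semicanonical_energies)
        assert np.abs(off).max() < 1e-10


def test_reduce_state_bookkeeping_and_second_truncation(h2co_631g):
    sp, j0 = h2co_631g.space, h2co_631g.j
    naf1 = compression.build_naf(j0, 0.1)
    j1 = j0.rotate_auxiliary(naf1.rotation)
    (w, vec), = solve_cis(1, j1, sp)
    # VNOs untouched (semicanonical rotation is unitary): the second NAF
    # truncation keeps exactly the first truncation's count
    sm0 = compression.reduce_state(j1, (w, vec), sp, eps_naf=0.1,
                                   eps_vno=0.0, naf_total_aux=j0.n_aux)
    assert sm0.bookkeeping["n_naf_kept"] == naf1.n_kept
    # with a biting VNO truncation the final NAF basis is strictly smaller
    sm = compression.reduce_state(j1, (w, vec), sp, eps_naf=0.1,
                                  eps_vno=7.5e-4, naf_total_aux=j0.n_aux)
    bk = sm.bookkeeping
    assert bk["n_vno_kept"] < sp.n_virt
    assert bk["n_naf_kept"] <= naf1.n_kept       # monotone 2nd truncation
    assert sm.retained_naf_fraction < naf1.kept_fraction  # strictly fewer
    assert sm.retained_vno_fraction == \
        pytest.approx(bk["n_vno_kept"] / bk["n_virt"])
    assert 0 < sm.retained_vno_fraction < 1.0


def test_thresholds_zero_recover_canonical(h2o_631g):
    """The central correctness property: eps_vno = eps_naf = 0 leaves the
    excitation energies unchanged to 1e-8 Hartree after the VNO rotation
    and semicanonicalization."""
    sp, j = h2o_631g.space, h2o_631g.j
    mp2 = adc2.mp2_intermediates(j, sp)
    guesses = solve_cis(2, j, sp)
    settings_ = adc2.SolverSettings(n_states=1, energy_tolerance=1e-10,
                                    residual_tolerance=1e-8)
    for k in range(2):
        canon = adc2.solve_adc2(settings_, j, sp, mp2, [guesses[k]])[0]
        sm = compression.reduce_state(j, guesses[k], sp,
                                      eps_naf=0.0, eps_vno=0.0)
        r0 = sm.project_singles(guesses[k][1].amplitudes)
        mp2r = adc2.mp2_intermediates(sm.reduced_j, sm.reduced_space)
        red = adc2.solve_adc2(
            settings_, sm.reduced_j, sm.reduced_space, mp2r,
            [(guesses[k][0],
              SinglesVector(r0 / np.linalg.norm(r0)))])[0]
        assert red.omega == pytest.approx(canon.omega, abs=1e-8)
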