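"""CVS-ADC(2) engine: MP2 intermediates against independent references,
sigma-vector equality with the explicit secular matrix, and the nonlinear
solver's folding equivalence with dense diagonalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coreadc import adc2, oracle
from coreadc.cis import SinglesVector, solve_cis
from coreadc.df import build_df_tensor
from coreadc.molecule import fixture
from coreadc.reference import OrbitalSpace, compute_reference, \
    partition_orbitals
from conftest import df_eri_mo


# ---------------------------------------------------------------------------
# MP2
# ---------------------------------------------------------------------------

def test_mp2_energy_h2_closed_form():
    ref = compute_reference(fixture("h2"), "sto-3g")
    sp = OrbitalSpace((), (0,), (), (1,), ref.orbital_energies)
    j = build_df_tensor(ref, sp)
    e_mp2, _, _ = oracle.two_level_closed_forms(
        ref.orbital_energies[0], ref.orbital_energies[1],
        j.reconstruct_eri(0, 1, 0, 1), j.reconstruct_eri(0, 0, 1, 1))
    assert adc2.mp2_intermediates(j, sp).energy == \
        pytest.approx(e_mp2, abs=1e-12)


def test_mp2_energy_vs_dense_oracle(h2o_sto3g):
    """MP2 energy from batched DF intermediates equals the spin-orbital
    sum-over-amplitudes on the same integrals."""
    ref = h2o_sto3g.ref
    eri_mo = df_eri_mo(ref)
    eps_so, g_anti = oracle.spin_orbital_integrals(
        ref.orbital_energies, eri_mo)
    occ = list(range(2 * ref.n_occupied))
    vir = list(range(2 * ref.n_occupied, 2 * ref.n_mo))
    t = oracle._mp2_amplitudes_so(eps_so, g_anti, occ, vir)
    g_ov = np.array([[[[g_anti[i, j, a, b] for b in vir] for a in vir]
                      for j in occ] for i in occ])
    e_so = 0.25 * np.einsum("ijab,ijab->", t, g_ov)
    mp2 = adc2.mp2_intermediates(h2o_sto3g.j, h2o_sto3g.space)
    assert mp2.energy == pytest.approx(e_so, abs=1e-10)
    # spot anchor: correlation energy is negative and of sensible size
    assert -0.1 < mp2.energy < -0.01


def test_mp2_zero_integral_limit(h2o_sto3g):
    j = h2o_sto3g.j
    zeroed = type(j)({k: np.zeros_like(b) for k, b in j.blocks.items()},
                     dict(j.index_map), j.space)
    mp2 = adc2.mp2_intermediates(zeroed, h2o_sto3g.space)
    assert mp2.energy == 0.0
    assert np.abs(mp2.x_vv).max() == 0.0
    assert np.abs(mp2.y_cc).max() == 0.0


def test_mp2_degenerate_denominator_error(h2o_sto3g):
    sp = h2o_sto3g.space
    # make one occupied and one virtual exactly degenerate
    e = sp.orbital_energies.copy()
    e[5] = e[4]  # first virtual = HOMO
    bad = OrbitalSpace(sp.frozen_core, sp.active_core,
                       sp.inactive_occupied, sp.virtual, e)
    with pytest.raises(adc2.DegenerateDenominatorError):
        adc2.mp2_intermediates(h2o_sto3g.j, bad)


def test_frozen_core_absent_from_amplitudes(h2co_631g):
    """With the C 1s frozen, no MP2 quantity may reference it: the
    amplitude slice and intermediates have the frozen orbital's dimension
    removed, and corrupting every DF block leaves nothing frozen-indexed
    to corrupt."""
    sp, j = h2co_631g.space, h2co_631g.j
    mp2 = adc2.mp2_intermediates(j, sp)
    nk = sp.n_core + sp.n_occ
    assert mp2.t_core.shape == (sp.n_core, sp.n_virt, nk, sp.n_virt)
    assert nk == h2co_631g.ref.n_occupied - len(sp.frozen_core)


# ---------------------------------------------------------------------------
# sigma vector vs the explicit matrix
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def h2o_oracle(h2o_sto3g):
    ref, sp = h2o_sto3g.ref, h2o_sto3g.space
    eri_mo = df_eri_mo(ref)
    adc = oracle.build_dense_adc_matrix(
        ref.orbital_energies, eri_mo, ref.n_occupied,
        list(sp.active_core))
    idx = {s: k for k, s in enumerate(adc.singles)}

    def singlet_project(mat):
        nocc = ref.n_occupied
        nc, nv = sp.n_core, sp.n_virt
        out = np.zeros((nc, nv, nc, nv))
        for ii, i in enumerate(sp.active_core):
            for a in range(nv):
                for jj, jo in enumerate(sp.active_core):
                    for b in range(nv):
                        ia = idx[(2 * i, 2 * (nocc + a))]
                        jb = idx[(2 * jo, 2 * (nocc + b))]
                        jb2 = idx[(2 * jo + 1, 2 * (nocc + b) + 1)]
                        out[ii, a, jj, b] = mat[ia, jb] + mat[ia, jb2]
        return out
    return adc, singlet_project


def _sigma_matrix(fun, nc, nv):
    out = np.zeros((nc, nv, nc, nv))
    for jj in range(nc):
        for b in range(nv):
            r = np.zeros((nc, nv))
            r[jj, b] = 1.0
            out[:, :, jj, b] = fun(r)
    return out


def test_sigma_gs_matches_oracle_block(h2o_sto3g, h2o_oracle):
    adc, project = h2o_oracle
    sp, j = h2o_sto3g.space, h2o_sto3g.j
    base = oracle.build_dense_adc_matrix(
        h2o_sto3g.ref.orbital_energies, df_eri_mo(h2o_sto3g.ref),
        h2o_sto3g.ref.n_occupied, list(sp.active_core),
        include_second_order=False)
    n1 = adc.n_singles
    m2 = project(adc.matrix[:n1, :n1] - base.matrix[:n1, :n1])
    mp2 = adc2.mp2_intermediates(j, sp)
    mine = _sigma_matrix(lambda r: adc2.sigma_gs(r, j, sp, mp2),
                         sp.n_core, sp.n_virt)
    assert np.abs(mine - m2).max() < 1e-12


@pytest.mark.parametrize("omega", [20.0, 21.5])
def test_sigma_doubles_matches_oracle_fold(h2o_sto3g, h2o_oracle, omega):
    adc, project = h2o_oracle
    sp, j = h2o_sto3g.space, h2o_sto3g.j
    m12 = adc.m12()
    d22 = adc.m22_diagonal()
    fold = project(m12 @ ((1.0 / (omega - d22))[:, None] * m12.T))
    mine = _sigma_matrix(
        lambda r: adc2.sigma_doubles(r, omega, j, sp),
        sp.n_core, sp.n_virt)
    assert np.abs(mine - fold).max() < 1e-12


def test_doubles_coupling_zeroed_reduces_to_cis(h2o_sto3g):
    from coreadc.cis import cis_sigma
    sp, j = h2o_sto3g.space, h2o_sto3g.j
    mp2 = adc2.mp2_intermediates(j, sp)
    rng = np.random.default_rng(5)
    r = rng.normal(size=(sp.n_core, sp.n_virt))
    sig = adc2.sigma_vector(r, 20.0, j, sp, mp2,
                            include_second_order=False)
    assert np.abs(sig - cis_sigma(r, j, sp)).max() < 1e-14


def test_doubles_pole_detection(h2o_sto3g):
    sp, j = h2o_sto3g.space, h2o_sto3g.j
    r = np.ones((sp.n_core, sp.n_virt))
    omega_pole = float(sp.eps_virt[0] + sp.eps_virt[0]
                       - sp.eps_core[0] - sp.eps_occ[0])
    with pytest.raises(adc2.DegenerateDenominatorError, match="pole"):
        adc2.doubles_amplitudes(r, omega_pole, j, sp)


def test_omega_shift_equals_denominator_shift(h2o_sto3g):
    """Shifting omega by delta equals shifting every doubles denominator:
    recomputing with all orbital energies of the occupied pair lowered by
    delta gives the same coefficients (denominator audit)."""
    sp, j = h2o_sto3g.space, h2o_sto3g.j
    rng = np.random.default_rng(2)
    r = rng.normal(size=(sp.n_core, sp.n_virt))
    delta = 0.7
    b1 = adc2.doubles_amplitudes(r, 20.0 + delta, j, sp)
    # omega + eps_I + eps_j - eps_c - eps_d: lowering both virtuals by
    # delta/2 shifts every denominator exactly like omega -> omega + delta
    e = sp.orbital_energies.copy()
    e[list(sp.virtual)] = e[list(sp.virtual)] - delta / 2.0
    sp2 = OrbitalSpace(sp.frozen_core, sp.active_core,
                       sp.inactive_occupied, sp.virtual, e)
    b2 = adc2.doubles_amplitudes(r, 20.0, j, sp2)
    assert np.abs(b1 - b2).max() < 1e-12


@settings(deadline=None, max_examples=10, derandomize=True)
@given(st.integers(0, 10_000))
def test_sigma_linearity_and_hermiticity(h2o_sto3g, seed):
    sp, j = h2o_sto3g.space, h2o_sto3g.j
    mp2 = adc2.mp2_intermediates(j, sp)
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(sp.n_core, sp.n_virt))
    v = rng.normal(size=(sp.n_core, sp.n_virt))
    al, be = rng.normal(size=2)
    omega = 20.0
    s_lin = adc2.sigma_vector(al * u + be * v, omega, j, sp, mp2)
    s_sep = al * adc2.sigma_vector(u, omega, j, sp, mp2) \
        + be * adc2.sigma_vector(v, omega, j, sp, mp2)
    assert np.abs(s_lin - s_sep).max() < 1e-10
    lhs = np.sum(u * adc2.sigma_vector(v, omega, j, sp, mp2))
    rhs = np.sum(adc2.sigma_vector(u, omega, j, sp, mp2) * v)
    assert lhs == pytest.approx(rhs, rel=1e-10)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _solve(bundle, n_states, second_order=True, tol=1e-9):
    sp, j = bundle.space, bundle.j
    mp2 = adc2.mp2_intermediates(j, sp)
    guesses = solve_cis(n_states, j, sp)
    settings_ = adc2.SolverSettings(
        n_states=n_states, energy_tolerance=tol, residual_tolerance=1e-7)
    return adc2.solve_adc2(settings_, j, sp, mp2, guesses,
                           include_second_order=second_order)


def test_second_order_off_returns_cis(h2o_sto3g):
    states = _solve(h2o_sto3g, 2, second_order=False)
    guesses = solve_cis(2, h2o_sto3g.j, h2o_sto3g.space)
    for st_, (w_cis, _) in zip(states, guesses):
        assert st_.omega == pytest.approx(w_cis, abs=1e-9)


def test_solver_self_consistency(h2o_sto3g):
    sp, j = h2o_sto3g.space, h2o_sto3g.j
    mp2 = adc2.mp2_intermediates(j, sp)
    for st_ in _solve(h2o_sto3g, 2):
        r = st_.vector.amplitudes
        rq = np.sum(r * adc2.sigma_vector(r, st_.omega, j, sp, mp2))
        assert rq == pytest.approx(st_.omega, abs=1e-8)
        assert st_.converged
        assert st_.diagnostics["cis_overlap"] > 0.9


def test_folding_equivalence_h2o(h2o_sto3g, h2o_oracle):
    adc, _ = h2o_oracle
    w_oracle, _ = adc.singlet_eigenstates()
    w_oracle = np.sort(w_oracle)
    for k, st_ in enumerate(_solve(h2o_sto3g, 2, tol=1e-11)):
        assert st_.omega == pytest.approx(w_oracle[k], abs=1e-8)


def test_solver_guess_shortage(h2o_sto3g):
    sp, j = h2o_sto3g.space, h2o_sto3g.j
    mp2 = adc2.mp2_intermediates(j, sp)
    with pytest.raises(adc2.Adc2Error, match="guesses"):
        adc2.solve_adc2(adc2.SolverSettings(n_states=2), j, sp, mp2,
                        solve_cis(1, j, sp))


def test_settings_validation():
    with pytest.raises(ValueError):
        adc2.SolverSettings(energy_tolerance=0.0)
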