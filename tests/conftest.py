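"""Shared fixtures: small SCF references and DF tensors, cached per
session (every input is generated programmatically from the built-in
geometry/basis library)."""

import numpy as np
import pytest

from coreadc import basis as basis_mod
from coreadc import integrals
from coreadc.df import build_df_tensor, metric_inverse_sqrt
from coreadc.molecule import fixture
from coreadc.reference import compute_reference, partition_orbitals
from coreadc.scf import restricted_hartree_fock


def full_mo_df_tensor(ref):
    """Metric-dressed three-center factor over ALL MOs (frozen included);
    contracting it with itself gives the DF-reconstructed MO ERI tensor
    that the dense oracles consume."""
    vih = metric_inverse_sqrt(ref.ao_metric())
    dressed = np.einsum("mnP,PQ->Qmn", ref.ao_three_center(), vih,
                        optimize=True)
    c = ref.mo_coefficients
    return np.einsum("Qmn,mp,nq->Qpq", dressed, c, c, optimize=True)


def df_eri_mo(ref):
    jfull = full_mo_df_tensor(ref)
    return np.einsum("Qpq,Qrs->pqrs", jfull, jfull, optimize=True)


class Bundle(dict):
    def __getattr__(self, name):
        try:
            return self[name]
        except KeyError:
            raise AttributeError(name) from None


def _bundle(name, basis, cvs):
    mol = fixture(name)
    ref = compute_reference(mol, basis)
    space = partition_orbitals(ref, cvs)
    j = build_df_tensor(ref, space)
    return Bundle(molecule=mol, ref=ref, space=space, j=j)


@pytest.fixture(scope="session")
def h2o_sto3g():
    return _bundle("h2o", "sto-3g", "O 1s")


@pytest.fixture(scope="session")
def h2o_631g():
    return _bundle("h2o", "6-31g", "O 1s")


@pytest.fixture(scope="session")
def h2co_631g():
    return _bundle("h2co", "6-31g", "O 1s")


@pytest.fixture(scope="session")
def h2_sto3g_scf():
    mol = fixture("h2")
    bas = basis_mod.build_basis(mol, "sto-3g")
    eri = integrals.eri_dense(bas)
    res = restricted_hartree_fock(mol, bas, eri)
    return Bundle(molecule=mol, basis=bas, eri=eri, scf=res)


def random_symmetric_eri(rng, n, scale=0.3):
    """Random two-electron tensor with full eightfold permutation
    symmetry (not positive definite; fine for algebraic checks)."""
    g = rng.normal(0.0, scale, (n, n, n, n))
    g = g + g.transpose(1, 0, 2, 3)
    g = g + g.transpose(0, 1, 3, 2)
    g = g + g.transpose(2, 3, 0, 1)
    return g
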