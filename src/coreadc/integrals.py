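"""Molecular integrals over contracted Cartesian Gaussians.

McMurchie-Davidson scheme throughout: Gaussian products are expanded in
Hermite Gaussians (coefficients ``E``), Coulomb-type integrals contract the
Hermite expansions with the auxiliary tensor ``R`` built from Boys functions.
Provides overlap, kinetic, nuclear attraction and dipole one-electron
matrices, dense four-center electron-repulsion integrals (small systems
only; the production path never calls them), and the two- and three-center
Coulomb integrals that feed the density-fitting factorization.

All quantities in Hartree atomic units.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaln

from .basis import BasisSet, Shell, cartesian_components

__all__ = [
    "overlap", "kinetic", "nuclear_attraction", "dipole",
    "eri_dense", "three_center", "two_center_coulomb", "boys",
]


def boys(m_max: int, t: np.ndarray) -> np.ndarray:
    """Boys functions F_0..F_m(t) for an array of arguments.

    Returns shape (m_max + 1, t.size).  Uses the regularized lower
    incomplete gamma function; the t -> 0 limit 1/(2m+1) is applied where
    the argument underflows.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty((m_max + 1, t.size))
    small = t < 1.0e-13
    ts = np.where(small, 1.0, t)
    for m in range(m_max + 1):
        a = m + 0.5
        gm = np.exp(gammaln(a))
        vals = gm * gammainc(a, ts) / (2.0 * ts ** a)
        out[m] = np.where(small, 1.0 / (2 * m + 1), vals)
    return out


def _hermite_e(imax: int, jmax: int, a: float, b: float,
               ab: float) -> np.ndarray:
    """1D Hermite expansion coefficients E[i, j, t] for the product of two
    primitives with exponents a, b separated by ab = A_x - B_x."""
    p = a + b
    mu = a * b / p
    xpa = -b * ab / p   # P - A
    xpb = a * ab / p    # P - B
    e = np.zeros((imax + 1, jmax + 1, imax + jmax + 2))
    e[0, 0, 0] = np.exp(-mu * ab * ab)
    for i in range(imax):
        for t in range(i + 2):
            e[i + 1, 0, t] = ((e[i, 0, t - 1] / (2 * p) if t > 0 else 0.0)
                              + xpa * e[i, 0, t]
                              + (t + 1) * e[i, 0, t + 1])
    for j in range(jmax):
        for i in range(imax + 1):
            for t in range(i + j + 2):
                e[i, j + 1, t] = ((e[i, j, t - 1] / (2 * p) if t > 0 else 0.0)
                                  + xpb * e[i, j, t]
                                  + (t + 1) * e[i, j, t + 1])
    return e


def _hermite_coulomb(tmax: int, umax: int, vmax: int, p: float,
                     pc: np.ndarray) -> np.ndarray:
    """Hermite Coulomb tensor R_{tuv}(p, PC) (n = 0 slice)."""
    L = tmax + umax + vmax
    T = p * float(pc @ pc)
    f = boys(L, np.array([T]))[:, 0]
    r = np.zeros((L + 1, tmax + 1, umax + 1, vmax + 1))
    for n in range(L + 1):
        r[n, 0, 0, 0] = (-2.0 * p) ** n * f[n]
    x, y, z = pc
    for t in range(tmax):
        for n in range(L - t):
            r[n, t + 1, 0, 0] = (t * r[n + 1, t - 1, 0, 0] if t > 0 else 0.0) \
                + x * r[n + 1, t, 0, 0]
    for u in range(umax):
        for n in range(L - u):
            r[n, :, u + 1, 0] = (u * r[n + 1, :, u - 1, 0] if u > 0 else 0.0) \
                + y * r[n + 1, :, u, 0]
    for v in range(vmax):
        for n in range(L - v):
            r[n, :, :, v + 1] = (v * r[n + 1, :, :, v - 1] if v > 0 else 0.0) \
                + z * r[n + 1, :, :, v]
    return r[0]


class _ShellData:
    """Pre-computed per-component contraction coefficients of one shell."""

    __slots__ = ("shell", "comps", "coefs")

    def __init__(self, shell: Shell):
        self.shell = shell
        self.comps = cartesian_components(shell.l)
        self.coefs = [shell.normalized_coefficients(*c) for c in self.comps]


def _shell_data(basis: BasisSet) -> list[_ShellData]:
    return [_ShellData(sh) for sh in basis.shells]


def _pair_e(sa: Shell, sb: Shell, extra: int = 0):
    """Hermite E tensors for every primitive pair of a shell pair.

    Yields (ia, ib, p, P, Ex, Ey, Ez); ``extra`` raises the ket angular
    range (kinetic/dipole operators)."""
    la, lb = sa.l, sb.l + extra
    ab = sa.center - sb.center
    for ia, a in enumerate(sa.exponents):
        for ib, b in enumerate(sb.exponents):
            p = a + b
            cp = (a * sa.center + b * sb.center) / p
            ex = _hermite_e(la, lb, a, b, ab[0])
            ey = _hermite_e(la, lb, a, b, ab[1])
            ez = _hermite_e(la, lb, a, b, ab[2])
            yield ia, ib, a, b, p, cp, ex, ey, ez


def overlap(basis: BasisSet) -> np.ndarray:
    data = _shell_data(basis)
    n = basis.n_functions
    s = np.zeros((n, n))
    for isa, da in enumerate(data):
        oa = basis.offsets[isa]
        for isb, db in enumerate(data[:isa + 1]):
            ob = basis.offsets[isb]
            blk = np.zeros((da.shell.n_functions, db.shell.n_functions))
            for ia, ib, a, b, p, cp, ex, ey, ez in _pair_e(da.shell, db.shell):
                pref = (np.pi / p) ** 1.5
                for ka, (ax, ay, az) in enumerate(da.comps):
                    ca = da.coefs[ka][ia]
                    for kb, (bx, by, bz) in enumerate(db.comps):
                        cb = db.coefs[kb][ib]
                        blk[ka, kb] += ca * cb * pref * \
                            ex[ax, bx, 0] * ey[ay, by, 0] * ez[az, bz, 0]
            s[oa:oa + blk.shape[0], ob:ob + blk.shape[1]] = blk
            s[ob:ob + blk.shape[1], oa:oa + blk.shape[0]] = blk.T
    return s


def kinetic(basis: BasisSet) -> np.ndarray:
    data = _shell_data(basis)
    n = basis.n_functions
    tmat = np.zeros((n, n))
    for isa, da in enumerate(data):
        oa = basis.offsets[isa]
        for isb, db in enumerate(data[:isa + 1]):
            ob = basis.offsets[isb]
            blk = np.zeros((da.shell.n_functions, db.shell.n_functions))
            for ia, ib, a, b, p, cp, ex, ey, ez in _pair_e(
                    da.shell, db.shell, extra=2):
                pref = (np.pi / p) ** 1.5

                def s1d(e, i, j):
                    return e[i, j, 0] if j >= 0 else 0.0

                def t1d(e, i, j):
                    out = b * (2 * j + 1) * s1d(e, i, j) \
                        - 2.0 * b * b * s1d(e, i, j + 2)
                    if j >= 2:
                        out -= 0.5 * j * (j - 1) * s1d(e, i, j - 2)
                    return out

                for ka, (ax, ay, az) in enumerate(da.comps):
                    ca = da.coefs[ka][ia]
                    for kb, (bx, by, bz) in enumerate(db.comps):
                        cb = db.coefs[kb][ib]
                        val = (t1d(ex, ax, bx) * s1d(ey, ay, by) * s1d(ez, az, bz)
                               + s1d(ex, ax, bx) * t1d(ey, ay, by) * s1d(ez, az, bz)
                               + s1d(ex, ax, bx) * s1d(ey, ay, by) * t1d(ez, az, bz))
                        blk[ka, kb] += ca * cb * pref * val
            tmat[oa:oa + blk.shape[0], ob:ob + blk.shape[1]] = blk
            tmat[ob:ob + blk.shape[1], oa:oa + blk.shape[0]] = blk.T
    return tmat


def dipole(basis: BasisSet, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Electric-dipole (position) integrals <mu| r - origin |nu>,
    shape (3, nao, nao)."""
    origin = np.asarray(origin, dtype=float)
    data = _shell_data(basis)
    n = basis.n_functions
    d = np.zeros((3, n, n))
    for isa, da in enumerate(data):
        oa = basis.offsets[isa]
        for isb, db in enumerate(data[:isa + 1]):
            ob = basis.offsets[isb]
            bc = db.shell.center - origin
            blk = np.zeros((3, da.shell.n_functions, db.shell.n_functions))
            for ia, ib, a, b, p, cp, ex, ey, ez in _pair_e(
                    da.shell, db.shell, extra=1):
                pref = (np.pi / p) ** 1.5
                for ka, (ax, ay, az) in enumerate(da.comps):
                    ca = da.coefs[ka][ia]
                    for kb, (bx, by, bz) in enumerate(db.comps):
                        cb = db.coefs[kb][ib]
                        sx, sy, sz = ex[ax, bx, 0], ey[ay, by, 0], ez[az, bz, 0]
                        mx = ex[ax, bx + 1, 0] + bc[0] * sx
                        my = ey[ay, by + 1, 0] + bc[1] * sy
                        mz = ez[az, bz + 1, 0] + bc[2] * sz
                        blk[0, ka, kb] += ca * cb * pref * mx * sy * sz
                        blk[1, ka, kb] += ca * cb * pref * sx * my * sz
                        blk[2, ka, kb] += ca * cb * pref * sx * sy * mz
            d[:, oa:oa + blk.shape[1], ob:ob + blk.shape[2]] = blk
            d[:, ob:ob + blk.shape[2], oa:oa + blk.shape[1]] = \
                blk.transpose(0, 2, 1)
    return d


def nuclear_attraction(basis: BasisSet, charges: np.ndarray,
                       centers: np.ndarray) -> np.ndarray:
    """Nuclear-attraction matrix  -sum_A Z_A <mu| 1/r_A |nu>  (centers in
    bohr)."""
    data = _shell_data(basis)
    n = basis.n_functions
    v = np.zeros((n, n))
    for isa, da in enumerate(data):
        oa = basis.offsets[isa]
        la = da.shell.l
        for isb, db in enumerate(data[:isa + 1]):
            ob = basis.offsets[isb]
            lb = db.shell.l
            blk = np.zeros((da.shell.n_functions, db.shell.n_functions))
            for ia, ib, a, b, p, cp, ex, ey, ez in _pair_e(da.shell, db.shell):
                pref = 2.0 * np.pi / p
                for z, c in zip(charges, centers):
                    r = _hermite_coulomb(la + lb, la + lb, la + lb, p, cp - c)
                    for ka, (ax, ay, az) in enumerate(da.comps):
                        ca = da.coefs[ka][ia]
                        for kb, (bx, by, bz) in enumerate(db.comps):
                            cb = db.coefs[kb][ib]
                            val = 0.0
                            for t in range(ax + bx + 1):
                                for u in range(ay + by + 1):
                                    for w in range(az + bz + 1):
                                        val += (ex[ax, bx, t] * ey[ay, by, u]
                                                * ez[az, bz, w] * r[t, u, w])
                            blk[ka, kb] -= z * ca * cb * pref * val
            v[oa:oa + blk.shape[0], ob:ob + blk.shape[1]] = blk
            v[ob:ob + blk.shape[1], oa:oa + blk.shape[0]] = blk.T
    return v


def _pair_hermite(da: _ShellData, db: _ShellData):
    """Collect Hermite representations of all contracted products of a
    shell pair: list of (p, P, coeff_tensor[t,u,v]) per (component pair,
    primitive pair), merged over components.

    Returns (ncomp_a, ncomp_b, entries) where each entry is
    (p, P, T[ka, kb, t, u, v])."""
    sa, sb = da.shell, db.shell
    la, lb = sa.l, sb.l
    nta = la + lb + 1
    entries = []
    for ia, ib, a, b, p, cp, ex, ey, ez in _pair_e(sa, sb):
        tt = np.zeros((len(da.comps), len(db.comps), nta, nta, nta))
        for ka, (ax, ay, az) in enumerate(da.comps):
            ca = da.coefs[ka][ia]
            for kb, (bx, by, bz) in enumerate(db.comps):
                cb = db.coefs[kb][ib]
                tt[ka, kb] = ca * cb * np.einsum(
                    "t,u,v->tuv",
                    ex[ax, bx, :nta], ey[ay, by, :nta], ez[az, bz, :nta])
        entries.append((p, cp, tt))
    return entries


def eri_dense(basis: BasisSet) -> np.ndarray:
    """Dense four-center ERIs (mu nu | rho sigma), chemists' notation.

    Meant for minimal-basis validation work; scales steeply and guards
    against accidental use on large systems."""
    n = basis.n_functions
    if n > 40:
        raise ValueError(
            f"dense ERI requested for {n} basis functions; this path is "
            "restricted to small (<= 40 function) validation systems")
    data = _shell_data(basis)
    pairs = {}
    for isa, da in enumerate(data):
        for isb, db in enumerate(data[:isa + 1]):
            pairs[isa, isb] = _pair_hermite(da, db)
    eri = np.zeros((n, n, n, n))
    keys = sorted(pairs)
    for ipair, (isa, isb) in enumerate(keys):
        oa, ob = basis.offsets[isa], basis.offsets[isb]
        for (isc, isd) in keys[:ipair + 1]:
            oc, od = basis.offsets[isc], basis.offsets[isd]
            bra = pairs[isa, isb]
            ket = pairs[isc, isd]
            nta = bra[0][2].shape[2]
            ntc = ket[0][2].shape[2]
            blk = np.zeros(bra[0][2].shape[:2] + ket[0][2].shape[:2])
            for p, cp, tb in bra:
                for q, cq, tk in ket:
                    alpha = p * q / (p + q)
                    pref = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                    r = _hermite_coulomb(nta + ntc - 2, nta + ntc - 2,
                                         nta + ntc - 2, alpha, cp - cq)
                    sgn = np.array([(-1.0) ** k for k in range(ntc)])
                    tks = tk * np.einsum("t,u,v->tuv", sgn, sgn, sgn)
                    # contract R over ket hermite indices
                    rk = np.einsum("TUVtuv,cdtuv->TUVcd",
                                   _r_shift(r, nta, ntc), tks)
                    blk += pref * np.einsum("abTUV,TUVcd->abcd", tb, rk)
            _fill_eri(eri, blk, oa, ob, oc, od)
    return eri


def _r_shift(r: np.ndarray, nta: int, ntc: int) -> np.ndarray:
    """View of R with split bra/ket Hermite indices:
    out[T,U,V,t,u,v] = R[T+t, U+u, V+v]."""
    out = np.empty((nta, nta, nta, ntc, ntc, ntc))
    for t in range(ntc):
        for u in range(ntc):
            for v in range(ntc):
                out[:, :, :, t, u, v] = r[t:t + nta, u:u + nta, v:v + nta]
    return out


def _fill_eri(eri, blk, oa, ob, oc, od):
    na, nb, nc, nd = blk.shape
    for ka in range(na):
        for kb in range(nb):
            for kc in range(nc):
                for kd in range(nd):
                    val = blk[ka, kb, kc, kd]
                    i, j, k, l = oa + ka, ob + kb, oc + kc, od + kd
                    eri[i, j, k, l] = val
                    eri[j, i, k, l] = val
                    eri[i, j, l, k] = val
                    eri[j, i, l, k] = val
                    eri[k, l, i, j] = val
                    eri[l, k, i, j] = val
                    eri[k, l, j, i] = val
                    eri[l, k, j, i] = val


def three_center(basis: BasisSet, aux: BasisSet) -> np.ndarray:
    """Three-center Coulomb integrals (mu nu | P), shape (nao, nao, naux)."""
    n, naux = basis.n_functions, aux.n_functions
    data = _shell_data(basis)
    adata = _shell_data(aux)
    out = np.zeros((n, n, naux))
    # Hermite representation of each auxiliary function (b = 0 partner)
    aux_herm = []
    for dc in adata:
        sc = dc.shell
        lc = sc.l
        per_prim = []
        for ic, g in enumerate(sc.exponents):
            ex = _hermite_e(lc, 0, g, 0.0, 0.0)
            tt = np.zeros((len(dc.comps), lc + 1, lc + 1, lc + 1))
            for kc, (cx, cy, cz) in enumerate(dc.comps):
                cc = dc.coefs[kc][ic]
                tt[kc] = cc * np.einsum(
                    "t,u,v->tuv", ex[cx, 0, :lc + 1], ex[cy, 0, :lc + 1],
                    ex[cz, 0, :lc + 1])
            per_prim.append((g, tt))
        aux_herm.append(per_prim)

    for isa, da in enumerate(data):
        oa = basis.offsets[isa]
        for isb, db in enumerate(data[:isa + 1]):
            ob = basis.offsets[isb]
            bra = _pair_hermite(da, db)
            nta = bra[0][2].shape[2]
            for isc, per_prim in enumerate(aux_herm):
                oc = aux.offsets[isc]
                sc = adata[isc].shell
                ntc = sc.l + 1
                blk = np.zeros((len(da.comps), len(db.comps),
                                len(adata[isc].comps)))
                for p, cp, tb in bra:
                    for q, tk in per_prim:
                        alpha = p * q / (p + q)
                        pref = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                        r = _hermite_coulomb(nta + ntc - 2, nta + ntc - 2,
                                             nta + ntc - 2, alpha,
                                             cp - sc.center)
                        sgn = np.array([(-1.0) ** k for k in range(ntc)])
                        tks = tk * np.einsum("t,u,v->tuv", sgn, sgn, sgn)[
                            None, :, :, :]
                        rk = np.einsum("TUVtuv,ctuv->TUVc",
                                       _r_shift(r, nta, ntc), tks)
                        blk += pref * np.einsum("abTUV,TUVc->abc", tb, rk)
                out[oa:oa + blk.shape[0], ob:ob + blk.shape[1],
                    oc:oc + blk.shape[2]] = blk
                out[ob:ob + blk.shape[1], oa:oa + blk.shape[0],
                    oc:oc + blk.shape[2]] = blk.transpose(1, 0, 2)
    return out


def two_center_coulomb(aux: BasisSet) -> np.ndarray:
    """Two-center Coulomb metric (P | Q) over the auxiliary basis."""
    adata = _shell_data(aux)
    naux = aux.n_functions
    v = np.zeros((naux, naux))
    for isa, da in enumerate(adata):
        oa = aux.offsets[isa]
        sa = da.shell
        la = sa.l
        for isb, db in enumerate(adata[:isa + 1]):
            ob = aux.offsets[isb]
            sb = db.shell
            lb = sb.l
            blk = np.zeros((len(da.comps), len(db.comps)))
            for ia, a in enumerate(sa.exponents):
                exa = _hermite_e(la, 0, a, 0.0, 0.0)
                for ib, b in enumerate(sb.exponents):
                    exb = _hermite_e(lb, 0, b, 0.0, 0.0)
                    alpha = a * b / (a + b)
                    pref = 2.0 * np.pi ** 2.5 / (a * b * np.sqrt(a + b))
                    r = _hermite_coulomb(la + lb, la + lb, la + lb, alpha,
                                         sa.center - sb.center)
                    for ka, (ax, ay, az) in enumerate(da.comps):
                        ca = da.coefs[ka][ia]
                        ta = np.einsum("t,u,v->tuv", exa[ax, 0, :la + 1],
                                       exa[ay, 0, :la + 1], exa[az, 0, :la + 1])
                        for kb, (bx, by, bz) in enumerate(db.comps):
                            cb = db.coefs[kb][ib]
                            tk = np.einsum(
                                "t,u,v->tuv", exb[bx, 0, :lb + 1],
                                exb[by, 0, :lb + 1], exb[bz, 0, :lb + 1])
                            sgn = np.array([(-1.0) ** k for k in range(lb + 1)])
                            tks = tk * np.einsum("t,u,v->tuv", sgn, sgn, sgn)
                            val = np.einsum(
                                "TUVtuv,tuv->TUV",
                                _r_shift(r, la + 1, lb + 1), tks)
                            blk[ka, kb] += pref * ca * cb * \
                                np.einsum("TUV,TUV->", ta, val)
            v[oa:oa + blk.shape[0], ob:ob + blk.shape[1]] = blk
            v[ob:ob + blk.shape[1], oa:oa + blk.shape[0]] = blk.T
    return v
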