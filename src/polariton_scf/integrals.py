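"""AO integrals over contracted cartesian Gaussians (McMurchie-Davidson).

Computes overlap, kinetic, nuclear attraction, position (dipole) and
electron-repulsion integrals with Hermite-Gaussian recurrences, compiled
with numba.  Cartesian integrals are assembled first and transformed to the
real solid-harmonic basis declared by the basis set.

The public entry point is :func:`fetch_ao_integrals`, the backend contract
behind which the rest of the package is isolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .basis import CART_COMPONENTS, BasisSet, build_basis
from .elements import atomic_number

_MMAX = 20  # highest Boys order ever needed (4 d functions -> 8, + margin)


# ----------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------

@njit(cache=True)
def _boys(T, mmax, out):
    """Boys function F_m(T) for m = 0..mmax into ``out``."""
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if T > 35.0:
        # exp(-T) negligible: stable upward recursion from the erf closed form
        out[0] = 0.5 * math.sqrt(math.pi / T) * math.erf(math.sqrt(T))
        expT = math.exp(-T)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - expT) / (2.0 * T)
        return
    # series at mmax, then downward recursion
    expT = math.exp(-T)
    term = 1.0 / (2 * mmax + 1)
    acc = term
    k = 1
    while True:
        term *= 2.0 * T / (2 * mmax + 2 * k + 1)
        acc += term
        if term < 1e-17 * acc or k > 300:
            break
        k += 1
    out[mmax] = acc * expT
    for m in range(mmax - 1, -1, -1):
        out[m] = (2.0 * T * out[m + 1] + expT) / (2 * m + 1)


@njit(cache=True)
def _efill(la, lb, A, B, a, b, E):
    """Hermite expansion coefficients E[i, j, t] for one dimension."""
    p = a + b
    mu = a * b / p
    AB = A - B
    PA = -b / p * AB
    PB = a / p * AB
    E[:, :, :] = 0.0
    E[0, 0, 0] = math.exp(-mu * AB * AB)
    for i in range(la):
        for t in range(i + 2):
            v = PA * E[i, 0, t]
            if t > 0:
                v += E[i, 0, t - 1] / (2.0 * p)
            if t + 1 <= i:
                v += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for i in range(la + 1):
        for j in range(lb):
            for t in range(i + j + 2):
                v = PB * E[i, j, t]
                if t > 0:
                    v += E[i, j, t - 1] / (2.0 * p)
                if t + 1 <= i + j:
                    v += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = v


@njit(cache=True)
def _rfill(tmax, umax, vmax, p, PCx, PCy, PCz, R):
    """Hermite Coulomb integrals R[t, u, v] (auxiliary order 0)."""
    N = tmax + umax + vmax
    T = p * (PCx * PCx + PCy * PCy + PCz * PCz)
    F = np.zeros(N + 1)
    _boys(T, N, F)
    Rn = np.zeros((N + 1, tmax + 1, umax + 1, vmax + 1))
    f = 1.0
    for n in range(N + 1):
        Rn[n, 0, 0, 0] = f * F[n]
        f *= -2.0 * p
    for t in range(tmax):
        for n in range(N - t):
            v = PCx * Rn[n + 1, t, 0, 0]
            if t > 0:
                v += t * Rn[n + 1, t - 1, 0, 0]
            Rn[n, t + 1, 0, 0] = v
    for t in range(tmax + 1):
        for u in range(umax):
            for n in range(N - t - u):
                v = PCy * Rn[n + 1, t, u, 0]
                if u > 0:
                    v += u * Rn[n + 1, t, u - 1, 0]
                Rn[n, t, u + 1, 0] = v
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for w in range(vmax):
                for n in range(N - t - u - w):
                    v = PCz * Rn[n + 1, t, u, w]
                    if w > 0:
                        v += w * Rn[n + 1, t, u, w - 1]
                    Rn[n, t, u, w + 1] = v
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for w in range(vmax + 1):
                R[t, u, w] = Rn[0, t, u, w]


@njit(cache=True)
def _one_electron(ns, sl, scen, sps, snp, pexp, pcoef, soff,
                  ncart, Zs, coords, nat,
                  S, Tk, V, DX, DY, DZ, clx, cly, clz, coff):
    lmax = 4
    for si in range(ns):
        la = sl[si]
        for sj in range(si + 1):
            lb = sl[sj]
            Ax, Ay, Az = scen[si, 0], scen[si, 1], scen[si, 2]
            Bx, By, Bz = scen[sj, 0], scen[sj, 1], scen[sj, 2]
            nca = (la + 1) * (la + 2) // 2
            ncb = (lb + 1) * (lb + 2) // 2
            sblk = np.zeros((nca, ncb))
            tblk = np.zeros((nca, ncb))
            vblk = np.zeros((nca, ncb))
            dxblk = np.zeros((nca, ncb))
            dyblk = np.zeros((nca, ncb))
            dzblk = np.zeros((nca, ncb))
            Ex = np.zeros((lmax + 1, lmax + 3, 2 * lmax + 5))
            Ey = np.zeros((lmax + 1, lmax + 3, 2 * lmax + 5))
            Ez = np.zeros((lmax + 1, lmax + 3, 2 * lmax + 5))
            Rh = np.zeros((2 * lmax + 1, 2 * lmax + 1, 2 * lmax + 1))
            for pi in range(snp[si]):
                a = pexp[sps[si] + pi]
                ca = pcoef[sps[si] + pi]
                for pj in range(snp[sj]):
                    b = pexp[sps[sj] + pj]
                    cb = pcoef[sps[sj] + pj]
                    cab = ca * cb
                    p = a + b
                    _efill(la, lb + 2, Ax, Bx, a, b, Ex)
                    _efill(la, lb + 2, Ay, By, a, b, Ey)
                    _efill(la, lb + 2, Az, Bz, a, b, Ez)
                    sq = math.sqrt(math.pi / p)
                    Px = (a * Ax + b * Bx) / p
                    Py = (a * Ay + b * By) / p
                    Pz = (a * Az + b * Bz) / p
                    for ia in range(nca):
                        ilx = clx[coff[la] + ia]
                        ily = cly[coff[la] + ia]
                        ilz = clz[coff[la] + ia]
                        for jb in range(ncb):
                            jlx = clx[coff[lb] + jb]
                            jly = cly[coff[lb] + jb]
                            jlz = clz[coff[lb] + jb]
                            sx = Ex[ilx, jlx, 0] * sq
                            sy = Ey[ily, jly, 0] * sq
                            sz = Ez[ilz, jlz, 0] * sq
                            # 1-D kinetic pieces
                            kx = -2.0 * b * b * Ex[ilx, jlx + 2, 0] * sq \
                                + b * (2 * jlx + 1) * sx
                            if jlx >= 2:
                                kx -= 0.5 * jlx * (jlx - 1) * Ex[ilx, jlx - 2, 0] * sq
                            ky = -2.0 * b * b * Ey[ily, jly + 2, 0] * sq \
                                + b * (2 * jly + 1) * sy
                            if jly >= 2:
                                ky -= 0.5 * jly * (jly - 1) * Ey[ily, jly - 2, 0] * sq
                            kz = -2.0 * b * b * Ez[ilz, jlz + 2, 0] * sq \
                                + b * (2 * jlz + 1) * sz
                            if jlz >= 2:
                                kz -= 0.5 * jlz * (jlz - 1) * Ez[ilz, jlz - 2, 0] * sq
                            # 1-D position (about the origin)
                            mx = Ex[ilx, jlx + 1, 0] * sq + Bx * sx
                            my = Ey[ily, jly + 1, 0] * sq + By * sy
                            mz = Ez[ilz, jlz + 1, 0] * sq + Bz * sz
                            sblk[ia, jb] += cab * sx * sy * sz
                            tblk[ia, jb] += cab * (kx * sy * sz + sx * ky * sz
                                                   + sx * sy * kz)
                            dxblk[ia, jb] += cab * mx * sy * sz
                            dyblk[ia, jb] += cab * sx * my * sz
                            dzblk[ia, jb] += cab * sx * sy * mz
                    # nuclear attraction
                    pref = 2.0 * math.pi / p * cab
                    for iat in range(nat):
                        PCx = Px - coords[iat, 0]
                        PCy = Py - coords[iat, 1]
                        PCz = Pz - coords[iat, 2]
                        _rfill(la + lb, la + lb, la + lb, p, PCx, PCy, PCz, Rh)
                        for ia in range(nca):
                            ilx = clx[coff[la] + ia]
                            ily = cly[coff[la] + ia]
                            ilz = clz[coff[la] + ia]
                            for jb in range(ncb):
                                jlx = clx[coff[lb] + jb]
                                jly = cly[coff[lb] + jb]
                                jlz = clz[coff[lb] + jb]
                                acc = 0.0
                                for t in range(ilx + jlx + 1):
                                    for u in range(ily + jly + 1):
                                        for w in range(ilz + jlz + 1):
                                            acc += Ex[ilx, jlx, t] \
                                                * Ey[ily, jly, u] \
                                                * Ez[ilz, jlz, w] * Rh[t, u, w]
                                vblk[ia, jb] -= Zs[iat] * pref * acc
            oi = soff[si]
            oj = soff[sj]
            for ia in range(nca):
                for jb in range(ncb):
                    S[oi + ia, oj + jb] = sblk[ia, jb]
                    S[oj + jb, oi + ia] = sblk[ia, jb]
                    Tk[oi + ia, oj + jb] = tblk[ia, jb]
                    Tk[oj + jb, oi + ia] = tblk[ia, jb]
                    V[oi + ia, oj + jb] = vblk[ia, jb]
                    V[oj + jb, oi + ia] = vblk[ia, jb]
                    DX[oi + ia, oj + jb] = dxblk[ia, jb]
                    DX[oj + jb, oi + ia] = dxblk[ia, jb]
                    DY[oi + ia, oj + jb] = dyblk[ia, jb]
                    DY[oj + jb, oi + ia] = dyblk[ia, jb]
                    DZ[oi + ia, oj + jb] = dzblk[ia, jb]
                    DZ[oj + jb, oi + ia] = dzblk[ia, jb]


@njit(cache=True)
def _eri(ns, sl, scen, sps, snp, pexp, pcoef, soff,
         g, clx, cly, clz, coff):
    lmax = 2
    for si in range(ns):
        la = sl[si]
        for sj in range(si + 1):
            lb = sl[sj]
            ij = si * (si + 1) // 2 + sj
            for sk in range(ns):
                lc = sl[sk]
                for sm in range(sk + 1):
                    ld = sl[sm]
                    kl = sk * (sk + 1) // 2 + sm
                    if ij < kl:
                        continue
                    nca = (la + 1) * (la + 2) // 2
                    ncb = (lb + 1) * (lb + 2) // 2
                    ncc = (lc + 1) * (lc + 2) // 2
                    ncd = (ld + 1) * (ld + 2) // 2
                    blk = np.zeros((nca, ncb, ncc, ncd))
                    Ax, Ay, Az = scen[si, 0], scen[si, 1], scen[si, 2]
                    Bx, By, Bz = scen[sj, 0], scen[sj, 1], scen[sj, 2]
                    Cx, Cy, Cz = scen[sk, 0], scen[sk, 1], scen[sk, 2]
                    Dx, Dy, Dz = scen[sm, 0], scen[sm, 1], scen[sm, 2]
                    E1x = np.zeros((lmax + 1, lmax + 1, 2 * lmax + 1))
                    E1y = np.zeros((lmax + 1, lmax + 1, 2 * lmax + 1))
                    E1z = np.zeros((lmax + 1, lmax + 1, 2 * lmax + 1))
                    E2x = np.zeros((lmax + 1, lmax + 1, 2 * lmax + 1))
                    E2y = np.zeros((lmax + 1, lmax + 1, 2 * lmax + 1))
                    E2z = np.zeros((lmax + 1, lmax + 1, 2 * lmax + 1))
                    Rh = np.zeros((4 * lmax + 1, 4 * lmax + 1, 4 * lmax + 1))
                    for pi in range(snp[si]):
                        a = pexp[sps[si] + pi]
                        ca = pcoef[sps[si] + pi]
                        for pj in range(snp[sj]):
                            b = pexp[sps[sj] + pj]
                            cb = pcoef[sps[sj] + pj]
                            p = a + b
                            Px = (a * Ax + b * Bx) / p
                            Py = (a * Ay + b * By) / p
                            Pz = (a * Az + b * Bz) / p
                            _efill(la, lb, Ax, Bx, a, b, E1x)
                            _efill(la, lb, Ay, By, a, b, E1y)
                            _efill(la, lb, Az, Bz, a, b, E1z)
                            for pk in range(snp[sk]):
                                c = pexp[sps[sk] + pk]
                                cc = pcoef[sps[sk] + pk]
                                for pm in range(snp[sm]):
                                    d = pexp[sps[sm] + pm]
                                    cd = pcoef[sps[sm] + pm]
                                    q = c + d
                                    Qx = (c * Cx + d * Dx) / q
                                    Qy = (c * Cy + d * Dy) / q
                                    Qz = (c * Cz + d * Dz) / q
                                    _efill(lc, ld, Cx, Dx, c, d, E2x)
                                    _efill(lc, ld, Cy, Dy, c, d, E2y)
                                    _efill(lc, ld, Cz, Dz, c, d, E2z)
                                    alpha = p * q / (p + q)
                                    _rfill(la + lb + lc + ld,
                                           la + lb + lc + ld,
                                           la + lb + lc + ld,
                                           alpha, Px - Qx, Py - Qy, Pz - Qz,
                                           Rh)
                                    pref = (2.0 * math.pi ** 2.5
                                            / (p * q * math.sqrt(p + q))
                                            * ca * cb * cc * cd)
                                    for ia in range(nca):
                                        ilx = clx[coff[la] + ia]
                                        ily = cly[coff[la] + ia]
                                        ilz = clz[coff[la] + ia]
                                        for jb in range(ncb):
                                            jlx = clx[coff[lb] + jb]
                                            jly = cly[coff[lb] + jb]
                                            jlz = clz[coff[lb] + jb]
                                            for kc in range(ncc):
                                                klx = clx[coff[lc] + kc]
                                                kly = cly[coff[lc] + kc]
                                                klz = clz[coff[lc] + kc]
                                                for md in range(ncd):
                                                    mlx = clx[coff[ld] + md]
                                                    mly = cly[coff[ld] + md]
                                                    mlz = clz[coff[ld] + md]
                                                    acc = 0.0
                                                    for t in range(ilx + jlx + 1):
                                                        e1 = E1x[ilx, jlx, t]
                                                        for u in range(ily + jly + 1):
                                                            e2 = e1 * E1y[ily, jly, u]
                                                            for w in range(ilz + jlz + 1):
                                                                e3 = e2 * E1z[ilz, jlz, w]
                                                                for tt in range(klx + mlx + 1):
                                                                    f1 = E2x[klx, mlx, tt]
                                                                    sg = 1.0 if tt % 2 == 0 else -1.0
                                                                    for uu in range(kly + mly + 1):
                                                                        f2 = f1 * E2y[kly, mly, uu]
                                                                        sg2 = sg if uu % 2 == 0 else -sg
                                                                        for ww in range(klz + mlz + 1):
                                                                            f3 = f2 * E2z[klz, mlz, ww]
                                                                            sg3 = sg2 if ww % 2 == 0 else -sg2
                                                                            acc += e3 * f3 * sg3 * Rh[t + tt, u + uu, w + ww]
                                                    blk[ia, jb, kc, md] += pref * acc
                    oi, oj, ok, om = soff[si], soff[sj], soff[sk], soff[sm]
                    for ia in range(nca):
                        for jb in range(ncb):
                            for kc in range(ncc):
                                for md in range(ncd):
                                    v = blk[ia, jb, kc, md]
                                    P, Q, R, S_ = oi + ia, oj + jb, ok + kc, om + md
                                    g[P, Q, R, S_] = v
                                    g[Q, P, R, S_] = v
                                    g[P, Q, S_, R] = v
                                    g[Q, P, S_, R] = v
                                    g[R, S_, P, Q] = v
                                    g[S_, R, P, Q] = v
                                    g[R, S_, Q, P] = v
                                    g[S_, R, Q, P] = v


# ----------------------------------------------------------------------
# python-level assembly
# ----------------------------------------------------------------------

@dataclass
class AOIntegralSet:
    """AO-level integrals for one molecule/basis (spherical AO basis).

    ``eri`` is in chemists' notation (pq|rs) with 8-fold permutational
    symmetry; ``dipole_e`` holds the three *position* integral matrices
    <mu| r_k |nu> (the electronic dipole operator is minus these);
    ``d_nuc = sum_A Z_A R_A``.
    """

    overlap: np.ndarray
    core_h: np.ndarray
    eri: np.ndarray
    dipole_e: np.ndarray  # (3, n, n) position integrals
    d_nuc: np.ndarray     # (3,)
    e_nuc: float
    n_basis: int


def _flatten(basis: BasisSet):
    ns = len(basis.shells)
    sl = np.array([sh.l for sh in basis.shells], dtype=np.int64)
    scen = np.array([sh.center for sh in basis.shells])
    snp = np.array([len(sh.exponents) for sh in basis.shells], dtype=np.int64)
    sps = np.zeros(ns, dtype=np.int64)
    sps[1:] = np.cumsum(snp)[:-1]
    pexp = np.concatenate([sh.exponents for sh in basis.shells])
    pcoef = np.concatenate([sh.coefficients for sh in basis.shells])
    soff = np.zeros(ns, dtype=np.int64)
    acc = 0
    for i, sh in enumerate(basis.shells):
        soff[i] = acc
        acc += sh.n_cartesian
    # cartesian component tables indexed by l
    lmax = max(CART_COMPONENTS)
    clx, cly, clz, coff = [], [], [], np.zeros(lmax + 1, dtype=np.int64)
    k = 0
    for l in range(lmax + 1):
        coff[l] = k
        for (lx, ly, lz) in CART_COMPONENTS[l]:
            clx.append(lx)
            cly.append(ly)
            clz.append(lz)
            k += 1
    return (ns, sl, scen, sps, snp, pexp, pcoef, soff,
            np.array(clx, dtype=np.int64), np.array(cly, dtype=np.int64),
            np.array(clz, dtype=np.int64), coff)


def compute_integrals(basis: BasisSet, Zs: np.ndarray,
                      coords: np.ndarray) -> AOIntegralSet:
    """All AO integrals for a laid-out basis and nuclei (bohr)."""
    (ns, sl, scen, sps, snp, pexp, pcoef, soff,
     clx, cly, clz, coff) = _flatten(basis)
    nc = basis.n_cartesian
    S = np.zeros((nc, nc))
    T = np.zeros((nc, nc))
    V = np.zeros((nc, nc))
    DX = np.zeros((nc, nc))
    DY = np.zeros((nc, nc))
    DZ = np.zeros((nc, nc))
    Zf = np.asarray(Zs, dtype=np.float64)
    _one_electron(ns, sl, scen, sps, snp, pexp, pcoef, soff, nc,
                  Zf, coords, len(Zf), S, T, V, DX, DY, DZ,
                  clx, cly, clz, coff)
    g = np.zeros((nc, nc, nc, nc))
    _eri(ns, sl, scen, sps, snp, pexp, pcoef, soff, g, clx, cly, clz, coff)

    Tr = basis.cart_to_sph_matrix()
    sph = lambda M: Tr.T @ M @ Tr
    g = np.einsum("pi,pqrs->iqrs", Tr, g, optimize=True)
    g = np.einsum("qj,iqrs->ijrs", Tr, g, optimize=True)
    g = np.einsum("rk,ijrs->ijks", Tr, g, optimize=True)
    g = np.einsum("sl,ijks->ijkl", Tr, g, optimize=True)

    e_nuc = 0.0
    for i in range(len(Zf)):
        for j in range(i):
            e_nuc += Zf[i] * Zf[j] / np.linalg.norm(coords[i] - coords[j])
    d_nuc = (Zf[:, None] * coords).sum(axis=0)

    return AOIntegralSet(
        overlap=sph(S),
        core_h=sph(T) + sph(V),
        eri=np.ascontiguousarray(g),
        dipole_e=np.stack([sph(DX), sph(DY), sph(DZ)]),
        d_nuc=d_nuc,
        e_nuc=e_nuc,
        n_basis=basis.n_spherical,
    )


_MAX_BASIS = 200


def fetch_ao_integrals(system) -> AOIntegralSet:
    """AO integrals for a :class:`~polariton_scf.system.MolecularSystem`.

    Holds full N^4 two-electron tensors in memory; refuses above
    200 basis functions (batched/Cholesky handling is a deliberate
    extension hook, not implemented).
    """
    basis = build_basis(system.atoms, system.coords, system.basis_name)
    if basis.n_spherical > _MAX_BASIS:
        raise ValueError(
            f"{basis.n_spherical} basis functions exceeds the in-memory "
            f"limit of {_MAX_BASIS}; integral batching (Cholesky decomposition "
            "of the two-electron tensor) is left as an extension hook"
        )
    Zs = np.array([atomic_number(a) for a in system.atoms], dtype=float)
    return compute_integrals(basis, Zs, system.coords)
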