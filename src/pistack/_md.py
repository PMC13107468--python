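"""McMurchie–Davidson Gaussian integral kernels (numba).

Cartesian Gaussians up to l = 3; overlap, kinetic, nuclear attraction and
two-electron repulsion integrals via Hermite expansion coefficients and
Boys-function Hermite Coulomb integrals.  Everything operates on the flat
shell arrays of :class:`pistack.basis.AOBasis` and works in atomic units.
"""

import math

import numpy as np
from numba import njit

LMAX = 3
_CART_MAX = (LMAX + 1) * (LMAX + 2) // 2


@njit(cache=True)
def _boys(mmax, T, F):
    """Fill F[0..mmax] with Boys functions F_m(T)."""
    if T < 1e-13:
        for m in range(mmax + 1):
            F[m] = 1.0 / (2 * m + 1)
        return
    if T > 35.0:
        F[0] = 0.5 * math.sqrt(math.pi / T)
        expT = math.exp(-T)
        for m in range(mmax):
            F[m + 1] = ((2 * m + 1) * F[m] - expT) / (2.0 * T)
        return
    # series for F_mmax, then stable downward recursion
    expT = math.exp(-T)
    term = 1.0 / (2 * mmax + 1)
    s = term
    i = 0
    while True:
        term *= 2.0 * T / (2 * mmax + 2 * i + 3)
        s += term
        i += 1
        if term < 1e-17 * s or i > 300:
            break
    F[mmax] = expT * s
    for m in range(mmax, 0, -1):
        F[m - 1] = (2.0 * T * F[m] + expT) / (2 * m - 1)


@njit(cache=True)
def _etable(la, lb, xpa, xpb, one_over_2p, k_dim, E):
    """Hermite expansion coefficients E[i, j, t] for one dimension."""
    for i in range(la + 2):
        for j in range(lb + 2):
            for t in range(la + lb + 2):
                E[i, j, t] = 0.0
    E[0, 0, 0] = k_dim
    for i in range(la):
        for t in range(i + 2):
            v = xpa * E[i, 0, t]
            if t > 0:
                v += one_over_2p * E[i, 0, t - 1]
            if t + 1 <= i:
                v += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for i in range(la + 1):
        for j in range(lb):
            for t in range(i + j + 2):
                v = xpb * E[i, j, t]
                if t > 0:
                    v += one_over_2p * E[i, j, t - 1]
                if t + 1 <= i + j:
                    v += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = v


@njit(cache=True)
def _rtable(L, p, X, Y, Z, R, R4, F):
    """Hermite Coulomb integrals R[t, u, v] for all t + u + v <= L.

    R4 and F are caller-provided workspaces of sufficient size; all entries
    read are written first, so stale contents are harmless.
    """
    T = p * (X * X + Y * Y + Z * Z)
    _boys(L, T, F)
    f = 1.0
    for n in range(L + 1):
        R4[n, 0, 0, 0] = f * F[n]
        f *= -2.0 * p
    for v in range(1, L + 1):
        for n in range(L - v + 1):
            val = Z * R4[n + 1, 0, 0, v - 1]
            if v > 1:
                val += (v - 1) * R4[n + 1, 0, 0, v - 2]
            R4[n, 0, 0, v] = val
    for u in range(1, L + 1):
        for v in range(L - u + 1):
            for n in range(L - u - v + 1):
                val = Y * R4[n + 1, 0, u - 1, v]
                if u > 1:
                    val += (u - 1) * R4[n + 1, 0, u - 2, v]
                R4[n, 0, u, v] = val
    for t in range(1, L + 1):
        for u in range(L - t + 1):
            for v in range(L - t - u + 1):
                for n in range(L - t - u - v + 1):
                    val = X * R4[n + 1, t - 1, u, v]
                    if t > 1:
                        val += (t - 1) * R4[n + 1, t - 2, u, v]
                    R4[n, t, u, v] = val
    for t in range(L + 1):
        for u in range(L - t + 1):
            for v in range(L - t - u + 1):
                R[t, u, v] = R4[0, t, u, v]


@njit(cache=True)
def _comp_table(l, comps):
    """Cartesian components (lx, ly, lz) of shell l; returns count."""
    k = 0
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            comps[k, 0] = lx
            comps[k, 1] = ly
            comps[k, 2] = l - lx - ly
            k += 1
    return k


@njit(cache=True)
def _dfact(n):
    out = 1.0
    k = n
    while k > 1:
        out *= k
        k -= 2
    return out


@njit(cache=True)
def _comp_norm(lx, ly, lz):
    l = lx + ly + lz
    return math.sqrt(_dfact(2 * l - 1) /
                     (_dfact(2 * lx - 1) * _dfact(2 * ly - 1) * _dfact(2 * lz - 1)))


@njit(cache=True)
def _overlap_kinetic_pair(la, lb, A, B, aexp, acoef, bexp, bcoef, Sblk, Tblk):
    """Overlap and kinetic blocks for one shell pair."""
    ca = np.zeros((_CART_MAX, 3), dtype=np.int64)
    cb = np.zeros((_CART_MAX, 3), dtype=np.int64)
    na = _comp_table(la, ca)
    nb = _comp_table(lb, cb)
    for i in range(na):
        for j in range(nb):
            Sblk[i, j] = 0.0
            Tblk[i, j] = 0.0
    E = np.zeros((3, la + 2, lb + 4, la + lb + 6))
    for ip in range(len(aexp)):
        a = aexp[ip]
        for jp in range(len(bexp)):
            b = bexp[jp]
            p = a + b
            mu = a * b / p
            cc = acoef[ip] * bcoef[jp]
            pref = cc * (math.pi / p) ** 1.5
            for d in range(3):
                xab = A[d] - B[d]
                xp = (a * A[d] + b * B[d]) / p
                _etable(la, lb + 2, xp - A[d], xp - B[d], 0.5 / p,
                        math.exp(-mu * xab * xab), E[d])
            for i in range(na):
                lxa, lya, lza = ca[i, 0], ca[i, 1], ca[i, 2]
                gna = _comp_norm(lxa, lya, lza)
                for j in range(nb):
                    lxb, lyb, lzb = cb[j, 0], cb[j, 1], cb[j, 2]
                    gn = gna * _comp_norm(lxb, lyb, lzb)
                    sx = E[0, lxa, lxb, 0]
                    sy = E[1, lya, lyb, 0]
                    sz = E[2, lza, lzb, 0]
                    Sblk[i, j] += pref * gn * sx * sy * sz
                    # 1D kinetic parts
                    tx = -2.0 * b * b * E[0, lxa, lxb + 2, 0] \
                        + b * (2 * lxb + 1) * E[0, lxa, lxb, 0]
                    if lxb >= 2:
                        tx -= 0.5 * lxb * (lxb - 1) * E[0, lxa, lxb - 2, 0]
                    ty = -2.0 * b * b * E[1, lya, lyb + 2, 0] \
                        + b * (2 * lyb + 1) * E[1, lya, lyb, 0]
                    if lyb >= 2:
                        ty -= 0.5 * lyb * (lyb - 1) * E[1, lya, lyb - 2, 0]
                    tz = -2.0 * b * b * E[2, lza, lzb + 2, 0] \
                        + b * (2 * lzb + 1) * E[2, lza, lzb, 0]
                    if lzb >= 2:
                        tz -= 0.5 * lzb * (lzb - 1) * E[2, lza, lzb - 2, 0]
                    Tblk[i, j] += pref * gn * (tx * sy * sz + sx * ty * sz
                                               + sx * sy * tz)


@njit(cache=True)
def build_overlap_kinetic(shell_l, shell_center, shell_pstart, shell_pcount,
                          shell_ao, prim_exp, prim_coef, nao):
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    nsh = len(shell_l)
    Sblk = np.zeros((_CART_MAX, _CART_MAX))
    Tblk = np.zeros((_CART_MAX, _CART_MAX))
    for ish in range(nsh):
        la = shell_l[ish]
        na = (la + 1) * (la + 2) // 2
        pa0, pan = shell_pstart[ish], shell_pcount[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            nb = (lb + 1) * (lb + 2) // 2
            pb0, pbn = shell_pstart[jsh], shell_pcount[jsh]
            _overlap_kinetic_pair(
                la, lb, shell_center[ish], shell_center[jsh],
                prim_exp[pa0:pa0 + pan], prim_coef[pa0:pa0 + pan],
                prim_exp[pb0:pb0 + pbn], prim_coef[pb0:pb0 + pbn],
                Sblk, Tblk)
            i0, j0 = shell_ao[ish], shell_ao[jsh]
            for i in range(na):
                for j in range(nb):
                    S[i0 + i, j0 + j] = Sblk[i, j]
                    S[j0 + j, i0 + i] = Sblk[i, j]
                    T[i0 + i, j0 + j] = Tblk[i, j]
                    T[j0 + j, i0 + i] = Tblk[i, j]
    return S, T


@njit(cache=True)
def _comp_norms(l, out):
    """Per-component normalization factors of shell l (1.0 for s and p)."""
    k = 0
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            lz = l - lx - ly
            out[k] = _comp_norm(lx, ly, lz)
            k += 1
    return k


@njit(cache=True)
def build_nuclear(shell_l, shell_center, shell_pstart, shell_pcount,
                  shell_ao, prim_exp, prim_coef, nao, charges, charge_pos):
    """Nuclear attraction matrix V = sum_C -Z_C <mu|1/|r-C||nu>."""
    V = np.zeros((nao, nao))
    nsh = len(shell_l)
    ca = np.zeros((_CART_MAX, 3), dtype=np.int64)
    cb = np.zeros((_CART_MAX, 3), dtype=np.int64)
    gna = np.zeros(_CART_MAX)
    gnb = np.zeros(_CART_MAX)
    R = np.zeros((2 * LMAX + 1, 2 * LMAX + 1, 2 * LMAX + 1))
    R4 = np.zeros((6 * LMAX + 1, 2 * LMAX + 1, 2 * LMAX + 1, 2 * LMAX + 1))
    Fb = np.zeros(6 * LMAX + 1)
    E = np.zeros((3, LMAX + 2, LMAX + 4, 2 * LMAX + 6))
    blk = np.zeros((_CART_MAX, _CART_MAX))
    for ish in range(nsh):
        la = shell_l[ish]
        na = _comp_table(la, ca)
        _comp_norms(la, gna)
        pa0, pan = shell_pstart[ish], shell_pcount[ish]
        A = shell_center[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            nb = _comp_table(lb, cb)
            _comp_norms(lb, gnb)
            pb0, pbn = shell_pstart[jsh], shell_pcount[jsh]
            B = shell_center[jsh]
            i0, j0 = shell_ao[ish], shell_ao[jsh]
            for i in range(na):
                for j in range(nb):
                    blk[i, j] = 0.0
            for ip in range(pan):
                a = prim_exp[pa0 + ip]
                for jp in range(pbn):
                    b = prim_exp[pb0 + jp]
                    p = a + b
                    mu = a * b / p
                    cc = prim_coef[pa0 + ip] * prim_coef[pb0 + jp]
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    for d in range(3):
                        xab = A[d] - B[d]
                        xp = (a * A[d] + b * B[d]) / p
                        _etable(la, lb, xp - A[d], xp - B[d], 0.5 / p,
                                math.exp(-mu * xab * xab), E[d])
                    pref = cc * 2.0 * math.pi / p
                    for ic in range(len(charges)):
                        _rtable(la + lb, p,
                                Px - charge_pos[ic, 0],
                                Py - charge_pos[ic, 1],
                                Pz - charge_pos[ic, 2], R, R4, Fb)
                        Z = charges[ic]
                        for i in range(na):
                            lxa, lya, lza = ca[i, 0], ca[i, 1], ca[i, 2]
                            for j in range(nb):
                                lxb, lyb, lzb = cb[j, 0], cb[j, 1], cb[j, 2]
                                gn = gna[i] * gnb[j]
                                s = 0.0
                                for t in range(lxa + lxb + 1):
                                    et = E[0, lxa, lxb, t]
                                    for u in range(lya + lyb + 1):
                                        eu = et * E[1, lya, lyb, u]
                                        for v in range(lza + lzb + 1):
                                            s += eu * E[2, lza, lzb, v] * R[t, u, v]
                                blk[i, j] += -Z * pref * gn * s
            for i in range(na):
                for j in range(nb):
                    V[i0 + i, j0 + j] = blk[i, j]
                    V[j0 + j, i0 + i] = blk[i, j]
    return V


@njit(cache=True)
def _eri_shell_quartet(la, lb, lc, ld, A, B, C, D,
                       aexp, acoef, bexp, bcoef, cexp, ccoef, dexp, dcoef,
                       out, Eab, Ecd, R, R4, Fb):
    """Contracted ERI block (ab|cd) for one shell quartet.

    Eab/Ecd/R/R4/Fb are caller-provided workspaces (see build_eri_*)."""
    ca = np.zeros((_CART_MAX, 3), dtype=np.int64)
    cb = np.zeros((_CART_MAX, 3), dtype=np.int64)
    cc_ = np.zeros((_CART_MAX, 3), dtype=np.int64)
    cd_ = np.zeros((_CART_MAX, 3), dtype=np.int64)
    gna = np.zeros(_CART_MAX)
    gnb = np.zeros(_CART_MAX)
    gnc = np.zeros(_CART_MAX)
    gnd = np.zeros(_CART_MAX)
    na = _comp_table(la, ca)
    nb = _comp_table(lb, cb)
    nc = _comp_table(lc, cc_)
    nd = _comp_table(ld, cd_)
    _comp_norms(la, gna)
    _comp_norms(lb, gnb)
    _comp_norms(lc, gnc)
    _comp_norms(ld, gnd)
    for i in range(na):
        for j in range(nb):
            for k in range(nc):
                for m in range(nd):
                    out[i, j, k, m] = 0.0
    lab = la + lb
    lcd = lc + ld
    for ip in range(len(aexp)):
        a = aexp[ip]
        for jp in range(len(bexp)):
            b = bexp[jp]
            p = a + b
            mup = a * b / p
            Px = (a * A[0] + b * B[0]) / p
            Py = (a * A[1] + b * B[1]) / p
            Pz = (a * A[2] + b * B[2]) / p
            for d in range(3):
                xab = A[d] - B[d]
                xp = (a * A[d] + b * B[d]) / p
                _etable(la, lb, xp - A[d], xp - B[d], 0.5 / p,
                        math.exp(-mup * xab * xab), Eab[d])
            cab = acoef[ip] * bcoef[jp]
            rab2 = (A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2 + (A[2] - B[2]) ** 2
            kab = math.exp(-mup * rab2)
            for kp in range(len(cexp)):
                c = cexp[kp]
                for mp in range(len(dexp)):
                    dd = dexp[mp]
                    q = c + dd
                    muq = c * dd / q
                    rcd2 = (C[0] - D[0]) ** 2 + (C[1] - D[1]) ** 2 \
                        + (C[2] - D[2]) ** 2
                    kcd = math.exp(-muq * rcd2)
                    bound = abs(cab * ccoef[kp] * dcoef[mp]) * kab * kcd \
                        * 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
                    if bound < 1e-16:
                        continue
                    Qx = (c * C[0] + dd * D[0]) / q
                    Qy = (c * C[1] + dd * D[1]) / q
                    Qz = (c * C[2] + dd * D[2]) / q
                    for d in range(3):
                        xcd = C[d] - D[d]
                        xq = (c * C[d] + dd * D[d]) / q
                        _etable(lc, ld, xq - C[d], xq - D[d], 0.5 / q,
                                math.exp(-muq * xcd * xcd), Ecd[d])
                    omega = p * q / (p + q)
                    _rtable(lab + lcd, omega,
                            Px - Qx, Py - Qy, Pz - Qz, R, R4, Fb)
                    pref = cab * ccoef[kp] * dcoef[mp] * 2.0 * math.pi ** 2.5 \
                        / (p * q * math.sqrt(p + q))
                    for i in range(na):
                        lxa, lya, lza = ca[i, 0], ca[i, 1], ca[i, 2]
                        for j in range(nb):
                            lxb, lyb, lzb = cb[j, 0], cb[j, 1], cb[j, 2]
                            for k in range(nc):
                                lxc, lyc, lzc = cc_[k, 0], cc_[k, 1], cc_[k, 2]
                                for m in range(nd):
                                    lxd, lyd, lzd = cd_[m, 0], cd_[m, 1], cd_[m, 2]
                                    gn = gna[i] * gnb[j] * gnc[k] * gnd[m]
                                    s = 0.0
                                    for t in range(lxa + lxb + 1):
                                        et = Eab[0, lxa, lxb, t]
                                        for u in range(lya + lyb + 1):
                                            eu = et * Eab[1, lya, lyb, u]
                                            for v in range(lza + lzb + 1):
                                                ev = eu * Eab[2, lza, lzb, v]
                                                s2 = 0.0
                                                for tt in range(lxc + lxd + 1):
                                                    ft = Ecd[0, lxc, lxd, tt]
                                                    for uu in range(lyc + lyd + 1):
                                                        fu = ft * Ecd[1, lyc, lyd, uu]
                                                        for vv in range(lzc + lzd + 1):
                                                            sg = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                            s2 += sg * fu * Ecd[2, lzc, lzd, vv] \
                                                                * R[t + tt, u + uu, v + vv]
                                                s += ev * s2
                                    out[i, j, k, m] += pref * gn * s


@njit(cache=True)
def _eri_workspaces():
    Eab = np.zeros((3, LMAX + 2, LMAX + 2, 2 * LMAX + 2))
    Ecd = np.zeros((3, LMAX + 2, LMAX + 2, 2 * LMAX + 2))
    k = 4 * LMAX
    R = np.zeros((k + 1, k + 1, k + 1))
    R4 = np.zeros((3 * k + 1, k + 1, k + 1, k + 1))
    Fb = np.zeros(3 * k + 1)
    return Eab, Ecd, R, R4, Fb


@njit(cache=True)
def _schwarz_shellpairs(shell_l, shell_center, shell_pstart, shell_pcount,
                        prim_exp, prim_coef):
    """sqrt(max |(ab|ab)|) per shell pair, for Cauchy-Schwarz screening."""
    nsh = len(shell_l)
    Q = np.zeros((nsh, nsh))
    blk = np.zeros((_CART_MAX, _CART_MAX, _CART_MAX, _CART_MAX))
    Eab, Ecd, R, R4, Fb = _eri_workspaces()
    for ish in range(nsh):
        la = shell_l[ish]
        na = (la + 1) * (la + 2) // 2
        pa0, pan = shell_pstart[ish], shell_pcount[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            nb = (lb + 1) * (lb + 2) // 2
            pb0, pbn = shell_pstart[jsh], shell_pcount[jsh]
            _eri_shell_quartet(
                la, lb, la, lb,
                shell_center[ish], shell_center[jsh],
                shell_center[ish], shell_center[jsh],
                prim_exp[pa0:pa0 + pan], prim_coef[pa0:pa0 + pan],
                prim_exp[pb0:pb0 + pbn], prim_coef[pb0:pb0 + pbn],
                prim_exp[pa0:pa0 + pan], prim_coef[pa0:pa0 + pan],
                prim_exp[pb0:pb0 + pbn], prim_coef[pb0:pb0 + pbn],
                blk, Eab, Ecd, R, R4, Fb)
            mx = 0.0
            for i in range(na):
                for j in range(nb):
                    v = abs(blk[i, j, i, j])
                    if v > mx:
                        mx = v
            Q[ish, jsh] = math.sqrt(mx)
            Q[jsh, ish] = Q[ish, jsh]
    return Q


@njit(cache=True)
def build_eri_dense(shell_l, shell_center, shell_pstart, shell_pcount,
                    shell_ao, prim_exp, prim_coef, nao, screen_thresh):
    """Full (nao, nao, nao, nao) ERI tensor in chemists' notation (ij|kl)."""
    eri = np.zeros((nao, nao, nao, nao))
    nsh = len(shell_l)
    Q = _schwarz_shellpairs(shell_l, shell_center, shell_pstart, shell_pcount,
                            prim_exp, prim_coef)
    blk = np.zeros((_CART_MAX, _CART_MAX, _CART_MAX, _CART_MAX))
    Eab, Ecd, R, R4, Fb = _eri_workspaces()
    for ish in range(nsh):
        la = shell_l[ish]
        na = (la + 1) * (la + 2) // 2
        pa0, pan = shell_pstart[ish], shell_pcount[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            nb = (lb + 1) * (lb + 2) // 2
            pb0, pbn = shell_pstart[jsh], shell_pcount[jsh]
            pij = ish * (ish + 1) // 2 + jsh
            for ksh in range(ish + 1):
                lc = shell_l[ksh]
                nc = (lc + 1) * (lc + 2) // 2
                pc0, pcn = shell_pstart[ksh], shell_pcount[ksh]
                for lsh in range(ksh + 1):
                    pkl = ksh * (ksh + 1) // 2 + lsh
                    if pkl > pij:
                        continue
                    if Q[ish, jsh] * Q[ksh, lsh] < screen_thresh:
                        continue
                    ld = shell_l[lsh]
                    nd = (ld + 1) * (ld + 2) // 2
                    pd0, pdn = shell_pstart[lsh], shell_pcount[lsh]
                    _eri_shell_quartet(
                        la, lb, lc, ld,
                        shell_center[ish], shell_center[jsh],
                        shell_center[ksh], shell_center[lsh],
                        prim_exp[pa0:pa0 + pan], prim_coef[pa0:pa0 + pan],
                        prim_exp[pb0:pb0 + pbn], prim_coef[pb0:pb0 + pbn],
                        prim_exp[pc0:pc0 + pcn], prim_coef[pc0:pc0 + pcn],
                        prim_exp[pd0:pd0 + pdn], prim_coef[pd0:pd0 + pdn],
                        blk, Eab, Ecd, R, R4, Fb)
                    i0, j0 = shell_ao[ish], shell_ao[jsh]
                    k0, l0 = shell_ao[ksh], shell_ao[lsh]
                    for i in range(na):
                        for j in range(nb):
                            for k in range(nc):
                                for m in range(nd):
                                    v = blk[i, j, k, m]
                                    ii, jj = i0 + i, j0 + j
                                    kk, ll = k0 + k, l0 + m
                                    eri[ii, jj, kk, ll] = v
                                    eri[jj, ii, kk, ll] = v
                                    eri[ii, jj, ll, kk] = v
                                    eri[jj, ii, ll, kk] = v
                                    eri[kk, ll, ii, jj] = v
                                    eri[ll, kk, ii, jj] = v
                                    eri[kk, ll, jj, ii] = v
                                    eri[ll, kk, jj, ii] = v
    return eri


@njit(cache=True)
def build_eri_packed(shell_l, shell_center, shell_pstart, shell_pcount,
                     shell_ao, prim_exp, prim_coef, nao, screen_thresh):
    """ERIs in canonically packed 1D storage (8-fold symmetry)."""
    npair = nao * (nao + 1) // 2
    eri = np.zeros(npair * (npair + 1) // 2)
    nsh = len(shell_l)
    Q = _schwarz_shellpairs(shell_l, shell_center, shell_pstart, shell_pcount,
                            prim_exp, prim_coef)
    blk = np.zeros((_CART_MAX, _CART_MAX, _CART_MAX, _CART_MAX))
    Eab, Ecd, R, R4, Fb = _eri_workspaces()
    for ish in range(nsh):
        la = shell_l[ish]
        na = (la + 1) * (la + 2) // 2
        pa0, pan = shell_pstart[ish], shell_pcount[ish]
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            nb = (lb + 1) * (lb + 2) // 2
            pb0, pbn = shell_pstart[jsh], shell_pcount[jsh]
            pij = ish * (ish + 1) // 2 + jsh
            for ksh in range(ish + 1):
                lc = shell_l[ksh]
                nc = (lc + 1) * (lc + 2) // 2
                pc0, pcn = shell_pstart[ksh], shell_pcount[ksh]
                for lsh in range(ksh + 1):
                    pkl = ksh * (ksh + 1) // 2 + lsh
                    if pkl > pij:
                        continue
                    if Q[ish, jsh] * Q[ksh, lsh] < screen_thresh:
                        continue
                    ld = shell_l[lsh]
                    nd = (ld + 1) * (ld + 2) // 2
                    pd0, pdn = shell_pstart[lsh], shell_pcount[lsh]
                    _eri_shell_quartet(
                        la, lb, lc, ld,
                        shell_center[ish], shell_center[jsh],
                        shell_center[ksh], shell_center[lsh],
                        prim_exp[pa0:pa0 + pan], prim_coef[pa0:pa0 + pan],
                        prim_exp[pb0:pb0 + pbn], prim_coef[pb0:pb0 + pbn],
                        prim_exp[pc0:pc0 + pcn], prim_coef[pc0:pc0 + pcn],
                        prim_exp[pd0:pd0 + pdn], prim_coef[pd0:pd0 + pdn],
                        blk, Eab, Ecd, R, R4, Fb)
                    i0, j0 = shell_ao[ish], shell_ao[jsh]
                    k0, l0 = shell_ao[ksh], shell_ao[lsh]
                    for i in range(na):
                        for j in range(nb):
                            ii, jj = i0 + i, j0 + j
                            if ii >= jj:
                                p = ii * (ii + 1) // 2 + jj
                            else:
                                p = jj * (jj + 1) // 2 + ii
                            for k in range(nc):
                                for m in range(nd):
                                    kk, ll = k0 + k, l0 + m
                                    if kk >= ll:
                                        q = kk * (kk + 1) // 2 + ll
                                    else:
                                        q = ll * (ll + 1) // 2 + kk
                                    if p >= q:
                                        idx = p * (p + 1) // 2 + q
                                    else:
                                        idx = q * (q + 1) // 2 + p
                                    eri[idx] = blk[i, j, k, m]
    return eri


@njit(cache=True)
def jk_from_packed(eri, D, nao):
    """Coulomb and exchange matrices from a symmetric (spinless) density D.

    J[p,q] = sum_rs (pq|rs) D[r,s];  K[p,s] = sum_qr (pq|rs) D[q,r].
    """
    J = np.zeros((nao, nao))
    K = np.zeros((nao, nao))
    idx = 0
    for i in range(nao):
        for j in range(i + 1):
            pij = i * (i + 1) // 2 + j
            for k in range(nao):
                if k > i:
                    break
                for l in range(k + 1):
                    pkl = k * (k + 1) // 2 + l
                    if pkl > pij:
                        break
                    v = eri[idx]
                    idx += 1
                    if v == 0.0:
                        continue
                    if i == j:
                        if k == l:
                            if pij == pkl:
                                J[i, j] += D[k, l] * v
                                K[i, l] += D[j, k] * v
                            else:
                                J[i, j] += D[k, l] * v
                                K[i, l] += D[j, k] * v
                                J[k, l] += D[i, j] * v
                                K[k, j] += D[l, i] * v
                        else:
                            J[i, j] += D[k, l] * v
                            K[i, l] += D[j, k] * v
                            J[i, j] += D[l, k] * v
                            K[i, k] += D[j, l] * v
                            J[k, l] += D[i, j] * v
                            K[k, j] += D[l, i] * v
                            J[l, k] += D[i, j] * v
                            K[l, j] += D[k, i] * v
                    else:
                        if k == l:
                            J[i, j] += D[k, l] * v
                            K[i, l] += D[j, k] * v
                            J[j, i] += D[k, l] * v
                            K[j, l] += D[i, k] * v
                            J[k, l] += D[i, j] * v
                            K[k, j] += D[l, i] * v
                            J[k, l] += D[j, i] * v
                            K[k, i] += D[l, j] * v
                        elif pij == pkl:
                            J[i, j] += D[k, l] * v
                            K[i, l] += D[j, k] * v
                            J[j, i] += D[k, l] * v
                            K[j, l] += D[i, k] * v
                            J[i, j] += D[l, k] * v
                            K[i, k] += D[j, l] * v
                            J[j, i] += D[l, k] * v
                            K[j, k] += D[i, l] * v
                        else:
                            J[i, j] += D[k, l] * v
                            K[i, l] += D[j, k] * v
                            J[j, i] += D[k, l] * v
                            K[j, l] += D[i, k] * v
                            J[i, j] += D[l, k] * v
                            K[i, k] += D[j, l] * v
                            J[j, i] += D[l, k] * v
                            K[j, k] += D[i, l] * v
                            J[k, l] += D[i, j] * v
                            K[k, j] += D[l, i] * v
                            J[l, k] += D[i, j] * v
                            K[l, j] += D[k, i] * v
                            J[k, l] += D[j, i] * v
                            K[k, i] += D[l, j] * v
                            J[l, k] += D[j, i] * v
                            K[l, i] += D[k, j] * v
    return J, K
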