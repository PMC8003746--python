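"""Independent Mie oracle used only by the test suite.

Computes stratified-sphere multipole coefficients by writing down the raw
interface boundary conditions per order and solving the resulting linear
system in 50-digit arithmetic (mpmath Riccati-Bessel functions from
half-integer Bessel functions).  Shares no code path with the production
log-derivative recursion: direct function evaluation vs recurrences,
linear solve vs layer recursion, arbitrary precision vs float64.
"""

from __future__ import annotations

import mpmath as mp

mp.mp.dps = 50


def _psi(n, z):
    z = mp.mpmathify(z)
    return mp.sqrt(mp.pi * z / 2) * mp.besselj(n + mp.mpf(1) / 2, z)


def _chi(n, z):
    z = mp.mpmathify(z)
    return -mp.sqrt(mp.pi * z / 2) * mp.bessely(n + mp.mpf(1) / 2, z)


def _xi(n, z):
    return _psi(n, z) - 1j * _chi(n, z)


def _dpsi(n, z):
    return _psi(n - 1, z) - n / z * _psi(n, z)


def _dchi(n, z):
    return _chi(n - 1, z) - n / z * _chi(n, z)


def _dxi(n, z):
    return _xi(n - 1, z) - n / z * _xi(n, z)


def coefficients(radii_nm, indices, medium_index, wavelength_nm, n_max):
    """(a_n, b_n) for n = 1..n_max of a stratified sphere, as complex lists.

    Boundary conditions per interface (time convention exp(-i omega t)):
    TM: u continuous, u'/m continuous;  TE: u continuous, m*u' continuous,
    with u the Riccati radial function of the local argument m_l * k * r.
    """
    k0 = 2 * mp.pi * medium_index / mp.mpmathify(wavelength_nm)
    x = [k0 * mp.mpmathify(r) for r in radii_nm]
    m = [mp.mpmathify(mi) / medium_index for mi in indices] + [mp.mpf(1)]
    L = len(x)
    a_out, b_out = [], []
    for n in range(1, n_max + 1):
        res = []
        for pol in ("TM", "TE"):
            # unknowns: c_1, (c_2,d_2), ..., (c_L,d_L), a  -> 2L unknowns
            nun = 2 * L
            A = mp.zeros(nun, nun)
            rhs = mp.zeros(nun, 1)

            def col_c(l):  # layer l in 1..L
                return 0 if l == 1 else 2 * l - 3

            def col_d(l):
                return 2 * l - 2  # only valid for l >= 2

            def wgt(mm):
                return 1 / mm if pol == "TM" else mm

            row = 0
            for j in range(1, L + 1):  # interface at radius x[j-1]
                z_in = m[j - 1] * x[j - 1]
                z_out = m[j] * x[j - 1]
                # continuity of u
                A[row, col_c(j)] = _psi(n, z_in)
                if j >= 2:
                    A[row, col_d(j)] = _chi(n, z_in)
                if j < L:
                    A[row, col_c(j + 1)] = -_psi(n, z_out)
                    A[row, col_d(j + 1)] = -_chi(n, z_out)
                else:
                    A[row, 2 * L - 1] = -_xi(n, z_out)
                    rhs[row, 0] = -_psi(n, z_out)
                row += 1
                # weighted continuity of u'
                A[row, col_c(j)] = wgt(m[j - 1]) * _dpsi(n, z_in)
                if j >= 2:
                    A[row, col_d(j)] = wgt(m[j - 1]) * _dchi(n, z_in)
                if j < L:
                    A[row, col_c(j + 1)] = -wgt(m[j]) * _dpsi(n, z_out)
                    A[row, col_d(j + 1)] = -wgt(m[j]) * _dchi(n, z_out)
                else:
                    A[row, 2 * L - 1] = -wgt(m[j]) * _dxi(n, z_out)
                    rhs[row, 0] = -wgt(m[j]) * _dpsi(n, z_out)
                row += 1
            sol = mp.lu_solve(A, rhs)
            res.append(complex(sol[2 * L - 1, 0]))
        a_out.append(res[0])
        b_out.append(res[1])
    return a_out, b_out


def efficiencies(radii_nm, indices, medium_index, wavelength_nm, n_max):
    """(q_ext, q_sca) from the boundary-condition solve."""
    a, b = coefficients(radii_nm, indices, medium_index, wavelength_nm, n_max)
    x = float(2 * mp.pi * medium_index * radii_nm[-1] / wavelength_nm)
    qe = qs = 0.0
    for i, (an, bn) in enumerate(zip(a, b), start=1):
        w = 2 * i + 1
        qe += w * (an + bn).real
        qs += w * (abs(an) ** 2 + abs(bn) ** 2)
    return 2 / x**2 * qe, 2 / x**2 * qs
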