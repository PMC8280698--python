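"""Optional numba-accelerated RK4 kernels for the two-state electronic step.

These reproduce exactly the arithmetic of the numpy reference kernels in
:mod:`hopdyn.dynamics` (same stage structure, same interpolation nodes); the
dispatcher falls back to numpy when numba is unavailable or for n_states > 2.
For SHXF the per-stage decoherence rate is folded into the kernel through
the precomputed projection g_i = sum_nu (Q_nu/M_nu)(f_0,nu - f_1,nu), since
for two states lam_0 = p~_1 g and lam_1 = -p~_0 g with p~ the live-state
normalized populations of the current stage coefficients.
"""

import numba as nb
import numpy as np  # noqa: F401  (kept for signature clarity)


@nb.njit(fastmath=False)
def rk4_two_state(c, ea0, dea, eb0, deb, k0, dk, dt, nsub):
    N = c.shape[0]
    h = dt / nsub
    out = c.copy()
    for i in range(N):
        c0 = out[i, 0]
        c1 = out[i, 1]
        for j in range(nsub):
            s0 = j / nsub
            sm = (j + 0.5) / nsub
            s1 = (j + 1) / nsub
            ea_a = ea0[i] + dea[i] * s0
            eb_a = eb0[i] + deb[i] * s0
            kk_a = k0[i] + dk[i] * s0
            ea_m = ea0[i] + dea[i] * sm
            eb_m = eb0[i] + deb[i] * sm
            kk_m = k0[i] + dk[i] * sm
            ea_b = ea0[i] + dea[i] * s1
            eb_b = eb0[i] + deb[i] * s1
            kk_b = k0[i] + dk[i] * s1
            a0 = -1j * ea_a * c0 - kk_a * c1
            a1 = -1j * eb_a * c1 + kk_a * c0
            x0 = c0 + 0.5 * h * a0
            x1 = c1 + 0.5 * h * a1
            b0 = -1j * ea_m * x0 - kk_m * x1
            b1 = -1j * eb_m * x1 + kk_m * x0
            x0 = c0 + 0.5 * h * b0
            x1 = c1 + 0.5 * h * b1
            g0 = -1j * ea_m * x0 - kk_m * x1
            g1 = -1j * eb_m * x1 + kk_m * x0
            x0 = c0 + h * g0
            x1 = c1 + h * g1
            d0 = -1j * ea_b * x0 - kk_b * x1
            d1 = -1j * eb_b * x1 + kk_b * x0
            c0 = c0 + (h / 6.0) * (a0 + 2 * b0 + 2 * g0 + d0)
            c1 = c1 + (h / 6.0) * (a1 + 2 * b1 + 2 * g1 + d1)
        out[i, 0] = c0
        out[i, 1] = c1
    return out


@nb.njit(fastmath=False)
def rk4_two_state_xf(c, ea0, dea, eb0, deb, k0, dk, g, l0, l1, dt, nsub):
    N = c.shape[0]
    h = dt / nsub
    out = c.copy()
    for i in range(N):
        c0 = out[i, 0]
        c1 = out[i, 1]
        gi = g[i]
        li0 = l0[i]
        li1 = l1[i]
        for j in range(nsub):
            s0 = j / nsub
            sm = (j + 0.5) / nsub
            s1 = (j + 1) / nsub
            ea_a = ea0[i] + dea[i] * s0
            eb_a = eb0[i] + deb[i] * s0
            kk_a = k0[i] + dk[i] * s0
            ea_m = ea0[i] + dea[i] * sm
            eb_m = eb0[i] + deb[i] * sm
            kk_m = k0[i] + dk[i] * sm
            ea_b = ea0[i] + dea[i] * s1
            eb_b = eb0[i] + deb[i] * s1
            kk_b = k0[i] + dk[i] * s1

            def _der(x0, x1, ea, eb, kk):
                w0 = li0 * (x0.real * x0.real + x0.imag * x0.imag)
                w1 = li1 * (x1.real * x1.real + x1.imag * x1.imag)
                tot = w0 + w1
                if tot > 0.0:
                    lam0 = (w1 / tot) * gi * li0
                    lam1 = -(w0 / tot) * gi * li1
                else:
                    lam0 = 0.0
                    lam1 = 0.0
                d0 = -1j * ea * x0 - kk * x1 + lam0 * x0
                d1 = -1j * eb * x1 + kk * x0 + lam1 * x1
                return d0, d1

            a0, a1 = _der(c0, c1, ea_a, eb_a, kk_a)
            b0, b1 = _der(c0 + 0.5 * h * a0, c1 + 0.5 * h * a1, ea_m, eb_m, kk_m)
            g0, g1 = _der(c0 + 0.5 * h * b0, c1 + 0.5 * h * b1, ea_m, eb_m, kk_m)
            d0, d1 = _der(c0 + h * g0, c1 + h * g1, ea_b, eb_b, kk_b)
            c0 = c0 + (h / 6.0) * (a0 + 2 * b0 + 2 * g0 + d0)
            c1 = c1 + (h / 6.0) * (a1 + 2 * b1 + 2 * g1 + d1)
        out[i, 0] = c0
        out[i, 1] = c1
    return out
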