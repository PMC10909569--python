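"""Compiled inner loops for the batched fitter.

The Monte Carlo studies evaluate the kinetic model hundreds of millions
of times; the numpy broadcasting path allocates large temporaries at each
step, so the profiled sum-of-squares objective is implemented here as a
numba kernel operating on flat arrays.  The numpy implementation in
`ceasl.model` remains the reference; the two are cross-checked in the
test suite.  When numba is unavailable the fitter transparently falls
back to the numpy path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

_DEG_TOL = 1e-6


@njit(cache=True)
def _w_pair(r, tp, t_l):
    """Phase kernel W(r) and derivatives W'(r), W''(r) for one point."""
    if tp <= t_l:
        eu = np.exp(-r * tp)
        n0 = 1.0 - eu
        n1 = tp * eu
        n2 = -(tp * tp) * eu
    else:
        u2 = tp - t_l
        eu = np.exp(-r * tp)
        eu2 = np.exp(-r * u2)
        n0 = eu2 - eu
        n1 = tp * eu - u2 * eu2
        n2 = u2 * u2 * eu2 - tp * tp * eu
    w0 = n0 / r
    w1 = n1 / r - n0 / (r * r)
    w2 = n2 / r - 2.0 * n1 / (r * r) + 2.0 * n0 / (r * r * r)
    return w0, w1, w2


@njit(cache=True)
def _unit_dm(tp, kb, r1b, r1e, t_l, amp):
    """Difference signal for f = 1 at one time point (amp excludes f)."""
    if tp <= 0.0:
        return 0.0
    j = kb + r1b
    wj, _, _ = _w_pair(j, tp, t_l)
    wr, wr1, wr2 = _w_pair(r1e, tp, t_l)
    h = j - r1e
    if abs(h) < _DEG_TOL:
        dd = -wr1 - 0.5 * h * wr2
    else:
        dd = (wr - wj) / h
    return amp * (wj + kb * dd)


@njit(cache=True)
def profiled_sse(ta_flat, kb_flat, t1e_b, m0_b, times, r1b_bn, y_bn, yy_b,
                 t_l, alpha, lam, ta_lo, ta_hi, kb_lo, kb_hi, f_lo, f_hi,
                 out):
    """Normalized SSE with f profiled out, one value per parameter point.

    Parameter points are ordered so that point i belongs to data row
    ``i % B``.  Out-of-bounds (t_A, k_b) are clipped for evaluation and
    penalized quadratically.
    """
    k = ta_flat.size
    b = y_bn.shape[0]
    n = times.size
    for i in range(k):
        bi = i % b
        ta = ta_flat[i]
        kb = kb_flat[i]
        ta_c = min(max(ta, ta_lo), ta_hi)
        kb_c = min(max(kb, kb_lo), kb_hi)
        pen = (ta - ta_c) ** 2 + (kb - kb_c) ** 2
        r1e = 1.0 / t1e_b[bi]
        amp0 = 2.0 * (1.0 / 6000.0) * (m0_b[bi] / lam) * alpha
        ss = 0.0
        sy = 0.0
        for jx in range(n):
            r1b = r1b_bn[bi, jx]
            amp = amp0 * np.exp(-r1b * ta_c)
            s = _unit_dm(times[jx] - ta_c, kb_c, r1b, r1e, t_l, amp)
            ss += s * s
            sy += s * y_bn[bi, jx]
        if ss > 0.0:
            fh = sy / ss
        else:
            fh = 0.0
        fh = min(max(fh, f_lo), f_hi)
        res = yy_b[bi] - 2.0 * fh * sy + fh * fh * ss
        norm = yy_b[bi] if yy_b[bi] > 1e-300 else 1e-300
        out[i] = res / norm + 100.0 * pen
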