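"""Direct 3×3 convolution kernels, JIT-compiled with numba when available.

The im2col + GEMM route materializes a 9× blow-up of every feature map,
which makes a CPU U-Net memory-bound; these direct kernels keep data in
place and fuse the 9 kernel taps into one pass over each output row so the
compiler can vectorize the contiguous inner column loop. If numba is
unavailable the caller falls back to the im2col path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected to be present
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f
        return deco


@njit(cache=True, fastmath=True)
def conv3x3_forward(xp, w, out):
    """out[n,o,r,c] = sum_{i,di,dj} w[o,i,di,dj] * xp[n,i,r+di,c+dj].

    ``xp`` is the zero-padded input (n, ci, h+2, w+2); ``out`` must be
    zero-initialized (n, co, h, w). Also computes the input gradient when
    given the spatially flipped, channel-transposed weights.
    """
    n, co, h, wd = out.shape
    ci = xp.shape[1]
    for b in range(n):
        for o in range(co):
            for i in range(ci):
                w00 = w[o, i, 0, 0]; w01 = w[o, i, 0, 1]; w02 = w[o, i, 0, 2]
                w10 = w[o, i, 1, 0]; w11 = w[o, i, 1, 1]; w12 = w[o, i, 1, 2]
                w20 = w[o, i, 2, 0]; w21 = w[o, i, 2, 1]; w22 = w[o, i, 2, 2]
                for r in range(h):
                    x0 = xp[b, i, r]
                    x1 = xp[b, i, r + 1]
                    x2 = xp[b, i, r + 2]
                    orow = out[b, o, r]
                    for c in range(wd):
                        orow[c] += (w00 * x0[c] + w01 * x0[c + 1] + w02 * x0[c + 2]
                                    + w10 * x1[c] + w11 * x1[c + 1] + w12 * x1[c + 2]
                                    + w20 * x2[c] + w21 * x2[c + 1] + w22 * x2[c + 2])


@njit(cache=True, fastmath=True)
def conv3x3_wgrad(xp, dout, dw):
    """dw[o,i,di,dj] += sum_{n,r,c} dout[n,o,r,c] * xp[n,i,r+di,c+dj]."""
    n, co, h, wd = dout.shape
    ci = xp.shape[1]
    for o in range(co):
        for i in range(ci):
            for di in range(3):
                a0 = np.float32(0.0)
                a1 = np.float32(0.0)
                a2 = np.float32(0.0)
                for b in range(n):
                    for r in range(h):
                        drow = dout[b, o, r]
                        xrow = xp[b, i, r + di]
                        for c in range(wd):
                            d = drow[c]
                            a0 += d * xrow[c]
                            a1 += d * xrow[c + 1]
                            a2 += d * xrow[c + 2]
                dw[o, i, di, 0] += a0
                dw[o, i, di, 1] += a1
                dw[o, i, di, 2] += a2
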