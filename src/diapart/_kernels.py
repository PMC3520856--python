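"""Low-level log-domain convolution kernels.

The whole package stores elementary-symmetric-function coefficients as
logarithms, so the inner loop of every merge is a log-sum-exp convolution

    out[k] = log sum_{j+l=k} exp(a[j] + b[l] + j*l*coupling)

with an optional bilinear coupling term used by the merge-level indirect
averaging.  All summands are non-negative in the linear domain, so the
reduction is cancellation-free by construction.

A numba version carries the production workload (128x128 lattices need
~1e8 cell updates per partition-function evaluation); a vectorized numpy
implementation of the identical reduction is kept both as a fallback and
as an in-repo cross-check.
"""

from __future__ import annotations

import numpy as np

__all__ = ["log_conv", "log_conv_numpy", "HAVE_NUMBA"]

# exp(x) for x < _EXP_CUTOFF is < 4e-18 relative to the running maximum
# and cannot move a double-precision sum; skipping it saves most of the
# libm calls at low temperature.
_EXP_CUTOFF = -40.0


def _log_conv_impl(a, b, coupling, out):  # pragma: no cover - jitted
    p = a.shape[0]
    q = b.shape[0]
    for k in range(p + q - 1):
        j_lo = k - q + 1
        if j_lo < 0:
            j_lo = 0
        j_hi = k
        if j_hi > p - 1:
            j_hi = p - 1
        m = -np.inf
        for j in range(j_lo, j_hi + 1):
            s = a[j] + b[k - j] + coupling * j * (k - j)
            if s > m:
                m = s
        if m == -np.inf:
            out[k] = -np.inf
            continue
        acc = 0.0
        for j in range(j_lo, j_hi + 1):
            d = a[j] + b[k - j] + coupling * j * (k - j) - m
            if d > _EXP_CUTOFF:
                acc += np.exp(d)
        out[k] = m + np.log(acc)
    return out


try:
    from numba import njit

    _log_conv_jit = njit(cache=True, fastmath=False)(_log_conv_impl)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _log_conv_jit = None
    HAVE_NUMBA = False


def log_conv_numpy(a: np.ndarray, b: np.ndarray, coupling: float = 0.0) -> np.ndarray:
    """Reference log-sum-exp convolution (vectorized numpy).

    Builds the (p, p+q-1) staircase matrix whose column k holds the
    anti-diagonal j + l = k and reduces it with a max-shifted sum.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    p, q = a.shape[0], b.shape[0]
    n_out = p + q - 1
    jj = np.arange(p)[:, None]
    ll = np.arange(q)[None, :]
    s = a[:, None] + b[None, :] + coupling * (jj * ll)
    stair = np.full((p, n_out), -np.inf)
    cols = jj + ll  # output index k = j + l
    stair[np.repeat(np.arange(p), q), cols.ravel()] = s.ravel()
    m = stair.max(axis=0)
    out = np.full(n_out, -np.inf)
    ok = np.isfinite(m)
    if np.any(ok):
        with np.errstate(invalid="ignore"):
            out[ok] = m[ok] + np.log(np.exp(stair[:, ok] - m[ok]).sum(axis=0))
    return out


def log_conv(a: np.ndarray, b: np.ndarray, coupling: float = 0.0) -> np.ndarray:
    """Log-domain convolution out[k] = LSE_{j+l=k}(a[j]+b[l]+coupling*j*l)."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if _log_conv_jit is not None:
        out = np.empty(a.shape[0] + b.shape[0] - 1)
        return _log_conv_jit(a, b, float(coupling), out)
    return log_conv_numpy(a, b, coupling)
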