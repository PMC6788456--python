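"""Numba kernels for the blockwise Gibbs location sweep.

The coefficient matrix of the mixed-model equations is held in CSR form
with a sparsity pattern that is fixed across iterations; only its data
array changes as variance components are updated.  One sweep visits every
sampling block (scalars for fixed effects, contiguous (intercept, slope)
pairs for random effects) and draws it from its conditional normal given
the current values of all other coefficients.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def csr_position_map(u_indptr, u_indices, rows, cols):
    """Positions of (rows[k], cols[k]) inside a canonical CSR pattern.

    The union pattern must contain every queried coordinate; indices are
    sorted within each row so a binary search suffices.
    """
    out = np.empty(rows.shape[0], dtype=np.int64)
    for k in range(rows.shape[0]):
        r = rows[k]
        c = cols[k]
        lo = u_indptr[r]
        hi = u_indptr[r + 1]
        while lo < hi:
            mid = (lo + hi) // 2
            if u_indices[mid] < c:
                lo = mid + 1
            else:
                hi = mid
        if lo >= u_indptr[r + 1] or u_indices[lo] != c:
            raise ValueError("coordinate not present in union pattern")
        out[k] = lo
    return out


@njit(cache=True)
def sweep_blocks(indptr, indices, data, rhs, theta, block_start, block_size, z):
    """One Gibbs sweep over all sampling blocks (sizes 1 and 2).

    For block b with rows s..s+sz-1 the conditional is
    N(C_bb^{-1} (rhs_b - C_b,-b theta_-b), C_bb^{-1}); ``z`` supplies one
    standard-normal deviate per coefficient so the caller controls the
    random stream.  ``theta`` is updated in place.
    """
    zi = 0
    for b in range(block_start.shape[0]):
        s = block_start[b]
        if block_size[b] == 1:
            acc = rhs[s]
            diag = 0.0
            for k in range(indptr[s], indptr[s + 1]):
                j = indices[k]
                if j == s:
                    diag = data[k]
                else:
                    acc -= data[k] * theta[j]
            theta[s] = acc / diag + z[zi] / np.sqrt(diag)
            zi += 1
        else:
            r0 = rhs[s]
            r1 = rhs[s + 1]
            c00 = 0.0
            c01 = 0.0
            c11 = 0.0
            for k in range(indptr[s], indptr[s + 1]):
                j = indices[k]
                if j == s:
                    c00 = data[k]
                elif j == s + 1:
                    c01 = data[k]
                else:
                    r0 -= data[k] * theta[j]
            for k in range(indptr[s + 1], indptr[s + 2]):
                j = indices[k]
                if j == s + 1:
                    c11 = data[k]
                elif j != s:
                    r1 -= data[k] * theta[j]
            # Cholesky of the 2x2 conditional precision.
            l00 = np.sqrt(c00)
            l10 = c01 / l00
            d = c11 - l10 * l10
            if d <= 0.0:  # numerical guard; precision is PD in exact arithmetic
                d = 1e-12
            l11 = np.sqrt(d)
            u0 = r0 / l00
            u1 = (r1 - l10 * u0) / l11
            m1 = u1 / l11
            m0 = (u0 - l10 * m1) / l00
            e1 = z[zi + 1] / l11
            e0 = (z[zi] - l10 * e1) / l00
            theta[s] = m0 + e0
            theta[s + 1] = m1 + e1
            zi += 2


@njit(cache=True)
def csr_matvec(indptr, indices, data, x, out):
    for i in range(out.shape[0]):
        acc = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            acc += data[k] * x[indices[k]]
        out[i] = acc
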