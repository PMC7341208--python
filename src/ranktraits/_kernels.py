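"""Compiled inner loops for the Gibbs sampler.

The per-individual blocked update of additive genetic effects is the only
truly sequential scan (each full conditional depends on the freshly updated
values of relatives through A⁻¹), so it runs under numba.  Matrices are tiny
(t traits, t <= 4 in practice), hence the hand-written Cholesky/solves.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sample_additive_sweep(indptr, indices, avals, a, ginv, w, sw, nrec, z):
    """One Gibbs sweep over all rows of the additive vector (in place).

    Parameters
    ----------
    indptr, indices, avals : CSR storage of A⁻¹ (size M x M, individuals
        followed by genetic-group columns).
    a : (M, t) additive effects, updated in place.
    ginv : (t, t) inverse of the genetic covariance matrix.
    w : (t, t) inverse of the residual covariance matrix.
    sw : (M, t) per-individual data terms  sum_r W (E_r + a_i_old),
        constant during the sweep because records belong to one individual.
    nrec : (M,) record count per individual (0 for groups).
    z : (M, t) standard-normal driving noise.
    """
    m, t = a.shape
    cross = np.empty(t)
    rhs = np.empty(t)
    prec = np.empty((t, t))
    chol = np.empty((t, t))
    u = np.empty(t)
    mean = np.empty(t)
    for i in range(m):
        aii = 0.0
        for q in range(t):
            cross[q] = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            v = avals[p]
            if j == i:
                aii = v
            else:
                for q in range(t):
                    cross[q] += v * a[j, q]
        if aii == 0.0 and nrec[i] == 0:
            # unused group column: no data, no prior precision
            for q in range(t):
                a[i, q] = 0.0
            continue
        for q in range(t):
            s = sw[i, q]
            for p in range(t):
                s -= ginv[q, p] * cross[p]
                prec[q, p] = nrec[i] * w[q, p] + aii * ginv[q, p]
            rhs[q] = s
        # Cholesky prec = L L'
        for q in range(t):
            s = prec[q, q]
            for p in range(q):
                s -= chol[q, p] * chol[q, p]
            chol[q, q] = np.sqrt(s)
            for r in range(q + 1, t):
                s = prec[r, q]
                for p in range(q):
                    s -= chol[r, p] * chol[q, p]
                chol[r, q] = s / chol[q, q]
        # mean = prec^{-1} rhs : forward then back substitution
        for q in range(t):
            s = rhs[q]
            for p in range(q):
                s -= chol[q, p] * u[p]
            u[q] = s / chol[q, q]
        for q in range(t - 1, -1, -1):
            s = u[q]
            for p in range(q + 1, t):
                s -= chol[p, q] * mean[p]
            mean[q] = s / chol[q, q]
        # draw: a_i = mean + L'^{-1} z_i  (covariance prec^{-1})
        for q in range(t - 1, -1, -1):
            s = z[i, q]
            for p in range(q + 1, t):
                s -= chol[p, q] * u[p]
            u[q] = s / chol[q, q]
        for q in range(t):
            a[i, q] = mean[q] + u[q]
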