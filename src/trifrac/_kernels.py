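"""Numba inner loops for the orthology HMM.

The joint hidden state is a tuple of per-genome track permutations, one of
6^n states.  The between-pillar transition kernel factorises over genomes
as K = (1-theta) I + (theta/5)(J - I), i.e. K = a I + b J with
a = 1 - 6 theta / 5 and b = theta / 5, so applying the joint kernel is n
axis-wise rank-one updates instead of a 6^n x 6^n matrix product.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _kernel_inplace(alpha, buf, n_genomes, a, b):
    """alpha := (K x K x ... x K) alpha, using buf as scratch."""
    S = alpha.shape[0]
    stride = S // 6
    flip = False
    for _ in range(n_genomes):
        src = buf if flip else alpha
        dst = alpha if flip else buf
        block = stride * 6
        nblocks = S // block
        for blk in range(nblocks):
            base = blk * block
            for off in range(stride):
                s6 = 0.0
                for k in range(6):
                    s6 += src[base + off + k * stride]
                for k in range(6):
                    idx = base + off + k * stride
                    dst[idx] = a * src[idx] + b * s6
        flip = not flip
        stride //= 6
    if flip:  # result currently in buf
        for s in range(S):
            alpha[s] = buf[s]


@njit(cache=True, fastmath=True)
def _kernel_rot_batch(src, dst, S, B, a, b, s6):
    """Kernel along the last state axis + rotate that axis to the front.

    src/dst are flat (S*B,) with the batch index fastest; a, b are the
    per-batch kernel coefficients; s6 is (B,) scratch.
    """
    m = S // 6
    for j in range(m):
        for bb in range(B):
            s6[bb] = 0.0
        for k in range(6):
            off = (j * 6 + k) * B
            for bb in range(B):
                s6[bb] += src[off + bb]
        for k in range(6):
            off = (j * 6 + k) * B
            offd = (k * m + j) * B
            for bb in range(B):
                dst[offd + bb] = a[bb] * src[off + bb] + b[bb] * s6[bb]


@njit(cache=True, fastmath=True)
def forward_ll_batch(red, idx, inv, brk, theta, n_genomes):
    """Batched scaled forward pass over reduced emissions.

    red: (B, U, R) emissions over the reduced per-genome leaf classes;
    idx: (U, S) maps each joint state to its reduced index; theta: (B,).
    Returns (B,) total ln-likelihoods, one per batch member.
    """
    B, U, R = red.shape
    S = idx.shape[1]
    n = inv.shape[0]
    a = np.empty(B)
    bc = np.empty(B)
    for bb in range(B):
        a[bb] = 1.0 - 1.2 * theta[bb]
        bc[bb] = theta[bb] / 5.0
    alpha = np.empty(S * B)
    buf = np.empty(S * B)
    s6 = np.empty(B)
    tot = np.empty(B)
    ll = np.zeros(B)
    for i in range(n):
        r = inv[i]
        if i == 0 or brk[i]:
            for s in range(S):
                off = s * B
                e = idx[r, s]
                for bb in range(B):
                    alpha[off + bb] = red[bb, r, e]
        else:
            flip = False
            for _ in range(n_genomes):
                if flip:
                    _kernel_rot_batch(buf, alpha, S, B, a, bc, s6)
                else:
                    _kernel_rot_batch(alpha, buf, S, B, a, bc, s6)
                flip = not flip
            if flip:
                for q in range(S * B):
                    alpha[q] = buf[q]
            for s in range(S):
                off = s * B
                e = idx[r, s]
                for bb in range(B):
                    alpha[off + bb] *= red[bb, r, e]
        for bb in range(B):
            tot[bb] = 0.0
        for s in range(S):
            off = s * B
            for bb in range(B):
                tot[bb] += alpha[off + bb]
        for bb in range(B):
            ll[bb] += np.log(tot[bb])
            tot[bb] = 1.0 / tot[bb] if tot[bb] > 0.0 else 0.0
        for s in range(S):
            off = s * B
            for bb in range(B):
                alpha[off + bb] *= tot[bb]
    # the uniform initial distribution contributes -ln S per chain segment
    nseg = 1
    for i in range(1, n):
        if brk[i]:
            nseg += 1
    for bb in range(B):
        ll[bb] -= nseg * np.log(S)
    return ll


@njit(cache=True, fastmath=True)
def forward_ll(em_u, inv, brk, theta, n_genomes):
    """Scaled forward recursion; returns the total ln-likelihood.

    em_u: (U, S) emission rows for the unique pillar patterns;
    inv:  (n,) pattern index per pillar; brk: (n,) chain re-init flags.
    """
    n = inv.shape[0]
    S = em_u.shape[1]
    a = 1.0 - 1.2 * theta
    b = theta / 5.0
    alpha = np.empty(S)
    buf = np.empty(S)
    uni = 1.0 / S
    ll = 0.0
    for i in range(n):
        e = em_u[inv[i]]
        if i == 0 or brk[i]:
            for s in range(S):
                alpha[s] = uni * e[s]
        else:
            _kernel_inplace(alpha, buf, n_genomes, a, b)
            for s in range(S):
                alpha[s] *= e[s]
        tot = 0.0
        for s in range(S):
            tot += alpha[s]
        ll += np.log(tot)
        if tot > 0.0:
            r = 1.0 / tot
            for s in range(S):
                alpha[s] *= r
    return ll


@njit(cache=True, fastmath=True)
def forward_backward(em_u, inv, brk, theta, n_genomes):
    """Returns (ln-likelihood, per-pillar posterior gamma of shape (n, S))."""
    n = inv.shape[0]
    S = em_u.shape[1]
    a = 1.0 - 1.2 * theta
    b = theta / 5.0
    alphas = np.empty((n, S))
    buf = np.empty(S)
    alpha = np.empty(S)
    uni = 1.0 / S
    ll = 0.0
    for i in range(n):
        e = em_u[inv[i]]
        if i == 0 or brk[i]:
            for s in range(S):
                alpha[s] = uni * e[s]
        else:
            _kernel_inplace(alpha, buf, n_genomes, a, b)
            for s in range(S):
                alpha[s] *= e[s]
        tot = 0.0
        for s in range(S):
            tot += alpha[s]
        ll += np.log(tot)
        if tot > 0.0:
            r = 1.0 / tot
            for s in range(S):
                alpha[s] *= r
        for s in range(S):
            alphas[i, s] = alpha[s]
    gamma = np.empty((n, S))
    beta = np.ones(S)
    for i in range(n - 1, -1, -1):
        tot = 0.0
        for s in range(S):
            g = alphas[i, s] * beta[s]
            gamma[i, s] = g
            tot += g
        if tot > 0.0:
            r = 1.0 / tot
            for s in range(S):
                gamma[i, s] *= r
        if i > 0:
            if brk[i]:
                for s in range(S):
                    beta[s] = 1.0
            else:
                e = em_u[inv[i]]
                for s in range(S):
                    beta[s] *= e[s]
                _kernel_inplace(beta, buf, n_genomes, a, b)
                tot = 0.0
                for s in range(S):
                    tot += beta[s]
                if tot > 0.0:
                    r = S / tot
                    for s in range(S):
                        beta[s] *= r
    return ll, gamma
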