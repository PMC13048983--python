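"""Numba kernels for the sequential inner loops.

The forward filter and backward sampler are inherently sequential in the bin
index, so they are compiled with numba rather than vectorized.  All kernels
are deterministic: random draws consume pre-generated uniforms so that
reproducibility is controlled entirely by the caller's numpy Generator.

Kernels return 0 on success or a positive 1-based bin index where a numerical
failure (all-zero weight row) occurred; callers turn that into an exception.
"""

import numpy as np
from numba import njit

_NEG_HUGE = -1.0e300


@njit(cache=True)
def forward_filter_kernel(x, mu, lam, A, pi, f, log_norm):
    """Normalized forward recursion.

    f[n, k] is the per-step-normalized forward weight; log_norm[n] the log of
    the step normalizer, so the unnormalized forward probability is
    f[n, k] * exp(sum(log_norm[: n + 1])).  Emission log-densities are
    max-shifted per step before exponentiation to avoid underflow.
    """
    N = x.shape[0]
    K = mu.shape[0]
    loge = np.empty(K)
    for n in range(N):
        emax = _NEG_HUGE
        for k in range(K):
            e = 0.5 * np.log(lam[k] / (2.0 * np.pi)) \
                - 0.5 * lam[k] * (x[n] - mu[k]) ** 2
            loge[k] = e
            if e > emax:
                emax = e
        tot = 0.0
        for k in range(K):
            if n == 0:
                pred = pi[k]
            else:
                pred = 0.0
                for ell in range(K):
                    pred += A[k, ell] * f[n - 1, ell]
            w = np.exp(loge[k] - emax) * pred
            f[n, k] = w
            tot += w
        if tot <= 0.0 or not np.isfinite(tot):
            return n + 1
        inv = 1.0 / tot
        for k in range(K):
            f[n, k] *= inv
        log_norm[n] = emax + np.log(tot)
    return 0


@njit(cache=True)
def backward_sample_kernel(f, A, u, labels):
    """Backward categorical sampling of the full hidden path.

    s_N ~ Categorical(f[N-1, :]); for n < N the weight of state k is
    f[n, k] * A[l, k] with l the already-sampled state at n + 1, normalized
    over k.  ``u`` holds one uniform per bin.
    """
    N, K = f.shape
    r = u[N - 1]
    c = 0.0
    lab = K - 1
    for k in range(K):
        c += f[N - 1, k]
        if r < c:
            lab = k
            break
    labels[N - 1] = lab
    for n in range(N - 2, -1, -1):
        ell = labels[n + 1]
        tot = 0.0
        for k in range(K):
            tot += f[n, k] * A[ell, k]
        if tot <= 0.0:
            return n + 1
        r = u[n] * tot
        c = 0.0
        lab = K - 1
        for k in range(K):
            c += f[n, k] * A[ell, k]
            if r < c:
                lab = k
                break
        labels[n] = lab
    return 0


@njit(cache=True)
def state_chain_kernel(A, pi, u, labels):
    """Simulate a Markov label chain: s_1 ~ pi, s_n | s_{n-1}=l ~ A[:, l]."""
    n_bins = u.shape[0]
    K = pi.shape[0]
    r = u[0]
    c = 0.0
    lab = K - 1
    for k in range(K):
        c += pi[k]
        if r < c:
            lab = k
            break
    labels[0] = lab
    for n in range(1, n_bins):
        ell = labels[n - 1]
        r = u[n]
        c = 0.0
        lab = K - 1
        for k in range(K):
            c += A[k, ell]
            if r < c:
                lab = k
                break
        labels[n] = lab
    return 0
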