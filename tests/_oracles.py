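"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with literal, loop-based code (no shared
implementation with the package) so they can serve as ground truth for the
relevance-propagation engine and the McNemar test.
"""

import numpy as np
from scipy.stats import binom


def eps_lrp_dense_oracle(layers_wb, x, target_index, eps):
    """Literal epsilon-rule propagation through a dense ReLU network.

    ``layers_wb`` is a list of (W, b); ReLU between layers, none after the
    last. Relevance starts at the target output's pre-softmax score. Returns
    the input relevance vector.
    """
    acts = [np.asarray(x, dtype=float)]
    for i, (W, b) in enumerate(layers_wb):
        z = acts[-1] @ W + b
        if i < len(layers_wb) - 1:
            z = np.maximum(z, 0.0)
        acts.append(z)
    R = np.zeros(len(acts[-1]))
    R[target_index] = acts[-1][target_index]
    for i in range(len(layers_wb) - 1, -1, -1):
        W, b = layers_wb[i]
        xin = acts[i]
        R_new = np.zeros(len(xin))
        for ii in range(len(xin)):
            total = 0.0
            for j in range(W.shape[1]):
                denom = b[j]
                for k in range(len(xin)):
                    denom += xin[k] * W[k, j]
                denom = denom + eps * (1.0 if denom >= 0 else -1.0)
                total += xin[ii] * W[ii, j] / denom * R[j]
            R_new[ii] = total
        R = R_new
    return R


def conv_as_dense(W, b, t_in, pad):
    """Unroll a same-padded 1D convolution into an explicit weight matrix.

    W is (filters, kernel, channels); returns (Wmat, bvec) mapping the
    flattened (t_in * channels) input to the flattened (t_in * filters)
    output, with the bias replicated at every output position.
    """
    f, k, c = W.shape
    Wmat = np.zeros((t_in * c, t_in * f))
    bvec = np.zeros(t_in * f)
    for tau in range(t_in):
        for fi in range(f):
            out = tau * f + fi
            bvec[out] = b[fi]
            for j in range(k):
                t = tau + j - pad
                if 0 <= t < t_in:
                    for ci in range(c):
                        Wmat[t * c + ci, out] = W[fi, j, ci]
    return Wmat, bvec


def gap_as_dense(t_in, channels):
    """Global average pooling as an explicit (t*c, c) uniform weight matrix."""
    Wmat = np.zeros((t_in * channels, channels))
    for t in range(t_in):
        for ci in range(channels):
            Wmat[t * channels + ci, ci] = 1.0 / t_in
    return Wmat, np.zeros(channels)


def mcnemar_exact_enumeration(b, c):
    """Two-sided exact McNemar p by enumerating the symmetric binomial null.

    Sums the probability of every discordant split at least as extreme
    (equal-or-smaller point probability) as the observed one.
    """
    n = b + c
    if n == 0:
        return 1.0
    observed = binom.pmf(min(b, c), n, 0.5)
    p = 0.0
    for k in range(n + 1):
        if binom.pmf(k, n, 0.5) <= observed * (1.0 + 1e-12):
            p += binom.pmf(k, n, 0.5)
    return min(1.0, float(p))
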