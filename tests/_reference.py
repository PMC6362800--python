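"""Independent reference likelihoods used as oracles.

These are deliberately written with a different algorithmic style than the
package (linear-space matrix products and direct formula evaluation, no
shared code) so agreement is evidence of correctness, not tautology.
"""

import numpy as np


def _year_detection_prob(hist, p):
    """P(history | station occupied) — Bernoulli product over surveyed
    intervals; NaN intervals contribute 1."""
    pr = 1.0
    for v in np.atleast_1d(hist):
        if np.isnan(v):
            continue
        pr *= p if v == 1 else (1.0 - p)
    return pr


def single_scale_dynamic_loglik(y, psi, eps, gam, p):
    """Dynamic single-scale occupancy likelihood (one station per unit,
    availability fixed at 1), via linear-space matrix products.

    y: (N, K, T) histories; psi: (N,); eps, gam: (N, T-1); p: (T,).
    """
    N, K, T = y.shape
    total = 0.0
    for i in range(N):
        v = np.array([1.0 - psi[i], psi[i]])
        for t in range(T):
            hist = y[i, :, t]
            clean = 1.0 if np.all((np.isnan(hist)) | (hist == 0)) else 0.0
            e = np.array([clean, _year_detection_prob(hist, p[t])])
            v = v * e
            if t < T - 1:
                M = np.array(
                    [
                        [1.0 - gam[i, t], gam[i, t]],
                        [eps[i, t], 1.0 - eps[i, t]],
                    ]
                )
                v = v @ M
        total += np.log(v.sum())
    return total


def static_multiscale_loglik(y, psi, theta, p):
    """Single-season multi-scale likelihood (psi–theta–p hierarchy).

    y: (N, R, K) histories; psi: (N,); theta: (N, R); p scalar.
    """
    N, R, K = y.shape
    total = 0.0
    for i in range(N):
        prod_occ = 1.0
        all_clean = True
        for j in range(R):
            hist = y[i, j, :]
            clean = np.all((np.isnan(hist)) | (hist == 0))
            all_clean &= bool(clean)
            prod_occ *= theta[i, j] * _year_detection_prob(hist, p) + (
                (1.0 - theta[i, j]) if clean else 0.0
            )
        lik = psi[i] * prod_occ + (1.0 - psi[i]) * (1.0 if all_clean else 0.0)
        total += np.log(lik)
    return total
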