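"""Independent reference Gibbs sampler for a standard latent class model on
categorical data.

Deliberately written with a different code path from the package's sampler
(per-row ``rng.dirichlet`` draws, cumulative-sum inverse-CDF categorical
sampling, explicit loops for the sufficient statistics) so it can serve as
an oracle for the degenerate reductions of the global/local model: with all
items pinned to the global process the joint model *is* this LCM on
(pi, theta); pinned to the local process with a single subgroup it is this
LCM on the local parameters.
"""

from __future__ import annotations

import numpy as np


def lcm_gibbs(y: np.ndarray, K: int, n_iter: int, burn_in: int, thin: int,
              seed: int, alpha_weights: float, alpha_theta: float = 1.0):
    """Collapsed-nothing, vanilla Gibbs for a K-class LCM.

    Parameters mirror the package's overfitted-mixture setup: symmetric
    Dirichlet(alpha_weights) on the class weights, Dirichlet(alpha_theta)
    on each item-level row.  ``y`` holds 1-based levels.

    Returns dict with retained draws: weights (T, K), theta (T, K, p, d),
    z (T, n).
    """
    rng = np.random.default_rng(seed)
    y0 = np.asarray(y) - 1
    n, p = y0.shape
    d = int(y0.max()) + 1

    weights = rng.dirichlet(np.full(K, alpha_weights))
    theta = np.stack([
        np.stack([rng.dirichlet(np.full(d, alpha_theta)) for _ in range(p)])
        for _ in range(K)
    ])
    z = rng.integers(0, K, size=n)

    T = (n_iter - burn_in) // thin
    out = {"weights": np.empty((T, K)), "theta": np.empty((T, K, p, d)),
           "z": np.empty((T, n), dtype=np.int64)}
    t = 0
    Jp = np.arange(p)
    for it in range(1, n_iter + 1):
        # class memberships via inverse-CDF on normalized posteriors
        logw = np.log(weights)[None, :] + np.log(
            np.maximum(theta[:, Jp, y0], 1e-300)).sum(axis=2).T  # (n, K)
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random(n)
        z = (u[:, None] > np.cumsum(w, axis=1)).sum(axis=1)

        counts = np.bincount(z, minlength=K)
        weights = rng.dirichlet(alpha_weights + counts)

        for k in range(K):
            yk = y0[z == k]
            for j in range(p):
                level_counts = np.bincount(yk[:, j], minlength=d)
                theta[k, j] = rng.dirichlet(alpha_theta + level_counts)

        if it > burn_in and (it - burn_in) % thin == 0:
            out["weights"][t] = weights
            out["theta"][t] = theta
            out["z"][t] = z
            t += 1
    return out
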