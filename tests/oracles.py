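"""Independent brute-force implementations used only as test oracles.

Deliberately written from the mathematical definitions, without reusing any
package internals: the diffusion map is built as the explicit dense
random-walk operator and solved with a general (non-symmetric) dense
eigendecomposition; the covariance and BH procedures are literal loops.
"""

import numpy as np
import scipy.linalg


def brute_force_diffusion_map(affinity, n_components, alpha=0.5, diffusion_time=0.0):
    """Dense diffusion-map embedding straight from the definition.

    Returns (components, eigenvalues) with eigenvalues descending and each
    component column unit-normalized before the diffusion-time scaling.
    Component signs are arbitrary (the caller compares up to sign).
    """
    a = np.asarray(affinity, dtype=float)
    p = a.shape[0]
    d = a.sum(axis=1)
    w = np.empty_like(a)
    for i in range(p):
        for j in range(p):
            w[i, j] = a[i, j] / (d[i] ** alpha * d[j] ** alpha)
    markov = w / w.sum(axis=1)[:, None]
    lam, vec = scipy.linalg.eig(markov)
    lam, vec = lam.real, vec.real
    order = np.argsort(-lam)
    lam, vec = lam[order], vec[:, order]
    assert abs(lam[0] - 1.0) < 1e-10, "stochastic operator must have eigenvalue 1"
    lam, vec = lam[1 : n_components + 1], vec[:, 1 : n_components + 1]
    vec = vec / np.linalg.norm(vec, axis=0)
    scale = lam / (1.0 - lam) if diffusion_time == 0 else lam**diffusion_time
    return vec * scale, lam


def brute_force_covariance(g, networks, length_scale, boost):
    """Entry-by-entry evaluation of the latent-distance covariance."""
    p = len(g)
    cov = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                cov[i, j] = 1.0 + boost
            else:
                cov[i, j] = np.exp(-abs(g[i] - g[j]) / length_scale)
                if networks[i] == networks[j]:
                    cov[i, j] += boost
    return cov


def brute_force_bh(p_values):
    """Step-up Benjamini–Hochberg by the textbook recipe."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def brute_force_pearson(x, y):
    """Pearson r from the covariance/SD definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
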