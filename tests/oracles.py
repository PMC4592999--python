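"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's forward-backward and least-squares
code paths: the HMM oracle enumerates every genotype path explicitly, and the
regression oracle solves the normal equations via the pseudoinverse.
"""

import itertools

import numpy as np

from crossalign.core_io import NA
from crossalign.genmap import inverse_map_r
from crossalign.genoprob import F2_PRIOR, f2_transition


def enumerate_posterior(obs, grid_positions, marker_flags, epsilon, map_function):
    """Posterior genotype probabilities by exhaustive path enumeration.

    obs: observed call codes per grid position (NA at pseudomarkers and missing
    markers); marker_flags: True where a position carries an observation slot.
    """
    n_pos = len(grid_positions)
    trans = [
        f2_transition(inverse_map_r(grid_positions[k + 1] - grid_positions[k], map_function))
        for k in range(n_pos - 1)
    ]

    def emit(k, state):
        if not marker_flags[k] or obs[k] == NA:
            return 1.0
        return 1.0 - epsilon if obs[k] == state else epsilon / 2.0

    post = np.zeros((n_pos, 3))
    for path in itertools.product(range(3), repeat=n_pos):
        p = F2_PRIOR[path[0]] * emit(0, path[0])
        for k in range(1, n_pos):
            p *= trans[k - 1][path[k - 1], path[k]] * emit(k, path[k])
        for k, s in enumerate(path):
            post[k, s] += p
    return post / post.sum(axis=1, keepdims=True)


def ols_lod(y, p, covariates=None, interactive=False):
    """LOD by explicit pseudoinverse projection (independent of lstsq)."""
    y = np.asarray(y, dtype=float)
    obs = np.isfinite(y)
    y = y[obs]
    p = np.asarray(p, dtype=float)[obs]
    n = y.size
    ones = np.ones((n, 1))
    geno = p[:, 1:3]
    if covariates is None:
        X0, X1 = ones, np.hstack([ones, geno])
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != obs.size:
            cov = cov.T
        cov = cov[obs]
        X0 = np.hstack([ones, cov])
        cols = [ones, geno, cov]
        if interactive:
            cols += [cov[:, [j]] * geno for j in range(cov.shape[1])]
        X1 = np.hstack(cols)

    def rss(X):
        yhat = X @ (np.linalg.pinv(X) @ y)
        return float(((y - yhat) ** 2).sum())

    return (n / 2.0) * np.log10(rss(X0) / rss(X1))
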