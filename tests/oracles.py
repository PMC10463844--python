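"""Independent oracles used by the test suite.

Each function recomputes a quantity by brute force (grid search, exhaustive
enumeration, per-base-pair counting, literal step-up recursion) without
touching the implementation paths it checks.
"""

import numpy as np
from scipy.special import betaln
from scipy.stats import multivariate_normal


def alpha_grid_oracle(betas, eps=1e-3, step=1e-3):
    """Symmetric-Beta MLE by exhaustive grid search on [0.01, 100]."""
    b = np.clip(np.asarray(betas, float), eps, 1 - eps)
    s = np.sum(np.log(b) + np.log1p(-b))
    grid = np.arange(0.01, 100 + step, step)
    ll = (grid - 1) * s - len(b) * betaln(grid, grid)
    return grid[np.argmax(ll)]


def viterbi_enumeration(model, X):
    """Most probable state path by scoring all 2^L binary paths."""
    L = len(X)
    logem = np.stack(
        [multivariate_normal(model.means[k], model.covars[k]).logpdf(X) for k in (0, 1)],
        axis=1,
    )
    paths = (np.arange(2**L)[:, None] >> np.arange(L)) & 1
    lp = np.log(model.startprob)[paths[:, 0]] + logem[0, paths[:, 0]]
    for t in range(1, L):
        lp += np.log(model.transmat)[paths[:, t - 1], paths[:, t]] + logem[t, paths[:, t]]
    return paths[np.argmax(lp)]


def bh_oracle(pvals):
    """Benjamini-Hochberg adjusted p-values by literal step-up recursion."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def bp_coverage(df, length):
    """Boolean per-base coverage of an interval frame on one chromosome."""
    cov = np.zeros(length, dtype=bool)
    for _, r in df.iterrows():
        cov[r["start"]: r["end"]] = True
    return cov
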