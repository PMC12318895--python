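"""Independent brute-force oracles used only by the tests.

Each oracle is a direct, quadratic-or-worse transcription of the definition
it checks, sharing no code with the package implementation.
"""

import itertools

import numpy as np


def nn_distances_bruteforce(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def empirical_g_bruteforce(points: np.ndarray, grid: np.ndarray) -> np.ndarray:
    nn = nn_distances_bruteforce(points)
    return np.array([(nn <= d).mean() for d in grid])


def min_cross_bruteforce(sources: np.ndarray, targets: np.ndarray) -> np.ndarray:
    s = np.asarray(sources, float)
    t = np.asarray(targets, float)
    d = np.sqrt(((s[:, None, :] - t[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1)


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact p by full enumeration of rank assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    mu = n1 * n2 / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    obs = abs(u_of(range(n1)) - mu)
    us = np.array([u_of(c) for c in itertools.combinations(range(n1 + n2), n1)])
    return float(np.mean(np.abs(us - mu) >= obs - 1e-9))


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided exact p by enumeration of all sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    ws = []
    for signs in itertools.product([False, True], repeat=n):
        s = np.array(signs)
        ws.append(min(ranks[s].sum(), ranks[~s].sum()))
    return float(np.mean(np.asarray(ws) <= w_obs + 1e-9))


def pearson_r_direct(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
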