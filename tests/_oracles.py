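"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: features are
recomputed from first-principles definitions with the ``statistics``
module and plain Python, the Friedman statistic from explicit ranking,
and the Wilcoxon null by full enumeration of sign assignments.
"""

import itertools
import math
import statistics

import numpy as np
from scipy import stats as sps


def brute_feature(x, name):
    """First-principles evaluation of one per-cycle statistic."""
    x = [float(v) for v in x]
    n = len(x)
    absx = [abs(v) for v in x]
    mean = sum(x) / n
    dev = [v - mean for v in x]
    m2 = sum(d * d for d in dev) / n
    if name == "mad":
        med = statistics.median(x)
        return statistics.median([abs(v - med) for v in x])
    if name == "kurtosis":
        if m2 == 0:
            return 0.0
        m4 = sum(d**4 for d in dev) / n
        return m4 / m2**2 - 3.0
    if name == "skewness":
        if m2 == 0:
            return 0.0
        m3 = sum(d**3 for d in dev) / n
        return m3 / m2**1.5
    if name == "rms":
        return math.sqrt(sum(v * v for v in x) / n)
    if name == "variance":
        return m2
    if name == "max_abs":
        return max(absx)
    if name == "min_abs":
        return min(absx)
    if name == "range":
        return max(x) - min(x)
    if name == "median_abs":
        return statistics.median(absx)
    if name == "ec":
        return sum(v * v for v in x) / n
    raise ValueError(name)


def brute_friedman_statistic(block):
    """From-scratch tie-corrected Friedman statistic via explicit ranking."""
    block = np.asarray(block, dtype=float)
    n, k = block.shape
    ranks = np.empty_like(block)
    for i, row in enumerate(block):
        order = np.argsort(row)
        r = np.empty(k)
        r[order] = np.arange(1, k + 1)
        for v in np.unique(row):  # average ranks over tied groups
            mask = row == v
            r[mask] = r[mask].mean()
        ranks[i] = r
    col = ranks.sum(axis=0)
    denom = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4
    if denom == 0:
        return 0.0
    return (k - 1) * ((col - n * (k + 1) / 2) ** 2).sum() / denom


def brute_wilcoxon_p(a, b):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))
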