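"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: plain Python
loops, literal formulas and exhaustive enumeration only.
"""

import itertools
import math

import numpy as np


def ordmag_bruteforce(sorted_counts, grid):
    """Literal re-evaluation of the OrdMag loss over a candidate grid.

    For each candidate c: m = 99th-percentile (linear interpolation) of the
    top-c counts; observed = #{counts strictly > m/10}; loss = (obs-c)^2/c.
    Returns (m_list, observed_list, losses, expected_cells).
    """
    counts = list(sorted_counts)
    m_list, obs_list, losses = [], [], []
    for c in grid:
        top = counts[:c]
        m = float(np.percentile(np.asarray(top, dtype=float), 99))
        observed = sum(1 for v in counts if v > m / 10.0)
        m_list.append(m)
        obs_list.append(observed)
        losses.append((observed - c) ** 2 / c)
    best_loss = min(losses)
    expected = next(c for c, loss in zip(grid, losses) if loss == best_loss)
    return m_list, obs_list, losses, expected


def multinomial_pmf(x, p):
    """Exact multinomial PMF via factorials (small totals only)."""
    n = sum(x)
    coeff = math.factorial(n)
    for xi in x:
        coeff //= math.factorial(xi)
    prob = float(coeff)
    for xi, pi in zip(x, p):
        prob *= pi**xi
    return prob


def enumerate_outcomes(total, n_genes):
    """All count vectors over n_genes summing to total."""
    if n_genes == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in enumerate_outcomes(total - first, n_genes - 1):
            yield (first, *rest)


def exact_pvalue(x_obs, profile):
    """P(loglik(Y) <= loglik(x_obs)) under Y ~ Multinomial(total, profile).

    Exhaustive enumeration; comparisons are done on exact PMFs (monotone in
    the log-likelihood), with a relative tolerance for ties.
    """
    total = sum(x_obs)
    p_obs = multinomial_pmf(x_obs, profile)
    acc = 0.0
    for outcome in enumerate_outcomes(total, len(profile)):
        p_out = multinomial_pmf(outcome, profile)
        if p_out <= p_obs * (1 + 1e-12):
            acc += p_out
    return acc


def bh_stepup(pvalues):
    """Literal BH step-up: min over j>=i of p_(j) * m / j, clipped to 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = min(running, 1.0)
    return adjusted


def pairwise_mean_distances(coords, labels):
    """Mean intra- vs inter-group Euclidean distance for a 2-group labelling."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    intra, inter = [], []
    for i, j in itertools.combinations(range(len(labels)), 2):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        (intra if labels[i] == labels[j] else inter).append(d)
    return float(np.mean(intra)), float(np.mean(inter))
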