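"""Independent brute-force oracle for the gaze segmentation score.

Enumerates every partition of a short series into contiguous segments
(each keeping at least ``min_segment_samples`` non-outlier samples)
crossed with every outlier subset of size <= ``max_outliers``, scores
each candidate with a direct, self-contained implementation of the
normative penalized log-likelihood, and returns the best. Used only to
validate the dynamic-programming solver on small instances; shares no
code with it.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import norm


def candidate_score(t, h, v, boundaries, outliers, params):
    """Score one candidate partition by direct evaluation.

    ``boundaries`` are segment start indices (first must be 0); OLS lines
    are fitted per segment per axis on non-outlier samples.
    """
    n = len(t)
    out = np.zeros(n, dtype=bool)
    out[list(outliers)] = True
    sigma = params.noise_sd
    dt = float(np.median(np.diff(t))) if n > 1 else 1.0 / 60.0
    q = max(params.outlier_rate * dt, 1e-12)
    score = 0.0
    ends = list(boundaries[1:]) + [n]
    for s, e in zip(boundaries, ends):
        use = ~out[s:e]
        n_in = int(use.sum())
        if n_in < params.min_segment_samples:
            return -np.inf
        for y in (h, v):
            coef = np.polyfit(t[s:e][use], y[s:e][use], 1)
            resid = y[s:e][use] - np.polyval(coef, t[s:e][use])
            score += float(np.sum(norm.logpdf(resid, scale=sigma)))
        score -= 2.0 * np.log(n_in)  # parameter cost, 2 per axis (BIC)
    n_out = int(out.sum())
    score += n_out * (np.log(q) + 2.0 * np.log(1.0 / (2.0 * params.outlier_range)))
    score += (n - n_out) * np.log1p(-q)
    pcs = np.clip(np.diff(t) / params.expected_segment_length, 1e-12, 0.5)
    cp = np.zeros(n - 1, dtype=bool)
    for b in boundaries[1:]:
        cp[b - 1] = True
    score += float(np.sum(np.where(cp, np.log(pcs), np.log1p(-pcs))))
    return score


def _partitions(n, min_size):
    """All boundary lists [0, b1, b2, ...] with parts >= min_size."""
    results = []

    def compose(start, bounds):
        remaining = n - start
        if remaining == 0:
            results.append(list(bounds))
            return
        for size in range(min_size, remaining + 1):
            if remaining - size != 0 and remaining - size < min_size:
                continue
            compose(start + size, bounds + [start])

    compose(0, [])
    return results


def oracle_best(t, h, v, params, max_outliers=2):
    """Exhaustive optimum (score, boundaries, outliers) over all
    partitions x outlier subsets."""
    n = len(t)
    parts = _partitions(n, params.min_segment_samples)
    best = (-np.inf, None, None)
    for k in range(0, max_outliers + 1):
        for O in combinations(range(n), k):
            for bounds in parts:
                s = candidate_score(t, h, v, bounds, O, params)
                if s > best[0]:
                    best = (s, bounds, O)
    return best
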