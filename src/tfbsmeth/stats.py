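"""Small exact-statistics helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def fisher_exact_2x2(table) -> tuple[float | None, float]:
    """Two-tailed Fisher exact test by direct hypergeometric enumeration.

    Returns ``(odds_ratio, p)``.  The p-value sums the probabilities of all
    tables (with the observed margins) at most as likely as the observed
    one, the same convention R and scipy use.  An empty margin makes the
    table uninformative: odds ratio ``None``, p = 1.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"counts must be non-negative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        return None, 1.0
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return float(odds) if np.isfinite(odds) else np.inf, min(1.0, p)


def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test returning ``(t, p)``.

    Handles the degenerate zero-variance case explicitly: identical vectors
    give ``(0, 1)``; a constant non-zero difference gives ``(inf, 0)``
    (every resample would reproduce the shift exactly).
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    diff = x - y
    if len(diff) < 2:
        raise ValueError("paired t-test needs >= 2 pairs")
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        import logging
        logging.getLogger(__name__).warning(
            "paired_t_test: zero variance of differences with non-zero mean")
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)
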