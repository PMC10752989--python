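"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: the ICC oracle
does the two-way ANOVA decomposition by explicit Python summation, and the
Wilcoxon oracle enumerates all 2^n sign assignments.
"""

from itertools import product

import numpy as np
from scipy import stats


def icc_consistency_bruteforce(x):
    """Consistency ICC via explicit two-way ANOVA sums (no vectorized tricks)."""
    x = [[float(v) for v in row] for row in x]
    n = len(x)
    k = len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (x[i][j] - row_means[i] - col_means[j] + grand) ** 2
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


def wilcoxon_exact_enumeration(a, b):
    """Two-sided exact Wilcoxon p by enumerating all 2^n sign assignments.

    Uses midranks for tied |differences| and drops zero differences, the
    same conventions the implementation pins, but computes the null
    distribution by literal enumeration.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [sum(r for r, s in zip(ranks, signs) if s) for signs in product([False, True], repeat=n)]
    w_all = np.asarray(w_all)
    n_le = np.sum(w_all <= w_obs + 1e-9)
    n_ge = np.sum(w_all >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(n_le, n_ge) / 2.0**n)


def pearson_direct_summation(x, y):
    """Pearson r by direct summation of the defining formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx**0.5 * vy**0.5)
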