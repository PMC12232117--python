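"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's own algorithms: the bout oracle
checks every contiguous lick range for cluster-validity instead of
splitting on gaps, and the RM-ANOVA oracle works from raw sums of squares.
"""

from __future__ import annotations

import numpy as np


def bout_oracle(times: np.ndarray, min_licks: int = 3, gap_s: float = 10.0):
    """All maximal contiguous ranges that form valid clusters.

    A range [i, j] is a maximal cluster iff every internal inter-lick
    interval is < gap_s and the gaps to the licks just outside (when they
    exist) are >= gap_s.  Quadratic scan over all ranges.
    """
    t = np.asarray(times, dtype=float)
    n = t.size
    out = []
    for i in range(n):
        for j in range(i, n):
            internal_ok = all(t[k + 1] - t[k] < gap_s for k in range(i, j))
            left_ok = i == 0 or t[i] - t[i - 1] >= gap_s
            right_ok = j == n - 1 or t[j + 1] - t[j] >= gap_s
            if internal_ok and left_ok and right_ok and (j - i + 1) >= min_licks:
                out.append((float(t[i]), float(t[j]), j - i + 1))
    return out


def rm_anova_oneway_oracle(data: np.ndarray):
    """One-way within-subjects F from raw sums of squares (n subjects x k)."""
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    return F, df1, df2


def gg_epsilon_oracle(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = data.shape[1]
    S = np.cov(data, rowvar=False, ddof=1)
    # double-center
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc * Sc)
    return float(num / den)
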