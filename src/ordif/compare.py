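"""Group comparison of total scores with and without uniform-DIF items.

The person-level "total score" is the mean of the remaining item
responses, so it stays on the item 1..m scale and is comparable before and
after removing flagged items.  Both the pooled-variance independent t-test
and the Mann-Whitney U-test are computed; the corrected comparison drops
the items carrying a uniform-DIF flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "person_scores",
    "t_test_independent",
    "mann_whitney_u",
    "compare_with_without_dif",
]

EXACT_LIMIT = 400  # use the exact U distribution when n_x * n_y <= this


def person_scores(data, exclude_items=()) -> np.ndarray:
    """Per-person mean response over the non-excluded items (1..m scale).

    Missing responses are ignored person-wise (mean over observed items).
    """
    if isinstance(data, pd.DataFrame):
        df = data
    else:
        df = data.responses
    exclude = set(exclude_items)
    keep = [c for c in df.columns if str(c) not in exclude]
    if not keep:
        raise ValueError("all items excluded; no score to compute")
    return df[keep].mean(axis=1, skipna=True).to_numpy()


def t_test_independent(x, y) -> tuple[float, float]:
    """Two-sided pooled-variance independent-samples t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
        len(x) + len(y) - 2
    )
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def _exact_u_pvalue(ranks2, nx, u_obs):
    """Exact two-sided p of the rank-sum via subset-sum dynamic programming.

    ``ranks2`` are pooled midranks doubled to integers.  The DP counts, for
    every attainable rank-sum, the number of size-``nx`` subsets of the
    pooled sample attaining it — the full permutation distribution, ties
    included (equivalent to exhaustive enumeration of labelings).
    """
    N = len(ranks2)
    smax = int(np.sort(ranks2)[-nx:].sum())
    # counts[k, s] = number of subsets of size k with doubled rank-sum s
    counts = np.zeros((nx + 1, smax + 1))
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        prev = counts.copy()  # 0/1 semantics: each person enters a subset once
        counts[1 : nx + 1, r:] = prev[1 : nx + 1, r:] + prev[0:nx, : smax + 1 - r]
    total = counts[nx]
    norm = total.sum()
    # doubled U = doubled rank-sum - nx(nx+1)
    u_all = (np.arange(smax + 1) - nx * (nx + 1)) / 2.0
    p_le = total[u_all <= u_obs + 1e-9].sum() / norm
    p_ge = total[u_all >= u_obs - 1e-9].sum() / norm
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test; U counts pairs with x above y.

    For ``n_x * n_y <= 400`` the p-value comes from the exact permutation
    distribution of the rank-sum (dynamic programming over all labelings,
    correct under ties); larger samples use the normal approximation with
    tie and continuity corrections.  Conventions: ``U = R_x - n_x(n_x+1)/2``
    with midranks, so a sample entirely below the other gives ``U = 0``;
    the two-sided exact p is twice the smaller point-inclusive tail,
    capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if nx * ny <= EXACT_LIMIT:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _exact_u_pvalue(ranks2, nx, u)
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
    return u, p


def compare_with_without_dif(data, report, config=None) -> pd.DataFrame:
    """Group comparison table, uncorrected and corrected for uniform DIF.

    One row per group level per correction state, with mean, SD, both
    p-values and the list of excluded items.  With no uniform-DIF flags the
    corrected rows duplicate the uncorrected ones.
    """
    g, levels = data.group_codes()
    excluded = list(report.uniform_flagged_items()) if report is not None else []
    rows = []
    for corrected, exclude in (("total", []), ("corrected", excluded)):
        scores = person_scores(data.responses, exclude)
        x, y = scores[g == 0], scores[g == 1]
        t, p_t = t_test_independent(x, y)
        _, p_u = mann_whitney_u(x, y)
        for code, level in enumerate(levels):
            s = scores[g == code]
            rows.append(
                {
                    "score": corrected,
                    "group": level,
                    "mean": s.mean(),
                    "sd": s.std(ddof=1),
                    "p_t_test": p_t,
                    "p_mann_whitney": p_u,
                    "excluded_items": ";".join(exclude),
                }
            )
    return pd.DataFrame(rows)
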