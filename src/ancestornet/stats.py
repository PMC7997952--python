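"""Paired divergence comparisons and verticality distribution tests.

The divergence analysis yields, for every taxonomic group, a vector of
per-tree representative root-to-tip distances over a shared tree set.
Group pairs are compared with a one-sided Wilcoxon signed-rank test
(H1: the first group sits closer to the root), across all pairs with a
Bonferroni correction. Verticality distributions are compared with the
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class DivergenceVector:
    group: str
    values: pd.Series  # indexed by tree_id


class UndefinedTestError(ValueError):
    """All paired differences are zero: the test is undefined."""


def wilcoxon_one_sided(
    d_a: Sequence[float], d_b: Sequence[float], exact_max_n: int = 12
) -> float:
    """One-sided Wilcoxon signed-rank p-value for H1: D_a < D_b.

    Zero differences are dropped (Wilcoxon's convention). Absolute
    differences are ranked with midranks for ties. With at most
    ``exact_max_n`` effective pairs the null distribution is enumerated
    exactly over all sign assignments (which remains valid under ties);
    otherwise the normal approximation with tie correction and
    continuity correction is used. Small p-values support D_a < D_b.
    """
    a = np.asarray(d_a, dtype=float)
    b = np.asarray(d_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_minus = float(ranks[d < 0].sum())  # evidence for D_a < D_b

    if n <= exact_max_n:
        # exact: P(W- >= observed) over all 2^n equiprobable sign
        # assignments, counted by dynamic programming over doubled
        # midranks (integers even under ties)
        r2 = np.rint(2.0 * ranks).astype(int)
        total = r2.sum()
        counts = np.zeros(total + 1, dtype=np.uint64)
        counts[0] = 1
        for r in r2:
            counts[r:] += counts[: counts.size - r].copy()
        obs = int(math.ceil(round(2.0 * w_minus, 6)))
        ge = int(counts[obs:].sum())
        return ge / float(2**n)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        raise UndefinedTestError("zero variance (complete ties)")
    z = (w_minus - mean - 0.5) / math.sqrt(var)  # continuity corrected
    return float(sps.norm.sf(z))


def pairwise_test_matrix(
    vectors: Mapping[str, DivergenceVector],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """All-pairs one-sided Wilcoxon matrix with Bonferroni correction.

    Cell (a, b) holds the p-value for H1: group a is less divergent
    than group b, so the matrix is asymmetric. Pairs sharing no trees
    are marked missing (NaN) but still reported. Returns (p-value
    matrix, boolean significance matrix of Bonferroni-adjusted p <
    alpha, number of tested pairs).
    """
    groups = sorted(vectors)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    p = pd.DataFrame(np.nan, index=groups, columns=groups)
    n_pairs = 0
    for ga, gb in itertools.combinations(groups, 2):
        va, vb = vectors[ga].values, vectors[gb].values
        shared = va.index.intersection(vb.index)
        if len(shared) == 0:
            continue
        n_pairs += 1
        try:
            p.loc[ga, gb] = wilcoxon_one_sided(
                va[shared].to_numpy(), vb[shared].to_numpy()
            )
            p.loc[gb, ga] = wilcoxon_one_sided(
                vb[shared].to_numpy(), va[shared].to_numpy()
            )
        except UndefinedTestError:
            pass  # cells stay NaN; the pair still counts as tested
    multiplier = max(n_pairs, 1)
    significant = (p * multiplier) < alpha
    return p, significant, n_pairs


def ks_two_sample(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over the pooled sample of the absolute ECDF
    difference; the two-sided p-value uses the asymptotic Kolmogorov
    distribution with effective size n_x * n_y / (n_x + n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
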