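"""Independent oracles for the rank statistics: the direct rank-sum formula
and full enumeration of the permutation distribution at small n."""

import itertools

import numpy as np
from scipy import stats


def kw_by_rank_formula(groups):
    """H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), midranks, no tie correction.

    Valid as stated only for tie-free data.
    """
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    h = 0.0
    offset = 0
    for g in groups:
        r = ranks[offset: offset + len(g)].sum()
        h += r * r / len(g)
        offset += len(g)
    return 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)


def _h_statistic(pooled_ranks, sizes):
    n_total = len(pooled_ranks)
    h = 0.0
    offset = 0
    for n in sizes:
        r = pooled_ranks[offset: offset + n].sum()
        h += r * r / n
        offset += n
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    # tie correction on the pooled ranks
    _, counts = np.unique(pooled_ranks, return_counts=True)
    tie = np.sum(counts**3 - counts)
    denom = 1 - tie / (n_total**3 - n_total)
    return h / denom if denom > 0 else 0.0


def exact_kw_permutation_p(groups):
    """P(H >= H_obs) over all distinct assignments of the pooled values."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]
    ranks = stats.rankdata(pooled)
    h_obs = _h_statistic(ranks, sizes)

    n_total = len(pooled)
    indices = range(n_total)
    count = 0
    total = 0
    for first in itertools.combinations(indices, sizes[0]):
        rest = [i for i in indices if i not in first]
        for second in itertools.combinations(rest, sizes[1]):
            third = [i for i in rest if i not in second]
            perm = list(first) + list(second) + third
            h = _h_statistic(ranks[perm], sizes)
            count += h >= h_obs - 1e-12
            total += 1
    return count / total
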