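"""Independent brute-force re-implementations used as test oracles.

Deliberately naive: explicit loops, scipy.stats.spearmanr for the rank
correlation, dictionary-based depth-first search for connected components.
They share only the quantile rule (np.quantile, linear interpolation) with
the package implementation.
"""

import numpy as np
from scipy import stats


def brute_spearman_t(P, c, n):
    rho = np.array([stats.spearmanr(P[:, r], c).statistic for r in range(P.shape[1])])
    return rho, rho * np.sqrt(n - 2) / np.sqrt(1.0 - rho**2)


def _dfs_components(nodes, neighbours):
    nodes = set(nodes)
    comps = []
    while nodes:
        stack = [nodes.pop()]
        comp = set(stack)
        while stack:
            v = stack.pop()
            for w in neighbours.get(v, ()):
                if w in nodes:
                    nodes.remove(w)
                    comp.add(w)
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def brute_cluster_permutation(P, c, edge_list, permutations, alpha_tail=0.025):
    """Enumerating re-implementation of the cluster permutation test.

    Returns a list of dicts: sign, members (indices), sum_t, p.
    """
    n, n_regions = P.shape
    neighbours = {}
    for a, b in edge_list:
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)

    _, t_obs = brute_spearman_t(P, c, n)
    t_perm = np.array(
        [brute_spearman_t(P, c[perm], n)[1] for perm in permutations]
    )
    upper = np.quantile(t_perm, 1.0 - alpha_tail, axis=0)
    lower = np.quantile(t_perm, alpha_tail, axis=0)

    def clusters_of(t_vec):
        pos = _dfs_components(
            [r for r in range(n_regions) if t_vec[r] > upper[r]], neighbours
        )
        neg = _dfs_components(
            [r for r in range(n_regions) if t_vec[r] < lower[r]], neighbours
        )
        return pos, neg

    null_pos, null_neg = [], []
    for row in t_perm:
        pos, neg = clusters_of(row)
        null_pos.append(max((sum(row[r] for r in cl) for cl in pos), default=0.0))
        null_neg.append(min((sum(row[r] for r in cl) for cl in neg), default=0.0))
    null_pos, null_neg = np.array(null_pos), np.array(null_neg)

    out = []
    pos, neg = clusters_of(t_obs)
    for cl in pos:
        s = float(sum(t_obs[r] for r in cl))
        out.append(
            {"sign": "positive", "members": cl, "sum_t": s,
             "p": float(np.mean(null_pos >= s))}
        )
    for cl in neg:
        s = float(sum(t_obs[r] for r in cl))
        out.append(
            {"sign": "negative", "members": cl, "sum_t": s,
             "p": float(np.mean(null_neg <= s))}
        )
    return out
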