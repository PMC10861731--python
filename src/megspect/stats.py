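"""Nonparametric statistics linking oscillatory parameters to covariates.

Three layers, mirroring how the analysis escalates from global to regional
questions:

1. **Global screening** — Spearman rank correlations with percentile
   bootstrap confidence intervals (default 5,000 resamples); a pair is
   called significant when the 95% interval excludes zero.

2. **Regional inference** — a cluster-based permutation test controlling
   the family-wise error rate over the region space.  Per region the rank
   correlation is converted to ``T = rho * sqrt(N-2) / sqrt(1-rho^2)``;
   the covariate is shuffled across subjects (default 5,000 permutations)
   to build each region's empirical null, regions beyond the 0.025 tails
   are grouped into positive/negative clusters by spatial adjacency, and
   each observed cluster's summed T is referred to the permutation
   distribution of the maximal (positive tail) or minimal (negative tail)
   cluster sum ("maxsum").  The cluster-forming threshold is *empirical*,
   taken from each region's own permutation distribution rather than a
   parametric t quantile, and the same permutation draws serve both the
   thresholds and the maxsum null.

3. **Confound screening** — a one-component partial least squares (PLS)
   regression of each regional parameter on two standardized predictors
   (the covariate of interest and age).  With one component the variable
   importance in projection reduces to ``VIP_j = sqrt(2) |w_j| / ||w||``
   with ``w ∝ X'y``, so ``VIP_1^2 + VIP_2^2 = 2`` identically.  Regions
   where age carries the larger VIP are pruned from significant clusters
   post hoc (cluster p-values are not recomputed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from ._exceptions import (
    ConstantInputError,
    DegeneratePredictorError,
    SchemaError,
)

__all__ = [
    "RegionAdjacency",
    "BootstrapCorrelation",
    "ClusterResult",
    "VIPComparison",
    "spearman_rho",
    "t_from_rho",
    "bootstrap_spearman",
    "cluster_permutation_correlation",
    "pls1_vip",
    "confound_screen",
]


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------


@dataclass
class RegionAdjacency:
    """Undirected region adjacency graph (no self-loops), label-addressed."""

    labels: list[str]
    edges: np.ndarray  # (E, 2) integer indices into labels

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if len(set(self.labels)) != len(self.labels):
            raise SchemaError("region labels must be unique")
        n = len(self.labels)
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise SchemaError("edge indices out of range")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise SchemaError("self-loops are not allowed")
        # canonical undirected form: sorted pairs, deduplicated
        edges = np.sort(edges, axis=1)
        self.edges = np.unique(edges, axis=0) if edges.size else edges

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def matrix(self) -> csr_matrix:
        n = self.n_regions
        if self.edges.size == 0:
            return csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(i))
        return csr_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n)
        )

    def degrees(self) -> np.ndarray:
        return np.asarray(self.matrix().sum(axis=1)).ravel().astype(int)

    def relabeled(self, order: np.ndarray) -> "RegionAdjacency":
        """Adjacency after permuting regions by ``order`` (new_pos -> old_pos)."""
        order = np.asarray(order, dtype=int)
        inverse = np.empty_like(order)
        inverse[order] = np.arange(order.size)
        return RegionAdjacency(
            labels=[self.labels[k] for k in order], edges=inverse[self.edges]
        )

    @classmethod
    def from_edge_labels(
        cls, labels: list[str], label_pairs: list[tuple[str, str]]
    ) -> "RegionAdjacency":
        index = {lab: k for k, lab in enumerate(labels)}
        try:
            edges = np.array([[index[a], index[b]] for a, b in label_pairs], dtype=int)
        except KeyError as err:
            raise SchemaError(f"edge references unknown region {err.args[0]!r}") from err
        return cls(labels=labels, edges=edges.reshape(-1, 2))


# ---------------------------------------------------------------------------
# rank correlation primitives
# ---------------------------------------------------------------------------


def _drop_missing(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise SchemaError("x and y must be paired (equal length)")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _standardized_ranks(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """Average ranks, centered and scaled to unit population SD along ``axis``."""
    r = rankdata(a, axis=axis)
    r = r - r.mean(axis=axis, keepdims=True)
    sd = r.std(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = r / sd
    z[np.broadcast_to(sd == 0, z.shape)] = np.nan
    return z


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rho: Pearson correlation of average-ranked values.

    Missing pairs are dropped listwise; ties receive average ranks.
    """
    x, y = _drop_missing(x, y)
    if x.size < 3:
        raise SchemaError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("rank correlation undefined for a constant vector")
    zx = _standardized_ranks(x)
    zy = _standardized_ranks(y)
    return float(np.clip(np.mean(zx * zy), -1.0, 1.0))


def t_from_rho(rho: np.ndarray | float, n: int) -> np.ndarray | float:
    """``T = rho * sqrt(N-2) / sqrt(1 - rho^2)`` — the t statistic of rho.

    At ``|rho| = 1`` the statistic diverges; a signed infinity is returned
    with a warning rather than raising, so vectorized callers survive
    degenerate regions.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if n < 3:
        raise SchemaError("need N >= 3 observations")
    saturated = np.abs(rho_arr) >= 1.0
    if np.any(saturated):
        warnings.warn("|rho| = 1: T statistic is infinite", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.atleast_1d(rho_arr * np.sqrt(n - 2) / np.sqrt(1.0 - rho_arr**2))
    if np.any(saturated):
        sat = np.atleast_1d(saturated)
        t[sat] = np.sign(np.atleast_1d(rho_arr)[sat]) * np.inf
    return float(t[0]) if rho_arr.ndim == 0 else t


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapCorrelation:
    """Percentile-bootstrap summary of a Spearman correlation."""

    rho_plugin: float  # rho on the original sample
    rho_mean: float  # mean rho across bootstrap iterations (as reported)
    ci_low: float
    ci_high: float
    significant: bool  # 95% CI excludes zero
    n: int
    n_boot: int
    seed: int | None


def bootstrap_spearman(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 5000,
    seed: int | None = None,
    ci: float = 0.95,
) -> BootstrapCorrelation:
    """Bootstrap the Spearman correlation of paired observations.

    Subject pairs are resampled with replacement ``n_boot`` times; the CI
    is the percentile interval of the resampled rho values. Degenerate
    resamples (a constant vector, possible with heavily tied data) are
    redrawn. Deterministic given ``seed``.
    """
    x, y = _drop_missing(x, y)
    n = x.size
    if n < 5:
        raise SchemaError("need at least 5 complete pairs to bootstrap")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("rank correlation undefined for a constant vector")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    for _ in range(100):
        xb, yb = x[idx], y[idx]
        bad = (np.ptp(xb, axis=1) == 0) | (np.ptp(yb, axis=1) == 0)
        if not bad.any():
            break
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    else:  # pragma: no cover - essentially impossible with non-constant data
        raise ConstantInputError("could not draw non-degenerate bootstrap resamples")
    zx = _standardized_ranks(xb, axis=1)
    zy = _standardized_ranks(yb, axis=1)
    rhos = np.clip(np.mean(zx * zy, axis=1), -1.0, 1.0)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(rhos, [alpha, 1.0 - alpha])
    return BootstrapCorrelation(
        rho_plugin=spearman_rho(x, y),
        rho_mean=float(rhos.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0.0 or hi < 0.0),
        n=n,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """One signed cluster of adjacent regions and its permutation p-value."""

    sign: str  # "positive" | "negative"
    members: list[str]
    member_indices: np.ndarray
    member_rho: np.ndarray
    member_t: np.ndarray
    sum_t: float
    mean_t: float
    mean_rho: float
    p_value: float
    n_perm: int
    alpha_tail: float
    n_subjects: int
    n_excluded: int = 0  # filled by the confound screen


def _component_indices(mask: np.ndarray, adj_csr: csr_matrix) -> list[np.ndarray]:
    """Connected components of the subgraph induced by ``mask`` (True nodes)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    if idx.size == 1:
        return [idx]
    sub = adj_csr[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    return [idx[labels == k] for k in range(n_comp)]


def _tail_extreme_sums(
    t_row: np.ndarray,
    upper: np.ndarray,
    lower: np.ndarray,
    adj_csr: csr_matrix,
) -> tuple[float, float]:
    """(max positive cluster sum, min negative cluster sum); 0 when no cluster."""
    pos = 0.0
    comps = _component_indices(t_row > upper, adj_csr)
    if comps:
        pos = max(float(t_row[c].sum()) for c in comps)
    neg = 0.0
    comps = _component_indices(t_row < lower, adj_csr)
    if comps:
        neg = min(float(t_row[c].sum()) for c in comps)
    return pos, neg


def _empirical_p(null: np.ndarray, observed: float, sign: str) -> float:
    """Fraction of null values at least as extreme as ``observed``.

    ``>=`` / ``<=`` convention including ties; the observed statistic is
    not added to the null sample.
    """
    if sign == "positive":
        return float(np.mean(null >= observed))
    return float(np.mean(null <= observed))


def cluster_permutation_correlation(
    P: np.ndarray | pd.DataFrame,
    c: np.ndarray | pd.Series,
    adjacency: RegionAdjacency,
    n_perm: int = 5000,
    alpha_tail: float = 0.025,
    seed: int | None = None,
    permutations: np.ndarray | None = None,
) -> list[ClusterResult]:
    """Cluster-based permutation test of region-wise rank correlations.

    Parameters
    ----------
    P
        Subjects x regions parameter matrix. A DataFrame is aligned to
        ``adjacency.labels`` by column name; a bare array must already be
        in adjacency order.
    c
        Covariate over subjects. Subjects with a missing covariate (or any
        missing regional value) are dropped listwise.
    permutations
        Optional explicit ``(n_perm, N)`` array of subject-index
        permutations, overriding the seeded shuffle — used for exhaustive
        or externally fixed permutation schemes.

    Returns
    -------
    list of ClusterResult, sorted by p-value then |sum T|.
    """
    labels = adjacency.labels
    if isinstance(P, pd.DataFrame):
        missing = [lab for lab in labels if lab not in P.columns]
        if missing:
            raise SchemaError(f"parameter matrix lacks regions {missing[:5]}...")
        P = P.loc[:, labels].to_numpy(dtype=float)
    else:
        P = np.asarray(P, dtype=float)
        if P.shape[1] != len(labels):
            raise SchemaError(
                f"parameter matrix has {P.shape[1]} regions; adjacency has {len(labels)}"
            )
    c = np.asarray(c, dtype=float).ravel()
    if c.size != P.shape[0]:
        raise SchemaError("covariate length must equal the number of subjects")

    keep = np.isfinite(c) & np.all(np.isfinite(P), axis=1)
    P, c = P[keep], c[keep]
    n = c.size
    if n < 10:
        raise SchemaError("cluster permutation test needs >= 10 complete subjects")
    if np.ptp(c) == 0:
        raise ConstantInputError("covariate is constant")

    zP = _standardized_ranks(P, axis=0)  # (n, R); NaN column => constant region
    if np.any(~np.isfinite(zP)):
        raise ConstantInputError("a regional parameter is constant across subjects")
    zc = _standardized_ranks(c)

    rho_obs = np.clip(zc @ zP / n, -1.0, 1.0)
    t_obs = t_from_rho(rho_obs, n)

    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.array([rng.permutation(n) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations, dtype=int)
        if permutations.ndim != 2 or permutations.shape[1] != n:
            raise SchemaError("permutations must be (n_perm, N) subject indices")
        n_perm = permutations.shape[0]

    zc_perm = zc[permutations]  # (n_perm, n)
    rho_perm = np.clip(zc_perm @ zP / n, -1.0, 1.0)
    t_perm = t_from_rho(rho_perm, n)

    upper = np.quantile(t_perm, 1.0 - alpha_tail, axis=0)
    lower = np.quantile(t_perm, alpha_tail, axis=0)

    adj_csr = adjacency.matrix()
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    for i in range(n_perm):
        null_pos[i], null_neg[i] = _tail_extreme_sums(t_perm[i], upper, lower, adj_csr)

    results: list[ClusterResult] = []
    for sign, comps in (
        ("positive", _component_indices(t_obs > upper, adj_csr)),
        ("negative", _component_indices(t_obs < lower, adj_csr)),
    ):
        null = null_pos if sign == "positive" else null_neg
        for comp in comps:
            s = float(t_obs[comp].sum())
            results.append(
                ClusterResult(
                    sign=sign,
                    members=[labels[k] for k in comp],
                    member_indices=comp,
                    member_rho=rho_obs[comp],
                    member_t=t_obs[comp],
                    sum_t=s,
                    mean_t=float(t_obs[comp].mean()),
                    mean_rho=float(rho_obs[comp].mean()),
                    p_value=_empirical_p(null, s, sign),
                    n_perm=n_perm,
                    alpha_tail=alpha_tail,
                    n_subjects=n,
                )
            )
    results.sort(key=lambda r: (r.p_value, -abs(r.sum_t)))
    return results


# ---------------------------------------------------------------------------
# PLS / VIP confound screen
# ---------------------------------------------------------------------------


@dataclass
class VIPComparison:
    """VIP scores of (covariate of interest, age) for one regional response."""

    vip_variable: float
    vip_age: float
    exclude: bool  # age dominates: vip_age > vip_variable
    region: str | None = None


def pls1_vip(y: np.ndarray, X: np.ndarray, region: str | None = None) -> VIPComparison:
    """One-component PLS of ``y`` on two predictors; VIP per predictor.

    Predictors and response are centered and unit-scaled; the single PLS
    weight vector is ``w ∝ X'y`` (oriented so the component covaries
    positively with y — VIP is sign-invariant regardless), giving
    ``VIP_j = sqrt(2) |w_j| / ||w||``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != 2:
        raise SchemaError("X must be (N, 2): [variable, age]")
    if X.shape[0] != y.size:
        raise SchemaError("predictors and response must have equal length")
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    if y.size < 5:
        raise SchemaError("need at least 5 complete cases")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise DegeneratePredictorError("a predictor is constant")
    if np.ptp(y) == 0:
        raise DegeneratePredictorError("response is constant")
    Xs = (X - X.mean(axis=0)) / sd
    ys = (y - y.mean()) / y.std()
    w = Xs.T @ ys
    norm = np.linalg.norm(w)
    if norm == 0:
        raise DegeneratePredictorError("response is orthogonal to both predictors")
    vip = np.sqrt(2.0) * np.abs(w) / norm
    return VIPComparison(
        vip_variable=float(vip[0]),
        vip_age=float(vip[1]),
        exclude=bool(vip[1] > vip[0]),
        region=region,
    )


def confound_screen(
    clusters: list[ClusterResult],
    vip: dict[str, VIPComparison],
) -> list[ClusterResult]:
    """Prune cluster members whose VIP comparison flags age dominance.

    Mean rho / mean T / sum T are recomputed over the surviving members;
    clusters left empty are dropped.  The screen is post hoc: p-values are
    carried over unchanged, not recomputed.
    """
    screened: list[ClusterResult] = []
    for cl in clusters:
        try:
            keep = np.array([not vip[m].exclude for m in cl.members], dtype=bool)
        except KeyError as err:
            raise SchemaError(
                f"no VIP comparison for cluster member {err.args[0]!r}"
            ) from err
        if not keep.any():
            continue
        members = [m for m, k in zip(cl.members, keep) if k]
        rho = cl.member_rho[keep]
        t = cl.member_t[keep]
        screened.append(
            ClusterResult(
                sign=cl.sign,
                members=members,
                member_indices=cl.member_indices[keep],
                member_rho=rho,
                member_t=t,
                sum_t=float(t.sum()),
                mean_t=float(t.mean()),
                mean_rho=float(rho.mean()),
                p_value=cl.p_value,
                n_perm=cl.n_perm,
                alpha_tail=cl.alpha_tail,
                n_subjects=cl.n_subjects,
                n_excluded=int((~keep).sum()) + cl.n_excluded,
            )
        )
    return screened
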