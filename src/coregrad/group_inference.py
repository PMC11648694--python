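"""PERMANOVA on distance matrices, k-means, and gap-statistic cluster selection.

PERMANOVA partitions the distance-based variance of a community distance
matrix by a covariate.  With G = -1/2 J D^2 J (Gower-centered squared
distances) and H the hat matrix of the centered design,

    pseudo-F = (tr(HGH)/m) / (tr((I-H)G(I-H))/(n-m-1)),   R^2 = tr(HGH)/tr(G)

with m the non-intercept design rank; significance comes from permuting the
covariate rows.  For a single categorical factor this is algebraically
identical to Anderson's sums-of-squares formulation
SS_T = sum_{i<j} d_ij^2 / n, SS_W = sum_g sum_{i<j in g} d_ij^2 / n_g.

The gap statistic compares log within-cluster dispersion on the data with its
expectation under a reference null (uniform over each feature's observed
range): Gap(k) = E*[log W_k] - log W_k, and the selected k is the smallest k
with Gap(k) >= Gap(k+1) - s_{k+1} (the one-standard-error rule).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from sklearn.cluster import KMeans

from coregrad._utils import as_rng, derive_seed


@dataclass(frozen=True)
class PermanovaResult:
    """PERMANOVA test result for one covariate."""

    covariate: str
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    kind: str  # "categorical" or "continuous"


def _model_ss_categorical(g: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    """tr(HG) for a one-factor design, via per-group quadratic forms.

    With G doubly centered, tr(HG) = sum_g (m_g' G m_g) / n_g over group
    indicator vectors m_g.
    """
    ss = 0.0
    for level in range(n_levels):
        m = codes == level
        n_g = m.sum()
        ss += g[np.ix_(m, m)].sum() / n_g
    return ss


def permanova(
    dm: skbio.DistanceMatrix,
    covariate,
    n_permutations: int = 999,
    seed: int | None = None,
    categorical: bool | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-covariate PERMANOVA with permutation p-value.

    `covariate` is a pandas Series (aligned to the matrix by sample id when
    the index matches, else by position) or an array.  Non-numeric values are
    treated as a categorical factor, numeric as one continuous column;
    override with `categorical`.  `exhaustive=True` enumerates all n!
    permutations (small n only) and reports p = #{F_perm >= F_obs} / n!.
    """
    ids = list(dm.ids)
    n = len(ids)
    if isinstance(covariate, pd.Series) and set(ids) <= set(covariate.index):
        values = covariate.loc[ids].to_numpy()
        name = str(covariate.name or "covariate")
    else:
        values = np.asarray(covariate)
        name = getattr(covariate, "name", None) or "covariate"
        if len(values) != n:
            raise ValueError("covariate length does not match the distance matrix")
    if categorical is None:
        categorical = not np.issubdtype(np.asarray(values).dtype, np.number)
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    d2 = np.asarray(dm.data, dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    g = (g + g.T) / 2.0
    ss_total = float(np.trace(g))

    if categorical:
        levels, codes = np.unique(np.asarray(values, dtype=str), return_inverse=True)
        n_levels = len(levels)
        if n_levels < 2:
            raise ValueError("categorical covariate must have >= 2 levels")
        m_rank = n_levels - 1

        def model_ss(perm: np.ndarray) -> float:
            return _model_ss_categorical(g, codes[perm], n_levels)

    else:
        x = np.asarray(values, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("continuous covariate is constant")
        m_rank = 1

        def model_ss(perm: np.ndarray) -> float:
            xp = x[perm]
            xc = xp - xp.mean()
            return float(xc @ g @ xc) / float(xc @ xc)

    if n - m_rank - 1 <= 0:
        raise ValueError("not enough residual degrees of freedom")

    identity = np.arange(n)
    ss_model = model_ss(identity)
    ss_resid = ss_total - ss_model

    def f_of(ssm: float) -> float:
        return (ssm / m_rank) / ((ss_total - ssm) / (n - m_rank - 1))

    f_obs = f_of(ss_model)

    if exhaustive:
        f_perms = [f_of(model_ss(np.asarray(p))) for p in itertools.permutations(range(n))]
        count = sum(fp >= f_obs - 1e-12 for fp in f_perms)
        p_value = count / len(f_perms)
        n_perm_done = len(f_perms)
    else:
        rng = as_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if f_of(model_ss(perm)) >= f_obs - 1e-12:
                count += 1
        p_value = (1 + count) / (1 + n_permutations)
        n_perm_done = n_permutations

    return PermanovaResult(
        covariate=name,
        r_squared=ss_model / ss_total if ss_total > 0 else 0.0,
        pseudo_f=f_obs,
        p_value=p_value,
        n_permutations=n_perm_done,
        n_samples=n,
        kind="categorical" if categorical else "continuous",
    )


def kmeans_cluster(
    points: np.ndarray, k: int, n_restarts: int = 10, seed: int | None = None
) -> tuple[np.ndarray, float]:
    """k-means (Lloyd, k-means++ seeding, best of `n_restarts`).

    Returns (labels, W) where W is the pooled within-cluster dispersion
    sum_r (1/(2 n_r)) sum_{i,i' in C_r} ||x_i - x_i'||^2, equal to the
    within-cluster sum of squared distances to centroids.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(points)
    return labels, float(km.inertia_)


@dataclass(frozen=True)
class GapResult:
    """Gap-statistic curve and the selected number of clusters.

    `table` has one row per k with columns k, log_w, e_log_w_star, gap, s_k;
    gap == e_log_w_star - log_w by construction.  `low_confidence` flags
    b == 1 runs, where the null spread cannot be estimated (s_k set to 0).
    """

    table: pd.DataFrame
    k_hat: int
    b: int
    low_confidence: bool = False


def gap_statistic(
    points: np.ndarray,
    k_max: int,
    b: int = 100,
    seed: int | None = None,
    n_restarts: int = 2,
) -> GapResult:
    """Tibshirani's gap statistic with k-means over k = 1..k_max.

    Reference datasets are drawn uniformly over each feature's observed range
    ("original" feature space, not PCA-rotated); features with zero range are
    constant under the null and contribute nothing to the reference spread
    (a warning is emitted).  k_hat is the smallest k satisfying the 1-SE rule
    Gap(k) >= Gap(k+1) - s_{k+1}, else k_max.
    """
    points = np.asarray(points, dtype=float)
    n, n_feat = points.shape
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be < n={n}")
    if b < 1:
        raise ValueError("b must be >= 1")
    lo, hi = points.min(axis=0), points.max(axis=0)
    if np.any(hi - lo == 0):
        warnings.warn(
            f"{int((hi - lo == 0).sum())} feature(s) have zero range; they are "
            "constant in the reference null"
        )
    ks = np.arange(1, k_max + 1)
    log_w = np.empty(len(ks))
    for i, k in enumerate(ks):
        _, w = kmeans_cluster(points, k, n_restarts, derive_seed(seed, "data", k))
        log_w[i] = np.log(w) if w > 0 else -np.inf
    rng = as_rng(derive_seed(seed, "reference"))
    log_w_star = np.empty((b, len(ks)))
    for rep in range(b):
        ref = rng.uniform(lo, hi, size=(n, n_feat))
        for i, k in enumerate(ks):
            _, w = kmeans_cluster(
                points=ref, k=k, n_restarts=n_restarts, seed=derive_seed(seed, "ref", rep, k)
            )
            log_w_star[rep, i] = np.log(w) if w > 0 else -np.inf
    e_star = log_w_star.mean(axis=0)
    gap = e_star - log_w
    low_confidence = b == 1
    if low_confidence:
        sd = np.zeros(len(ks))
    else:
        sd = log_w_star.std(axis=0, ddof=1)
    s_k = sd * np.sqrt(1 + 1 / b)
    k_hat = int(ks[-1])
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            k_hat = int(ks[i])
            break
    table = pd.DataFrame(
        {"k": ks, "log_w": log_w, "e_log_w_star": e_star, "gap": gap, "s_k": s_k}
    )
    return GapResult(table=table, k_hat=k_hat, b=b, low_confidence=low_confidence)
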