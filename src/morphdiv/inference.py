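"""Statistical comparison of family disparities and morphospace positions.

Three complementary procedures:

* Welch's two-tailed t test (Satterthwaite degrees of freedom) on the
  per-species distances to the family centroid — a parametric comparison of
  mean disparity between two families.
* A label-shuffling permutation test on the disparity difference: group
  labels are reassigned at random, preserving group sizes, and both group
  centroids and disparities are recomputed each time. Preserving sizes makes
  the null distribution account automatically for unequal numbers of species
  per family.
* Non-parametric MANOVA (PERMANOVA): Euclidean distance-based partitioning of
  the score matrix into between- and within-group sums of squares with a
  pseudo-F statistic, with significance from whole-row label permutations.

Permutation p-values use the small-sample correction
``p = (1 + #{extreme}) / (n_perm + 1)``, counting the observed arrangement as
one member of its own null distribution. With 999 permutations the smallest
attainable p is therefore 1/1000.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PermutationResult",
    "NpManovaResult",
    "welch_t",
    "permutation_disparity_test",
    "np_manova",
]


@dataclasses.dataclass
class PermutationResult:
    """Observed disparity difference against its label-shuffled null."""

    observed_difference: float
    null_differences: np.ndarray
    null_min: float
    null_max: float
    p_value: float
    n_perm: int
    seed: int | None


@dataclasses.dataclass
class NpManovaResult:
    """PERMANOVA pseudo-F partition of morphospace positions by group."""

    pseudo_F: float
    r_squared: float
    p_value: float
    df_between: int
    df_within: int
    n_perm: int
    seed: int | None


def welch_t(distances_a, distances_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test, two-tailed.

    Returns ``(t, df, p)`` with fractional Satterthwaite degrees of freedom.
    Requires at least 2 values per sample and nonzero variance in at least
    one sample.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("zero variance in both samples; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _group_disparities(X: np.ndarray, mask_a: np.ndarray) -> tuple[float, float]:
    """Mean distance to own centroid for the two label groups."""
    A = X[mask_a]
    B = X[~mask_a]
    da = np.linalg.norm(A - A.mean(axis=0), axis=1).mean()
    db = np.linalg.norm(B - B.mean(axis=0), axis=1).mean()
    return float(da), float(db)


def permutation_disparity_test(scores, family_labels, m: int | None = None,
                               n_perm: int = 1000, seed: int | None = None,
                               family_order: list[str] | None = None,
                               ) -> PermutationResult:
    """Label-shuffling permutation test on the disparity difference.

    The observed statistic is disparity(first family) - disparity(second
    family). Each permutation reassigns the family labels uniformly at
    random while preserving group sizes, recomputes both group centroids and
    disparities, and records the difference. The two-tailed p-value compares
    absolute differences.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(family_labels)
    present = list(dict.fromkeys(labels.tolist()))
    if family_order is None:
        family_order = present
    if len(family_order) != 2 or set(family_order) != set(present):
        raise ValueError(f"exactly two families required, got {present}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mask_a = labels == family_order[0]
    n_a = int(mask_a.sum())
    n = len(labels)
    if n_a < 2 or n - n_a < 2:
        raise ValueError("each family needs at least 2 species")
    if m is None:
        m = scores.shape[1]
    X = scores[:, :m]
    da, db = _group_disparities(X, mask_a)
    observed = da - db
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_mask = mask_a[rng.permutation(n)]
        pa, pb = _group_disparities(X, perm_mask)
        null[i] = pa - pb
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed) - 1e-15)) / (n_perm + 1.0)
    return PermutationResult(
        observed_difference=float(observed),
        null_differences=null,
        null_min=float(null.min()),
        null_max=float(null.max()),
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def _permanova_ss(D2: np.ndarray, labels: np.ndarray, groups) -> tuple[float, float]:
    """Total and within-group distance sums of squares from squared distances."""
    n = len(labels)
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def np_manova(scores, family_labels, m: int | None = None, n_perm: int = 999,
              seed: int | None = None) -> NpManovaResult:
    """Non-parametric MANOVA (PERMANOVA) on Euclidean morphospace scores.

    Partitions ``SS_total = sum_{i<j} d_ij^2 / N`` into within- and
    between-group components and forms the pseudo-F ratio
    ``(SS_between / (a - 1)) / (SS_within / (N - a))`` for ``a`` groups.
    Significance comes from whole-row permutations of the group labels.
    In the univariate two-group case pseudo-F equals the classical one-way
    ANOVA F.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(family_labels)
    groups = list(dict.fromkeys(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if np.count_nonzero(labels == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    if m is None:
        m = scores.shape[1]
    if m < 1:
        raise ValueError("m must be >= 1")
    X = scores[:, :m]
    n = len(labels)
    a = len(groups)
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    ss_total, ss_within = _permanova_ss(D2, labels, groups)
    if ss_total <= 0.0:
        raise ValueError("degenerate data: all observations identical")
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    f_obs = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, ss_w = _permanova_ss(D2, labels[perm], groups)
        ss_b = ss_total - ss_w
        f_star = (ss_b / df_b) / (ss_w / df_w) if ss_w > 0 else np.inf
        if f_star >= f_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return NpManovaResult(
        pseudo_F=float(f_obs),
        r_squared=float(ss_between / ss_total),
        p_value=float(p),
        df_between=df_b,
        df_within=df_w,
        n_perm=n_perm,
        seed=seed,
    )
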