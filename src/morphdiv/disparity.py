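"""Morphological diversity as mean Euclidean distance to the family centroid.

For a family of n species with scores on the first m morphospace axes, the
family centroid is the per-axis mean score and each species' contribution is
its Euclidean distance to that centroid::

    diversity = (1/n) * sum_species sqrt( sum_i (PCn_i - PCc_i)^2 )

i.e. the mean over species of per-species distances. The standard error is
the sample standard deviation of the distances divided by sqrt(n). Each
family uses its own centroid, never the global one, so the statistic measures
within-family dispersion in the shared morphospace.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["DisparityResult", "family_disparity", "disparity_table"]


@dataclasses.dataclass
class DisparityResult:
    """Per-family disparity: distances of member species to their centroid."""

    family: str
    n: int
    axes_used: int
    centroid: np.ndarray  # (m,)
    distances: np.ndarray  # (n,)
    mean: float
    se: float


def family_disparity(scores, members=None, m: int | None = None,
                     family: str = "") -> DisparityResult:
    """Mean Euclidean distance of member species to their family centroid.

    Parameters
    ----------
    scores : ndarray of shape (n_species, n_axes)
        PC scores (or any Euclidean coordinates) for all species.
    members : boolean mask or integer indices, optional
        Rows belonging to the family; all rows by default.
    m : int, optional
        Number of leading axes to use; all axes by default.
    family : str
        Label carried into the result.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if members is None:
        sub = scores
    else:
        sub = scores[np.asarray(members)]
    if len(sub) == 0:
        raise ValueError("empty family membership")
    if m is None:
        m = sub.shape[1]
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > sub.shape[1]:
        raise ValueError(f"m={m} exceeds available axes ({sub.shape[1]})")
    sub = sub[:, :m]
    centroid = sub.mean(axis=0)
    distances = np.linalg.norm(sub - centroid, axis=1)
    n = len(distances)
    se = float(distances.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return DisparityResult(
        family=family,
        n=n,
        axes_used=int(m),
        centroid=centroid,
        distances=distances,
        mean=float(distances.mean()),
        se=se,
    )


def disparity_table(scores, family_labels, m: int | None = None,
                    family_order: list[str] | None = None,
                    ) -> tuple[DisparityResult, DisparityResult, float]:
    """Disparity of two families plus their difference of means.

    Each family uses its own centroid. The difference is first-family mean
    minus second-family mean, the order taken from ``family_order`` (default:
    order of first appearance in ``family_labels``).
    """
    labels = np.asarray(family_labels)
    present = list(dict.fromkeys(labels.tolist()))
    if family_order is None:
        family_order = present
    if len(family_order) != 2 or set(family_order) != set(present):
        raise ValueError(
            f"exactly two families required; labels present: {present}, "
            f"order requested: {family_order}"
        )
    results = []
    for fam in family_order:
        mask = labels == fam
        if not mask.any():
            raise ValueError(f"family {fam!r} has zero members")
        results.append(family_disparity(scores, mask, m=m, family=fam))
    return results[0], results[1], results[0].mean - results[1].mean
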