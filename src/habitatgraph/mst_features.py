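"""Branch-length statistics of per-habitat minimum spanning trees.

Seven statistics of the MST edge-weight set W = {w_1, ..., w_n}:

* mean          f_mu        = (1/n) sum w_i
* median                      middle value (average of middle two for even n)
* sd            f_sigma     = [(1/n) sum (w_i - f_mu)^2]^(1/2)   (population)
* skewness                  = (1/(n f_sigma^3)) sum (w_i - f_mu)^3
* kurtosis                  = (1/(n f_sigma^4)) sum (w_i - f_mu)^4  (non-excess)
* ratio         f_r         = max(W) / min(W)
* disorder                  = f_sigma / f_mu

All moments use the population 1/n normalization, not sample-corrected; the
kurtosis is the raw (non-excess) fourth standardized moment, so large normal
samples approach 3. When f_sigma = 0 (all branch lengths equal) skewness and
kurtosis are defined as 0. With four habitats this yields 28 features per
subject.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientPointsError, UndefinedFeatureError
from .habitats import HABITAT_KEY, HabitatLabel, HabitatMasks
from .spatial_graph import SpanningTree, build_mst, grid_centroids

__all__ = [
    "MST_STAT_NAMES",
    "MST_FEATURE_NAMES",
    "branch_length_stats",
    "mst_feature_vector",
    "subject_mst_features",
]

MST_STAT_NAMES = ("mean", "median", "sd", "skewness", "kurtosis", "ratio", "disorder")

#: fixed column order: habitat-major, statistic-minor
MST_FEATURE_NAMES = [
    f"{HABITAT_KEY[label]}_{stat}" for label in HabitatLabel for stat in MST_STAT_NAMES
]


def branch_length_stats(weights: np.ndarray) -> dict:
    """The seven branch-length statistics of a weight set.

    Raises
    ------
    InsufficientPointsError
        Empty weight set.
    UndefinedFeatureError
        min(W) = 0 (coincident centroids), which leaves the max/min ratio
        undefined.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if w.size == 0:
        raise InsufficientPointsError("MST has no edges")
    mu = w.mean()
    med = float(np.median(w))
    sigma = float(np.sqrt(np.mean((w - mu) ** 2)))
    if sigma == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean((w - mu) ** 3) / sigma**3)
        kurt = float(np.mean((w - mu) ** 4) / sigma**4)
    wmin = w.min()
    if wmin <= 0:
        raise UndefinedFeatureError("min branch length is 0: max/min ratio undefined")
    return {
        "mean": float(mu),
        "median": med,
        "sd": sigma,
        "skewness": skew,
        "kurtosis": kurt,
        "ratio": float(w.max() / wmin),
        "disorder": sigma / mu,
    }


def mst_feature_vector(tree: SpanningTree) -> dict:
    """Seven branch-length statistics of a spanning tree."""
    return branch_length_stats(tree.weights)


def subject_mst_features(
    masks: HabitatMasks, grid_spacing: int = 8
) -> dict:
    """28 named MST features for one subject (7 statistics x 4 habitats).

    A habitat with fewer than 2 grid centroids has no spanning tree; its seven
    statistics are recorded as NaN (missing), leaving the other habitats
    unaffected.
    """
    features: dict = {}
    for label in HabitatLabel:
        key = HABITAT_KEY[label]
        points = grid_centroids(masks[label], masks.spacing_mm, grid_spacing)
        if len(points) < 2:
            stats = {stat: np.nan for stat in MST_STAT_NAMES}
        else:
            stats = mst_feature_vector(build_mst(points, habitat=label))
        for stat in MST_STAT_NAMES:
            features[f"{key}_{stat}"] = stats[stat]
    return features
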