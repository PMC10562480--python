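"""Intensity habitats: GMM-based low/high splitting of tumor ROI intensities.

For each MR sequence (post-contrast T1-weighted, T2-FLAIR), the intensities
inside the tumor ROI are linearly rescaled to [0, 1], a two-component Gaussian
mixture is fitted, and the ROI is split at the average of the two component
means. This produces four binary habitat masks per subject: T1-high, T1-low,
T2-high, T2-low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from sklearn.mixture import GaussianMixture

from .errors import DegenerateROIError, ParameterError, UnimodalROIError

__all__ = [
    "HabitatLabel",
    "SlicePair",
    "HabitatMasks",
    "scale_intensities",
    "fit_gmm_threshold",
    "make_habitat_masks",
]


class HabitatLabel(IntEnum):
    """The four intensity habitats, with a stable integer encoding."""

    T1_HIGH = 0
    T1_LOW = 1
    T2_HIGH = 2
    T2_LOW = 3


#: short lowercase keys used in feature names and CSV columns
HABITAT_KEY = {
    HabitatLabel.T1_HIGH: "t1high",
    HabitatLabel.T1_LOW: "t1low",
    HabitatLabel.T2_HIGH: "t2high",
    HabitatLabel.T2_LOW: "t2low",
}


@dataclass
class SlicePair:
    """One subject's paired 2D slices with per-sequence ROI masks.

    Parameters
    ----------
    t1c, flair
        2D intensity arrays in arbitrary scanner units.
    roi_t1, roi_flair
        Binary tumor masks aligned with ``t1c`` / ``flair`` respectively.
        The two sequences are segmented independently, so the masks may differ.
    spacing_mm
        (row, col) pixel size in millimetres.
    subject_id
        Opaque identifier carried through to feature tables.
    truth
        Optional generator ground truth (synthetic phantoms only): mapping with
        boolean masks of the pixels drawn from the high-intensity mixture
        component, keys ``"t1_high"`` and ``"flair_high"``.
    """

    t1c: np.ndarray
    flair: np.ndarray
    roi_t1: np.ndarray
    roi_flair: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    subject_id: str = "subject"
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t1c = np.asarray(self.t1c, dtype=float)
        self.flair = np.asarray(self.flair, dtype=float)
        self.roi_t1 = np.asarray(self.roi_t1, dtype=bool)
        self.roi_flair = np.asarray(self.roi_flair, dtype=bool)
        if self.t1c.ndim != 2 or self.flair.ndim != 2:
            raise ParameterError("slices must be 2D arrays")
        if self.t1c.shape != self.roi_t1.shape:
            raise ParameterError("t1c and roi_t1 shapes differ")
        if self.flair.shape != self.roi_flair.shape:
            raise ParameterError("flair and roi_flair shapes differ")
        if not self.roi_t1.any() or not self.roi_flair.any():
            raise ParameterError("ROI masks must be nonempty")
        if min(self.spacing_mm) <= 0:
            raise ParameterError("pixel spacing must be positive")


@dataclass
class HabitatMasks:
    """Four binary habitat masks plus the fitted GMM thresholds.

    The HIGH and LOW masks of a sequence partition that sequence's ROI:
    pixels with scaled intensity strictly above the threshold are HIGH,
    pixels at or below it are LOW.
    """

    masks: dict
    gmm_threshold_t1: float
    gmm_threshold_t2: float
    gmm_means: dict
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    subject_id: str = "subject"

    def __getitem__(self, label: HabitatLabel) -> np.ndarray:
        return self.masks[HabitatLabel(label)]


def scale_intensities(values: np.ndarray) -> np.ndarray:
    """Linearly rescale intensities so min -> 0 and max -> 1.

    Raises
    ------
    DegenerateROIError
        If all values are equal (zero range): the habitat split is undefined.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ParameterError("need at least 2 intensity values to rescale")
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateROIError("constant ROI intensities: habitat split undefined")
    return (values - lo) / (hi - lo)


def fit_gmm_threshold(
    scaled: np.ndarray,
    seed: int = 0,
    min_size: int = 20,
    separation_tol: float = 1e-3,
    equal_variance: bool = False,
) -> tuple[float, float, float]:
    """Fit a two-component univariate GMM and return the mean-of-means threshold.

    The threshold is (mu_low + mu_high) / 2, the average of the two fitted
    component means. EM is initialized from k-means with 5 restarts and a fixed
    seed, so the result is deterministic.

    Parameters
    ----------
    scaled
        1D intensities rescaled to [0, 1].
    seed
        RNG seed for EM initialization.
    min_size
        Minimum number of values required for a trustworthy fit.
    separation_tol
        If the fitted component means differ by less than this, the ROI is
        treated as unimodal and an error is raised.
    equal_variance
        If True, constrain both components to share one variance.

    Returns
    -------
    (threshold, mean_low, mean_high)
    """
    scaled = np.asarray(scaled, dtype=float).ravel()
    if scaled.size < min_size:
        raise ParameterError(
            f"need >= {min_size} values for a 2-component GMM fit, got {scaled.size}"
        )
    if scaled.min() < 0 or scaled.max() > 1:
        raise ParameterError("scaled intensities must lie in [0, 1]")
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="tied" if equal_variance else "full",
        n_init=5,
        init_params="kmeans",
        random_state=int(seed),
    )
    gmm.fit(scaled.reshape(-1, 1))
    mean_low, mean_high = sorted(float(m) for m in gmm.means_.ravel())
    if mean_high - mean_low < separation_tol:
        raise UnimodalROIError(
            f"GMM components collapsed (|mu2 - mu1| = {mean_high - mean_low:.2e})"
        )
    threshold = 0.5 * (mean_low + mean_high)
    return threshold, mean_low, mean_high


def assign_high_low(scaled: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean high-habitat assignment: strictly above threshold is HIGH.

    Values exactly equal to the threshold go to LOW.
    """
    return np.asarray(scaled, dtype=float) > threshold


def make_habitat_masks(
    slices: SlicePair,
    seed: int = 0,
    min_size: int = 20,
    equal_variance: bool = False,
) -> HabitatMasks:
    """Compute the four habitat masks for one subject.

    Per sequence: rescale ROI intensities to [0, 1], fit the two-component GMM
    threshold, and split the ROI into HIGH (scaled value > threshold) and LOW
    (<= threshold). Degenerate or unimodal ROIs raise errors tagged with the
    sequence name.
    """
    masks: dict = {}
    thresholds: dict = {}
    means: dict = {}
    for seq, image, roi, high_label, low_label in (
        ("t1", slices.t1c, slices.roi_t1, HabitatLabel.T1_HIGH, HabitatLabel.T1_LOW),
        ("t2", slices.flair, slices.roi_flair, HabitatLabel.T2_HIGH, HabitatLabel.T2_LOW),
    ):
        roi_values = image[roi]
        try:
            scaled = scale_intensities(roi_values)
            threshold, mean_low, mean_high = fit_gmm_threshold(
                scaled, seed=seed, min_size=min_size, equal_variance=equal_variance
            )
        except (DegenerateROIError, UnimodalROIError, ParameterError) as exc:
            raise type(exc)(f"[sequence {seq}] {exc}") from exc
        high = np.zeros(image.shape, dtype=bool)
        high[roi] = assign_high_low(scaled, threshold)
        masks[high_label] = high
        masks[low_label] = roi & ~high
        thresholds[seq] = threshold
        means[seq] = (mean_low, mean_high)
    return HabitatMasks(
        masks=masks,
        gmm_threshold_t1=thresholds["t1"],
        gmm_threshold_t2=thresholds["t2"],
        gmm_means=means,
        spacing_mm=slices.spacing_mm,
        subject_id=slices.subject_id,
    )
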