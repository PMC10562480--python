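"""Synthetic tumor phantoms with known habitat structure.

Each phantom is a pair of 2D slices (labelled "t1" and "flair") with an
elliptical tumor ROI. Within the ROI, pixel intensities are drawn from a
two-component Gaussian mixture per sequence; the spatial placement of the
high-intensity component is controlled by a ``clustering`` knob: at 0 the high
pixels are scattered uniformly over the ROI, at 1 they are concentrated in a
few compact blobs. Cohorts plant a class effect by shifting ``clustering``
(and optionally ``high_fraction``) between the two outcome classes, giving a
ground-truth discriminative signal for the MST/GRLM feature pipeline.

Ground-truth component masks are attached to every generated slice pair, so
habitat recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .habitats import SlicePair

__all__ = ["PhantomParams", "CohortSpec", "generate_phantom", "generate_cohort"]

_SEQUENCES = ("t1", "flair")


@dataclass
class PhantomParams:
    """Knobs of a single tumor phantom.

    Parameters
    ----------
    image_size
        Pixels per side of the square image.
    roi_axes
        Ellipse semi-axes (row, col) in pixels; the ellipse is centred in the
        image and must fit inside it.
    mixture_means
        Per-sequence (low, high) in-ROI intensity means, arbitrary scanner
        scale, with low < high.
    mixture_sds
        Per-sequence (low, high) standard deviations.
    high_fraction
        Proportion of ROI pixels assigned to the high-intensity component,
        in (0, 1); applied to both sequences.
    clustering
        Scalar in [0, 1]: fraction of high pixels packed into compact blobs
        (the rest are scattered uniformly over the ROI).
    blob_count
        Number of compact high-intensity blobs.
    seed
        RNG seed; phantoms are bit-reproducible given identical parameters.
    """

    image_size: int = 128
    roi_axes: tuple[float, float] = (52.0, 40.0)
    mixture_means: dict = field(
        default_factory=lambda: {"t1": (100.0, 200.0), "flair": (90.0, 180.0)}
    )
    mixture_sds: dict = field(
        default_factory=lambda: {"t1": (10.0, 10.0), "flair": (10.0, 10.0)}
    )
    high_fraction: float = 0.2
    clustering: float = 0.0
    blob_count: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ParameterError("image_size must be >= 16 pixels")
        a, b = self.roi_axes
        if a <= 0 or b <= 0 or 2 * a >= self.image_size or 2 * b >= self.image_size:
            raise ParameterError("roi_axes must be positive and the ROI must fit inside the image")
        for seq in _SEQUENCES:
            lo, hi = self.mixture_means[seq]
            if not lo < hi:
                raise ParameterError(f"mixture means must satisfy low < high (sequence {seq})")
            sds = self.mixture_sds[seq]
            if min(sds) <= 0:
                raise ParameterError(f"mixture SDs must be positive (sequence {seq})")
        if not 0.0 < self.high_fraction < 1.0:
            raise ParameterError("high_fraction must lie in (0, 1)")
        if not 0.0 <= self.clustering <= 1.0:
            raise ParameterError("clustering must lie in [0, 1]")
        if self.blob_count < 1:
            raise ParameterError("blob_count must be >= 1")


@dataclass
class CohortSpec:
    """Two-class cohort: class 1 phantoms get shifted generator knobs.

    ``clustering_effect`` (and optionally ``high_fraction_effect``) are added
    to the base parameters for class-1 subjects, clipped to the valid range.
    With both effects at 0 the two classes are exchangeable.
    """

    n_per_class: int = 30
    clustering_effect: float = 0.0
    high_fraction_effect: float = 0.0
    base_params: PhantomParams = field(default_factory=PhantomParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ParameterError("n_per_class must be >= 2")


def _ellipse_mask(size: int, axes: tuple[float, float]) -> np.ndarray:
    center = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    a, b = axes
    return ((rr - center) / a) ** 2 + ((cc - center) / b) ** 2 <= 1.0


def _sample_blob_centers(
    roi_pixels: np.ndarray,
    n_blobs: int,
    min_sep: float,
    rng: np.random.Generator,
    max_tries: int = 500,
) -> np.ndarray:
    """Rejection-sample blob centers inside the ROI with a minimum pairwise
    separation of one blob radius; after ``max_tries`` the separation
    constraint is relaxed so generation never fails."""
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_blobs:
        cand = roi_pixels[rng.integers(len(roi_pixels))].astype(float)
        tries += 1
        ok = all(np.linalg.norm(cand - c) >= min_sep for c in centers)
        if ok or tries > max_tries:
            centers.append(cand)
    return np.array(centers)


def _place_high_pixels(
    roi: np.ndarray,
    high_fraction: float,
    clustering: float,
    blob_count: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask of ROI pixels assigned to the high-intensity component."""
    roi_pixels = np.argwhere(roi)
    n_roi = len(roi_pixels)
    n_high = max(1, int(round(high_fraction * n_roi)))
    n_clustered = int(round(clustering * n_high))
    chosen = np.zeros(n_roi, dtype=bool)
    if n_clustered > 0:
        quota = np.full(blob_count, n_clustered // blob_count)
        quota[: n_clustered % blob_count] += 1
        blob_radius = np.sqrt(max(quota.max(), 1) / np.pi)
        centers = _sample_blob_centers(roi_pixels, blob_count, blob_radius, rng)
        for center, q in zip(centers, quota):
            if q == 0:
                continue
            avail = np.flatnonzero(~chosen)
            d = np.linalg.norm(roi_pixels[avail] - center, axis=1)
            chosen[avail[np.argsort(d, kind="stable")[:q]]] = True
    n_scatter = n_high - int(chosen.sum())
    if n_scatter > 0:
        avail = np.flatnonzero(~chosen)
        chosen[rng.choice(avail, size=n_scatter, replace=False)] = True
    high = np.zeros(roi.shape, dtype=bool)
    high[tuple(roi_pixels[chosen].T)] = True
    return high


def generate_phantom(params: PhantomParams, subject_id: str = "phantom") -> SlicePair:
    """Generate one phantom slice pair (deterministic given the seed).

    Both sequences share the elliptical ROI; each has its own independent
    spatial placement of the high component and its own intensity draws.
    Outside the ROI, the background is Gaussian noise at 10% of the
    low-component mean. Ground-truth high-component masks are attached as
    ``result.truth`` with keys ``"t1_high"`` and ``"flair_high"``.
    """
    rng = np.random.default_rng(params.seed)
    roi = _ellipse_mask(params.image_size, params.roi_axes)
    images: dict = {}
    truth: dict = {}
    for seq in _SEQUENCES:
        low_mean, high_mean = params.mixture_means[seq]
        low_sd, high_sd = params.mixture_sds[seq]
        high = _place_high_pixels(
            roi, params.high_fraction, params.clustering, params.blob_count, rng
        )
        img = rng.normal(0.1 * low_mean, 0.02 * low_mean, roi.shape)
        low = roi & ~high
        img[low] = rng.normal(low_mean, low_sd, int(low.sum()))
        img[high] = rng.normal(high_mean, high_sd, int(high.sum()))
        images[seq] = img
        truth[f"{seq}_high"] = high
    return SlicePair(
        t1c=images["t1"],
        flair=images["flair"],
        roi_t1=roi,
        roi_flair=roi.copy(),
        spacing_mm=(1.0, 1.0),  # phantoms mimic 1 mm isotropic resampling
        subject_id=subject_id,
        truth=truth,
    )


def generate_cohort(spec: CohortSpec) -> list[tuple[SlicePair, int]]:
    """Generate 2 * n_per_class phantoms with balanced binary labels.

    Class-1 subjects use the base parameters shifted by the class effects
    (clipped to valid ranges); per-subject seeds are spawned deterministically
    from the cohort seed.
    """
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(
        2 * spec.n_per_class
    ) % (2**31)
    cohort: list[tuple[SlicePair, int]] = []
    idx = 0
    for cls in (0, 1):
        if cls == 0:
            params_cls = spec.base_params
        else:
            hf = spec.base_params.high_fraction + spec.high_fraction_effect
            params_cls = replace(
                spec.base_params,
                clustering=float(
                    np.clip(spec.base_params.clustering + spec.clustering_effect, 0.0, 1.0)
                ),
                high_fraction=float(np.clip(hf, 1e-3, 1 - 1e-3)),
            )
        for i in range(spec.n_per_class):
            params = replace(params_cls, seed=int(child_seeds[idx]))
            subject_id = f"class{cls}_{i:03d}"
            cohort.append((generate_phantom(params, subject_id=subject_id), cls))
            idx += 1
    return cohort
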