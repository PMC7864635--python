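"""Fluorescence summary statistics from corrected images and pixel regions.

Raw fluorescence frames are corrected for sensor dark current and for
spatial variation in illumination (flat-field), then summarized over a
region of interest — either an arbitrary boolean mask (e.g. the segmented
animal) or a circle of fixed radius around a manually annotated anatomical
landmark (pharynx, vulva) for dim, spatially restricted reporters.

The summary statistics are order/mean statistics of the in-region pixel
intensity multiset: mean, maximum, 95th and 99th percentile, and the mean
of pixels strictly above the region's 99th percentile.  Percentiles use
linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CorrectionError",
    "RegionError",
    "CorrectedImage",
    "RegionSpec",
    "correct_image",
    "disk_mask",
    "summarize_region",
    "SUMMARY_STATISTICS",
]

SUMMARY_STATISTICS = ("mean", "max", "p95", "p99", "mean_over_p99")


class CorrectionError(ValueError):
    """Sensor-correction inputs are unusable (e.g. non-positive flat field)."""


class RegionError(ValueError):
    """The region of interest resolves to no pixels."""


@dataclass
class CorrectedImage:
    """A dark-subtracted, flat-field normalized intensity grid."""

    pixels: np.ndarray
    provenance: str = ""


@dataclass
class RegionSpec:
    """A region of interest: a boolean mask XOR a landmark circle.

    A landmark circle is given as ``(center_row, center_col, radius)`` in
    pixels; membership is pixel centers at Euclidean distance <= radius,
    clipped to the image bounds.  Published landmark radii for this kind of
    data: 5 px at the pharynx for very tight expression domains, 25 px at
    the pharynx or vulva for broader ones.
    """

    mask: np.ndarray | None = None
    landmark: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if (self.mask is None) == (self.landmark is None):
            raise RegionError("specify exactly one of mask or landmark")
        if self.landmark is not None and self.landmark[2] <= 0:
            raise RegionError("landmark radius must be > 0")

    def resolve(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != shape:
                raise RegionError(f"mask shape {mask.shape} != image shape {shape}")
        else:
            row, col, radius = self.landmark
            mask = disk_mask(shape, row, col, radius)
        if not mask.any():
            raise RegionError("region resolves to zero pixels")
        return mask

    def complement(self, within: np.ndarray) -> "RegionSpec":
        """The part of ``within`` outside this region.

        Dual-reporter tissue separation: one reporter is measured inside the
        annotated landmark circle, the other from the animal mask excluding
        that circle.
        """
        within = np.asarray(within, dtype=bool)
        return RegionSpec(mask=within & ~self.resolve(within.shape))


def disk_mask(shape: tuple[int, int], row: float, col: float, radius: float) -> np.ndarray:
    """Boolean mask of pixel centers within ``radius`` of (row, col)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def correct_image(
    raw: np.ndarray, dark: np.ndarray, flat: np.ndarray
) -> CorrectedImage:
    """Dark-current subtraction and flat-field normalization.

    ``output = (raw - dark) / flat_norm`` where ``flat_norm`` is the
    dark-subtracted flat field scaled to mean 1 over the frame, so the
    correction removes the illumination *pattern* without changing the
    frame's overall intensity scale.
    """
    raw = np.asarray(raw, dtype=float)
    dark = np.asarray(dark, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if not (raw.shape == dark.shape == flat.shape):
        raise CorrectionError("raw, dark and flat must share a shape")
    flat_sub = flat - dark
    n_bad = int(np.count_nonzero(flat_sub <= 0))
    if n_bad:
        raise CorrectionError(
            f"flat field has {n_bad} non-positive pixels after dark subtraction"
        )
    flat_norm = flat_sub / flat_sub.mean()
    return CorrectedImage(
        pixels=(raw - dark) / flat_norm,
        provenance="dark-subtracted, flat-field normalized (mean-1 flat)",
    )


def summarize_region(
    image: CorrectedImage | np.ndarray, region: RegionSpec, statistic: str
) -> float:
    """One summary statistic of the in-region pixel intensities.

    ``mean_over_p99`` is the mean of pixels *strictly greater* than the
    region's 99th-percentile value; when no pixel exceeds it (tiny or
    uniform regions) it falls back to the maximum.
    """
    pixels = image.pixels if isinstance(image, CorrectedImage) else np.asarray(image, float)
    values = pixels[region.resolve(pixels.shape)].astype(float)
    if statistic == "mean":
        return float(values.mean())
    if statistic == "max":
        return float(values.max())
    if statistic == "p95":
        return float(np.percentile(values, 95))
    if statistic == "p99":
        return float(np.percentile(values, 99))
    if statistic == "mean_over_p99":
        cutoff = np.percentile(values, 99)
        over = values[values > cutoff]
        return float(over.mean()) if over.size else float(values.max())
    raise ValueError(f"unknown statistic {statistic!r}")
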