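"""Apparent diffusion coefficient (ADC) mapping from two-b-value DWI.

The ADC at each pixel is obtained by inverting the mono-exponential decay

    S(b) = S(0) * exp(-b * ADC)

between a b=0 s/mm^2 image and a single diffusion-weighted image (here
b=500 s/mm^2).  Magnitude-MRI signals ride on a Rician noise floor, so
before taking the log-quotient both signals are rectified by quadrature
subtraction of a configurable noise-floor level:

    S' = sqrt(max(S^2 - NF^2, 0))

With NF=0 this degenerates to the plain log-quotient.  ADC is physically
non-negative; pixels where the rectified DW signal exceeds the rectified
b=0 signal are clipped to zero and flagged.

Per-slice ROI mean ADCs are pooled into a per-nodule weighted mean with
ROI pixel areas as weights:

    xbar = sum(w_i * x_i) / sum(w_i)

Rasters are indexed (row, column), 0-based, row 0 at the image top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DWISlicePair:
    """Co-registered b=0 and diffusion-weighted signal rasters for one slice.

    Parameters
    ----------
    s0 : ndarray
        Signal raster at b=0 s/mm^2, arbitrary units, non-negative.
    sb : ndarray
        Signal raster at ``b_value`` s/mm^2 on the same grid.
    b_value : float
        Diffusion weighting in s/mm^2, > 0.
    pixel_spacing : float
        Edge length of a pixel in mm.
    slice_id, nodule_id : str
        Identifiers linking the slice to its nodule.
    """

    s0: np.ndarray
    sb: np.ndarray
    b_value: float = 500.0
    pixel_spacing: float = 1.0
    slice_id: str = ""
    nodule_id: str = ""

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.sb = np.asarray(self.sb, dtype=float)
        if self.s0.shape != self.sb.shape:
            raise ValueError(
                f"s0 shape {self.s0.shape} != sb shape {self.sb.shape}"
            )
        if self.b_value <= 0:
            raise ValueError(f"b_value must be > 0, got {self.b_value}")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if np.any(self.s0 < 0) or np.any(self.sb < 0):
            raise ValueError("signals must be non-negative")


@dataclass
class ADCMap:
    """Per-pixel ADC raster in mm^2/s with a validity mask.

    ``values`` is finite and >= 0 wherever ``valid_mask`` is set.
    ``n_clipped`` counts pixels whose raw log-quotient was negative and
    was clipped to zero.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    n_clipped: int = 0


@dataclass
class ROIMask:
    """Binary region-of-interest mask on a slice grid."""

    mask: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.area_px < 1:
            raise ValueError("ROI mask must contain at least one pixel")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_px * self.pixel_spacing**2


@dataclass
class ROISummary:
    """One slice's ROI area (the pooling weight) and mean ADC."""

    area: float
    mean_adc: float
    nodule_id: str = ""
    slice_id: str = ""

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("ROI area must be > 0")
        if self.mean_adc < 0:
            raise ValueError("mean ADC must be >= 0")


def rectify(signal: np.ndarray, noise_floor: float) -> np.ndarray:
    """Quadrature noise-floor rectification S' = sqrt(max(S^2 - NF^2, 0))."""
    s = np.asarray(signal, dtype=float)
    return np.sqrt(np.maximum(s * s - noise_floor * noise_floor, 0.0))


def compute_adc(pair: DWISlicePair, noise_floor: float = 0.0) -> ADCMap:
    """Compute a noise-rectified ADC map from a b=0 / b=500 slice pair.

    Pixels where either rectified signal is zero are marked invalid.
    Pixels where the rectified DW signal exceeds the rectified b=0 signal
    (negative apparent ADC) are clipped to 0, kept valid, and counted in
    ``n_clipped``.
    """
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")
    s0r = rectify(pair.s0, noise_floor)
    sbr = rectify(pair.sb, noise_floor)
    valid = (s0r > 0) & (sbr > 0)
    values = np.zeros_like(s0r)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(s0r / sbr) / pair.b_value
    negative = valid & (adc < 0)
    adc = np.where(valid, np.maximum(adc, 0.0), 0.0)
    return ADCMap(values=adc, valid_mask=valid, n_clipped=int(negative.sum()))


def roi_mean_adc(adc: ADCMap, roi: ROIMask) -> ROISummary:
    """Mean ADC over the valid pixels of a ROI; area reported in pixels."""
    if roi.mask.shape != adc.values.shape:
        raise ValueError(
            f"ROI shape {roi.mask.shape} != ADC shape {adc.values.shape}"
        )
    inside = roi.mask & adc.valid_mask
    if not inside.any():
        raise ValueError("no valid ADC pixel inside the ROI")
    return ROISummary(area=float(roi.area_px),
                      mean_adc=float(adc.values[inside].mean()))


def weighted_mean_adc(summaries: list[ROISummary]) -> float:
    """Area-weighted mean ADC pooled over a nodule's slice ROIs."""
    if not summaries:
        raise ValueError("need at least one ROI summary")
    w = np.array([s.area for s in summaries], dtype=float)
    x = np.array([s.mean_adc for s in summaries], dtype=float)
    return float(np.sum(w * x) / np.sum(w))
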