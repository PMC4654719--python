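"""Synthetic DW-MRI thyroid-nodule cohort generator.

Emulates the statistical structure of a two-site thyroid DWI study so
the full analysis chain (ADC mapping, texture extraction, feature
selection, LDA) can be exercised without patient data:

* class-conditional nodule-level mean ADC: benign 2.24e-3 mm^2/s,
  malignant 1.92e-3 mm^2/s, with between-nodule spread matching the
  reported 95% CIs;
* maximum nodule diameters benign 29.3 +/- 8.0 mm, malignant
  33.3 +/- 10.4 mm;
* 1-7 slices per nodule (uniform, mean 4), elliptical ROIs of at least
  17 pixels whose through-plane extent shrinks toward the end slices;
* 256 x 256 reconstructed matrix, 220 mm field of view, b = 0 and
  500 s/mm^2, Rician magnitude noise on both images;
* a class-dependent intranodular texture: the ADC field inside a nodule
  is the nodule mean plus a Gaussian random field whose correlation
  length and heterogeneity SD differ between classes (malignant tissue
  is modelled as more heterogeneous at a finer spatial scale), the
  feature the texture classifier is meant to detect.

Nodule position is drawn independently of class, so mask-position
features carry no class information by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .adc import DWISlicePair, ROIMask


@dataclass
class CohortConfig:
    """All distributional parameters of the simulated study.

    ADC values are in mm^2/s, lengths in mm, signals in arbitrary
    magnitude units.
    """

    n_benign: int = 16
    n_malignant: int = 8
    adc_mean_benign: float = 2.24e-3
    adc_mean_malignant: float = 1.92e-3
    adc_sd_benign: float = 0.30e-3        # between-nodule SD
    adc_sd_malignant: float = 0.39e-3
    adc_slice_sd: float = 0.05e-3         # within-nodule slice-to-slice SD
    diameter_mean_benign: float = 29.3
    diameter_sd_benign: float = 8.0
    diameter_mean_malignant: float = 33.3
    diameter_sd_malignant: float = 10.4
    min_diameter: float = 8.0
    # intranodular texture (the class signal beyond mean ADC)
    corr_len_benign: float = 4.0          # GRF correlation length, mm
    corr_len_malignant: float = 1.5
    heterogeneity_benign: float = 0.10e-3  # GRF SD, mm^2/s
    heterogeneity_malignant: float = 0.35e-3
    background_adc: float = 1.2e-3
    min_slices: int = 1
    max_slices: int = 7
    slice_thickness: float = 5.0
    matrix: int = 256
    fov: float = 220.0
    b_value: float = 500.0
    s0_level: float = 400.0
    rician_sd: float = 8.0
    min_roi_px: int = 17
    seed: int = 0

    @property
    def pixel_spacing(self) -> float:
        return self.fov / self.matrix

    def null(self) -> "CohortConfig":
        """A no-effect variant: both classes share the benign ADC mean,
        diameter, and texture parameters, leaving no class signal."""
        return replace(
            self,
            adc_mean_malignant=self.adc_mean_benign,
            adc_sd_malignant=self.adc_sd_benign,
            diameter_mean_malignant=self.diameter_mean_benign,
            diameter_sd_malignant=self.diameter_sd_benign,
            corr_len_malignant=self.corr_len_benign,
            heterogeneity_malignant=self.heterogeneity_benign,
        )


@dataclass
class SyntheticNodule:
    nodule_id: str
    label: str                       # "benign" | "malignant"
    slices: list[DWISlicePair]
    rois: list[ROIMask]
    true_slice_adc: list[float]      # noiseless in-ROI mean ADC per slice
    diameter_mm: float
    nodule_mean_adc: float


@dataclass
class Cohort:
    training: list[SyntheticNodule]
    test: list[SyntheticNodule]
    manifest: pd.DataFrame
    config: CohortConfig


def _grf(shape: tuple[int, int], corr_len_px: float,
         rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with Gaussian
    correlation of the given length (pixels)."""
    noise = rng.standard_normal(shape)
    if corr_len_px <= 0:
        return noise
    f = gaussian_filter(noise, corr_len_px, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _rician(signal: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI measurement of a noiseless signal."""
    if sd <= 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sd, signal.shape)
    im = rng.normal(0.0, sd, signal.shape)
    return np.hypot(re, im)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  semi_a: float, semi_b: float, angle: float) -> np.ndarray:
    rr, cc = np.indices(shape)
    y = rr - center[0]
    x = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = x * ca + y * sa
    v = -x * sa + y * ca
    return (u / semi_a) ** 2 + (v / semi_b) ** 2 <= 1.0


def generate_nodule(config: CohortConfig, label: str,
                    rng: np.random.Generator,
                    nodule_id: str = "n0") -> SyntheticNodule:
    """Simulate one multi-slice nodule with its DWI pairs and ROI masks.

    The in-plane ROI is an ellipse (eccentricity U(0.6, 1.0), random
    orientation) whose extent shrinks on end slices following a
    spherical chord profile; slices whose discretized ROI would fall
    below the minimum area trigger a diameter redraw.
    """
    if label == "benign":
        d_mu, d_sd = config.diameter_mean_benign, config.diameter_sd_benign
        adc_mu, adc_sd = config.adc_mean_benign, config.adc_sd_benign
        corr_len, het = config.corr_len_benign, config.heterogeneity_benign
    elif label == "malignant":
        d_mu, d_sd = config.diameter_mean_malignant, config.diameter_sd_malignant
        adc_mu, adc_sd = config.adc_mean_malignant, config.adc_sd_malignant
        corr_len, het = config.corr_len_malignant, config.heterogeneity_malignant
    else:
        raise ValueError(f"unknown label {label!r}")

    px = config.pixel_spacing
    n = config.matrix
    nodule_adc = max(rng.normal(adc_mu, adc_sd), 0.2e-3)
    n_slices = int(rng.integers(config.min_slices, config.max_slices + 1))
    ecc = rng.uniform(0.6, 1.0)
    angle = rng.uniform(0, np.pi)
    # position independent of class: uniform within a central window
    margin = n // 4
    center = (rng.uniform(margin, n - margin), rng.uniform(margin, n - margin))

    for _attempt in range(100):
        diameter = max(rng.normal(d_mu, d_sd), config.min_diameter)
        semi_a = diameter / 2.0 / px
        semi_b = semi_a * ecc
        # through-plane chord scale per slice: ~spherical cross-sections
        half = n_slices * config.slice_thickness / 2.0
        z = (np.arange(n_slices) - (n_slices - 1) / 2.0) * config.slice_thickness
        scale = np.sqrt(np.clip(1.0 - (z / (half + config.slice_thickness / 2.0)) ** 2,
                                0.25, 1.0))
        masks = [_ellipse_mask((n, n), center, semi_a * s, semi_b * s, angle)
                 for s in scale]
        if all(m.sum() >= config.min_roi_px for m in masks):
            break
    else:
        raise RuntimeError("could not draw a nodule meeting the minimum ROI area")

    slices: list[DWISlicePair] = []
    rois: list[ROIMask] = []
    true_adc: list[float] = []
    for k, mask in enumerate(masks):
        slice_adc = max(nodule_adc + rng.normal(0.0, config.adc_slice_sd), 0.2e-3)
        texture = het * _grf((n, n), corr_len / px, rng)
        background = config.background_adc * (
            1.0 + 0.1 * _grf((n, n), 10.0 / px, rng))
        adc_field = np.where(mask, slice_adc + texture, background)
        adc_field = np.maximum(adc_field, 0.0)
        s0 = config.s0_level * (1.0 + 0.05 * _grf((n, n), 15.0 / px, rng))
        s0 = np.maximum(s0, 1.0)
        sb = s0 * np.exp(-config.b_value * adc_field)
        pair = DWISlicePair(
            s0=_rician(s0, config.rician_sd, rng),
            sb=_rician(sb, config.rician_sd, rng),
            b_value=config.b_value, pixel_spacing=px,
            slice_id=f"{nodule_id}_s{k}", nodule_id=nodule_id)
        slices.append(pair)
        rois.append(ROIMask(mask=mask, pixel_spacing=px))
        true_adc.append(float(adc_field[mask].mean()))

    return SyntheticNodule(nodule_id=nodule_id, label=label, slices=slices,
                           rois=rois, true_slice_adc=true_adc,
                           diameter_mm=float(diameter),
                           nodule_mean_adc=float(nodule_adc))


def generate_cohort(config: CohortConfig,
                    n_benign_test: int = 9, n_malignant_test: int = 9,
                    test_rician_sd: float | None = None) -> Cohort:
    """Generate independent training and test sub-cohorts.

    The test sub-cohort emulates a second institution: same class
    structure, optionally different noise level (default 1.25x the
    training Rician SD).  A manifest records every slice with its
    nodule, site, label, and true mean ADC.
    """
    rng = np.random.default_rng(config.seed)
    if test_rician_sd is None:
        test_rician_sd = 1.25 * config.rician_sd
    test_config = replace(config, rician_sd=test_rician_sd)

    def make(site: str, cfg: CohortConfig, n_b: int, n_m: int):
        labels = ["benign"] * n_b + ["malignant"] * n_m
        return [
            generate_nodule(cfg, lab, rng, nodule_id=f"{site}{i:03d}")
            for i, lab in enumerate(labels)
        ]

    training = make("tr", config, config.n_benign, config.n_malignant)
    test = make("te", test_config, n_benign_test, n_malignant_test)

    rows = []
    for site, nodules in (("training", training), ("test", test)):
        for nod in nodules:
            for pair, roi, adc in zip(nod.slices, nod.rois, nod.true_slice_adc):
                rows.append({
                    "site": site, "nodule_id": nod.nodule_id,
                    "slice_id": pair.slice_id, "label": nod.label,
                    "area_px": roi.area_px, "true_mean_adc": adc,
                    "diameter_mm": nod.diameter_mm, "seed": config.seed,
                })
    manifest = pd.DataFrame(rows)
    return Cohort(training=training, test=test, manifest=manifest,
                  config=config)
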