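"""Quantitative metric suite: PSNR, SSIM, RMSE, RC, COV and lesion metrics.

All metrics operate on a voxel mask.  SSIM is the single global form of the
index -- one statistic computed from mask-wide means, variances and
covariance with absolute stabilizing constants (c1 = 0.01, c2 = 0.03) -- not
a sliding-window mean.  Moments use the population convention (divide by N).
PSNR defaults to the standard 20 log10(Max / RMSE); a ``denominator="mse"``
switch computes the literal Max / MSE variant for comparison.  Recovery
coefficients (measured ROI mean over ground-truth ROI mean) quantify how
much activity the partial-volume-degraded or enhanced image retains;
relative lesion activity (RLA) is the lesion-ROI mean of a lesioned image
over the same ROI in its matched unlesioned image, so lower RLA means a more
conspicuous hypometabolic lesion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .anatomy import BRAIN_LABELS, CODE, LabelVolume
from .errors import ConfigurationError, GridMismatchError
from .phantom import LesionSpec


@dataclass
class ROISet:
    """Masks used by the metric suite, all on the anatomy grid."""

    gm_mask: np.ndarray
    wm_mask: np.ndarray
    wm_mask_eroded: np.ndarray
    brain_mask: np.ndarray
    erosion_radius_vox: float
    voxel_size_mm: tuple[float, float, float]
    lesion_rois: list[LesionSpec] = field(default_factory=list)

    @property
    def volumes_mm3(self) -> dict[str, float]:
        vv = float(np.prod(self.voxel_size_mm))
        out = {
            "gm": float(self.gm_mask.sum()) * vv,
            "wm_eroded": float(self.wm_mask_eroded.sum()) * vv,
            "brain": float(self.brain_mask.sum()) * vv,
        }
        for i, l in enumerate(self.lesion_rois):
            out[f"lesion_{i}"] = l.realized_volume_mm3
        return out


def make_rois(
    vol: LabelVolume,
    erosion_radius_vox: float = 6.0,
    lesions: list[LesionSpec] | None = None,
) -> ROISet:
    """Build GM, eroded-WM and brain masks from a label volume.

    The WM mask is eroded by a Euclidean ball of the given radius (in
    voxels, voxel-center rule): a voxel survives iff no non-WM voxel center
    lies within the radius, computed via the Euclidean distance transform.
    The aggressive erosion gives a conservative WM ROI free of boundary
    voxels contaminated by gray-matter spill-over.
    """
    gm = vol.grid == CODE["GM"]
    wm = vol.grid == CODE["WM"]
    if erosion_radius_vox > 0:
        eroded = ndimage.distance_transform_edt(wm) > erosion_radius_vox
    else:
        eroded = wm.copy()
    if not eroded.any():
        raise ConfigurationError(
            f"WM mask empty after erosion radius {erosion_radius_vox}; "
            "use a smaller radius"
        )
    brain = vol.mask(*BRAIN_LABELS)
    return ROISet(
        gm_mask=gm,
        wm_mask=wm,
        wm_mask_eroded=eroded,
        brain_mask=brain,
        erosion_radius_vox=float(erosion_radius_vox),
        voxel_size_mm=vol.voxel_size_mm,
        lesion_rois=list(lesions or []),
    )


def _check_mask(x: np.ndarray, mask: np.ndarray) -> None:
    if mask.shape != x.shape:
        raise GridMismatchError(f"mask shape {mask.shape} != image shape {x.shape}")
    if not mask.any():
        raise ValueError("empty mask")


def rmse(x: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    """Root mean squared error over the mask (L = mask voxel count)."""
    _check_mask(x, mask)
    d = x[mask] - y[mask]
    return float(np.sqrt(np.mean(d * d)))


def psnr(
    x: np.ndarray, y: np.ndarray, mask: np.ndarray, denominator: str = "rmse"
) -> float:
    """Peak signal-to-noise ratio in dB, with x as the reference.

    Returns ``inf`` when the images agree exactly on the mask.
    """
    _check_mask(x, mask)
    peak = float(x[mask].max())
    if peak <= 0:
        raise ValueError("reference image has no positive maximum on the mask")
    err = rmse(x, y, mask)
    if denominator == "mse":
        err = err * err
    elif denominator != "rmse":
        raise ConfigurationError("psnr denominator must be 'rmse' or 'mse'")
    if err == 0.0:
        return float("inf")
    return float(20.0 * np.log10(peak / err))


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    c1: float = 0.01,
    c2: float = 0.03,
) -> float:
    """Global structural similarity over the mask (population moments)."""
    _check_mask(x, mask)
    xv, yv = x[mask].astype(np.float64), y[mask].astype(np.float64)
    mx, my = xv.mean(), yv.mean()
    vx, vy = xv.var(), yv.var()
    cxy = float(np.mean((xv - mx) * (yv - my)))
    return float(
        (2 * mx * my + c1) * (2 * cxy + c2) / ((mx * mx + my * my + c1) * (vx + vy + c2))
    )


def recovery_coefficient(
    measured: np.ndarray, ground_truth: np.ndarray, roi: np.ndarray
) -> float:
    """ROI mean of the measured image over the ground-truth ROI mean."""
    _check_mask(measured, roi)
    denom = float(ground_truth[roi].mean())
    if denom <= 0:
        raise ValueError("ground-truth ROI mean must be positive")
    return float(measured[roi].mean() / denom)


def cov(image: np.ndarray, roi: np.ndarray) -> float:
    """Coefficient of variation in percent (population std over mean)."""
    _check_mask(image, roi)
    vals = image[roi]
    mu = float(vals.mean())
    if mu <= 0:
        raise ValueError("ROI mean must be positive")
    return float(100.0 * vals.std() / mu)


def relative_lesion_activity(
    lesioned_img: np.ndarray, unlesioned_img: np.ndarray, lesion_roi: np.ndarray
) -> float:
    """Lesion-ROI mean of the lesioned image over the unlesioned image."""
    _check_mask(lesioned_img, lesion_roi)
    denom = float(unlesioned_img[lesion_roi].mean())
    if denom <= 0:
        raise ValueError("unlesioned ROI mean must be positive")
    return float(lesioned_img[lesion_roi].mean() / denom)


def relative_rla_error(
    rla_measured: float, rla_ground_truth: float, absolute: bool = False
) -> float:
    """(measured - truth) / truth; optionally its absolute value."""
    if rla_ground_truth <= 0:
        raise ValueError("ground-truth RLA must be positive")
    err = (rla_measured - rla_ground_truth) / rla_ground_truth
    return float(abs(err)) if absolute else float(err)


@dataclass
class MetricsReport:
    """One comparison's worth of metrics, serializable as a table row."""

    psnr_db: float
    ssim: float
    rmse: float
    rc: dict[str, float]
    cov_percent: dict[str, float]
    lesions: pd.DataFrame | None = None

    def to_row(self) -> dict:
        row = {"psnr_db": self.psnr_db, "ssim": self.ssim, "rmse": self.rmse}
        for name, v in self.rc.items():
            row[f"rc_{name}"] = v
        for name, v in self.cov_percent.items():
            row[f"cov_{name}_pct"] = v
        return row

    def to_json(self, path=None) -> str:
        payload = {k: (None if not np.isfinite(v) else v) if isinstance(v, float) else v
                   for k, v in self.to_row().items()}
        # serialize +inf PSNR explicitly
        if np.isinf(self.psnr_db):
            payload["psnr_db"] = "inf"
        if self.lesions is not None and len(self.lesions):
            payload["lesions"] = self.lesions.to_dict(orient="records")
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_pair(
    reference: np.ndarray,
    test: np.ndarray,
    rois: ROISet,
    lesions: list[LesionSpec] | None = None,
    unlesioned_test: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    psnr_denominator: str = "rmse",
) -> MetricsReport:
    """Compute the full metric suite for one (reference, test) image pair.

    PSNR/SSIM/RMSE run over the brain mask (or an explicit ``mask``
    override); RC and COV over the GM ROI and the eroded WM ROI.  When
    ``lesions`` are given, the matched ``unlesioned_test`` image is required:
    RLA compares lesioned against unlesioned test over each lesion ROI, the
    relative RLA error compares that to the lesion's assigned contrast (the
    ground-truth RLA), and the lesion RC compares test against reference.
    """
    if reference.shape != test.shape:
        raise GridMismatchError(
            f"reference grid {reference.shape} != test grid {test.shape}"
        )
    m = mask if mask is not None else rois.brain_mask
    rc = {
        "gm": recovery_coefficient(test, reference, rois.gm_mask),
        "wm": recovery_coefficient(test, reference, rois.wm_mask_eroded),
    }
    cv = {
        "gm": cov(test, rois.gm_mask),
        "wm": cov(test, rois.wm_mask_eroded),
    }
    lesion_df = None
    lesions = lesions if lesions is not None else rois.lesion_rois
    if lesions:
        if unlesioned_test is None:
            raise ConfigurationError(
                "lesion metrics need the matched unlesioned test image"
            )
        rows = []
        for i, spec in enumerate(lesions):
            rla = relative_lesion_activity(test, unlesioned_test, spec.roi)
            row = {
                "lesion": i,
                "region": spec.region,
                "realized_volume_mm3": spec.realized_volume_mm3,
                "rla": rla,
                "lesion_rc": recovery_coefficient(test, reference, spec.roi),
            }
            if spec.contrast is not None:
                row["rla_ground_truth"] = spec.contrast
                row["relative_rla_error"] = relative_rla_error(rla, spec.contrast)
            rows.append(row)
        lesion_df = pd.DataFrame(rows)
    return MetricsReport(
        psnr_db=psnr(reference, test, m, denominator=psnr_denominator),
        ssim=ssim(reference, test, m),
        rmse=rmse(reference, test, m),
        rc=rc,
        cov_percent=cv,
        lesions=lesion_df,
    )
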