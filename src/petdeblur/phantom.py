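"""Ground-truth FDG activity phantoms: activity assignment, lesions, datasets.

A ground-truth high-quality phantom is a piecewise-constant activity map
(Bq/cm^3) over a nine-label anatomy.  White-matter activity is drawn from a
configurable lognormal, cerebral gray matter is an exact multiple of it (the
GM/WM contrast ratio, on a grid from 1.2 to 6.6), cerebellar GM is exactly
80% of cerebral GM, and bone/air carry no activity.  Small hypometabolic
lesions emulating focal cortical dysplasias are inserted as the largest
connected component of a digital sphere intersected with the GM ribbon, with
lesion activity a fixed fraction (0.6 or 0.3) of GM activity.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .anatomy import CODE, LABEL_SCHEME, LabelVolume
from .errors import ConfigurationError, GridMismatchError, PlacementError

#: GM-to-WM activity ratios assigned across the dataset.
GM_WM_RATIOS: tuple[float, ...] = (1.2, 1.8, 2.4, 3.0, 3.6, 4.2, 4.8, 5.4, 6.0, 6.6)

#: Lesion sphere volumes in mm^3 (largest to smallest).
LESION_VOLUMES_MM3: tuple[float, ...] = (1008.0, 612.0, 319.0)

#: Lesion-to-GM activity ratios; the smaller ratio is the stronger lesion.
LESION_CONTRASTS: tuple[float, ...] = (0.6, 0.3)

#: Cerebellar GM activity as a fraction of cerebral GM activity.
CEREB_GM_FRACTION = 0.80

#: Default (median Bq/cm^3, coefficient of variation) of the lognormal
#: activity distributions for the labels that are sampled rather than derived.
#: These are documented placeholders standing in for population values
#: estimated from a normal-subject database, chosen to give clinically
#: plausible absolute activities; override them in config for other tracers
#: or populations.
DEFAULT_ACTIVITY_DISTS: dict[str, tuple[float, float]] = {
    "WM": (3500.0, 0.20),
    "CSF": (1200.0, 0.30),
    "SOFT": (1800.0, 0.30),
    "BG": (11000.0, 0.20),
}


@dataclass(frozen=True)
class ActivityAssignment:
    """Per-label activity in Bq/cm^3 plus the parameters that produced it."""

    activities: dict[str, float]
    gm_wm_ratio: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, a in self.activities.items():
            if a < 0:
                raise ConfigurationError(f"negative activity for {name}")

    def lut(self, label_scheme: dict[int, str] | None = None) -> np.ndarray:
        """Code-indexed activity lookup table."""
        scheme = label_scheme or LABEL_SCHEME
        lut = np.zeros(max(scheme) + 1)
        for code, name in scheme.items():
            lut[code] = self.activities.get(name, 0.0)
        return lut


@dataclass
class LesionSpec:
    """A realized GM-restricted spherical lesion."""

    center_mm: tuple[float, float, float]
    sphere_volume_mm3: float
    roi: np.ndarray  # boolean mask on the anatomy grid
    realized_volume_mm3: float
    contrast: float | None = None
    region: str | None = None


@dataclass
class GroundTruthPET:
    """Piecewise-constant ground-truth activity volume (Bq/cm^3)."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    anatomy_id: str
    assignment: ActivityAssignment
    lesions: list[LesionSpec] = field(default_factory=list)


def sample_activity_assignment(
    dist_params: dict[str, tuple[float, float]] | None = None,
    gm_wm_ratio: float = 3.6,
    rng: np.random.Generator | None = None,
) -> ActivityAssignment:
    """Draw one activity assignment.

    WM, CSF, SOFT and BG are drawn independently from lognormals
    parameterized by (median, coefficient of variation); cerebral GM is
    exactly ``gm_wm_ratio`` times WM, cerebellar GM exactly 80% of cerebral
    GM, cerebellar WM equals cerebral WM, and bone/air are zero.  A zero
    coefficient of variation collapses the draw to the median.
    """
    if gm_wm_ratio <= 0:
        raise ConfigurationError("gm_wm_ratio must be positive")
    params = dict(DEFAULT_ACTIVITY_DISTS)
    if dist_params:
        params.update(dist_params)
    rng = rng or np.random.default_rng()
    draws: dict[str, float] = {}
    for name in ("WM", "CSF", "SOFT", "BG"):
        median, cv = params[name]
        if median <= 0:
            raise ConfigurationError(f"{name} distribution median must be positive")
        if cv < 0:
            raise ConfigurationError(f"{name} coefficient of variation must be >= 0")
        sigma = float(np.sqrt(np.log1p(cv * cv)))
        draws[name] = float(median * np.exp(sigma * rng.standard_normal()))
    gm = gm_wm_ratio * draws["WM"]
    activities = {
        "WM": draws["WM"],
        "GM": gm,
        "CEREB_GM": CEREB_GM_FRACTION * gm,
        "CEREB_WM": draws["WM"],
        "CSF": draws["CSF"],
        "SOFT": draws["SOFT"],
        "BG": draws["BG"],
        "BONE": 0.0,
        "AIR": 0.0,
    }
    return ActivityAssignment(
        activities=activities,
        gm_wm_ratio=float(gm_wm_ratio),
        provenance={"dist_params": params},
    )


def render_ground_truth(vol: LabelVolume, a: ActivityAssignment) -> GroundTruthPET:
    """Map each voxel's label to its assigned activity (no smoothing)."""
    present = {vol.label_scheme[c] for c in np.unique(vol.grid)}
    missing = sorted(present - set(a.activities))
    if missing:
        raise ConfigurationError(f"assignment missing labels: {missing}")
    values = a.lut(vol.label_scheme)[vol.grid]
    return GroundTruthPET(
        values=values,
        voxel_size_mm=vol.voxel_size_mm,
        anatomy_id=vol.anatomy_id,
        assignment=a,
    )


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def make_lesion_roi(
    vol: LabelVolume,
    center_mm: tuple[float, float, float],
    sphere_volume_mm3: float,
    region: str | None = None,
) -> LesionSpec:
    """Realize a lesion ROI: digital sphere intersected with cerebral GM.

    The sphere of radius ``(3V / 4 pi)^(1/3)`` keeps every voxel whose center
    lies within the closed ball; the ROI is the largest 26-connected
    component of the intersection with the GM mask.
    """
    if sphere_volume_mm3 <= 0:
        raise ConfigurationError("sphere_volume_mm3 must be positive")
    radius = (3.0 * sphere_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    cx, cy, cz = vol.coords_mm()
    dist2 = (
        ((cx - center_mm[0]) ** 2)[:, None, None]
        + ((cy - center_mm[1]) ** 2)[None, :, None]
        + ((cz - center_mm[2]) ** 2)[None, None, :]
    )
    sphere = dist2 <= radius * radius
    hit = sphere & (vol.grid == CODE["GM"])
    if not hit.any():
        raise PlacementError("sphere does not touch GM")
    labels, n = ndimage.label(hit, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        hit = labels == (int(np.argmax(sizes)) + 1)
    return LesionSpec(
        center_mm=tuple(float(c) for c in center_mm),
        sphere_volume_mm3=float(sphere_volume_mm3),
        roi=hit,
        realized_volume_mm3=float(hit.sum()) * vol.voxel_volume_mm3,
        region=region,
    )


def insert_lesion(
    gt: GroundTruthPET, roi: LesionSpec, contrast: float
) -> GroundTruthPET:
    """Return a copy of ``gt`` with lesion voxels set to ``contrast`` x GM.

    Lesion ROIs within one phantom must be disjoint (lesions live in
    different lobes); overlap raises.
    """
    if not 0.0 < contrast <= 1.0:
        raise ConfigurationError("contrast must lie in (0, 1]")
    if roi.roi.shape != gt.values.shape:
        raise GridMismatchError(
            f"lesion grid {roi.roi.shape} != phantom grid {gt.values.shape}"
        )
    for prev in gt.lesions:
        if np.any(prev.roi & roi.roi):
            raise PlacementError("overlapping lesion ROIs in one phantom")
    values = gt.values.copy()
    values[roi.roi] = contrast * gt.assignment.activities["GM"]
    spec = LesionSpec(
        center_mm=roi.center_mm,
        sphere_volume_mm3=roi.sphere_volume_mm3,
        roi=roi.roi,
        realized_volume_mm3=roi.realized_volume_mm3,
        contrast=float(contrast),
        region=roi.region,
    )
    return GroundTruthPET(
        values=values,
        voxel_size_mm=gt.voxel_size_mm,
        anatomy_id=gt.anatomy_id,
        assignment=gt.assignment,
        lesions=list(gt.lesions) + [spec],
    )


#: Lobe-like octants of the cortical ribbon used to draw lesion centers, as a
#: reproducible stand-in for manual placement in the right frontal and left
#: temporal cortex.  Predicates act on FOV-centered (x, y, z) mm coordinates
#: (x: left-right, y: posterior-anterior, z: inferior-superior).
LESION_REGIONS = {
    "right_frontal": lambda x, y, z: (x > 0) & (y > 0) & (z > 0),
    "left_temporal": lambda x, y, z: (x < 0) & (y > 0) & (z < 0),
}


def choose_lesion_center(
    vol: LabelVolume, region: str, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Draw a GM voxel center uniformly from the named cortical octant."""
    cx, cy, cz = vol.coords_mm()
    x = cx[:, None, None] + 0 * cy[None, :, None] + 0 * cz[None, None, :]
    y = 0 * cx[:, None, None] + cy[None, :, None] + 0 * cz[None, None, :]
    z = 0 * cx[:, None, None] + 0 * cy[None, :, None] + cz[None, None, :]
    candidates = (vol.grid == CODE["GM"]) & LESION_REGIONS[region](x, y, z)
    idx = np.flatnonzero(candidates)
    if idx.size == 0:
        raise PlacementError(f"no GM voxels in region {region}")
    pick = np.unravel_index(int(rng.choice(idx)), vol.grid.shape)
    return tuple(float(c[i]) for c, i in zip((cx, cy, cz), pick))


@dataclass
class DatasetManifest:
    """Tables describing a built phantom dataset: one row per phantom, one
    row per realized lesion."""

    phantoms: pd.DataFrame
    lesions: pd.DataFrame

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        self.phantoms.to_csv(out / "phantoms.csv", index=False)
        self.lesions.to_csv(out / "lesions.csv", index=False)

    @classmethod
    def load(cls, out_dir) -> "DatasetManifest":
        def read(path):
            try:
                return pd.read_csv(path)
            except pd.errors.EmptyDataError:
                return pd.DataFrame()

        out = Path(out_dir)
        return cls(
            phantoms=read(out / "phantoms.csv"),
            lesions=read(out / "lesions.csv"),
        )


def write_pet(values: np.ndarray, voxel_size_mm, path) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    img.header["descrip"] = b"activity Bq/cm3"
    nib.save(img, str(path))


def read_pet(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


def stable_seed(master_seed: int, tag: str) -> int:
    """Deterministic per-item seed derived from a master seed and a tag."""
    return int(
        np.random.SeedSequence([master_seed, zlib.crc32(tag.encode())]).generate_state(
            1
        )[0]
        % (2**31)
    )


def build_dataset(
    anatomies: list[LabelVolume],
    ratios: tuple[float, ...] = GM_WM_RATIOS,
    out_dir=None,
    seed: int = 0,
    dist_params: dict[str, tuple[float, float]] | None = None,
    lesion_models: int = 0,
    lesion_ratio: float = 3.6,
    lesion_volumes: tuple[float, ...] = LESION_VOLUMES_MM3,
    lesion_contrasts: tuple[float, ...] = LESION_CONTRASTS,
    lesion_regions: tuple[str, ...] = ("right_frontal", "left_temporal"),
    write: bool = True,
) -> DatasetManifest:
    """Build the phantom design grid and (optionally) write it to disk.

    One plain phantom is rendered per (anatomy x ratio) cell; if
    ``lesion_models`` > 0, the first ``lesion_models`` anatomies additionally
    get one lesioned phantom per (sphere volume x contrast) cell at the
    ``lesion_ratio`` GM/WM contrast, each carrying one lesion per entry of
    ``lesion_regions``.  With ``write=False`` the manifest (including sampled
    activities and realized lesion volumes) is built without writing NIfTI
    files, which is useful for design checks and dry runs.
    """
    out = Path(out_dir) if out_dir is not None else None
    if write:
        if out is None:
            raise ConfigurationError("out_dir is required when write=True")
        out.mkdir(parents=True, exist_ok=True)
    phantom_rows, lesion_rows = [], []

    for vol in anatomies:
        for ratio in ratios:
            tag = f"{vol.anatomy_id}_r{ratio:g}"
            cell_seed = stable_seed(seed, tag)
            a = sample_activity_assignment(
                dist_params, ratio, np.random.default_rng(cell_seed)
            )
            path = out / f"gt_{tag}.nii.gz" if out is not None else f"gt_{tag}.nii.gz"
            if write:
                gt = render_ground_truth(vol, a)
                write_pet(gt.values, gt.voxel_size_mm, path)
            phantom_rows.append(
                {
                    "phantom_id": tag,
                    "anatomy_id": vol.anatomy_id,
                    "gm_wm_ratio": ratio,
                    "wm_activity": a.activities["WM"],
                    "gm_activity": a.activities["GM"],
                    "lesioned": False,
                    "path": str(path),
                    "seed": cell_seed,
                }
            )

    for vol in anatomies[: int(lesion_models)]:
        centers = {}
        rng = np.random.default_rng(stable_seed(seed, f"{vol.anatomy_id}_lesionloc"))
        for region in lesion_regions:
            centers[region] = choose_lesion_center(vol, region, rng)
        tag0 = f"{vol.anatomy_id}_r{lesion_ratio:g}"
        a = sample_activity_assignment(
            dist_params, lesion_ratio, np.random.default_rng(stable_seed(seed, tag0))
        )
        for volume_mm3 in lesion_volumes:
            rois = {
                region: make_lesion_roi(vol, centers[region], volume_mm3, region)
                for region in lesion_regions
            }
            for contrast in lesion_contrasts:
                tag = f"{vol.anatomy_id}_r{lesion_ratio:g}_v{volume_mm3:g}_c{contrast:g}"
                path = (
                    out / f"gt_{tag}.nii.gz" if out is not None else f"gt_{tag}.nii.gz"
                )
                gt = render_ground_truth(vol, a)
                for region in lesion_regions:
                    gt = insert_lesion(gt, rois[region], contrast)
                if write:
                    write_pet(gt.values, gt.voxel_size_mm, path)
                phantom_rows.append(
                    {
                        "phantom_id": tag,
                        "anatomy_id": vol.anatomy_id,
                        "gm_wm_ratio": lesion_ratio,
                        "wm_activity": a.activities["WM"],
                        "gm_activity": a.activities["GM"],
                        "lesioned": True,
                        "path": str(path),
                        "seed": stable_seed(seed, tag),
                    }
                )
                for region in lesion_regions:
                    roi = rois[region]
                    lesion_rows.append(
                        {
                            "phantom_id": tag,
                            "anatomy_id": vol.anatomy_id,
                            "region": region,
                            "sphere_volume_mm3": volume_mm3,
                            "contrast": contrast,
                            "realized_volume_mm3": roi.realized_volume_mm3,
                            "center_x_mm": roi.center_mm[0],
                            "center_y_mm": roi.center_mm[1],
                            "center_z_mm": roi.center_mm[2],
                        }
                    )

    manifest = DatasetManifest(
        phantoms=pd.DataFrame(phantom_rows),
        lesions=pd.DataFrame(lesion_rows),
    )
    if write:
        manifest.save(out)
    return manifest
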