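"""Procedural nine-label head anatomies and label-volume I/O.

The rest of the pipeline consumes a nine-tissue labeled head volume (gray
matter, white matter, their cerebellar counterparts, CSF, basal ganglia,
bone, air and soft tissue).  In a clinical setting such volumes come from a
segmented T1-weighted MRI; this module instead generates them procedurally
from nested ellipsoid shells so that the whole pipeline runs from a seed with
no input data, and reads/writes the same nine-label scheme as NIfTI for users
who bring their own segmentations.

Geometry convention used throughout the package: voxel ``i`` along an axis of
length ``n`` with spacing ``v`` has its center at physical coordinate
``(i - (n - 1) / 2) * v``, i.e. the origin is the field-of-view center.
Axis 0 is left-right, axis 1 posterior-anterior, axis 2 inferior-superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, FormatError

#: Fixed label codes, 0-8.  The order is part of the on-disk contract and is
#: recorded in the description field of every NIfTI header this module writes.
LABEL_SCHEME: dict[int, str] = {
    0: "AIR",
    1: "SOFT",
    2: "BONE",
    3: "CSF",
    4: "GM",
    5: "WM",
    6: "CEREB_GM",
    7: "CEREB_WM",
    8: "BG",
}

CODE: dict[str, int] = {name: code for code, name in LABEL_SCHEME.items()}

#: Labels that carry tracer activity (bone and air are activity-free).
ACTIVE_LABELS = ("WM", "GM", "CEREB_GM", "CEREB_WM", "CSF", "BG", "SOFT")

#: Brain labels used for the evaluation brain mask.
BRAIN_LABELS = ("GM", "WM", "CEREB_GM", "CEREB_WM", "BG", "CSF")

_DESCRIP = "labels 0-8: AIR,SOFT,BONE,CSF,GM,WM,CEREB_GM,CEREB_WM,BG"


@dataclass(frozen=True)
class AnatomyConfig:
    """Parameters of the nested-ellipsoid head model.

    ``head_axes_mm`` are the outer semi-axes of the scalp ellipsoid;
    ``shell_thicknesses_mm`` are the (soft tissue, bone, CSF) shell widths
    peeled off it in that order; whatever remains is brain, split into a
    cortical GM ribbon of ``cortical_thickness_mm`` around WM.  A cerebellar
    ellipsoid (semi-axes ``cerebellum_fraction`` times the brain's) with its
    own GM/WM is embedded posterior-inferiorly, separated from the cerebrum
    by a CSF gap, and ``bg_blob_spec = (count, radius_mm)`` basal-ganglia
    spheres are carved out of deep WM.  ``jitter_scale`` is the relative
    standard deviation of the seeded morphological jitter applied to the
    ellipsoid axes and ribbon thickness, giving reproducible per-subject
    variability.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_axes_mm: tuple[float, float, float] = (38.0, 45.0, 40.0)
    cortical_thickness_mm: float = 3.0
    shell_thicknesses_mm: tuple[float, float, float] = (3.0, 4.0, 2.5)
    cerebellum_fraction: float = 0.35
    cereb_gap_mm: float = 2.0
    bg_blob_spec: tuple[int, float] = (2, 5.0)
    jitter_scale: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ConfigurationError("grid_shape axes must all be >= 8")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigurationError("voxel_size_mm must be strictly positive")
        if any(a <= 0 for a in self.head_axes_mm):
            raise ConfigurationError("head_axes_mm must be strictly positive")
        if any(t <= 0 for t in self.shell_thicknesses_mm):
            raise ConfigurationError("shell_thicknesses_mm must be strictly positive")
        if self.cortical_thickness_mm < max(self.voxel_size_mm):
            raise ConfigurationError(
                "cortical_thickness_mm must be at least one voxel"
            )
        if not 0.0 < self.cerebellum_fraction < 1.0:
            raise ConfigurationError("cerebellum_fraction must lie in (0, 1)")
        if self.jitter_scale < 0:
            raise ConfigurationError("jitter_scale must be non-negative")
        count, radius = self.bg_blob_spec
        if count < 1 or radius <= 0:
            raise ConfigurationError("bg_blob_spec needs count >= 1 and radius > 0")
        # The head (plus a one-voxel air border) must fit the grid, and the
        # brain must retain a WM core after peeling shells and cortex.
        extent = [n * v / 2.0 for n, v in zip(self.grid_shape, self.voxel_size_mm)]
        for ax, ext, v in zip(self.head_axes_mm, extent, self.voxel_size_mm):
            if ax + 1.5 * v > ext:
                raise ConfigurationError(
                    f"head axis {ax} mm + air border exceeds grid half-extent {ext} mm"
                )
        peel = sum(self.shell_thicknesses_mm) + self.cortical_thickness_mm
        if min(self.head_axes_mm) - peel <= 2.0:
            raise ConfigurationError(
                "shells plus cortical ribbon leave no white-matter core; "
                "enlarge head_axes_mm or thin the shells"
            )


@dataclass
class LabelVolume:
    """A nine-label head volume on a regular grid."""

    grid: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    anatomy_id: str
    label_scheme: dict[int, str] = field(default_factory=lambda: dict(LABEL_SCHEME))
    seed: int | None = None

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the union of the named labels."""
        codes = [CODE[n] for n in names]
        return np.isin(self.grid, codes)

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers (FOV-centered)."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.grid.shape, self.voxel_size_mm)
        )


@dataclass
class ValidationReport:
    counts: dict[str, int]
    partition_ok: bool
    boundary_air_ok: bool
    empty_labels: list[str]
    total_voxels: int


def _ellipsoid(coords, center, axes) -> np.ndarray:
    x, y, z = coords
    q = (
        ((x - center[0]) / axes[0])[:, None, None] ** 2
        + ((y - center[1]) / axes[1])[None, :, None] ** 2
        + ((z - center[2]) / axes[2])[None, None, :] ** 2
    )
    return q <= 1.0


def generate_anatomy(config: AnatomyConfig) -> LabelVolume:
    """Generate a nine-label head volume from nested ellipsoid shells.

    Deterministic in ``config`` (including its seed): the seeded jitter is the
    only source of randomness.  Construction proceeds outside-in -- air, soft
    tissue, bone, CSF, cortical GM ribbon, WM -- then embeds the cerebellum
    (with a CSF gap against the cerebrum) and basal-ganglia blobs inside WM.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.jitter_scale
    axes = np.asarray(config.head_axes_mm) * (1.0 + j * rng.standard_normal(3))
    cortex = config.cortical_thickness_mm * float(
        np.clip(1.0 + j * rng.standard_normal(), 0.7, 1.3)
    )
    soft_t, bone_t, csf_t = config.shell_thicknesses_mm
    # Jitter must never thin the CSF shell below ~2 voxels, or bone could
    # become adjacent to GM; clip accordingly.
    csf_t = max(csf_t * float(np.clip(1.0 + j * rng.standard_normal(), 0.8, 1.2)),
                2.0 * max(config.voxel_size_mm))

    coords = tuple(
        (np.arange(n) - (n - 1) / 2.0) * v
        for n, v in zip(config.grid_shape, config.voxel_size_mm)
    )
    center = np.zeros(3)
    grid = np.full(config.grid_shape, CODE["AIR"], dtype=np.int16)

    bone_axes = axes - soft_t
    csf_axes = bone_axes - bone_t
    brain_axes = csf_axes - csf_t
    wm_axes = brain_axes - cortex
    grid[_ellipsoid(coords, center, axes)] = CODE["SOFT"]
    grid[_ellipsoid(coords, center, bone_axes)] = CODE["BONE"]
    grid[_ellipsoid(coords, center, csf_axes)] = CODE["CSF"]
    grid[_ellipsoid(coords, center, brain_axes)] = CODE["GM"]
    grid[_ellipsoid(coords, center, wm_axes)] = CODE["WM"]

    # Cerebellum: an ellipsoid strictly inside the brain envelope, displaced
    # posterior-inferiorly, wrapped in its own GM ribbon and a CSF gap.
    frac = config.cerebellum_fraction
    cereb_axes = brain_axes * frac
    direction = np.array([0.0, -1.0, -1.0]) / np.sqrt(2.0)
    cereb_center = brain_axes * direction * max(1.0 - frac - 0.06, 0.0)
    gap = _ellipsoid(coords, cereb_center, cereb_axes + config.cereb_gap_mm)
    brain_tissue = (grid == CODE["GM"]) | (grid == CODE["WM"])
    grid[gap & brain_tissue] = CODE["CSF"]
    grid[_ellipsoid(coords, cereb_center, cereb_axes)] = CODE["CEREB_GM"]
    cereb_wm_axes = np.maximum(cereb_axes - cortex, 0.5)
    grid[_ellipsoid(coords, cereb_center, cereb_wm_axes)] = CODE["CEREB_WM"]

    # Basal-ganglia blobs in deep white matter, mirrored left/right.
    count, radius = config.bg_blob_spec
    for i in range(count):
        side = 1.0 if i % 2 == 0 else -1.0
        offset = np.array([side * 0.35, 0.1, 0.0]) * wm_axes
        offset += j * radius * rng.standard_normal(3)
        blob = _ellipsoid(coords, offset, np.full(3, radius))
        grid[blob & (grid == CODE["WM"])] = CODE["BG"]

    return LabelVolume(
        grid=grid,
        voxel_size_mm=tuple(float(v) for v in config.voxel_size_mm),
        anatomy_id=f"anat{config.seed:05d}",
        seed=config.seed,
    )


def validate_labels(vol: LabelVolume) -> ValidationReport:
    """Report per-label counts, the partition check and the boundary-air check.

    Never raises and never mutates its input; callers decide what to do with
    a failing report.
    """
    grid = vol.grid
    counts = {
        name: int(np.count_nonzero(grid == code))
        for code, name in vol.label_scheme.items()
    }
    known = int(sum(counts.values()))
    total = int(grid.size)
    boundary = np.concatenate(
        [
            np.asarray(grid[sl]).ravel()
            for sl in (
                np.s_[0, :, :], np.s_[-1, :, :],
                np.s_[:, 0, :], np.s_[:, -1, :],
                np.s_[:, :, 0], np.s_[:, :, -1],
            )
        ]
    )
    return ValidationReport(
        counts=counts,
        partition_ok=bool(known == total and np.issubdtype(grid.dtype, np.integer)),
        boundary_air_ok=bool(np.all(boundary == CODE["AIR"])),
        empty_labels=[name for name, c in counts.items() if c == 0],
        total_voxels=total,
    )


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a label volume as integer NIfTI with an RAS diagonal affine."""
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol.grid.astype(np.int16), affine)
    img.header["descrip"] = _DESCRIP.encode()
    nib.save(img, str(path))


def read_label_volume(path, label_scheme: dict[int, str] | None = None) -> LabelVolume:
    """Read a nine-label NIfTI volume, validating its codes.

    Raises :class:`FormatError` for non-integer data or codes outside the
    scheme (listing the offending codes).  Labels that are merely absent are
    reported by :func:`validate_labels`, which is run automatically; the
    report is attached to the returned volume as ``validation``.
    """
    scheme = dict(label_scheme or LABEL_SCHEME)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise FormatError(f"{path}: label volume has non-integer data")
        data = np.round(data).astype(np.int16)
    codes = np.unique(data)
    unknown = sorted(int(c) for c in codes if int(c) not in scheme)
    if unknown:
        raise FormatError(f"{path}: unknown label codes {unknown}")
    zooms = img.header.get_zooms()[:3]
    from pathlib import Path

    vol = LabelVolume(
        grid=data.astype(np.int16),
        voxel_size_mm=tuple(float(z) for z in zooms),
        anatomy_id=Path(str(path)).name.split(".")[0],
        label_scheme=scheme,
    )
    vol.validation = validate_labels(vol)  # type: ignore[attr-defined]
    return vol


def jittered_configs(base: AnatomyConfig, n: int, seed: int) -> list[AnatomyConfig]:
    """``n`` anatomy configs differing only by seed, derived from ``seed``."""
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    return [replace(base, seed=int(s)) for s in seeds]


def cortical_thickness_estimate(vol: LabelVolume) -> float:
    """Mean cortical-ribbon thickness from Euclidean distance transforms.

    For each cerebral GM voxel the depth to the outer (CSF) side plus the
    depth to the inner (WM) side minus one voxel equals the ribbon thickness
    exactly on a flat slab and approximately on a curved ribbon.
    """
    gm = vol.grid == CODE["GM"]
    sampling = vol.voxel_size_mm
    d_out = ndimage.distance_transform_edt(vol.grid != CODE["CSF"], sampling=sampling)
    inner = (vol.grid != CODE["WM"]) & (vol.grid != CODE["BG"])
    d_in = ndimage.distance_transform_edt(inner, sampling=sampling)
    mean_vox = float(np.mean(d_out[gm] + d_in[gm])) - float(np.mean(sampling))
    return mean_vox
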