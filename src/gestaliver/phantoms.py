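"""Synthetic abdominal phantoms with known ground-truth tissue labels.

The phantom is 2.5D: every axial slice shares the same topology (elliptical
body cross-section, peripheral subcutaneous fat ring, muscle wall, interior
organ compartment, scattered visceral fat blobs) while the body outline
varies slowly along the axial axis. Intensities follow the T1 ordering
adipose > organ > muscle > background, with a multiplicative smooth bias
field and additive Gaussian noise, so that every downstream segmentation
stage can be scored against exact voxel-level truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import ImageVolume, LabelVolume, SAT, VAT, MUSCLE, ORGAN, UNLABELED
from .volumetrics import SliceROISeries

__all__ = [
    "PhantomSpec",
    "ExclusionMasks",
    "AbdomenPhantom",
    "make_abdomen_phantom",
    "make_seed_labels",
    "make_liver_slice_stack",
]


@dataclass
class PhantomSpec:
    """Geometry, intensity, and corruption parameters of an abdomen phantom."""

    shape: tuple[int, int, int] = (160, 160, 30)
    spacing: tuple[float, float, float] = (1.25, 1.25, 6.0)
    body_radii_mm: tuple[float, float] = (90.0, 70.0)
    sat_thickness_mm: float = 12.0
    muscle_thickness_mm: float = 8.0
    vat_blob_count: int = 12
    vat_blob_radius_mm: tuple[float, float] = (5.0, 12.0)
    vat_clearance_mm: float = 6.0
    include_liver: bool = True
    include_uterus: bool = True
    #: class mean intensities; adipose must be brightest
    mean_background: float = 10.0
    mean_muscle: float = 80.0
    mean_organ: float = 120.0
    mean_adipose: float = 200.0
    #: bright interior regions that mimic adipose false positives
    mean_liver: float = 160.0
    mean_uterus: float = 195.0
    noise_sd: float = 0.0
    bias_amplitude: float = 0.0
    bias_smoothness_mm: float = 60.0
    #: fractional shrinkage of the body outline at the axial ends
    axial_taper: float = 0.15
    two_stations: bool = False
    station_overlap_slices: int = 4
    seed: int = 0

    def validate(self) -> None:
        if min(self.shape) < 1:
            raise ValueError("shape must be >= 1 per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.sat_thickness_mm <= 0 or self.muscle_thickness_mm <= 0:
            raise ValueError("layer thicknesses must be positive")
        shell = self.sat_thickness_mm + self.muscle_thickness_mm
        if shell >= min(self.body_radii_mm) * (1.0 - self.axial_taper):
            raise ValueError(
                f"SAT+muscle shell ({shell} mm) is thicker than the tapered body "
                f"radius; no interior remains"
            )
        if not (self.mean_adipose > self.mean_organ > self.mean_muscle > self.mean_background):
            raise ValueError("class means must satisfy adipose > organ > muscle > background")
        if self.vat_blob_radius_mm[0] <= 0 or self.vat_blob_radius_mm[0] > self.vat_blob_radius_mm[1]:
            raise ValueError("vat_blob_radius_mm must be a positive (lo, hi) range")
        if not 0 <= self.axial_taper < 1:
            raise ValueError("axial_taper must be in [0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        raw = json.loads(Path(path).read_text())
        for key in ("shape", "spacing", "body_radii_mm", "vat_blob_radius_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ExclusionMasks:
    """Binary uterus/liver masks used to correct adipose false positives."""

    uterus: np.ndarray
    liver: np.ndarray

    def union(self) -> np.ndarray:
        return self.uterus | self.liver


@dataclass
class AbdomenPhantom:
    """Bundle returned by :func:`make_abdomen_phantom`."""

    image: ImageVolume
    truth: LabelVolume
    bias: ImageVolume
    exclusion: ExclusionMasks
    body_mask: np.ndarray
    #: list of (center_mm (3,), radii_mm (3,)) of the accepted VAT blobs
    vat_blobs: list[tuple[np.ndarray, np.ndarray]]
    spec: PhantomSpec


def _grid_coords_mm(shape, spacing):
    """Voxel-center world coordinates, xy centered on the grid, z from 0."""
    nx, ny, nz = shape
    sx, sy, sz = spacing
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    z = np.arange(nz) * sz
    return np.meshgrid(x, y, z, indexing="ij")


def _ellipse_stack(xg, yg, taper_scale, rx, ry, margin=0.0):
    """Per-slice elliptical membership with an inward margin (mm)."""
    rxk = np.maximum(rx * taper_scale - margin, 1e-9)
    ryk = np.maximum(ry * taper_scale - margin, 1e-9)
    return (xg / rxk) ** 2 + (yg / ryk) ** 2 <= 1.0


def _ellipsoid_mask(xg, yg, zg, center, radii):
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((xg - cx) / rx) ** 2 + ((yg - cy) / ry) ** 2 + ((zg - cz) / rz) ** 2 <= 1.0


def _smooth_bias_field(shape, spacing, amplitude, smoothness_mm, rng, support=None):
    """Multiplicative field 1 + a*u with max |u| = 1 over the support mask."""
    if amplitude == 0:
        return np.ones(shape)
    raw = rng.standard_normal(shape)
    sigma_vox = [max(smoothness_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(raw, sigma=sigma_vox, mode="nearest")
    region = smooth[support] if support is not None and support.any() else smooth
    peak = np.max(np.abs(region))
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * smooth / peak


def make_abdomen_phantom(spec: PhantomSpec) -> AbdomenPhantom:
    """Generate an abdomen phantom with ground truth, bias field, and masks.

    Intensity model: ``image = class_mean_map * bias_field + noise`` with
    the liver/uterus interior regions overriding the organ mean so they act
    as bright adipose false positives for the exclusion-mask stage.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    xg, yg, zg = _grid_coords_mm(spec.shape, spec.spacing)
    rx, ry = spec.body_radii_mm

    # slow axial variation of the body outline
    if nz > 1:
        t = np.linspace(-1.0, 1.0, nz)
    else:
        t = np.zeros(1)
    taper = 1.0 - spec.axial_taper * t**2
    taper3 = taper[None, None, :]

    body = _ellipse_stack(xg, yg, taper3, rx, ry)
    inner_sat = _ellipse_stack(xg, yg, taper3, rx, ry, margin=spec.sat_thickness_mm)
    inner_muscle = _ellipse_stack(
        xg, yg, taper3, rx, ry, margin=spec.sat_thickness_mm + spec.muscle_thickness_mm
    )

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[body & ~inner_sat] = SAT
    labels[inner_sat & ~inner_muscle] = MUSCLE
    labels[inner_muscle] = ORGAN

    clear = spec.vat_clearance_mm
    interior_core = _ellipse_stack(
        xg, yg, taper3, rx, ry,
        margin=spec.sat_thickness_mm + spec.muscle_thickness_mm + clear,
    )

    # interior organ sub-regions, sized relative to the mid-slice interior
    rx_in = rx - spec.sat_thickness_mm - spec.muscle_thickness_mm
    ry_in = ry - spec.sat_thickness_mm - spec.muscle_thickness_mm
    lz = (nz - 1) * spec.spacing[2] if nz > 1 else spec.spacing[2]
    liver_mask = np.zeros(spec.shape, dtype=bool)
    uterus_mask = np.zeros(spec.shape, dtype=bool)
    if spec.include_liver:
        liver_mask = _ellipsoid_mask(
            xg, yg, zg,
            center=(0.35 * rx_in, 0.10 * ry_in, 0.80 * lz),
            radii=(0.42 * rx_in, 0.45 * ry_in, max(0.30 * lz, spec.spacing[2])),
        ) & inner_muscle
    if spec.include_uterus:
        uterus_mask = _ellipsoid_mask(
            xg, yg, zg,
            center=(-0.30 * rx_in, -0.25 * ry_in, 0.20 * lz),
            radii=(0.35 * rx_in, 0.35 * ry_in, max(0.25 * lz, spec.spacing[2])),
        ) & inner_muscle

    forbidden = ndimage.binary_dilation(
        liver_mask | uterus_mask,
        iterations=max(1, int(round(clear / min(spec.spacing[:2])))),
    )
    allowed = interior_core & ~forbidden

    # rejection-sample VAT blob ellipsoids fully inside the allowed region
    vat = np.zeros(spec.shape, dtype=bool)
    blobs: list[tuple[np.ndarray, np.ndarray]] = []
    lo, hi = spec.vat_blob_radius_mm
    allowed_idx = np.argwhere(allowed)
    attempts = 0
    max_attempts = 200 * max(spec.vat_blob_count, 1)
    while len(blobs) < spec.vat_blob_count and attempts < max_attempts and allowed_idx.size:
        attempts += 1
        i, j, k = allowed_idx[rng.integers(len(allowed_idx))]
        center = np.array([xg[i, j, k], yg[i, j, k], zg[i, j, k]])
        radii = np.array([
            rng.uniform(lo, hi),
            rng.uniform(lo, hi),
            rng.uniform(max(lo, spec.spacing[2] * 0.8), hi * 1.2),
        ])
        cand = _ellipsoid_mask(xg, yg, zg, center, radii)
        if not cand.any() or not np.all(allowed[cand]):
            continue
        vat |= cand
        blobs.append((center, radii))

    labels[vat] = VAT

    means = np.array(
        [spec.mean_background, spec.mean_adipose, spec.mean_adipose, spec.mean_muscle, spec.mean_organ]
    )
    intensity = means[labels]
    intensity[liver_mask & (labels == ORGAN)] = spec.mean_liver
    intensity[uterus_mask & (labels == ORGAN)] = spec.mean_uterus

    bias = _smooth_bias_field(
        spec.shape, spec.spacing, spec.bias_amplitude, spec.bias_smoothness_mm, rng, support=body
    )
    image = intensity * bias
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    return AbdomenPhantom(
        image=ImageVolume(image, spec.spacing),
        truth=LabelVolume(labels, spec.spacing),
        bias=ImageVolume(bias, spec.spacing),
        exclusion=ExclusionMasks(uterus=uterus_mask, liver=liver_mask),
        body_mask=body,
        vat_blobs=blobs,
        spec=spec,
    )


def make_seed_labels(
    truth: LabelVolume, slice_indices, erosion_radius: int = 1
) -> LabelVolume:
    """Sparse seed map: ground-truth classes on selected axial slices only.

    Emulates a manual few-slice segmentation used to seed the watershed;
    each class is eroded in-plane so seeds sit away from true boundaries.
    """
    seeds = np.zeros(truth.shape, dtype=np.int16)
    struct = ndimage.generate_binary_structure(2, 1)
    for k in slice_indices:
        if not 0 <= k < truth.shape[2]:
            raise IndexError(f"slice index {k} outside axial range 0..{truth.shape[2] - 1}")
        for code in (SAT, VAT, MUSCLE, ORGAN):
            m = truth.labels[:, :, k] == code
            if erosion_radius > 0:
                m = ndimage.binary_erosion(m, structure=struct, iterations=erosion_radius)
            seeds[:, :, k][m] = code
    return LabelVolume(seeds, truth.spacing, truth.origin)


def make_liver_slice_stack(
    target_volume_cm3: float,
    n_slices: int,
    interval_cm: float,
    shape_profile: str = "ellipsoid",
    seed: int | None = None,
    stage: str | None = None,
    jitter: float = 0.10,
) -> SliceROISeries:
    """Per-slice liver ROI areas whose slice-summation volume hits the target.

    ``shape_profile`` is ``"uniform"`` (equal areas) or ``"ellipsoid"``
    (parabolic area profile, like slicing an ellipsoid). With a seed, a
    smooth multiplicative perturbation of relative size ``jitter`` is
    applied before the exact renormalization, so stacks differ between
    participants while conserving the target volume to < 0.1%.
    """
    if target_volume_cm3 <= 0:
        raise ValueError(f"target volume must be positive, got {target_volume_cm3}")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if interval_cm <= 0:
        raise ValueError("interval must be positive")

    if shape_profile == "uniform":
        profile = np.ones(n_slices)
    elif shape_profile == "ellipsoid":
        if n_slices == 1:
            profile = np.ones(1)
        else:
            u = np.linspace(-1.0, 1.0, n_slices)
            profile = 1.0 - 0.9 * u**2
    else:
        raise ValueError(f"unknown shape_profile {shape_profile!r}")

    if seed is not None and n_slices > 1 and jitter > 0:
        rng = np.random.default_rng(seed)
        rough = rng.standard_normal(n_slices)
        smooth = ndimage.gaussian_filter1d(rough, sigma=max(n_slices / 10.0, 1.0))
        peak = np.max(np.abs(smooth))
        if peak > 0:
            profile = profile * (1.0 + jitter * smooth / peak)
    profile = np.clip(profile, 1e-9, None)

    areas = profile * (target_volume_cm3 / (profile.sum() * interval_cm))
    return SliceROISeries(areas=areas, interval_cm=interval_cm, stage=stage)
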