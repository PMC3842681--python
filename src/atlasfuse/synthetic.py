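"""Synthetic phantoms and deformed-atlas ensembles.

Deformable registration of real atlases is replaced by forward simulation:
a phantom target (an ellipsoid-union structure in textured noise) is warped
by random smooth displacement fields — a stand-in for B-spline registration
output — to produce an ensemble of segmentation proposals whose quality is
controlled by the displacement magnitude.  Image noise is coupled to the
displacement so that image similarity in the structure's neighborhood is
statistically informative about segmentation quality, the premise the
probabilistic weighting model relies on.  Because the deformations are
known, every ensemble carries its ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .distance_maps import signed_distance
from .metrics import dice
from .volumes_io import AtlasProposal, BinaryMask, GridGeometry, ImageVolume

__all__ = [
    "PhantomSpec",
    "DeformationSpec",
    "make_phantom",
    "smooth_displacement_field",
    "apply_deformation",
    "make_ensemble",
    "default_noise_policy",
]

Ellipsoid = tuple[tuple[float, float, float], tuple[float, float, float]]


@dataclass(frozen=True)
class PhantomSpec:
    """A phantom target: 1-3 ellipsoids (an elongated node-like structure)
    over correlated background texture plus white observation noise.

    ``ellipsoids`` is a tuple of (center_mm, semi_axes_mm) pairs; intensities
    are in arbitrary units with ``contrast`` separating structure from
    background.  The structure must keep >= 5 mm clearance from the grid
    boundary.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ellipsoids: tuple[Ellipsoid, ...] = (
        ((31.5, 26.5, 24.5), (14.0, 12.0, 10.0)),
        ((31.5, 38.5, 38.5), (14.0, 12.0, 10.0)),
    )
    contrast: float = 25.0
    texture_amplitude: float = 30.0
    texture_corr_mm: float = 30.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ellipsoids or len(self.ellipsoids) > 3:
            raise ValueError("PhantomSpec requires 1-3 ellipsoids")
        for center, axes in self.ellipsoids:
            if any(a <= 0 for a in axes):
                raise ValueError("ellipsoid semi-axes must be positive")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(shape=self.shape, spacing=self.spacing)


@dataclass(frozen=True)
class DeformationSpec:
    """A random smooth displacement field emulating B-spline registration error.

    Independent normal displacements (``displacement_sigma_mm`` per axis) on a
    coarse control-point lattice (``control_point_spacing_mm``) are cubic-spline
    interpolated to the voxel grid; ``intensity_noise_sigma`` is added to the
    warped image.
    """

    control_point_spacing_mm: float = 16.0
    displacement_sigma_mm: float | tuple[float, float, float] = 2.0
    intensity_noise_sigma: float = 0.0
    seed: int = 0

    def sigma_per_axis(self) -> tuple[float, float, float]:
        s = self.displacement_sigma_mm
        if np.isscalar(s):
            s = (float(s),) * 3
        if any(v < 0 for v in s):
            raise ValueError("displacement sigma must be nonnegative")
        return tuple(float(v) for v in s)


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask]:
    """Deterministically render the phantom image and ground-truth mask.

    Mask membership uses the voxel-center rule (center inside the ellipsoid
    union); the image is ``contrast * mask + texture + white noise``.
    """
    geom = spec.geometry
    extent = [(n - 1) * s for n, s in zip(geom.shape, geom.spacing)]
    for center, axes in spec.ellipsoids:
        for a in range(3):
            lo, hi = center[a] - axes[a], center[a] + axes[a]
            if lo < 5.0 or hi > extent[a] - 5.0:
                raise ValueError(
                    f"ellipsoid at {center} with semi-axes {axes} violates the "
                    f"5 mm clearance on axis {a} (grid extent {extent[a]:.1f} mm)"
                )

    zz, yy, xx = geom.voxel_centers()
    member = np.zeros(geom.shape, dtype=bool)
    for (c0, c1, c2), (a0, a1, a2) in spec.ellipsoids:
        member |= ((zz - c0) / a0) ** 2 + ((yy - c1) / a1) ** 2 + ((xx - c2) / a2) ** 2 <= 1.0

    rng = np.random.default_rng(spec.seed)
    image = spec.contrast * member.astype(np.float64)
    if spec.texture_amplitude > 0:
        sigma_vox = [spec.texture_corr_mm / s for s in geom.spacing]
        texture = ndimage.gaussian_filter(rng.standard_normal(geom.shape), sigma_vox)
        std = texture.std()
        if std > 0:
            image += spec.texture_amplitude * texture / std
    # noise is drawn even at sigma 0 so specs differing only in noise_sigma
    # share the same texture realization for a given seed
    image += spec.noise_sigma * rng.standard_normal(geom.shape)
    return ImageVolume(geom, image), BinaryMask(geom, member)


def smooth_displacement_field(spec: DeformationSpec, geometry: GridGeometry) -> np.ndarray:
    """Sample a smooth random displacement field, in mm, shape (3, *grid).

    Control-point displacements are i.i.d. N(0, sigma_axis^2); cubic-spline
    interpolation to the voxel grid keeps the field smooth and zero-mean in
    expectation.  Deterministic given the spec's seed.
    """
    cp = spec.control_point_spacing_mm
    if cp < 2 * max(geometry.spacing):
        raise ValueError("control-point spacing must be >= 2x voxel spacing")
    sigmas = spec.sigma_per_axis()
    field_arr = np.zeros((3,) + geometry.shape, dtype=np.float64)
    if all(s == 0 for s in sigmas):
        return field_arr
    rng = np.random.default_rng(spec.seed)
    # control lattice covers the grid with one extra point of margin each side
    n_cp = [int(np.ceil((n - 1) * sp / cp)) + 3 for n, sp in zip(geometry.shape, geometry.spacing)]
    # voxel-center positions in control-lattice coordinates (offset by the margin point)
    coords = np.meshgrid(
        *[np.arange(n) * sp / cp + 1.0 for n, sp in zip(geometry.shape, geometry.spacing)],
        indexing="ij",
    )
    for axis in range(3):
        control = rng.normal(0.0, sigmas[axis], size=n_cp)
        field_arr[axis] = ndimage.map_coordinates(control, coords, order=3, mode="nearest")
    return field_arr


def apply_deformation(
    image: ImageVolume,
    mask: BinaryMask,
    field_mm: np.ndarray,
    atlas_id: str = "warped",
    intensity_noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> AtlasProposal:
    """Warp an image/mask pair by backward mapping with the given field.

    At each output voxel the input is sampled (trilinear) at
    ``center + field``.  The mask is warped through its signed distance map
    and re-thresholded at < 0, which avoids the aliasing of nearest-neighbor
    label warping.  Samples outside the grid take the background intensity
    (0) for the image and a large positive distance for the mask.
    """
    geom = image.geometry
    if field_mm.shape != (3,) + geom.shape:
        raise ValueError(f"field shape {field_mm.shape} != (3, *{geom.shape})")
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in geom.shape], indexing="ij")
    sample = [idx[a] + field_mm[a] / geom.spacing[a] for a in range(3)]

    warped_img = ndimage.map_coordinates(
        image.intensities.astype(np.float64), sample, order=1, mode="constant", cval=0.0
    )
    if intensity_noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        warped_img += intensity_noise_sigma * rng.standard_normal(geom.shape)

    sdm = signed_distance(mask)
    far_outside = geom.diagonal_mm + 1.0
    warped_sdm = ndimage.map_coordinates(
        sdm.value, sample, order=1, mode="constant", cval=far_outside
    )
    warped_mask = warped_sdm < 0
    if not warped_mask.any():
        warnings.warn(f"proposal {atlas_id!r}: warped mask is empty", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # AtlasProposal re-warns on empty masks
        return AtlasProposal(
            atlas_id=atlas_id,
            image=ImageVolume(geom, warped_img),
            mask=BinaryMask(geom, warped_mask),
        )


def default_noise_policy(sigma_mm: float) -> float:
    """Image-noise sigma coupled linearly to deformation magnitude.

    Worse registrations produce noisier (less target-like) images, so local
    image similarity carries information about segmentation quality.  The
    coupling is kept mild — a fraction of the observation noise floor — so
    image decorrelation remains dominated by the misalignment itself.
    """
    return 0.5 + 0.25 * sigma_mm


def make_ensemble(
    phantom: PhantomSpec,
    n_atlases: int = 15,
    quality_spread: Sequence[float] | None = None,
    intensity_noise_policy: Callable[[float], float] = default_noise_policy,
    control_point_spacing_mm: float = 16.0,
    anatomy_sigma_mm: float = 3.0,
) -> tuple[ImageVolume, BinaryMask, list[AtlasProposal], pd.DataFrame]:
    """Generate a target, its ground truth, and N deformed atlas proposals.

    ``quality_spread`` gives each proposal's registration-error sigma in mm
    (default: drawn uniformly from [1, 8], the assumed registration-error
    range); ``intensity_noise_policy`` maps that sigma to the image-noise
    sigma added after warping.

    Each proposal's mask is additionally warped by an independent
    anatomy-difference field (``anatomy_sigma_mm``) that does not touch the
    proposal image.  This mirrors how deformable registration behaves in
    homogeneous soft tissue: intensities are aligned almost perfectly (the
    aperture problem leaves nothing for image similarity to see), while the
    structure inherited from a different subject keeps an irreducible shape
    error.  Image similarity therefore ranks the registration-error
    component statistically, not deterministically, and even the
    best-scoring proposals disagree with one another — the premise under
    which similarity-weighted shape averaging operates.

    Returns the manifest DataFrame with per-proposal sigma, noise and DSC
    to truth.  Fully determined by ``phantom.seed``.
    """
    if n_atlases < 1:
        raise ValueError("n_atlases must be >= 1")
    if anatomy_sigma_mm < 0:
        raise ValueError("anatomy_sigma_mm must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([phantom.seed, 0xA71A5]))
    if quality_spread is None:
        quality_spread = rng.uniform(1.0, 8.0, size=n_atlases)
    quality_spread = [float(s) for s in quality_spread]
    if len(quality_spread) != n_atlases:
        raise ValueError("quality_spread must have one sigma per atlas")

    target, truth = make_phantom(phantom)
    # Proposal images are warps of the noise-free phantom plus their own
    # independent acquisition noise: a deformed atlas never shares the
    # target's observation-noise realization, so a well-registered proposal
    # cannot score a spuriously perfect NCC through common noise voxels.
    clean, _ = make_phantom(replace(phantom, noise_sigma=0.0))
    proposals: list[AtlasProposal] = []
    rows = []
    for i, sigma in enumerate(quality_spread):
        reg_spec = DeformationSpec(
            control_point_spacing_mm=control_point_spacing_mm,
            displacement_sigma_mm=sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        anat_spec = DeformationSpec(
            control_point_spacing_mm=control_point_spacing_mm,
            displacement_sigma_mm=anatomy_sigma_mm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        reg_field = smooth_displacement_field(reg_spec, phantom.geometry)
        anat_field = smooth_displacement_field(anat_spec, phantom.geometry)
        noise = float(intensity_noise_policy(sigma))
        image_warp = apply_deformation(
            clean,
            truth,
            reg_field,
            atlas_id=f"atlas_{i:02d}",
            intensity_noise_sigma=noise,
            rng=rng,
        )
        mask_warp = apply_deformation(
            clean, truth, reg_field + anat_field, atlas_id=f"atlas_{i:02d}"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-mask warning already raised above
            proposal = AtlasProposal(
                atlas_id=f"atlas_{i:02d}", image=image_warp.image, mask=mask_warp.mask
            )
        proposals.append(proposal)
        rows.append(
            {
                "atlas_id": proposal.atlas_id,
                "displacement_sigma_mm": sigma,
                "intensity_noise_sigma": noise,
                "dsc_to_truth": dice(proposal.mask, truth),
            }
        )
    manifest = pd.DataFrame(rows)
    return target, truth, proposals, manifest
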