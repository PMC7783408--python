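"""Synthetic rat-brain phantoms with ground-truth lesion masks.

The real pre-clinical T2-weighted data this package targets cannot be
redistributed, so every downstream stage (training, post-processing,
evaluation) is exercised on phantoms generated here.  A phantom is an
ellipsoidal "brain" of homogeneous tissue inside a dark background,
carrying a unilateral hyperintense lesion — the appearance of an
ischemic lesion after middle cerebral artery occlusion, which is
confined to one hemisphere.  Lesions are unions of a few smoothed
spheroids, thresholded back to a binary mask; intensities are
piecewise-constant tissue classes plus additive Gaussian noise.

The default grid is a desk-scale 64 x 64 x 18 with the acquisition-like
anisotropic spacing (0.117, 0.117, 1.0) mm — 256 x 256 in-plane
matrices are available through the config.

:func:`corrupt_mask` injects disconnected foreground *islands* and
enclosed background *holes* of exactly requested voxel counts into a
clean mask, producing the fixtures against which connected-component
post-processing is validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from lesionseg.errors import InvalidConfigError, PlacementError
from lesionseg.volume_io import SegmentationMask, VolumeImage, save_volume

__all__ = [
    "PhantomConfig",
    "CorruptionPlan",
    "generate_phantom",
    "corrupt_mask",
    "generate_dataset",
    "write_dataset",
]

# 26-connectivity structuring element for foreground components
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
# 6-connectivity (face-adjacency) for background components
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class PhantomConfig:
    """Parameters of one synthetic brain volume.

    Attributes
    ----------
    grid_shape
        Voxels per axis, (x, y, z); x is the left-right axis.
    spacing
        mm per voxel, matching the anisotropic acquisition geometry
        (thin in-plane voxels, 1 mm slices) by default.
    brain_semiaxes
        Semi-axes of the brain ellipsoid in mm.
    lesion_count_range
        Inclusive interval for the number of lesion spheroids; ``(0, 0)``
        produces a sham-like volume with an empty mask.
    lesion_radius_range
        Inclusive interval for spheroid radii in mm.
    lesion_contrast
        Intensity offset of lesion over brain tissue (> 0: lesions are
        T2-hyperintense).
    noise_sigma
        Standard deviation of the additive Gaussian noise.
    smoothing_sigma
        mm; Gaussian smoothing of the lesion indicator before
        re-thresholding, which rounds and mildly irregularizes lesion
        boundaries.  0 disables it.
    hemisphere
        ``"left"`` or ``"right"``: the half of the x axis lesions are
        confined to.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 18)
    spacing: tuple[float, float, float] = (0.117, 0.117, 1.0)
    brain_semiaxes: tuple[float, float, float] = (3.2, 3.2, 7.5)
    lesion_count_range: tuple[int, int] = (1, 4)
    lesion_radius_range: tuple[float, float] = (0.7, 1.5)
    lesion_contrast: float = 4.0
    noise_sigma: float = 1.0
    smoothing_sigma: float = 0.15
    hemisphere: str = "right"
    brain_intensity: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.grid_shape) != 3 or any(g <= 0 for g in self.grid_shape):
            raise InvalidConfigError(f"grid_shape must be 3 positive ints: {self.grid_shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidConfigError(f"spacing must be 3 positive reals: {self.spacing}")
        if any(a <= 0 for a in self.brain_semiaxes):
            raise InvalidConfigError("brain_semiaxes must be positive")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise InvalidConfigError(f"bad lesion_count_range {self.lesion_count_range}")
        rlo, rhi = self.lesion_radius_range
        if rlo <= 0 or rhi < rlo:
            raise InvalidConfigError(f"bad lesion_radius_range {self.lesion_radius_range}")
        if self.lesion_contrast <= 0:
            raise InvalidConfigError("lesion_contrast must be > 0 (lesions are hyperintense)")
        if self.noise_sigma < 0 or self.smoothing_sigma < 0:
            raise InvalidConfigError("noise_sigma and smoothing_sigma must be >= 0")
        if self.hemisphere not in ("left", "right"):
            raise InvalidConfigError(f"hemisphere must be 'left' or 'right': {self.hemisphere}")


@dataclass
class CorruptionPlan:
    """Defects to inject into a clean mask: exact voxel counts per defect."""

    island_sizes: list[int] = field(default_factory=list)
    hole_sizes: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.island_sizes = [int(s) for s in self.island_sizes]
        self.hole_sizes = [int(s) for s in self.hole_sizes]
        if any(s < 1 for s in self.island_sizes + self.hole_sizes):
            raise InvalidConfigError("defect sizes must be positive integers")


def _coordinate_grids(shape, spacing):
    """Physical (mm) coordinates of voxel centers, origin at the grid center."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(config: PhantomConfig) -> tuple[VolumeImage, SegmentationMask]:
    """Generate one synthetic brain volume and its lesion mask.

    Deterministic: the same config (including its seed) always yields a
    bit-identical pair.

    Returns
    -------
    (VolumeImage, SegmentationMask)
        Image and mask share the grid and spacing.  Before noise, lesion
        voxels sit exactly ``lesion_contrast`` above brain tissue.

    Raises
    ------
    InvalidConfigError
        If the brain ellipsoid covers no voxel of the grid.
    """
    rng = np.random.default_rng(config.seed)
    shape, spacing = config.grid_shape, config.spacing
    xs, ys, zs = _coordinate_grids(shape, spacing)
    a, b, c = config.brain_semiaxes
    brain = (xs / a) ** 2 + (ys / b) ** 2 + (zs / c) ** 2 <= 1.0
    if not brain.any():
        raise InvalidConfigError("brain ellipsoid does not intersect the voxel grid")

    n_lo, n_hi = config.lesion_count_range
    n_lesions = int(rng.integers(n_lo, n_hi + 1))

    # Unilateral: restrict to the requested half of the x (left-right) axis.
    if config.hemisphere == "right":
        hemi = xs > 0
    else:
        hemi = xs < 0

    lesion = np.zeros(shape, dtype=bool)
    for _ in range(n_lesions):
        r = rng.uniform(*config.lesion_radius_range)
        # seed the spheroid center inside the lesion-eligible brain half,
        # pulled toward the hemisphere interior so blobs survive clipping
        sign = 1.0 if config.hemisphere == "right" else -1.0
        cx = sign * rng.uniform(0.25 * a, 0.7 * a)
        cy = rng.uniform(-0.5 * b, 0.5 * b)
        cz = rng.uniform(-0.6 * c, 0.6 * c)
        # mild random anisotropy of the spheroid
        sx, sy, sz = r * rng.uniform(0.7, 1.3, size=3)
        blob = ((xs - cx) / sx) ** 2 + ((ys - cy) / sy) ** 2 + ((zs - cz) / sz) ** 2 <= 1.0
        lesion |= blob

    if config.smoothing_sigma > 0 and lesion.any():
        sig_vox = [config.smoothing_sigma / s for s in spacing]
        smoothed = ndimage.gaussian_filter(lesion.astype(np.float32), sigma=sig_vox)
        lesion = smoothed > 0.5

    lesion &= brain & hemi

    image = np.zeros(shape, dtype=np.float32)
    image[brain] = config.brain_intensity
    image[lesion] += config.lesion_contrast
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=shape).astype(np.float32)

    vol = VolumeImage(data=image.astype(np.float32), spacing=spacing)
    mask = SegmentationMask(data=lesion.astype(np.uint8), spacing=spacing)
    return vol, mask


def generate_dataset(
    n: int, config: PhantomConfig, seed: int
) -> list[tuple[VolumeImage, SegmentationMask]]:
    """Generate ``n`` independent phantoms with per-item derived seeds.

    Item ``i`` uses ``seed + i`` on top of the shared config, so the
    dataset is deterministic given ``(n, config, seed)``.
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    items = []
    for i in range(n):
        cfg_i = PhantomConfig(**{**asdict(config), "seed": int(seed) + i})
        items.append(generate_phantom(cfg_i))
    return items


def write_dataset(
    n: int, config: PhantomConfig, seed: int, out_dir: str | Path
) -> list[dict]:
    """Generate a dataset and write it as paired NIfTI files plus a JSON sidecar.

    Returns the manifest entries (paths and per-item seeds).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (vol, mask) in enumerate(generate_dataset(n, config, seed)):
        img_path = out / f"phantom_{i:03d}_img.nii.gz"
        msk_path = out / f"phantom_{i:03d}_mask.nii.gz"
        save_volume(vol, img_path)
        save_volume(mask, msk_path)
        entries.append(
            {"image": img_path.name, "mask": msk_path.name, "seed": int(seed) + i}
        )
    sidecar = {"n": n, "seed": int(seed), "config": asdict(config), "items": entries}
    (out / "manifest.json").write_text(json.dumps(sidecar, indent=2))
    return entries


# ---------------------------------------------------------------------------
# mask corruption


def _grow_component(
    allowed: np.ndarray, size: int, rng: np.random.Generator, struct: np.ndarray
) -> np.ndarray | None:
    """Grow a connected voxel set of exactly ``size`` inside ``allowed``.

    Breadth-first growth from a random seed voxel, adding random eligible
    neighbors (under ``struct`` connectivity) until the target size is
    reached.  Returns a boolean mask, or None if growth stalled.
    """
    coords = np.argwhere(allowed)
    if len(coords) == 0:
        return None
    offsets = np.argwhere(struct) - 1  # neighbor offsets incl. center (harmless)
    shape = allowed.shape
    for _ in range(10):  # retry from a few different seeds
        start = tuple(coords[rng.integers(len(coords))])
        grown = np.zeros(shape, dtype=bool)
        grown[start] = True
        frontier = [start]
        count = 1
        while count < size and frontier:
            # random frontier voxel, random neighbor order
            idx = int(rng.integers(len(frontier)))
            vox = frontier[idx]
            order = rng.permutation(len(offsets))
            added = False
            for oi in order:
                nb = tuple(np.add(vox, offsets[oi]))
                if any(q < 0 or q >= s for q, s in zip(nb, shape)):
                    continue
                if allowed[nb] and not grown[nb]:
                    grown[nb] = True
                    frontier.append(nb)
                    count += 1
                    added = True
                    break
            if not added:
                frontier.pop(idx)
        if count == size:
            return grown
    return None


def corrupt_mask(
    mask: SegmentationMask, plan: CorruptionPlan
) -> tuple[SegmentationMask, "ClusterInventory"]:
    """Inject islands and holes of exact sizes into a clean mask.

    Islands are connected foreground components added in the background,
    separated from the main component (and from each other) by at least
    one empty voxel in every direction, so 26-connectivity labeling keeps
    them distinct.  Holes are cavities carved strictly inside the main
    component: every carved voxel keeps a full shell of foreground
    between itself and the outside background, so the cavity is a
    6-connected background component with no path to the border.

    The output is re-checked with independent component labeling; any
    discrepancy with the requested plan raises :class:`PlacementError`.

    Returns
    -------
    (SegmentationMask, ClusterInventory)
        The corrupted mask and the inventory of injected defects with
        exact sizes.
    """
    from lesionseg.postprocess import ClusterInventory, ClusterEntry, find_clusters

    rng = np.random.default_rng(plan.seed)
    data = mask.bool().copy()
    if not data.any() and (plan.island_sizes or plan.hole_sizes):
        raise PlacementError("cannot corrupt an empty mask")

    entries: list[ClusterEntry] = []

    # --- islands: background far enough from all existing foreground
    for size in plan.island_sizes:
        forbidden = ndimage.binary_dilation(data, structure=_STRUCT26, iterations=2)
        allowed = ~forbidden
        # keep islands off the volume border so dilation math stays simple
        allowed[0, :, :] = allowed[-1, :, :] = False
        allowed[:, 0, :] = allowed[:, -1, :] = False
        allowed[:, :, 0] = allowed[:, :, -1] = False
        grown = None
        for _ in range(20):
            cand = _grow_component(allowed, size, rng, _STRUCT26)
            if cand is None:
                break
            # reject shapes that enclose a background cavity, which would
            # inject an unplanned hole into the corrupted mask
            if (ndimage.binary_fill_holes(cand) == cand).all():
                grown = cand
                break
        if grown is None:
            raise PlacementError(f"no room for an island of {size} voxels")
        data |= grown
        entries.append(
            ClusterEntry(kind="island", size=size, voxels=np.argwhere(grown))
        )

    # --- holes: carve inside the eroded main component
    if plan.hole_sizes:
        labels, n = ndimage.label(data, structure=_STRUCT26)
        if n == 0:
            raise PlacementError("no foreground component to carve holes into")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        main = labels == (int(np.argmax(sizes)) + 1)
        carved_all = np.zeros_like(data)
        for size in plan.hole_sizes:
            interior = ndimage.binary_erosion(main, structure=_STRUCT6, iterations=2)
            # stay clear of previously carved cavities
            near_carved = ndimage.binary_dilation(
                carved_all, structure=_STRUCT26, iterations=2
            )
            allowed = interior & data & ~near_carved
            grown = None
            for _ in range(20):
                cand = _grow_component(allowed, size, rng, _STRUCT6)
                if cand is None:
                    break
                # a cavity must not itself enclose a foreground pocket, which
                # would turn into an unplanned island
                if (ndimage.binary_fill_holes(cand) == cand).all():
                    grown = cand
                    break
            if grown is None:
                raise PlacementError(f"no room for a hole of {size} voxels")
            data &= ~grown
            carved_all |= grown
            entries.append(
                ClusterEntry(kind="hole", size=size, voxels=np.argwhere(grown))
            )

    out = SegmentationMask(data=data.astype(np.uint8), spacing=mask.spacing, affine=mask.affine)

    # independent verification: labeling the result must find exactly the plan
    found = find_clusters(out)
    found_islands = sorted(e.size for e in found.entries if e.kind == "island")
    found_holes = sorted(e.size for e in found.entries if e.kind == "hole")
    want_islands = sorted(plan.island_sizes)
    want_holes = sorted(plan.hole_sizes)
    # pre-existing defects in the input mask are counted too
    base = find_clusters(mask)
    base_islands = sorted(e.size for e in base.entries if e.kind == "island")
    base_holes = sorted(e.size for e in base.entries if e.kind == "hole")
    if found_islands != sorted(want_islands + base_islands) or found_holes != sorted(
        want_holes + base_holes
    ):
        raise PlacementError(
            f"defect verification failed: islands {found_islands} vs plan {want_islands}, "
            f"holes {found_holes} vs plan {want_holes}"
        )
    inventory = ClusterInventory(entries=entries, connectivity=26)
    return out, inventory
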