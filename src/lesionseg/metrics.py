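"""Segmentation evaluation: Dice, compactness, Hausdorff distance, statistics.

Dice overlap is computed on voxel counts.  Compactness and the Hausdorff
distance are computed in physical units and therefore account for voxel
anisotropy: surface areas come from exposed voxel faces weighted by the
per-face physical area, volumes from voxel counts times the physical
voxel volume, and boundary-to-boundary distances from voxel-center
coordinates scaled by the spacing.

Compactness is ``area^1.5 / volume`` — dimensionless, minimized by
smooth solid shapes; holes, islands and rough borders all raise it, so
low values indicate realistic masks.

The Hausdorff distance is the symmetric maximum of the two directed
max-min Euclidean distances between boundary voxels (in mm): the largest
segmentation error rather than the average one.

Sham convention: compactness and Hausdorff distance are *undefined*
(reported as NaN, excluded from aggregates) when a mask is empty;
Dice of two empty masks is 1.0.

Significance of paired metric differences is assessed with a paired
permutation (sign-flip) test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage

from lesionseg.errors import InvalidConfigError, UndefinedMetricError
from lesionseg.volume_io import SegmentationMask, require_same_geometry

__all__ = [
    "dice",
    "surface_area",
    "compactness",
    "boundary_voxels",
    "hausdorff",
    "paired_permutation_test",
    "evaluate_set",
    "MetricReport",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def dice(a: SegmentationMask, b: SegmentationMask) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)``.

    Two empty masks score 1.0 (a correctly predicted sham); empty versus
    non-empty scores 0.0.
    """
    require_same_geometry(a, b)
    am, bm = a.bool(), b.bool()
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    inter = int(np.count_nonzero(am & bm))
    return 2.0 * inter / denom


def surface_area(mask: SegmentationMask) -> float:
    """Total physical area (mm^2) of exposed voxel faces.

    A face is exposed when a foreground voxel meets background across it
    or lies on the volume border.  Each face contributes the product of
    the two in-face spacings, so anisotropic voxels weight the three
    face orientations differently.

    Raises
    ------
    UndefinedMetricError
        For an empty mask.
    """
    m = mask.bool()
    if not m.any():
        raise UndefinedMetricError("surface area of an empty mask is undefined")
    sx, sy, sz = mask.spacing
    face_area = (sy * sz, sx * sz, sx * sy)  # faces normal to x, y, z
    total = 0.0
    for axis, fa in enumerate(face_area):
        # internal exposed faces: foreground/background transitions
        diff = np.diff(m.astype(np.int8), axis=axis)
        exposed = int(np.abs(diff).sum())
        # border faces at both ends of the axis
        first = np.take(m, 0, axis=axis)
        last = np.take(m, m.shape[axis] - 1, axis=axis)
        exposed += int(first.sum()) + int(last.sum())
        total += exposed * fa
    return float(total)


def compactness(mask: SegmentationMask) -> float:
    """``surface_area^1.5 / volume`` with both in physical units.

    The 1.5 exponent balances dimensions (mm^3 over mm^3), making the
    measure invariant to isotropic rescaling of the voxel spacing.

    Raises
    ------
    UndefinedMetricError
        For an empty mask.
    """
    m = mask.bool()
    count = int(m.sum())
    if count == 0:
        raise UndefinedMetricError("compactness of an empty mask is undefined")
    area = surface_area(mask)
    volume = count * mask.voxel_volume
    return float(area**1.5 / volume)


def boundary_voxels(mask: SegmentationMask) -> np.ndarray:
    """Coordinates (n, 3) of foreground voxels with an exposed 6-neighbor.

    A boundary voxel has at least one face-neighbor that is background
    or outside the volume.

    Raises
    ------
    UndefinedMetricError
        For an empty mask.
    """
    m = mask.bool()
    if not m.any():
        raise UndefinedMetricError("boundary of an empty mask is undefined")
    interior = ndimage.binary_erosion(m, structure=_STRUCT6, border_value=0)
    return np.argwhere(m & ~interior)


def hausdorff(a: SegmentationMask, b: SegmentationMask) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in mm.

    ``max{ max_a min_b |b - a|, max_b min_a |a - b| }`` over boundary
    voxel centers, with coordinates scaled by the voxel spacing.
    Computed with Euclidean distance transforms of the two boundary
    sets, which is exact for center-to-center distances.

    Raises
    ------
    UndefinedMetricError
        If either mask is empty.
    """
    require_same_geometry(a, b)
    am, bm = a.bool(), b.bool()
    if not am.any() or not bm.any():
        raise UndefinedMetricError("Hausdorff distance is undefined for empty masks")
    ba = boundary_voxels(a)
    bb = boundary_voxels(b)
    bound_a = np.zeros(am.shape, dtype=bool)
    bound_a[tuple(ba.T)] = True
    bound_b = np.zeros(bm.shape, dtype=bool)
    bound_b[tuple(bb.T)] = True
    spacing = a.spacing
    # EDT of the complement: distance from every voxel to the nearest boundary voxel
    dist_to_b = ndimage.distance_transform_edt(~bound_b, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~bound_a, sampling=spacing)
    d_ab = float(dist_to_b[bound_a].max())
    d_ba = float(dist_to_a[bound_b].max())
    return max(d_ab, d_ba)


def paired_permutation_test(
    x,
    y,
    iterations: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided paired permutation (sign-flip) test on the mean difference.

    The observed statistic is the mean of ``x - y``.  Under the null the
    pair labels are exchangeable, so each difference's sign is flipped
    at random.  When all ``2^n`` sign patterns number at most
    ``iterations`` they are enumerated exactly; otherwise ``iterations``
    random patterns are drawn and the add-one Monte-Carlo estimator
    ``p = (1 + #{|t*| >= |t|}) / (1 + iterations)`` is used, which never
    returns 0.

    Returns the p-value in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidConfigError("x and y must be 1D arrays of equal length")
    if len(x) < 1:
        raise InvalidConfigError("need at least one pair")
    if iterations < 1:
        raise InvalidConfigError("iterations must be >= 1")
    d = x - y
    n = len(d)
    observed = abs(d.mean())

    if 2**n <= iterations:
        # exact enumeration of all sign patterns
        count = 0
        total = 2**n
        for signs in product((1.0, -1.0), repeat=n):
            stat = abs(np.dot(signs, d) / n)
            if stat >= observed - 1e-12:
                count += 1
        return count / total

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(iterations, n))
    stats = np.abs(signs @ d / n)
    count = int(np.count_nonzero(stats >= observed - 1e-12))
    return (1 + count) / (1 + iterations)


@dataclass
class MetricReport:
    """Per-scan metric rows plus aggregates over defined entries."""

    per_scan: pd.DataFrame  # columns: scan_id, dice, compactness, hausdorff_mm
    aggregates: pd.DataFrame  # index: metric; columns: mean, std, n

    def to_csv(self, path) -> None:
        self.per_scan.to_csv(path, index=False)


def evaluate_set(
    predictions: list[SegmentationMask],
    truths: list[SegmentationMask],
    scan_ids: list[str] | None = None,
) -> MetricReport:
    """Evaluate matched prediction/truth mask lists.

    Dice is reported for every pair (two empty masks give 1.0).
    Compactness (of the prediction) and Hausdorff distance are undefined
    — NaN in the table — whenever the relevant mask is empty, and
    aggregates are computed over the defined entries only, so scans
    without lesions never distort the surface-based statistics.
    """
    if len(predictions) != len(truths):
        raise InvalidConfigError(
            f"{len(predictions)} predictions vs {len(truths)} truths"
        )
    if scan_ids is None:
        scan_ids = [f"scan_{i:03d}" for i in range(len(predictions))]
    rows = []
    for sid, pred, truth in zip(scan_ids, predictions, truths):
        d = dice(pred, truth)
        try:
            # surface metrics only on lesion-bearing scans: undefined when
            # either mask is empty
            if not truth.bool().any():
                raise UndefinedMetricError("sham scan")
            comp = compactness(pred)
        except UndefinedMetricError:
            comp = np.nan
        try:
            hd = hausdorff(pred, truth)
        except UndefinedMetricError:
            hd = np.nan
        rows.append(
            {"scan_id": sid, "dice": d, "compactness": comp, "hausdorff_mm": hd}
        )
    per_scan = pd.DataFrame(rows)
    agg_rows = {}
    for metric in ("dice", "compactness", "hausdorff_mm"):
        vals = per_scan[metric].dropna()
        agg_rows[metric] = {
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "std": float(vals.std(ddof=0)) if len(vals) else np.nan,
            "n": int(len(vals)),
        }
    aggregates = pd.DataFrame(agg_rows).T
    return MetricReport(per_scan=per_scan, aggregates=aggregates)
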