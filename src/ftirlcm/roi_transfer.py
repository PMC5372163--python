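"""From classified label maps to dissectable shapes.

Connected regions of the tissue class of interest are extracted from the
label map; the centers of their marginal pixels (pixels with at least one
4-neighbor outside the region) form the cutting polygon.  Oversized regions
are split by a distance-transform watershed so every shape respects the
instrument's size limit.  Shapes are transferred into the microdissection
stage frame by a 4-parameter planar Helmert (similarity) transformation
estimated from >=3 fiducial pairs, after an anisotropic-scale + rotation
aberration calibration measured on a resolution target.  Finally, fragments
can be pooled per sample so each pool carries a near-equal summed amide I
integral, i.e. near-equal relative protein amount.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .errors import ConditioningError, InfeasibleError, ParameterError, ValidationError
from .hyperspec_io import LabelMap, ReferencePointSet, pixel_centers_um

__all__ = [
    "ROI",
    "Fragment",
    "HelmertTransform",
    "AberrationCalibration",
    "extract_rois",
    "marginal_pixels",
    "trace_boundary",
    "watershed_split",
    "estimate_helmert",
    "apply_helmert",
    "calibrate_aberration",
    "select_fragments_balanced",
]

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


# ---------------------------------------------------------------------------
# ROI extraction and boundary tracing


@dataclass
class ROI:
    """8-connected region of one class with its marginal-pixel polygon."""

    class_label: int
    class_name: str
    pixels: np.ndarray  # (n, 2) of (row, col)
    pixel_size: tuple[float, float]
    stage_origin: tuple[float, float]
    boundary_rc: np.ndarray  # ordered marginal pixels (row, col)

    @property
    def area_um2(self) -> float:
        return self.pixels.shape[0] * self.pixel_size[0] * self.pixel_size[1]

    @property
    def boundary_polygon_um(self) -> np.ndarray:
        """Ordered marginal-pixel centers (x, y) in the source stage frame."""
        return pixel_centers_um(
            self.boundary_rc[:, 0],
            self.boundary_rc[:, 1],
            self.pixel_size,
            self.stage_origin,
        )


@dataclass
class Fragment:
    """Watershed piece of one ROI, annotated with its amide I integral."""

    parent_roi: int
    pixels: np.ndarray
    pixel_size: tuple[float, float]
    stage_origin: tuple[float, float]
    boundary_rc: np.ndarray
    amide_integral_sum: float

    @property
    def area_um2(self) -> float:
        return self.pixels.shape[0] * self.pixel_size[0] * self.pixel_size[1]

    @property
    def boundary_polygon_um(self) -> np.ndarray:
        return pixel_centers_um(
            self.boundary_rc[:, 0],
            self.boundary_rc[:, 1],
            self.pixel_size,
            self.stage_origin,
        )


def marginal_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean map of region pixels with >=1 non-member 4-neighbor."""
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return mask & ~interior


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered outer-boundary pixels of a connected region (Moore tracing).

    The walk starts at the top-most then left-most region pixel and proceeds
    counter-clockwise in image coordinates (row down, col right).  Returns
    (n, 2) of (row, col); pixels on one-pixel-wide necks may appear more
    than once (the walk is a closed curve).  Only the outer boundary is
    traced; marginal pixels bordering interior holes are not visited.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return np.zeros((0, 2), dtype=int)
    if rows.size == 1:
        return np.array([[rows[0], cols[0]]])

    start = (int(rows.min()), int(cols[rows == rows.min()].min()))
    # Moore neighborhood scanned in the order W, SW, S, SE, E, NE, N, NW,
    # giving a counter-clockwise walk in image coordinates (y down)
    offsets = [(0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1)]

    def inside(p):
        return 0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1] and mask[p]

    current = start
    backtrack = (start[0], start[1] - 1)  # exterior: start is row-leftmost
    boundary = [start]
    visited_states: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    while True:
        dir_b = offsets.index((backtrack[0] - current[0], backtrack[1] - current[1]))
        found = False
        for d in range(1, 9):
            k = (dir_b + d) % 8
            cand = (current[0] + offsets[k][0], current[1] + offsets[k][1])
            if inside(cand):
                prev = (dir_b + d - 1) % 8
                backtrack = (current[0] + offsets[prev][0], current[1] + offsets[prev][1])
                current = cand
                found = True
                break
        if not found:
            break  # single pixel with no neighbors (handled above), safety
        state = (current, backtrack)
        if state in visited_states or (current == start and len(boundary) > 1 and state == ((start), (start[0], start[1] - 1))):
            break
        visited_states.add(state)
        boundary.append(current)
        if len(boundary) > 8 * mask.size:
            raise RuntimeError("boundary tracing failed to terminate")
    arr = np.array(boundary, dtype=int)
    if arr.shape[0] > 1 and np.array_equal(arr[0], arr[-1]):
        arr = arr[:-1]
    keep = np.ones(arr.shape[0], dtype=bool)
    keep[1:] = np.any(arr[1:] != arr[:-1], axis=1)
    return arr[keep]


def _boundary_marginal(mask: np.ndarray) -> np.ndarray:
    """Ordered marginal-pixel ring: traced boundary restricted to marginal
    pixels, duplicates removed (first visit wins)."""
    ring = trace_boundary(mask)
    marg = marginal_pixels(mask)
    seen: set[tuple[int, int]] = set()
    ordered = []
    for r, c in ring:
        if marg[r, c] and (r, c) not in seen:
            ordered.append((r, c))
            seen.add((r, c))
    return np.array(ordered, dtype=int) if ordered else np.zeros((0, 2), dtype=int)


def extract_rois(
    label_map: LabelMap,
    target_class: str | int,
    min_pixels: int = 1,
    pixel_size: tuple[float, float] = (5.5, 5.5),
    stage_origin: tuple[float, float] = (0.0, 0.0),
) -> list[ROI]:
    """8-connected components of one class, each with its boundary polygon.

    Components smaller than ``min_pixels`` are dropped.  An absent class
    yields an empty list.  Component order follows scanline order of the
    top-left pixel (deterministic).
    """
    if isinstance(target_class, str):
        matches = [lbl for lbl, (name, _) in label_map.legend.items() if name == target_class]
        if not matches:
            raise ValidationError(f"class '{target_class}' not in legend")
        label = matches[0]
    else:
        label = int(target_class)
        if label not in label_map.legend:
            raise ValidationError(f"label {label} not in legend")
    mask = label_map.labels == label
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    comp, n_comp = ndi.label(mask, structure=structure)
    rois = []
    for i in range(1, n_comp + 1):
        comp_mask = comp == i
        n_px = int(comp_mask.sum())
        if n_px < min_pixels:
            continue
        pixels = np.argwhere(comp_mask)
        rois.append(
            ROI(
                class_label=label,
                class_name=label_map.legend[label][0],
                pixels=pixels,
                pixel_size=pixel_size,
                stage_origin=stage_origin,
                boundary_rc=_boundary_marginal(comp_mask),
            )
        )
    return rois


# ---------------------------------------------------------------------------
# watershed size splitting


def _split_oversized(mask: np.ndarray, max_pixels: int) -> list[np.ndarray]:
    """Recursively bisect a pixel mask along its longer axis until each
    connected piece holds <= max_pixels."""
    n = int(mask.sum())
    if n <= max_pixels:
        return [mask]
    rows, cols = np.nonzero(mask)
    span_r, span_c = rows.max() - rows.min(), cols.max() - cols.min()
    coords = rows if span_r >= span_c else cols
    cut = np.median(coords)
    sel = coords <= cut
    if sel.all() or not sel.any():  # all coordinates identical up to median
        sel = np.zeros(n, dtype=bool)
        sel[: n // 2] = True
    pieces = []
    for half in (sel, ~sel):
        half_mask = np.zeros_like(mask)
        half_mask[rows[half], cols[half]] = True
        # keep pieces connected: re-split into components first
        comp, k = ndi.label(half_mask, structure=np.ones((3, 3), bool))
        for i in range(1, k + 1):
            pieces.extend(_split_oversized(comp == i, max_pixels))
    return pieces


def _merge_small(labels: np.ndarray, max_pixels: int) -> np.ndarray:
    """Greedily merge adjacent catchments smallest-first while the merged
    size stays within the limit.  Ties broken by label id (seed order)."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        if ids.size <= 1:
            return labels
        # adjacency via dilation of each region
        merged = False
        order = ids[np.argsort(counts, kind="stable")]
        sizes = dict(zip(ids.tolist(), counts.tolist()))
        for lbl in order:
            region = labels == lbl
            dilated = ndi.binary_dilation(region, structure=np.ones((3, 3), bool))
            neighbor_ids = np.unique(labels[dilated & ~region])
            neighbor_ids = [n for n in neighbor_ids if n > 0 and n != lbl]
            candidates = [
                n for n in neighbor_ids if sizes[lbl] + sizes[n] <= max_pixels
            ]
            if candidates:
                target = min(candidates, key=lambda n: (sizes[n], n))
                labels[region] = target
                merged = True
                break
        if not merged:
            return labels


def watershed_split(
    roi: ROI, amide_map: np.ndarray, max_shape_area_um2: float = 250_000.0
) -> list[Fragment]:
    """Split an ROI into fragments no larger than the shape-size limit.

    The interior Euclidean distance map is watershed-segmented from its
    regional maxima; any catchment still above the limit is bisected along
    its longer axis, and adjacent catchments are re-merged smallest-first
    while the result stays within the limit.  Fragments partition the ROI
    exactly, so areas and amide integrals are additive.
    """
    pixel_area = roi.pixel_size[0] * roi.pixel_size[1]
    if max_shape_area_um2 < pixel_area:
        raise ParameterError("max_shape_area smaller than one pixel")
    max_pixels = int(np.floor(max_shape_area_um2 / pixel_area))

    shape = amide_map.shape
    mask = np.zeros(shape, dtype=bool)
    mask[roi.pixels[:, 0], roi.pixels[:, 1]] = True

    if int(mask.sum()) <= max_pixels:
        pieces = [mask]
    else:
        dist = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(dist, labels=mask, exclude_border=False)
        markers = np.zeros(shape, dtype=int)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() < 2:
            catchments = mask.astype(int)
        else:
            catchments = watershed(-dist, markers=markers, mask=mask)
        pieces = []
        for lbl in np.unique(catchments[catchments > 0]):
            pieces.extend(_split_oversized(catchments == lbl, max_pixels))
        # relabel and merge back small slivers
        labels = np.zeros(shape, dtype=int)
        for i, piece in enumerate(pieces, start=1):
            labels[piece] = i
        labels = _merge_small(labels, max_pixels)
        pieces = [labels == lbl for lbl in np.unique(labels[labels > 0])]

    fragments = []
    for piece in pieces:
        pixels = np.argwhere(piece)
        fragments.append(
            Fragment(
                parent_roi=id(roi),
                pixels=pixels,
                pixel_size=roi.pixel_size,
                stage_origin=roi.stage_origin,
                boundary_rc=_boundary_marginal(piece),
                amide_integral_sum=float(amide_map[piece].sum()),
            )
        )
    _assert_partition(roi, fragments, max_pixels)
    return fragments


def _assert_partition(roi: ROI, fragments: list[Fragment], max_pixels: int) -> None:
    """Partition invariants checked on every run: disjoint, exact union,
    size limit respected."""
    roi_set = {tuple(p) for p in roi.pixels}
    seen: set[tuple[int, int]] = set()
    for frag in fragments:
        frag_set = {tuple(p) for p in frag.pixels}
        if frag_set & seen:
            raise RuntimeError("watershed fragments overlap")
        if len(frag_set) > max_pixels:
            raise RuntimeError("watershed fragment exceeds the size limit")
        seen |= frag_set
    if seen != roi_set:
        raise RuntimeError("watershed fragments do not cover the ROI")


# ---------------------------------------------------------------------------
# Helmert transform and aberration calibration


@dataclass(frozen=True)
class HelmertTransform:
    """4-parameter planar similarity: x' = t + s R(theta) x.

    Equivalently ``x' = tx + a x - b y``, ``y' = ty + b x + a y`` with
    ``a = s cos(theta)``, ``b = s sin(theta)``.  ``rms_residual`` is the
    root-mean-square fit residual over the reference pairs (um).
    """

    tx: float
    ty: float
    scale: float
    theta: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError("similarity scale must be positive")

    @property
    def a(self) -> float:
        return self.scale * np.cos(self.theta)

    @property
    def b(self) -> float:
        return self.scale * np.sin(self.theta)

    def inverse(self) -> "HelmertTransform":
        a, b = self.a, self.b
        s2 = self.scale**2
        ai, bi = a / s2, -b / s2
        txi = -(ai * self.tx - bi * self.ty)
        tyi = -(bi * self.tx + ai * self.ty)
        return HelmertTransform(
            tx=txi,
            ty=tyi,
            scale=1.0 / self.scale,
            theta=-self.theta,
            rms_residual=self.rms_residual,
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "tx_um": self.tx,
            "ty_um": self.ty,
            "scale": self.scale,
            "theta_rad": self.theta,
            "rms_residual_um": self.rms_residual,
        }


def estimate_helmert(points: ReferencePointSet) -> HelmertTransform:
    """Least-squares similarity fit from >=3 non-collinear fiducial pairs.

    The model is linear in (tx, ty, a, b); scale and rotation follow as
    ``s = sqrt(a^2 + b^2)``, ``theta = atan2(b, a)``.
    """
    points.require_estimable()
    src, dst = points.source, points.destination
    n = src.shape[0]
    design = np.zeros((2 * n, 4))
    target = np.zeros(2 * n)
    design[0::2] = np.column_stack(
        [np.ones(n), np.zeros(n), src[:, 0], -src[:, 1]]
    )
    design[1::2] = np.column_stack(
        [np.zeros(n), np.ones(n), src[:, 1], src[:, 0]]
    )
    target[0::2], target[1::2] = dst[:, 0], dst[:, 1]
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < 4:
        raise ConditioningError("reference geometry is rank-deficient")
    tx, ty, a, b = coef
    scale = float(np.hypot(a, b))
    if scale <= 0:
        raise ConditioningError("degenerate similarity fit (zero scale)")
    residual = (design @ coef - target).reshape(n, 2)
    # rms of the per-point Euclidean residual vector length
    rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return HelmertTransform(
        tx=float(tx),
        ty=float(ty),
        scale=scale,
        theta=float(np.arctan2(b, a)),
        rms_residual=rms,
    )


def apply_helmert(transform: HelmertTransform, points: np.ndarray) -> np.ndarray:
    """Map (n, 2) source-frame points into the destination frame."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points must be finite")
    a, b = transform.a, transform.b
    out = np.column_stack(
        [
            transform.tx + a * pts[:, 0] - b * pts[:, 1],
            transform.ty + b * pts[:, 0] + a * pts[:, 1],
        ]
    )
    return out[0] if single else out


@dataclass(frozen=True)
class AberrationCalibration:
    """Anisotropic pixel scale + visible/IR rotation from a grid target.

    Applied before the strictly 4-parameter Helmert transfer, so anisotropy
    never leaks into the similarity map.
    """

    pixel_size_x_um: float
    pixel_size_y_um: float
    rotation_deg: float
    tx: float = 0.0
    ty: float = 0.0
    rms_residual_um: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_x_um <= 0 or self.pixel_size_y_um <= 0:
            raise ParameterError("pixel sizes must be positive")

    def apply(self, points_px: np.ndarray) -> np.ndarray:
        """Map grid (pixel) coordinates to calibrated um coordinates."""
        pts = np.atleast_2d(np.asarray(points_px, float))
        phi = np.deg2rad(self.rotation_deg)
        x = self.pixel_size_x_um * (pts[:, 0] * np.cos(phi) - pts[:, 1] * np.sin(phi))
        y = self.pixel_size_y_um * (pts[:, 0] * np.sin(phi) + pts[:, 1] * np.cos(phi))
        return np.column_stack([x + self.tx, y + self.ty])


def calibrate_aberration(grid_pairs: ReferencePointSet) -> AberrationCalibration:
    """Fit per-axis scale, rotation and offset from resolution-target pairs.

    Source coordinates are nominal grid positions (pixels), destinations the
    measured um positions.  The model ``x' = sx (x cos phi - y sin phi) + tx``,
    ``y' = sy (x sin phi + y cos phi) + ty`` is recovered by a full affine
    least-squares fit followed by decomposition.
    """
    if len(grid_pairs) < 4:
        raise ConditioningError("aberration calibration needs >=4 grid pairs")
    grid_pairs.require_estimable()
    src, dst = grid_pairs.source, grid_pairs.destination
    # x and y share no parameters in the affine fit; solve each row separately
    design = np.column_stack([src, np.ones(len(grid_pairs))])
    coef_x, *_ = np.linalg.lstsq(design, dst[:, 0], rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, dst[:, 1], rcond=None)
    a11, a12, tx = coef_x
    a21, a22, ty = coef_y
    sx = float(np.hypot(a11, a12))
    sy = float(np.hypot(a21, a22))
    if sx <= 0 or sy <= 0:
        raise ConditioningError("degenerate aberration fit")
    phi_x = np.arctan2(-a12, a11)
    phi_y = np.arctan2(a21, a22)
    phi = float((phi_x + phi_y) / 2.0)
    fitted = np.column_stack([design @ coef_x, design @ coef_y])
    rms = float(np.sqrt(np.mean(np.sum((fitted - dst) ** 2, axis=1))))
    return AberrationCalibration(
        pixel_size_x_um=sx,
        pixel_size_y_um=sy,
        rotation_deg=float(np.rad2deg(phi)),
        tx=float(tx),
        ty=float(ty),
        rms_residual_um=rms,
    )


# ---------------------------------------------------------------------------
# absorbance-balanced pooling


def _subset_sum(values: np.ndarray) -> float:
    return float(values.sum()) if values.size else 0.0


def select_fragments_balanced(
    samples: dict[str, list[Fragment]] | dict[str, list[float]],
    target_integral: float,
    tolerance: float | None = None,
) -> dict[str, dict]:
    """Pick per-sample fragment subsets with near-equal summed amide integral.

    Collecting equal *absorbance integrals* rather than equal areas equalizes
    the relative protein amount across sample pools (Lambert-Beer).  The
    subset is found greedily largest-first, then refined by single add /
    remove / swap moves.  Default tolerance: 2% of the target.

    Returns per sample: chosen indices, achieved integral, deviation.  Raises
    :class:`InfeasibleError` naming any sample whose total integral cannot
    reach the target band.
    """
    if tolerance is None:
        tolerance = 0.02 * target_integral
    if target_integral <= 0:
        raise ParameterError("target integral must be positive")
    results: dict[str, dict] = {}
    for sample, fragments in samples.items():
        values = np.array(
            [
                f.amide_integral_sum if isinstance(f, Fragment) else float(f)
                for f in fragments
            ]
        )
        total = values.sum()
        if total < target_integral - tolerance:
            raise InfeasibleError(
                f"sample '{sample}': total integral {total:.4g} below target "
                f"{target_integral:.4g} (tolerance {tolerance:.4g})"
            )
        chosen = _greedy_subset(values, target_integral, tolerance)
        achieved = _subset_sum(values[sorted(chosen)])
        if abs(achieved - target_integral) > tolerance + 1e-9:
            raise InfeasibleError(
                f"sample '{sample}': no fragment subset reaches "
                f"{target_integral:.4g} +/- {tolerance:.4g} "
                f"(best achieved {achieved:.4g})"
            )
        results[sample] = {
            "indices": sorted(chosen),
            "achieved_integral": achieved,
            "deviation": achieved - target_integral,
        }
    achieved_all = [r["achieved_integral"] for r in results.values()]
    spread = max(achieved_all) - min(achieved_all) if achieved_all else 0.0
    for r in results.values():
        r["cross_sample_spread"] = spread
    return results


def _greedy_subset(values: np.ndarray, target: float, tol: float) -> set[int]:
    """Largest-first greedy fill refined by best single add/remove/swap."""
    order = np.argsort(-values, kind="stable")
    chosen: set[int] = set()
    acc = 0.0
    for i in order:
        if acc + values[i] <= target + tol + 1e-12:
            chosen.add(int(i))
            acc += values[i]
            if acc >= target - tol:
                break

    def err(s: float) -> float:
        return abs(s - target)

    improved = True
    while improved and err(acc) > tol:
        improved = False
        best_move, best_err = None, err(acc)
        outside = [i for i in range(values.size) if i not in chosen]
        for i in outside:  # add
            e = err(acc + values[i])
            if e < best_err - 1e-12:
                best_move, best_err = ("add", i, None), e
        for j in chosen:  # remove
            e = err(acc - values[j])
            if e < best_err - 1e-12:
                best_move, best_err = ("remove", j, None), e
        for i, j in itertools.product(outside, list(chosen)):  # swap
            e = err(acc + values[i] - values[j])
            if e < best_err - 1e-12:
                best_move, best_err = ("swap", i, j), e
        if best_move is not None:
            kind, i, j = best_move
            if kind == "add":
                chosen.add(i)
                acc += values[i]
            elif kind == "remove":
                chosen.discard(i)
                acc -= values[i]
            else:
                chosen.add(i)
                chosen.discard(j)
                acc += values[i] - values[j]
            improved = True
    return chosen
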