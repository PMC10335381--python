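"""Per-slice, per-object shape morphometrics from chain-code analysis.

For every 8-connected object of a class mask the module measures

* area ``A`` — the pixel count (× dx² for nm²);
* perimeter ``P`` — from the object's Freeman chain code, the closed
  Moore-neighbour boundary trace: axial moves contribute one pixel side,
  diagonal moves √2;
* convex hull area ``CA`` and perimeter ``CP`` — the hull of the boundary
  pixel centres is rasterised back to a pixel mask (a pixel belongs to the
  hull mask iff its centre is inside or on the hull) and measured with the
  same pixel-count / chain-code estimators, so a digitally convex object has
  ``CA = A`` and ``CP = P`` exactly;
* centroid–boundary radii — Euclidean distances from the area centroid (mean
  of all object pixel centres) to each boundary pixel, summarised as
  mean/min/max.

Three dimensionless ratios follow: convexity ``CP:P``, solidity ``A:CA`` and
sphericity ``Rmin:Rmax``.  Per-slice class summaries are area-weighted means
over the objects of a class, one row per slice per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .proximity import boundary_mask
from .volume import LabelVolume, class_mask

_EIGHT = np.ones((3, 3), dtype=bool)

# Freeman directions, clockwise on screen (y down): E, SE, S, SW, W, NW, N, NE.
# Even codes are axial steps, odd codes diagonal.
CHAIN_OFFSETS = (
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
)
_DIR_INDEX = {off: i for i, off in enumerate(CHAIN_OFFSETS)}


@dataclass
class MorphometricRecord:
    """All measured quantities for one object in one slice."""

    z: int
    class_name: str
    object_id: int
    area_px: int
    area_nm2: float
    perimeter_px: float
    perimeter_nm: float
    hull_area_nm2: float | None  # CA; None when the hull is degenerate
    hull_perimeter_nm: float | None  # CP
    r_mean_nm: float
    r_min_nm: float
    r_max_nm: float
    convexity: float | None  # CP : P
    solidity: float | None  # A : CA
    sphericity: float  # Rmin : Rmax
    touches_border: bool


def label_objects(
    mask: np.ndarray, min_area_px: int = 16
) -> tuple[list[np.ndarray], int, int]:
    """Split a binary mask into 8-connected objects of at least *min_area_px*.

    Returns ``(object_masks, n_dropped, dropped_area_px)``; small components
    are dropped but counted so area conservation stays checkable.
    """
    mask = np.asarray(mask, dtype=bool)
    labelled, n = ndimage.label(mask, structure=_EIGHT)
    objects: list[np.ndarray] = []
    n_dropped = 0
    dropped_area = 0
    for i in range(1, n + 1):
        obj = labelled == i
        area = int(obj.sum())
        if area < min_area_px:
            n_dropped += 1
            dropped_area += area
        else:
            objects.append(obj)
    return objects, n_dropped, dropped_area


def trace_freeman_chain(object_mask: np.ndarray) -> list[int]:
    """Closed Moore-neighbour boundary trace of a single 8-connected object.

    Starts at the lexicographically first (topmost, then leftmost) object
    pixel and walks the outer boundary clockwise, emitting one Freeman code
    (0–7, E/SE/S/.../NE) per step until the walk re-enters the start pixel
    and is about to repeat its first move.  An isolated single pixel has an
    empty chain.
    """
    mask = np.asarray(object_mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cannot trace an empty mask")
    order = np.lexsort((xs, ys))
    start = (int(ys[order[0]]), int(xs[order[0]]))
    h, w = mask.shape

    def is_fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    chain: list[int] = []
    p = start
    backtrack = (start[0], start[1] - 1)  # left neighbour: background by choice of start
    max_steps = 8 * ys.size + 8
    while True:
        db = _DIR_INDEX[(backtrack[0] - p[0], backtrack[1] - p[1])]
        nxt = None
        for k in range(1, 9):
            d = (db + k) % 8
            q = (p[0] + CHAIN_OFFSETS[d][0], p[1] + CHAIN_OFFSETS[d][1])
            if is_fg(q):
                nxt = (d, q)
                break
            backtrack = q
        if nxt is None:  # isolated pixel
            return []
        d, q = nxt
        if p == start and chain and d == chain[0]:
            return chain  # about to repeat the first move: boundary closed
        chain.append(d)
        p = q
        if len(chain) > max_steps:
            raise RuntimeError("boundary trace failed to close")


def perimeter_from_chain(chain: list[int], dx_nm: float) -> float:
    """Chain-code perimeter: axial steps count 1, diagonal steps √2 (× dx)."""
    chain = list(chain)
    n_axial = sum(1 for c in chain if c % 2 == 0)
    n_diag = len(chain) - n_axial
    return (n_axial + n_diag * np.sqrt(2.0)) * dx_nm


def rasterise_hull(object_mask: np.ndarray) -> np.ndarray | None:
    """Filled hull mask of an object: pixel centres inside or on the convex
    hull of the object's boundary pixel centres.  None when degenerate
    (fewer than three non-collinear boundary points)."""
    mask = np.asarray(object_mask, dtype=bool)
    pts = np.argwhere(boundary_mask(mask)).astype(float)
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError):
        return None
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max()
    x0, x1 = xs.min(), xs.max()
    gy, gx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    grid = np.column_stack([gy.ravel(), gx.ravel()]).astype(float)
    # half-space test: inside-or-on within a small tolerance
    a, b = hull.equations[:, :2], hull.equations[:, 2]
    inside = (grid @ a.T + b <= 1e-9).all(axis=1)
    out = np.zeros_like(mask)
    out[gy.ravel()[inside], gx.ravel()[inside]] = True
    return out


def convex_hull_metrics(
    object_mask: np.ndarray, dx_nm: float, mode: str = "raster"
) -> tuple[float | None, float | None]:
    """Convex-hull area CA (nm²) and perimeter CP (nm) of an object.

    ``mode="raster"`` (default) measures the rasterised hull mask with the
    same pixel-count and chain-code estimators as A and P, so convex objects
    give CA = A and CP = P exactly.  ``mode="polygon"`` returns the
    continuous hull polygon's area and perimeter instead.
    """
    if mode not in ("raster", "polygon"):
        raise ValueError("mode must be 'raster' or 'polygon'")
    mask = np.asarray(object_mask, dtype=bool)
    if mode == "polygon":
        pts = np.argwhere(boundary_mask(mask)).astype(float)
        try:
            hull = ConvexHull(pts)
        except (QhullError, ValueError):
            return None, None
        return float(hull.volume) * dx_nm**2, float(hull.area) * dx_nm
    hull_mask = rasterise_hull(mask)
    if hull_mask is None:
        return None, None
    ca = float(hull_mask.sum()) * dx_nm**2
    cp = perimeter_from_chain(trace_freeman_chain(hull_mask), dx_nm)
    return ca, cp


def radius_stats(object_mask: np.ndarray, dx_nm: float) -> tuple[float, float, float]:
    """(R_mean, R_min, R_max) in nm: centroid-to-boundary-pixel distances.

    The centroid is the mean of *all* object pixel centres; radii are taken
    over boundary pixels only.
    """
    mask = np.asarray(object_mask, dtype=bool)
    pix = np.argwhere(mask)
    centroid = pix.mean(axis=0)
    bpix = np.argwhere(boundary_mask(mask))
    r = np.hypot(*(bpix - centroid).T) * dx_nm
    return float(r.mean()), float(r.min()), float(r.max())


def shape_ratios(
    area_nm2: float,
    perimeter_nm: float,
    hull_area_nm2: float | None,
    hull_perimeter_nm: float | None,
    r_min_nm: float,
    r_max_nm: float,
) -> tuple[float | None, float | None, float]:
    """(convexity CP:P, solidity A:CA, sphericity Rmin:Rmax); hull ratios are
    None when the hull was degenerate."""
    convexity = None if hull_perimeter_nm is None else hull_perimeter_nm / perimeter_nm
    solidity = None if hull_area_nm2 is None else area_nm2 / hull_area_nm2
    sphericity = r_min_nm / r_max_nm
    return convexity, solidity, sphericity


def measure_object(
    object_mask: np.ndarray,
    dx_nm: float,
    z: int = 0,
    class_name: str = "",
    object_id: int = 0,
    hull_mode: str = "raster",
) -> MorphometricRecord:
    """Measure one object mask into a full :class:`MorphometricRecord`."""
    mask = np.asarray(object_mask, dtype=bool)
    area_px = int(mask.sum())
    chain = trace_freeman_chain(mask)
    p_px = perimeter_from_chain(chain, 1.0)
    ca, cp = convex_hull_metrics(mask, dx_nm, mode=hull_mode)
    r_mean, r_min, r_max = radius_stats(mask, dx_nm)
    area_nm2 = area_px * dx_nm**2
    p_nm = p_px * dx_nm
    convexity, solidity, sphericity = shape_ratios(area_nm2, p_nm, ca, cp, r_min, r_max)
    ys, xs = np.nonzero(mask)
    touches = bool(
        (ys.min() == 0)
        or (xs.min() == 0)
        or (ys.max() == mask.shape[0] - 1)
        or (xs.max() == mask.shape[1] - 1)
    )
    return MorphometricRecord(
        z=z,
        class_name=class_name,
        object_id=object_id,
        area_px=area_px,
        area_nm2=area_nm2,
        perimeter_px=p_px,
        perimeter_nm=p_nm,
        hull_area_nm2=ca,
        hull_perimeter_nm=cp,
        r_mean_nm=r_mean,
        r_min_nm=r_min,
        r_max_nm=r_max,
        convexity=convexity,
        solidity=solidity,
        sphericity=sphericity,
        touches_border=touches,
    )


_RECORD_COLUMNS = [
    "z",
    "class_name",
    "object_id",
    "area_px",
    "area_nm2",
    "perimeter_px",
    "perimeter_nm",
    "hull_area_nm2",
    "hull_perimeter_nm",
    "r_mean_nm",
    "r_min_nm",
    "r_max_nm",
    "convexity",
    "solidity",
    "sphericity",
    "touches_border",
]


def measure_volume(
    vol: LabelVolume,
    classes: list[str] | None = None,
    min_area_px: int = 16,
    hull_mode: str = "raster",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Measure every object of every class on every slice.

    Returns a records DataFrame (one row per object per slice) and a count
    of dropped sub-threshold components per class.  Border-touching objects
    are measured but flagged ``touches_border`` — their true extent is
    censored by the field of view.
    """
    if classes is None:
        classes = sorted(
            n for n in set(vol.class_map.values()) if n != "background"
        )
    rows = []
    dropped: dict[str, int] = {}
    for cls in classes:
        dropped[cls] = 0
        for z in range(vol.n_slices):
            mask = class_mask(vol, cls, z)
            if not mask.any():
                continue
            objects, n_drop, _ = label_objects(mask, min_area_px)
            dropped[cls] += n_drop
            for i, obj in enumerate(objects):
                rec = measure_object(
                    obj, vol.dx_nm, z=z, class_name=cls, object_id=i, hull_mode=hull_mode
                )
                rows.append([getattr(rec, c) for c in _RECORD_COLUMNS])
    df = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    return df, dropped


#: Metrics that enter the per-slice, per-class area-weighted summaries.
SUMMARY_METRICS = [
    "perimeter_nm",
    "r_mean_nm",
    "convexity",
    "solidity",
    "sphericity",
]


def slice_class_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Area-weighted mean of each metric per (slice, class).

    Each row summarises all measured objects of one class in one slice:
    Σ(Aᵢ·mᵢ)/Σ(Aᵢ).  Objects with degenerate hulls (NaN ratios) are skipped
    for the affected metrics only.
    """
    out = []
    for (z, cls), grp in records.groupby(["z", "class_name"], sort=True):
        row: dict = {
            "z": z,
            "class_name": cls,
            "n_objects": len(grp),
            "total_area_nm2": grp["area_nm2"].sum(),
        }
        for metric in SUMMARY_METRICS:
            m = pd.to_numeric(grp[metric], errors="coerce")
            ok = m.notna()
            w = grp.loc[ok, "area_nm2"]
            row[metric] = float((m[ok] * w).sum() / w.sum()) if ok.any() else np.nan
        out.append(row)
    return pd.DataFrame(out)
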