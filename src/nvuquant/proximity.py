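"""In-plane boundary proximity statistics between segmented classes.

For each image slice and ordered class pair (A → B) the analysis measures,
from every boundary pixel of A, the Euclidean distance (pixel centre to pixel
centre, in nm) to the nearest boundary pixel of B.  Per-slice distances are
binned into normalised histograms, consolidated into an unweighted stack-mean
histogram with per-bin SD, and integrated into a cumulative distribution
function: the CDF value at distance d is the percentage of A-boundary pixels
lying within d of B.  Two derived summaries mirror the biology of the
pericyte–endothelial interface:

* the *contact fraction* — the percentage of A-boundary pixels within a small
  contact threshold (default 10 nm ≈ two 6 nm pixels, i.e. effectively
  touching) of B;
* *ensheathment coverage* — the percentage of the abluminal endothelial
  boundary (endothelial boundary pixels not facing the lumen) within a
  coverage threshold (default 200 nm) of the pericyte layer.

Distances are strictly in-plane; sections are never bridged.  A boundary
pixel is a mask pixel with at least one 4-neighbour outside the mask, the
image border counting as outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import LabelVolume, class_mask

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity

#: Distances (nm) at which summary CDF readings are conventionally reported.
REPORT_DISTANCES_NM = (10, 100, 250, 500, 1000)


@dataclass
class BoundarySet:
    """Boundary pixels of one class in one slice."""

    z: int
    class_name: str
    pixels: np.ndarray  # (n, 2) int array of (y, x); may be empty

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class ProximityResult:
    """Full proximity statistics for one ordered class pair over a stack."""

    class_a: str
    class_b: str
    bin_edges_nm: np.ndarray  # len n_bins + 1; final edge is +inf (overflow)
    per_slice_hist: np.ndarray  # (n_slices, n_bins); NaN rows = pair absent
    stack_mean_hist: np.ndarray
    stack_sd_hist: np.ndarray
    cdf_pct: np.ndarray  # cumulative % at each upper bin edge
    contact_nm: float
    contact_pct_per_slice: np.ndarray  # NaN where pair absent
    contact_pct_mean: float
    contact_pct_sd: float
    contact_pct_min: float
    contact_pct_max: float
    excluded_slices: list[int] = field(default_factory=list)

    def cdf_at(self, distance_nm: float) -> float:
        """CDF reading (%) at a distance: % of A-boundary pixels within it of B."""
        upper = self.bin_edges_nm[1:]
        idx = np.searchsorted(upper, distance_nm, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.cdf_pct[min(idx, len(self.cdf_pct) - 1)])


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Pixels of *mask* with ≥1 four-neighbour outside it (border = outside)."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~interior


def extract_boundary(mask: np.ndarray, z: int, class_name: str) -> BoundarySet:
    """Boundary pixel set of a class mask in one slice."""
    pix = np.argwhere(boundary_mask(mask))
    return BoundarySet(z=z, class_name=class_name, pixels=pix)


def min_distances(a: BoundarySet, b: BoundarySet, dx_nm: float) -> np.ndarray:
    """Minimal distance (nm) from each A-boundary pixel to the nearest B pixel.

    Returns one distance per A pixel, in A's pixel order.  Raises if B is
    empty — callers flag those slices as "class absent" and exclude them.
    """
    if len(b) == 0:
        raise ValueError(
            f"class {b.class_name!r} absent in slice {b.z}: no boundary pixels"
        )
    if len(a) == 0:
        return np.empty(0, dtype=float)
    tree = cKDTree(b.pixels)
    d, _ = tree.query(a.pixels, k=1)
    return d * dx_nm


def build_histogram(
    distances_nm: np.ndarray, bin_width_nm: float = 6.0, max_nm: float = 2004.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised left-closed right-open histogram with a final overflow bin.

    Bins are ``[k·w, (k+1)·w)`` for k = 0 .. max/w − 1 plus ``[max, ∞)``.
    Returns ``(fractions, edges)`` where ``edges`` has ``len(fractions)+1``
    entries and ends in ``inf``.  Empty input yields an all-zero histogram
    (flagged by its zero sum).
    """
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be positive")
    distances_nm = np.asarray(distances_nm, dtype=float)
    n_bins = int(np.ceil(max_nm / bin_width_nm))
    edges = np.append(np.arange(n_bins + 1) * bin_width_nm, np.inf)
    counts, _ = np.histogram(distances_nm, bins=edges)
    total = counts.sum()
    frac = counts / total if total else counts.astype(float)
    return frac, edges


def stack_mean_histogram(
    per_slice: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Unweighted mean ± SD per bin across slices where the pair is present.

    *per_slice* is ``(n_slices, n_bins)`` with NaN rows marking slices where
    either class was absent.  Returns ``(mean, sd, n_excluded)``; raises if
    every slice is excluded.
    """
    per_slice = np.asarray(per_slice, dtype=float)
    valid = ~np.isnan(per_slice).any(axis=1)
    if not valid.any():
        raise ValueError("pair absent from stack: no slice has both classes")
    h = per_slice[valid]
    return h.mean(axis=0), h.std(axis=0, ddof=0), int((~valid).sum())


def cdf_from_histogram(hist: np.ndarray) -> np.ndarray:
    """Cumulative percentage at each upper bin edge (running sum × 100)."""
    return np.cumsum(np.asarray(hist, dtype=float)) * 100.0


def contact_fraction(
    a: BoundarySet, b: BoundarySet, dx_nm: float, contact_nm: float = 10.0
) -> float:
    """% of A-boundary pixels whose minimal distance to B is ≤ *contact_nm*."""
    d = min_distances(a, b, dx_nm)
    if d.size == 0:
        return float("nan")
    return float((d <= contact_nm).mean() * 100.0)


def analyze_pair(
    vol: LabelVolume,
    class_a: str,
    class_b: str,
    bin_width_nm: float = 6.0,
    max_nm: float = 2004.0,
    contact_nm: float = 10.0,
    pooled: bool = False,
) -> ProximityResult:
    """Full per-stack proximity statistics for one ordered pair A → B.

    Slices where either class has no boundary pixels are excluded from the
    histograms and contact aggregation (their rows are NaN).  With
    ``pooled=True`` the stack histogram pools all pixels' distances instead
    of averaging per-slice histograms (the per-slice mean remains the
    default because stack mean ± SD summaries require per-slice values).
    """
    n_bins = int(np.ceil(max_nm / bin_width_nm))
    per_slice = np.full((vol.n_slices, n_bins + 1), np.nan)
    contact_per_slice = np.full(vol.n_slices, np.nan)
    pooled_distances: list[np.ndarray] = []
    edges = None
    excluded: list[int] = []
    for z in range(vol.n_slices):
        a = extract_boundary(class_mask(vol, class_a, z), z, class_a)
        b = extract_boundary(class_mask(vol, class_b, z), z, class_b)
        if len(a) == 0 or len(b) == 0:
            excluded.append(z)
            continue
        d = min_distances(a, b, vol.dx_nm)
        frac, edges = build_histogram(d, bin_width_nm, max_nm)
        per_slice[z] = frac
        contact_per_slice[z] = (d <= contact_nm).mean() * 100.0
        if pooled:
            pooled_distances.append(d)
    if edges is None:
        raise ValueError(
            f"pair ({class_a!r}, {class_b!r}) absent from stack: "
            "no slice has both classes"
        )
    if pooled:
        mean_hist, edges = build_histogram(
            np.concatenate(pooled_distances), bin_width_nm, max_nm
        )
        sd_hist = np.zeros_like(mean_hist)
    else:
        mean_hist, sd_hist, _ = stack_mean_histogram(per_slice)
    valid_contact = contact_per_slice[~np.isnan(contact_per_slice)]
    return ProximityResult(
        class_a=class_a,
        class_b=class_b,
        bin_edges_nm=edges,
        per_slice_hist=per_slice,
        stack_mean_hist=mean_hist,
        stack_sd_hist=sd_hist,
        cdf_pct=cdf_from_histogram(mean_hist),
        contact_nm=contact_nm,
        contact_pct_per_slice=contact_per_slice,
        contact_pct_mean=float(valid_contact.mean()),
        contact_pct_sd=float(valid_contact.std(ddof=0)),
        contact_pct_min=float(valid_contact.min()),
        contact_pct_max=float(valid_contact.max()),
        excluded_slices=excluded,
    )


def abluminal_boundary(vol: LabelVolume, z: int) -> BoundarySet:
    """Endothelial boundary pixels not 4-adjacent to the lumen.

    The abluminal surface is the outward-facing side of the endothelium —
    the side the basement membrane and pericytes appose.  Pixels touching
    the lumen (the luminal surface) are removed from the full boundary.
    """
    endo = class_mask(vol, "endothelium", z)
    bound = boundary_mask(endo)
    if vol.has_class("lumen"):
        lumen = class_mask(vol, "lumen", z)
        near_lumen = ndimage.binary_dilation(lumen, structure=_CROSS)
        bound &= ~near_lumen
    return BoundarySet(z=z, class_name="endothelium_abluminal", pixels=np.argwhere(bound))


@dataclass
class CoverageResult:
    """Pericyte ensheathment of the abluminal endothelial surface."""

    coverage_nm: float
    per_slice_pct: np.ndarray
    mean_pct: float
    sd_pct: float
    min_pct: float
    max_pct: float
    pericyte_absent_slices: list[int]
    include_absent_as_zero: bool


def ensheathment_coverage(
    vol: LabelVolume,
    coverage_nm: float = 200.0,
    target: str = "boundary",
    include_absent_as_zero: bool = True,
) -> CoverageResult:
    """Per-slice % of the abluminal endothelial boundary within *coverage_nm*
    of the pericyte layer, with stack mean ± SD and range.

    ``target`` selects the pericyte reference: its boundary pixels
    (``"boundary"``, default) or the full pericyte mask (``"mask"``).
    Slices with no pericyte score 0% and are included in the aggregate by
    default (``include_absent_as_zero``); pass False to exclude them.
    """
    if target not in ("boundary", "mask"):
        raise ValueError("target must be 'boundary' or 'mask'")
    per_slice = np.full(vol.n_slices, np.nan)
    absent: list[int] = []
    for z in range(vol.n_slices):
        ablum = abluminal_boundary(vol, z)
        if len(ablum) == 0:
            raise ValueError(f"endothelium absent (or lumen-only) in slice {z}")
        peri = class_mask(vol, "pericyte", z) if vol.has_class("pericyte") else None
        if peri is None or not peri.any():
            absent.append(z)
            per_slice[z] = 0.0
            continue
        ref = peri if target == "mask" else boundary_mask(peri)
        # exact Euclidean distance (in px) from every pixel to the reference set
        dist_px = ndimage.distance_transform_edt(~ref)
        d = dist_px[ablum.pixels[:, 0], ablum.pixels[:, 1]] * vol.dx_nm
        per_slice[z] = (d <= coverage_nm).mean() * 100.0
    agg = per_slice if include_absent_as_zero else np.delete(per_slice, absent)
    if agg.size == 0:
        raise ValueError("no slices left to aggregate: pericyte absent everywhere")
    return CoverageResult(
        coverage_nm=coverage_nm,
        per_slice_pct=per_slice,
        mean_pct=float(agg.mean()),
        sd_pct=float(agg.std(ddof=0)),
        min_pct=float(agg.min()),
        max_pct=float(agg.max()),
        pericyte_absent_slices=absent,
        include_absent_as_zero=include_absent_as_zero,
    )
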