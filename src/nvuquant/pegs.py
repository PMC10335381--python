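"""Rule-based 3D detection of peg-and-socket membrane protrusions.

Pericytes and endothelial cells interdigitate through breaks in their shared
basement membrane (BM): a finger of one cell (the peg) is engulfed by an
invagination of the other (the socket).  The detector mirrors a
dilation–intersection pipeline: per slice, the host class is morphologically
dilated and its intersection with the protruding class marks potential
interaction sites; the sites are grown into 3D candidate regions and each
candidate is screened against five compulsory geometric criteria:

1. *z-span* — the candidate spans ≥ 200 nm along z (distinct sections ×
   section thickness, closed inequality);
2. *attachment* — in at least one member slice the candidate touches the
   cell body (the slice's largest same-class component besides itself);
3. *BM traversal* — the candidate occupies a local break in the BM sheath,
   exposed as (morphological closing of the BM by a disk) minus the BM;
4. *engulfment* — in at least one slice, ≥ θ (default 2/3) of the candidate
   boundary pixels that do not face their own class are 8-adjacent to the
   host class;
5. *minimum extent* — principal-axis extents of at least 100 nm (length)
   and 70 nm (width) in some member slice.

A candidate is an accepted peg only if all five hold.

Because the grown candidate necessarily drags in a collar of its own cell
body (and, in the reverse scan, the socket lining around a true peg of the
partner class is itself tagged), extent, engulfment and BM traversal are
evaluated on the candidate's *protrusion core*: the candidate minus a
dilation of the remaining cell body.  A true peg keeps a substantial core;
socket linings and flat contact strips — close appositions that are not
pegs — lose their entire core and fail, which is exactly the superset
behaviour expected of the dilation–intersection stage (it tags all pegs
plus mere close contacts, and the criteria then discard the latter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import LabelVolume, class_volume_mask

_EIGHT = np.ones((3, 3), dtype=bool)
_SHIFTS8 = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]

CRITERIA = ("z_span", "attachment", "bm_traversal", "engulfment", "min_extent")


@dataclass
class PegParams:
    """Detector thresholds; defaults follow the five compulsory criteria."""

    dilation_px: int = 2  # host dilation radius (12 nm at 6 nm/px)
    context_radius_px: int = 18  # geodesic growth of candidate seeds
    r_bm_px: int = 12  # BM closing radius: bridges breaks up to ~2r wide
    engulfment_theta: float = 2.0 / 3.0
    z_span_min_nm: float = 200.0
    min_length_nm: float = 100.0
    min_width_nm: float = 70.0

    @property
    def core_margin_px(self) -> int:
        # a grown candidate can reach at most this far from the residual body
        return self.context_radius_px + self.dilation_px


@dataclass
class PegCandidate:
    """One 3D candidate region with its per-criterion verdicts."""

    component_id: int
    direction: str  # "pericyte_facing" or "endothelium_facing"
    protruder: str
    host: str
    voxels: np.ndarray  # (n, 3) int (z, y, x)
    core_voxels: np.ndarray  # protrusion core subset
    z_sections: int = 0
    z_span_nm: float = 0.0
    length_nm: float = 0.0  # max per-slice major-axis extent of the core
    width_nm: float = 0.0  # max per-slice minor-axis extent of the core
    criteria: dict[str, bool] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return bool(self.criteria) and all(self.criteria[c] for c in CRITERIA)

    def member_slices(self) -> np.ndarray:
        return np.unique(self.voxels[:, 0])

    def slice_mask(self, z: int, shape: tuple[int, int], core: bool = False) -> np.ndarray:
        vox = self.core_voxels if core else self.voxels
        sel = vox[vox[:, 0] == z]
        m = np.zeros(shape, dtype=bool)
        m[sel[:, 1], sel[:, 2]] = True
        return m


def disk_dilate(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Exact Euclidean-disk dilation via the distance transform."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or radius_px <= 0:
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius_px


def disk_closing(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean-disk closing (dilation then erosion) via distance transforms."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or radius_px <= 0:
        return mask.copy()
    dilated = ndimage.distance_transform_edt(~mask) <= radius_px
    if dilated.all():
        return dilated
    # erosion: keep pixels farther than radius from the dilated set's complement
    return ndimage.distance_transform_edt(dilated) > radius_px


def _chebyshev_dilate(mask: np.ndarray, radius_px: int) -> np.ndarray:
    if not mask.any() or radius_px <= 0:
        return mask.copy()
    dt = ndimage.distance_transform_cdt(~mask, metric="chessboard")
    return dt <= radius_px


def candidate_regions(
    vol: LabelVolume,
    protruder: str,
    host: str,
    dilation_px: int = 2,
    context_radius_px: int = 18,
) -> list[np.ndarray]:
    """3D candidate components of the protruding class.

    Per slice the host mask is dilated by a Euclidean disk and intersected
    with the protruder mask; the intersection seeds a geodesic flood fill
    within the protruder class (8-connected in-plane, up to
    *context_radius_px* steps), and the grown voxels are split into
    26-connected 3D components.  Returns one ``(n, 3)`` voxel index array
    per component, in deterministic (raster) order.
    """
    if not (vol.has_class(protruder) and vol.has_class(host)):
        return []
    prot = class_volume_mask(vol, protruder)
    host_m = class_volume_mask(vol, host)
    if not prot.any() or not host_m.any():
        return []
    grown = np.zeros_like(prot)
    for z in range(vol.n_slices):
        seed = prot[z] & disk_dilate(host_m[z], dilation_px)
        if not seed.any():
            continue
        grown[z] = ndimage.binary_dilation(
            seed, structure=_EIGHT, iterations=context_radius_px, mask=prot[z]
        )
    labelled, n = ndimage.label(grown, structure=np.ones((3, 3, 3), dtype=bool))
    return [np.argwhere(labelled == i) for i in range(1, n + 1)]


def protrusion_core(
    cand_voxels: np.ndarray, prot: np.ndarray, core_margin_px: int
) -> np.ndarray:
    """Candidate voxels farther (in-plane Chebyshev) than *core_margin_px*
    from the residual cell body (the protruder class minus the candidate)."""
    core = []
    for z in np.unique(cand_voxels[:, 0]):
        sel = cand_voxels[cand_voxels[:, 0] == z]
        cmask = np.zeros(prot.shape[1:], dtype=bool)
        cmask[sel[:, 1], sel[:, 2]] = True
        body = prot[z] & ~cmask
        keep = cmask & ~_chebyshev_dilate(body, core_margin_px)
        for y, x in np.argwhere(keep):
            core.append((z, y, x))
    return np.array(core, dtype=np.int64).reshape(-1, 3)


def check_z_span(cand: PegCandidate, dz_nm: float, min_nm: float = 200.0) -> bool:
    """Criterion 1: distinct sections × dz ≥ min (closed inequality)."""
    return cand.z_sections * dz_nm >= min_nm


def check_attachment(cand: PegCandidate, vol: LabelVolume) -> bool:
    """Criterion 2: in ≥1 member slice the candidate is 8-adjacent to the
    slice's largest same-class component excluding the candidate itself."""
    prot = class_volume_mask(vol, cand.protruder)
    shape = prot.shape[1:]
    for z in cand.member_slices():
        cmask = cand.slice_mask(z, shape)
        body = prot[z] & ~cmask
        if not body.any():
            continue
        labelled, n = ndimage.label(body, structure=_EIGHT)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(body, labelled, index=np.arange(1, n + 1))
        largest = labelled == (1 + int(np.argmax(sizes)))
        if (ndimage.binary_dilation(cmask, structure=_EIGHT) & largest).any():
            return True
    return False


def check_bm_traversal(
    cand: PegCandidate,
    vol: LabelVolume,
    r_bm_px: int = 12,
    reach_px: int | None = None,
) -> bool:
    """Criterion 3: the protrusion core sits in (or hard against) a local
    break in the BM sheath, exposed as closing(BM) minus BM.

    *reach_px* (default: the core margin used to carve the core) re-expands
    the core toward the break it crossed — the core itself starts strictly
    inside the host, one body-margin away from the BM band.  Wide BM-absent
    sectors are not breaks: the closing cannot bridge them, so candidates
    there fail.
    """
    if reach_px is None:
        reach_px = PegParams().core_margin_px
    bm = (
        class_volume_mask(vol, "basement_membrane")
        if vol.has_class("basement_membrane")
        else None
    )
    if bm is None or not bm.any():
        warnings.warn("basement membrane absent from volume: BM traversal is false")
        return False
    shape = bm.shape[1:]
    for z in np.unique(cand.core_voxels[:, 0]) if len(cand.core_voxels) else []:
        core = cand.slice_mask(z, shape, core=True)
        if not core.any() or not bm[z].any():
            continue
        band = disk_closing(bm[z], r_bm_px) & ~bm[z]
        if not band.any():
            continue
        if (_chebyshev_dilate(core, reach_px) & band).any():
            return True
    return False


def _component_solidity(pixels: np.ndarray) -> float:
    """Pixel count over rasterised-convex-hull pixel count of a 2D component."""
    from .morphometrics import rasterise_hull

    span = pixels.max(axis=0) - pixels.min(axis=0) + 1
    local = np.zeros(span, dtype=bool)
    local[pixels[:, 0] - pixels[:, 0].min(), pixels[:, 1] - pixels[:, 1].min()] = True
    hull = rasterise_hull(local)
    if hull is None:
        return 1.0
    return float(local.sum() / hull.sum())


def _opposing_contact(host_pixels: np.ndarray, centroid: np.ndarray) -> bool:
    """True when host contacts wrap the region: two contact pixels seen from
    the component centroid at ≥ 120° from each other (a peg is gripped on
    both flanks; a socket lining touches the partner from one side only)."""
    u = host_pixels.astype(float) - centroid
    norm = np.hypot(u[:, 0], u[:, 1])
    u = u[norm > 0] / norm[norm > 0, None]
    if len(u) < 2:
        return False
    if len(u) > 200:  # deterministic thinning; extremes survive subsampling
        u = u[:: len(u) // 200 + 1]
    return bool((u @ u.T).min() <= -0.5)


def check_engulfment(
    cand: PegCandidate, vol: LabelVolume, theta: float = 2.0 / 3.0
) -> bool:
    """Criterion 4: in ≥1 member slice, one connected component of the
    protrusion core has ≥ θ of its exposed boundary pixels (those not facing
    their own class) 8-adjacent to the host class, with host contact coming
    from opposing directions around the component.

    The component must itself be compact (solidity ≥ 0.75): an engulfed peg
    is a solid finger the host wraps around, whereas a socket lining — the
    host-side shell the reverse scan tags around a true peg of the partner
    class — is concave around its apparent host and is rejected here."""
    if len(cand.core_voxels) == 0:
        return False
    prot_label = vol.label_of(cand.protruder)
    host_label = vol.label_of(cand.host)
    shape = vol.voxels.shape[1:]
    if theta <= 0:  # degenerate threshold: any host contact passes
        for z, y, x in cand.core_voxels:
            y0, y1 = max(y - 1, 0), min(y + 2, shape[0])
            x0, x1 = max(x - 1, 0), min(x + 2, shape[1])
            if (vol.voxels[z, y0:y1, x0:x1] == host_label).any():
                return True
        return False
    for z in np.unique(cand.core_voxels[:, 0]):
        core = cand.slice_mask(z, shape, core=True)
        labels = vol.voxels[z].astype(np.int64)
        has_nonown = np.zeros(shape, dtype=bool)
        has_host = np.zeros(shape, dtype=bool)
        for dy, dx in _SHIFTS8:
            shifted = np.full(shape, -1, dtype=labels.dtype)
            ys = slice(max(dy, 0), shape[0] + min(dy, 0))
            xs = slice(max(dx, 0), shape[1] + min(dx, 0))
            ys_src = slice(max(-dy, 0), shape[0] + min(-dy, 0))
            xs_src = slice(max(-dx, 0), shape[1] + min(-dx, 0))
            shifted[ys, xs] = labels[ys_src, xs_src]
            has_nonown |= shifted != prot_label
            has_host |= shifted == host_label
        comp, n = ndimage.label(core, structure=_EIGHT)
        if n == 0:
            continue
        # judge the dominant core component only: slivers left over from
        # body-margin carving are artifacts, not the protrusion itself
        sizes = ndimage.sum_labels(core, comp, index=np.arange(1, n + 1))
        for i in [1 + int(np.argmax(sizes))]:
            region = comp == i
            exposed = region & has_nonown
            n_exposed = int(exposed.sum())
            if n_exposed == 0:
                continue
            host_contact = exposed & has_host
            if int(host_contact.sum()) / n_exposed < theta:
                continue
            pix = np.argwhere(region)
            if _component_solidity(pix) < 0.75:
                continue
            if _opposing_contact(np.argwhere(host_contact), pix.mean(axis=0)):
                return True
    return False


def slice_extents_px(pixels: np.ndarray) -> tuple[float, float]:
    """Principal-axis (length, width) extents of a 2D pixel set, in px.

    Extent along each principal axis is (max − min projection) + 1 pixel of
    footprint; a single pixel measures 1 × 1.
    """
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 2)
    if len(pixels) == 0:
        return 0.0, 0.0
    if len(pixels) == 1:
        return 1.0, 1.0
    centred = pixels - pixels.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    _, vecs = np.linalg.eigh(cov)  # ascending eigenvalues: minor then major
    proj = centred @ vecs
    wid = float(proj[:, 0].max() - proj[:, 0].min()) + 1.0
    length = float(proj[:, 1].max() - proj[:, 1].min()) + 1.0
    return max(length, wid), min(length, wid)


def check_min_extent(
    cand: PegCandidate,
    dx_nm: float,
    min_length_nm: float = 100.0,
    min_width_nm: float = 70.0,
) -> tuple[bool, float, float]:
    """Criterion 5: in some member slice a single connected component of the
    protrusion core measures ≥ 100 nm along its major axis and ≥ 70 nm along
    its minor axis.  Returns ``(flag, length_nm, width_nm)``; the recorded
    extents are the per-component maxima over slices."""
    if len(cand.core_voxels) == 0:
        return False, 0.0, 0.0
    best_len = best_wid = 0.0
    flag = False
    for z in np.unique(cand.core_voxels[:, 0]):
        sel = cand.core_voxels[cand.core_voxels[:, 0] == z]
        if len(sel) == 0:
            continue
        span = sel[:, 1:].max(axis=0) - sel[:, 1:].min(axis=0) + 3
        origin = sel[:, 1:].min(axis=0) - 1
        local = np.zeros(span, dtype=bool)
        local[sel[:, 1] - origin[0], sel[:, 2] - origin[1]] = True
        comp, n = ndimage.label(local, structure=_EIGHT)
        for i in range(1, n + 1):
            length, wid = slice_extents_px(np.argwhere(comp == i))
            best_len = max(best_len, length * dx_nm)
            best_wid = max(best_wid, wid * dx_nm)
            if length * dx_nm >= min_length_nm and wid * dx_nm >= min_width_nm:
                flag = True
    return flag, best_len, best_wid


@dataclass
class PegDetectionResult:
    candidates: list[PegCandidate]
    z_distribution: np.ndarray  # per-slice count of accepted pegs present
    params: PegParams

    @property
    def accepted(self) -> list[PegCandidate]:
        return [c for c in self.candidates if c.accepted]


_DIRECTIONS = {
    "pericyte_facing": ("pericyte", "endothelium"),
    "endothelium_facing": ("endothelium", "pericyte"),
}


def detect_pegs(vol: LabelVolume, params: PegParams | None = None) -> PegDetectionResult:
    """Run candidate generation in both directions and apply all five checks.

    The per-slice z-distribution counts accepted pegs present in each
    section; a peg spanning N sections contributes to each of them.
    """
    params = params or PegParams()
    candidates: list[PegCandidate] = []
    cid = 0
    for direction, (protruder, host) in _DIRECTIONS.items():
        regions = candidate_regions(
            vol, protruder, host, params.dilation_px, params.context_radius_px
        )
        if not regions:
            continue
        prot = class_volume_mask(vol, protruder)
        for vox in regions:
            core = protrusion_core(vox, prot, params.core_margin_px)
            cand = PegCandidate(
                component_id=cid,
                direction=direction,
                protruder=protruder,
                host=host,
                voxels=vox,
                core_voxels=core,
            )
            cid += 1
            cand.z_sections = len(cand.member_slices())
            cand.z_span_nm = cand.z_sections * vol.dz_nm
            ext_ok, cand.length_nm, cand.width_nm = check_min_extent(
                cand, vol.dx_nm, params.min_length_nm, params.min_width_nm
            )
            cand.criteria = {
                "z_span": check_z_span(cand, vol.dz_nm, params.z_span_min_nm),
                "attachment": check_attachment(cand, vol),
                "bm_traversal": check_bm_traversal(
                    cand, vol, params.r_bm_px, params.core_margin_px
                ),
                "engulfment": check_engulfment(cand, vol, params.engulfment_theta),
                "min_extent": ext_ok,
            }
            candidates.append(cand)
    z_dist = np.zeros(vol.n_slices, dtype=int)
    for cand in candidates:
        if cand.accepted:
            z_dist[cand.member_slices()] += 1
    return PegDetectionResult(candidates=candidates, z_distribution=z_dist, params=params)
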