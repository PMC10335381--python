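"""Synthetic capillary phantoms with exact geometric ground truth.

The generator renders the cross-sectional anatomy of a retinal capillary as
concentric, optionally jittered annuli on each section: a central lumen
wrapped by the endothelial tube, a thin basement-membrane (BM) sheath, a
partial pericyte sheath covering a chosen fraction of the abluminal
circumference, and an outer patchwork of macroglia and neurons.  On top of
the base anatomy it can carve gaps in the BM (bringing pericyte and
endothelium into direct contact) and insert peg-and-socket protrusions of
either cell into the other, each annotated with exactly which of the five
detection criteria it satisfies — so every analysis stage of the pipeline
can be validated against known truth without any acquired data.

Geometry notes
--------------
* The default canvas is 512 × 512 px at 6 nm/px (desk scale; the acquired
  stacks this emulates are 3000 × 3000 px at the same pixel size — the
  anatomy here is scaled to fit while keeping all thicknesses in real nm).
* The pericyte arc angle is calibrated so that *measured* ensheathment at
  the calibration threshold (default 200 nm) equals the requested coverage
  fraction: abluminal pixels just beyond the arc ends still fall within the
  threshold of the arc-end boundary, so the rendered arc is shrunk by that
  capture angle.
* Boundary jitter is a band-limited radial perturbation per interface
  (harmonics 2–5, slowly drifting along z), keeping every class simply
  connected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import DEFAULT_CLASS_MAP, LabelVolume, write_label_stack

TRUTH_SCHEMA_VERSION = 1

# rendering constants (nm)
PEG_BASE_OVERLAP_NM = 18.0  # peg base reaches into its parent sheath
PEG_DETACH_NM = 42.0  # BM plug isolating a detached decoy from its body
PEG_EXPOSURE_NM = 24.0  # width of the BM strip exposing a decoy flank
LUMEN_CLEARANCE_NM = 12.0

# criterion thresholds used for truth annotation (mirrors the detector)
Z_SPAN_MIN_NM = 200.0
MIN_LENGTH_NM = 100.0
MIN_WIDTH_NM = 70.0
ENGULF_THETA = 2.0 / 3.0


@dataclass
class PegSpec:
    """One peg-and-socket protrusion to insert.

    ``direction`` names the protruding class: a pericyte-facing peg is a
    pericyte finger socketed in the endothelium, and vice versa.  ``angle``
    is the angular position (radians); ``length_nm`` is the radial reach
    beyond the protruder's own BM interface, ``width_nm`` the transverse
    extent.  ``attached=False`` renders an orphan island separated from its
    cell body by a BM plug; ``through_bm_gap=False`` skips carving a local
    BM break (the caller must place the peg inside a pre-carved wide BM-free
    sector); ``engulf_frac`` below 2/3 exposes one flank to the BM instead
    of the host.
    """

    direction: str  # "pericyte_facing" | "endothelium_facing"
    z_start: int
    n_sections: int
    angle: float
    length_nm: float
    width_nm: float
    attached: bool = True
    through_bm_gap: bool = True
    engulf_frac: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("pericyte_facing", "endothelium_facing"):
            raise ValueError(f"unknown peg direction {self.direction!r}")
        if self.n_sections < 1:
            raise ValueError("n_sections must be ≥ 1")
        if self.length_nm <= 0 or self.width_nm <= 0:
            raise ValueError("length_nm and width_nm must be positive")

    def criterion_flags(self, dz_nm: float) -> dict[str, bool]:
        """Which of the five detection criteria this peg satisfies, by design."""
        return {
            "z_span": self.n_sections * dz_nm >= Z_SPAN_MIN_NM,
            "attachment": self.attached,
            "bm_traversal": self.through_bm_gap,
            "engulfment": self.engulf_frac >= ENGULF_THETA,
            "min_extent": (
                self.length_nm >= MIN_LENGTH_NM and self.width_nm >= MIN_WIDTH_NM
            ),
        }


@dataclass
class BmGapSpec:
    """An angular sector of the BM to carve over a z-range (half-open)."""

    z_start: int
    z_stop: int
    theta_start: float
    theta_stop: float


@dataclass
class PhantomParams:
    """Full description of a phantom; identical params ⇒ identical voxels."""

    n_slices: int = 16
    slice_px: int = 512
    dx_nm: float = 6.0
    dz_nm: float = 120.0
    lumen_radius_nm: float = 700.0
    endo_thickness_nm: float = 350.0
    bm_thickness_nm: float = 60.0
    pericyte_thickness_nm: float = 250.0
    pericyte_coverage_frac: float = 0.35
    pericyte_arc_center: float = np.pi / 2
    outer_radius_nm: float = 1500.0
    macroglia_frac: float = 0.7
    neuron_frac: float = 0.3
    n_outer_patches: int = 6
    jitter_nm: float = 12.0
    coverage_calibration_nm: float = 200.0
    bm_gap_specs: list[BmGapSpec] = field(default_factory=list)
    peg_specs: list[PegSpec] = field(default_factory=list)
    seed: int = 0

    # cumulative interface radii
    @property
    def r_lumen(self) -> float:
        return self.lumen_radius_nm

    @property
    def r_endo_out(self) -> float:
        return self.r_lumen + self.endo_thickness_nm

    @property
    def r_bm_out(self) -> float:
        return self.r_endo_out + self.bm_thickness_nm

    @property
    def r_peri_out(self) -> float:
        return self.r_bm_out + self.pericyte_thickness_nm

    def validate(self) -> None:
        for name in (
            "lumen_radius_nm",
            "endo_thickness_nm",
            "bm_thickness_nm",
            "pericyte_thickness_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.pericyte_coverage_frac <= 1.0:
            raise ValueError("pericyte_coverage_frac must be in [0, 1]")
        half_width = (self.slice_px / 2 - 2) * self.dx_nm
        if self.r_peri_out >= half_width:
            raise ValueError(
                "geometrically impossible: ring radii exceed the slice half-width "
                f"({self.r_peri_out:.0f} ≥ {half_width:.0f} nm)"
            )
        if self.outer_radius_nm < self.r_peri_out:
            raise ValueError("outer_radius_nm must be ≥ the pericyte outer radius")
        min_thick = min(
            self.endo_thickness_nm, self.bm_thickness_nm, self.pericyte_thickness_nm
        )
        if self.jitter_nm > min_thick / 2:
            raise ValueError("jitter_nm exceeds half the thinnest layer")
        if self.macroglia_frac < 0 or self.neuron_frac < 0:
            raise ValueError("composition fractions must be non-negative")
        if self.macroglia_frac + self.neuron_frac > 1 + 1e-9:
            raise ValueError("macroglia_frac + neuron_frac must be ≤ 1")

    def arc_half_angle(self) -> float:
        """Rendered pericyte arc half-angle, calibrated for measured coverage.

        An abluminal pixel at angular offset Δφ beyond the arc end is still
        within the calibration distance of the arc-end boundary edge while
        √(g² + r²Δφ²) ≤ cal (g = BM thickness, r ≈ geometric-mean radius),
        so the arc is shrunk by that capture angle on each side.
        """
        f = self.pericyte_coverage_frac
        if f <= 0:
            return -1.0  # no pericyte at all
        if f >= 1:
            return np.pi  # full ring
        g = self.bm_thickness_nm
        cal = self.coverage_calibration_nm
        r_eff = np.sqrt(self.r_endo_out * self.r_bm_out)
        capture = np.sqrt(max(cal**2 - g**2, 0.0)) / r_eff
        half = np.pi * f - capture
        if half <= 0:
            raise ValueError(
                "pericyte_coverage_frac too small to calibrate: the arc-end "
                "capture angle exceeds the requested arc"
            )
        return half


def _wrap(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-π, π]."""
    return (np.asarray(angle) + np.pi) % (2 * np.pi) - np.pi


_GRID_CACHE: dict[tuple[int, float], tuple[np.ndarray, ...]] = {}


def _grids(slice_px: int, dx_nm: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(X, Y, R, Θ) pixel-centre coordinate grids in nm, origin at the canvas centre."""
    key = (slice_px, dx_nm)
    if key not in _GRID_CACHE:
        c = (slice_px - 1) / 2.0
        yy, xx = np.mgrid[0:slice_px, 0:slice_px].astype(float)
        x = (xx - c) * dx_nm
        y = (yy - c) * dx_nm
        _GRID_CACHE[key] = (x, y, np.hypot(x, y), np.arctan2(y, x))
    return _GRID_CACHE[key]


@dataclass
class PegTruth:
    """Ground truth for one inserted peg."""

    spec: PegSpec
    criteria: dict[str, bool]
    voxels: np.ndarray  # (n, 3) int (z, y, x) of the rendered protrusion

    @property
    def valid(self) -> bool:
        return all(self.criteria.values())


@dataclass
class BmGapTruth:
    spec: BmGapSpec
    voxels: np.ndarray  # BM voxels reassigned by the carve


@dataclass
class PhantomTruth:
    """Everything the generator knows about a rendered phantom."""

    params: PhantomParams
    per_slice_coverage_frac: np.ndarray
    pegs: list[PegTruth] = field(default_factory=list)
    bm_gaps: list[BmGapTruth] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        p = asdict(self.params)
        p["bm_gap_specs"] = [asdict(g) for g in self.params.bm_gap_specs]
        p["peg_specs"] = [asdict(s) for s in self.params.peg_specs]
        pegs = []
        for peg in self.pegs:
            bbox = (
                peg.voxels.min(axis=0).tolist() + peg.voxels.max(axis=0).tolist()
                if len(peg.voxels)
                else None
            )
            pegs.append(
                {
                    "spec": asdict(peg.spec),
                    "criteria": peg.criteria,
                    "valid": peg.valid,
                    "n_voxels": int(len(peg.voxels)),
                    "bbox_zyx": bbox,
                }
            )
        return {
            "schema_version": TRUTH_SCHEMA_VERSION,
            "params": p,
            "per_slice_coverage_frac": self.per_slice_coverage_frac.tolist(),
            "pegs": pegs,
            "bm_gaps": [
                {"spec": asdict(g.spec), "n_voxels": int(len(g.voxels))}
                for g in self.bm_gaps
            ],
        }


def _outer_label(theta: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Patchwork assignment of the outer field by angle."""
    u = (((theta + np.pi) / (2 * np.pi)) * params.n_outer_patches) % 1.0
    lab = np.zeros(theta.shape, dtype=np.uint8)  # background
    lab[u < params.neuron_frac + params.macroglia_frac] = 5  # macroglia
    lab[u < params.neuron_frac] = 6  # neuron
    return lab


def _interface_jitter(params: PhantomParams, rng: np.random.Generator):
    """Per-interface band-limited radial perturbation j(θ, z), |j| ≤ jitter_nm."""
    harmonics = np.arange(2, 6)
    funcs = []
    for _ in range(4):  # lumen, endo-out, bm-out, peri-out interfaces
        amp = rng.uniform(0.5, 1.0, size=harmonics.size)
        amp *= params.jitter_nm / amp.sum()
        phase = rng.uniform(0, 2 * np.pi, size=harmonics.size)
        drift = rng.uniform(-0.15, 0.15, size=harmonics.size)

        def j(theta, z, amp=amp, phase=phase, drift=drift):
            out = np.zeros_like(theta)
            for a, k, p, d in zip(amp, harmonics, phase, drift):
                out += a * np.cos(k * theta + p + d * z)
            return out

        funcs.append(j)
    return funcs


def generate_capillary_volume(params: PhantomParams) -> tuple[LabelVolume, PhantomTruth]:
    """Render a phantom and its ground truth.  Deterministic given the seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    j_lumen, j_endo, j_bm, j_peri = _interface_jitter(params, rng)
    _, _, radius, theta = _grids(params.slice_px, params.dx_nm)
    half = params.arc_half_angle()
    voxels = np.zeros((params.n_slices, params.slice_px, params.slice_px), dtype=np.uint8)
    outer = _outer_label(theta, params)
    for z in range(params.n_slices):
        lab = np.zeros((params.slice_px, params.slice_px), dtype=np.uint8)
        in_outer = radius < params.outer_radius_nm
        lab[in_outer] = outer[in_outer]
        in_peri = radius < params.r_peri_out + j_peri(theta, z)
        if half >= np.pi:
            arc = np.ones_like(in_peri)
        elif half < 0:
            arc = np.zeros_like(in_peri)
        else:
            arc = np.abs(_wrap(theta - params.pericyte_arc_center)) <= half
        lab[in_peri & arc] = 4
        lab[radius < params.r_bm_out + j_bm(theta, z)] = 3
        lab[radius < params.r_endo_out + j_endo(theta, z)] = 2
        lab[radius < params.r_lumen + j_lumen(theta, z)] = 1
        voxels[z] = lab
    vol = LabelVolume(
        voxels=voxels,
        dx_nm=params.dx_nm,
        dy_nm=params.dx_nm,
        dz_nm=params.dz_nm,
        class_map=dict(DEFAULT_CLASS_MAP),
    )
    truth = PhantomTruth(
        params=params,
        per_slice_coverage_frac=np.full(
            params.n_slices, params.pericyte_coverage_frac
        ),
    )
    for gap in params.bm_gap_specs:
        carve_bm_gap(vol, gap, truth=truth, params=params)
    for spec in params.peg_specs:
        insert_peg(vol, truth, spec, params=params)
    return vol, truth


def carve_bm_gap(
    vol: LabelVolume,
    gap: BmGapSpec,
    truth: PhantomTruth | None = None,
    params: PhantomParams | None = None,
) -> LabelVolume:
    """Reassign BM voxels in an angular sector to the adjacent classes.

    The inner half of the sheath becomes endothelium and the outer half
    takes the class lying just outside the BM at that angle (pericyte where
    the arc is present, otherwise the outer field), so the carve brings the
    neighbours into direct contact.  An empty intersection is a warning and
    a no-op.
    """
    if params is None and truth is not None:
        params = truth.params
    if params is None:
        raise ValueError("carve_bm_gap needs PhantomParams (directly or via truth)")
    _, _, radius, theta = _grids(params.slice_px, params.dx_nm)
    mid = _wrap((gap.theta_start + gap.theta_stop) / 2.0)
    span = (gap.theta_stop - gap.theta_start) % (2 * np.pi)
    in_sector = np.abs(_wrap(theta - mid)) <= span / 2.0
    r_mid = (params.r_endo_out + params.r_bm_out) / 2.0
    half = params.arc_half_angle()
    in_arc = (
        np.ones_like(in_sector)
        if half >= np.pi
        else (np.abs(_wrap(theta - params.pericyte_arc_center)) <= half)
    )
    outer = _outer_label(theta, params)
    carved: list[np.ndarray] = []
    for z in range(gap.z_start, gap.z_stop):
        lab = vol.voxels[z]
        bm_here = (lab == 3) & in_sector
        if not bm_here.any():
            continue
        inner = bm_here & (radius < r_mid)
        outer_half = bm_here & ~inner
        lab[inner] = 2
        lab[outer_half & in_arc] = 4
        fill = outer_half & ~in_arc
        lab[fill] = outer[fill]
        idx = np.argwhere(bm_here)
        carved.append(np.column_stack([np.full(len(idx), z), idx]))
    if not carved:
        warnings.warn("BM gap sector intersects no BM voxels: no-op")
        vox = np.empty((0, 3), dtype=np.int64)
    else:
        vox = np.concatenate(carved)
    if truth is not None:
        truth.bm_gaps.append(BmGapTruth(spec=gap, voxels=vox))
    return vol


def insert_peg(
    vol: LabelVolume,
    truth: PhantomTruth,
    spec: PegSpec,
    params: PhantomParams | None = None,
) -> tuple[LabelVolume, PhantomTruth]:
    """Render one peg-and-socket protrusion and record its ground truth.

    The peg is a rectangular-cross-section radial finger of the protruding
    class replacing host-class (and, when carving a break, BM) voxels over
    ``n_sections`` consecutive slices.  Raises before touching the volume if
    the peg would leave the volume or overrun the opposing layer.
    """
    if params is None:
        params = truth.params
    z_stop = spec.z_start + spec.n_sections
    if spec.z_start < 0 or z_stop > vol.n_slices:
        raise ValueError(
            f"peg z-range [{spec.z_start}, {z_stop}) exits the volume "
            f"(0..{vol.n_slices})"
        )
    x, y, radius, theta = _grids(params.slice_px, params.dx_nm)
    s = x * np.cos(spec.angle) + y * np.sin(spec.angle)  # radial coordinate
    t = -x * np.sin(spec.angle) + y * np.cos(spec.angle)  # transverse
    pericyte_facing = spec.direction == "pericyte_facing"
    prot_label, host_label = (4, 2) if pericyte_facing else (2, 4)
    if pericyte_facing:
        interface = params.r_bm_out  # pericyte inner surface
        tip = interface - spec.length_nm
        base = interface + PEG_BASE_OVERLAP_NM if spec.attached else interface - PEG_DETACH_NM
        if tip <= params.r_lumen + LUMEN_CLEARANCE_NM:
            raise ValueError("peg would exit the endothelium into the lumen")
        lo, hi = tip, base
    else:
        interface = params.r_endo_out  # endothelium outer surface
        tip = interface + spec.length_nm
        base = interface - PEG_BASE_OVERLAP_NM if spec.attached else interface + PEG_DETACH_NM
        if tip >= params.r_peri_out - LUMEN_CLEARANCE_NM:
            raise ValueError("peg would exit the pericyte sheath")
        half = params.arc_half_angle()
        if half < np.pi:
            ang_margin = np.abs(_wrap(spec.angle - params.pericyte_arc_center))
            if ang_margin + spec.width_nm / interface > half:
                raise ValueError("no pericyte at the requested peg angle")
        lo, hi = base, tip
    foot = (np.abs(t) <= spec.width_nm / 2.0) & (s >= lo) & (s <= hi)
    voxels: list[np.ndarray] = []
    for z in range(spec.z_start, z_stop):
        lab = vol.voxels[z]
        editable = (lab == host_label) | (lab == prot_label)
        if spec.through_bm_gap:
            editable |= lab == 3
        region = foot & editable
        lab[region] = prot_label
        if spec.engulf_frac < ENGULF_THETA:
            # expose one flank and the tip cap to the BM so the host wraps
            # well under the engulfment threshold
            s_lo, s_hi = (tip, interface) if pericyte_facing else (interface, tip)
            flank = (
                (t > spec.width_nm / 2.0)
                & (t <= spec.width_nm / 2.0 + PEG_EXPOSURE_NM)
                & (s >= s_lo)
                & (s <= s_hi)
            )
            if pericyte_facing:
                cap = (s >= tip - PEG_EXPOSURE_NM) & (s < tip)
            else:
                cap = (s > tip) & (s <= tip + PEG_EXPOSURE_NM)
            cap &= np.abs(t) <= spec.width_nm / 2.0 + PEG_EXPOSURE_NM
            strip = (flank | cap) & (lab == host_label)
            lab[strip] = 3
        idx = np.argwhere(foot & (lab == prot_label))
        voxels.append(np.column_stack([np.full(len(idx), z), idx]))
    truth.pegs.append(
        PegTruth(
            spec=spec,
            criteria=spec.criterion_flags(vol.dz_nm),
            voxels=np.concatenate(voxels) if voxels else np.empty((0, 3), dtype=np.int64),
        )
    )
    return vol, truth


def _deg(d: float) -> float:
    return float(np.deg2rad(d))


def peg_gallery_params(seed: int = 0, n_slices: int = 16) -> PhantomParams:
    """A full-sheath phantom carrying six valid pegs and five decoys, each
    decoy violating exactly one detection criterion.

    The wide BM-free sector around 310° serves double duty: the peg placed
    at its centre crosses no local BM break (the traversal decoy), and the
    pericyte–endothelium contact along the sector exercises the candidate
    superset behaviour (close appositions tagged but rejected).
    """
    # pegs are spaced ≥ 32° apart and staggered along z so that neighbouring
    # sockets never interlock: two pegs engulfed in the same sections at
    # small angular offset would grip the host tissue between them from both
    # sides, which is a genuinely ambiguous configuration, not a test of the
    # criteria
    valid = [
        PegSpec("pericyte_facing", 2, 3, _deg(192), 300, 100),
        PegSpec("pericyte_facing", 12, 3, _deg(64), 280, 110),
        PegSpec("pericyte_facing", 2, 3, _deg(96), 300, 120),
        PegSpec("endothelium_facing", 12, 3, _deg(160), 240, 100),
        PegSpec("pericyte_facing", 9, 3, _deg(224), 260, 100),
        PegSpec("endothelium_facing", 3, 3, _deg(256), 230, 110),
    ]
    decoys = [
        # one section at 120 nm: fails the 200 nm z-span
        PegSpec("pericyte_facing", 8, 1, _deg(128), 300, 100),
        # orphan island behind a BM plug: fails attachment
        PegSpec("pericyte_facing", 8, 3, _deg(280), 280, 100, attached=False),
        # centred in the wide BM-free sector: no local BM break to traverse
        PegSpec("pericyte_facing", 6, 3, _deg(310), 300, 100, through_bm_gap=False),
        # one flank exposed to the BM: fails engulfment
        PegSpec("pericyte_facing", 8, 3, _deg(32), 300, 100, engulf_frac=0.4),
        # 60 nm wide: fails the 70 nm minimum transverse extent
        PegSpec("pericyte_facing", 3, 3, _deg(0), 300, 60),
    ]
    return PhantomParams(
        n_slices=n_slices,
        pericyte_coverage_frac=1.0,
        jitter_nm=0.0,
        bm_gap_specs=[BmGapSpec(0, n_slices, _deg(298), _deg(322))],
        peg_specs=valid + decoys,
        seed=seed,
    )


def make_peg_gallery(seed: int = 0, n_slices: int = 16) -> tuple[LabelVolume, PhantomTruth]:
    return generate_capillary_volume(peg_gallery_params(seed=seed, n_slices=n_slices))


def render_fixture_suite(out_dir: str | Path, seed: int = 0) -> pd.DataFrame:
    """Write the canonical test phantoms (volumes, truth JSONs, manifest).

    Returns the manifest; regeneration with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suite: dict[str, tuple[PhantomParams, str]] = {
        "full_sheath": (
            PhantomParams(
                n_slices=8, pericyte_coverage_frac=1.0, jitter_nm=0.0, seed=seed
            ),
            "complete pericyte sheath: 100% ensheathment on every slice",
        ),
        "partial_sheath": (
            PhantomParams(
                n_slices=8, pericyte_coverage_frac=0.5, jitter_nm=0.0, seed=seed + 1
            ),
            "half-arc pericyte sheath: 50% ensheathment",
        ),
        "peg_gallery": (
            peg_gallery_params(seed=seed + 2),
            "six valid pegs plus five single-criterion decoys and a contact sector",
        ),
    }
    rows = []
    for name, (params, desc) in suite.items():
        vol, truth = generate_capillary_volume(params)
        tiff = out_dir / f"{name}.tif"
        meta = out_dir / f"{name}.meta.json"
        write_label_stack(vol, tiff, meta)
        with open(out_dir / f"{name}.truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        rows.append(
            {"file": tiff.name, "seed": params.seed, "description": desc}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def coverage_series_params(
    coverage_frac: float, seed: int = 0, n_slices: int = 8
) -> PhantomParams:
    """Zero-jitter phantom for coverage parameter-recovery experiments."""
    return PhantomParams(
        n_slices=n_slices,
        pericyte_coverage_frac=coverage_frac,
        jitter_nm=0.0,
        seed=seed,
    )
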