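"""Segmented label volumes and their on-disk representation.

A :class:`LabelVolume` is the universal input of the pipeline: a 3D grid of
integer class labels (one label per voxel, slices along z) together with the
anisotropic voxel geometry of serial block-face SEM (isotropic in-plane pixel
size, much coarser section thickness) and a map from label ids to the
controlled class vocabulary of the neurovascular unit.

On disk a volume is a multi-page TIFF (one page per section, uint8/uint16)
plus a JSON sidecar carrying ``dx_nm``, ``dy_nm``, ``dz_nm`` and the
``class_map``.  The sidecar is deliberately plain text so that provenance is
inspectable without any imaging software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Controlled vocabulary of class names.
CLASS_VOCABULARY = frozenset(
    {
        "background",
        "lumen",
        "endothelium",
        "basement_membrane",
        "pericyte",
        "macroglia",
        "neuron",
        "other",
    }
)

#: Conventional label assignment used by the phantom generator and examples.
DEFAULT_CLASS_MAP = {
    0: "background",
    1: "lumen",
    2: "endothelium",
    3: "basement_membrane",
    4: "pericyte",
    5: "macroglia",
    6: "neuron",
}


class ValidationError(ValueError):
    """A volume or its metadata violates an invariant."""


@dataclass
class LabelVolume:
    """A segmented 3D label grid with voxel geometry and class map.

    Parameters
    ----------
    voxels
        ``(n_slices, n_rows, n_cols)`` array of non-negative integer labels,
        indexed ``(z, y, x)``.
    dx_nm, dy_nm
        In-plane pixel size in nm.  Must be equal (isotropic in-plane);
        default 6 nm, the acquisition pixel size of the SBF-SEM stacks this
        pipeline targets.
    dz_nm
        Section thickness in nm (typically 100 or 120 nm).
    class_map
        Mapping from label id to class name.  Every label present in
        ``voxels`` must appear; class names must be unique.
    """

    voxels: np.ndarray
    dx_nm: float = 6.0
    dy_nm: float = 6.0
    dz_nm: float = 120.0
    class_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"voxels must be 3D (z, y, x); got shape {self.voxels.shape}"
            )
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValidationError("voxels must be an integer array")
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.dx_nm != self.dy_nm:
            raise ValidationError(
                "anisotropic in-plane pixels unsupported "
                f"(dx_nm={self.dx_nm}, dy_nm={self.dy_nm})"
            )
        if self.dx_nm <= 0 or self.dz_nm <= 0:
            raise ValidationError("voxel sizes must be positive")
        present = np.unique(self.voxels)
        if present.size and present.min() < 0:
            raise ValidationError("labels must be non-negative")
        missing = [int(lab) for lab in present if int(lab) not in self.class_map]
        if missing:
            raise ValidationError(
                f"labels {missing} present in volume but absent from class_map"
            )
        names = list(self.class_map.values())
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            offending = sorted(
                lab for lab, n in self.class_map.items() if n in dupes
            )
            raise ValidationError(
                f"duplicate class names {dupes} (labels {offending}); "
                "at most one label may map to each class"
            )
        unknown = sorted(set(names) - CLASS_VOCABULARY)
        if unknown:
            raise ValidationError(f"class names {unknown} not in controlled vocabulary")

    # -- conveniences ---------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def label_of(self, class_name: str) -> int:
        """Return the label id mapped to *class_name*.

        Raises
        ------
        KeyError
            If no label maps to *class_name*.
        """
        for lab, name in self.class_map.items():
            if name == class_name:
                return lab
        raise KeyError(f"no label maps to class {class_name!r}")

    def has_class(self, class_name: str) -> bool:
        try:
            self.label_of(class_name)
        except KeyError:
            return False
        return True

    def metadata(self) -> dict:
        return {
            "dx_nm": self.dx_nm,
            "dy_nm": self.dy_nm,
            "dz_nm": self.dz_nm,
            "class_map": {str(k): v for k, v in sorted(self.class_map.items())},
        }


def class_mask(vol: LabelVolume, class_name: str, z: int) -> np.ndarray:
    """Binary mask of one class on one slice.

    True exactly where the slice's label maps to *class_name*.  Classes
    absent from ``class_map`` are an error (rather than silently empty) so
    that typos do not masquerade as biology.
    """
    if not 0 <= z < vol.n_slices:
        raise IndexError(f"slice index {z} out of range [0, {vol.n_slices})")
    label = vol.label_of(class_name)  # KeyError for unknown class
    return vol.voxels[z] == label


def class_volume_mask(vol: LabelVolume, class_name: str) -> np.ndarray:
    """3D binary mask of one class over the whole stack."""
    return vol.voxels == vol.label_of(class_name)


def load_label_stack(tiff_path: str | Path, meta_path: str | Path) -> LabelVolume:
    """Read a multi-page TIFF label stack and its JSON metadata sidecar.

    Slice order equals TIFF page order.  The sidecar must provide
    ``dx_nm``, ``dy_nm``, ``dz_nm`` and ``class_map`` (label ids serialised
    as strings, per JSON).
    """
    tiff_path, meta_path = Path(tiff_path), Path(meta_path)
    if not tiff_path.exists():
        raise FileNotFoundError(f"label stack not found: {tiff_path}")
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    for key in ("dx_nm", "dy_nm", "dz_nm", "class_map"):
        if key not in meta:
            raise ValidationError(f"metadata sidecar missing required key {key!r}")
    voxels = tifffile.imread(tiff_path)
    if voxels.ndim == 2:  # single-page stacks come back 2D
        voxels = voxels[None, :, :]
    class_map = {int(k): str(v) for k, v in meta["class_map"].items()}
    return LabelVolume(
        voxels=voxels,
        dx_nm=float(meta["dx_nm"]),
        dy_nm=float(meta["dy_nm"]),
        dz_nm=float(meta["dz_nm"]),
        class_map=class_map,
    )


def write_label_stack(
    vol: LabelVolume, tiff_path: str | Path, meta_path: str | Path
) -> None:
    """Write a volume as multi-page TIFF + JSON sidecar.

    ``load_label_stack`` inverts this exactly (voxel- and metadata-exact).
    """
    tiff_path, meta_path = Path(tiff_path), Path(meta_path)
    max_label = int(vol.voxels.max()) if vol.voxels.size else 0
    dtype = np.uint8 if max_label < 256 else np.uint16
    tifffile.imwrite(tiff_path, vol.voxels.astype(dtype), photometric="minisblack")
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(vol.metadata(), fh, indent=2, sort_keys=True)
        fh.write("\n")
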