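"""Quantitative 3D map container and NIfTI I/O.

A :class:`QuantMap` is a scalar field on a regular voxel grid together with
its spacing, physical units, the physiological quantity it represents, and a
per-voxel validity mask.  All downstream stages (oxygen mapping, range
thresholding, radiomic extraction) operate on this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np


class Quantity(str, Enum):
    """Physiological quantity carried by a :class:`QuantMap`."""

    R2STAR = "R2STAR"
    R2 = "R2"
    CBV = "CBV"
    CBF = "CBF"
    OEF = "OEF"
    CMRO2 = "CMRO2"
    CAPIPO2 = "CAPIPO2"
    MITOPO2 = "MITOPO2"
    S0 = "S0"


#: Conventional units for each quantity (OEF is carried as a fraction
#: internally and expressed in percent for feature extraction).
DEFAULT_UNITS: dict[Quantity, str] = {
    Quantity.R2STAR: "1/s",
    Quantity.R2: "1/s",
    Quantity.CBV: "fraction",
    Quantity.CBF: "mL/100g/min",
    Quantity.OEF: "fraction",
    Quantity.CMRO2: "umol/100g/min",
    Quantity.CAPIPO2: "mmHg",
    Quantity.MITOPO2: "mmHg",
    Quantity.S0: "a.u.",
}


@dataclass
class QuantMap:
    """A 3D scalar field with spacing, units and a validity mask.

    Parameters
    ----------
    values
        3D array of map values.  Entries outside ``valid`` are carried but
        must not be interpreted.
    spacing
        Voxel spacing in mm per axis, all strictly positive.
    quantity
        The physiological quantity represented.
    units
        Unit string; defaults to the conventional unit for ``quantity``.
    valid
        Boolean validity mask, same shape as ``values``.  Defaults to all
        finite voxels.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    quantity: Quantity
    units: str = ""
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if not self.units:
            self.units = DEFAULT_UNITS.get(self.quantity, "")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape must match values shape")
        # invariant: values finite wherever valid
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite on valid voxels")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def valid_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid voxel values, optionally restricted to ``mask``."""
        sel = self.valid if mask is None else (self.valid & np.asarray(mask, dtype=bool))
        return self.values[sel]

    def with_values(self, values: np.ndarray, quantity: Quantity | None = None,
                    units: str | None = None, valid: np.ndarray | None = None) -> "QuantMap":
        """New map on the same grid with replaced values/metadata."""
        q = self.quantity if quantity is None else quantity
        return QuantMap(
            values=values,
            spacing=self.spacing,
            quantity=q,
            units=units if units is not None else DEFAULT_UNITS.get(q, ""),
            valid=self.valid.copy() if valid is None else valid,
        )

    def same_grid(self, other: "QuantMap") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def require_same_grid(*maps: QuantMap) -> None:
    """Raise ``ValueError`` unless all maps share shape and spacing."""
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise ValueError(
                f"grid mismatch: {first.quantity.value} {first.shape}@{first.spacing} vs "
                f"{m.quantity.value} {m.shape}@{m.spacing}"
            )


@dataclass
class OxygenMapSet:
    """The four co-registered oxygen-metabolism biomarker maps for one case."""

    oef: QuantMap
    cmro2: QuantMap
    capipo2: QuantMap
    mitopo2: QuantMap

    def __post_init__(self) -> None:
        require_same_grid(self.oef, self.cmro2, self.capipo2, self.mitopo2)

    def as_dict(self) -> dict[str, QuantMap]:
        return {
            "OEF": self.oef,
            "CMRO2": self.cmro2,
            "capiPO2": self.capipo2,
            "mitoPO2": self.mitopo2,
        }


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_map(qmap: QuantMap, path: str | Path) -> None:
    """Write a map as NIfTI; invalid voxels are stored as NaN."""
    data = qmap.values.copy()
    data[~qmap.valid] = np.nan
    img = nib.Nifti1Image(data, _affine(qmap.spacing))
    img.header.set_zooms(qmap.spacing)
    nib.save(img, str(path))


def load_map(path: str | Path, quantity: Quantity, units: str = "") -> QuantMap:
    """Read a NIfTI map; NaN voxels become invalid."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    valid = np.isfinite(data)
    data = np.where(valid, data, 0.0)
    return QuantMap(values=data, spacing=spacing, quantity=quantity, units=units, valid=valid)


def save_mask(mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()) > 0.5, spacing


def save_echo_train(magnitudes: np.ndarray, echo_times: np.ndarray,
                    spacing: tuple[float, float, float], path: str | Path) -> None:
    """Write a 4D echo stack plus a JSON echo-time sidecar (seconds)."""
    path = Path(path)
    stack = np.moveaxis(np.asarray(magnitudes, dtype=np.float64), 0, -1)
    img = nib.Nifti1Image(stack, _affine(spacing))
    nib.save(img, str(path))
    sidecar = path.with_name(path.name.split(".")[0] + "_echoes.json")
    sidecar.write_text(json.dumps({"echo_times_s": list(map(float, echo_times))}))


def load_echo_train(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Read a 4D echo stack; returns (magnitudes[echo,...], echo_times_s, spacing)."""
    path = Path(path)
    img = nib.load(str(path))
    stack = np.asarray(img.get_fdata(), dtype=np.float64)
    magnitudes = np.moveaxis(stack, -1, 0)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = path.with_name(path.name.split(".")[0] + "_echoes.json")
    echo_times = np.asarray(json.loads(sidecar.read_text())["echo_times_s"], dtype=np.float64)
    return magnitudes, echo_times, spacing
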