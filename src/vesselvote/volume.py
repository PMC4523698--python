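"""3-D scalar volumes with physical voxel spacing and NIfTI round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class ScalarVolume:
    """A 3-D intensity grid with per-axis voxel size in mm.

    The affine carries anatomical orientation metadata; it is passed
    through unchanged to any output written from this volume.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 8:
            raise ValueError(f"all dims must be >= 8, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.affine is None:
            self.affine = np.diag((*self.spacing, 1.0))
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @classmethod
    def from_nifti(cls, path) -> "ScalarVolume":
        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj, dtype=np.float64)
        except Exception as exc:  # corrupt header / unreadable file
            raise IOError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
        data = np.squeeze(data)
        if data.ndim != 3:
            raise ValueError(f"{path!r}: expected 3-D data, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=data, spacing=spacing, affine=np.asarray(img.affine))

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """New volume on this grid (same spacing/affine) with other data."""
        return ScalarVolume(data=data, spacing=self.spacing, affine=self.affine.copy())


def save_scalar(data: np.ndarray, reference: ScalarVolume, path) -> None:
    """Write an arbitrary scalar (or vector, last-axis) grid on a reference grid."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), reference.affine)
    nib.save(img, str(path))
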