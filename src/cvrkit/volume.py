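"""In-memory container for a preprocessed 4D BOLD series."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import ValidationError


@dataclass
class BoldVolume:
    """A 4D BOLD array with its affine, brain mask and repetition time.

    Attributes
    ----------
    data : ndarray, shape (X, Y, Z, T)
        BOLD intensities (arbitrary scanner units).
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine, carried through to every output map.
    mask : ndarray of bool, shape (X, Y, Z)
        Brain mask; analysis is restricted to in-mask voxels.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 4:
            raise ValidationError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match BOLD grid {self.data.shape[:3]}"
            )
        if not self.tr > 0:
            raise ValidationError(f"repetition time must be positive, got {self.tr}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each volume, frame i at i*TR seconds."""
        return np.arange(self.n_frames) * self.tr

    def global_signal(self) -> np.ndarray:
        """Mean timecourse over the brain mask."""
        if not self.mask.any():
            raise ValidationError("brain mask is empty")
        return self.data[self.mask].mean(axis=0)

    def to_img(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    @classmethod
    def from_files(cls, bold_path, mask_path, tr: float | None = None) -> "BoldVolume":
        img = nib.load(str(bold_path))
        mask_img = nib.load(str(mask_path))
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        return cls(
            data=np.asanyarray(img.dataobj, dtype=np.float64),
            affine=img.affine,
            mask=np.asanyarray(mask_img.dataobj) > 0,
            tr=tr,
        )
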