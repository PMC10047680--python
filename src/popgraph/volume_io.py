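"""NIfTI volume containers and I/O.

The pipeline's working containers are small dataclasses around NumPy
arrays: a 4D functional volume with its repetition time (TR), a 3D
integer labelmap (parcellation), and a channel-labelled stack of 3D
summary maps.  The channel axis is always the *last* axis and voxel
indexing is 0-based; the stored axis order of a file is treated as
authoritative and never transposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ShapeError, ValidationError

__all__ = [
    "Volume4D",
    "LabelMap",
    "SummaryStack",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "stack_channels",
]


@dataclass
class Volume4D:
    """A 4D (x, y, z, t) functional volume.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal values.  3D arrays are promoted to 4D with a single
        timepoint.
    tr_seconds : float
        Repetition time between consecutive timepoints.
    mask : ndarray of bool, shape (x, y, z), optional
        Brain mask.  When absent, :meth:`get_mask` falls back to the
        voxels with nonzero temporal variance.
    """

    data: np.ndarray
    tr_seconds: float = 2.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ShapeError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ShapeError(
                    f"mask shape {self.mask.shape} does not match spatial "
                    f"dims {self.data.shape[:3]}"
                )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def get_mask(self) -> np.ndarray:
        """Explicit mask if set, else voxels with nonzero temporal variance."""
        if self.mask is not None:
            return self.mask
        if self.n_timepoints == 1:
            return np.isfinite(self.data[..., 0])
        return self.data.var(axis=3) > 0


@dataclass
class LabelMap:
    """3D integer parcellation; 0 is background."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError("labelmap must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.array_equal(rounded, self.data):
                raise ValidationError("labelmap values must be integers")
            self.data = rounded.astype(np.int32)
        if (self.data < 0).any():
            raise ValidationError("labelmap values must be nonnegative")

    @property
    def region_ids(self) -> list[int]:
        """Sorted distinct nonzero labels."""
        ids = np.unique(self.data)
        return [int(i) for i in ids if i != 0]

    def roi_mask(self, roi_id: int) -> np.ndarray:
        return self.data == roi_id


@dataclass
class SummaryStack:
    """4D (x, y, z, channel) stack of summary maps with channel names."""

    data: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ShapeError("summary stack must be 4D (x, y, z, channel)")
        if len(self.channel_names) != self.data.shape[3]:
            raise ShapeError(
                f"{self.data.shape[3]} channels but "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]


def read_volume(path: str | Path, tr_seconds: float | None = None) -> Volume4D:
    """Read a 3D/4D NIfTI file as a :class:`Volume4D`.

    3D images are promoted to 4D with a single timepoint.  TR is taken
    from the header's 4th zoom unless ``tr_seconds`` overrides it.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ShapeError(f"{path}: expected 3D or 4D image, got {data.ndim}D")
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ValidationError(f"{path}: {n_bad} non-finite voxel value(s)")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return Volume4D(data=data, tr_seconds=tr_seconds)


def write_volume(vol: Volume4D, path: str | Path) -> None:
    """Write a :class:`Volume4D` as NIfTI-1, recording TR in the header."""
    img = nib.Nifti1Image(vol.data, affine=np.eye(4))
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr_seconds
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_labelmap(path: str | Path) -> LabelMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return LabelMap(data=data)


def write_labelmap(atlas: LabelMap, path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.data.astype(np.int32), affine=np.eye(4))
    nib.save(img, str(path))


def stack_channels(
    volumes: list[np.ndarray | SummaryStack], names: list[str]
) -> SummaryStack:
    """Concatenate 3D maps and/or stacks along the channel (last) axis.

    ``names`` must supply one name per resulting channel, in order.
    """
    blocks: list[np.ndarray] = []
    for v in volumes:
        arr = v.data if isinstance(v, SummaryStack) else np.asarray(v, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[..., np.newaxis]
        if arr.ndim != 4:
            raise ShapeError("each input must be a 3D map or a 4D stack")
        blocks.append(arr)
    shapes = {b.shape[:3] for b in blocks}
    if len(shapes) > 1:
        raise ShapeError(f"inconsistent spatial shapes: {sorted(shapes)}")
    data = np.concatenate(blocks, axis=3)
    return SummaryStack(data=data, channel_names=list(names))
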