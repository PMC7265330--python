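"""In-memory containers for volumes and movies.

Axis convention is TCZYX throughout: a :class:`Movie` holds a 5D array
``(T, C, Z, Y, X)``; a :class:`VoxelGrid` holds one 3D channel volume
``(Z, Y, X)`` with its physical voxel spacing ``(dz, dy, dx)`` in µm.
Frame indices (including the NEBD frame) are 0-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ChannelNotFoundError, InvalidParameterError

__all__ = ["VoxelGrid", "Movie", "SegmentationMask"]


@dataclass
class VoxelGrid:
    """One 3D intensity volume for one channel at one time point.

    Parameters
    ----------
    data
        3D array of non-negative, finite intensities, axes (Z, Y, X).
    spacing
        Physical voxel size ``(dz, dy, dx)`` in µm; all entries > 0.
    channel
        Channel label, e.g. ``"MIS12"``.
    frame_index
        0-based time index within the parent movie.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidParameterError(
                f"VoxelGrid data must be 3D (Z, Y, X); got ndim={self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"spacing must be three positive lengths; got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("VoxelGrid intensities must be finite")
        if np.any(self.data < 0):
            raise InvalidParameterError("VoxelGrid intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        dz, dy, dx = self.spacing
        return np.isclose(dz, dy) and np.isclose(dy, dx)

    def with_data(self, data: np.ndarray, spacing: tuple[float, float, float] | None = None) -> "VoxelGrid":
        """Copy of this grid with new intensities (and optionally new spacing)."""
        return replace(self, data=data, spacing=spacing if spacing is not None else self.spacing)


@dataclass
class Movie:
    """Ordered multi-channel voxel-grid sequence.

    ``data`` has axes (T, C, Z, Y, X); all frames share shape and voxel
    size. ``nebd_frame`` is the 0-based index of nuclear envelope
    breakdown, supplied by the user (never detected).
    """

    data: np.ndarray
    channel_labels: list[str]
    frame_interval: float
    spacing: tuple[float, float, float]
    nebd_frame: int | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise InvalidParameterError(
                f"Movie data must be 5D (T, C, Z, Y, X); got ndim={self.data.ndim}"
            )
        if len(self.channel_labels) != self.data.shape[1]:
            raise InvalidParameterError(
                f"{len(self.channel_labels)} channel labels for {self.data.shape[1]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidParameterError("channel labels must be unique")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"voxel sizes must be > 0; got {self.spacing}")
        if self.nebd_frame is not None and not (0 <= self.nebd_frame < self.n_frames):
            raise InvalidParameterError(
                f"nebd_frame {self.nebd_frame} outside [0, {self.n_frames})"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ChannelNotFoundError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None

    def grid(self, frame: int, channel: str | int) -> VoxelGrid:
        """Extract one channel volume at one time point as a VoxelGrid."""
        c = channel if isinstance(channel, int) else self.channel_index(channel)
        label = self.channel_labels[c]
        return VoxelGrid(self.data[frame, c], self.spacing, channel=label, frame_index=frame)

    def times_rel_nebd(self, nebd_frame: int | None = None) -> np.ndarray:
        """Frame times in minutes relative to NEBD: (k - nebd) * frame_interval."""
        nebd = self.nebd_frame if nebd_frame is None else nebd_frame
        if nebd is None:
            raise InvalidParameterError("no NEBD frame set on movie and none supplied")
        return (np.arange(self.n_frames) - nebd) * self.frame_interval


@dataclass
class SegmentationMask:
    """Binary 3D kinetochore-spot mask with threshold provenance.

    ``applied_threshold`` is ``otsu_scale * otsu_value``; ``n_components``
    counts 26-connected components of the opened mask.
    """

    mask: np.ndarray
    otsu_value: float
    applied_threshold: float
    n_components: int
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise InvalidParameterError("SegmentationMask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())
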