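"""OME-TIFF movie reading/writing plus CSV/JSON helpers.

Movies are stored with TCZYX axes and OME ``PhysicalSizeX/Y/Z`` voxel
metadata (µm) plus ``TimeIncrement`` (min). Reading promotes intensities
to floating point; writing preserves the in-memory dtype, so integer
movies round-trip bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .containers import Movie
from .errors import InvalidParameterError, MissingMetadataError

__all__ = ["read_movie", "write_movie", "write_mask", "sha256_of"]

_AXES = "TCZYX"


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as OME-TIFF with physical voxel-size metadata."""
    dz, dy, dx = movie.spacing
    metadata = {
        "axes": _AXES,
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "µm",
        "TimeIncrement": movie.frame_interval,
        "TimeIncrementUnit": "min",
        "Channel": {"Name": list(movie.channel_labels)},
    }
    tifffile.imwrite(Path(path), movie.data, ome=True, metadata=metadata)


def _pixels_attrs(ome_xml: str) -> dict:
    meta = tifffile.xml2dict(ome_xml)
    try:
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        return image["Pixels"]
    except (KeyError, TypeError):
        return {}


def read_movie(
    path: str | Path,
    spacing: tuple[float, float, float] | None = None,
    frame_interval: float | None = None,
    nebd_frame: int | None = None,
    channel_labels: list[str] | None = None,
) -> Movie:
    """Read an OME-TIFF (or plain TIFF) movie into TCZYX layout.

    Voxel sizes come from the OME ``PhysicalSize`` metadata unless
    ``spacing`` overrides them; missing sizes without an override raise
    :class:`MissingMetadataError`. A plain 2D TIFF is wrapped as a
    single-frame, single-slice movie with a warning. Intensities are
    promoted to float32/float64.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C").replace("Q", "")
        ome_xml = tf.ome_metadata

    if data.ndim == 2:
        warnings.warn(f"{path.name}: 2D image read as single-frame, single-slice movie")
        axes = "YX"
    if len(axes) != data.ndim:
        axes = _AXES[-data.ndim:]
    if any(ax not in _AXES for ax in axes):
        raise InvalidParameterError(f"cannot interpret axes {axes!r} as a subset of TCZYX")
    # reorder/expand to TCZYX
    for i, ax in enumerate(_AXES):
        if ax not in axes:
            data = np.expand_dims(data, i)
            axes = axes[:i] + ax + axes[i:]
    data = np.transpose(data, [axes.index(ax) for ax in _AXES])
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)

    attrs = _pixels_attrs(ome_xml) if ome_xml else {}
    if spacing is None:
        try:
            spacing = (
                float(attrs["PhysicalSizeZ"]),
                float(attrs["PhysicalSizeY"]),
                float(attrs["PhysicalSizeX"]),
            )
        except KeyError as exc:
            raise MissingMetadataError(
                f"{path.name}: no PhysicalSize{str(exc).strip(chr(39))[-1]} metadata "
                "and no spacing override given"
            ) from None
    if frame_interval is None:
        if "TimeIncrement" in attrs:
            frame_interval = float(attrs["TimeIncrement"])
        else:
            if data.shape[0] > 1:
                warnings.warn(f"{path.name}: no TimeIncrement metadata; assuming 1.0 min")
            frame_interval = 1.0

    if channel_labels is None:
        channel_labels = _channel_names(attrs, data.shape[1])

    return Movie(
        data=data,
        channel_labels=channel_labels,
        frame_interval=frame_interval,
        spacing=spacing,
        nebd_frame=nebd_frame,
        source_path=str(path),
    )


def _channel_names(attrs: dict, n_channels: int) -> list[str]:
    channels = attrs.get("Channel", [])
    if isinstance(channels, dict):
        channels = [channels]
    names = [c.get("Name") for c in channels if isinstance(c, dict)]
    if len(names) == n_channels and all(names):
        return [str(n) for n in names]
    return [f"ch{i}" for i in range(n_channels)]


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary 3D mask as an 8-bit TIFF (255 = foreground)."""
    tifffile.imwrite(
        Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)), photometric="minisblack"
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
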