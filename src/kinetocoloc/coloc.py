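"""Scaled spot colocalization in 3D+T and NEBD-relative trace assembly.

The per-frame statistic is the mean signal intensity within the segmented
kinetochore spots divided by the mean signal intensity in a background
shell 1–15 voxels away from the spots but still inside the nucleus. A
value of 1 means no enrichment over the diffuse nuclear pool; the ratio is
invariant to uniform rescaling of the signal channel.

Traces from many cells are aggregated on the shared NEBD-relative time
lattice as mean ± SEM per time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .containers import Movie, SegmentationMask, VoxelGrid
from .errors import (
    EmptyAggregateError,
    EmptyShellError,
    InvalidParameterError,
    NoSpotsError,
    UndefinedRatioError,
)
from .segment import (
    CONNECTIVITY_26,
    ColocParams,
    gaussian_smooth,
    otsu_threshold,
    reslice_isotropic,
    segment_spots,
)

__all__ = [
    "ColocTrace",
    "AggregateTrace",
    "background_shell",
    "scaled_colocalization",
    "derive_nucleus_mask",
    "analyze_movie",
    "aggregate_traces",
]


@dataclass
class ColocTrace:
    """Per-frame scaled colocalization values on an NEBD-relative time axis.

    ``value`` is NaN at frames where the spot mask or shell was empty;
    those frames are flagged in ``flags`` rather than dropped.
    """

    t_rel_nebd: np.ndarray
    value: np.ndarray
    cell_id: str = ""
    n_mask_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_shell_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_rel_nebd = np.asarray(self.t_rel_nebd, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t_rel_nebd.shape != self.value.shape:
            raise InvalidParameterError("times and values must have equal length")
        if np.any(np.diff(self.t_rel_nebd) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        defined = np.isfinite(self.value)
        if np.any(self.value[defined] <= 0):
            raise InvalidParameterError("defined colocalization values must be > 0")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "t_rel_nebd": self.t_rel_nebd,
                "value": self.value,
                "n_mask_voxels": self.n_mask_voxels,
                "n_shell_voxels": self.n_shell_voxels,
                "flag": self.flags,
            }
        )


@dataclass
class AggregateTrace:
    """Cross-cell mean ± SEM per NEBD-relative time point.

    SEM is sample SD / sqrt(n); it is reported as NaN (missing) wherever
    fewer than two cells contribute.
    """

    t_rel_nebd: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_cells: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_rel_nebd": self.t_rel_nebd,
                "mean": self.mean,
                "sem": self.sem,
                "n_cells": self.n_cells,
            }
        )


def background_shell(
    spots: SegmentationMask | np.ndarray,
    nucleus: np.ndarray,
    dmin: float = 1.0,
    dmax: float = 15.0,
    metric: str = "euclidean",
) -> np.ndarray:
    """Nuclear background shell at distance [dmin, dmax] voxels from spots.

    A voxel belongs to the shell when it lies inside the nucleus, outside
    every spot, and its distance (in voxel units, to the nearest spot
    voxel) falls within the closed interval. Euclidean distance on the
    isotropic grid by default; ``metric="chebyshev"`` selects chessboard
    distance.
    """
    spot_mask = spots.mask if isinstance(spots, SegmentationMask) else np.asarray(spots, dtype=bool)
    nucleus = np.asarray(nucleus, dtype=bool)
    if not (0 <= dmin < dmax):
        raise InvalidParameterError("need 0 <= dmin < dmax")
    if not spot_mask.any():
        raise NoSpotsError("cannot build a background shell around an empty spot mask")
    if metric == "euclidean":
        dist = ndi.distance_transform_edt(~spot_mask)
    elif metric == "chebyshev":
        dist = ndi.distance_transform_cdt(~spot_mask, metric="chessboard").astype(float)
    else:
        raise InvalidParameterError(f"unknown metric {metric!r}")
    shell = nucleus & ~spot_mask & (dist >= dmin) & (dist <= dmax)
    if not shell.any():
        raise EmptyShellError("background shell is empty")
    return shell


def scaled_colocalization(
    signal: VoxelGrid | np.ndarray,
    spots: SegmentationMask | np.ndarray,
    shell: np.ndarray,
) -> float:
    """mean(signal | spots) / mean(signal | shell)."""
    data = signal.data if isinstance(signal, VoxelGrid) else np.asarray(signal)
    spot_mask = spots.mask if isinstance(spots, SegmentationMask) else np.asarray(spots, dtype=bool)
    shell = np.asarray(shell, dtype=bool)
    if not spot_mask.any():
        raise NoSpotsError("empty spot mask")
    if not shell.any():
        raise EmptyShellError("empty shell")
    shell_mean = float(data[shell].mean())
    if shell_mean <= 0:
        raise UndefinedRatioError(f"shell mean {shell_mean} <= 0: ratio undefined")
    return float(data[spot_mask].mean()) / shell_mean


def derive_nucleus_mask(signal: VoxelGrid, sigma: float = 5.0, erosion: int = 3) -> np.ndarray:
    """Nucleus mask from the diffuse nuclear pool of the signal channel.

    The signal channel is smoothed heavily (σ = 5 voxels by default) so
    that kinetochore spots wash into the nuclear background, Otsu-
    thresholded, hole-filled, and reduced to the largest 26-connected
    component; the mask is then eroded by ``erosion`` voxels so the
    background shell samples the nuclear interior rather than the
    intensity roll-off at the envelope (which would otherwise bias the
    shell mean low). Pass a precomputed mask to :func:`analyze_movie` to
    bypass this heuristic (e.g. with a dedicated nuclear marker).
    """
    smoothed = gaussian_smooth(signal, sigma)
    thr = otsu_threshold(smoothed)
    mask = smoothed.data > thr
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask, structure=CONNECTIVITY_26)
    if n > 0:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    if erosion > 0:
        eroded = ndi.binary_erosion(mask, iterations=erosion)
        if eroded.any():   # keep the uneroded mask for tiny nuclei
            mask = eroded
    return mask


def analyze_movie(
    movie: Movie,
    marker_channel: str,
    signal_channel: str,
    nebd_frame: int | None = None,
    params: ColocParams | None = None,
    nucleus_masks: list[np.ndarray] | np.ndarray | None = None,
    cell_id: str = "",
) -> ColocTrace:
    """Run the full per-frame quantification over a movie.

    Per frame: reslice both channels to isotropic voxels, smooth with
    σ = ``params.smooth_sigma``, segment the marker channel, derive (or
    take) the nucleus mask, build the background shell, and compute the
    scaled colocalization of the signal channel. Times are reported in
    minutes relative to NEBD. Frames where the spot mask or shell is
    empty are flagged and carry NaN, never silently dropped.

    ``nucleus_masks`` may be one 3D mask (reused for all frames, on the
    isotropic grid) or one mask per frame.
    """
    params = params or ColocParams()
    nebd = movie.nebd_frame if nebd_frame is None else nebd_frame
    if nebd is None:
        raise InvalidParameterError("NEBD frame required (movie has none set)")
    if not (0 <= nebd < movie.n_frames):
        raise InvalidParameterError(f"nebd_frame {nebd} outside [0, {movie.n_frames})")
    # raises ChannelNotFoundError early if a channel is missing
    movie.channel_index(marker_channel)
    movie.channel_index(signal_channel)

    times = movie.times_rel_nebd(nebd)
    values = np.full(movie.n_frames, np.nan)
    n_mask = np.zeros(movie.n_frames, dtype=int)
    n_shell = np.zeros(movie.n_frames, dtype=int)
    flags: list[str] = []

    for k in range(movie.n_frames):
        marker = reslice_isotropic(movie.grid(k, marker_channel), params.interpolation_order)
        signal = reslice_isotropic(movie.grid(k, signal_channel), params.interpolation_order)
        marker_s = gaussian_smooth(marker, params.smooth_sigma)
        signal_s = gaussian_smooth(signal, params.smooth_sigma)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seg = segment_spots(marker_s, params)
        n_mask[k] = seg.n_voxels
        if nucleus_masks is None:
            nucleus = derive_nucleus_mask(signal, sigma=params.nucleus_sigma,
                                          erosion=params.nucleus_erosion)
        elif isinstance(nucleus_masks, np.ndarray) and nucleus_masks.ndim == 3:
            nucleus = nucleus_masks
        else:
            nucleus = np.asarray(nucleus_masks[k], dtype=bool)
        flag = "ok" if k <= nebd else "post-nebd"
        try:
            shell = background_shell(
                seg, nucleus, params.shell_dmin, params.shell_dmax, params.shell_metric
            )
            n_shell[k] = int(shell.sum())
            values[k] = scaled_colocalization(signal_s, seg, shell)
        except NoSpotsError:
            flag = "empty-mask"
        except EmptyShellError:
            flag = "empty-shell"
        except UndefinedRatioError:
            flag = "undefined-ratio"
        flags.append(flag)

    return ColocTrace(
        t_rel_nebd=times,
        value=values,
        cell_id=cell_id,
        n_mask_voxels=n_mask,
        n_shell_voxels=n_shell,
        flags=flags,
    )


def aggregate_traces(traces: list[ColocTrace], decimals: int = 9) -> AggregateTrace:
    """Cross-cell mean and SEM on the union of NEBD-relative time points.

    Traces are assumed to share a common frame interval; time points are
    matched after rounding to ``decimals`` decimal places (no
    interpolation across cells). At each time, only cells with a defined
    value contribute; SEM = sample SD / sqrt(n), missing when n < 2.
    """
    if not traces:
        raise EmptyAggregateError("no traces to aggregate")
    buckets: dict[float, list[float]] = {}
    for tr in traces:
        for t, v in zip(np.round(tr.t_rel_nebd, decimals), tr.value):
            if np.isfinite(v):
                buckets.setdefault(float(t), []).append(float(v))
    if not buckets:
        raise EmptyAggregateError("no time point has a defined value in any trace")
    times = np.array(sorted(buckets))
    mean = np.empty_like(times)
    sem = np.full_like(times, np.nan)
    n_cells = np.zeros(times.size, dtype=int)
    for i, t in enumerate(times):
        vals = np.asarray(buckets[float(t)])
        n_cells[i] = vals.size
        mean[i] = vals.mean()
        if vals.size >= 2:
            sem[i] = vals.std(ddof=1) / np.sqrt(vals.size)
    return AggregateTrace(t_rel_nebd=times, mean=mean, sem=sem, n_cells=n_cells)
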