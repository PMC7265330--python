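"""Synthetic two-channel 3D+T movies with known ground truth.

Emulates the live-cell imaging regime of an RPE cell expressing a
kinetochore marker (RFP670-MIS12-like: ~46 diffraction-limited spots in a
nucleus) and a checkpoint-protein signal channel (Ruby-MAD2-like: a
diffuse nuclear pool plus a spot-localized fraction that follows a
sigmoid recruitment time-course relative to NEBD). Voxels are anisotropic
(z coarser than xy); noise is Poisson shot noise plus Gaussian read
noise, the standard sCMOS approximation.

The signal channel is calibrated so that the *operational* ground truth
holds exactly in the noise-free limit: the mean spot intensity over the
reference segmentation of the marker channel, divided by the mean over
the 1–15 voxel background shell, equals ``1 + f(t) * (R - 1)`` where
``f`` is the recruited fraction and ``R`` the enrichment ratio at full
recruitment. See docs/methods.md for the calibration derivation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coloc import background_shell, derive_nucleus_mask
from .containers import Movie, VoxelGrid
from .errors import DegenerateGeometryError, InvalidParameterError
from .segment import ColocParams, gaussian_smooth, reslice_isotropic, segment_spots

__all__ = [
    "SyntheticParams",
    "SyntheticGroundTruth",
    "recruitment_curve",
    "generate_movie",
    "write_ground_truth",
]


@dataclass
class SyntheticParams:
    """Parameters of the synthetic movie generator.

    Lengths are µm, times are minutes, intensities are arbitrary units on
    a [0, ~1] scale before noise. ``enrichment_ratio`` is the true
    spot/shell signal ratio at full recruitment; the recruitment
    time-course is ``f(t) = fmax / (1 + exp(-(t - t50)/tau))`` with t in
    minutes relative to NEBD.
    """

    nucleus_radius: float = 6.0
    n_spots: int = 46
    spot_sigma: float = 0.3
    voxel_size_xy: float = 0.25
    voxel_size_z: float = 0.5
    frame_interval: float = 2.0
    n_frames: int = 10
    nebd_frame: int = 5
    enrichment_ratio: float = 3.0
    recruit_fmax: float = 0.8
    recruit_t50: float = -10.0
    recruit_tau: float = 2.0
    photon_scale: float = 200.0
    read_noise_sd: float = 0.005
    seed: int = 0
    # volume shape (Z, Y, X); None -> fitted around the nucleus
    shape: tuple[int, int, int] | None = (32, 96, 96)
    # intensity model
    marker_background: float = 0.01
    marker_amplitude: float = 1.0
    signal_baseline: float = 0.5
    # geometry of spot placement
    min_separation: float = 2.0      # µm, center-to-center
    boundary_margin: float = 2.0     # in units of spot_sigma, erosion of nucleus
    motion_sd: float = 0.0           # µm/frame random-walk step; 0 = static
    noise: bool = True
    marker_label: str = "MIS12"
    signal_label: str = "MAD2"

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise InvalidParameterError("n_spots must be >= 1")
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")
        if not (0 <= self.nebd_frame < self.n_frames):
            raise InvalidParameterError("need 0 <= nebd_frame < n_frames")
        if not (self.voxel_size_z >= self.voxel_size_xy > 0):
            raise InvalidParameterError("need voxel_size_z >= voxel_size_xy > 0")
        if self.recruit_tau <= 0:
            raise InvalidParameterError("recruit_tau must be > 0")
        if self.enrichment_ratio <= 0:
            raise InvalidParameterError("enrichment_ratio must be > 0")
        if not (0 <= self.recruit_fmax <= 1):
            raise InvalidParameterError("recruit_fmax must be in [0, 1]")
        if self.spot_sigma <= 0 or self.nucleus_radius <= 0:
            raise InvalidParameterError("spot_sigma and nucleus_radius must be > 0")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")

    @property
    def snr(self) -> float:
        """Peak marker amplitude over the noise SD at peak intensity."""
        shot_var = self.marker_amplitude / self.photon_scale if self.photon_scale > 0 else 0.0
        return self.marker_amplitude / np.sqrt(shot_var + self.read_noise_sd**2)

    def times_rel_nebd(self) -> np.ndarray:
        return (np.arange(self.n_frames) - self.nebd_frame) * self.frame_interval


@dataclass
class SyntheticGroundTruth:
    """Ground truth accompanying a generated movie.

    ``spot_centers`` holds one (n_spots, 3) array of physical (z, y, x)
    coordinates in µm per frame; ``true_enrichment`` is the noise-free
    spot-mean/shell-mean ratio ``1 + f(t)(R-1)`` per frame.
    """

    spot_centers: list[np.ndarray]
    recruited_fraction: np.ndarray
    true_enrichment: np.ndarray
    nucleus_mask: np.ndarray
    params: SyntheticParams = field(repr=False, default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.recruited_fraction)),
                "t_rel_nebd": self.params.times_rel_nebd(),
                "recruited_fraction": self.recruited_fraction,
                "true_enrichment": self.true_enrichment,
            }
        )


def recruitment_curve(
    t_rel_nebd: float | np.ndarray, fmax: float, t50: float, tau: float
) -> float | np.ndarray:
    """Sigmoid recruited fraction f(t) = fmax / (1 + exp(-(t - t50)/tau)).

    ``t_rel_nebd`` is in minutes relative to NEBD; ``fmax`` in [0, 1] is
    the plateau fraction, ``t50`` the half-recruitment time and ``tau``
    the rise time constant.
    """
    if tau <= 0:
        raise InvalidParameterError("tau must be > 0")
    if not (0 <= fmax <= 1):
        raise InvalidParameterError("fmax must be in [0, 1]")
    t = np.asarray(t_rel_nebd, dtype=float)
    with np.errstate(over="ignore"):
        f = fmax / (1.0 + np.exp(-(t - t50) / tau))
    return float(f) if np.isscalar(t_rel_nebd) or t.ndim == 0 else f


def _fit_shape(p: SyntheticParams) -> tuple[int, int, int]:
    margin = 4  # voxels of free space on each side
    nz = 2 * int(np.ceil(p.nucleus_radius / p.voxel_size_z)) + 1 + 2 * margin
    nxy = 2 * int(np.ceil(p.nucleus_radius / p.voxel_size_xy)) + 1 + 2 * margin
    return (nz, nxy, nxy)


def _physical_axes(shape: tuple[int, int, int], spacing: tuple[float, float, float]):
    # physical coordinate of each voxel node, centred on the volume
    return [
        (np.arange(n) - (n - 1) / 2.0) * d for n, d in zip(shape, spacing)
    ]


def _sample_centers(p: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform random centers inside the eroded nucleus with min separation."""
    r_avail = p.nucleus_radius - p.boundary_margin * p.spot_sigma
    if r_avail <= 0:
        raise DegenerateGeometryError(
            "nucleus too small for spot placement after boundary erosion"
        )
    centers: list[np.ndarray] = []
    min_d2 = p.min_separation**2
    for _ in range(200_000):
        c = rng.uniform(-r_avail, r_avail, size=3)
        if c @ c > r_avail**2:
            continue
        if all(np.sum((c - o) ** 2) >= min_d2 for o in centers):
            centers.append(c)
            if len(centers) == p.n_spots:
                return np.array(centers)
    raise DegenerateGeometryError(
        f"could not place {p.n_spots} spots with min separation "
        f"{p.min_separation} µm inside radius {r_avail:.2f} µm"
    )


def _render_spots(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centers: np.ndarray,
    sigma_um: float,
) -> np.ndarray:
    """Sum of unit-peak isotropic (in physical units) Gaussian spots."""
    axes = _physical_axes(shape, spacing)
    vol = np.zeros(shape)
    half = 4.0 * sigma_um
    for c in centers:
        sl = []
        local_axes = []
        for ax, (coord, d, n) in enumerate(zip(c, spacing, shape)):
            i0 = max(0, int(np.floor((coord - half - axes[ax][0]) / d)))
            i1 = min(n, int(np.ceil((coord + half - axes[ax][0]) / d)) + 1)
            sl.append(slice(i0, i1))
            local_axes.append(axes[ax][i0:i1] - coord)
        dz2 = (local_axes[0] ** 2)[:, None, None]
        dy2 = (local_axes[1] ** 2)[None, :, None]
        dx2 = (local_axes[2] ** 2)[None, None, :]
        vol[tuple(sl)] += np.exp(-(dz2 + dy2 + dx2) / (2.0 * sigma_um**2))
    return vol


def _reference_geometry(
    p: SyntheticParams,
    marker_clean: np.ndarray,
    spot_field: np.ndarray,
    nucleus: np.ndarray,
    coloc_params: ColocParams,
):
    """Run the reference segmentation on the noise-free marker and measure
    the mean of the unit spot field and of the nucleus indicator over the
    spot mask and the background shell (after the same reslice + smooth
    chain the analysis applies)."""
    spacing = (p.voxel_size_z, p.voxel_size_xy, p.voxel_size_xy)

    def processed(arr: np.ndarray) -> VoxelGrid:
        g = reslice_isotropic(VoxelGrid(arr, spacing), coloc_params.interpolation_order)
        return gaussian_smooth(g, coloc_params.smooth_sigma)

    marker_p = processed(marker_clean)
    seg = segment_spots(marker_p, coloc_params)
    if seg.n_voxels == 0:
        raise DegenerateGeometryError("reference segmentation of the noise-free marker is empty")
    # nucleus as the analysis will see it: derived from the diffuse pool of
    # the (baseline-only) signal channel on the resliced grid
    nucleus_iso = derive_nucleus_mask(
        reslice_isotropic(VoxelGrid(nucleus.astype(float), spacing), "linear"),
        sigma=coloc_params.nucleus_sigma,
        erosion=coloc_params.nucleus_erosion,
    )
    shell = background_shell(
        seg, nucleus_iso, coloc_params.shell_dmin, coloc_params.shell_dmax,
        coloc_params.shell_metric,
    )
    spot_p = processed(spot_field).data
    nuc_p = processed(nucleus.astype(float)).data
    m = seg.mask
    return (
        float(spot_p[m].mean()),
        float(spot_p[shell].mean()),
        float(nuc_p[m].mean()),
        float(nuc_p[shell].mean()),
    )


def _spot_amplitude(
    rho: float, baseline: float, m_spot: float, m_shell: float, u_spot: float, u_shell: float
) -> float:
    """Amplitude A solving (B·u_s + A·m_s) / (B·u_h + A·m_h) = rho."""
    denom = m_spot - rho * m_shell
    if denom <= 0:
        raise DegenerateGeometryError(
            f"enrichment ratio {rho:.3g} not representable: spot/shell contrast too low"
        )
    return baseline * (rho * u_shell - u_spot) / denom


def generate_movie(params: SyntheticParams) -> tuple[Movie, SyntheticGroundTruth]:
    """Generate a two-channel synthetic movie and its ground truth.

    The marker channel is a dim diffuse nuclear background plus
    unit-amplitude Gaussian spots at fixed random centers; the signal
    channel is a uniform nuclear baseline plus the same spot profile
    scaled per frame so the noise-free spot/shell mean ratio equals
    ``1 + f(t)(R - 1)``. Identical params (including seed) give
    bit-identical output.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    shape = tuple(p.shape) if p.shape is not None else _fit_shape(p)
    spacing = (p.voxel_size_z, p.voxel_size_xy, p.voxel_size_xy)

    axes = _physical_axes(shape, spacing)
    zz = (axes[0] ** 2)[:, None, None]
    yy = (axes[1] ** 2)[None, :, None]
    xx = (axes[2] ** 2)[None, None, :]
    nucleus = (zz + yy + xx) <= p.nucleus_radius**2
    if not nucleus.any():
        raise DegenerateGeometryError("nucleus smaller than one voxel")
    extent = [a[-1] - a[0] if a.size > 1 else 0.0 for a in axes]
    if any(2 * p.nucleus_radius > e for e in extent):
        raise DegenerateGeometryError("volume too small to contain the nucleus")

    centers0 = _sample_centers(p, rng)
    times = p.times_rel_nebd()
    f = np.asarray(recruitment_curve(times, p.recruit_fmax, p.recruit_t50, p.recruit_tau))
    rho = 1.0 + f * (p.enrichment_ratio - 1.0)

    coloc_params = ColocParams()
    nuc_f = nucleus.astype(float)

    # per-frame spot centers (static by default, optional random walk)
    per_frame_centers: list[np.ndarray] = [centers0]
    for _ in range(1, p.n_frames):
        if p.motion_sd > 0:
            step = rng.normal(0.0, p.motion_sd, size=centers0.shape)
            nxt = per_frame_centers[-1] + step
            # keep spots inside the eroded nucleus by rejecting outward steps
            r_avail = p.nucleus_radius - p.boundary_margin * p.spot_sigma
            norms = np.sqrt((nxt**2).sum(axis=1))
            bad = norms > r_avail
            nxt[bad] = per_frame_centers[-1][bad]
            per_frame_centers.append(nxt)
        else:
            per_frame_centers.append(centers0)

    static = p.motion_sd == 0
    spot_field0 = _render_spots(shape, spacing, centers0, p.spot_sigma)
    marker_clean0 = p.marker_background * nuc_f + p.marker_amplitude * spot_field0

    geom_cache: tuple[float, float, float, float] | None = None

    def geometry(spot_field: np.ndarray, marker_clean: np.ndarray):
        nonlocal geom_cache
        if static and geom_cache is not None:
            return geom_cache
        g = _reference_geometry(p, marker_clean, spot_field, nucleus, coloc_params)
        if static:
            geom_cache = g
        return g

    def add_noise(clean: np.ndarray) -> np.ndarray:
        clean = np.clip(clean, 0.0, None)
        if not p.noise:
            return clean.astype(np.float32)
        img = rng.poisson(clean * p.photon_scale).astype(float)
        img /= p.photon_scale
        img += rng.normal(0.0, p.read_noise_sd, size=clean.shape)
        return np.clip(img, 0.0, None).astype(np.float32)

    data = np.empty((p.n_frames, 2, *shape), dtype=np.float32)
    for k in range(p.n_frames):
        if static:
            spot_field, marker_clean = spot_field0, marker_clean0
        else:
            spot_field = _render_spots(shape, spacing, per_frame_centers[k], p.spot_sigma)
            marker_clean = p.marker_background * nuc_f + p.marker_amplitude * spot_field
        if f[k] > 0:
            m_s, m_h, u_s, u_h = geometry(spot_field, marker_clean)
            amp = _spot_amplitude(rho[k], p.signal_baseline, m_s, m_h, u_s, u_h)
        else:
            amp = 0.0  # no recruitment: signal channel has no spot excess
        signal_clean = p.signal_baseline * nuc_f + amp * spot_field
        data[k, 0] = add_noise(marker_clean)
        data[k, 1] = add_noise(signal_clean)

    movie = Movie(
        data=data,
        channel_labels=[p.marker_label, p.signal_label],
        frame_interval=p.frame_interval,
        spacing=spacing,
        nebd_frame=p.nebd_frame,
    )
    truth = SyntheticGroundTruth(
        spot_centers=per_frame_centers,
        recruited_fraction=f,
        true_enrichment=rho,
        nucleus_mask=nucleus,
        params=p,
    )
    return movie, truth


def write_ground_truth(truth: SyntheticGroundTruth, path_json: str | Path) -> None:
    """Write ground truth as JSON (full) and CSV (per-frame curves).

    The CSV is written next to the JSON with a ``.csv`` suffix and holds
    frame, t_rel_nebd, recruited_fraction, true_enrichment.
    """
    path_json = Path(path_json)
    payload = {
        "params": dataclasses.asdict(truth.params),
        "recruited_fraction": truth.recruited_fraction.tolist(),
        "true_enrichment": truth.true_enrichment.tolist(),
        "spot_centers_um_zyx": [c.tolist() for c in truth.spot_centers],
        "n_nucleus_voxels": int(truth.nucleus_mask.sum()),
    }
    path_json.write_text(json.dumps(payload, indent=2))
    truth.to_frame().to_csv(path_json.with_suffix(".csv"), index=False)
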