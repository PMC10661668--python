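"""Synthetic two-channel calcium-imaging movies with ground truth.

The generator emulates the statistical structure a somatic calcium-imaging
pipeline has to cope with: a functional (GCaMP-like) channel in which each
neuron's baseline fluorescence is modulated by calcium transients, and a
static nuclear (tdTomato-like) channel used for cell detection.  Network
activity mixes synchronized events shared across neurons (a homogeneous
Poisson process thinned per neuron by a participation probability) with
neuron-specific events (independent Poisson).  Transients rise
instantaneously and decay as a single exponential, fast-indicator style.
Nuisance structure is a slow multiplicative bleaching trend and additive
Gaussian read noise (optionally Poisson shot noise); frames are rendered to
the 8-bit range.

Every quantity needed to score a pipeline — rasterized cell masks, per-cell
spike frames, baselines — is returned as ground truth, and the whole
simulation is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from .errors import CapacityError, DomainError

__all__ = [
    "MovieSpec",
    "CellGroundTruth",
    "ActivityModel",
    "NuisanceModel",
    "SyntheticMovie",
    "sample_cells",
    "simulate_spikes",
    "render_movie",
    "simulate_movie",
    "ground_truth_mask",
    "save_movie",
]


@dataclass(frozen=True)
class MovieSpec:
    """Acquisition geometry: 128x128 px, 120 ms frame interval, 8-bit.

    The 1000-frame default corresponds to a 2-minute recording.
    """

    height: int = 128
    width: int = 128
    n_frames: int = 1000
    frame_interval: float = 0.120
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise DomainError("a movie needs at least 2 frames")
        if min(self.height, self.width) < 1 or self.frame_interval <= 0:
            raise DomainError("invalid movie geometry")
        if self.bit_depth != 8:
            raise DomainError("only 8-bit rendering is supported")

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def intensity_max(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class CellGroundTruth:
    """One simulated soma: a disk footprint plus its activity ground truth."""

    id: int
    center: tuple[float, float]  # (row, col)
    radius: float
    nuclear_intensity: float
    baseline: float
    spike_frames: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class ActivityModel:
    """Spiking statistics: shared network events and private events.

    Rates are per minute; ``network_participation`` is the probability a
    given neuron joins a given network event.  ``transient_amplitude`` is
    the peak fluorescence change as a fraction of baseline; ``decay_tau``
    the exponential decay constant in seconds (rise is instantaneous).
    """

    network_event_rate: float = 3.0
    network_participation: float = 0.8
    private_rate: float = 2.0
    transient_amplitude: float = 0.3
    decay_tau: float = 0.4

    def __post_init__(self) -> None:
        if min(self.network_event_rate, self.private_rate) < 0:
            raise DomainError("rates must be >= 0")
        if not 0 <= self.network_participation <= 1:
            raise DomainError("participation must be in [0, 1]")
        if self.transient_amplitude < 0 or self.decay_tau <= 0:
            raise DomainError("invalid transient parameters")


@dataclass(frozen=True)
class NuisanceModel:
    """Slow multiplicative bleaching plus additive noise.

    ``bleach_tau`` is the time constant (seconds) of the exponential decay
    multiplying the fluorophore signal; ``None`` disables the trend.  The
    default is ten movie lengths, i.e. a mild drift.  ``noise_sigma`` is the
    SD of additive Gaussian noise in counts; ``shot_noise`` replaces it with
    Poisson noise on the noiseless intensity.
    """

    bleach_tau: float | None = 1200.0
    noise_sigma: float = 5.0
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if self.bleach_tau is not None and self.bleach_tau <= 0:
            raise DomainError("bleach_tau must be > 0 or None")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")

    def trend(self, times: np.ndarray) -> np.ndarray:
        if self.bleach_tau is None:
            return np.ones_like(times)
        return np.exp(-times / self.bleach_tau)


@dataclass
class SyntheticMovie:
    """Rendered movie pair plus its ground truth bundle."""

    functional: np.ndarray  # (T, H, W) uint8
    nuclear: np.ndarray  # (T, H, W) uint8
    cells: list[CellGroundTruth]
    spec: MovieSpec

    @property
    def label_mask(self) -> np.ndarray:
        return ground_truth_mask(self.cells, self.spec)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _disk_pixels(center: tuple[float, float], radius: float,
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the rasterized disk |p - c| <= r inside ``shape``."""
    r0, c0 = center
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return np.nonzero(inside)


def sample_cells(
    spec: MovieSpec,
    n_cells: int = 30,
    radius_range: tuple[float, float] = (3.0, 5.0),
    rng_seed: int | np.random.Generator = 0,
    *,
    baseline_range: tuple[float, float] = (80.0, 140.0),
    nuclear_intensity: float = 180.0,
    min_gap: float = 2.0,
    max_attempts: int = 20000,
) -> list[CellGroundTruth]:
    """Place ``n_cells`` pairwise-disjoint disk somata fully inside the frame.

    Rejection sampling: a candidate is kept if its disk stays ``min_gap``
    pixels clear of every accepted disk (centre distance > r_i + r_j +
    min_gap) and fully inside the image.  Deterministic under a fixed seed;
    raises :class:`CapacityError` if the packing budget is exhausted.
    """
    rng = np.random.default_rng(rng_seed)
    lo, hi = radius_range
    if not 0 < lo <= hi:
        raise DomainError("invalid radius range")
    cells: list[CellGroundTruth] = []
    attempts = 0
    while len(cells) < n_cells:
        if attempts >= max_attempts:
            raise CapacityError(
                f"placed {len(cells)}/{n_cells} cells in {max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(lo, hi)
        margin = r + 1.0
        center = (
            rng.uniform(margin, spec.height - margin),
            rng.uniform(margin, spec.width - margin),
        )
        ok = all(
            np.hypot(center[0] - c.center[0], center[1] - c.center[1])
            > r + c.radius + min_gap
            for c in cells
        )
        if not ok:
            continue
        cells.append(
            CellGroundTruth(
                id=len(cells) + 1,
                center=center,
                radius=r,
                nuclear_intensity=nuclear_intensity,
                baseline=rng.uniform(*baseline_range),
            )
        )
    return cells


def simulate_spikes(
    cells: list[CellGroundTruth],
    activity: ActivityModel,
    spec: MovieSpec,
    rng_seed: int | np.random.Generator = 0,
) -> list[list[int]]:
    """Draw spike frames for each cell and store them on the ground truth.

    Network events form a homogeneous Poisson process over the movie; each
    cell joins each event independently with the participation probability.
    Private spikes are an independent Poisson process per cell.  The union is
    sorted and de-duplicated at frame resolution.
    """
    rng = np.random.default_rng(rng_seed)
    duration_min = spec.duration / 60.0

    n_events = rng.poisson(activity.network_event_rate * duration_min)
    event_times = np.sort(rng.uniform(0, spec.duration, size=n_events))

    spikes: list[list[int]] = []
    for cell in cells:
        joins = rng.random(n_events) < activity.network_participation
        times = list(event_times[joins])
        n_priv = rng.poisson(activity.private_rate * duration_min)
        times.extend(rng.uniform(0, spec.duration, size=n_priv))
        frames = sorted({
            f for t in times
            if (f := int(t / spec.frame_interval)) < spec.n_frames
        })
        cell.spike_frames = frames
        spikes.append(frames)
    return spikes


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def ground_truth_mask(cells: list[CellGroundTruth], spec: MovieSpec) -> np.ndarray:
    """Label image (H, W): 0 background, k inside cell k — the exact disks
    used for rendering."""
    mask = np.zeros((spec.height, spec.width), dtype=np.int32)
    for cell in cells:
        rr, cc = _disk_pixels(cell.center, cell.radius, mask.shape)
        mask[rr, cc] = cell.id
    return mask


def _transient_course(frames: list[int], activity: ActivityModel,
                      spec: MovieSpec) -> np.ndarray:
    """Summed transient kernel a(t) = sum_s amp * exp(-(t - t_s)/tau), t >= t_s."""
    a = np.zeros(spec.n_frames)
    t = spec.times
    for f in frames:
        t_s = f * spec.frame_interval
        tail = slice(f, spec.n_frames)
        a[tail] += activity.transient_amplitude * np.exp(-(t[tail] - t_s) / activity.decay_tau)
    return a


def render_movie(
    cells: list[CellGroundTruth],
    activity: ActivityModel,
    nuisance: NuisanceModel,
    spec: MovieSpec,
    rng_seed: int | np.random.Generator = 0,
    *,
    background: float = 20.0,
    nuclear_background: float = 20.0,
    clip_warn_fraction: float = 0.01,
) -> SyntheticMovie:
    """Render the functional and nuclear channels from sampled ground truth.

    Functional channel, per pixel of cell k:
    ``F(t) = trend(t) * F0_k * (1 + a_k(t)) + noise`` with ``a_k`` the summed
    transient kernel; background pixels sit at a constant offset.  Nuclear
    channel: static disks at each cell's nuclear intensity.  Both channels
    are clipped to the 8-bit range; a warning is raised if clipping touches
    more than ``clip_warn_fraction`` of in-cell pixel-frames.
    """
    rng = np.random.default_rng(rng_seed)
    T, H, W = spec.n_frames, spec.height, spec.width
    trend = nuisance.trend(spec.times)

    functional = np.full((T, H, W), background, dtype=np.float32)
    nuclear_frame = np.full((H, W), nuclear_background, dtype=np.float32)

    n_cell_pixel_frames = 0
    n_clipped = 0
    for cell in cells:
        rr, cc = _disk_pixels(cell.center, cell.radius, (H, W))
        a = _transient_course(cell.spike_frames, activity, spec)
        course = trend * cell.baseline * (1.0 + a)  # (T,)
        functional[:, rr, cc] = course[:, None]
        nuclear_frame[rr, cc] = cell.nuclear_intensity
        n_cell_pixel_frames += rr.size * T
        n_clipped += int(np.count_nonzero(course > spec.intensity_max)) * rr.size

    if n_cell_pixel_frames and n_clipped / n_cell_pixel_frames > clip_warn_fraction:
        warnings.warn(
            f"{n_clipped / n_cell_pixel_frames:.1%} of in-cell pixel-frames "
            "exceed the bit depth and will clip; lower baselines or amplitude",
            stacklevel=2,
        )

    if nuisance.shot_noise:
        functional = rng.poisson(np.clip(functional, 0, None)).astype(np.float32)
        nuclear = rng.poisson(
            np.clip(np.broadcast_to(nuclear_frame, (T, H, W)), 0, None)
        ).astype(np.float32)
    else:
        nuclear = np.broadcast_to(nuclear_frame, (T, H, W)).copy()
        if nuisance.noise_sigma:
            functional += rng.normal(0.0, nuisance.noise_sigma, functional.shape).astype(np.float32)
            nuclear += rng.normal(0.0, nuisance.noise_sigma, nuclear.shape).astype(np.float32)

    functional = np.clip(functional, 0, spec.intensity_max).round().astype(np.uint8)
    nuclear = np.clip(nuclear, 0, spec.intensity_max).round().astype(np.uint8)
    return SyntheticMovie(functional=functional, nuclear=nuclear, cells=cells, spec=spec)


def simulate_movie(
    spec: MovieSpec | None = None,
    activity: ActivityModel | None = None,
    nuisance: NuisanceModel | None = None,
    n_cells: int = 30,
    radius_range: tuple[float, float] = (3.0, 5.0),
    seed: int = 0,
    **render_kwargs,
) -> SyntheticMovie:
    """One-call simulation: sample cells, draw spikes, render both channels.

    The seed is split into independent streams for placement, spiking and
    noise, so the whole movie is reproducible from a single integer.
    """
    spec = spec or MovieSpec()
    activity = activity or ActivityModel()
    nuisance = nuisance or NuisanceModel()
    ss = np.random.SeedSequence(seed).spawn(3)
    cells = sample_cells(spec, n_cells, radius_range,
                         np.random.default_rng(ss[0]))
    simulate_spikes(cells, activity, spec, np.random.default_rng(ss[1]))
    return render_movie(cells, activity, nuisance, spec,
                        np.random.default_rng(ss[2]), **render_kwargs)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_movie(movie: SyntheticMovie, out_dir: str | Path, stem: str = "sim") -> dict[str, Path]:
    """Write TIFF stacks, label-mask TIFF and ground-truth JSON to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gcamp": out / f"{stem}_gcamp.tif",
        "nuclear": out / f"{stem}_nuclear.tif",
        "mask": out / f"{stem}_mask.tif",
        "truth": out / f"{stem}_truth.json",
    }
    tifffile.imwrite(paths["gcamp"], movie.functional)
    tifffile.imwrite(paths["nuclear"], movie.nuclear)
    tifffile.imwrite(paths["mask"], movie.label_mask.astype(np.uint16))
    truth = {
        "spec": asdict(movie.spec),
        "cells": [asdict(c) for c in movie.cells],
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
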