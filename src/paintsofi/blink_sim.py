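"""DNA-PAINT blinking-movie simulator.

Transient hybridization of dye-coupled imager strands to target-bound docking
strands produces fluorescent blinking that is programmable through sequence
design (repeat motifs multiply the binding-event frequency), imager
concentration (shortens the dark time) and duplex destabilizers such as
ethylene carbonate (shorten the bright time).  This module simulates that
process as an alternating renewal process per docking motif, integrates the
resulting occupancy over camera frames with exact interval arithmetic, and
renders photon-count movies through a Gaussian optical model and an sCMOS
camera model (shot noise, read noise, gain, offset).

Coordinates: the sample frame is in nm with the origin at the field corner;
camera pixel (row, col) = (i, j) covers [j*p, (j+1)*p) x [i*p, (i+1)*p) nm
for pixel size p, i.e. positions are continuous and pixels half-open.

Randomness: every public entry point takes a single master seed.  Child
streams are derived deterministically per site (and per frame for camera
noise), so adding a docking site to a phantom does not perturb the traces of
the existing sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.special import erf

__all__ = [
    "KineticParams",
    "DockingSite",
    "Phantom",
    "OpticsCamera",
    "MovieStack",
    "BindingTrace",
    "BindingStatistics",
    "make_filament_phantom",
    "make_point_pair_phantom",
    "make_grid_phantom",
    "simulate_binding_trace",
    "integrate_occupancy",
    "render_movie",
    "binding_statistics",
]

# Extra diffusive-imager background relative to TIRF sectioning.
ILLUMINATION_BACKGROUND_FACTOR = {"TIRF": 1.0, "HILO": 2.5, "EPI": 8.0}


@dataclass(frozen=True)
class KineticParams:
    """Hybridization kinetics of one docking site.

    Parameters
    ----------
    per_site_binding_rate:
        Binding events per second *per motif* at the working imager
        concentration (the rate is proportional to concentration; the
        concentration itself is carried only as metadata).
    mean_bound_time:
        Mean bright (bound) dwell time in seconds, tau_on = 1/k_off.
    n_repeat_motifs:
        Number of concatenated docking motifs (1 for a P3-like strand,
        5 for a 5xR1-like repeat strand).
    destabilizer_on_time_factor:
        Multiplies ``mean_bound_time``; in (0, 1].  Models duplex
        destabilization by additives such as ethylene carbonate.
    imager_concentration_nM:
        Metadata only.
    """

    per_site_binding_rate: float
    mean_bound_time: float
    n_repeat_motifs: int = 1
    destabilizer_on_time_factor: float = 1.0
    imager_concentration_nM: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.per_site_binding_rate) and self.per_site_binding_rate > 0):
            raise ValueError("per_site_binding_rate must be finite and > 0")
        if not (np.isfinite(self.mean_bound_time) and self.mean_bound_time > 0):
            raise ValueError("mean_bound_time must be finite and > 0")
        if int(self.n_repeat_motifs) != self.n_repeat_motifs or self.n_repeat_motifs < 1:
            raise ValueError("n_repeat_motifs must be an integer >= 1")
        if not (0.0 < self.destabilizer_on_time_factor <= 1.0):
            raise ValueError("destabilizer_on_time_factor must be in (0, 1]")

    @property
    def effective_mean_bound_time(self) -> float:
        return self.mean_bound_time * self.destabilizer_on_time_factor

    @property
    def mean_unbound_time(self) -> float:
        """Mean dark time of a single motif."""
        return 1.0 / self.per_site_binding_rate


@dataclass(frozen=True)
class DockingSite:
    position: tuple[float, float]  # (x, y) in nm
    kinetics: KineticParams

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError("site position must be finite")


@dataclass
class Phantom:
    """Ground-truth sample: docking sites plus parametric truth geometry."""

    sites: list[DockingSite]
    extent: tuple[float, float]  # (width, height) nm
    structure_label: str = ""
    truth_geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w, h = self.extent
        for s in self.sites:
            x, y = s.position
            if not (0.0 <= x <= w and 0.0 <= y <= h):
                raise ValueError(f"site at ({x}, {y}) outside extent {self.extent}")

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=float).reshape(-1, 2)

    def translated(self, dx_nm: float, dy_nm: float, new_extent: tuple[float, float]) -> "Phantom":
        """Shift all sites by (-dx, -dy) and crop to a new extent (tile windowing)."""
        sites = []
        w, h = new_extent
        for s in self.sites:
            x, y = s.position
            x2, y2 = x - dx_nm, y - dy_nm
            if 0.0 <= x2 <= w and 0.0 <= y2 <= h:
                sites.append(DockingSite((x2, y2), s.kinetics))
        return Phantom(sites, new_extent, self.structure_label, dict(self.truth_geometry))


@dataclass(frozen=True)
class OpticsCamera:
    """Optical and sCMOS camera model for movie rendering."""

    pixel_size: float = 100.0  # nm/pixel
    psf_fwhm: float = 300.0  # nm, 2-D Gaussian approximation
    frame_time: float = 0.01  # s (100 Hz)
    n_frames: int = 500
    photons_per_bound_imager_per_s: float = 50_000.0
    background_photons_per_pixel_per_frame: float = 10.0
    illumination_mode: str = "TIRF"
    camera_gain: float = 2.0  # counts/photon
    camera_offset: float = 100.0  # counts
    read_noise_sd: float = 1.6  # counts
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "psf_fwhm", "frame_time", "photons_per_bound_imager_per_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.camera_offset < 0 or self.read_noise_sd < 0:
            raise ValueError("camera_offset and read_noise_sd must be >= 0")
        if self.background_photons_per_pixel_per_frame < 0:
            raise ValueError("background must be >= 0")
        if self.psf_fwhm <= self.pixel_size:
            raise ValueError("psf_fwhm must exceed pixel_size (sampled PSF)")
        if self.illumination_mode not in ILLUMINATION_BACKGROUND_FACTOR:
            raise ValueError(f"unknown illumination_mode {self.illumination_mode!r}")

    @property
    def psf_sigma_nm(self) -> float:
        return self.psf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size

    @property
    def duration(self) -> float:
        return self.frame_time * self.n_frames

    @property
    def effective_background(self) -> float:
        return (
            self.background_photons_per_pixel_per_frame
            * ILLUMINATION_BACKGROUND_FACTOR[self.illumination_mode]
        )


@dataclass
class MovieStack:
    """T x H x W photon-count movie with acquisition metadata."""

    frames: np.ndarray
    meta: OpticsCamera
    phantom_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if self.frames.shape[0] != self.meta.n_frames:
            raise ValueError("frame count does not match metadata n_frames")
        if np.any(self.frames < 0):
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class BindingTrace:
    """Per-motif binding intervals of one docking site."""

    motif_intervals: list[np.ndarray]  # each (k, 2): [bind, unbind], clipped, sorted
    duration: float
    kinetics: KineticParams

    def all_intervals(self) -> np.ndarray:
        """All intervals pooled across motifs, sorted by bind time, shape (k, 2)."""
        parts = [iv for iv in self.motif_intervals if len(iv)]
        if not parts:
            return np.zeros((0, 2))
        out = np.concatenate(parts, axis=0)
        return out[np.argsort(out[:, 0])]

    @property
    def n_events(self) -> int:
        return sum(len(iv) for iv in self.motif_intervals)


# ----------------------------------------------------------------------------
# RNG plumbing


def _site_rng(master_seed: int, site_index: int, acquisition: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(master_seed, spawn_key=(0, acquisition, site_index))
    return np.random.default_rng(ss)


def _noise_rng(master_seed: int, acquisition: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(master_seed, spawn_key=(1, acquisition))
    return np.random.default_rng(ss)


# ----------------------------------------------------------------------------
# Phantoms


def make_filament_phantom(
    n_filaments: int,
    extent: tuple[float, float],
    site_linear_density: float,
    kinetics: KineticParams,
    curvature: float = 0.5,
    seed: int = 0,
    margin_fraction: float = 0.12,
) -> Phantom:
    """Random smooth filaments decorated with Poisson-spaced docking sites.

    Each filament is a cubic spline through a jittered random walk of control
    points; docking sites are dropped along the arc with exponential spacing
    of mean ``1/site_linear_density`` (a Poisson process on arc length).
    ``curvature`` in [0, 1] scales the direction jitter of the walk.
    """
    if site_linear_density <= 0:
        raise ValueError("site_linear_density must be > 0 (sites/nm)")
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    w, h = extent
    mx, my = w * margin_fraction, h * margin_fraction
    if w - 2 * mx <= 0:
        raise ValueError(f"extent width {w} nm too small to place a filament")
    if h - 2 * my <= 0:
        raise ValueError(f"extent height {h} nm too small to place a filament")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    sites: list[DockingSite] = []
    curves = []
    for _ in range(n_filaments):
        n_ctrl = 6
        # random walk across the field
        start = np.array([rng.uniform(mx, w - mx), rng.uniform(my, h - my)])
        angle = rng.uniform(0, 2 * np.pi)
        step = 0.9 * max(w, h) / n_ctrl
        pts = [start]
        for _k in range(n_ctrl - 1):
            angle += curvature * rng.normal(0.0, 0.8)
            nxt = pts[-1] + step * np.array([np.cos(angle), np.sin(angle)])
            # reflect off the margin box to stay inside
            for d, lo, hi in ((0, mx, w - mx), (1, my, h - my)):
                if nxt[d] < lo:
                    nxt[d] = 2 * lo - nxt[d]
                    angle = np.pi - angle if d == 0 else -angle
                if nxt[d] > hi:
                    nxt[d] = 2 * hi - nxt[d]
                    angle = np.pi - angle if d == 0 else -angle
            nxt[0] = np.clip(nxt[0], mx, w - mx)
            nxt[1] = np.clip(nxt[1], my, h - my)
            pts.append(nxt)
        pts_arr = np.array(pts)
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts_arr, axis=0), axis=1))])
        if chord[-1] <= 0:
            continue
        spl = CubicSpline(chord, pts_arr, axis=0)
        # dense resample for arc-length parametrization
        t = np.linspace(0, chord[-1], 2048)
        xy = spl(t)
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        total = arclen[-1]
        # Poisson process on arc length
        positions_s = []
        s = rng.exponential(1.0 / site_linear_density)
        while s < total:
            positions_s.append(s)
            s += rng.exponential(1.0 / site_linear_density)
        if positions_s:
            sx = np.interp(positions_s, arclen, xy[:, 0])
            sy = np.interp(positions_s, arclen, xy[:, 1])
            for x, y in zip(sx, sy):
                if 0 <= x <= w and 0 <= y <= h:
                    sites.append(DockingSite((float(x), float(y)), kinetics))
        curves.append({"control_points": pts_arr.tolist(), "arc_length_nm": float(total)})

    return Phantom(
        sites,
        extent,
        structure_label="filaments",
        truth_geometry={"curves": curves, "site_linear_density_per_nm": site_linear_density},
    )


def make_point_pair_phantom(
    separation_nm: float,
    kinetics: KineticParams,
    extent: tuple[float, float] = (3200.0, 3200.0),
    strands_per_point: int = 1,
    strand_spread_nm: float = 8.0,
    seed: int = 0,
) -> Phantom:
    """Two point targets separated by ``separation_nm``, symmetric about center.

    With ``strands_per_point`` > 1 each point is a tight cluster of docking
    strands (Gaussian spread ``strand_spread_nm``), as on DNA-origami
    resolution targets; clustering averages per-strand blinking statistics
    so the two points have comparable cumulant amplitudes.  The same
    ``kinetics`` object is shared (by reference) by every site.
    """
    if separation_nm < 0:
        raise ValueError("separation_nm must be >= 0")
    if strands_per_point < 1:
        raise ValueError("strands_per_point must be >= 1")
    cx, cy = extent[0] / 2.0, extent[1] / 2.0
    centers = [(cx - separation_nm / 2.0, cy), (cx + separation_nm / 2.0, cy)]
    sites: list[DockingSite] = []
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(8,)))
    for cx0, cy0 in centers:
        if strands_per_point == 1:
            sites.append(DockingSite((cx0, cy0), kinetics))
            continue
        for _ in range(strands_per_point):
            dx, dy = rng.normal(0.0, strand_spread_nm, size=2)
            sites.append(DockingSite((cx0 + dx, cy0 + dy), kinetics))
    return Phantom(
        sites,
        extent,
        structure_label="point pair",
        truth_geometry={
            "separation_nm": separation_nm,
            "center_nm": (cx, cy),
            "strands_per_point": strands_per_point,
        },
    )


def make_grid_phantom(
    spacing_nm: float,
    extent: tuple[float, float],
    kinetics: KineticParams,
    offset_nm: float | None = None,
) -> Phantom:
    """Uniform square grid of identical sites (homogeneity / flattening tests)."""
    if spacing_nm <= 0:
        raise ValueError("spacing_nm must be > 0")
    off = spacing_nm / 2.0 if offset_nm is None else offset_nm
    xs = np.arange(off, extent[0], spacing_nm)
    ys = np.arange(off, extent[1], spacing_nm)
    sites = [DockingSite((float(x), float(y)), kinetics) for y in ys for x in xs]
    return Phantom(sites, extent, "uniform grid", {"spacing_nm": spacing_nm})


# ----------------------------------------------------------------------------
# Kinetics


def _renewal_intervals(
    rng: np.random.Generator,
    binding_rate: float,
    mean_on: float,
    duration: float,
    start_bound: bool,
) -> np.ndarray:
    """Alternating renewal process for one motif; returns (k, 2) clipped intervals."""
    binds: list[float] = []
    unbinds: list[float] = []
    t = 0.0
    first = True
    # draw dwells in batches for speed
    batch = max(16, int(duration * binding_rate * 1.2) + 8)
    while t < duration:
        waits = rng.exponential(1.0 / binding_rate, size=batch)
        ons = rng.exponential(mean_on, size=batch)
        for w_, on in zip(waits, ons):
            if first and start_bound:
                b = 0.0
                first = False
            else:
                b = t + w_
                first = False
            u = b + on
            if b >= duration:
                t = b
                break
            binds.append(b)
            unbinds.append(u)
            t = u
        if t >= duration or (binds and binds[-1] >= duration):
            break
    if not binds:
        return np.zeros((0, 2))
    iv = np.column_stack([binds, unbinds])
    iv = iv[iv[:, 0] < duration]
    iv[:, 1] = np.minimum(iv[:, 1], duration)
    iv[:, 0] = np.maximum(iv[:, 0], 0.0)
    return iv


def simulate_binding_trace(
    kinetics: KineticParams,
    duration: float,
    seed: int | np.random.Generator = 0,
    start_bound: bool = False,
    allow_simultaneous: bool = True,
) -> BindingTrace:
    """Simulate imager binding to one docking site.

    Each of the ``n_repeat_motifs`` motifs is an independent alternating
    renewal process: unbound dwell ~ Exp(mean 1/per_site_binding_rate), bound
    dwell ~ Exp(mean mean_bound_time * destabilizer_on_time_factor).
    Simultaneous occupancy of distinct motifs is allowed by default and sums
    to multi-emitter brightness; with ``allow_simultaneous=False`` the site is
    a single process with the pooled binding rate that blocks while bound.
    """
    if not (np.isfinite(duration) and duration > 0):
        raise ValueError("duration must be finite and > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_on = kinetics.effective_mean_bound_time
    if allow_simultaneous:
        motifs = [
            _renewal_intervals(
                rng, kinetics.per_site_binding_rate, mean_on, duration, start_bound and m == 0
            )
            for m in range(kinetics.n_repeat_motifs)
        ]
    else:
        pooled = kinetics.per_site_binding_rate * kinetics.n_repeat_motifs
        motifs = [_renewal_intervals(rng, pooled, mean_on, duration, start_bound)]
    return BindingTrace(motifs, duration, kinetics)


def integrate_occupancy(
    trace: BindingTrace | np.ndarray,
    frame_time: float,
    n_frames: int,
) -> np.ndarray:
    """Per-frame occupancy in emitter-seconds, by exact interval arithmetic.

    Element t is the total bound time (summed over motifs) intersecting
    [t*dt, (t+1)*dt).  The sum over frames equals the total clipped interval
    length within the movie window exactly (no sub-frame discretization).
    """
    if frame_time <= 0:
        raise ValueError("frame_time must be > 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    intervals = trace.all_intervals() if isinstance(trace, BindingTrace) else np.asarray(trace, float).reshape(-1, 2)
    occ = np.zeros(n_frames)
    t_end = frame_time * n_frames
    for t0, t1 in intervals:
        t0 = max(t0, 0.0)
        t1 = min(t1, t_end)
        if t1 <= t0:
            continue
        f0 = int(t0 / frame_time)
        f1 = min(int(math.ceil(t1 / frame_time)), n_frames)
        if f1 <= f0:
            f1 = f0 + 1
        fr = np.arange(f0, f1)
        lo = np.maximum(t0, fr * frame_time)
        hi = np.minimum(t1, (fr + 1) * frame_time)
        occ[fr] += np.maximum(hi - lo, 0.0)
    return occ


# ----------------------------------------------------------------------------
# Rendering


def _integrated_gaussian_1d(n: int, center_px: float, sigma_px: float) -> np.ndarray:
    """Gaussian integrated over unit pixels: pixel i covers [i, i+1)."""
    edges = np.arange(n + 1, dtype=float)
    z = (edges - center_px) / (sigma_px * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf)


def psf_kernel_matrix(positions_nm: np.ndarray, optics: OpticsCamera, shape: tuple[int, int]) -> np.ndarray:
    """(n_sites, H*W) matrix of pixel-integrated Gaussian PSFs (unit total mass)."""
    H, W = shape
    sigma_px = optics.psf_sigma_px
    out = np.empty((len(positions_nm), H * W))
    for k, (x, y) in enumerate(positions_nm):
        fx = _integrated_gaussian_1d(W, x / optics.pixel_size, sigma_px)
        fy = _integrated_gaussian_1d(H, y / optics.pixel_size, sigma_px)
        out[k] = np.outer(fy, fx).ravel()
    return out


def render_movie(
    phantom: Phantom,
    optics: OpticsCamera,
    noise: bool = True,
    start_bound: bool = False,
    acquisition: int = 0,
    out_of_focus_background: float = 0.0,
    out_of_focus_fwhm_nm: float = 2000.0,
    return_occupancy: bool = False,
):
    """Render a blinking movie from a phantom.

    Expected photons per frame = sum over sites of occupancy (emitter-seconds)
    x photons/s x pixel-integrated Gaussian PSF, plus the uniform diffusive
    background (scaled by the illumination mode).  With ``noise=True`` the
    observed counts are gain * Poisson(expected) + N(0, read_noise) + offset,
    rounded and clipped at 0; with ``noise=False`` the expected photon image
    is returned unchanged (no gain/offset), which conserves photons exactly.

    ``out_of_focus_background`` adds a static structural background: the
    phantom's site density convolved with a wide Gaussian, scaled so its mean
    equals the given photons/pixel/frame (emulates EPI vs TIRF sectioning).
    Sites whose PSF mass in the field is < 1e-6 are dropped with a warning.
    """
    H = int(round(phantom.extent[1] / optics.pixel_size))
    W = int(round(phantom.extent[0] / optics.pixel_size))
    if H < 1 or W < 1:
        raise ValueError("phantom extent smaller than one pixel")
    T = optics.n_frames
    if len(phantom.sites) == 0 and optics.effective_background <= 0 and out_of_focus_background <= 0:
        raise ValueError("empty phantom with zero background renders nothing")

    positions = phantom.positions
    n_sites = len(positions)
    occ = np.zeros((T, n_sites))
    for k in range(n_sites):
        rng = _site_rng(optics.seed, k, acquisition)
        tr = simulate_binding_trace(phantom.sites[k].kinetics, optics.duration, rng, start_bound=start_bound)
        occ[:, k] = integrate_occupancy(tr, optics.frame_time, T)

    if n_sites:
        kernels = psf_kernel_matrix(positions, optics, (H, W))
        mass = kernels.sum(axis=1)
        inside = mass > 1e-6
        if not np.all(inside):
            import warnings

            warnings.warn(f"dropping {np.count_nonzero(~inside)} site(s) outside the field")
            kernels = kernels[inside]
            occ = occ[:, inside]
        expected = (occ * optics.photons_per_bound_imager_per_s) @ kernels
        expected = expected.reshape(T, H, W)
    else:
        expected = np.zeros((T, H, W))

    expected += optics.effective_background
    if out_of_focus_background > 0 and n_sites:
        density = np.zeros((H, W))
        ij = np.floor(positions[:, ::-1] / optics.pixel_size).astype(int)
        np.add.at(density, (np.clip(ij[:, 0], 0, H - 1), np.clip(ij[:, 1], 0, W - 1)), 1.0)
        blur = gaussian_filter(density, out_of_focus_fwhm_nm / 2.355 / optics.pixel_size, mode="constant")
        if blur.mean() > 0:
            expected += out_of_focus_background * blur / blur.mean()

    if noise:
        rng = _noise_rng(optics.seed, acquisition)
        counts = optics.camera_gain * rng.poisson(expected).astype(float)
        if optics.read_noise_sd > 0:
            counts += rng.normal(0.0, optics.read_noise_sd, size=counts.shape)
        counts += optics.camera_offset
        frames = np.clip(np.rint(counts), 0, 65535)
    else:
        frames = expected

    stack = MovieStack(frames, meta=optics, phantom_label=phantom.structure_label)
    if return_occupancy:
        return stack, occ
    return stack


# ----------------------------------------------------------------------------
# Statistics


@dataclass
class BindingStatistics:
    n_events: int
    mean_on_time: float | None
    mean_off_time: float | None
    events_per_s: float
    duty_cycle: float

    @property
    def defined(self) -> bool:
        return self.n_events > 0


def _union_length(intervals: np.ndarray) -> float:
    if len(intervals) == 0:
        return 0.0
    iv = intervals[np.argsort(intervals[:, 0])]
    total = 0.0
    cur0, cur1 = iv[0]
    for t0, t1 in iv[1:]:
        if t0 > cur1:
            total += cur1 - cur0
            cur0, cur1 = t0, t1
        else:
            cur1 = max(cur1, t1)
    return total + (cur1 - cur0)


def binding_statistics(traces: Sequence[BindingTrace]) -> BindingStatistics:
    """Pooled kinetic estimators over one or more site traces.

    On-times are interval lengths; off-times are within-motif gaps (so the
    off-time estimator targets the single-motif dark time 1/rate); events/s
    is the site-level event rate (motif multiplicity included); duty cycle is
    the fraction of total time with at least one motif bound.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    on_times: list[np.ndarray] = []
    off_times: list[np.ndarray] = []
    n_events = 0
    total_time = 0.0
    bound_time = 0.0
    for tr in traces:
        total_time += tr.duration
        bound_time += _union_length(tr.all_intervals())
        for iv in tr.motif_intervals:
            n_events += len(iv)
            if len(iv):
                on_times.append(iv[:, 1] - iv[:, 0])
            if len(iv) > 1:
                off_times.append(iv[1:, 0] - iv[:-1, 1])
    on = np.concatenate(on_times) if on_times else np.array([])
    off = np.concatenate(off_times) if off_times else np.array([])
    return BindingStatistics(
        n_events=n_events,
        mean_on_time=float(on.mean()) if len(on) else None,
        mean_off_time=float(off.mean()) if len(off) else None,
        events_per_s=n_events / total_time if total_time > 0 else 0.0,
        duty_cycle=bound_time / total_time if total_time > 0 else 0.0,
    )
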