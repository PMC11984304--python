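"""Zero-lag auto- and cross-cumulant SOFI images (orders 2-6).

SOFI computes nth-order temporal cumulants of pixel intensity fluctuations:
for independently blinking emitters the cumulant image is the sum of single
emitter contributions with the optical PSF raised to the nth power, i.e. a
sqrt(n) (and with deconvolution up to n-fold) resolution gain.

The joint cumulant of series X_1..X_n is evaluated by the moment/partition
formula

    kappa(X_1..X_n) = sum over partitions pi of {1..n}
                      (-1)^(|pi|-1) (|pi|-1)! prod_{B in pi} E[prod_{i in B} X_i]

with every series mean-subtracted first (biased, 1/T moment estimators), so
partitions containing singleton blocks vanish identically.

Cross-cumulants of n *distinct* pixels are attributed to the pixel centroid,
yielding an n-fold oversampled virtual lattice; the emitter-independent
Gaussian prefactor exp(-sum_i |r_i - rbar|^2 / (2 sigma^2)) is recorded per
lattice site as the distance factor for later flattening.

Long acquisitions are split into 1000-frame subsequences, each cumulant is
computed per block, blocks are registered to the first by cross-correlation
(inter-subsequence drift correction) and averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .blink_sim import MovieStack

__all__ = [
    "CumulantImage",
    "SubsequencePlan",
    "joint_cumulant",
    "auto_cumulant_image",
    "cross_cumulant_image",
    "split_subsequences",
    "combine_subsequence_cumulants",
    "estimate_block_shifts",
    "virtual_pixel_combination",
]

MAX_ORDER = 6


@dataclass
class CumulantImage:
    """An nth-order SOFI image on a (possibly oversampled) virtual lattice."""

    order: int
    values: np.ndarray
    oversampling: int
    distance_factors: np.ndarray | None = None
    pixel_size_nm: float | None = None  # lattice pixel size
    flattened: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.oversampling not in (1, self.order):
            raise ValueError("oversampling must be 1 (auto) or order (cross)")

    def copy_with(self, values: np.ndarray, **updates) -> "CumulantImage":
        out = CumulantImage(
            order=self.order,
            values=values,
            oversampling=self.oversampling,
            distance_factors=self.distance_factors,
            pixel_size_nm=self.pixel_size_nm,
            flattened=self.flattened,
            provenance=dict(self.provenance),
        )
        for k, v in updates.items():
            setattr(out, k, v)
        return out


@dataclass(frozen=True)
class SubsequencePlan:
    """Disjoint, ordered, consecutive frame blocks covering <= T frames."""

    blocks: tuple[tuple[int, int], ...]  # (start, stop) half-open
    block_length: int
    n_frames: int

    @property
    def n_dropped(self) -> int:
        return self.n_frames - sum(b - a for a, b in self.blocks)


# ----------------------------------------------------------------------------
# Partition machinery


@lru_cache(maxsize=None)
def set_partitions(n: int) -> tuple[tuple[tuple[int, ...], ...], ...]:
    """All partitions of {0..n-1} as tuples of blocks (restricted-growth order)."""
    if n == 0:
        return ((),)
    result: list[tuple[tuple[int, ...], ...]] = []

    def rec(i: int, blocks: list[list[int]]) -> None:
        if i == n:
            result.append(tuple(tuple(b) for b in blocks))
            return
        for b in blocks:
            b.append(i)
            rec(i + 1, blocks)
            b.pop()
        blocks.append([i])
        rec(i + 1, blocks)
        blocks.pop()

    rec(0, [])
    return tuple(result)


@lru_cache(maxsize=None)
def _partition_terms(n: int) -> tuple[tuple[float, tuple[tuple[int, ...], ...]], ...]:
    """(coefficient, blocks) pairs, singleton-containing partitions removed."""
    terms = []
    for part in set_partitions(n):
        if any(len(b) == 1 for b in part) and n > 1:
            continue  # mean-subtracted: singleton blocks vanish identically
        coeff = (-1.0) ** (len(part) - 1) * math.factorial(len(part) - 1)
        terms.append((coeff, part))
    return tuple(terms)


def joint_cumulant(series_tuple: Sequence[np.ndarray]) -> float:
    """Joint zero-lag cumulant of n equal-length series (n in 1..6).

    Biased (1/T) moment estimators; symmetric and multilinear in its inputs.
    """
    xs = [np.asarray(s, dtype=float) for s in series_tuple]
    n = len(xs)
    if not 1 <= n <= MAX_ORDER:
        raise ValueError(f"order must be in 1..{MAX_ORDER}, got {n}")
    T = xs[0].size
    for x in xs:
        if x.ndim != 1 or x.size != T:
            raise ValueError("all series must be 1-D with equal length")
    if T < n:
        raise ValueError("series length must be >= order")
    if not all(np.all(np.isfinite(x)) for x in xs):
        raise ValueError("series must be finite")
    if n == 1:
        return float(xs[0].mean())
    xc = [x - x.mean() for x in xs]
    total = 0.0
    for coeff, blocks in _partition_terms(n):
        term = 1.0
        for b in blocks:
            prod_ = xc[b[0]].copy()
            for i in b[1:]:
                prod_ *= xc[i]
            term *= prod_.mean()
        total += coeff * term
    return float(total)


def _cumulant_from_block_moments(order: int, moment) -> np.ndarray:
    """Partition sum where ``moment(block)`` returns E[prod_{i in block} X_i]."""
    out = None
    for coeff, blocks in _partition_terms(order):
        term = None
        for b in blocks:
            m = moment(b)
            term = m.copy() if term is None else term * m
        term *= coeff
        out = term if out is None else out + term
    return out


# ----------------------------------------------------------------------------
# Cumulant images


def _frames(movie: MovieStack | np.ndarray) -> np.ndarray:
    if isinstance(movie, MovieStack):
        return np.asarray(movie.frames, dtype=float)
    return np.asarray(movie, dtype=float)


def _check_order(order: int) -> None:
    if order < 2 or order > MAX_ORDER:
        raise ValueError(f"order must be in 2..{MAX_ORDER}, got {order}")


def auto_cumulant_image(movie: MovieStack | np.ndarray, order: int) -> CumulantImage:
    """Per-pixel zero-lag auto-cumulant image (oversampling 1)."""
    _check_order(order)
    frames = _frames(movie)
    T = frames.shape[0]
    if T < 100 * order:
        import warnings

        warnings.warn(f"only {T} frames for order {order}; recommend >= {100 * order}")
    xc = frames - frames.mean(axis=0)
    # central moment images m_k = E[x^k]
    moments = {1: np.zeros(frames.shape[1:])}
    p = xc.copy()
    for k in range(2, order + 1):
        p *= xc
        moments[k] = p.mean(axis=0)

    values = _cumulant_from_block_moments(order, lambda b: moments[len(b)])
    px = movie.meta.pixel_size if isinstance(movie, MovieStack) else None
    return CumulantImage(
        order=order,
        values=values,
        oversampling=1,
        distance_factors=np.ones_like(values),
        pixel_size_nm=px,
        provenance={"kind": "auto", "n_frames": T, "lags": "zero"},
    )


@lru_cache(maxsize=None)
def virtual_pixel_combination(order: int, a: int, b: int) -> tuple[tuple[int, int], ...]:
    """Offsets (dy, dx) of the n physical pixels for fine-lattice offset (a, b).

    Fine-lattice point (n*i + a, n*j + b) sits at camera coordinate
    (i + a/n, j + b/n); the chosen pixel multiset has offset sums
    sum(dy) = a, sum(dx) = b and minimizes the spread sum |r_k - rbar|^2
    (the spread is separable in y and x, so the floor/ceil split of a/n and
    b/n is a global optimum).  Ties are broken by pairing the sorted dy with
    the sorted dx, the lexicographically smallest sorted-coordinate multiset.
    """
    n = order
    if not (0 <= a < n and 0 <= b < n):
        raise ValueError("fine offsets must be in 0..order-1")
    dy = sorted([0] * (n - a) + [1] * a)
    dx = sorted([0] * (n - b) + [1] * b)
    return tuple(zip(dy, dx))


def _combination_spread(order: int, a: int, b: int) -> float:
    combo = np.array(virtual_pixel_combination(order, a, b), dtype=float)
    c = combo.mean(axis=0)
    return float(((combo - c) ** 2).sum())


def cross_cumulant_image(
    movie: MovieStack | np.ndarray,
    order: int,
    neighborhood_radius: int | None = None,
    psf_sigma_px: float | None = None,
) -> CumulantImage:
    """Cross-cumulant image on an order-fold oversampled virtual lattice.

    For each fine-lattice point one combination of ``order`` physical pixels
    whose centroid equals the point is selected (see
    :func:`virtual_pixel_combination`), and the joint cumulant of their time
    series is placed there.  The Gaussian distance factor
    exp(-sum_i |r_i - rbar|^2 / (2 sigma^2)) is recorded per lattice site;
    division by it (flattening) removes the lattice-periodic gain.

    Pixel borders are handled periodically (np.roll); the provenance records
    a 1-camera-pixel edge margin that downstream metrics should crop.
    """
    _check_order(order)
    frames = _frames(movie)
    T, H, W = frames.shape
    n = order
    radius = neighborhood_radius if neighborhood_radius is not None else max(1, math.ceil(n / 2))
    if radius < 1:
        raise ValueError("neighborhood_radius must be >= 1")
    if H < 2 * radius + 1 or W < 2 * radius + 1:
        raise ValueError("movie smaller than the pixel neighborhood")
    if psf_sigma_px is None:
        psf_sigma_px = movie.meta.psf_sigma_px if isinstance(movie, MovieStack) else 1.3

    xc = frames - frames.mean(axis=0)
    shifted: dict[tuple[int, int], np.ndarray] = {(0, 0): xc}

    def get_shifted(d: tuple[int, int]) -> np.ndarray:
        if d not in shifted:
            shifted[d] = np.roll(xc, shift=(-d[0], -d[1]), axis=(1, 2))
        return shifted[d]

    moment_cache: dict[tuple[tuple[int, int], ...], np.ndarray] = {}

    def multiset_moment(shifts: tuple[tuple[int, int], ...]) -> np.ndarray:
        key = tuple(sorted(shifts))
        m = moment_cache.get(key)
        if m is None:
            prod_ = get_shifted(key[0]).copy()
            for d in key[1:]:
                prod_ *= get_shifted(d)
            m = prod_.mean(axis=0)
            moment_cache[key] = m
        return m

    fine = np.empty((n * H, n * W))
    dfac = np.empty((n * H, n * W))
    sigma2 = psf_sigma_px**2
    for a, b in product(range(n), repeat=2):
        combo = virtual_pixel_combination(n, a, b)
        val = _cumulant_from_block_moments(
            n, lambda blk, combo=combo: multiset_moment(tuple(combo[i] for i in blk))
        )
        fine[a::n, b::n] = val
        dfac[a::n, b::n] = math.exp(-_combination_spread(n, a, b) / (2.0 * sigma2))

    meta = movie.meta if isinstance(movie, MovieStack) else None
    return CumulantImage(
        order=n,
        values=fine,
        oversampling=n,
        distance_factors=dfac,
        pixel_size_nm=(meta.pixel_size / n) if meta is not None else None,
        provenance={
            "kind": "cross",
            "n_frames": T,
            "lags": "zero",
            "neighborhood_radius": radius,
            "psf_sigma_px": psf_sigma_px,
            "edge_margin_camera_px": 1,
        },
    )


# ----------------------------------------------------------------------------
# Subsequences and drift correction


def split_subsequences(movie: MovieStack | np.ndarray | int, block_length: int = 1000) -> SubsequencePlan:
    """Split T frames into consecutive blocks of ``block_length``.

    floor(T/block_length) full blocks; if T < block_length a single block of
    length T; remainder frames beyond the last full block are dropped (equal
    variance blocks for drift correction and jackknife).
    """
    if isinstance(movie, int):
        T = movie
    else:
        T = _frames(movie).shape[0]
    if T < 1:
        raise ValueError("need at least one frame")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if T < block_length:
        return SubsequencePlan(blocks=((0, T),), block_length=T, n_frames=T)
    k = T // block_length
    blocks = tuple((i * block_length, (i + 1) * block_length) for i in range(k))
    return SubsequencePlan(blocks=blocks, block_length=block_length, n_frames=T)


def estimate_block_shifts(images: Sequence[CumulantImage | np.ndarray]) -> np.ndarray:
    """Per-block (dy, dx) shifts (lattice px) registering each image to the first."""
    arrs = [im.values if isinstance(im, CumulantImage) else np.asarray(im, float) for im in images]
    ref = arrs[0]
    shifts = [np.zeros(2)]
    for im in arrs[1:]:
        sh, _err, _ph = phase_cross_correlation(ref, im, upsample_factor=20, normalization=None)
        shifts.append(np.asarray(sh, dtype=float))
    return np.array(shifts)


def combine_subsequence_cumulants(
    images: Sequence[CumulantImage],
    shifts: np.ndarray | None = None,
) -> CumulantImage:
    """Register per-subsequence cumulant images to the first and average.

    ``shifts`` (blocks x 2, lattice px, +shift moves a block onto the
    reference) may be supplied externally — e.g. estimated on the order-2
    images and rescaled — otherwise they are estimated here by
    cross-correlation.  Applied shifts are stored in provenance.
    """
    if len(images) == 0:
        raise ValueError("need at least one cumulant image")
    first = images[0]
    for im in images[1:]:
        if im.order != first.order or im.values.shape != first.values.shape:
            raise ValueError("all images must share order and lattice")
    if len(images) == 1:
        out = first.copy_with(first.values.copy())
        out.provenance["block_shifts"] = [[0.0, 0.0]]
        out.provenance["n_blocks"] = 1
        return out
    if shifts is None:
        shifts = estimate_block_shifts(images)
    shifts = np.asarray(shifts, dtype=float)
    acc = np.zeros_like(first.values)
    for im, sh in zip(images, shifts):
        if np.allclose(sh, 0.0):
            acc += im.values
        else:
            acc += ndi.shift(im.values, sh, order=1, mode="nearest")
    out = first.copy_with(acc / len(images))
    out.provenance["block_shifts"] = shifts.tolist()
    out.provenance["n_blocks"] = len(images)
    out.provenance["n_frames"] = int(sum(im.provenance.get("n_frames", 0) for im in images))
    return out
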