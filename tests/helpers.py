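"""Shared test oracles, independent of the package implementation."""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import curve_fit
from sympy.utilities.iterables import multiset_partitions


def brute_force_joint_cumulant(series: list[np.ndarray]) -> float:
    """Joint cumulant by exhaustive partition enumeration on *raw* moments.

    Independent oracle: partitions come from sympy, moments are uncentered
    (the partition sum over raw moments equals the central-moment form as an
    algebraic identity), and singleton blocks are kept.
    """
    xs = [np.asarray(s, dtype=float) for s in series]
    n = len(xs)
    if n == 1:
        return float(xs[0].mean())
    total = 0.0
    for part in multiset_partitions(list(range(n))):
        coeff = (-1.0) ** (len(part) - 1) * math.factorial(len(part) - 1)
        term = 1.0
        for block in part:
            prod = np.ones_like(xs[0])
            for i in block:
                prod = prod * xs[i]
            term *= prod.mean()
        total += coeff * term
    return float(total)


def fit_gaussian_fwhm_2d(img: np.ndarray) -> float:
    """FWHM (px) of a 2-D Gaussian + offset fitted to an image."""
    H, W = img.shape
    yy, xx = np.mgrid[:H, :W].astype(float)

    def model(_, amp, x0, y0, sigma, off):
        return (amp * np.exp(-(((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma**2))) + off).ravel()

    i0 = np.unravel_index(np.argmax(np.abs(img)), img.shape)
    p0 = [img[i0], i0[1], i0[0], 2.0, 0.0]
    popt, _ = curve_fit(model, None, img.ravel(), p0=p0, maxfev=20000)
    return 2.0 * math.sqrt(2.0 * math.log(2.0)) * abs(popt[3])


def bernoulli_cumulants(rho: float) -> tuple[float, float, float]:
    """Closed-form kappa_2..kappa_4 of a Bernoulli(rho) variable."""
    k2 = rho * (1 - rho)
    k3 = rho * (1 - rho) * (1 - 2 * rho)
    k4 = rho * (1 - rho) * (1 - 6 * rho + 6 * rho**2)
    return k2, k3, k4
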