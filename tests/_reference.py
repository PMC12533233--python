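"""Independent brute-force oracles used only by the test suite.

Everything here deliberately avoids the package's computational paths:
the wavelet transform is a naive time-domain convolution (the package uses
FFTs), smoothing is explicit kernel summation (the package uses
scipy.ndimage), and the Mann-Whitney null is full enumeration over
labelings (the package uses a counting recurrence).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def reference_cwt(x: np.ndarray, dt: float, scales: np.ndarray, omega0: float = 6.0) -> np.ndarray:
    """Time-domain Morlet CWT of the mean-removed, zero-extended signal."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = x.size
    out = np.empty((scales.size, n), complex)
    for si, s in enumerate(scales):
        half = int(math.ceil(5.0 * s / dt))  # Gaussian support
        k = np.arange(-half, half + 1)
        eta = k * dt / s
        psi = math.pi**-0.25 * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)
        # W[n] = sum_m x[m] sqrt(dt/s) psi*((m-n) dt/s), i.e. convolution of x
        # with sqrt(dt/s) psi(u dt/s) since psi*(-eta) = psi(eta)
        kernel = psi * math.sqrt(dt / s)
        conv = np.convolve(x, kernel, mode="full")
        out[si] = conv[half : half + n]
    return out


def _smooth_time_reference(field: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    out = np.empty_like(field)
    for i, s in enumerate(scales):
        sigma = s / (math.sqrt(2.0) * dt)
        if sigma < 1e-8:
            out[i] = field[i]
            continue
        half = max(1, int(round(4.0 * sigma)))
        k = np.arange(-half, half + 1)
        kern = np.exp(-0.5 * (k / sigma) ** 2)
        kern /= kern.sum()
        padded = np.pad(field[i], half, mode="symmetric")
        out[i] = np.convolve(padded, kern, mode="valid")
    return out


def _smooth_scale_reference(field: np.ndarray, scales: np.ndarray) -> np.ndarray:
    if scales.size < 2:
        return field
    dj = math.log2(scales[1] / scales[0])
    width = int(round(0.6 / dj))
    if width % 2 == 0:
        width += 1
    if width <= 1:
        return field
    half = width // 2
    padded = np.pad(field, ((half, half), (0, 0)), mode="edge")
    out = np.empty_like(field)
    for t in range(field.shape[1]):
        out[:, t] = np.convolve(padded[:, t], np.ones(width) / width, mode="valid")
    return out


def reference_smooth(field: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    return _smooth_scale_reference(_smooth_time_reference(field, scales, dt), scales)


def reference_wtc_r2(
    a: np.ndarray, b: np.ndarray, dt: float, scales: np.ndarray, omega0: float = 6.0
) -> np.ndarray:
    """Squared wavelet coherence computed entirely with the brute-force path."""
    wa = reference_cwt(a, dt, scales, omega0)
    wb = reference_cwt(b, dt, scales, omega0)
    inv_s = 1.0 / scales[:, None]
    sa = reference_smooth(np.abs(wa) ** 2 * inv_s, scales, dt)
    sb = reference_smooth(np.abs(wb) ** 2 * inv_s, scales, dt)
    wab = wa * np.conj(wb)
    sre = reference_smooth(wab.real * inv_s, scales, dt)
    sim = reference_smooth(wab.imag * inv_s, scales, dt)
    return (sre**2 + sim**2) / (sa * sb)


def enumerate_mann_whitney(
    a: np.ndarray, b: np.ndarray, alternative: str = "greater"
) -> tuple[float, float]:
    """Exact Mann-Whitney by enumerating all C(m+n, m) group labelings."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m, n = a.size, b.size
    pooled = np.concatenate([a, b])

    def u_of(idx_a: tuple[int, ...]) -> float:
        mask = np.zeros(m + n, bool)
        mask[list(idx_a)] = True
        aa, bb = pooled[mask], pooled[~mask]
        return float(np.sum(aa[:, None] > bb[None, :]) + 0.5 * np.sum(aa[:, None] == bb[None, :]))

    u_obs = u_of(tuple(range(m)))
    us = np.array([u_of(c) for c in itertools.combinations(range(m + n), m)])
    p_greater = np.mean(us >= u_obs - 1e-12)
    if alternative == "greater":
        return u_obs, float(p_greater)
    p_less = np.mean(us <= u_obs + 1e-12)
    return u_obs, float(min(1.0, 2.0 * min(p_greater, p_less)))


def brute_cliffs_delta(a: np.ndarray, b: np.ndarray) -> float:
    total = 0
    for x in a:
        for y in b:
            total += int(x > y) - int(x < y)
    return total / (len(a) * len(b))


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q
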