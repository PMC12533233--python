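"""Analytic Morlet continuous wavelet transform and wavelet coherence.

The transform follows the standard dyadic-grid construction: a mean-removed,
zero-padded signal is convolved (via FFT) with scaled copies of the analytic
Morlet wavelet ``psi(eta) = pi**-0.25 * exp(1j*omega0*eta) * exp(-eta**2/2)``.
Wavelet coherence is the smoothed, normalised magnitude-squared cross
spectrum of two transforms — a local correlation coefficient in [0, 1] at
every time and scale.  Smoothing uses the conventional pair of operators:
a Gaussian in time whose width tracks the wavelet scale, and a boxcar over
0.6 octaves in scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

__all__ = [
    "WaveletParams",
    "CWTResult",
    "WTCResult",
    "fourier_factor",
    "morlet_cwt",
    "smooth_field",
    "wtc",
    "cone_of_influence",
    "phase_arrow_mask",
]

#: Decorrelation length of the Morlet wavelet in octaves; width of the
#: scale-axis boxcar used when smoothing coherence fields.
SCALE_DECORRELATION_OCTAVES = 0.6

#: Tolerated floating-point excursion of coherence above 1 before clipping.
R2_TOLERANCE = 1e-9


def fourier_factor(omega0: float) -> float:
    """Conversion from wavelet scale to equivalent Fourier period.

    ``period = fourier_factor(omega0) * scale``; approximately 1.0330 for
    the standard choice ``omega0 = 6``.
    """
    return 4.0 * math.pi / (omega0 + math.sqrt(2.0 + omega0**2))


@dataclass(frozen=True)
class WaveletParams:
    """Morlet CWT configuration on a dyadic scale grid ``s_j = s0 * 2**(j*dj)``.

    Parameters
    ----------
    omega0
        Dimensionless central frequency of the Morlet wavelet.
    dj
        Scale resolution as a fraction of an octave.
    s0
        Smallest scale in seconds; at least the sampling interval.
    n_scales
        Number of scales.
    dt
        Sampling interval in seconds.
    """

    omega0: float = 6.0
    dj: float = 1.0 / 12.0
    s0: float = 360.0
    n_scales: int = 97
    dt: float = 180.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.omega0) and self.omega0 > 0):
            raise ValueError(f"omega0 must be positive, got {self.omega0}")
        if not (np.isfinite(self.dj) and self.dj > 0):
            raise ValueError(f"dj must be positive, got {self.dj}")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.s0 < self.dt:
            raise ValueError(f"s0 ({self.s0}) must be >= dt ({self.dt})")
        if self.n_scales < 2:
            raise ValueError(f"n_scales must be >= 2, got {self.n_scales}")

    @classmethod
    def for_signal(
        cls,
        n_times: int,
        dt: float,
        *,
        omega0: float = 6.0,
        dj: float = 1.0 / 12.0,
        s0: float | None = None,
        n_scales: int | None = None,
    ) -> "WaveletParams":
        """Default dyadic grid for a series of ``n_times`` samples.

        ``s0 = 2*dt`` and the largest scale reaches the series duration:
        ``n_scales = floor(log2(n_times*dt/s0)/dj) + 1``.
        """
        if n_times < 4:
            raise ValueError("need at least 4 samples to build a scale grid")
        if s0 is None:
            s0 = 2.0 * dt
        if n_scales is None:
            n_scales = int(math.floor(math.log2(n_times * dt / s0) / dj)) + 1
        return cls(omega0=omega0, dj=dj, s0=s0, n_scales=n_scales, dt=dt)

    @property
    def scales(self) -> np.ndarray:
        return self.s0 * 2.0 ** (np.arange(self.n_scales) * self.dj)

    @property
    def freqs(self) -> np.ndarray:
        """Equivalent Fourier frequencies (Hz), decreasing with scale."""
        return 1.0 / (fourier_factor(self.omega0) * self.scales)


@dataclass
class CWTResult:
    """Complex Morlet coefficients on a scale x time grid."""

    coeffs: np.ndarray          # complex, (n_scales, n_times)
    scales: np.ndarray          # s, increasing
    freqs: np.ndarray           # Hz, decreasing
    coi_period: np.ndarray      # s, per time sample
    dt: float
    params: WaveletParams = field(repr=False, default=None)


@dataclass
class WTCResult:
    """Magnitude-squared wavelet coherence with cross-wavelet phase."""

    r2: np.ndarray              # (n_scales, n_times), in [0, 1]
    phase: np.ndarray           # rad, in (-pi, pi]
    scales: np.ndarray
    freqs: np.ndarray
    coi_period: np.ndarray
    dt: float
    coi_mask: np.ndarray        # True where the pixel's period <= coi_period
    params: WaveletParams = field(repr=False, default=None)


def _validate_signal(signal: np.ndarray) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"signal must be 1-D, got shape {x.shape}")
    if x.size < 4:
        raise ValueError(f"signal must have >= 4 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return x


def morlet_cwt(signal: np.ndarray, dt: float, params: WaveletParams | None = None) -> CWTResult:
    """Continuous wavelet transform with the analytic Morlet wavelet.

    The signal mean is removed and the series zero-padded to the next power
    of two before the FFT-domain convolution; padding is discarded from the
    returned coefficient matrix.  Coefficients are normalised so that every
    scaled wavelet has unit energy.
    """
    x = _validate_signal(signal)
    n = x.size
    if params is None:
        params = WaveletParams.for_signal(n, dt)
    elif abs(params.dt - dt) > 1e-9:
        raise ValueError(f"params.dt ({params.dt}) disagrees with dt ({dt})")

    x = x - x.mean()
    # pad beyond the series so large-scale wavelets cannot wrap around
    n_pad = 1 << (int(math.floor(math.log2(n) + 0.4999)) + 1)
    xh = np.fft.fft(x, n_pad)
    # angular frequencies of the padded grid
    omega = 2.0 * math.pi * np.fft.fftfreq(n_pad, d=dt)

    scales = params.scales
    arg = scales[:, None] * omega[None, :] - params.omega0
    # analytic wavelet: support on positive frequencies only
    psi_hat = (
        math.pi ** -0.25
        * np.sqrt(2.0 * math.pi * scales[:, None] / dt)
        * np.exp(-0.5 * arg**2)
        * (omega[None, :] > 0)
    )
    coeffs = np.fft.ifft(xh[None, :] * psi_hat, axis=1)[:, :n]

    coi = cone_of_influence(n, dt, params)
    return CWTResult(
        coeffs=coeffs,
        scales=scales,
        freqs=params.freqs,
        coi_period=coi,
        dt=dt,
        params=params,
    )


def smooth_field(field: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Coherence smoothing operator on a scale x time field.

    Per-scale Gaussian smoothing in time (sd ``s / (sqrt(2) * dt)`` samples,
    tracking the wavelet's own time support) followed by a boxcar across 0.6
    octaves in scale.  Both kernels are normalised, so a constant field is
    preserved and non-negative input stays non-negative.
    """
    field = np.asarray(field, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if field.ndim != 2 or field.shape[0] != scales.size:
        raise ValueError(
            f"field shape {field.shape} inconsistent with {scales.size} scales"
        )
    out = np.empty_like(field)
    for i, s in enumerate(scales):
        sigma = s / (math.sqrt(2.0) * dt)
        if sigma < 1e-8:
            out[i] = field[i]
        else:
            out[i] = gaussian_filter1d(field[i], sigma, mode="reflect")
    if scales.size > 1:
        dj = math.log2(scales[1] / scales[0])
        width = int(round(SCALE_DECORRELATION_OCTAVES / dj))
        if width % 2 == 0:
            width += 1
        if width > 1:
            out = uniform_filter1d(out, size=width, axis=0, mode="nearest")
    return out


def wtc(
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    dt: float,
    params: WaveletParams | None = None,
) -> WTCResult:
    """Magnitude-squared wavelet coherence of two equally sampled signals.

    ``R2(s,t) = |S(W_ab/s)|**2 / (S(|W_a|**2/s) * S(|W_b|**2/s))`` with
    ``W_ab = W_a * conj(W_b)`` and ``S`` the :func:`smooth_field` operator.
    The phase matrix is the argument of the smoothed cross spectrum: positive
    values mean ``sig_a`` leads ``sig_b``.

    Raises
    ------
    ValueError
        If the signals have different lengths — callers must align series
        before comparing them.
    RuntimeError
        If coherence exceeds 1 by more than a float-noise tolerance, which
        indicates a broken smoothing kernel rather than data trouble.
    """
    a = _validate_signal(sig_a)
    b = _validate_signal(sig_b)
    if a.size != b.size:
        raise ValueError(
            f"signals must have equal length (got {a.size} and {b.size}); "
            "align them first"
        )
    if params is None:
        params = WaveletParams.for_signal(a.size, dt)

    cwt_a = morlet_cwt(a, dt, params)
    cwt_b = morlet_cwt(b, dt, params)
    scales = cwt_a.scales
    inv_s = 1.0 / scales[:, None]

    wab = cwt_a.coeffs * np.conj(cwt_b.coeffs)
    s_a = smooth_field(np.abs(cwt_a.coeffs) ** 2 * inv_s, scales, dt)
    s_b = smooth_field(np.abs(cwt_b.coeffs) ** 2 * inv_s, scales, dt)
    s_ab_re = smooth_field(wab.real * inv_s, scales, dt)
    s_ab_im = smooth_field(wab.imag * inv_s, scales, dt)

    denom = s_a * s_b
    num = s_ab_re**2 + s_ab_im**2
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, num / denom, 0.0)
    excess = np.nanmax(r2) - 1.0
    if excess > R2_TOLERANCE:
        raise RuntimeError(
            f"coherence exceeds 1 by {excess:.3e}: smoothing is inconsistent"
        )
    r2 = np.clip(r2, 0.0, 1.0)
    phase = np.arctan2(s_ab_im, s_ab_re)

    period = fourier_factor(params.omega0) * scales
    coi_mask = period[:, None] <= cwt_a.coi_period[None, :]
    return WTCResult(
        r2=r2,
        phase=phase,
        scales=scales,
        freqs=cwt_a.freqs,
        coi_period=cwt_a.coi_period,
        dt=dt,
        coi_mask=coi_mask,
        params=params,
    )


def cone_of_influence(n_times: int, dt: float, params: WaveletParams) -> np.ndarray:
    """Per-time maximum reliable period (s) under zero-padding edge effects.

    Morlet e-folding construction: ``coi(t) = FF * sqrt(2) * dt *
    min(t + 0.5, n - 0.5 - t)``, symmetric about the series midpoint.
    Pixels whose equivalent Fourier period exceeds this bound sit in the
    region where boundary artefacts dominate.
    """
    if n_times < 2:
        raise ValueError(f"n_times must be >= 2, got {n_times}")
    idx = np.arange(n_times, dtype=float)
    ff = fourier_factor(params.omega0)
    return ff * math.sqrt(2.0) * dt * np.minimum(idx + 0.5, n_times - 0.5 - idx)


def phase_arrow_mask(result: WTCResult, threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of pixels where phase arrows should be drawn.

    Arrows are conventionally displayed only where squared coherence exceeds
    a display threshold (0.5 by default) so that phase estimates from
    incoherent pixels are not over-interpreted.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return result.r2 > threshold
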