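"""Coupled-oscillator generator for simulated circumnutating plant dyads.

Each plant is modelled as a self-sustained phase oscillator: it keeps its
own nutation rhythm and adjusts it through weak interaction with its
partner.  Phases follow the stochastic Adler/Kuramoto pair

    dphi_i = [omega_i + K_i * sin(phi_j - phi_i - Delta_i)] dt
             + sigma_i * sqrt(dt) * xi,

integrated by Euler-Maruyama on the sampling grid (an internal substep
factor is available).  The tendril tip traces a circle of radius A in the
horizontal (x, z) plane with slow linear vertical growth and additive
Gaussian measurement noise:

    x = A cos(phi) + eps,   z = A sin(phi) + eps,   y = g*t + eps.

Defaults emulate the study conditions of the pea-plant intertwining
experiment this package analyses: frames every 180 s, a base nutation
period of 8000 s (~0.125 mHz), series of 559 frames (~28 h of movement),
and ~24% relative spread of frequency and duration across dyads.  Coupling
strength and phase-noise defaults put real dyads in the weak-coupling
phase-locking regime while leaving independently generated plants free to
drift apart — the contrast the pseudo-dyad null is built to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .trajectory import DyadRecord, TrajectorySeries

__all__ = [
    "OscillatorParams",
    "simulate_coupled_dyad",
    "simulate_population",
    "make_pseudo_dyads",
]


@dataclass(frozen=True)
class OscillatorParams:
    """Parameters of one plant's phase-oscillator model.

    Attributes
    ----------
    omega
        Natural angular frequency (rad/s).  Default ``2*pi/8000`` —
        a nutation period of 8000 s.
    coupling_k
        Coupling gain K (rad/s) toward the partner's phase.
    phase_lag
        Preferred phase offset Delta (rad) relative to the partner.
    sigma_phase
        Phase-diffusion intensity (rad/sqrt(s)).
    amplitude
        Mean nutation radius (mm).
    sigma_obs
        Additive measurement-noise sd (mm), emulating tracking error.
    growth_rate
        Vertical drift (mm/s).
    dt
        Sampling interval (s); 180 s = one frame every 3 min.
    n_samples
        Series length in frames.
    onset_index
        First frame of analysable movement.
    seed
        RNG seed carried for config serialisation; the simulation
        functions take an explicit seed that takes precedence.
    """

    omega: float = 2.0 * math.pi / 8000.0
    coupling_k: float = 4.0e-4
    phase_lag: float = 0.0
    sigma_phase: float = 8.0e-3
    amplitude: float = 25.0
    sigma_obs: float = 1.0
    growth_rate: float = 1.3e-4
    dt: float = 180.0
    n_samples: int = 559
    onset_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "omega",
            "coupling_k",
            "phase_lag",
            "sigma_phase",
            "amplitude",
            "sigma_obs",
            "growth_rate",
            "dt",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite, got {getattr(self, name)}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.coupling_k < 0:
            raise ValueError(f"coupling_k must be >= 0, got {self.coupling_k}")
        if self.sigma_phase < 0:
            raise ValueError(f"sigma_phase must be >= 0, got {self.sigma_phase}")
        if self.sigma_obs < 0:
            raise ValueError(f"sigma_obs must be >= 0, got {self.sigma_obs}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if not (0 <= self.onset_index < self.n_samples):
            raise ValueError(
                f"onset_index {self.onset_index} outside [0, {self.n_samples})"
            )


def simulate_coupled_dyad(
    params_handler: OscillatorParams,
    params_grasper: OscillatorParams,
    seed: int,
    *,
    dyad_id: str = "sim",
    substeps: int = 1,
    initial_phases: tuple[float, float] | None = None,
) -> tuple[TrajectorySeries, TrajectorySeries]:
    """Simulate one handler/grasper pair of weakly coupled oscillators.

    Euler-Maruyama integration at step ``dt / substeps``; positions are read
    off at the sampling grid.  Bit-reproducible for a fixed seed.  When
    ``initial_phases`` is None both initial phases are drawn uniformly on
    [0, 2*pi).
    """
    ph, pg = params_handler, params_grasper
    if abs(ph.dt - pg.dt) > 1e-12:
        raise ValueError(f"mismatched dt: {ph.dt} vs {pg.dt}")
    if ph.n_samples != pg.n_samples:
        raise ValueError(
            f"dyad members must share n_samples ({ph.n_samples} vs {pg.n_samples})"
        )
    if substeps < 1:
        raise ValueError(f"substeps must be >= 1, got {substeps}")

    rng = np.random.default_rng(seed)
    n = ph.n_samples
    h = ph.dt / substeps
    sqrt_h = math.sqrt(h)

    if initial_phases is None:
        phi_h, phi_g = rng.uniform(0.0, 2.0 * math.pi, size=2)
    else:
        phi_h, phi_g = (float(v) for v in initial_phases)

    phases = np.empty((2, n))
    phases[:, 0] = (phi_h, phi_g)
    for i in range(1, n):
        for _ in range(substeps):
            xi_h, xi_g = rng.standard_normal(2)
            dphi_h = (
                ph.omega + ph.coupling_k * math.sin(phi_g - phi_h - ph.phase_lag)
            ) * h + ph.sigma_phase * sqrt_h * xi_h
            dphi_g = (
                pg.omega + pg.coupling_k * math.sin(phi_h - phi_g - pg.phase_lag)
            ) * h + pg.sigma_phase * sqrt_h * xi_g
            phi_h += dphi_h
            phi_g += dphi_g
        phases[:, i] = (phi_h, phi_g)

    t = np.arange(n) * ph.dt
    out = []
    for row, p, role in ((0, ph, "handler"), (1, pg, "grasper")):
        phi = phases[row]
        noise = rng.standard_normal((3, n)) * p.sigma_obs
        out.append(
            TrajectorySeries(
                plant_id=f"{dyad_id}-{role}",
                dyad_id=dyad_id,
                role=role,  # type: ignore[arg-type]
                dt=p.dt,
                onset_index=p.onset_index,
                x=p.amplitude * np.cos(phi) + noise[0],
                y=p.growth_rate * t + noise[1],
                z=p.amplitude * np.sin(phi) + noise[2],
            )
        )
    return out[0], out[1]


def simulate_population(
    n_dyads: int,
    base: tuple[OscillatorParams, OscillatorParams] | None = None,
    heterogeneity: float = 0.24,
    seed: int = 0,
) -> list[DyadRecord]:
    """Simulate a population of real dyads with between-dyad variability.

    Each plant's natural frequency and each dyad's series length are drawn
    around the base values with relative sd ``heterogeneity`` (default 0.24,
    the relative spread of movement durations in the study population this
    generator emulates).  Members of a dyad share acquisition timing:
    identical length and onset, as for simultaneously recorded plants.
    """
    if n_dyads < 2:
        raise ValueError(f"need >= 2 dyads, got {n_dyads}")
    if heterogeneity < 0:
        raise ValueError(f"heterogeneity must be >= 0, got {heterogeneity}")
    if base is None:
        base = (OscillatorParams(), OscillatorParams())
    bh, bg = base
    if abs(bh.dt - bg.dt) > 1e-12:
        raise ValueError(f"mismatched dt in base parameters: {bh.dt} vs {bg.dt}")

    root = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    dyad_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_dyads + 1)[1:]]

    records = []
    for d in range(n_dyads):
        # per-dyad length and onset, shared by both members (simultaneous
        # acquisition); per-plant frequency mismatch drives the Adler dynamics
        length = max(64, int(round(bh.n_samples * (1.0 + heterogeneity * draw_rng.standard_normal()))))
        onset = int(draw_rng.integers(0, max(1, length // 10)))
        factors = 1.0 + heterogeneity * draw_rng.standard_normal(2)
        factors = np.clip(factors, 0.05, None)
        p_handler = replace(
            bh, omega=bh.omega * factors[0], n_samples=length, onset_index=onset
        )
        p_grasper = replace(
            bg, omega=bg.omega * factors[1], n_samples=length, onset_index=onset
        )
        handler, grasper = simulate_coupled_dyad(
            p_handler, p_grasper, seed=dyad_seeds[d], dyad_id=f"dyad{d + 1:02d}"
        )
        records.append(DyadRecord(handler=handler, grasper=grasper, kind="real"))
    return records


def _random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform derangement of range(n) by rejection sampling."""
    if n < 2:
        raise ValueError("derangements require n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def make_pseudo_dyads(
    real_dyads: list[DyadRecord], seed: int = 0
) -> list[DyadRecord]:
    """Shuffle real dyads into artificial pseudo dyads.

    Pseudo dyad ``i`` keeps the handler of real dyad ``i`` and takes the
    grasper of real dyad ``sigma(i)``, where ``sigma`` is a uniformly random
    derangement — no pseudo dyad ever reunites the two plants of a real
    dyad.  Outputs are marked ``kind='pseudo'`` and left unaligned; apply
    :func:`plantsync.trajectory.align_dyad` before analysis.
    """
    n = len(real_dyads)
    if n < 2:
        raise ValueError(f"need >= 2 real dyads to build pseudo dyads, got {n}")
    rng = np.random.default_rng(seed)
    perm = _random_derangement(n, rng)
    return [
        DyadRecord(
            handler=real_dyads[i].handler,
            grasper=real_dyads[int(perm[i])].grasper,
            kind="pseudo",
            aligned=False,
        )
        for i in range(n)
    ]
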