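"""Declarative time-dependent drives and Ornstein-Uhlenbeck noise.

Both simulation scales (spiking network and mean-field) consume the same
stimulus descriptions, so state-comparison protocols are guaranteed to feed
identical drives to both backends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["StimulusSpec", "OUNoiseSpec", "drive_rate", "sample_ou"]

logger = logging.getLogger(__name__)

_KINDS = ("constant", "rectangular", "oscillatory", "split_gaussian", "poisson_fixed_rate")


@dataclass(frozen=True)
class StimulusSpec:
    """A time-dependent firing-rate drive.

    kind:
        constant            rate = baseline + A for all t
        rectangular         baseline + A on [t0, t0 + width)
        oscillatory         baseline + A (1 - cos(2 pi f t)) / 2  (raised
                            cosine, so the rate oscillates between baseline
                            and baseline + A and never goes negative)
        split_gaussian      two-sided Gaussian pulse peaking at t0 with left
                            width sigma_l and right width sigma_r; the peak
                            amplitude equals A (amplitude convention)
        poisson_fixed_rate  alias of constant, for single-spike-train drives
    """

    kind: str
    A: float = 0.0            # Hz
    baseline: float = 0.0     # Hz
    t0: float = 0.0           # ms
    width: float = 0.0        # ms (rectangular)
    frequency: float = 1.0    # Hz (oscillatory)
    sigma_l: float = 1.0      # ms (split_gaussian left std)
    sigma_r: float = 1.0      # ms (split_gaussian right std)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}; have {_KINDS}")
        if self.A < 0:
            raise ValueError("amplitude A must be >= 0")
        if self.kind == "split_gaussian" and (self.sigma_l <= 0 or self.sigma_r <= 0):
            raise ValueError("split_gaussian widths must be positive")


@dataclass(frozen=True)
class OUNoiseSpec:
    """Ornstein-Uhlenbeck noise process.

    target selects where the noise enters: as a membrane current (pA) for
    single cells, or as an excitatory/inhibitory static conductance (nS) for
    the mean-field / network extension.
    """

    mean: float               # pA or nS
    sd: float                 # pA or nS
    tau_corr: float           # ms
    target: str = "current"   # current | conductance_e | conductance_i

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.tau_corr <= 0:
            raise ValueError("correlation time must be positive")
        if self.target not in ("current", "conductance_e", "conductance_i"):
            raise ValueError(f"unknown OU target {self.target!r}")


def drive_rate(spec: StimulusSpec, t):
    """Drive rate in Hz at time(s) ``t`` (ms); vectorized over ``t``.

    Rates are clipped at zero (with a log notice) if a parameterization would
    dip below it.
    """
    t = np.asarray(t, dtype=float)
    if spec.kind in ("constant", "poisson_fixed_rate"):
        out = np.full_like(t, spec.baseline + spec.A)
    elif spec.kind == "rectangular":
        out = spec.baseline + spec.A * ((t >= spec.t0) & (t < spec.t0 + spec.width))
    elif spec.kind == "oscillatory":
        out = spec.baseline + spec.A * (1.0 - np.cos(2e-3 * np.pi * spec.frequency * t)) / 2.0
    elif spec.kind == "split_gaussian":
        dt = t - spec.t0
        sigma = np.where(dt < 0, spec.sigma_l, spec.sigma_r)
        out = spec.baseline + spec.A * np.exp(-0.5 * (dt / sigma) ** 2)
    else:  # pragma: no cover - guarded by StimulusSpec
        raise ValueError(f"unknown stimulus kind {spec.kind!r}")
    if np.any(out < 0):
        logger.warning("drive_rate clipped negative rates to 0 for %s", spec)
        out = np.clip(out, 0.0, None)
    return out if out.ndim else float(out)


def sample_ou(spec: OUNoiseSpec, duration: float, dt: float, seed=None) -> np.ndarray:
    """Exact-discretization OU path over [0, duration) sampled every ``dt`` ms.

    The path starts from the stationary distribution, so its marginal moments
    are (mean, sd) at every sample.  Returns ``ceil(duration/dt)`` samples.
    """
    if dt >= spec.tau_corr:
        raise ValueError("dt must be smaller than the correlation time")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration / dt))
    rho = np.exp(-dt / spec.tau_corr)
    x = np.empty(n)
    if spec.sd == 0.0:
        x[:] = spec.mean
        return x
    innov_sd = spec.sd * np.sqrt(1.0 - rho**2)
    # AR(1) recursion x_i = rho x_{i-1} + eps_i run through an IIR filter.
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, spec.sd)  # stationary start
    from scipy.signal import lfilter

    x[:] = spec.mean + lfilter([1.0], [1.0, -rho], eps)
    return x
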