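"""Temporal-to-spatial linkage: delayed low-pass filter, convolution, decimation.

The filter is a gamma-variate,

    h(t) = (t - delta)^a * exp(-(t - delta) / b) * heaviside(t - delta),

which has a single peak at t = delta + a*b. A temporal source is circularly
convolved with the sampled filter and integer-decimated by a factor ``q`` to
produce one column of spatial mixing coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TransferConfig",
    "sample_transfer_function",
    "apply_transfer",
    "perturb_transfer",
    "standardize",
]

_PERTURB_MODES = ("shape-fixed-peak", "peak-shift-fixed-decay", "delay-shift")


def standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Return ``x`` with zero mean and unit variance along ``axis``.

    Constant slices raise ValueError; callers that must tolerate them should
    check variance first.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant vector")
    return (x - mu) / sd


@dataclass(frozen=True)
class TransferConfig:
    """Parameters of the temporal-to-spatial transfer.

    Attributes
    ----------
    a : float
        Shape exponent (> 0).
    b : float
        Decay scale in seconds (> 0).
    delta : float
        Onset delay in seconds (>= 0).
    dt : float
        Sample interval of the temporal grid in seconds.
    q : int
        Integer decimation factor (>= 1); must divide the signal length.
    conv_mode : str
        ``"circulant"`` (circular convolution) or ``"linear-zeropad"``.
    normalize : str
        Filter normalization: ``"peak-one"``, ``"unit-sum"`` or ``"none"``.
    identity : bool
        If True the filter is a unit impulse (bypasses the gamma-variate);
        useful for testing the decimation path in isolation.
    """

    a: float = 6.0
    b: float = 1.0
    delta: float = 2.0
    dt: float = 0.2
    q: int = 16
    conv_mode: str = "circulant"
    normalize: str = "peak-one"
    identity: bool = False

    def __post_init__(self) -> None:
        if not self.identity:
            if self.a <= 0:
                raise ValueError(f"shape exponent a must be > 0, got {self.a}")
            if self.b <= 0:
                raise ValueError(f"decay scale b must be > 0, got {self.b}")
            if self.delta < 0:
                raise ValueError(f"delay delta must be >= 0, got {self.delta}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if int(self.q) != self.q or self.q < 1:
            raise ValueError(f"decimation factor q must be a positive integer, got {self.q}")
        if self.conv_mode not in ("circulant", "linear-zeropad"):
            raise ValueError(f"unknown conv_mode {self.conv_mode!r}")
        if self.normalize not in ("peak-one", "unit-sum", "none"):
            raise ValueError(f"unknown normalize {self.normalize!r}")

    @property
    def peak_time(self) -> float:
        """Analytic peak location delta + a*b."""
        return self.delta + self.a * self.b

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "delta": self.delta,
            "dt": self.dt,
            "q": int(self.q),
            "conv_mode": self.conv_mode,
            "normalize": self.normalize,
            "identity": self.identity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransferConfig":
        return cls(**d)


def sample_transfer_function(cfg: TransferConfig, n_samples: int) -> np.ndarray:
    """Evaluate the filter on the grid t = 0, dt, ..., (n_samples-1)*dt."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if cfg.identity:
        h = np.zeros(n_samples)
        h[0] = 1.0
        return h
    t = np.arange(n_samples) * cfg.dt
    u = t - cfg.delta
    h = np.zeros(n_samples)
    pos = u > 0
    h[pos] = u[pos] ** cfg.a * np.exp(-u[pos] / cfg.b)
    if not np.any(h > 0):
        raise ValueError(
            f"sampled filter is identically zero: grid spans "
            f"[0, {t[-1]:.4g}] s but onset delay is {cfg.delta:.4g} s"
        )
    if cfg.normalize == "peak-one":
        h /= h.max()
    elif cfg.normalize == "unit-sum":
        h /= h.sum()
    return h


def apply_transfer(
    source: np.ndarray,
    cfg: TransferConfig,
    phase: int = 0,
    standardize_output: bool = True,
) -> np.ndarray:
    """Convolve ``source`` with the sampled filter and decimate by ``cfg.q``.

    Returns the standardized (zero-mean, unit-variance) decimated signal of
    length ``len(source) // q``. A constant result is returned unstandardized
    with a warning. ``phase`` selects which sample of each decimation block is
    kept (default 0). ``standardize_output=False`` returns the raw decimated
    convolution (the transform is then exactly linear).
    """
    s = np.asarray(source, dtype=float).ravel()
    n = s.size
    if n % cfg.q != 0:
        raise ValueError(f"decimation factor q={cfg.q} does not divide signal length {n}")
    if not (0 <= phase < cfg.q):
        raise ValueError(f"phase must lie in [0, q), got {phase}")
    h = sample_transfer_function(cfg, n) if n >= 2 else np.ones(1)
    if cfg.conv_mode == "circulant":
        conv = np.fft.irfft(np.fft.rfft(s) * np.fft.rfft(h), n=n)
    else:  # linear convolution, zero-padded, truncated to the input length
        conv = np.convolve(s, h)[:n]
    dec = conv[phase :: cfg.q]
    if not standardize_output:
        return dec
    sd = dec.std()
    if sd == 0:
        warnings.warn("transfer output is constant; returned unstandardized", RuntimeWarning)
        return dec
    return (dec - dec.mean()) / sd


def perturb_transfer(cfg: TransferConfig, mode: str, factor: float) -> TransferConfig:
    """Return a perturbed copy of ``cfg`` for misspecification experiments.

    Modes
    -----
    shape-fixed-peak
        a' = a*factor, b' = b/factor — rise/decay change, peak delta + a*b fixed.
    peak-shift-fixed-decay
        a' = a*factor — peak moves, asymptotic decay scale b fixed.
    delay-shift
        delta' = delta*factor — onset delay scaled, shape fixed.
    """
    if mode not in _PERTURB_MODES:
        raise ValueError(f"unknown perturbation mode {mode!r}; expected one of {_PERTURB_MODES}")
    if mode == "delay-shift":
        if factor < 0:
            raise ValueError("delay-shift factor must be >= 0")
        return replace(cfg, delta=cfg.delta * factor)
    if factor <= 0 or not math.isfinite(factor):
        raise ValueError(f"multiplicative factor must be > 0, got {factor}")
    if mode == "shape-fixed-peak":
        return replace(cfg, a=cfg.a * factor, b=cfg.b / factor)
    return replace(cfg, a=cfg.a * factor)
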