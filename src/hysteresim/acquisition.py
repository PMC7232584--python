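"""Simulated perfusion-MRI sampling: frame grids and Gaussian noise.

A CBF frame is treated as an instantaneous sample of the time-effect curve
at the frame midpoint; within-frame integration is deliberately omitted
(the signal varies slowly relative to a 34-s frame except during loading).
Noisy values are not clipped at zero — clipping would bias estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError

__all__ = ["TimeEffectSeries", "frame_grid", "add_noise", "DEFAULT_FRAME_DURATION_S"]

DEFAULT_FRAME_DURATION_S = 34.0


@dataclass(frozen=True)
class TimeEffectSeries:
    """Sampled (frame-time, effect-value) pairs, noiseless or noisy.

    frame_times : frame midpoints in minutes, strictly increasing
    values : effect values in ml/hg/min
    noisy : whether Gaussian noise has been applied
    noise_cov : coefficient of variation of the applied noise (fraction)
    seed : RNG seed used for the noise draw, if any
    """

    frame_times: np.ndarray
    values: np.ndarray
    noisy: bool = False
    noise_cov: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.frame_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ParameterError("frame_times and values must be one-dimensional")
        if t.size != v.size:
            raise ParameterError("frame_times and values must have equal length")
        if t.size == 0:
            raise ParameterError("series must contain at least one frame")
        if not np.all(np.diff(t) > 0):
            raise ParameterError("frame_times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ParameterError("values must be finite")
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.frame_times.size)


def frame_grid(t_start: float, t_end: float, frame_duration_s: float = DEFAULT_FRAME_DURATION_S) -> np.ndarray:
    """Midpoints (minutes) of contiguous frames covering [t_start, t_end].

    Frames of ``frame_duration_s`` seconds are laid end to end starting at
    ``t_start``; a trailing partial frame is dropped.
    """
    if t_end <= t_start:
        raise ParameterError("t_end must exceed t_start")
    if not (5.0 <= frame_duration_s <= 60.0):
        raise ParameterError("frame duration must be between 5 and 60 seconds")
    dur_min = frame_duration_s / 60.0
    n = int(np.floor((t_end - t_start) / dur_min + 1e-9))
    if n < 1:
        raise ParameterError("span shorter than one frame: empty grid")
    return t_start + dur_min * (np.arange(n) + 0.5)


def add_noise(
    series: TimeEffectSeries,
    cov: float,
    seed: int | None = None,
    reference: str = "signal",
    baseline: float | None = None,
) -> TimeEffectSeries:
    """Add mean-zero Gaussian noise at a given coefficient of variation.

    Each value receives N(0, (cov * reference_i)^2) where reference_i is the
    noiseless value itself (``reference="signal"``, default) or a fixed
    baseline level (``reference="baseline"``, requires ``baseline``).

    Reproducible: the same seed yields the same realization.
    """
    if series.noisy:
        raise ParameterError("series is already noisy")
    if cov < 0:
        raise ParameterError("cov must be non-negative")
    if reference == "signal":
        ref = np.abs(series.values)
    elif reference == "baseline":
        if baseline is None:
            raise ParameterError("baseline reference requires a baseline value")
        ref = np.full(len(series), abs(float(baseline)))
    else:
        raise ParameterError(f"unknown noise reference {reference!r}")

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=len(series)) * cov * ref
    return replace(
        series,
        values=series.values + noise,
        noisy=cov > 0,
        noise_cov=float(cov),
        seed=seed,
    )
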