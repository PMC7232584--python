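"""Core effect-compartment PK-PD mathematics.

Units are fixed throughout the package: time in minutes, drug concentration
in ng/mL, effect (regional cerebral blood flow) in ml/hg/min.

The plasma concentration time course is represented as a piecewise-linear
curve.  For a linear plasma segment the effect-site concentration obeys the
first-order equilibration ODE

    dCe/dt = ke * (Cp(t) - Ce(t))

which has an exact closed-form solution on each segment; :func:`effect_site`
evaluates that solution, propagating the effect-site value across segment
boundaries so the result is exact and grid independent.  A fixed-step
Runge-Kutta integrator (:func:`effect_site_ode_oracle`) provides an
independent numerical check and is used only in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .errors import ParameterError, RangeError

__all__ = [
    "PlasmaCurve",
    "EffectSiteCurve",
    "PDParams",
    "interp_plasma",
    "effect_site",
    "effect_site_ode_oracle",
    "hill_effect",
    "t_half_e",
    "ke_from_t_half",
    "predict_time_effect",
]

LN2 = np.log(2.0)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ParameterError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class PlasmaCurve:
    """Piecewise-linear plasma concentration curve Cp(t).

    Parameters
    ----------
    times :
        Knot times in minutes, strictly increasing, at least two.
    concentrations :
        Knot concentrations in ng/mL, non-negative, one per knot.
    """

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        t = _as_float_array(self.times, "times")
        c = _as_float_array(self.concentrations, "concentrations")
        if t.size < 2:
            raise ParameterError("a plasma curve needs at least two knots")
        if t.size != c.size:
            raise ParameterError("times and concentrations must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ParameterError("knot times must be strictly increasing")
        if np.any(c < 0):
            raise ParameterError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def slopes(self) -> np.ndarray:
        """Per-segment slopes m_i in ng/mL per minute."""
        return np.diff(self.concentrations) / np.diff(self.times)

    def scaled(self, factor: float) -> "PlasmaCurve":
        """Return a copy with concentrations multiplied by ``factor``."""
        if factor < 0:
            raise ParameterError("scale factor must be non-negative")
        return PlasmaCurve(self.times.copy(), self.concentrations * factor)


@dataclass(frozen=True)
class EffectSiteCurve:
    """Effect-compartment concentration Ce(t) evaluated on a time grid."""

    times: np.ndarray
    concentrations: np.ndarray
    ke: float
    ce0: float

    def __post_init__(self):
        t = _as_float_array(self.times, "times")
        c = _as_float_array(self.concentrations, "concentrations")
        if t.size != c.size:
            raise ParameterError("times and concentrations must have equal length")
        if self.ke <= 0:
            raise ParameterError("ke must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class PDParams:
    """Pharmacodynamic parameter set for the sigmoid Emax response.

    e0 : baseline effect, ml/hg/min
    emax : maximal effect increment above baseline, ml/hg/min
    ec50 : effect-site concentration at half-maximal effect, ng/mL
    n : Hill coefficient (dimensionless)
    ke : effect-site equilibration rate constant, 1/min
    """

    e0: float
    emax: float
    ec50: float
    n: float
    ke: float

    def __post_init__(self):
        if self.e0 < 0:
            raise ParameterError("e0 must be >= 0")
        if self.emax < 0:
            raise ParameterError("emax must be >= 0")
        if self.ec50 <= 0:
            raise ParameterError("ec50 must be > 0")
        if self.n <= 0:
            raise ParameterError("n must be > 0")
        if self.ke <= 0:
            raise ParameterError("ke must be > 0")

    @property
    def t_half_e(self) -> float:
        return t_half_e(self.ke)

    def with_(self, **kwargs) -> "PDParams":
        return replace(self, **kwargs)


def _check_span(curve: PlasmaCurve, t: np.ndarray) -> None:
    lo, hi = curve.span
    tmin, tmax = float(np.min(t)), float(np.max(t))
    if tmin < lo or tmax > hi:
        raise RangeError(
            f"evaluation times [{tmin:g}, {tmax:g}] outside plasma span [{lo:g}, {hi:g}]"
        )


def interp_plasma(curve: PlasmaCurve, t):
    """Linearly interpolate Cp at time(s) ``t`` (minutes).

    No extrapolation: ``t`` must lie within the curve's span.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    _check_span(curve, t_arr)
    out = np.interp(t_arr, curve.times, curve.concentrations)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def _knot_effect_site(curve: PlasmaCurve, ke: float, ce0: float) -> np.ndarray:
    """Exact Ce at every plasma knot, propagated segment by segment.

    Over segment i the closed form gives the affine recurrence
        Ce(t_{i+1}) = a_i * Ce(t_i) + b_i
    with a_i = exp(-ke*dt_i) and
        b_i = (Cp(t_i) - m_i/ke) * (1 - a_i) + m_i * dt_i.
    Solved in vectorized form via a cumulative-product rescaling; falls
    back to a sequential loop when exp(ke * span) would overflow.
    """
    t = curve.times
    cp = curve.concentrations
    dt = np.diff(t)
    m = np.diff(cp) / dt
    a = np.exp(-ke * dt)
    b = (cp[:-1] - m / ke) * (1.0 - a) + m * dt

    ce = np.empty_like(t)
    ce[0] = ce0
    if ke * (t[-1] - t[0]) < 500.0:
        # ce_k = P_k * (ce0 + sum_{j<k} b_j / P_{j+1}), P_k = prod_{j<k} a_j
        log_p = np.concatenate(([0.0], np.cumsum(-ke * dt)))
        p = np.exp(log_p)
        ce[1:] = p[1:] * (ce0 + np.cumsum(b / p[1:]))
    else:
        acc = ce0
        for i in range(dt.size):
            acc = a[i] * acc + b[i]
            ce[i + 1] = acc
    return ce


def effect_site(curve: PlasmaCurve, ke: float, ce0: float, eval_times) -> EffectSiteCurve:
    """Closed-form effect-site concentration curve.

    Evaluates, on each plasma segment [t_i, t_{i+1}] with slope m_i,

        Ce(t) = (Cp(t_i) - m_i/ke) + m_i (t - t_i)
                + (Ce(t_i) - Cp(t_i) + m_i/ke) exp(-ke (t - t_i))

    seeding each segment with the exact value at its left knot.

    Parameters
    ----------
    curve : PlasmaCurve
    ke : equilibration rate constant, 1/min (> 0)
    ce0 : initial effect-site concentration at the curve's first knot, ng/mL
    eval_times : evaluation times in minutes, all within the curve's span
    """
    if ke <= 0:
        raise ParameterError("ke must be positive")
    if ce0 < 0:
        raise ParameterError("ce0 must be non-negative")
    et = np.atleast_1d(np.asarray(eval_times, dtype=float))
    _check_span(curve, et)

    t = curve.times
    cp = curve.concentrations
    m = curve.slopes()
    ce_knots = _knot_effect_site(curve, ke, ce0)

    idx = np.clip(np.searchsorted(t, et, side="right") - 1, 0, t.size - 2)
    tau = et - t[idx]
    steady = cp[idx] - m[idx] / ke
    vals = steady + m[idx] * tau + (ce_knots[idx] - steady) * np.exp(-ke * tau)
    return EffectSiteCurve(times=et, concentrations=vals, ke=ke, ce0=ce0)


def effect_site_ode_oracle(
    curve: PlasmaCurve, ke: float, ce0: float, eval_times, step: float = 0.001
) -> EffectSiteCurve:
    """Brute-force fixed-step RK4 integration of dCe/dt = ke (Cp - Ce).

    Independent of the closed form; intended for verification in tests.
    Evaluation times are snapped to the nearest integration node (the step
    should be small relative to both 1/ke and the requested resolution).
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    if ke <= 0:
        raise ParameterError("ke must be positive")
    et = np.atleast_1d(np.asarray(eval_times, dtype=float))
    _check_span(curve, et)

    # Integrate between "anchor" times (plasma knots + requested times) so
    # no RK4 step crosses a slope discontinuity and every requested time is
    # hit exactly; within an anchor segment the sub-step is uniform.
    anchors = np.union1d(curve.times, et)
    values_at = {}
    y = float(ce0)
    values_at[anchors[0]] = y
    for lo, hi in zip(anchors[:-1], anchors[1:]):
        seg = hi - lo
        n_sub = max(1, int(np.ceil(seg / step - 1e-12)))
        h = seg / n_sub
        nodes = lo + h * np.arange(n_sub + 1)
        cp_lo = np.interp(nodes[:-1], curve.times, curve.concentrations)
        cp_mid = np.interp(nodes[:-1] + h / 2, curve.times, curve.concentrations)
        cp_hi = np.interp(nodes[1:], curve.times, curve.concentrations)

        # For this linear ODE each RK4 step is affine in y: y+ = a*y + b_i,
        # with k_j = p_j - q_j*y expanded symbolically; the constant-a
        # recurrence is then solved with an IIR filter, keeping the oracle
        # fast at tiny steps.
        u = ke * h
        q1 = ke
        q2 = ke - (u / 2) * q1
        q3 = ke - (u / 2) * q2
        q4 = ke - u * q3
        a = 1.0 - (h / 6.0) * (q1 + 2 * q2 + 2 * q3 + q4)

        p1 = ke * cp_lo
        p2 = ke * cp_mid - (u / 2) * p1
        p3 = ke * cp_mid - (u / 2) * p2
        p4 = ke * cp_hi - u * p3
        b = (h / 6.0) * (p1 + 2 * p2 + 2 * p3 + p4)

        y_path, _ = lfilter([1.0], [1.0, -a], b, zi=np.array([a * y]))
        y = float(y_path[-1])
        values_at[hi] = y

    vals = np.array([values_at[t] for t in et])
    return EffectSiteCurve(times=et, concentrations=vals, ke=ke, ce0=ce0)


def hill_effect(ce, params: PDParams):
    """Sigmoid Emax response: e0 + emax * ce^n / (ec50^n + ce^n).

    Accepts a scalar or array of effect-site concentrations (ng/mL, >= 0)
    and returns the effect in ml/hg/min, bounded in [e0, e0 + emax).
    """
    ce_arr = np.atleast_1d(np.asarray(ce, dtype=float))
    if np.any(ce_arr < 0):
        raise ParameterError("effect-site concentration must be non-negative")
    with np.errstate(over="ignore", invalid="ignore"):
        x = (ce_arr / params.ec50) ** params.n
        frac = x / (1.0 + x)
    frac = np.where(np.isnan(frac), 1.0, frac)  # x overflowed -> saturated
    out = params.e0 + params.emax * frac
    return float(out[0]) if np.ndim(ce) == 0 else out


def t_half_e(ke: float) -> float:
    """Equilibration half-life (minutes): t_half_e = ln2 / ke."""
    if ke <= 0:
        raise ParameterError("ke must be positive")
    return LN2 / ke


def ke_from_t_half(t_half: float) -> float:
    """Inverse of :func:`t_half_e`: ke = ln2 / t_half_e."""
    if t_half <= 0:
        raise ParameterError("t_half_e must be positive")
    return LN2 / t_half


def predict_time_effect(curve: PlasmaCurve, params: PDParams, eval_times):
    """Noiseless time-effect series from a plasma curve and PD parameters.

    The effect-site curve is seeded with ce0 = Cp(t0) and passed through
    the sigmoid Emax response.  Returns a
    :class:`~hysteresim.acquisition.TimeEffectSeries`.
    """
    from .acquisition import TimeEffectSeries

    ce0 = float(curve.concentrations[0])
    ce = effect_site(curve, params.ke, ce0, eval_times)
    values = hill_effect(np.maximum(ce.concentrations, 0.0), params)
    return TimeEffectSeries(
        frame_times=ce.times, values=np.atleast_1d(values), noisy=False
    )
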