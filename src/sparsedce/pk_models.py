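"""Pharmacokinetic core: extended Tofts forward model, Patlak graphical
analysis, and signal/concentration conversions.

Conventions used throughout the package:

* time is measured in **minutes** from the start of contrast-agent injection;
* concentrations are in **mM**; plasma concentration is whole-blood
  concentration divided by ``(1 - Hct)``;
* T1 relaxation times are in **seconds**, relaxivity ``r1`` in mM^-1 s^-1
  (the internal time unit for kinetics stays minutes; ``r1`` only ever
  multiplies concentrations against 1/T1 in s^-1, so no conversion of the
  kinetic time axis is needed).

The extended Tofts model describes the tissue concentration as

    C_t(t) = v_p C_p(t) + Ktrans * int_0^t C_p(tau) exp(-kep (t - tau)) dtau

with ``kep = Ktrans / v_e``.  The Patlak linearization plots
``y = C_t(t)/C_p(t)`` against the normalized exposure
``x = int_0^t C_p / C_p(t)``; for negligible backflux the slope of the
regression line is the leakage rate ``K_i`` and its intercept the plasma
volume fraction ``v_p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "InvalidInputError",
    "DegeneratePlasmaError",
    "SingularFitError",
    "TissueParams",
    "VIFModel",
    "ConcentrationCurve",
    "PatlakPoints",
    "PatlakResult",
    "RelaxationConstants",
    "MonoExpFit",
    "extended_tofts",
    "patlak_coords",
    "patlak_fit",
    "t1_to_concentration",
    "concentration_to_t1",
    "blood_to_plasma",
    "monoexp_fit",
    "DEFAULT_GRID_STEP",
]

#: Dense-grid step (minutes) used for convolution / trapezoid integration.
#: 0.5 s, i.e. well below the 1.86 s dynamic-scan spacing.
DEFAULT_GRID_STEP = 0.5 / 60.0


class InvalidInputError(ValueError):
    """Raised for inputs violating an operation's preconditions."""


class DegeneratePlasmaError(ValueError):
    """Raised when the plasma concentration is non-positive at a requested time."""


class SingularFitError(ValueError):
    """Raised when a least-squares fit has no unique solution."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth pharmacokinetic state of one tissue class.

    Parameters
    ----------
    ktrans : float
        Exchange (leakage) rate constant in min^-1; plays the role of the
        "true" K_i when generating curves.
    vp : float
        Fractional plasma volume, dimensionless in [0, 1).
    ve : float
        Fractional extravascular-extracellular volume, dimensionless in
        (0, 1).  Governs backflux through ``kep = ktrans / ve``.
    """

    ktrans: float
    vp: float
    ve: float

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise InvalidInputError(f"ktrans must be >= 0, got {self.ktrans}")
        if not 0 <= self.vp < 1:
            raise InvalidInputError(f"vp must be in [0, 1), got {self.vp}")
        if not 0 < self.ve < 1:
            raise InvalidInputError(f"ve must be in (0, 1), got {self.ve}")
        if self.vp + self.ve > 1:
            raise InvalidInputError(
                f"vp + ve must be <= 1, got {self.vp + self.ve}"
            )

    @property
    def kep(self) -> float:
        """Backflux rate constant Ktrans/ve in min^-1."""
        return self.ktrans / self.ve


@dataclass(frozen=True)
class VIFModel:
    """Parametric vascular input function C_p(t) (bolus + washout).

    Zero before ``t0``, rises to ``a_peak`` at ``t_peak`` (linearly, or as a
    gamma-variate bump for ``shape='gamma'``), then decays mono-exponentially
    with rate ``m``.  Continuous at the peak by construction.

    The defaults emulate a slow-infusion venous (superior sagittal sinus)
    curve: peak 0.93 min after injection start (30 dynamic volumes at
    1.86 s), peak plasma concentration 1.5 mM, washout 0.03 min^-1.
    """

    t0: float = 0.0
    t_peak: float = 0.93
    a_peak: float = 1.5
    m: float = 0.03
    shape: str = "linear"
    #: gamma-variate steepness (only used for shape='gamma')
    gamma_alpha: float = 3.0

    def __post_init__(self) -> None:
        if self.t_peak <= self.t0:
            raise InvalidInputError("t_peak must be > t0")
        if self.a_peak <= 0:
            raise InvalidInputError("a_peak must be > 0")
        if self.m < 0:
            raise InvalidInputError("washout rate m must be >= 0")
        if self.shape not in ("linear", "gamma"):
            raise InvalidInputError(f"unknown VIF shape {self.shape!r}")

    # -- evaluation ---------------------------------------------------------

    def concentration(self, t) -> np.ndarray:
        """Plasma concentration (mM) at time(s) ``t`` (minutes)."""
        t = np.asarray(t, dtype=float)
        s = (t - self.t0) / (self.t_peak - self.t0)
        if self.shape == "linear":
            rise = self.a_peak * s
        else:
            with np.errstate(invalid="ignore"):
                rise = self.a_peak * np.where(
                    s > 0,
                    np.abs(s) ** self.gamma_alpha
                    * np.exp(self.gamma_alpha * (1.0 - s)),
                    0.0,
                )
        tail = self.a_peak * np.exp(-self.m * (t - self.t_peak))
        out = np.where(t <= self.t0, 0.0, np.where(t < self.t_peak, rise, tail))
        return out if out.ndim else float(out)

    __call__ = concentration

    def cumulative_integral(self, t) -> np.ndarray:
        """``int_0^t C_p(tau) dtau`` in mM*min.

        Analytic for the linear rise and the exponential tail; the
        gamma-variate rise is integrated once on a dense grid and cached.
        """
        t = np.asarray(t, dtype=float)
        if self.shape == "linear":
            rise_at = lambda u: 0.5 * self.a_peak * (u - self.t0) ** 2 / (
                self.t_peak - self.t0
            )
            rise_total = rise_at(self.t_peak)
        else:
            grid, cum = self._gamma_rise_table()
            rise_at = lambda u: np.interp(u, grid, cum)
            rise_total = cum[-1]
        if self.m > 0:
            tail = (
                self.a_peak
                / self.m
                * (1.0 - np.exp(-self.m * (t - self.t_peak)))
            )
        else:
            tail = self.a_peak * (t - self.t_peak)
        out = np.where(
            t <= self.t0,
            0.0,
            np.where(
                t < self.t_peak,
                rise_at(np.clip(t, self.t0, self.t_peak)),
                rise_total + np.where(t > self.t_peak, tail, 0.0),
            ),
        )
        return out if out.ndim else float(out)

    def _gamma_rise_table(self):
        grid = np.linspace(self.t0, self.t_peak, 2001)
        cum = cumulative_trapezoid(self.concentration(grid), grid, initial=0.0)
        return grid, cum


@dataclass(frozen=True)
class ConcentrationCurve:
    """A sampled concentration-time curve (times in min, values in mM)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if times.shape != values.shape:
            raise InvalidInputError(
                f"times and values differ in length: {times.shape} vs {values.shape}"
            )
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PatlakPoints:
    """Patlak-plot coordinates: x = int C_p / C_p(t) [min], y = C_t/C_p."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if x.shape != y.shape:
            raise InvalidInputError("x and y must have equal length")
        if x.size < 2:
            raise InvalidInputError("Patlak analysis needs >= 2 points")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class PatlakResult:
    """Patlak regression outcome: slope ``ki`` (min^-1), intercept ``vp``."""

    ki: float
    vp: float
    n_points: int
    rss: float


@dataclass(frozen=True)
class RelaxationConstants:
    """Contrast-agent relaxivity and hematocrit used for conversions.

    Defaults: ``r1 = 4.2`` mM^-1 s^-1 (gadobutrol at 7 T) and
    ``hct = 0.45``.
    """

    r1: float = 4.2
    hct: float = 0.45

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise InvalidInputError(f"r1 must be > 0, got {self.r1}")
        if not 0 <= self.hct < 1:
            raise InvalidInputError(f"hct must be in [0, 1), got {self.hct}")


@dataclass(frozen=True)
class MonoExpFit:
    """Result of a log-linear mono-exponential fit C(t) = A exp(-m t)."""

    amplitude: float
    rate: float
    clamped: bool = False

    def __iter__(self):
        return iter((self.amplitude, self.rate))

    def __call__(self, t):
        return self.amplitude * np.exp(-self.rate * np.asarray(t, dtype=float))


PlasmaLike = Union[VIFModel, ConcentrationCurve, Callable]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _check_times(times) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise InvalidInputError("empty time vector")
    if np.any(times < 0):
        raise InvalidInputError("times must be non-negative")
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise InvalidInputError("times must be strictly increasing")
    return times


def extended_tofts(
    vif: Union[VIFModel, Callable],
    params: TissueParams,
    times,
    *,
    grid_step: float = DEFAULT_GRID_STEP,
) -> ConcentrationCurve:
    """Tissue concentration curve from the extended Tofts model.

    The convolution integral is evaluated by the trapezoid rule on a dense
    uniform grid (default step 0.5 s) and read out at ``times`` by linear
    interpolation.

    Parameters
    ----------
    vif : VIFModel or callable
        Plasma input function; any callable ``C_p(t)`` in mM is accepted.
    params : TissueParams
    times : array-like
        Non-negative, strictly increasing sample times in minutes.
    """
    times = _check_times(times)
    cp_of = vif.concentration if isinstance(vif, VIFModel) else vif

    if params.ktrans == 0.0:
        ct = params.vp * np.asarray(cp_of(times), dtype=float)
        return ConcentrationCurve(times, ct)

    t_max = float(times[-1])
    n = max(int(np.ceil(t_max / grid_step)), 1)
    grid = np.linspace(0.0, t_max, n + 1)
    cp = np.asarray(cp_of(grid), dtype=float)
    kep = params.kep
    # F(t) = exp(-kep t) * int_0^t cp(tau) exp(kep tau) dtau; kep*t_max is
    # small in this regime so the exponential weights stay well-scaled.
    weighted = cp * np.exp(kep * grid)
    integral = cumulative_trapezoid(weighted, grid, initial=0.0)
    leak = params.ktrans * np.exp(-kep * grid) * integral
    ct_grid = params.vp * cp + leak
    ct = np.interp(times, grid, ct_grid)
    if not np.all(np.isfinite(ct)):
        raise FloatingPointError("non-finite tissue concentration")
    return ConcentrationCurve(times, ct)


def patlak_coords(
    curve_t: ConcentrationCurve,
    plasma: PlasmaLike,
    *,
    grid_step: float = DEFAULT_GRID_STEP,
) -> PatlakPoints:
    """Patlak-plot coordinates of a tissue curve against a plasma input.

    ``plasma`` may be a :class:`VIFModel` (analytic cumulative integral), an
    object exposing ``concentration(t)`` and ``cumulative_integral(t)``
    (e.g. a fitted plasma model), or a densely sampled
    :class:`ConcentrationCurve` (trapezoid integration on its own grid).
    """
    times = curve_t.times
    if isinstance(plasma, ConcentrationCurve):
        if plasma.times[0] > 0 or plasma.times[-1] < times[-1]:
            raise InvalidInputError(
                "plasma curve must cover [0, max(tissue times)]"
            )
        cum = cumulative_trapezoid(plasma.values, plasma.times, initial=0.0)
        cp_t = np.interp(times, plasma.times, plasma.values)
        int_t = np.interp(times, plasma.times, cum)
    elif hasattr(plasma, "concentration") and hasattr(
        plasma, "cumulative_integral"
    ):
        cp_t = np.asarray(plasma.concentration(times), dtype=float)
        int_t = np.asarray(plasma.cumulative_integral(times), dtype=float)
    elif callable(plasma):
        t_max = float(times[-1])
        n = max(int(np.ceil(t_max / grid_step)), 1)
        grid = np.linspace(0.0, t_max, n + 1)
        cp_grid = np.asarray(plasma(grid), dtype=float)
        cum = cumulative_trapezoid(cp_grid, grid, initial=0.0)
        cp_t = np.interp(times, grid, cp_grid)
        int_t = np.interp(times, grid, cum)
    else:  # pragma: no cover - defensive
        raise InvalidInputError(f"unsupported plasma input {type(plasma)!r}")

    bad = cp_t <= 0
    if np.any(bad):
        t_bad = times[bad][0]
        raise DegeneratePlasmaError(
            f"plasma concentration is non-positive at t = {t_bad:g} min"
        )
    return PatlakPoints(x=int_t / cp_t, y=curve_t.values / cp_t)


def patlak_fit(points: PatlakPoints) -> PatlakResult:
    """Unweighted ordinary-least-squares line through Patlak points.

    The slope is the leakage rate ``K_i`` (min^-1) and the intercept the
    plasma volume fraction ``v_p``.  With exactly two points the line
    interpolates them (rss = 0).
    """
    x, y = points.x, points.y
    xm = x.mean()
    dx = x - xm
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise SingularFitError("all Patlak x-coordinates are equal")
    ki = float(dx @ (y - y.mean())) / sxx
    vp = float(y.mean() - ki * xm)
    resid = y - (ki * x + vp)
    return PatlakResult(ki=ki, vp=vp, n_points=x.size, rss=float(resid @ resid))


def t1_to_concentration(t1_pre, t1_post, consts: RelaxationConstants):
    """Contrast concentration (mM) from pre/post T1 (seconds).

    ``C = (1/T1_post - 1/T1_pre) / r1``.  Negative values (noise) are
    retained.  Non-positive or non-finite T1 values are flagged as NaN
    rather than silently propagated; callers treat NaN as "no data".
    """
    t1_pre = np.asarray(t1_pre, dtype=float)
    t1_post = np.asarray(t1_post, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (1.0 / t1_post - 1.0 / t1_pre) / consts.r1
    invalid = ~(np.isfinite(t1_pre) & np.isfinite(t1_post)) | (t1_pre <= 0) | (
        t1_post <= 0
    )
    c = np.where(invalid, np.nan, c)
    return c if c.ndim else float(c)


def concentration_to_t1(t1_pre, conc, consts: RelaxationConstants):
    """Forward map used by the phantom: ``1/T1_post = 1/T1_pre + r1 C``.

    Exact inverse of :func:`t1_to_concentration` on positive T1.
    """
    t1_pre = np.asarray(t1_pre, dtype=float)
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_post = 1.0 / t1_pre + consts.r1 * conc
        out = np.where(t1_pre > 0, 1.0 / r1_post, np.nan)
    return out if out.ndim else float(out)


def blood_to_plasma(cb, consts: RelaxationConstants):
    """Whole-blood to plasma concentration: ``C_p = C_b / (1 - Hct)``."""
    if consts.hct >= 1:
        raise InvalidInputError("hct must be < 1")
    cb = np.asarray(cb, dtype=float)
    out = cb / (1.0 - consts.hct)
    return out if out.ndim else float(out)


def monoexp_fit(times, values) -> MonoExpFit:
    """Fit ``C(t) = A exp(-m t)`` by least squares on log-concentration.

    Deterministic and closed-form, which is all the three-point plasma tail
    fit requires.  A negative fitted rate is clamped to zero (flat tail) and
    flagged via ``clamped``.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if times.shape != values.shape or times.size < 2:
        raise InvalidInputError("need >= 2 (time, concentration) pairs")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise InvalidInputError("all concentrations must be positive")
    logc = np.log(values)
    tm = times.mean()
    dt = times - tm
    stt = float(dt @ dt)
    if stt == 0.0:
        raise SingularFitError("all fit times are equal")
    slope = float(dt @ (logc - logc.mean())) / stt
    rate = -slope
    if rate < 0:
        return MonoExpFit(
            amplitude=float(np.exp(logc.mean())), rate=0.0, clamped=True
        )
    amplitude = float(np.exp(logc.mean() - slope * tm))
    return MonoExpFit(amplitude=amplitude, rate=rate, clamped=False)
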