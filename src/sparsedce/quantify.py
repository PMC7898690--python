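"""Voxelwise K_i / v_p quantification from sparse T1 maps.

The in vivo-style pipeline: extract the blood curve from a venous ROI in
the dynamic series, correct for hematocrit, fit the plasma tail with a
mono-exponential through the last dynamic point and the map-derived blood
points, then convert each voxel's pre/post T1 pair to concentration and
Patlak-fit it against the plasma model.  ROI statistics use central-95%
trimming of the voxel distribution; WM vs GM comparisons use the paired
Wilcoxon signed-rank test.

All volumes must be co-registered on one grid; registration and
segmentation are out of scope and assumed done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import wilcoxon

from .pk_models import (
    ConcentrationCurve,
    InvalidInputError,
    DegeneratePlasmaError,
    RelaxationConstants,
    blood_to_plasma,
    monoexp_fit,
    t1_to_concentration,
)

__all__ = [
    "VolumeImage",
    "DynamicSeries",
    "PlasmaModel",
    "ROISummary",
    "UndefinedTestError",
    "extract_blood_curve",
    "fit_plasma_model",
    "voxelwise_patlak",
    "roi_summary",
    "compare_wm_gm",
    "wilcoxon_exact_enumeration",
]


class UndefinedTestError(ValueError):
    """Raised when a statistical test is undefined for the given data."""


@dataclass
class VolumeImage:
    """A 3D scalar volume with voxel size (mm), units tag and optional
    acquisition time (minutes after injection; the map's k-space-center
    time)."""

    voxels: np.ndarray
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: str = ""
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise InvalidInputError(
                f"expected a 3D volume, got shape {self.voxels.shape}"
            )
        if any(s <= 0 for s in self.voxel_size):
            raise InvalidInputError("voxel sizes must be positive")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class DynamicSeries:
    """A 4D dynamic series (x, y, z, t) with per-volume times in minutes."""

    data: np.ndarray
    times: np.ndarray
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise InvalidInputError("dynamic series must be 4D (x, y, z, t)")
        if self.times.shape != (self.data.shape[-1],):
            raise InvalidInputError("one timestamp per dynamic volume required")


def _mask_array(mask) -> np.ndarray:
    m = mask.voxels if isinstance(mask, VolumeImage) else np.asarray(mask)
    return m.astype(bool)


def extract_blood_curve(dynamic: DynamicSeries, roi_mask) -> ConcentrationCurve:
    """Spatial mean over the venous ROI at every dynamic time point.

    Returns whole-blood concentration (the series' native units); apply
    :func:`sparsedce.pk_models.blood_to_plasma` before plasma fitting.
    """
    m = _mask_array(roi_mask)
    if m.shape != dynamic.data.shape[:3]:
        raise InvalidInputError(
            f"mask shape {m.shape} does not match series grid "
            f"{dynamic.data.shape[:3]}"
        )
    if not m.any():
        raise InvalidInputError("blood ROI mask is empty")
    values = dynamic.data[m].mean(axis=0)
    return ConcentrationCurve(dynamic.times, values)


@dataclass
class PlasmaModel:
    """Piecewise plasma curve: measured dynamic segment + fitted
    mono-exponential tail ``A exp(-m t)`` beyond the last dynamic point.

    Both pieces are in plasma (hematocrit-corrected) units.  The cumulative
    integral uses the trapezoid rule over the measured segment (from t = 0)
    and the analytic tail integral afterwards.
    """

    measured: ConcentrationCurve
    tail_amplitude: float
    tail_rate: float
    t_switch: float
    tail_clamped: bool = False
    _grid: np.ndarray = field(init=False, repr=False)
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.tail_amplitude * np.exp(-self.tail_rate * self.t_switch) <= 0:
            raise InvalidInputError("plasma tail must be positive at t_switch")
        t = self.measured.times
        v = self.measured.values
        keep = t >= 0
        if not keep.any() or t[keep][0] > 0:
            # anchor the integral at t = 0 (concentration 0 before injection)
            t0v = np.interp(0.0, t, v) if t.min() < 0 <= t.max() else 0.0
            grid = np.concatenate([[0.0], t[t > 0]])
            vals = np.concatenate([[t0v], v[t > 0]])
        else:
            grid, vals = t[keep], v[keep]
        self._grid = grid
        self._cum = cumulative_trapezoid(vals, grid, initial=0.0)

    def concentration(self, t):
        t = np.asarray(t, dtype=float)
        tail = self.tail_amplitude * np.exp(-self.tail_rate * t)
        meas = np.interp(t, self.measured.times, self.measured.values)
        out = np.where(t > self.t_switch, tail, meas)
        return out if out.ndim else float(out)

    def cumulative_integral(self, t):
        t = np.asarray(t, dtype=float)
        base = np.interp(np.minimum(t, self.t_switch), self._grid, self._cum)
        i_switch = self._cum[-1]
        if self.tail_rate > 0:
            tail = (
                self.tail_amplitude
                / self.tail_rate
                * (
                    np.exp(-self.tail_rate * self.t_switch)
                    - np.exp(-self.tail_rate * np.maximum(t, self.t_switch))
                )
            )
        else:
            tail = self.tail_amplitude * np.maximum(t - self.t_switch, 0.0)
        out = np.where(t > self.t_switch, i_switch + tail, base)
        return out if out.ndim else float(out)


def fit_plasma_model(
    dynamic_blood: ConcentrationCurve,
    map_blood_points: Sequence[Tuple[float, float]],
    consts: RelaxationConstants,
) -> PlasmaModel:
    """Fit the plasma tail through the last dynamic point and the
    T1-map-derived blood points.

    Both inputs must already be hematocrit-corrected to plasma units
    (``consts`` is carried for provenance and sanity only).  The tail is
    the log-linear mono-exponential through {last dynamic point} union
    {map points}.
    """
    if len(dynamic_blood) == 0:
        raise InvalidInputError("dynamic blood curve is empty")
    pts = list(map_blood_points)
    if len(pts) < 1:
        raise InvalidInputError("need at least one map-derived blood point")
    t_switch = float(dynamic_blood.times[-1])
    fit_t = np.array([t_switch] + [float(t) for t, _ in pts])
    fit_c = np.array([float(dynamic_blood.values[-1])] + [float(c) for _, c in pts])
    if np.any(fit_c <= 0):
        raise InvalidInputError("non-positive blood concentration among fit points")
    fit = monoexp_fit(fit_t, fit_c)
    return PlasmaModel(
        measured=dynamic_blood,
        tail_amplitude=fit.amplitude,
        tail_rate=fit.rate,
        t_switch=t_switch,
        tail_clamped=fit.clamped,
    )


def voxelwise_patlak(
    pre_t1: VolumeImage,
    post_t1_maps: Sequence[VolumeImage],
    plasma: PlasmaModel,
    consts: RelaxationConstants,
    mask,
) -> Tuple[VolumeImage, VolumeImage]:
    """Per-voxel Patlak fit from one precontrast and >= 2 postcontrast T1 maps.

    Each postcontrast map is converted to concentration via Delta-R1, the
    Patlak coordinates are formed against the plasma model at the map's
    timestamp, and an OLS line is fitted per voxel.  Voxels with
    non-positive or non-finite T1 are set to NaN and excluded.

    Returns ``(ki_map, vp_map)`` with units min^-1 and dimensionless.
    """
    if len(post_t1_maps) < 2:
        raise InvalidInputError("need >= 2 postcontrast T1 maps")
    shapes = {pre_t1.shape, *(m.shape for m in post_t1_maps)}
    m = _mask_array(mask)
    shapes.add(m.shape)
    if len(shapes) != 1:
        raise InvalidInputError(f"volumes are not on one grid: shapes {shapes}")
    times = []
    for vol in post_t1_maps:
        if vol.timestamp is None:
            raise InvalidInputError("every postcontrast map needs a timestamp")
        times.append(float(vol.timestamp))
    times = np.asarray(times)

    cp = np.asarray(plasma.concentration(times), dtype=float)
    if np.any(cp <= 0):
        t_bad = times[cp <= 0][0]
        raise DegeneratePlasmaError(
            f"plasma concentration non-positive at map time {t_bad:g} min"
        )
    x = np.asarray(plasma.cumulative_integral(times), dtype=float) / cp

    conc = np.stack(
        [
            t1_to_concentration(pre_t1.voxels, vol.voxels, consts)
            for vol in post_t1_maps
        ]
    )  # (k, X, Y, Z); NaN marks invalid T1
    valid = m & np.all(np.isfinite(conc), axis=0)

    ki_map = np.full(pre_t1.shape, np.nan)
    vp_map = np.full(pre_t1.shape, np.nan)
    if valid.any():
        y = conc[:, valid] / cp[:, None]  # (k, n_vox)
        xm = x.mean()
        dx = x - xm
        sxx = float(dx @ dx)
        ki = dx @ (y - y.mean(axis=0)[None, :]) / sxx
        vp = y.mean(axis=0) - ki * xm
        ki_map[valid] = ki
        vp_map[valid] = vp
    return (
        VolumeImage(ki_map, pre_t1.voxel_size, units="1/min"),
        VolumeImage(vp_map, pre_t1.voxel_size, units=""),
    )


@dataclass(frozen=True)
class ROISummary:
    """Trimmed mean/SD over an ROI's voxel distribution."""

    mean: float
    sd: float
    n_total: int
    n_kept: int
    trim_bounds: Tuple[float, float]


def roi_summary(map_img: VolumeImage, mask, trim: float = 0.95) -> ROISummary:
    """Outlier-robust ROI statistics: keep the central ``trim`` fraction.

    Voxels outside the [(1-trim)/2, 1-(1-trim)/2] percentiles of the ROI's
    own distribution are excluded; mean/SD are over the kept voxels.  NaN
    (no-data) voxels never count.
    """
    m = _mask_array(mask)
    if m.shape != map_img.shape:
        raise InvalidInputError("mask and map are not on one grid")
    if not m.any():
        raise InvalidInputError("ROI mask is empty")
    values = map_img.voxels[m]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise InvalidInputError("ROI contains no valid voxels")
    alpha = (1.0 - trim) / 2.0 * 100.0
    lo, hi = np.percentile(values, [alpha, 100.0 - alpha])
    kept = values[(values >= lo) & (values <= hi)]
    ddof = 1 if kept.size > 1 else 0
    return ROISummary(
        mean=float(kept.mean()),
        sd=float(kept.std(ddof=ddof)),
        n_total=int(values.size),
        n_kept=int(kept.size),
        trim_bounds=(float(lo), float(hi)),
    )


def compare_wm_gm(
    per_subject_pairs: Sequence[Tuple[float, float]], mode: str = "asymptotic"
) -> Tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test on (WM, GM) value pairs.

    ``mode='asymptotic'`` uses the normal approximation without continuity
    correction (the only way a two-sided p < 0.05 is attainable at n = 5);
    ``mode='exact'`` uses the exact permutation null.  Returns
    ``(statistic, p_value)``.
    """
    pairs = np.asarray(per_subject_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise InvalidInputError("need >= 2 (wm, gm) pairs")
    if np.any(~np.isfinite(pairs)):
        raise InvalidInputError("missing values in pairs")
    wm, gm = pairs[:, 0], pairs[:, 1]
    if np.all(gm - wm == 0):
        raise UndefinedTestError("all paired differences are zero")
    if mode == "asymptotic":
        res = wilcoxon(gm, wm, correction=False, method="approx")
    elif mode == "exact":
        res = wilcoxon(gm, wm, method="exact")
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_exact_enumeration(differences) -> float:
    """Two-sided signed-rank p by full enumeration of the 2^n sign flips.

    Zero differences are discarded (the same convention the exact test
    uses); ties in |d| get midranks.  Intended for small n as an
    independent check of the exact mode.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all differences are zero")
    order = np.abs(d)
    from scipy.stats import rankdata

    ranks = rankdata(order)
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    # two-sided: distance from the null mean total/2
    dev_obs = abs(w_obs - total / 2.0)
    count = 0
    for bits in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if bits >> i & 1)
        if abs(w - total / 2.0) >= dev_obs - 1e-12:
            count += 1
    return count / 2.0 ** n
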