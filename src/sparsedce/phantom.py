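"""Digital phantom emulating the sparsely sampled 7 T DCE protocol.

The phantom provides what the in vivo pipeline consumes, with known ground
truth: a precontrast T1 volume, a 90-volume dynamic blood series (1.86 s
spacing, bolus peak near the 30th post-injection volume), two or more
postcontrast T1 maps at the scheme times, and disjoint WM/GM/SSS masks.

Geometry is deliberately simple (nested blocks plus a venous column) —
the per-voxel math is geometry-independent.  Postcontrast T1 is obtained
by inverting the linear Delta-R1 relation, so at zero noise the pipeline's
T1-to-concentration conversion recovers the programmed concentrations
exactly.  Noise is additive Gaussian on T1 for the maps and on blood
concentration for the dynamic series; the default map noise is calibrated
per tissue class so that the resulting concentration-domain noise is
2.0e-3 mM, the level used by the protocol simulations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .pk_models import (
    ConcentrationCurve,
    InvalidInputError,
    PatlakResult,
    RelaxationConstants,
    TissueParams,
    VIFModel,
    concentration_to_t1,
    extended_tofts,
    patlak_coords,
    patlak_fit,
)
from .protocol_sim import FIRST_MAP_TIME, GM, WM, SamplingScheme, make_scheme
from .pk_models import blood_to_plasma, t1_to_concentration
from .quantify import (
    DynamicSeries,
    VolumeImage,
    extract_blood_curve,
    fit_plasma_model,
    voxelwise_patlak,
)

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "make_phantom",
    "run_pipeline",
    "recovery_report",
    "t1_noise_for_concentration_sd",
    "DEFAULT_T1_BASELINE",
]

#: Plausible 7 T baseline T1 values in seconds (realism only; the math
#: depends on Delta-R1, not on the baselines themselves).
DEFAULT_T1_BASELINE = {"WM": 1.2, "GM": 2.0, "SSS": 2.4}

#: In vivo two-map protocol: first map at 4:20, last about 25 min.
_DEFAULT_SCHEME = make_scheme(FIRST_MAP_TIME, 25.0, 0)

#: Concentration-domain noise level (mM) the default map noise reproduces.
DEFAULT_CONC_NOISE_SD = 2.0e-3


def t1_noise_for_concentration_sd(
    conc_sd: float, t1_post: float, r1: float
) -> float:
    """T1-domain noise SD (s) producing a given concentration noise SD.

    First-order propagation of ``C = (1/T1_post - 1/T1_pre)/r1``:
    ``sd(C) ~= sd(T1_post) / (r1 * T1_post^2)``.
    """
    return conc_sd * r1 * t1_post**2


@dataclass(frozen=True)
class PhantomSpec:
    """Generating parameters of the phantom (all config-exposed)."""

    shape: Tuple[int, int, int] = (32, 32, 32)
    voxel_size: Tuple[float, float, float] = (1.2, 1.2, 1.2)
    tissues: Mapping[str, TissueParams] = field(
        default_factory=lambda: {"WM": WM, "GM": GM}
    )
    t1_baseline: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_T1_BASELINE)
    )
    vif: VIFModel = VIFModel()
    scheme: SamplingScheme = _DEFAULT_SCHEME
    constants: RelaxationConstants = RelaxationConstants()
    #: additive Gaussian T1 noise on the postcontrast maps, seconds.
    #: None -> calibrate per class so concentration noise = conc_noise_sd.
    map_noise_sd: Optional[float] = None
    conc_noise_sd: float = DEFAULT_CONC_NOISE_SD
    #: additive Gaussian noise on the dynamic blood concentrations, mM
    dynamic_noise_sd: float = 0.02
    #: additive Gaussian T1 noise on the precontrast map, seconds
    pre_noise_sd: float = 0.0
    n_dynamic: int = 90
    dynamic_dt: float = 1.86 / 60.0
    n_pre_injection: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, t1 in self.t1_baseline.items():
            if t1 <= 0:
                raise InvalidInputError(f"baseline T1 for {name!r} must be > 0")
        missing = set(self.tissues) - set(self.t1_baseline)
        if missing or "SSS" not in self.t1_baseline:
            raise InvalidInputError(
                f"baseline T1 missing for classes: {missing or {'SSS'}}"
            )


@dataclass
class PhantomDataset:
    """Generated volumes, dynamic series, masks and ground truth."""

    pre_t1: VolumeImage
    post_t1: list
    masks: Dict[str, np.ndarray]
    dynamic_blood: DynamicSeries
    #: per class: {"params": TissueParams, "ki": noiseless Patlak slope,
    #: "vp": noiseless Patlak intercept}
    truth: Dict[str, dict]
    spec: PhantomSpec


def _block(shape, margin_frac: float) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    lo = [max(1, round(n * margin_frac)) for n in shape]
    sl = tuple(slice(l, n - l) for l, n in zip(lo, shape))
    m[sl] = True
    return m


def default_masks(shape: Tuple[int, int, int]) -> Dict[str, np.ndarray]:
    """Nested-block geometry: WM core, GM shell, SSS column; disjoint."""
    inner = _block(shape, 10 / 32)  # 12^3 = 1728 voxels at the default grid
    outer = _block(shape, 8 / 32)  # 16^3 shell -> 2368 GM voxels
    if not inner.any() or not (outer & ~inner).any():
        raise InvalidInputError(f"grid {shape} too small for the phantom geometry")
    sss = np.zeros(shape, dtype=bool)
    nz = shape[2]
    sss[1:4, 1:4, nz // 4 : nz // 4 + max(2, min(20, nz // 2))] = True
    sss &= ~outer
    if not sss.any():
        raise InvalidInputError("no room for the venous (SSS) column")
    return {"WM": inner, "GM": outer & ~inner, "SSS": sss}


def _noiseless_truth(spec: PhantomSpec) -> Dict[str, dict]:
    truth: Dict[str, dict] = {}
    times = np.asarray(spec.scheme.times)
    for name, params in spec.tissues.items():
        curve = extended_tofts(spec.vif, params, times)
        fit: PatlakResult = patlak_fit(patlak_coords(curve, spec.vif))
        truth[name] = {"params": params, "ki": fit.ki, "vp": fit.vp}
    return truth


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomDataset:
    """Generate the full synthetic dataset for the quantify pipeline.

    Fully seeded: the same spec (including seed) yields a bit-identical
    dataset.
    """
    rng = np.random.default_rng(spec.seed)
    masks = default_masks(spec.shape)
    overlap = sum(m.astype(int) for m in masks.values())
    if int(overlap.max(initial=0)) > 1:
        raise InvalidInputError("phantom masks overlap")

    consts = spec.constants
    times = np.asarray(spec.scheme.times)

    # precontrast T1: class baselines, 0 (no signal) in the background
    pre = np.zeros(spec.shape)
    for name, m in masks.items():
        pre[m] = spec.t1_baseline[name]
    if spec.pre_noise_sd > 0:
        pre = pre + rng.normal(0.0, spec.pre_noise_sd, size=pre.shape)
    pre_img = VolumeImage(pre, spec.voxel_size, units="s")

    # per-class concentrations at the map times
    cp_at_maps = np.asarray(spec.vif.concentration(times), dtype=float)
    conc_by_class = {
        name: extended_tofts(spec.vif, params, times).values
        for name, params in spec.tissues.items()
    }
    conc_by_class["SSS"] = cp_at_maps * (1.0 - consts.hct)  # whole blood

    # per-class T1 noise (calibrated unless given explicitly)
    post_maps = []
    for j, t_j in enumerate(times):
        conc_vol = np.zeros(spec.shape)
        for name, m in masks.items():
            conc_vol[m] = conc_by_class[name][j]
        t1_post = concentration_to_t1(pre_img.voxels, conc_vol, consts)
        t1_post = np.where(np.isfinite(t1_post), t1_post, 0.0)
        noise = np.zeros(spec.shape)
        for name, m in masks.items():
            if spec.map_noise_sd is not None:
                sd = spec.map_noise_sd
            else:
                t1_nom = concentration_to_t1(
                    spec.t1_baseline[name], conc_by_class[name][j], consts
                )
                sd = t1_noise_for_concentration_sd(
                    spec.conc_noise_sd, t1_nom, consts.r1
                )
            if sd > 0:
                noise[m] = rng.normal(0.0, sd, size=int(m.sum()))
        post_maps.append(
            VolumeImage(
                t1_post + noise,
                spec.voxel_size,
                units="s",
                timestamp=float(t_j),
            )
        )

    # dynamic whole-blood series; injection starts after n_pre_injection
    # volumes, bolus peak at spec.vif.t_peak
    idx = np.arange(spec.n_dynamic)
    dyn_times = (idx - (spec.n_pre_injection - 1)) * spec.dynamic_dt
    cb = spec.vif.concentration(dyn_times) * (1.0 - consts.hct)
    dyn = np.zeros(spec.shape + (spec.n_dynamic,))
    dyn[masks["SSS"]] = cb
    if spec.dynamic_noise_sd > 0:
        dyn += rng.normal(0.0, spec.dynamic_noise_sd, size=dyn.shape)
    dynamic = DynamicSeries(dyn, dyn_times, spec.voxel_size)

    return PhantomDataset(
        pre_t1=pre_img,
        post_t1=post_maps,
        masks=masks,
        dynamic_blood=dynamic,
        truth=_noiseless_truth(spec),
        spec=spec,
    )


def run_pipeline(dataset: PhantomDataset):
    """Run the full in vivo-style quantification on a phantom dataset.

    Mirrors what the ``fit`` CLI does on files: venous blood curve from the
    dynamic series, hematocrit correction, mono-exponential plasma tail
    through the last dynamic point and the map-derived blood points, then
    the voxelwise Patlak fit over the WM+GM mask.

    Returns ``(ki_map, vp_map, plasma_model)``.
    """
    spec = dataset.spec
    consts = spec.constants
    blood = extract_blood_curve(dataset.dynamic_blood, dataset.masks["SSS"])
    plasma_dyn = ConcentrationCurve(
        blood.times, blood_to_plasma(blood.values, consts)
    )
    sss = dataset.masks["SSS"]
    map_points = []
    for vol in dataset.post_t1:
        cb = t1_to_concentration(
            dataset.pre_t1.voxels[sss], vol.voxels[sss], consts
        )
        cb = cb[np.isfinite(cb)]
        if cb.size == 0:
            raise InvalidInputError("no valid SSS voxels in a postcontrast map")
        map_points.append(
            (vol.timestamp, float(blood_to_plasma(cb.mean(), consts)))
        )
    plasma = fit_plasma_model(plasma_dyn, map_points, consts)
    tissue_mask = np.zeros(spec.shape, dtype=bool)
    for name in dataset.truth:
        tissue_mask |= dataset.masks[name]
    ki_map, vp_map = voxelwise_patlak(
        dataset.pre_t1, dataset.post_t1, plasma, consts, tissue_mask
    )
    return ki_map, vp_map, plasma


def recovery_report(
    dataset: PhantomDataset,
    ki_map: VolumeImage,
    vp_map: Optional[VolumeImage] = None,
) -> pd.DataFrame:
    """Per-class comparison of pipeline output against phantom truth.

    Relative error is taken against the *noiseless Patlak* value — the
    estimand of the pipeline, which already carries the known backflux
    underestimate — not against the generating ktrans.
    """
    rows = []
    for name, info in dataset.truth.items():
        if name not in dataset.masks:
            raise InvalidInputError(f"no mask for tissue class {name!r}")
        m = dataset.masks[name]
        vals = ki_map.voxels[m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise InvalidInputError(f"no recovered voxels in class {name!r}")
        row = {
            "tissue": name,
            "true_ktrans": info["params"].ktrans,
            "noiseless_ki": info["ki"],
            "recovered_ki_mean": float(vals.mean()),
            "recovered_ki_sd": float(vals.std(ddof=1 if vals.size > 1 else 0)),
            "rel_error_ki": float(vals.mean() / info["ki"] - 1.0),
            "n_voxels": int(vals.size),
        }
        if vp_map is not None:
            vvals = vp_map.voxels[m]
            vvals = vvals[np.isfinite(vvals)]
            row["noiseless_vp"] = info["vp"]
            row["recovered_vp_mean"] = float(vvals.mean())
            row["rel_error_vp"] = float(vvals.mean() / info["vp"] - 1.0)
        rows.append(row)
    return pd.DataFrame(rows)
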