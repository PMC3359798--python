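"""Synthetic concentration curves, cohorts and 4D phantoms.

Everything downstream of image reconstruction is emulated here so the
whole pipeline (forward models → fitting → IOF) can be exercised and
validated without real MRI data: per-subject kinetic parameters are drawn
from zero-truncated normal distributions whose default locations sit
inside the physiologically reported ranges (blood input rate
0.0427–0.0956 mM/min, blood elimination 0.0281–0.0344 1/min, tissue
transfer constants 0–0.0005 1/min, CSF-voxel blood fractions 9.4–16.5%),
noiseless curves are evaluated with the closed-form models, and
measurement noise is additive i.i.d. zero-mean Gaussian on concentration.
Noise on real data is Rician on the complex MR signal; the additive
Gaussian model holds in the post-conversion, high-SNR regime this package
operates in (see docs/methods.md for what that does and does not cover).

All randomness flows through a single integer seed per call, making every
output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .models import (
    BloodParams,
    CSFParams,
    ConcentrationCurve,
    TissueParams,
    aif,
    blood_concentration,
    csf_input_function,
    csf_voxel_concentration,
    ees_concentration,
    ies_concentration,
    tissue_concentration,
)

__all__ = [
    "Dist",
    "TimeGrid",
    "CohortSpec",
    "CohortData",
    "PhantomLayout",
    "generate_curve",
    "generate_cohort",
    "generate_phantom",
    "default_cohort_spec",
]

_MODEL_FNS = {
    "aif": lambda t, blood=None, tissue=None, csf=None: aif(t, blood),
    "blood": lambda t, blood=None, tissue=None, csf=None: blood_concentration(t, blood),
    "ees": lambda t, blood=None, tissue=None, csf=None: ees_concentration(t, tissue, blood),
    "ies": lambda t, blood=None, tissue=None, csf=None: ies_concentration(t, tissue, blood),
    "tissue": lambda t, blood=None, tissue=None, csf=None: tissue_concentration(t, tissue, blood),
    "csfif": lambda t, blood=None, tissue=None, csf=None: csf_input_function(t, csf),
    "csf": lambda t, blood=None, tissue=None, csf=None: csf_voxel_concentration(t, csf, blood),
}


@dataclass(frozen=True)
class Dist:
    """Normal distribution truncated at zero (physical rates are >= 0).

    ``sd = 0`` degenerates to the point mass at ``mean``.  A mean far
    below zero relative to ``sd`` leaves essentially no mass above the
    truncation point and is rejected.
    """

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.sd == 0.0:
            if self.mean < 0:
                raise ValueError(f"point mass at {self.mean} < 0 is infeasible")
        elif (0.0 - self.mean) / self.sd > 6.0:
            raise ValueError(
                f"truncation at 0 is infeasible for mean={self.mean}, sd={self.sd}"
            )

    def sample(self, rng: np.random.Generator, size=None):
        if self.sd == 0.0:
            return self.mean if size is None else np.full(size, self.mean)
        a = (0.0 - self.mean) / self.sd
        return truncnorm.rvs(
            a, np.inf, loc=self.mean, scale=self.sd, size=size, random_state=rng
        )


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid in minutes: ``start, start+step, ..., <=stop``."""

    start: float = 0.0
    stop: float = 60.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.stop <= self.start or self.step <= 0:
            raise ValueError(f"invalid time grid {self}")

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)


def generate_curve(
    model_id: str,
    time_grid,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    blood: BloodParams | None = None,
    tissue: TissueParams | None = None,
    csf: CSFParams | None = None,
) -> ConcentrationCurve:
    """Forward-model curve plus additive zero-mean Gaussian noise.

    ``model_id`` is one of ``aif, blood, ees, ies, tissue, csfif, csf``;
    the parameter sets it requires must be supplied as keywords.  With
    ``noise_sd=0`` the output is exactly the noiseless model curve; a
    fixed seed makes the noisy output reproducible.
    """
    if model_id not in _MODEL_FNS:
        raise ValueError(
            f"unknown model_id {model_id!r}; expected one of {sorted(_MODEL_FNS)}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ts = time_grid.times if isinstance(time_grid, TimeGrid) else np.asarray(time_grid, float)
    needs = {
        "aif": ("blood",), "blood": ("blood",),
        "ees": ("blood", "tissue"), "ies": ("blood", "tissue"),
        "tissue": ("blood", "tissue"),
        "csfif": ("csf",), "csf": ("blood", "csf"),
    }[model_id]
    supplied = {"blood": blood, "tissue": tissue, "csf": csf}
    for name in needs:
        if supplied[name] is None:
            raise ValueError(f"model {model_id!r} requires {name} parameters")
    values = np.asarray(_MODEL_FNS[model_id](ts, blood=blood, tissue=tissue, csf=csf))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return ConcentrationCurve(times=ts, values=values)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic multi-stage, multi-region CSF cohort.

    ``stages`` maps stage label → region label → parameter name →
    :class:`Dist` for the CSF-voxel parameters ``k_in_prime``,
    ``k_out_prime`` and ``v_blood``.  Per-subject blood-pool parameters
    are drawn from ``blood_c_in`` / ``blood_k_out``; every subject also
    yields a blood-ROI curve (region label ``"blood"``) so the two-stage
    fit can run end to end.
    """

    stages: Mapping[str, Mapping[str, Mapping[str, Dist]]]
    control_stage: str = "control"
    n_per_stage: int = 20
    noise_sd: float = 0.005  # mM
    time_grid: TimeGrid = field(default_factory=TimeGrid)
    blood_c_in: Dist = field(default_factory=lambda: Dist(0.069, 0.013))
    blood_k_out: Dist = field(default_factory=lambda: Dist(0.031, 0.0016))
    hct: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_stage < 1:
            raise ValueError("n_per_stage must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.control_stage not in self.stages:
            raise ValueError(
                f"control stage {self.control_stage!r} missing from stages"
            )
        for stage, regions in self.stages.items():
            for region, params in regions.items():
                missing = {"k_in_prime", "k_out_prime", "v_blood"} - set(params)
                if missing:
                    raise ValueError(
                        f"stage {stage!r} region {region!r} lacks {sorted(missing)}"
                    )


@dataclass(frozen=True)
class CohortData:
    """Generated cohort: per-subject truth table and measured curves.

    ``truth`` has one row per (subject, region) with the generating CSF
    parameters and stage; ``blood_truth`` one row per subject;
    ``curves`` is a list of ``(subject, region, ConcentrationCurve)``
    including a ``"blood"`` ROI curve per subject.
    """

    truth: pd.DataFrame
    blood_truth: pd.DataFrame
    curves: list[tuple[str, str, ConcentrationCurve]]


def default_cohort_spec(
    n_per_stage: int = 20,
    noise_sd: float = 0.005,
    k_in_scale: Mapping[str, float] | None = None,
    k_out_scale: Mapping[str, float] | None = None,
    regions: tuple[str, ...] = ("lateral_ventricle", "aqueduct", "fourth_ventricle"),
    seed: int = 0,
) -> CohortSpec:
    """Three-stage (control/mild/severe) cohort with equal-mean stages.

    ``k_in_scale`` / ``k_out_scale`` multiply the corresponding rate mean
    per non-control stage (e.g. ``{"mild": 2.0}`` doubles the mild-stage
    filtration rate, driving that stage's expected IOF to 2).
    """
    k_in_scale = dict(k_in_scale or {})
    k_out_scale = dict(k_out_scale or {})
    base = {
        "k_in_prime": (0.06, 0.012),  # mM/min
        "k_out_prime": (0.05, 0.005),  # 1/min
        "v_blood": (0.13, 0.02),
    }
    stages = {}
    for stage in ("control", "mild", "severe"):
        fin = k_in_scale.get(stage, 1.0)
        fout = k_out_scale.get(stage, 1.0)
        stages[stage] = {
            region: {
                "k_in_prime": Dist(base["k_in_prime"][0] * fin, base["k_in_prime"][1] * fin),
                "k_out_prime": Dist(base["k_out_prime"][0] * fout, base["k_out_prime"][1] * fout),
                "v_blood": Dist(*base["v_blood"]),
            }
            for region in regions
        }
    return CohortSpec(
        stages=stages, n_per_stage=n_per_stage, noise_sd=noise_sd, seed=seed
    )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> CohortData:
    """Draw a cohort and synthesize all measured curves.

    Subject-level parameters come from the spec's truncated normals; each
    subject contributes one blood-ROI curve and one CSF-voxel curve per
    region, all with additive Gaussian noise of sd ``spec.noise_sd``.
    ``seed`` overrides ``spec.seed`` when given.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    truth_rows = []
    blood_rows = []
    curves: list[tuple[str, str, ConcentrationCurve]] = []
    ts = spec.time_grid.times
    idx = 0
    for stage in spec.stages:
        for i in range(spec.n_per_stage):
            subject = f"s{idx:04d}"
            idx += 1
            blood = BloodParams(
                c_in=float(spec.blood_c_in.sample(rng)),
                k_out=float(spec.blood_k_out.sample(rng)),
                hct=spec.hct,
            )
            blood_rows.append(
                {"subject": subject, "stage": stage,
                 "c_in": blood.c_in, "k_out": blood.k_out, "hct": blood.hct}
            )
            vals = np.asarray(blood_concentration(ts, blood))
            if spec.noise_sd > 0:
                vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
            curves.append((subject, "blood", ConcentrationCurve(ts, vals)))
            for region, dists in spec.stages[stage].items():
                v_blood = float(np.clip(dists["v_blood"].sample(rng), 0.0, 1.0))
                csf = CSFParams(
                    k_in_prime=float(dists["k_in_prime"].sample(rng)),
                    k_out_prime=float(dists["k_out_prime"].sample(rng)),
                    v_blood=v_blood,
                    v_csf=1.0 - v_blood,
                )
                truth_rows.append(
                    {"subject": subject, "region": region, "stage": stage,
                     "k_in_prime": csf.k_in_prime,
                     "k_out_prime": csf.k_out_prime,
                     "v_blood": csf.v_blood}
                )
                vals = np.asarray(csf_voxel_concentration(ts, csf, blood))
                if spec.noise_sd > 0:
                    vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
                curves.append((subject, region, ConcentrationCurve(ts, vals)))
    return CohortData(
        truth=pd.DataFrame(truth_rows),
        blood_truth=pd.DataFrame(blood_rows),
        curves=curves,
    )


# --------------------------------------------------------------------------
# 4D phantoms
# --------------------------------------------------------------------------

CLASS_CODES = {"background": 0, "blood": 1, "tissue": 2, "csf": 3}


@dataclass(frozen=True)
class PhantomLayout:
    """Voxel-class map plus the parameter set of each present class.

    ``class_map`` is a 3-d integer array using :data:`CLASS_CODES`
    (0 background, 1 blood, 2 tissue, 3 CSF).  Parameter sets are
    required only for the classes that actually occur.
    """

    class_map: np.ndarray
    blood: BloodParams | None = None
    tissue: TissueParams | None = None
    csf: CSFParams | None = None

    def __post_init__(self) -> None:
        cm = np.asarray(self.class_map)
        if cm.ndim != 3:
            raise ValueError("class_map must be 3-dimensional")
        codes = set(np.unique(cm).tolist())
        if not codes <= set(CLASS_CODES.values()):
            raise ValueError(f"unknown class codes {codes - set(CLASS_CODES.values())}")
        if (1 in codes or 2 in codes or 3 in codes) and self.blood is None:
            raise ValueError("blood parameters required for non-background voxels")
        if 2 in codes and self.tissue is None:
            raise ValueError("tissue parameters required for tissue voxels")
        if 3 in codes and self.csf is None:
            raise ValueError("csf parameters required for CSF voxels")
        object.__setattr__(self, "class_map", cm.astype(np.int8))


_TRUTH_PARAMS = {
    2: ("k_trans", "k_ep", "k_pi", "k_ip", "v_blood", "v_ees", "v_ies", "v_now"),
    3: ("k_in_prime", "k_out_prime", "v_blood", "v_csf"),
}


def generate_phantom(
    layout: PhantomLayout,
    time_grid,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Synthesize a 4D concentration image and per-parameter truth maps.

    Returns ``(image, truth)`` where ``image`` has shape
    ``class_map.shape + (n_times,)`` and ``truth`` maps each kinetic
    parameter name to a 3-d array (zero in voxels where it does not
    apply).  Background voxels are identically zero before noise.
    """
    ts = time_grid.times if isinstance(time_grid, TimeGrid) else np.asarray(time_grid, float)
    cm = layout.class_map
    img = np.zeros(cm.shape + (ts.size,), dtype=float)
    series = {
        1: None if layout.blood is None else np.asarray(blood_concentration(ts, layout.blood)),
        2: None if layout.tissue is None else np.asarray(
            tissue_concentration(ts, layout.tissue, layout.blood)
        ),
        3: None if layout.csf is None else np.asarray(
            csf_voxel_concentration(ts, layout.csf, layout.blood)
        ),
    }
    for code, curve in series.items():
        if curve is not None:
            img[cm == code] = curve
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    truth: dict[str, np.ndarray] = {}
    for code, names in _TRUTH_PARAMS.items():
        src = layout.tissue if code == 2 else layout.csf
        if src is None:
            continue
        for name in names:
            truth.setdefault(name, np.zeros(cm.shape))
            truth[name][cm == code] = getattr(src, name)
    return img, truth
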