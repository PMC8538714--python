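"""Virtual patients and synthetic three-stream concentration datasets.

The generator emulates the design of the observational study the model
was built on: two groups (6 patients with acute-on-chronic liver failure,
9 without liver failure) on continuous RRT, weight-based q12h dosing
(6 mg/kg twice as loading, then 4 mg/kg) given as 30-min infusions, and
sampling of pre-filter, post-filter and effluent streams at
0, 1, 2, 4, 6, 8, 12, 24, 25, 48 and 49 h after the first monitored dose.

Random effects follow the standard pharmacometric conventions:
log-normal interindividual variability on the six structural parameters,
log-normal interoccasion variability on body clearance (one occasion per
dosing interval), and proportional residual error per stream.  The two
groups are exchangeable by construction unless an explicit group effect
on body clearance is injected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    IIV_PARAMS,
    DoseEvent,
    PopulationParameters,
    RealizedParams,
    predict_streams,
    simulate_cohort,
)
from .rrt import RRTSettings

__all__ = [
    "StudyDesign",
    "VirtualPatient",
    "Population",
    "cv_to_variance",
    "draw_population",
    "draw_weights",
    "generate_dataset",
    "STREAMS",
]

log = logging.getLogger(__name__)

STREAMS = ("pre", "post", "effluent")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling/dosing layout of one synthetic study."""

    n_aclf: int = 6
    n_nlf: int = 9
    sampling_times: tuple = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 25.0, 48.0, 49.0)
    streams: tuple = STREAMS
    loading_mg_kg: float = 6.0
    maintenance_mg_kg: float = 4.0
    n_loading: int = 2
    tau_h: float = 12.0
    infusion_h: float = 0.5
    horizon_h: float = 49.0
    occasion_h: float = 12.0
    weight_median_kg: float = 80.0
    weight_cv: float = 20.0
    weight_bounds: tuple = (40.0, 150.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_times)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be non-negative and strictly increasing")

    @property
    def n_total(self) -> int:
        return self.n_aclf + self.n_nlf

    @property
    def n_occasions(self) -> int:
        return max(1, int(np.ceil(self.horizon_h / self.occasion_h)))

    def dose_events(self, weights: np.ndarray, *, bolus: bool = False) -> list[DoseEvent]:
        """Weight-based q12h schedule over the design horizon."""
        weights = np.asarray(weights, dtype=float)
        events = []
        k = 0
        t = 0.0
        while t < self.horizon_h:
            mg_kg = self.loading_mg_kg if k < self.n_loading else self.maintenance_mg_kg
            events.append(DoseEvent(t, mg_kg * weights, 0.0 if bolus else self.infusion_h))
            k += 1
            t += self.tau_h
        return events


@dataclass(frozen=True)
class VirtualPatient:
    id: str
    group: str  # "ACLF" | "NLF"
    weight: float
    eta: dict
    kappa: np.ndarray  # per-occasion IOV deviates on CL_body, log scale
    params: dict  # realized individual parameters

    def __post_init__(self) -> None:
        if any(v <= 0 for k, v in self.params.items() if k != "f_ads"):
            raise ValueError("realized parameters must be positive")
        if not 0.0 <= self.params["f_ads"] <= 1.0:
            raise ValueError("realized f_ads must lie in [0, 1]")


@dataclass
class Population:
    """A drawn cohort, both as patient records and as simulation-ready arrays."""

    patients: list
    weights: np.ndarray
    params: RealizedParams
    iov_mult: np.ndarray  # (n, n_occasions), exp(kappa)
    groups: np.ndarray
    ids: np.ndarray

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": p.id, "group": p.group, "weight_kg": p.weight, **p.params} for p in self]
        return pd.DataFrame(rows)


def cv_to_variance(cv_percent: float) -> float:
    """Log-normal variance matching a coefficient of variation in percent.

    omega^2 = ln(1 + (cv/100)^2); small CVs give omega ~ cv/100.
    """
    if cv_percent < 0:
        raise ValueError("cv must be >= 0")
    return float(np.log1p((cv_percent / 100.0) ** 2))


def draw_weights(n: int, design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    """Log-normal body weights (median/CV from the design), truncated by resampling."""
    sigma = np.sqrt(cv_to_variance(design.weight_cv))
    mu = np.log(design.weight_median_kg)
    lo, hi = design.weight_bounds
    if not lo < design.weight_median_kg < hi:
        raise ValueError("weight bounds must bracket the median")
    w = rng.lognormal(mu, sigma, size=n)
    for _ in range(1000):
        bad = (w < lo) | (w > hi)
        if not bad.any():
            return w
        w[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
    raise RuntimeError("weight truncation failed to converge")


def draw_population(
    n: int,
    params: PopulationParameters,
    design: StudyDesign | None = None,
    seed: int | np.random.Generator = 0,
    *,
    n_occasions: int | None = None,
    include_iiv: bool = True,
    include_iov: bool = True,
    group_effect_cl_body: float = 1.0,
    groups: Sequence[str] | None = None,
) -> Population:
    """Draw ``n`` virtual patients.

    Parameters are realized as typical * exp(eta) with independent
    log-normal eta per structural parameter; body clearance additionally
    carries exp(kappa) per dosing occasion.  Adsorption-fraction draws
    above 1 are rejected and resampled.  ``group_effect_cl_body``
    multiplies CL_body in the ACLF group (1.0 = the null the study
    reported).  Reproducible: the same seed yields the identical cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    design = design or StudyDesign()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_occ = n_occasions if n_occasions is not None else design.n_occasions

    if groups is None:
        n_aclf = round(n * design.n_aclf / design.n_total)
        groups = np.array(["ACLF"] * n_aclf + ["NLF"] * (n - n_aclf))
    else:
        groups = np.asarray(groups)
        if groups.size != n:
            raise ValueError("groups must have length n")

    weights = draw_weights(n, design, rng)
    etas = {}
    for name in IIV_PARAMS:
        omega2 = cv_to_variance(params.iiv_cv.get(name, 0.0)) if include_iiv else 0.0
        etas[name] = rng.normal(0.0, np.sqrt(omega2), size=n) if omega2 > 0 else np.zeros(n)
    omega2_iov = cv_to_variance(params.iov_cv_cl_body) if include_iov else 0.0
    kappa = (
        rng.normal(0.0, np.sqrt(omega2_iov), size=(n, n_occ))
        if omega2_iov > 0
        else np.zeros((n, n_occ))
    )

    typ = {name: getattr(params, name) for name in IIV_PARAMS}
    realized = {name: typ[name] * np.exp(etas[name]) for name in IIV_PARAMS}
    # reject and resample adsorption fractions above 1 (a fraction cannot exceed unity)
    omega_fads = np.sqrt(cv_to_variance(params.iiv_cv.get("f_ads", 0.0))) if include_iiv else 0.0
    if params.f_ads >= 1.0 and omega_fads > 0:
        raise ValueError("typical f_ads at 1 with variability cannot be truncated below 1")
    for _ in range(1000):
        bad = realized["f_ads"] > 1.0
        if not bad.any():
            break
        etas["f_ads"][bad] = rng.normal(0.0, omega_fads, size=int(bad.sum()))
        realized["f_ads"] = typ["f_ads"] * np.exp(etas["f_ads"])
    else:
        raise RuntimeError("f_ads rejection sampling failed to converge")

    if group_effect_cl_body != 1.0:
        realized["cl_body"] = realized["cl_body"] * np.where(
            groups == "ACLF", group_effect_cl_body, 1.0
        )

    rp = RealizedParams(ads_max=params.ads_max, **realized)
    ids = np.array([f"S{i + 1:03d}" for i in range(n)])
    patients = [
        VirtualPatient(
            id=ids[i],
            group=str(groups[i]),
            weight=float(weights[i]),
            eta={k: float(etas[k][i]) for k in IIV_PARAMS},
            kappa=kappa[i].copy(),
            params={k: float(realized[k][i]) for k in IIV_PARAMS},
        )
        for i in range(n)
    ]
    return Population(
        patients=patients,
        weights=weights,
        params=rp,
        iov_mult=np.exp(kappa),
        groups=np.asarray(groups),
        ids=ids,
    )


def generate_dataset(
    population: Population,
    params: PopulationParameters,
    rrt: RRTSettings,
    design: StudyDesign | None = None,
    seed: int | np.random.Generator = 0,
    *,
    include_ruv: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the study design and emit a long observation table.

    Observations are ``predicted * (1 + eps)`` with stream-specific
    proportional error; negative draws are truncated at zero and counted.
    Returns the table (columns id, group, time_h, stream, conc_mg_L) and a
    manifest dictionary (seed-independent design description plus the
    truncation count) sufficient to regenerate the data.
    """
    design = design or StudyDesign()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    doses = design.dose_events(population.weights)
    traj = simulate_cohort(
        population.params,
        doses,
        design.horizon_h,
        design.sampling_times,
        iov_mult=population.iov_mult,
        occasion_h=design.occasion_h,
    )
    c_pre, c_post, c_effl = predict_streams(traj, rrt, params.rbctp)
    preds = {"pre": c_pre, "post": c_post, "effluent": c_effl}

    frames = []
    n_truncated = 0
    for stream in design.streams:
        cv = params.ruv_prop.get(stream, 0.0) / 100.0
        pred = preds[stream]
        eps = rng.normal(0.0, cv, size=pred.shape) if include_ruv and cv > 0 else np.zeros_like(pred)
        obs = pred * (1.0 + eps)
        neg = obs < 0
        n_truncated += int(neg.sum())
        obs = np.where(neg, 0.0, obs)
        frames.append(
            pd.DataFrame(
                {
                    "id": np.repeat(population.ids, traj.times.size),
                    "group": np.repeat(population.groups, traj.times.size),
                    "time_h": np.tile(traj.times, len(population)),
                    "stream": stream,
                    "conc_mg_L": obs.ravel(),
                }
            )
        )
    if n_truncated:
        log.warning("truncated %d negative observation(s) at zero", n_truncated)
    table = pd.concat(frames, ignore_index=True).sort_values(
        ["id", "time_h", "stream"], kind="stable"
    ).reset_index(drop=True)

    manifest = {
        "design": {
            "n_aclf": design.n_aclf,
            "n_nlf": design.n_nlf,
            "sampling_times": list(map(float, design.sampling_times)),
            "loading_mg_kg": design.loading_mg_kg,
            "maintenance_mg_kg": design.maintenance_mg_kg,
            "n_loading": design.n_loading,
            "tau_h": design.tau_h,
            "infusion_h": design.infusion_h,
            "horizon_h": design.horizon_h,
            "occasion_h": design.occasion_h,
        },
        "rrt": {
            "q_blood": rrt.q_blood, "q_dial": rrt.q_dial, "q_rf_pre": rrt.q_rf_pre,
            "q_frr": rrt.q_frr, "hct": rrt.hct, "modality": rrt.modality,
        },
        "parameters": {k: float(getattr(params, k)) for k in
                       ("cl_body", "v1", "q", "v2", "cl_rrt", "f_ads", "ads_max", "rbctp")},
        "ruv_prop": dict(params.ruv_prop),
        "weights_kg": {str(i): float(w) for i, w in zip(population.ids, population.weights)},
        "n_truncated": n_truncated,
    }
    return table, manifest
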