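"""Filter-side clearance arithmetic for continuous renal replacement therapy.

Two independent estimators of the extracorporeal clearance of a drug are
available at the bedside: one from the concentration drop across the
hemofilter (pre- vs. post-filter plasma), one from the amount appearing in
the effluent.  For a drug that is only removed by diffusion/convection the
two agree; a persistent gap between them is the signature of adsorption
onto the filter membrane.

All flows are litres per hour, all concentrations mg/L.  Helpers here are
deliberately scalar-or-array polymorphic (plain numpy ufunc arithmetic) so
they can be applied to whole observation tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RRTSettings",
    "FilterConcentrations",
    "adjusted_blood_flow",
    "prepost_clearance",
    "correct_postfilter",
    "effluent_flow",
    "effluent_clearance",
    "saturation_coefficient",
    "clearance_table",
]

log = logging.getLogger(__name__)


class DomainError(ValueError):
    """An input is outside the physical domain of an estimator."""


@dataclass(frozen=True)
class RRTSettings:
    """Machine settings of one continuous RRT prescription.

    Parameters
    ----------
    q_blood : blood flow through the circuit, L/h.
    q_dial : dialysate flow, L/h (CVVHD route).
    q_rf_pre : pre-filter replacement fluid flow, L/h (CVVH route).
    q_frr : net fluid removal rate, L/h.
    hct : hematocrit as a fraction in [0, 0.7].
    modality : "CVVHD", "CVVH" or "none".
    """

    q_blood: float = 6.0
    q_dial: float = 2.4
    q_rf_pre: float = 0.0
    q_frr: float = 0.1
    hct: float = 0.30
    modality: str = "CVVHD"

    def __post_init__(self) -> None:
        for name in ("q_blood", "q_dial", "q_rf_pre", "q_frr"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.hct <= 0.7:
            raise DomainError(f"hct must lie in [0, 0.7], got {self.hct}")
        if self.q_frr >= self.q_blood > 0:
            raise DomainError(
                f"fluid removal q_frr={self.q_frr} must be below blood flow q_blood={self.q_blood}"
            )
        if self.modality not in ("CVVHD", "CVVH", "none"):
            raise DomainError(f"unknown modality {self.modality!r}")

    def q_blood_adjusted(self, rbctp: float) -> float:
        """Drug-carrying blood flow given the red-cell-to-plasma ratio."""
        return adjusted_blood_flow(self.q_blood, self.hct, rbctp)

    @property
    def q_effluent(self) -> float:
        return effluent_flow(self.q_dial, self.q_rf_pre, self.q_frr)


@dataclass(frozen=True)
class FilterConcentrations:
    """One paired sampling of the three circuit streams, mg/L."""

    c_pre: float
    c_post: float
    c_effl: float
    flagged: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        for name in ("c_pre", "c_post", "c_effl"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        # C_post > C_pre is physically odd for a cleared drug, but it is
        # data (assay noise), not an error: flag, keep.
        if self.c_post > self.c_pre:
            object.__setattr__(self, "flagged", True)
            log.warning(
                "post-filter concentration %.3g exceeds pre-filter %.3g", self.c_post, self.c_pre
            )


def _require_nonneg(**kwargs):
    for name, value in kwargs.items():
        if np.any(np.asarray(value) < 0):
            raise DomainError(f"{name} must be >= 0")


def adjusted_blood_flow(q_blood, hct, rbctp):
    """Blood flow corrected for the drug carried inside red cells.

    ``Q_blood * (1 - Hct + Hct * RBCtP)``: plasma fraction plus cell
    fraction weighted by the red-cell-to-plasma concentration ratio.
    Identity when RBCtP = 1 or Hct = 0.
    """
    _require_nonneg(q_blood=q_blood, rbctp=rbctp)
    if np.any(np.asarray(hct) < 0) or np.any(np.asarray(hct) >= 1):
        raise DomainError("hct must lie in [0, 1)")
    return q_blood * (1.0 - hct + hct * rbctp)


def prepost_clearance(q_blood_adj, c_pre, c_post_corr):
    """Clearance from the concentration drop across the filter.

    ``Q_blood_adj * (C_pre - C_post) / C_pre`` — adjusted flow times the
    extraction ratio.  ``c_post_corr`` should already be corrected for
    hemoconcentration (see :func:`correct_postfilter`).
    """
    if np.any(np.asarray(c_pre) <= 0):
        raise DomainError("c_pre must be > 0 (extraction undefined)")
    _require_nonneg(q_blood_adj=q_blood_adj, c_post_corr=c_post_corr)
    return q_blood_adj * (c_pre - c_post_corr) / c_pre


def correct_postfilter(c_post_meas, q_blood_adj, q_frr):
    """Remove the hemoconcentration bias from a measured post-filter level.

    Net fluid removal concentrates the blood leaving the filter; the
    measured concentration is scaled by ``(Q_blood_adj - Q_FRR) / Q_blood_adj``
    to what it would be at the inlet flow.
    """
    _require_nonneg(c_post_meas=c_post_meas, q_frr=q_frr)
    if np.any(np.asarray(q_blood_adj) <= 0):
        raise DomainError("q_blood_adj must be > 0")
    if np.any(np.asarray(q_frr) >= np.asarray(q_blood_adj)):
        raise DomainError("q_frr must be below q_blood_adj")
    return c_post_meas * (q_blood_adj - q_frr) / q_blood_adj


def effluent_flow(q_dial, q_rf_pre, q_frr):
    """Total effluent flow: dialysate + pre-filter replacement + fluid removal."""
    _require_nonneg(q_dial=q_dial, q_rf_pre=q_rf_pre, q_frr=q_frr)
    return q_dial + q_rf_pre + q_frr


def effluent_clearance(q_effl, c_effl, c_pre):
    """Clearance from drug recovery in the effluent: ``Q_effl * C_effl / C_pre``."""
    if np.any(np.asarray(c_pre) <= 0):
        raise DomainError("c_pre must be > 0")
    _require_nonneg(q_effl=q_effl, c_effl=c_effl)
    return q_effl * c_effl / c_pre


def saturation_coefficient(c_effl, c_pre):
    """Effluent-to-plasma concentration ratio S_eff (sieving analogue).

    Values above 1 are physically implausible for a partially
    protein-bound drug and are flagged via a warning, not rejected.
    """
    if np.any(np.asarray(c_pre) <= 0):
        raise DomainError("c_pre must be > 0")
    _require_nonneg(c_effl=c_effl)
    s = np.asarray(c_effl) / np.asarray(c_pre)
    if np.any(s > 1.0):
        log.warning("saturation coefficient > 1 encountered (max %.3g)", float(np.max(s)))
    return s if s.ndim else float(s)


def clearance_table(obs: pd.DataFrame, settings: dict[str, RRTSettings], rbctp: float) -> pd.DataFrame:
    """Per-subject, per-timepoint clearance estimates from a long observation table.

    ``obs`` must hold columns id, time_h, stream, conc_mg_L with streams
    "pre", "post", "effluent".  Timepoints missing a positive pre-filter
    concentration are dropped with a warning (clearance undefined there).

    Returns a frame with both clearance estimates, their gap (the
    adsorption signal) and the saturation coefficient.
    """
    wide = obs.pivot_table(index=["id", "time_h"], columns="stream", values="conc_mg_L").reset_index()
    missing = [s for s in ("pre", "post", "effluent") if s not in wide.columns]
    if missing:
        raise DomainError(f"observation table lacks stream(s): {missing}")
    bad = ~(wide["pre"] > 0)
    if bad.any():
        log.warning("dropping %d record(s) with non-positive pre-filter concentration", int(bad.sum()))
        wide = wide[~bad].copy()

    rows = []
    for sid, grp in wide.groupby("id", sort=False):
        rrt = settings[str(sid)] if str(sid) in settings else settings[sid]
        qba = rrt.q_blood_adjusted(rbctp)
        c_post_corr = correct_postfilter(grp["post"].to_numpy(), qba, rrt.q_frr)
        cl_pp = prepost_clearance(qba, grp["pre"].to_numpy(), c_post_corr)
        cl_eff = effluent_clearance(rrt.q_effluent, grp["effluent"].to_numpy(), grp["pre"].to_numpy())
        rows.append(
            pd.DataFrame(
                {
                    "id": sid,
                    "time_h": grp["time_h"].to_numpy(),
                    "cl_prepost_L_h": cl_pp,
                    "cl_effluent_L_h": cl_eff,
                    "cl_adsorption_gap_L_h": cl_pp - cl_eff,
                    "s_eff": grp["effluent"].to_numpy() / grp["pre"].to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
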