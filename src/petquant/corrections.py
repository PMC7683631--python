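"""Lesion-level uptake corrections.

Implements the correction chain applied to each segmented lesion's uptake
metrics, in this fixed order:

1. peak fallback (SUV_peak := SUV_mean for lesions smaller than the peak VOI),
2. recovery-coefficient lookup by lesion volume and partial-volume correction
   (PVEC) per statistic:  SUV_pvec = SUV/RC - SUV_bg * (1/RC - 1),
3. ratio metrics from the PVE-corrected values: tumor-to-liver SUVTLR and
   tumor-to-blood SUR,
4. uptake-time normalization of SUR and SUV to the standard time T0 = 60 min:

       SUR_0 = (T0/T) (SUR_T - V_r) + V_r       ~  SUR_T * T0/T
       SUV_0 = SUV_T (SUR_0/SUR_T) (T0/T)^-b    ~  SUV_T * (T0/T)^(1-b)

   with apparent volume of distribution V_r = 0.53 and b = 0.313.  The
   approximate forms (right) are the default; the exact affine forms are
   available via ``mode="exact"``.

PVEC inverts the forward attenuation model measured = RC*true + (1-RC)*bg
exactly.  A PVE-corrected value that comes out non-positive (local background
exceeding the lesion signal at small RC) is flagged, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .rc_model import RCCurve, STATISTICS

#: Correction variants emitted by :func:`correct_cohort`, keyed by column prefix.
METRIC_FAMILIES = (
    "suv",
    "suv_pvec",
    "suvtlr_pvec",
    "suv_pvec_time",
    "sur_time",
    "sur_pvec_time",
)


@dataclass(frozen=True)
class UptakeCorrectionParams:
    """Parameters of the tumor-to-blood uptake-time normalization.

    ``vr`` is the apparent volume of distribution (the asymptotic
    blood-normalized uptake offset) and ``b`` the power-law exponent of the
    blood SUV decay; defaults are the published population values.
    """

    t0_min: float = 60.0
    vr: float = 0.53
    b: float = 0.313

    def __post_init__(self) -> None:
        if not self.t0_min > 0:
            raise ValueError("T0 must be positive")
        if self.vr < 0:
            raise ValueError("V_r must be >= 0")
        if not 0 <= self.b < 1:
            raise ValueError("b must lie in [0, 1)")


def pvec(suv_stat, rc, suv_bg_local):
    """Partial-volume-corrected SUV: suv/rc - bg*(1/rc - 1).

    The same formula serves mean, peak and max, each with its
    statistic-matched recovery coefficient.
    """
    rc = np.asarray(rc, dtype=float)
    if np.any(rc <= 0):
        raise ValueError("recovery coefficient must be positive")
    return np.asarray(suv_stat, dtype=float) / rc - np.asarray(suv_bg_local, dtype=float) * (
        1.0 / rc - 1.0
    )


def suvtlr(suv_pvec_value, suv_liver_mean):
    """Tumor-to-liver ratio of the PVE-corrected lesion SUV."""
    liver = np.asarray(suv_liver_mean, dtype=float)
    if np.any(liver <= 0):
        raise ValueError("mean liver SUV must be positive")
    return np.asarray(suv_pvec_value, dtype=float) / liver


def sur(suv_stat, suv_blood_mean):
    """Tumor-to-blood standard uptake ratio.

    Being a ratio of SUVs, SUR cancels any common multiplicative
    miscalibration (injected activity, residual activity, weight, scanner
    calibration) between lesion and blood.
    """
    blood = np.asarray(suv_blood_mean, dtype=float)
    if np.any(blood <= 0):
        raise ValueError("mean blood SUV must be positive")
    return np.asarray(suv_stat, dtype=float) / blood


def time_correct_sur(sur_t, t_min, params: UptakeCorrectionParams = UptakeCorrectionParams(),
                     mode: str = "approx"):
    """Normalize a SUR measured at uptake time ``t_min`` to T0.

    ``exact`` applies the affine form (T0/T)(SUR_T - V_r) + V_r, which has
    V_r as a fixed point; ``approx`` the plain ratio SUR_T * T0/T.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t <= 0):
        raise ValueError("uptake time must be positive")
    sur_t = np.asarray(sur_t, dtype=float)
    ratio = params.t0_min / t
    if mode == "exact":
        return ratio * (sur_t - params.vr) + params.vr
    if mode == "approx":
        return sur_t * ratio
    raise ValueError(f"unknown mode {mode!r}; expected 'exact' or 'approx'")


def time_correct_suv(suv_t, t_min, params: UptakeCorrectionParams = UptakeCorrectionParams(),
                     mode: str = "approx", sur_t=None):
    """Normalize an SUV measured at uptake time ``t_min`` to T0.

    ``approx`` is the power law SUV_T * (T0/T)^(1-b).  ``exact`` consumes the
    lesion's SUR at time T and applies SUV_T (SUR_0/SUR_T)(T0/T)^-b with
    SUR_0 from the exact SUR correction.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t <= 0):
        raise ValueError("uptake time must be positive")
    suv_t = np.asarray(suv_t, dtype=float)
    ratio = params.t0_min / t
    if mode == "approx":
        return suv_t * ratio ** (1.0 - params.b)
    if mode == "exact":
        if sur_t is None:
            raise ValueError("exact SUV time correction requires sur_t")
        sur_t = np.asarray(sur_t, dtype=float)
        if np.any(sur_t <= 0):
            raise ValueError("sur_t must be positive in exact mode")
        sur_0 = time_correct_sur(sur_t, t, params, mode="exact")
        return suv_t * (sur_0 / sur_t) * ratio ** (-params.b)
    raise ValueError(f"unknown mode {mode!r}; expected 'exact' or 'approx'")


def peak_fallback(df: pd.DataFrame, peak_voi_ml: float = 1.0) -> pd.DataFrame:
    """Substitute SUV_mean for SUV_peak where the lesion is smaller than the peak VOI.

    Returns a copy with ``suv_peak`` replaced where ``volume_ml < peak_voi_ml``
    and a boolean ``peak_substituted`` column recording the substitution.
    """
    out = df.copy()
    small = out["volume_ml"] < peak_voi_ml
    out["peak_substituted"] = small
    out.loc[small, "suv_peak"] = out.loc[small, "suv_mean"]
    return out


REQUIRED_COLUMNS = (
    "volume_ml",
    "suv_mean",
    "suv_peak",
    "suv_max",
    "suv_bg_local",
    "suv_liver_mean",
    "suv_blood_mean",
    "uptake_time_min",
)

_FAMILY_REQUIREMENTS: Mapping[str, tuple[str, ...]] = {
    "suv": (),
    "suv_pvec": ("suv_bg_local", "volume_ml"),
    "suvtlr_pvec": ("suv_bg_local", "volume_ml", "suv_liver_mean"),
    "suv_pvec_time": ("suv_bg_local", "volume_ml", "uptake_time_min"),
    "sur_time": ("suv_blood_mean", "uptake_time_min"),
    "sur_pvec_time": ("suv_bg_local", "volume_ml", "suv_blood_mean", "uptake_time_min"),
}


def correct_cohort(
    cohort: pd.DataFrame,
    rc_curves: Mapping[str, RCCurve],
    params: UptakeCorrectionParams = UptakeCorrectionParams(),
    time_mode: str = "approx",
    peak_voi_ml: float = 1.0,
    families: tuple[str, ...] = METRIC_FAMILIES,
) -> pd.DataFrame:
    """Apply the full correction chain to a lesion table.

    Emits one wide row per input lesion with columns ``{family}_{statistic}``
    for every requested metric family, plus ``pvec_implausible_{statistic}``
    flags where the PVE-corrected value is non-positive.  A family whose
    required inputs are missing raises a ``KeyError`` naming the columns.
    """
    unknown = set(families) - set(METRIC_FAMILIES)
    if unknown:
        raise ValueError(f"unknown metric families: {sorted(unknown)}")
    for fam in families:
        missing = [c for c in _FAMILY_REQUIREMENTS[fam] if c not in cohort.columns]
        if missing:
            raise KeyError(f"family {fam!r} requires missing column(s): {missing}")
    for col in ("suv_mean", "suv_peak", "suv_max", "volume_ml"):
        if col not in cohort.columns:
            raise KeyError(f"cohort table lacks required column {col!r}")

    df = peak_fallback(cohort, peak_voi_ml=peak_voi_ml)
    out = df.copy()

    needs_pvec = any(f in families for f in ("suv_pvec", "suvtlr_pvec", "suv_pvec_time",
                                             "sur_pvec_time"))
    pvec_vals: dict[str, np.ndarray] = {}
    if needs_pvec:
        for stat in STATISTICS:
            if stat not in rc_curves:
                raise KeyError(f"no RC curve provided for statistic {stat!r}")
            rc = rc_curves[stat](df["volume_ml"].to_numpy())
            out[f"rc_{stat}"] = rc
            corrected = pvec(df[f"suv_{stat}"].to_numpy(), rc, df["suv_bg_local"].to_numpy())
            pvec_vals[stat] = corrected
            out[f"pvec_implausible_{stat}"] = corrected <= 0

    t = df["uptake_time_min"].to_numpy() if "uptake_time_min" in df.columns else None

    for stat in STATISTICS:
        raw = df[f"suv_{stat}"].to_numpy()
        if "suv" in families:
            out[f"suv_{stat}"] = raw
        if "suv_pvec" in families:
            out[f"suv_pvec_{stat}"] = pvec_vals[stat]
        if "suvtlr_pvec" in families:
            out[f"suvtlr_pvec_{stat}"] = suvtlr(pvec_vals[stat], df["suv_liver_mean"].to_numpy())
        if "suv_pvec_time" in families:
            if time_mode == "exact":
                sur_pv = sur(pvec_vals[stat], df["suv_blood_mean"].to_numpy())
                out[f"suv_pvec_time_{stat}"] = time_correct_suv(
                    pvec_vals[stat], t, params, mode="exact", sur_t=sur_pv
                )
            else:
                out[f"suv_pvec_time_{stat}"] = time_correct_suv(
                    pvec_vals[stat], t, params, mode="approx"
                )
        if "sur_time" in families:
            out[f"sur_time_{stat}"] = time_correct_sur(
                sur(raw, df["suv_blood_mean"].to_numpy()), t, params, mode=time_mode
            )
        if "sur_pvec_time" in families:
            out[f"sur_pvec_time_{stat}"] = time_correct_sur(
                sur(pvec_vals[stat], df["suv_blood_mean"].to_numpy()), t, params, mode=time_mode
            )
    return out


def correct_lesion(
    metrics: Mapping[str, float],
    rc_curves: Mapping[str, RCCurve],
    params: UptakeCorrectionParams = UptakeCorrectionParams(),
    **kwargs,
) -> dict[str, float]:
    """Single-lesion convenience wrapper around :func:`correct_cohort`."""
    row = pd.DataFrame([metrics])
    res = correct_cohort(row, rc_curves, params, **kwargs)
    return res.iloc[0].to_dict()
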