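"""Synthetic multi-matrix disposition study generator.

Plasma follows a one-compartment model with first-order oral absorption,
superposed over the once-daily dosing schedule:

    C(t) = sum_{t_i <= t} (D ka) / (V/F (ka - ke)) (e^{-ke (t-t_i)} - e^{-ka (t-t_i)})

Urine and faeces receive fixed fractions of the absorbed dose with an
instantaneous-absorption approximation (valid for ka >> ke); the unabsorbed
fraction transits to faeces with a one-day lag. Hair receives
incorporation_coeff x plasma AUC x lognormal between-animal noise, by
default using the day-7 AUC(0-12 h) so the generating coefficient is on the
same scale as the recovered incorporation degree. Measurements are
internal-standard response ratios with proportional noise plus additive
blank noise; matched calibration sets (15 levels over 0.01-500) and blanks
are generated per substance and matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .design import GROUP_DOSES, MeasurementModel, PKParameters, StudyDesign
from .io import RESPONSE_COLUMNS
from .panel import SubstanceRecord

__all__ = [
    "SyntheticStudy",
    "plasma_concentration",
    "plasma_auc_exact",
    "excretion_interval",
    "simulate_hair",
    "simulate_study",
    "calibration_levels",
]

#: ng/mL per (mg/kg)/(L/kg): mg/L = ug/mL = 1000 ng/mL
_MGKG_TO_NGML = 1000.0


def plasma_concentration(
    params: PKParameters,
    dose_mg_per_kg: float,
    dose_times_h,
    t_h,
) -> np.ndarray | float:
    """Plasma concentration (ng/mL) at time(s) t_h under superposition."""
    if np.isclose(params.ka, params.ke):
        raise ValueError("degenerate ka == ke not supported; perturb one rate")
    t = np.asarray(t_h, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    amp = (
        dose_mg_per_kg * params.ka
        / (params.v_over_f * (params.ka - params.ke))
        * _MGKG_TO_NGML
    )
    conc = np.zeros_like(t)
    for ti in dose_times_h:
        dt = t - ti
        mask = dt >= 0
        conc[mask] += amp * (
            np.exp(-params.ke * dt[mask]) - np.exp(-params.ka * dt[mask])
        )
    return float(conc[0]) if scalar else conc


def plasma_auc_exact(
    params: PKParameters,
    dose_mg_per_kg: float,
    dose_times_h,
    t_start: float,
    t_end: float,
) -> float:
    """Closed-form AUC (ng.h/mL) of the superposed curve over [t_start, t_end]."""
    amp = (
        dose_mg_per_kg * params.ka
        / (params.v_over_f * (params.ka - params.ke))
        * _MGKG_TO_NGML
    )
    auc = 0.0
    for ti in dose_times_h:
        a = max(0.0, t_start - ti)
        b = t_end - ti
        if b <= 0:
            continue
        auc += amp * (
            (np.exp(-params.ke * a) - np.exp(-params.ke * b)) / params.ke
            - (np.exp(-params.ka * a) - np.exp(-params.ka * b)) / params.ka
        )
    return float(auc)


def excretion_interval(
    params: PKParameters,
    dose_schedule: list[tuple[float, float]],
    interval: tuple[float, float],
    matrix: str = "urine",
) -> float:
    """Amount (ng) excreted into a matrix during a collection interval.

    dose_schedule is a list of (time_h, dose_ng). Absorption is treated as
    instantaneous at the dose time; faeces additionally receives the
    unabsorbed fraction of any dose given in (a-24, b-24] (one-day transit).
    """
    a, b = interval
    if not a < b:
        raise ValueError("interval must satisfy a < b")
    if matrix == "urine":
        f_x = params.f_urine
    elif matrix == "faeces":
        f_x = params.f_faeces
    else:
        raise ValueError(f"no excretion model for matrix {matrix!r}")
    amount = 0.0
    for ti, dose_ng in dose_schedule:
        d_abs = params.f_abs * dose_ng
        amount += f_x * d_abs * (
            np.exp(-params.ke * max(0.0, a - ti))
            - np.exp(-params.ke * max(0.0, b - ti))
        )
        if matrix == "faeces" and (a - 24.0) < ti <= (b - 24.0):
            amount += (1.0 - params.f_abs) * dose_ng
    return float(amount)


def simulate_hair(params: PKParameters, auc_total: float, rng: np.random.Generator) -> float:
    """Hair concentration (pg/mg) deposited from a plasma exposure.

    Between-animal variability is lognormal with mean one
    (eps ~ Normal(-sigma^2/2, sigma^2)), so incorporation_coeff is the
    population MEAN deposition per unit exposure, the estimand of the
    pooled mean degree.
    """
    if auc_total < 0:
        raise ValueError("auc_total must be >= 0")
    if auc_total == 0 or params.incorporation_coeff == 0:
        return 0.0
    s = params.bsv_sigma
    eps = rng.normal(-0.5 * s * s, s) if s > 0 else 0.0
    return float(params.incorporation_coeff * auc_total * np.exp(eps))


def calibration_levels(low: float = 0.01, high: float = 500.0, n: int = 15) -> np.ndarray:
    """Geometrically spaced calibrator concentrations (matrix units)."""
    return np.geomspace(low, high, n)


@dataclass
class SyntheticStudy:
    """Generated study: measured response ratios plus the noise-free truth."""

    design: StudyDesign
    panel: list[SubstanceRecord]
    responses: pd.DataFrame          # RESPONSE_COLUMNS schema
    true_concentrations: pd.DataFrame
    seed: int


def _measure(conc, meas: MeasurementModel, rng: np.random.Generator,
             cv: float | None = None) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    cv = meas.proportional_cv if cv is None else cv
    prop = 1.0 + cv * rng.standard_normal(conc.shape)
    return meas.response_slope * conc * prop + rng.normal(0.0, meas.blank_sd, conc.shape)


def simulate_study(
    panel: list[SubstanceRecord],
    design: StudyDesign,
    pk_map: dict[str, PKParameters],
    meas: MeasurementModel,
    seed: int,
    hair_auc_basis: str = "day7",
    n_blanks: int = 6,
) -> SyntheticStudy:
    """Generate one full study: samples, calibrators and blanks, seeded.

    hair_auc_basis selects the plasma exposure driving hair deposition:
    "day7" (AUC over the dense day-7 grid window, the same convention as
    the recovered degree) or "block" (total AUC of the whole dosing block
    to an effectively infinite horizon).
    """
    missing = [s.name for s in panel if s.name not in pk_map]
    if missing:
        raise KeyError(f"missing PK parameters for: {', '.join(missing)}")
    if hair_auc_basis not in ("day7", "block"):
        raise ValueError("hair_auc_basis must be 'day7' or 'block'")

    dose_times = design.dose_times_h()
    last_dose = dose_times[-1]
    day7_window = (last_dose, last_dose + design.plasma_times_day7[-1])
    matrices = list(design.collection_days)

    resp_rows: list[tuple] = []
    true_rows: list[tuple] = []

    for sub in panel:
        params = pk_map[sub.name]
        rng = substream(seed, f"study/{sub.name}")

        # per-animal biology: lognormal multipliers on clearance and deposition
        animals = [
            (grp, f"{grp[0].upper()}{i+1:02d}")
            for grp, n in design.group_sizes.items()
            for i in range(n)
        ]
        # clearance multipliers are median-1; incorporation multipliers are
        # mean-1 so the coefficient is the mean deposition per unit exposure
        s = params.bsv_sigma
        eta_cl = rng.normal(0.0, s, len(animals))
        eta_inc = rng.normal(-0.5 * s * s, s, len(animals))

        for idx, (grp, animal) in enumerate(animals):
            dose = GROUP_DOSES[grp]
            p_i = (
                PKParameters(
                    ka=params.ka,
                    ke=params.ke * float(np.exp(eta_cl[idx])),
                    v_over_f=params.v_over_f,
                    f_abs=params.f_abs,
                    f_urine=params.f_urine,
                    f_faeces=params.f_faeces,
                    incorporation_coeff=params.incorporation_coeff,
                    bsv_sigma=0.0,
                )
                if params.bsv_sigma > 0
                else params
            )
            dose_ng = dose * design.body_mass_kg * 1e6

            if "plasma" in matrices:
                for day in design.collection_days["plasma"]:
                    times = design.plasma_times_day7 if day == 7 else (0.0,)
                    for tau in times:
                        t_abs = 24.0 * day + tau
                        c = (
                            plasma_concentration(p_i, dose, dose_times, t_abs)
                            if dose > 0
                            else 0.0
                        )
                        true_rows.append((sub.name, "plasma", animal, grp, day, tau, c))

            for mat in ("urine", "faeces"):
                if mat not in matrices:
                    continue
                for day in design.collection_days[mat]:
                    iv = (24.0 * day, 24.0 * (day + 1))
                    amt = (
                        excretion_interval(
                            p_i, [(t, dose_ng) for t in dose_times], iv, mat
                        )
                        if dose > 0
                        else 0.0
                    )
                    denom = (
                        design.urine_volume_ml
                        if mat == "urine"
                        else design.faeces_mass_g
                    )
                    true_rows.append((sub.name, mat, animal, grp, day, 0.0, amt / denom))

            if "hair" in matrices:
                if dose > 0:
                    if hair_auc_basis == "day7":
                        auc = plasma_auc_exact(p_i, dose, dose_times, *day7_window)
                    else:
                        horizon = last_dose + 20.0 / p_i.ke
                        auc = plasma_auc_exact(p_i, dose, dose_times, 0.0, horizon)
                    hair = (
                        p_i.incorporation_coeff * auc * float(np.exp(eta_inc[idx]))
                        if params.bsv_sigma > 0
                        else p_i.incorporation_coeff * auc
                    )
                else:
                    hair = 0.0
                for day in design.collection_days["hair"]:
                    v = hair if day >= design.hair_harvest_day else 0.0
                    true_rows.append((sub.name, "hair", animal, grp, day, 0.0, v))

        # matched calibration sets and blanks per matrix
        cal = calibration_levels()
        for mat in matrices:
            mrng = substream(seed, f"calibration/{sub.name}/{mat}")
            ccv = meas.calibration_cv
            blanks = _measure(np.zeros(n_blanks), meas, mrng, cv=ccv)
            for j, r in enumerate(blanks):
                resp_rows.append(
                    (sub.name, mat, f"blank{j+1}", "vehicle", 0, 0.0, "blank", 0.0, float(r))
                )
            ratios = _measure(cal, meas, mrng, cv=ccv)
            for c, r in zip(cal, ratios):
                resp_rows.append(
                    (sub.name, mat, "cal", "vehicle", 0, 0.0, "calibrator", float(c), float(r))
                )
            qc = _measure([1.0, 100.0], meas, mrng, cv=ccv)
            for c, r in zip((1.0, 100.0), qc):
                resp_rows.append(
                    (sub.name, mat, "qc", "vehicle", 0, 0.0, "qc", float(c), float(r))
                )

    true_frame = pd.DataFrame(
        true_rows,
        columns=["substance", "matrix", "animal_id", "group", "day", "time_h", "value"],
    )

    # measure every sample row through the response model
    for sub in panel:
        rng = substream(seed, f"measure/{sub.name}")
        mask = true_frame["substance"] == sub.name
        ratios = _measure(true_frame.loc[mask, "value"].to_numpy(), meas, rng)
        part = true_frame.loc[mask]
        resp_rows.extend(
            (
                sub.name,
                part["matrix"].iat[i],
                part["animal_id"].iat[i],
                part["group"].iat[i],
                int(part["day"].iat[i]),
                float(part["time_h"].iat[i]),
                "sample",
                np.nan,
                float(ratios[i]),
            )
            for i in range(len(part))
        )

    responses = pd.DataFrame(resp_rows, columns=RESPONSE_COLUMNS)
    return SyntheticStudy(
        design=design,
        panel=list(panel),
        responses=responses,
        true_concentrations=true_frame,
        seed=seed,
    )
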