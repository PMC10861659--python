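"""Hair incorporation degree and the cross-matrix detection grid.

The incorporation degree of a substance in one animal is its hair
concentration (pg/mg) divided by its plasma AUC (ng.h/mL); it is only
defined when the substance was detected in BOTH matrices. Group summaries
pool the treated dose groups (legitimate because the degree is a ratio of
two dose-linear quantities and hence dose-independent under linear PK) and
report mean +/- SEM with the n actually used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Incalculable",
    "IncorporationResult",
    "DetectionGrid",
    "compute_degree",
    "group_summary",
    "incorporation_table",
    "build_detection_grid",
]

#: Unit convention, printed in every report header.
DEGREE_UNITS = "(pg/mg) / (ng.h/mL)"


class Incalculable(ValueError):
    """Degree undefined: the substance was not detected in hair or plasma."""


def compute_degree(
    hair_conc: float,
    plasma_auc: float,
    hair_censored: bool = False,
    auc_censored: bool = False,
) -> float:
    """Incorporation degree = hair concentration / plasma AUC.

    Raises :class:`Incalculable` (never returns 0) when either input is a
    non-detection - a drug seen in hair but not plasma, or vice versa, has
    no defined degree.
    """
    if hair_censored or auc_censored:
        raise Incalculable("degree requires detection in both hair and plasma")
    if not plasma_auc > 0:
        raise Incalculable("degree requires a positive plasma AUC")
    if hair_conc < 0:
        raise ValueError("hair concentration must be >= 0")
    return hair_conc / plasma_auc


def group_summary(degrees) -> tuple[float, Optional[float], int]:
    """(mean, SEM, n) of per-animal degrees; SEM is None when n == 1."""
    d = np.asarray(list(degrees), dtype=float)
    if d.size == 0:
        raise ValueError("no degrees to summarise")
    mean = float(d.mean())
    sem = float(d.std(ddof=1) / math.sqrt(d.size)) if d.size > 1 else None
    return mean, sem, int(d.size)


@dataclass(frozen=True)
class IncorporationResult:
    substance: str
    per_animal_degree: tuple[float, ...]
    mean: float
    sem: Optional[float]
    n: int
    per_dose_mean: dict[str, float]
    units: str = DEGREE_UNITS


def incorporation_table(
    pk_summaries: pd.DataFrame,
    hair: pd.DataFrame,
    treated_groups: tuple[str, ...] = ("half", "one", "two"),
) -> list[IncorporationResult]:
    """Per-substance pooled incorporation results.

    ``pk_summaries`` is the summarize_plasma output; ``hair`` is the
    quantified concentration frame restricted to hair rows at the harvest
    day. Animals with a censored hair value or zero AUC are excluded; the
    reported n is the count actually used.
    """
    hair = hair[(hair["matrix"] == "hair") & (hair["group"].isin(treated_groups))]
    hair_last = hair[hair["day"] == hair["day"].max()] if len(hair) else hair
    results = []
    for sub, hpart in hair_last.groupby("substance", sort=True):
        spart = pk_summaries[pk_summaries["substance"] == sub]
        auc = dict(zip(spart["animal_id"], spart["auc_0_12"]))
        grp_of = dict(zip(spart["animal_id"], spart["group"]))
        degrees, groups = [], []
        for r in hpart.itertuples():
            a = auc.get(r.animal_id)
            if a is None:
                continue
            try:
                deg = compute_degree(r.value, a, hair_censored=r.censored,
                                     auc_censored=not a > 0)
            except Incalculable:
                continue
            degrees.append(deg)
            groups.append(grp_of[r.animal_id])
        if not degrees:
            continue
        mean, sem, n = group_summary(degrees)
        per_dose = {
            g: float(np.mean([d for d, gg in zip(degrees, groups) if gg == g]))
            for g in sorted(set(groups))
        }
        results.append(
            IncorporationResult(
                substance=str(sub),
                per_animal_degree=tuple(degrees),
                mean=mean,
                sem=sem,
                n=n,
                per_dose_mean=per_dose,
            )
        )
    return results


@dataclass
class DetectionGrid:
    """(substance, matrix) -> detected flag and last detected study day."""

    entries: dict[tuple[str, str], tuple[bool, Optional[int]]]

    def detected_count(self, matrix: str) -> int:
        return sum(1 for (s, m), (det, _) in self.entries.items()
                   if m == matrix and det)

    def detected_in_all(self, matrices) -> int:
        subs = {s for (s, _m) in self.entries}
        return sum(
            1 for s in subs
            if all(self.entries.get((s, m), (False, None))[0] for m in matrices)
        )


def build_detection_grid(
    concentrations: pd.DataFrame,
    lods: dict[tuple[str, str], float],
    treated_groups: tuple[str, ...] = ("half", "one", "two"),
) -> DetectionGrid:
    """Detected iff any treated animal has a non-censored value above LOD."""
    part = concentrations[concentrations["group"].isin(treated_groups)]
    entries: dict[tuple[str, str], tuple[bool, Optional[int]]] = {}
    for (sub, mat), g in part.groupby(["substance", "matrix"], sort=True):
        lod = lods.get((str(sub), str(mat)), 0.0)
        hit = g[(~g["censored"].astype(bool)) & (g["value"] > lod)]
        if len(hit):
            entries[(str(sub), str(mat))] = (True, int(hit["day"].max()))
        else:
            entries[(str(sub), str(mat))] = (False, None)
    return DetectionGrid(entries)
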