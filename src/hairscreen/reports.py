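"""Human-readable report tables.

Includes the segmental hair report: per-subject ordered segment
concentrations (proximal to distal), the concentration trend along the
strand, and a consistency flag for all-censored profiles from subjects
whose drug use lasted under five weeks (hair bearing the drug has not yet
emerged from the scalp in that window).
"""

from __future__ import annotations

import pandas as pd

from .incorporation import DEGREE_UNITS, DetectionGrid, IncorporationResult
from .panel import HairSegmentProfile

__all__ = ["segment_report", "incorporation_report", "detection_grid_report"]

SHORT_USE_WEEKS = 5.0


def _trend(concs: list[float]) -> str:
    detected = [c for c in concs if c is not None]
    if len(detected) < 2:
        return "indeterminate"
    diffs = [b - a for a, b in zip(detected, detected[1:])]
    if all(d < 0 for d in diffs):
        return "decreasing"
    if all(d > 0 for d in diffs):
        return "increasing"
    return "mixed"


def segment_report(profiles: list[HairSegmentProfile]) -> pd.DataFrame:
    """One row per subject: segments, trend, and short-use consistency flag."""
    rows = []
    for p in profiles:
        segs = sorted(p.segments, key=lambda s: s[0])
        concs = [c for _, _, c in segs]
        all_censored = all(c is None for c in concs)
        short_use = (
            p.use_duration_weeks is not None
            and p.use_duration_weeks < SHORT_USE_WEEKS
        )
        rows.append(
            {
                "subject_id": p.subject_id,
                "drug": p.drug,
                "n_segments": len(segs),
                "segments_cm": "; ".join(f"{lo:g}-{hi:g}" for lo, hi, _ in segs),
                "concentrations_pg_mg": "; ".join(
                    "nd" if c is None else f"{c:g}" for c in concs
                ),
                "trend_proximal_to_distal": _trend(concs),
                "all_censored": all_censored,
                "short_duration_consistent": bool(short_use and all_censored),
                "cosmetic_treatment": "+".join(sorted(p.cosmetic_treatment)),
            }
        )
    return pd.DataFrame(rows)


def incorporation_report(results: list[IncorporationResult]) -> pd.DataFrame:
    """Per-substance degrees; the unit convention is carried in the header."""
    rows = [
        {
            f"mean_degree [{DEGREE_UNITS}]": r.mean,
            "substance": r.substance,
            "n": r.n,
            "sem": r.sem,
            **{f"mean_{g}": m for g, m in r.per_dose_mean.items()},
        }
        for r in results
    ]
    frame = pd.DataFrame(rows)
    if len(frame):
        cols = ["substance", "n", f"mean_degree [{DEGREE_UNITS}]", "sem"]
        frame = frame[cols + [c for c in frame.columns if c not in cols]]
    return frame


def detection_grid_report(grid: DetectionGrid) -> pd.DataFrame:
    rows = [
        {
            "substance": s,
            "matrix": m,
            "detected": det,
            "last_detected_day": last,
        }
        for (s, m), (det, last) in sorted(grid.entries.items())
    ]
    return pd.DataFrame(rows)
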