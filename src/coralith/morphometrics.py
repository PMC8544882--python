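"""Corallite morphometrics and tissue thickness.

Three traits summarize the light-capture geometry of a coral's surface and
tissue from raw counts and width measurements:

* **Corallite complexity** — septa weighted by cycle: primary-cycle septa
  count double, secondary septa count once; the score is the weighted sum.
  More septa mean a more structured "photon trap".
* **Calice-to-coenosteum ratio (CtC)** — mean calice width (maximum width
  averaged with the width at 90 degrees to it) divided by the mean of the two
  coenosteum widths flanking the corallite.  Higher values mean larger
  light-trapping cups relative to inter-corallite skeleton.
* **Tissue thickness** — mean of point measurements (nominally 10) along a
  skeletal cross-section.

Per-specimen values are unweighted means over the measured corallites
(nominally 3).  Only two septal cycles are modelled; input carrying higher
cycles is rejected rather than silently weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

__all__ = [
    "CoralliteObservation",
    "TissueProfile",
    "MorphometricProfile",
    "corallite_complexity",
    "calice_coenosteum_ratio",
    "specimen_profile",
    "profile_table",
]

NOMINAL_TISSUE_POINTS = 10


@dataclass(frozen=True)
class CoralliteObservation:
    """Raw measurements for one corallite of one specimen."""

    specimen_id: str
    corallite_index: int
    primary_septa: int
    secondary_septa: int
    max_calice_width_mm: float
    perp_calice_width_mm: float
    coenosteum_width_1_mm: float
    coenosteum_width_2_mm: float

    def __post_init__(self) -> None:
        for name in ("primary_septa", "secondary_septa"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise DomainError(
                    f"{self.specimen_id}: {name} must be a non-negative integer, got {v}"
                )
        widths = {
            "max_calice_width_mm": self.max_calice_width_mm,
            "perp_calice_width_mm": self.perp_calice_width_mm,
            "coenosteum_width_1_mm": self.coenosteum_width_1_mm,
            "coenosteum_width_2_mm": self.coenosteum_width_2_mm,
        }
        for name, v in widths.items():
            if not v > 0:
                raise DomainError(f"{self.specimen_id}: {name} must be > 0, got {v}")
        if self.perp_calice_width_mm > self.max_calice_width_mm:
            raise DomainError(
                f"{self.specimen_id}: perpendicular calice width "
                f"({self.perp_calice_width_mm}) exceeds maximum width "
                f"({self.max_calice_width_mm})"
            )


@dataclass(frozen=True)
class TissueProfile:
    """Tissue-thickness point measurements along one specimen's cross-section."""

    specimen_id: str
    thickness_points_mm: tuple[float, ...]
    short_profile: bool = False  # set when fewer than the nominal 10 points

    def __post_init__(self) -> None:
        pts = tuple(float(p) for p in self.thickness_points_mm)
        object.__setattr__(self, "thickness_points_mm", pts)
        if len(pts) == 0:
            raise DomainError(f"{self.specimen_id}: tissue profile has no points")
        if any(not p > 0 for p in pts):
            raise DomainError(f"{self.specimen_id}: tissue thickness points must be > 0")
        if len(pts) < NOMINAL_TISSUE_POINTS:
            object.__setattr__(self, "short_profile", True)
            warnings.warn(
                f"{self.specimen_id}: tissue profile has {len(pts)} points "
                f"(nominal {NOMINAL_TISSUE_POINTS})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MorphometricProfile:
    specimen_id: str
    complexity: float
    ctc_ratio: float
    tissue_thickness_mm: float
    n_corallites: int
    n_tissue_points: int


def corallite_complexity(primary_septa: int, secondary_septa: int) -> int:
    """Weighted septa sum: ``2 * primary + secondary``."""
    for name, v in (("primary_septa", primary_septa), ("secondary_septa", secondary_septa)):
        if v != int(v) or v < 0:
            raise DomainError(f"{name} must be a non-negative integer, got {v}")
    return 2 * int(primary_septa) + int(secondary_septa)


def calice_coenosteum_ratio(obs: CoralliteObservation) -> float:
    """Mean calice width over mean flanking coenosteum width for one corallite."""
    calice = 0.5 * (obs.max_calice_width_mm + obs.perp_calice_width_mm)
    coen = 0.5 * (obs.coenosteum_width_1_mm + obs.coenosteum_width_2_mm)
    return calice / coen


def specimen_profile(
    observations: Sequence[CoralliteObservation],
    tissue: TissueProfile,
    *,
    ctc_aggregation: str = "mean_of_ratios",
) -> MorphometricProfile:
    """Per-specimen morphometric summary over 1-3 corallites.

    ``ctc_aggregation="mean_of_ratios"`` (default) averages per-corallite
    ratios; ``"pooled_means"`` takes the ratio of pooled mean widths — a
    sensitivity-check alternative.
    """
    if len(observations) == 0:
        raise DomainError("specimen_profile requires at least one corallite observation")
    if len(observations) > 3:
        raise DomainError(
            f"at most 3 corallites are measured per specimen, got {len(observations)}"
        )
    sids = {o.specimen_id for o in observations} | {tissue.specimen_id}
    if len(sids) != 1:
        raise DomainError(f"mixed specimen ids in one profile: {sorted(sids)}")
    complexity = float(
        np.mean([corallite_complexity(o.primary_septa, o.secondary_septa) for o in observations])
    )
    if ctc_aggregation == "mean_of_ratios":
        ctc = float(np.mean([calice_coenosteum_ratio(o) for o in observations]))
    elif ctc_aggregation == "pooled_means":
        calice = np.mean(
            [0.5 * (o.max_calice_width_mm + o.perp_calice_width_mm) for o in observations]
        )
        coen = np.mean(
            [0.5 * (o.coenosteum_width_1_mm + o.coenosteum_width_2_mm) for o in observations]
        )
        ctc = float(calice / coen)
    else:
        raise ValueError(
            f"ctc_aggregation must be 'mean_of_ratios' or 'pooled_means', got {ctc_aggregation!r}"
        )
    return MorphometricProfile(
        specimen_id=tissue.specimen_id,
        complexity=complexity,
        ctc_ratio=ctc,
        tissue_thickness_mm=float(np.mean(tissue.thickness_points_mm)),
        n_corallites=len(observations),
        n_tissue_points=len(tissue.thickness_points_mm),
    )


_CORALLITE_COLUMNS = (
    "specimen_id",
    "corallite_index",
    "primary_septa",
    "secondary_septa",
    "max_calice_width_mm",
    "perp_calice_width_mm",
    "coenosteum_width_1_mm",
    "coenosteum_width_2_mm",
)


def profile_table(
    corallites: pd.DataFrame,
    tissue: pd.DataFrame,
    *,
    ctc_aggregation: str = "mean_of_ratios",
) -> pd.DataFrame:
    """Per-specimen morphometric profiles from tidy corallite and tissue tables.

    ``corallites`` has one row per corallite (columns as in
    :class:`CoralliteObservation`); ``tissue`` has one row per point with
    columns specimen_id, point_index, thickness_mm.
    """
    for col in _CORALLITE_COLUMNS:
        if col not in corallites.columns:
            raise SchemaError(f"corallite table is missing required column {col!r}")
    higher = [c for c in corallites.columns if c in ("tertiary_septa", "quaternary_septa")]
    if higher:
        raise SchemaError(
            f"corallite table carries unmodelled higher septal cycles: {higher}; "
            "only primary and secondary cycles are scored"
        )
    for col in ("specimen_id", "point_index", "thickness_mm"):
        if col not in tissue.columns:
            raise SchemaError(f"tissue table is missing required column {col!r}")
    rows = []
    tissue_by_sid = dict(tuple(tissue.groupby("specimen_id", sort=True)))
    for sid, grp in corallites.groupby("specimen_id", sort=True):
        if sid not in tissue_by_sid:
            raise SchemaError(f"specimen {sid!r} has corallites but no tissue points")
        obs = [
            CoralliteObservation(
                specimen_id=str(sid),
                corallite_index=int(r["corallite_index"]),
                primary_septa=int(r["primary_septa"]),
                secondary_septa=int(r["secondary_septa"]),
                max_calice_width_mm=float(r["max_calice_width_mm"]),
                perp_calice_width_mm=float(r["perp_calice_width_mm"]),
                coenosteum_width_1_mm=float(r["coenosteum_width_1_mm"]),
                coenosteum_width_2_mm=float(r["coenosteum_width_2_mm"]),
            )
            for _, r in grp.sort_values("corallite_index").iterrows()
        ]
        tp = tissue_by_sid[sid].sort_values("point_index")["thickness_mm"]
        prof = specimen_profile(
            obs,
            TissueProfile(specimen_id=str(sid), thickness_points_mm=tuple(tp)),
            ctc_aggregation=ctc_aggregation,
        )
        rows.append(
            {
                "specimen_id": prof.specimen_id,
                "complexity": prof.complexity,
                "ctc_ratio": prof.ctc_ratio,
                "tissue_thickness_mm": prof.tissue_thickness_mm,
                "n_corallites": prof.n_corallites,
                "n_tissue_points": prof.n_tissue_points,
            }
        )
    return pd.DataFrame(rows)
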