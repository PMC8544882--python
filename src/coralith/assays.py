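"""Endolithic biomass and chlorophyll assays.

Two laboratory assays quantify the microbial biofilm living inside a coral
skeleton, both normalized to the fragment's estimated biomineral volume:

* **AFDW** (ash-free dry weight): the organic mass lost between drying at
  70 degC and ashing at 550 degC, in mg cm^-3 of skeleton.
* **Quadrichroic chlorophyll spectrophotometry**: chlorophylls a, b, c and d
  are resolved simultaneously from optical densities of a 90 % acetone
  extract at four wavelengths by solving the 4x4 linear system
  ``E . c = OD`` where ``E`` holds pigment-specific absorption coefficients
  and ``c`` is the concentration vector in ug ml^-1.  Negative solutions
  (noise below the detection floor) are clamped to zero and flagged
  not-detected.

The shipped coefficient set is a transcription of the quadrichroic equations
of Ritchie (2008) for 90 % acetone, stored in their published
"concentration = M . OD" form and inverted numerically.  The solver is fully
generic: any invertible 4x4 system with strictly increasing wavelengths can
be supplied.

A note on wavelengths: the conventional quadrichroic channel set is
(630, 647, 664, 691) nm.  Some field protocols report 674 nm in place of
647 nm; both labellings are supported (``wavelength_set``), and they differ
only in how the second channel is labelled — the coefficient values are
those of the cited reference.  The extraction protocol's HCl decalcification
step acidifies part of the chlorophyll *a* pool to phaeophytin *a*, which
depresses the 664 nm channel; no correction for this is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

__all__ = [
    "CoefficientMatrix",
    "PigmentAssay",
    "PigmentResult",
    "quantify_pigments",
    "quantify_pigment_table",
    "afdw",
    "afdw_table",
    "PIGMENTS",
]

PIGMENTS = ("chl_a", "chl_b", "chl_c", "chl_d")

#: Quadrichroic wavelength labels, nm.  "printed" follows field reports that
#: list 674 nm; "conventional" is the 647 nm labelling of the source equations.
WAVELENGTH_SETS = {
    "printed": (630.0, 664.0, 674.0, 691.0),
    "conventional": (630.0, 647.0, 664.0, 691.0),
}

MAX_CONDITION_NUMBER = 1e8
OD_FLOOR = -0.05  # small negative baseline noise tolerated


@dataclass(frozen=True)
class CoefficientMatrix:
    """4x4 specific-absorption system for quadrichroic chlorophyll analysis.

    ``E`` has one row per wavelength and one column per pigment (a, b, c, d),
    in units of OD per (ug ml^-1) per cm of path, so that ``E . c = OD``.
    """

    wavelengths_nm: tuple[float, ...]
    E: np.ndarray
    pigments: tuple[str, ...] = PIGMENTS
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", E)
        if E.shape != (4, 4):
            raise DomainError(f"coefficient matrix must be 4x4, got {E.shape}")
        wl = tuple(float(w) for w in self.wavelengths_nm)
        object.__setattr__(self, "wavelengths_nm", wl)
        if len(wl) != 4 or any(b <= a for a, b in zip(wl, wl[1:])):
            raise DomainError(f"wavelengths must be 4 strictly increasing values, got {wl}")
        if not np.all(np.isfinite(E)):
            raise DomainError("coefficient matrix contains non-finite entries")
        if self.condition_number > MAX_CONDITION_NUMBER:
            raise DomainError(
                f"coefficient matrix is ill-conditioned (cond={self.condition_number:.3g} "
                f"> {MAX_CONDITION_NUMBER:.0e})"
            )

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.E))

    def synthesize_od(self, concentrations: Sequence[float]) -> np.ndarray:
        """Forward model: mean ODs produced by a concentration vector (ug ml^-1)."""
        c = np.asarray(concentrations, dtype=float)
        return self.E @ c * self.path_length_cm

    def solve(self, od_mean: Sequence[float]) -> np.ndarray:
        """Invert ``E . c = OD`` for the concentration vector (ug ml^-1)."""
        od = np.asarray(od_mean, dtype=float) / self.path_length_cm
        return np.linalg.solve(self.E, od)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientMatrix":
        wl = tuple(float(w) for w in d["wavelengths_nm"])
        pigments = tuple(d.get("pigments", PIGMENTS))
        path = float(d.get("path_length_cm", 1.0))
        M = np.array([d["coefficients"][p] for p in pigments], dtype=float)
        if d.get("form", "absorption") == "concentration_equations":
            # Stored as c = M . OD (rows pigments, cols wavelengths); invert to E.
            E = np.linalg.inv(M)
        else:
            # Stored as E directly: rows wavelengths — keys index columns.
            E = M.T
        return cls(wavelengths_nm=wl, E=E, pigments=pigments, path_length_cm=path)

    @classmethod
    def from_json(cls, path) -> "CoefficientMatrix":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def ritchie_90_acetone(cls, wavelength_set: str = "printed") -> "CoefficientMatrix":
        """The shipped Ritchie (2008) 90 % acetone system.

        ``wavelength_set`` selects only the channel labelling
        ("printed": 674 nm, "conventional": 647 nm); coefficients are identical.
        """
        if wavelength_set not in WAVELENGTH_SETS:
            raise ValueError(
                f"wavelength_set must be one of {sorted(WAVELENGTH_SETS)}, got {wavelength_set!r}"
            )
        ref = resources.files("coralith.data") / "ritchie_quadrichroic_90acetone.json"
        cm = cls.from_dict(json.loads(ref.read_text()))
        wl = WAVELENGTH_SETS[wavelength_set]
        return cls(
            wavelengths_nm=wl, E=cm.E, pigments=cm.pigments, path_length_cm=cm.path_length_cm
        )


@dataclass
class PigmentAssay:
    """Triplicate optical densities for one specimen's acetone extract.

    ``od_readings`` maps wavelength (nm) to its replicate ODs (nominally 3).
    """

    specimen_id: str
    od_readings: Mapping[float, Sequence[float]]
    v_bio_e_cm3: float
    extract_volume_ml: float = 10.0

    def __post_init__(self) -> None:
        if not self.extract_volume_ml > 0:
            raise DomainError(
                f"{self.specimen_id}: extract_volume_ml must be > 0, "
                f"got {self.extract_volume_ml}"
            )
        if not self.v_bio_e_cm3 > 0:
            raise DomainError(
                f"{self.specimen_id}: v_bio_e_cm3 must be > 0, got {self.v_bio_e_cm3}"
            )
        for wl, reps in self.od_readings.items():
            arr = np.asarray(reps, dtype=float)
            if np.any(arr < OD_FLOOR) or np.any(~np.isfinite(arr)):
                raise DomainError(
                    f"{self.specimen_id}: OD readings at {wl} nm below baseline floor "
                    f"{OD_FLOOR} or non-finite: {list(arr)}"
                )

    def mean_od(self, wavelengths: Sequence[float], *, allow_partial: bool = False) -> np.ndarray:
        means = []
        for wl in wavelengths:
            if wl not in self.od_readings:
                raise DomainError(f"{self.specimen_id}: no OD readings at {wl} nm")
            reps = np.asarray(self.od_readings[wl], dtype=float)
            if reps.size != 3 and not allow_partial:
                raise DomainError(
                    f"{self.specimen_id}: expected 3 replicates at {wl} nm, got {reps.size} "
                    "(pass allow_partial_replicates to accept)"
                )
            if reps.size == 0:
                raise DomainError(f"{self.specimen_id}: empty replicate set at {wl} nm")
            means.append(reps.mean())
        return np.array(means)


@dataclass
class PigmentResult:
    """Chlorophyll concentrations for one specimen, per cm^3 of skeleton."""

    specimen_id: str
    chl_a: float
    chl_b: float
    chl_c: float
    chl_d: float
    detected: dict = field(default_factory=dict)  # pigment -> bool
    raw_concentrations: dict = field(default_factory=dict)  # pigment -> ug/ml, pre-clamp

    def as_dict(self) -> dict:
        d = {"specimen_id": self.specimen_id}
        for p, v in zip(PIGMENTS, (self.chl_a, self.chl_b, self.chl_c, self.chl_d)):
            d[p + "_ug_cm3"] = v
        for p in PIGMENTS:
            d["detected_" + p[-1]] = self.detected[p]
        for p in PIGMENTS:
            d["raw_" + p + "_ug_ml"] = self.raw_concentrations[p]
        return d


def quantify_pigments(
    assay: PigmentAssay,
    coefficients: CoefficientMatrix | None = None,
    *,
    allow_partial_replicates: bool = False,
) -> PigmentResult:
    """Solve the quadrichroic system for one specimen.

    Triplicate ODs are averaged per wavelength, the 4x4 system is solved for
    extract concentrations (ug ml^-1), concentrations are scaled to pigment
    masses by the extract volume and normalized by the skeletal biomineral
    volume.  Negative solutions are clamped to zero with ``detected=False``.
    """
    E = coefficients if coefficients is not None else CoefficientMatrix.ritchie_90_acetone()
    od = assay.mean_od(E.wavelengths_nm, allow_partial=allow_partial_replicates)
    raw = E.solve(od)
    detected = {p: bool(c > 0) for p, c in zip(E.pigments, raw)}
    clamped = np.maximum(raw, 0.0)
    per_volume = clamped * assay.extract_volume_ml / assay.v_bio_e_cm3
    return PigmentResult(
        specimen_id=assay.specimen_id,
        chl_a=float(per_volume[0]),
        chl_b=float(per_volume[1]),
        chl_c=float(per_volume[2]),
        chl_d=float(per_volume[3]),
        detected=detected,
        raw_concentrations={p: float(c) for p, c in zip(E.pigments, raw)},
    )


def afdw(dried_mass_mg, ashed_mass_mg, v_bio_e):
    """Ash-free dry weight ``(dried - ashed) / v_bio_e`` in mg cm^-3."""
    d = np.asarray(dried_mass_mg, dtype=float)
    a = np.asarray(ashed_mass_mg, dtype=float)
    v = np.asarray(v_bio_e, dtype=float)
    if np.any(a < 0):
        raise DomainError(f"ashed_mass_mg must be >= 0, got {ashed_mass_mg}")
    if np.any(a > d):
        raise DomainError(
            f"ashed_mass_mg ({ashed_mass_mg}) exceeds dried_mass_mg ({dried_mass_mg}): "
            "combustion cannot add mass"
        )
    if np.any(v <= 0):
        raise DomainError(f"v_bio_e must be > 0, got {v_bio_e}")
    out = (d - a) / v
    return float(out) if out.ndim == 0 else out


def quantify_pigment_table(
    od_table: pd.DataFrame,
    specimen_table: pd.DataFrame,
    coefficients: CoefficientMatrix | None = None,
    *,
    allow_partial_replicates: bool = False,
) -> pd.DataFrame:
    """Quantify pigments for every specimen in a tidy OD table.

    ``od_table`` columns: specimen_id, wavelength_nm, replicate, od.
    ``specimen_table`` columns: specimen_id, extract_volume_ml, v_bio_e_cm3.
    """
    for col in ("specimen_id", "wavelength_nm", "replicate", "od"):
        if col not in od_table.columns:
            raise SchemaError(f"OD table is missing required column {col!r}")
    for col in ("specimen_id", "extract_volume_ml", "v_bio_e_cm3"):
        if col not in specimen_table.columns:
            raise SchemaError(f"specimen table is missing required column {col!r}")
    E = coefficients if coefficients is not None else CoefficientMatrix.ritchie_90_acetone()
    meta = specimen_table.set_index("specimen_id")
    rows = []
    for sid, grp in od_table.groupby("specimen_id", sort=True):
        if sid not in meta.index:
            raise SchemaError(f"specimen {sid!r} has ODs but no extract/volume metadata")
        readings = {
            float(wl): sub["od"].to_numpy()
            for wl, sub in grp.groupby("wavelength_nm", sort=True)
        }
        assay = PigmentAssay(
            specimen_id=str(sid),
            od_readings=readings,
            v_bio_e_cm3=float(meta.loc[sid, "v_bio_e_cm3"]),
            extract_volume_ml=float(meta.loc[sid, "extract_volume_ml"]),
        )
        res = quantify_pigments(assay, E, allow_partial_replicates=allow_partial_replicates)
        rows.append(res.as_dict())
    return pd.DataFrame(rows)


def afdw_table(furnace_table: pd.DataFrame, specimen_table: pd.DataFrame) -> pd.DataFrame:
    """AFDW per specimen from furnace masses joined to normalizing volumes."""
    for col in ("specimen_id", "dried_mass_mg", "ashed_mass_mg"):
        if col not in furnace_table.columns:
            raise SchemaError(f"furnace table is missing required column {col!r}")
    meta = specimen_table.set_index("specimen_id")
    rows = []
    for _, r in furnace_table.iterrows():
        sid = r["specimen_id"]
        if sid not in meta.index:
            raise SchemaError(f"specimen {sid!r} has furnace masses but no volume metadata")
        rows.append(
            {
                "specimen_id": sid,
                "afdw_mg_cm3": afdw(
                    r["dried_mass_mg"], r["ashed_mass_mg"], float(meta.loc[sid, "v_bio_e_cm3"])
                ),
            }
        )
    return pd.DataFrame(rows)
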