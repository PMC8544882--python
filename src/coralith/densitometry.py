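"""Buoyant-weight densitometry of coral skeletons.

Converts balance readings of coral skeletal fragments — dry mass in air,
apparent (wet) mass suspended in seawater, and optionally the same pair for a
wax-coated fragment — into biomineral volume, skeletal microdensity, bulk
volume and porosity via Archimedes' principle:

* biomineral volume  ``V_bio = (DM - WM) / rho_sw``
* microdensity       ``rho_micro = DM / V_bio``
* estimated dry mass ``DM = WM / (1 - rho_sw / rho_micro)`` when only the wet
  mass of a fragment is known and a species-level microdensity reference is
  available
* porosity           ``P = V_bulk - V_bio``, fraction ``P / V_bulk``

Seawater density is computed from temperature and practical salinity with the
UNESCO EOS-80 one-atmosphere equation of state (Millero & Poisson 1981),
quantized to a 0.1 degC temperature grid to emulate a logging protocol that
re-evaluates density at every 0.1 degC change.

The printed literature formula for the *estimated* biomineral volume divides
the buoyant mass deficit by the microdensity rather than by the seawater
density.  That is dimensionally a volume but physically inconsistent with the
measured-volume formula above (it understates volume by a factor
``rho_sw / rho_micro``).  The Archimedes-consistent denominator ``rho_sw`` is
the default here; ``literal_eq2=True`` reproduces the literal published form
for fidelity studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

__all__ = [
    "BuoyantWeightRecord",
    "DerivedSkeleton",
    "seawater_density",
    "estimate_dry_mass",
    "biomineral_volume",
    "estimated_biomineral_volume",
    "microdensity",
    "porosity",
    "bulk_volume_from_wax",
    "species_reference_density",
    "derive_skeletons",
]

#: Density of aragonite single crystals, g cm^-3 — hard upper bound for
#: coral skeletal microdensity.
ARAGONITE_DENSITY = 2.94

#: Paraffin wax density used to subtract the wax shell volume from
#: wax-coated buoyant-weight readings, g cm^-3.
DEFAULT_WAX_DENSITY = 0.90

DEFAULT_SALINITY_PSU = 35.0


@dataclass
class BuoyantWeightRecord:
    """One specimen's balance readings plus the water context they were taken in.

    ``dry_mass_g`` is the mass in air; ``wet_mass_g`` the apparent mass
    suspended in seawater.  Wax-coated masses are present only for specimens
    that went through the paraffin-dip porosity protocol.
    """

    specimen_id: str
    species: str
    wet_mass_g: float
    dry_mass_g: float | None = None
    water_temp_C: float = 25.0
    salinity_psu: float = DEFAULT_SALINITY_PSU
    waxed_dry_mass_g: float | None = None
    waxed_wet_mass_g: float | None = None

    def __post_init__(self) -> None:
        if not self.wet_mass_g > 0:
            raise DomainError(
                f"{self.specimen_id}: wet_mass_g must be > 0, got {self.wet_mass_g}"
            )
        if self.dry_mass_g is not None and not self.dry_mass_g > self.wet_mass_g:
            raise DomainError(
                f"{self.specimen_id}: dry_mass_g ({self.dry_mass_g}) must exceed "
                f"wet_mass_g ({self.wet_mass_g})"
            )
        if not 0.0 <= self.salinity_psu <= 42.0:
            raise DomainError(
                f"{self.specimen_id}: salinity_psu out of range [0, 42]: {self.salinity_psu}"
            )
        if not 0.0 <= self.water_temp_C <= 40.0:
            raise DomainError(
                f"{self.specimen_id}: water_temp_C out of range [0, 40]: {self.water_temp_C}"
            )
        if (
            self.waxed_dry_mass_g is not None
            and self.dry_mass_g is not None
            and self.waxed_dry_mass_g < self.dry_mass_g
        ):
            raise DomainError(
                f"{self.specimen_id}: waxed_dry_mass_g ({self.waxed_dry_mass_g}) "
                f"cannot be below dry_mass_g ({self.dry_mass_g})"
            )

    @property
    def seawater_density_g_cm3(self) -> float:
        return seawater_density(self.water_temp_C, self.salinity_psu)


@dataclass
class DerivedSkeleton:
    """Derived skeletal quantities for one specimen."""

    specimen_id: str
    v_bio_cm3: float
    rho_micro_g_cm3: float | None = None
    v_bulk_cm3: float | None = None
    pore_volume_cm3: float | None = None
    porosity_fraction: float | None = None
    volume_provenance: str = "measured"  # "measured" (V_Bio_M) or "estimated" (V_Bio_E)
    literal_eq2: bool = False


def seawater_density(
    temp_C: float | np.ndarray,
    salinity: float | np.ndarray = DEFAULT_SALINITY_PSU,
    *,
    quantize: bool = True,
):
    """Seawater density in g cm^-3 at one atmosphere (EOS-80).

    Parameters
    ----------
    temp_C : temperature in degC, valid on [0, 40].
    salinity : practical salinity, valid on [0, 42].
    quantize : round temperature to the nearest 0.1 degC before evaluating,
        mirroring a protocol that recalculates density on a 0.1 degC grid.
    """
    t = np.asarray(temp_C, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if np.any(t < 0.0) or np.any(t > 40.0) or np.any(~np.isfinite(t)):
        raise DomainError(f"water_temp_C out of range [0, 40]: {temp_C}")
    if np.any(s < 0.0) or np.any(s > 42.0) or np.any(~np.isfinite(s)):
        raise DomainError(f"salinity_psu out of range [0, 42]: {salinity}")
    if quantize:
        t = np.round(t, 1)
    # Pure-water term (Bigg 1967, as adopted by EOS-80), kg m^-3.
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    rho = rho_w + a * s + b * s**1.5 + 4.8314e-4 * s**2
    rho = rho / 1000.0  # kg m^-3 -> g cm^-3
    return float(rho) if rho.ndim == 0 else rho


def estimate_dry_mass(wet_mass, rho_sw, rho_micro):
    """Equivalent dry mass from a wet (buoyant) mass: ``WM / (1 - rho_sw/rho_micro)``."""
    wm = np.asarray(wet_mass, dtype=float)
    rs = np.asarray(rho_sw, dtype=float)
    rm = np.asarray(rho_micro, dtype=float)
    if np.any(wm <= 0):
        raise DomainError(f"wet_mass must be > 0, got {wet_mass}")
    if np.any(rm <= 0):
        raise DomainError(f"rho_micro must be > 0, got {rho_micro}")
    if np.any(rs < 0):
        raise DomainError(f"rho_sw must be >= 0, got {rho_sw}")
    if np.any(rm <= rs):
        raise DomainError(
            f"rho_micro ({rho_micro}) must exceed rho_sw ({rho_sw}); "
            "denominator 1 - rho_sw/rho_micro would be <= 0"
        )
    out = wm / (1.0 - rs / rm)
    return float(out) if out.ndim == 0 else out


def biomineral_volume(dry_mass, wet_mass, rho_sw):
    """Biomineral volume ``(DM - WM) / rho_sw`` in cm^3 (Archimedes)."""
    dm = np.asarray(dry_mass, dtype=float)
    wm = np.asarray(wet_mass, dtype=float)
    rs = np.asarray(rho_sw, dtype=float)
    if np.any(rs <= 0):
        raise DomainError(f"rho_sw must be > 0, got {rho_sw}")
    if np.any(dm <= wm):
        raise DomainError(
            f"dry_mass ({dry_mass}) must exceed wet_mass ({wet_mass}): a neutrally "
            "or negatively buoyant reading gives no displaced-volume information"
        )
    out = (dm - wm) / rs
    return float(out) if out.ndim == 0 else out


def estimated_biomineral_volume(
    dry_mass, wet_mass, rho_sw, rho_micro=None, *, literal_eq2: bool = False
):
    """Estimated biomineral volume V_Bio_E for wet-mass-only specimens.

    Default divides the mass deficit by the seawater density (physically
    consistent with the measured-volume route).  ``literal_eq2=True`` divides
    by the species microdensity instead, reproducing the literal published
    formula; ``rho_micro`` is then required.
    """
    if literal_eq2:
        if rho_micro is None:
            raise DomainError("literal_eq2=True requires rho_micro")
        dm = np.asarray(dry_mass, dtype=float)
        wm = np.asarray(wet_mass, dtype=float)
        rm = np.asarray(rho_micro, dtype=float)
        if np.any(rm <= 0):
            raise DomainError(f"rho_micro must be > 0, got {rho_micro}")
        if np.any(dm <= wm):
            raise DomainError(f"dry_mass ({dry_mass}) must exceed wet_mass ({wet_mass})")
        out = (dm - wm) / rm
        return float(out) if out.ndim == 0 else out
    return biomineral_volume(dry_mass, wet_mass, rho_sw)


def microdensity(dry_mass, v_bio):
    """Skeletal microdensity ``DM / V_bio`` in g cm^-3."""
    dm = np.asarray(dry_mass, dtype=float)
    v = np.asarray(v_bio, dtype=float)
    if np.any(v <= 0):
        raise DomainError(f"v_bio must be > 0, got {v_bio}")
    if np.any(dm <= 0):
        raise DomainError(f"dry_mass must be > 0, got {dry_mass}")
    out = dm / v
    return float(out) if out.ndim == 0 else out


def porosity(v_bulk, v_bio):
    """Pore volume ``V_bulk - V_bio`` and porosity fraction ``P / V_bulk``."""
    vb = np.asarray(v_bulk, dtype=float)
    vm = np.asarray(v_bio, dtype=float)
    if np.any(vm <= 0):
        raise DomainError(f"v_bio must be > 0, got {v_bio}")
    if np.any(vb < vm):
        raise DomainError(
            f"v_bulk ({v_bulk}) < v_bio ({v_bio}): wax-coat measurement inconsistency"
        )
    pore = vb - vm
    frac = pore / vb
    if pore.ndim == 0:
        return float(pore), float(frac)
    return pore, frac


def bulk_volume_from_wax(
    waxed_dry_mass,
    waxed_wet_mass,
    dry_mass,
    rho_sw,
    wax_density: float = DEFAULT_WAX_DENSITY,
):
    """Bulk skeletal volume from wax-coated balance readings.

    The wax seal closes the pores, so the coated fragment displaces its bulk
    volume plus the volume of the wax shell.  The shell volume is recovered
    from the wax mass (coated minus uncoated dry mass) and the wax density:

    ``V_bulk = (WDM - WWM) / rho_sw - (WDM - DM) / rho_wax``
    """
    wdm = np.asarray(waxed_dry_mass, dtype=float)
    wwm = np.asarray(waxed_wet_mass, dtype=float)
    dm = np.asarray(dry_mass, dtype=float)
    rs = np.asarray(rho_sw, dtype=float)
    if np.any(wdm < dm):
        raise DomainError(
            f"waxed_dry_mass ({waxed_dry_mass}) below dry_mass ({dry_mass})"
        )
    if np.any(wdm <= wwm):
        raise DomainError("waxed_dry_mass must exceed waxed_wet_mass")
    if wax_density <= 0:
        raise DomainError(f"wax_density must be > 0, got {wax_density}")
    out = (wdm - wwm) / rs - (wdm - dm) / wax_density
    return float(out) if out.ndim == 0 else out


def species_reference_density(
    records: pd.DataFrame | Iterable[tuple[str, float]] | Mapping[str, Iterable[float]],
    *,
    stat: str = "mean",
) -> pd.DataFrame:
    """Per-species reference microdensity table.

    Aggregates per-specimen microdensities into one central value per species
    (arithmetic mean by default, ``stat="median"`` available), with the
    specimen count and the spread (sample standard deviation, or scaled MAD
    under the median).

    Returns a DataFrame indexed by species with columns
    ``rho_micro_ref``, ``n``, ``spread``.
    """
    if isinstance(records, Mapping):
        rows = [(sp, v) for sp, vals in records.items() for v in vals]
        df = pd.DataFrame(rows, columns=["species", "rho_micro"])
    elif isinstance(records, pd.DataFrame):
        df = records[["species", "rho_micro"]].copy()
    else:
        df = pd.DataFrame(list(records), columns=["species", "rho_micro"])
    if df.empty:
        raise DomainError("no microdensity records supplied")
    if df["rho_micro"].isna().any():
        raise DomainError("missing microdensity values in reference records")
    if stat == "mean":
        agg = df.groupby("species")["rho_micro"].agg(
            rho_micro_ref="mean", n="size", spread=lambda v: v.std(ddof=1)
        )
    elif stat == "median":
        agg = df.groupby("species")["rho_micro"].agg(
            rho_micro_ref="median",
            n="size",
            spread=lambda v: 1.4826 * (v - v.median()).abs().median(),
        )
    else:
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    agg["spread"] = agg["spread"].fillna(0.0)
    bad = agg[(agg["rho_micro_ref"] <= 1.0) | (agg["rho_micro_ref"] >= ARAGONITE_DENSITY)]
    if not bad.empty:
        raise DomainError(
            "species reference microdensity outside (1.0, "
            f"{ARAGONITE_DENSITY}) g cm^-3 for: {', '.join(bad.index)}"
        )
    return agg


_REQUIRED_COLUMNS = ("specimen_id", "species", "wet_mass_g")


def derive_skeletons(
    records: pd.DataFrame,
    *,
    species_table: pd.DataFrame | None = None,
    literal_eq2: bool = False,
    default_salinity: float = DEFAULT_SALINITY_PSU,
    wax_density: float = DEFAULT_WAX_DENSITY,
    reference_stat: str = "mean",
) -> pd.DataFrame:
    """Derive skeletal quantities for a table of buoyant-weight records.

    Rows with a ``dry_mass_g`` reading follow the measured route (V_Bio_M,
    microdensity, and — when wax-coated masses are present — bulk volume and
    porosity).  Rows without it follow the estimated route (V_Bio_E): the dry
    mass is estimated from the wet mass using the species reference
    microdensity, taken from ``species_table`` or computed from the measured
    rows of the same table.

    Returns a DataFrame with one row per specimen: seawater density, volumes,
    microdensity, porosity and provenance flags.
    """
    for col in _REQUIRED_COLUMNS:
        if col not in records.columns:
            raise SchemaError(f"buoyant-weight table is missing required column {col!r}")
    df = records.copy()
    if "water_temp_c" not in df.columns:
        df["water_temp_c"] = 25.0
    if "salinity_psu" not in df.columns:
        df["salinity_psu"] = default_salinity
    df["salinity_psu"] = df["salinity_psu"].fillna(default_salinity)

    out_rows = []
    measured = df[df.get("dry_mass_g").notna()] if "dry_mass_g" in df.columns else df.iloc[0:0]
    if species_table is None and not measured.empty:
        ref_rows = []
        for _, r in measured.iterrows():
            rho_sw = seawater_density(r["water_temp_c"], r["salinity_psu"])
            v = biomineral_volume(r["dry_mass_g"], r["wet_mass_g"], rho_sw)
            ref_rows.append((r["species"], microdensity(r["dry_mass_g"], v)))
        species_table = species_reference_density(ref_rows, stat=reference_stat)

    for _, r in df.iterrows():
        rho_sw = seawater_density(r["water_temp_c"], r["salinity_psu"])
        row = {
            "specimen_id": r["specimen_id"],
            "species": r["species"],
            "rho_sw_g_cm3": rho_sw,
            "v_bulk_cm3": np.nan,
            "pore_volume_cm3": np.nan,
            "porosity_fraction": np.nan,
            "literal_eq2": literal_eq2,
        }
        has_dry = "dry_mass_g" in df.columns and pd.notna(r.get("dry_mass_g"))
        if has_dry:
            v_bio = biomineral_volume(r["dry_mass_g"], r["wet_mass_g"], rho_sw)
            rho_micro = microdensity(r["dry_mass_g"], v_bio)
            row.update(
                v_bio_cm3=v_bio,
                rho_micro_g_cm3=rho_micro,
                volume_provenance="measured",
            )
            if pd.notna(r.get("waxed_dry_mass_g")) and pd.notna(r.get("waxed_wet_mass_g")):
                v_bulk = bulk_volume_from_wax(
                    r["waxed_dry_mass_g"],
                    r["waxed_wet_mass_g"],
                    r["dry_mass_g"],
                    rho_sw,
                    wax_density=wax_density,
                )
                pore, frac = porosity(v_bulk, v_bio)
                row.update(
                    v_bulk_cm3=v_bulk, pore_volume_cm3=pore, porosity_fraction=frac
                )
        else:
            if species_table is None or r["species"] not in species_table.index:
                raise DomainError(
                    f"{r['specimen_id']}: no species reference microdensity available "
                    f"for {r['species']!r} to estimate the dry mass"
                )
            rho_ref = float(species_table.loc[r["species"], "rho_micro_ref"])
            dm = estimate_dry_mass(r["wet_mass_g"], rho_sw, rho_ref)
            v_bio = estimated_biomineral_volume(
                dm, r["wet_mass_g"], rho_sw, rho_ref, literal_eq2=literal_eq2
            )
            row.update(
                v_bio_cm3=v_bio,
                rho_micro_g_cm3=rho_ref,
                volume_provenance="estimated",
            )
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    cols = [
        "specimen_id",
        "species",
        "rho_sw_g_cm3",
        "v_bio_cm3",
        "rho_micro_g_cm3",
        "v_bulk_cm3",
        "pore_volume_cm3",
        "porosity_fraction",
        "volume_provenance",
        "literal_eq2",
    ]
    return out[cols]
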