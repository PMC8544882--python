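"""Synthetic raw-measurement generator.

Builds, by *inverse construction*, the full bundle of raw tables the analysis
chain consumes — buoyant-weight balance readings, wax-coated masses,
quadrichroic optical-density triplicates, furnace masses, septa counts,
calice/coenosteum widths, and tissue-thickness points — for a configurable
community of coral species (default: five species, ten specimens per species
in each of two sample sets, mirroring a typical reef-flat collection design).

Each species profile states its *true* microdensity, porosity, morphometric
trait medians, pigment concentrations and AFDW biomass; the generator runs
the physics backwards (e.g. ``WM = (rho_micro - rho_sw) * V`` for a drawn
biomineral volume, ``OD = E . c`` for pigment concentrations) and then
applies relative instrument noise.  With zero noise the measurement chain
recovers every target exactly, which makes the generator an oracle for the
whole pipeline.  A ground-truth sidecar records every per-specimen realized
value so all derived quantities can be recomputed without rerunning the
generator.

Biological variation around the species medians is gamma for pigments and
lognormal for AFDW (matching the response families the regression assumes),
parameterized so the species *median* equals the stated target.

A second entry point, :func:`generate_planted_dataset`, builds bare
morphology matrices with a known latent axis and responses with a planted
link-scale effect of PC1/PC2 — the parameter-recovery harness for the
principal-component regression.

All randomness descends from a single seed through named
``numpy.random.SeedSequence`` spawns (one stream per measurement family), so
bundles are byte-identical for identical seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .assays import PIGMENTS, CoefficientMatrix
from .densitometry import ARAGONITE_DENSITY, seawater_density
from .errors import DomainError
from .pcreg import MORPHOLOGY_VARIABLES, pca, standardize

__all__ = [
    "SpeciesProfile",
    "PlantedEffectSpec",
    "SyntheticBundle",
    "default_species_profiles",
    "generate_raw_measurements",
    "generate_planted_dataset",
]

#: Stream names of the seed-splitting scheme, in spawn order.
_STREAMS = ("volumes", "balance", "pigments", "optical", "furnace", "corallites", "tissue")


@dataclass
class SpeciesProfile:
    """Ground-truth parameters for one species.

    Pigment and AFDW targets are species *medians* (the scale on which field
    studies report them); ``measurement_noise`` holds relative standard
    deviations per instrument class.  Morphometric spreads are plausible
    values for reef-flat corals, not literature-derived constants.
    """

    name: str
    true_rho_micro: float
    true_porosity_fraction: float
    primary_septa: int
    secondary_septa: int
    calice_width_mm: float
    ctc_ratio: float
    tissue_mm: float
    pigment_targets: dict
    afdw_target: float
    pigment_zero_prob: dict = field(default_factory=dict)
    pigment_shape: float = 6.0  # gamma shape of biological pigment variation
    afdw_sigma: float = 0.4  # log-sd of biological AFDW variation
    measurement_noise: dict = field(
        default_factory=lambda: {"balance": 0.001, "od": 0.01, "width": 0.03, "tissue": 0.05}
    )

    def validate(self) -> None:
        if not 1.2 < self.true_rho_micro < ARAGONITE_DENSITY:
            raise DomainError(
                f"{self.name}: true_rho_micro must lie in (1.2, {ARAGONITE_DENSITY}), "
                f"got {self.true_rho_micro}"
            )
        if not 0.0 <= self.true_porosity_fraction < 1.0:
            raise DomainError(
                f"{self.name}: porosity fraction must lie in [0, 1), "
                f"got {self.true_porosity_fraction}"
            )
        for p in PIGMENTS:
            if p not in self.pigment_targets:
                raise DomainError(f"{self.name}: missing pigment target for {p}")
            if self.pigment_targets[p] < 0:
                raise DomainError(f"{self.name}: pigment target {p} must be >= 0")
        if self.afdw_target <= 0:
            raise DomainError(f"{self.name}: afdw_target must be > 0")
        if self.primary_septa < 0 or self.secondary_septa < 0:
            raise DomainError(f"{self.name}: septa counts must be >= 0")
        if min(self.calice_width_mm, self.ctc_ratio, self.tissue_mm) <= 0:
            raise DomainError(f"{self.name}: widths/thickness must be > 0")
        if self.pigment_shape <= 0 or self.afdw_sigma < 0:
            raise DomainError(f"{self.name}: invalid variation parameters")
        if any(v < 0 for v in self.measurement_noise.values()):
            raise DomainError(f"{self.name}: negative measurement noise")


def default_species_profiles() -> list[SpeciesProfile]:
    """Five reef-flat species spanning the observed trait ranges.

    AFDW and chlorophyll medians follow published reef-flat values for these
    species; microdensities span the low-density *Goniastrea* to the dense
    (~2.8 g cm^-3) *Isopora*/*Montipora* skeletons.  Morphometric spreads are
    plausible, not literature constants.
    """
    return [
        SpeciesProfile(
            name="Goniastrea retiformis",
            true_rho_micro=2.50,
            true_porosity_fraction=0.55,
            primary_septa=12,
            secondary_septa=12,
            calice_width_mm=5.0,
            ctc_ratio=2.5,
            tissue_mm=1.5,
            pigment_targets={"chl_a": 49.534, "chl_b": 11.236, "chl_c": 2.0, "chl_d": 3.393},
            pigment_zero_prob={"chl_c": 0.9},
            afdw_target=86.495,
        ),
        SpeciesProfile(
            name="Isopora palifera",
            true_rho_micro=2.80,
            true_porosity_fraction=0.55,
            primary_septa=6,
            secondary_septa=6,
            calice_width_mm=1.5,
            ctc_ratio=0.8,
            tissue_mm=4.0,
            pigment_targets={"chl_a": 3.059, "chl_b": 1.112, "chl_c": 0.515, "chl_d": 0.758},
            afdw_target=27.899,
        ),
        SpeciesProfile(
            name="Montipora digitata",
            true_rho_micro=2.80,
            true_porosity_fraction=0.35,
            primary_septa=6,
            secondary_septa=6,
            calice_width_mm=1.0,
            ctc_ratio=0.9,
            tissue_mm=1.2,
            pigment_targets={"chl_a": 5.458, "chl_b": 2.379, "chl_c": 2.491, "chl_d": 2.139},
            afdw_target=29.102,
        ),
        SpeciesProfile(
            name="Porites cylindrica",
            true_rho_micro=2.70,
            true_porosity_fraction=0.35,
            primary_septa=12,
            secondary_septa=10,
            calice_width_mm=1.8,
            ctc_ratio=1.8,
            tissue_mm=3.8,
            pigment_targets={"chl_a": 24.107, "chl_b": 8.833, "chl_c": 6.047, "chl_d": 5.979},
            afdw_target=110.3,
        ),
        SpeciesProfile(
            name="Porites cf. mayeri",
            true_rho_micro=2.60,
            true_porosity_fraction=0.50,
            primary_septa=12,
            secondary_septa=8,
            calice_width_mm=1.6,
            ctc_ratio=1.4,
            tissue_mm=2.6,
            pigment_targets={"chl_a": 33.372, "chl_b": 9.683, "chl_c": 0.081, "chl_d": 5.622},
            pigment_zero_prob={"chl_c": 0.5},
            afdw_target=39.242,
        ),
    ]


@dataclass
class SyntheticBundle:
    """All raw tables the pipeline reads, plus the ground-truth sidecar."""

    buoyant_weights: pd.DataFrame
    optical_density: pd.DataFrame
    assay_meta: pd.DataFrame
    furnace: pd.DataFrame
    corallites: pd.DataFrame
    tissue: pd.DataFrame
    ground_truth: dict

    _TABLES = (
        "buoyant_weights",
        "optical_density",
        "assay_meta",
        "furnace",
        "corallites",
        "tissue",
    )

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False, lineterminator="\n")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _median_gamma(rng, median, shape, size=None):
    """Gamma draw whose *median* is the requested value."""
    scale = median / stats.gamma.ppf(0.5, shape)
    return rng.gamma(shape, scale, size=size)


def _median_lognormal(rng, median, sigma, size=None):
    return np.exp(np.log(median) + sigma * rng.standard_normal(size))


def generate_raw_measurements(
    profiles: list[SpeciesProfile] | None = None,
    n_per_species: int = 10,
    seed: int = 0,
    *,
    water_temp_C: float = 25.0,
    salinity_psu: float = 35.0,
    extract_volume_ml: float = 10.0,
    wax_density: float = 0.90,
    coefficients: CoefficientMatrix | None = None,
    outdir=None,
) -> SyntheticBundle:
    """Generate the full raw-measurement bundle for a species community.

    Two sample sets are produced per species: the morphology set (``-M``
    suffix) carries dry, wet and wax-coated masses plus corallite and tissue
    measurements; the assay set (``-A``) carries wet masses, OD triplicates
    and furnace masses.  ``pair_id`` links the i-th specimen of each set so
    downstream regression can join morphology to responses explicitly.
    """
    profiles = list(profiles) if profiles is not None else default_species_profiles()
    if not profiles:
        raise DomainError("at least one species profile is required")
    if n_per_species < 1:
        raise DomainError(f"n_per_species must be >= 1, got {n_per_species}")
    for prof in profiles:
        prof.validate()  # fail before anything is drawn or written
    E = coefficients if coefficients is not None else CoefficientMatrix.ritchie_90_acetone()

    ss = np.random.SeedSequence(seed)
    rngs = dict(zip(_STREAMS, (np.random.default_rng(c) for c in ss.spawn(len(_STREAMS)))))
    rho_sw = seawater_density(water_temp_C, salinity_psu)

    bw_rows, od_rows, meta_rows, furnace_rows, cor_rows, tissue_rows = [], [], [], [], [], []
    truth_specimens = {}

    for prof in profiles:
        abbr = "".join(w[0] for w in prof.name.split()[:2]).upper() + prof.name.split()[-1][:3]
        noise = prof.measurement_noise
        for i in range(1, n_per_species + 1):
            pair = f"{abbr}-{i:02d}"
            # ---- morphology-set specimen: measured densitometry + wax + traits
            sid_m = f"{abbr}-M{i:02d}"
            v_bio = float(rngs["volumes"].uniform(3.0, 6.0))
            dm_true = prof.true_rho_micro * v_bio
            wm_true = (prof.true_rho_micro - rho_sw) * v_bio
            v_bulk = v_bio / (1.0 - prof.true_porosity_fraction)
            v_wax = 0.03 * v_bulk
            eps = rngs["balance"].standard_normal(4) * noise["balance"]
            dm = dm_true * (1 + eps[0])
            wm = wm_true * (1 + eps[1])
            # wax-mass increment and buoyancy deficit carry their own reading
            # noise, preserving the waxed_dry >= dry and waxed_dry > waxed_wet
            # orderings that the wax protocol guarantees physically
            wdm = dm + wax_density * v_wax * (1 + eps[2])
            wwm = wdm - rho_sw * (v_bulk + v_wax) * (1 + eps[3])
            bw_rows.append(
                dict(
                    specimen_id=sid_m,
                    species=prof.name,
                    sample_set="morphology",
                    pair_id=pair,
                    dry_mass_g=dm,
                    wet_mass_g=wm,
                    water_temp_c=water_temp_C,
                    salinity_psu=salinity_psu,
                    waxed_dry_mass_g=wdm,
                    waxed_wet_mass_g=wwm,
                )
            )
            # corallites and tissue for the morphology specimen
            complexities, ratios = [], []
            for ci in range(1, 4):
                prim = int(max(0, prof.primary_septa + rngs["corallites"].integers(-1, 2)))
                sec = int(max(0, prof.secondary_septa + rngs["corallites"].integers(-2, 3)))
                max_w = prof.calice_width_mm * (
                    1 + noise["width"] * rngs["corallites"].standard_normal()
                )
                max_w = max(max_w, 0.05)
                perp_w = max_w * rngs["corallites"].uniform(0.7, 1.0)
                calice_mean = 0.5 * (max_w + perp_w)
                coen_mean = calice_mean / prof.ctc_ratio
                c1 = max(coen_mean * (1 + 0.05 * rngs["corallites"].standard_normal()), 0.01)
                c2 = max(2 * coen_mean - c1, 0.01)
                cor_rows.append(
                    dict(
                        specimen_id=sid_m,
                        corallite_index=ci,
                        primary_septa=prim,
                        secondary_septa=sec,
                        max_calice_width_mm=max_w,
                        perp_calice_width_mm=perp_w,
                        coenosteum_width_1_mm=c1,
                        coenosteum_width_2_mm=c2,
                    )
                )
                complexities.append(2 * prim + sec)
                ratios.append(calice_mean / (0.5 * (c1 + c2)))
            tissue_pts = prof.tissue_mm * (
                1 + noise["tissue"] * rngs["tissue"].standard_normal(10)
            )
            tissue_pts = np.maximum(tissue_pts, 0.05)
            for pi, tp in enumerate(tissue_pts, start=1):
                tissue_rows.append(
                    dict(specimen_id=sid_m, point_index=pi, thickness_mm=float(tp))
                )
            truth_specimens[sid_m] = dict(
                species=prof.name,
                sample_set="morphology",
                pair_id=pair,
                v_bio_cm3=v_bio,
                rho_micro_g_cm3=prof.true_rho_micro,
                v_bulk_cm3=v_bulk,
                porosity_fraction=prof.true_porosity_fraction,
                complexity=float(np.mean(complexities)),
                ctc_ratio=float(np.mean(ratios)),
                tissue_thickness_mm=float(np.mean(tissue_pts)),
            )

            # ---- assay-set specimen: wet mass only + OD triplicates + furnace
            sid_a = f"{abbr}-A{i:02d}"
            v_bio_a = float(rngs["volumes"].uniform(3.0, 6.0))
            wm_a = (prof.true_rho_micro - rho_sw) * v_bio_a
            wm_a *= 1 + rngs["balance"].standard_normal() * noise["balance"]
            bw_rows.append(
                dict(
                    specimen_id=sid_a,
                    species=prof.name,
                    sample_set="assay",
                    pair_id=pair,
                    dry_mass_g=np.nan,
                    wet_mass_g=wm_a,
                    water_temp_c=water_temp_C,
                    salinity_psu=salinity_psu,
                    waxed_dry_mass_g=np.nan,
                    waxed_wet_mass_g=np.nan,
                )
            )
            conc_true = {}
            for p in PIGMENTS:
                target = prof.pigment_targets[p]
                zp = prof.pigment_zero_prob.get(p, 0.0)
                if target <= 0 or rngs["pigments"].uniform() < zp:
                    conc_true[p] = 0.0
                else:
                    conc_true[p] = float(
                        _median_gamma(rngs["pigments"], target, prof.pigment_shape)
                    )
            c_extract = (
                np.array([conc_true[p] for p in PIGMENTS]) * v_bio_a / extract_volume_ml
            )
            od_mean = E.synthesize_od(c_extract)
            for wl, od0 in zip(E.wavelengths_nm, od_mean):
                reps = od0 * (1 + noise["od"] * rngs["optical"].standard_normal(3))
                for ri, od in enumerate(reps, start=1):
                    od_rows.append(
                        dict(specimen_id=sid_a, wavelength_nm=wl, replicate=ri, od=float(od))
                    )
            meta_rows.append(dict(specimen_id=sid_a, extract_volume_ml=extract_volume_ml))
            afdw_true = float(
                _median_lognormal(rngs["furnace"], prof.afdw_target, prof.afdw_sigma)
            )
            ashed_true = 20.0
            dried_true = ashed_true + afdw_true * v_bio_a
            feps = rngs["furnace"].standard_normal(2) * noise["balance"]
            dried = dried_true * (1 + feps[0])
            ashed = min(ashed_true * (1 + feps[1]), dried)
            furnace_rows.append(
                dict(specimen_id=sid_a, dried_mass_mg=dried, ashed_mass_mg=ashed)
            )
            truth_specimens[sid_a] = dict(
                species=prof.name,
                sample_set="assay",
                pair_id=pair,
                v_bio_cm3=v_bio_a,
                rho_micro_g_cm3=prof.true_rho_micro,
                pigments_ug_cm3=conc_true,
                afdw_mg_cm3=afdw_true,
            )

    ground_truth = {
        "config": {
            "seed": int(seed),
            "n_per_species": int(n_per_species),
            "water_temp_C": water_temp_C,
            "salinity_psu": salinity_psu,
            "rho_sw_g_cm3": rho_sw,
            "extract_volume_ml": extract_volume_ml,
            "wax_density_g_cm3": wax_density,
            "stream_order": list(_STREAMS),
        },
        "species_targets": {
            p.name: {
                k: v for k, v in asdict(p).items() if k != "name"
            }
            for p in profiles
        },
        "specimens": truth_specimens,
    }
    bundle = SyntheticBundle(
        buoyant_weights=pd.DataFrame(bw_rows),
        optical_density=pd.DataFrame(od_rows),
        assay_meta=pd.DataFrame(meta_rows),
        furnace=pd.DataFrame(furnace_rows),
        corallites=pd.DataFrame(cor_rows),
        tissue=pd.DataFrame(tissue_rows),
        ground_truth=ground_truth,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


@dataclass
class PlantedEffectSpec:
    """A planted link-scale effect of the leading morphology axes on a response."""

    b0: float = 1.0
    b_pc1: float = 0.5
    b_pc2: float = 0.0
    family: str = "gamma-log"  # or "lognormal"
    shape: float = 5.0  # gamma shape of the response noise
    sigma: float = 0.5  # log-sd for the lognormal family
    n_per_species: int = 10
    n_species: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.family not in ("gamma-log", "lognormal"):
            raise DomainError(f"family must be 'gamma-log' or 'lognormal', got {self.family!r}")
        if self.shape <= 0:
            raise DomainError(f"shape must be > 0, got {self.shape}")
        if self.sigma <= 0:
            raise DomainError(f"sigma must be > 0, got {self.sigma}")
        if self.n_per_species < 2:
            raise DomainError(f"n_per_species must be >= 2, got {self.n_per_species}")


@dataclass
class PlantedDataset:
    morphology: pd.DataFrame  # n x 5 raw-scale morphology variables
    responses: np.ndarray
    scores: np.ndarray  # realized n x 2 PC scores the responses were built from
    truth: dict


def generate_planted_dataset(spec: PlantedEffectSpec) -> PlantedDataset:
    """Correlated morphology variables plus responses with a planted PC effect.

    Two latent axes drive the five morphology variables (the first loads
    complexity, calice/coenosteum ratio and — negatively — microdensity; the
    second loads porosity and tissue thickness, echoing the loading pattern
    such trait sets produce).  The variables are standardized, decomposed by
    :func:`coralith.pcreg.pca`, and the responses are drawn from the stated
    family with link-scale mean ``b0 + b_pc1*PC1 + b_pc2*PC2`` computed from
    the *realized* scores, so the planted coefficients are exactly the
    estimands of the downstream regression.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species * spec.n_per_species
    f1 = rng.standard_normal(n)
    f2 = rng.standard_normal(n)
    e = rng.standard_normal((n, 5))
    morph = pd.DataFrame(
        {
            "rho_micro_g_cm3": 2.70 - 0.08 * f1 + 0.05 * f2 + 0.03 * e[:, 0],
            "porosity_fraction": 0.45 + 0.10 * f2 + 0.03 * e[:, 1],
            "complexity": 25.0 + 8.0 * f1 + 2.0 * e[:, 2],
            "ctc_ratio": 1.5 + 0.5 * f1 + 0.15 * e[:, 3],
            "tissue_thickness_mm": 2.5 - 0.6 * f2 + 0.2 * e[:, 4],
        },
        columns=list(MORPHOLOGY_VARIABLES),
    )
    pc = pca(standardize(morph))
    s = pc.scores[:, :2]
    eta = spec.b0 + spec.b_pc1 * s[:, 0] + spec.b_pc2 * s[:, 1]
    mu = np.exp(eta)
    if spec.family == "gamma-log":
        y = rng.gamma(spec.shape, mu / spec.shape)
    else:
        y = np.exp(eta + spec.sigma * rng.standard_normal(n))
    truth = {
        "b0": spec.b0,
        "b_pc1": spec.b_pc1,
        "b_pc2": spec.b_pc2,
        "family": spec.family,
        "shape": spec.shape,
        "sigma": spec.sigma,
        "seed": spec.seed,
        "n": n,
        "pc1_variance_fraction": float(pc.variance_fraction[0]),
        "pc2_variance_fraction": float(pc.variance_fraction[1]),
    }
    return PlantedDataset(morphology=morph, responses=y, scores=s, truth=truth)
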