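"""Archimedean densitometry: equation-of-state values, volume/density algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coralith.densitometry import (
    BuoyantWeightRecord,
    biomineral_volume,
    bulk_volume_from_wax,
    derive_skeletons,
    estimate_dry_mass,
    estimated_biomineral_volume,
    microdensity,
    porosity,
    seawater_density,
    species_reference_density,
)
from coralith.errors import DomainError, SchemaError


class TestSeawaterDensity:
    @pytest.mark.parametrize(
        ("temp", "sal", "expected", "tol"),
        [
            # UNESCO EOS-80 one-atmosphere check values (kg m^-3 / 1000)
            (25.0, 35.0, 1.023343, 1e-5),
            (0.0, 35.0, 1.028106, 1e-5),
            (4.0, 0.0, 1.000000, 1e-4),  # pure water near its density maximum
            (0.0, 0.0, 0.999842594, 1e-5),
            (25.0, 0.0, 0.99704796, 1e-5),
            (5.0, 0.0, 0.99996675, 1e-5),
            (5.0, 35.0, 1.02767547, 1e-5),
        ],
    )
    def test_eos80_check_values(self, temp, sal, expected, tol):
        assert seawater_density(temp, sal) == pytest.approx(expected, abs=tol)

    def test_monotone_decreasing_in_temperature_above_4C(self):
        t = np.arange(5.0, 40.5, 5.0)
        rho = seawater_density(t, 35.0)
        assert np.all(np.diff(rho) < 0)

    def test_monotone_increasing_in_salinity(self):
        s = np.arange(0.0, 42.5, 7.0)
        rho = seawater_density(25.0, s)
        assert np.all(np.diff(rho) > 0)

    @pytest.mark.parametrize(
        ("temp", "sal", "field"),
        [(-1.0, 35.0, "water_temp_C"), (41.0, 35.0, "water_temp_C"),
         (25.0, -0.5, "salinity_psu"), (25.0, 43.0, "salinity_psu")],
    )
    def test_out_of_range_names_field(self, temp, sal, field):
        with pytest.raises(DomainError, match=field):
            seawater_density(temp, sal)

    def test_temperature_quantized_to_tenth_degree(self):
        assert seawater_density(25.04, 35.0) == seawater_density(25.0, 35.0)
        assert seawater_density(25.06, 35.0) == seawater_density(25.1, 35.0)


class TestArchimedeanAlgebra:
    @pytest.mark.parametrize(
        ("wm", "rho_sw", "rho_micro", "expected"),
        [(1.0, 0.0, 2.8, 1.0), (1.0, 1.4, 2.8, 2.0), (1.0, 1.025, 2.8, 1.577465)],
    )
    def test_estimate_dry_mass(self, wm, rho_sw, rho_micro, expected):
        assert estimate_dry_mass(wm, rho_sw, rho_micro) == pytest.approx(expected, abs=1e-5)

    def test_estimate_dry_mass_denominator_error(self):
        with pytest.raises(DomainError):
            estimate_dry_mass(1.0, 2.8, 2.8)
        with pytest.raises(DomainError):
            estimate_dry_mass(1.0, 3.0, 2.8)

    @pytest.mark.parametrize(
        ("dm", "wm", "rho_sw", "expected"),
        [(2.0, 1.0, 1.0, 1.0), (1.577465, 1.0, 1.025, 0.563380)],
    )
    def test_biomineral_volume(self, dm, wm, rho_sw, expected):
        assert biomineral_volume(dm, wm, rho_sw) == pytest.approx(expected, abs=1e-5)

    def test_neutrally_buoyant_has_no_volume(self):
        with pytest.raises(DomainError):
            biomineral_volume(1.0, 1.0, 1.025)

    def test_microdensity_and_chained_round_trip(self):
        assert microdensity(2.0, 1.0) == 2.0
        assert microdensity(2.8, 1.0) == 2.8
        dm = estimate_dry_mass(1.0, 1.025, 2.8)
        v = biomineral_volume(dm, 1.0, 1.025)
        assert microdensity(dm, v) == pytest.approx(2.8, abs=1e-4)

    @pytest.mark.parametrize(
        ("vb", "vm", "pore", "frac"),
        [(2.0, 1.0, 1.0, 0.5), (1.0, 1.0, 0.0, 0.0), (4.0, 1.0, 3.0, 0.75)],
    )
    def test_porosity(self, vb, vm, pore, frac):
        assert porosity(vb, vm) == (pytest.approx(pore), pytest.approx(frac))

    def test_porosity_inconsistent_wax_measurement(self):
        with pytest.raises(DomainError):
            porosity(0.9, 1.0)

    def test_literal_volume_formula_understates_by_density_ratio(self):
        dm, wm, rho_sw, rho_micro = 2.8, 1.775, 1.025, 2.8
        v_default = estimated_biomineral_volume(dm, wm, rho_sw, rho_micro)
        v_literal = estimated_biomineral_volume(dm, wm, rho_sw, rho_micro, literal_eq2=True)
        assert v_literal == pytest.approx(v_default * rho_sw / rho_micro, rel=1e-12)
        with pytest.raises(DomainError):
            estimated_biomineral_volume(dm, wm, rho_sw, literal_eq2=True)


class TestArchimedeanProperties:
    @given(
        v=st.floats(0.1, 100.0),
        rho_micro=st.floats(1.2, 2.94, exclude_min=True, exclude_max=True),
        rho_sw=st.floats(1.0, 1.04),
    )
    def test_round_trip_recovers_volume_and_density(self, v, rho_micro, rho_sw):
        wm = (rho_micro - rho_sw) * v
        dm = rho_micro * v
        assert biomineral_volume(dm, wm, rho_sw) == pytest.approx(v, rel=1e-12)
        assert microdensity(dm, v) == pytest.approx(rho_micro, rel=1e-12)

    @given(
        wm=st.floats(0.1, 50.0),
        rho_micro=st.floats(1.2, 2.94, exclude_min=True, exclude_max=True),
        rho_sw=st.floats(1.0, 1.04),
    )
    def test_estimated_mass_then_volume_has_closed_form(self, wm, rho_micro, rho_sw):
        dm = estimate_dry_mass(wm, rho_sw, rho_micro)
        v = biomineral_volume(dm, wm, rho_sw)
        assert v == pytest.approx(wm / (rho_micro - rho_sw), rel=1e-12)

    @given(
        v_bio=st.floats(0.1, 10.0),
        extra1=st.floats(0.0, 10.0),
        extra2=st.floats(0.001, 10.0),
    )
    def test_pore_volume_conserved_and_fraction_monotone(self, v_bio, extra1, extra2):
        pore, frac = porosity(v_bio + extra1, v_bio)
        assert v_bio + pore == pytest.approx(v_bio + extra1, rel=1e-15)
        pore2, frac2 = porosity(v_bio + extra1 + extra2, v_bio)
        assert frac2 > frac


class TestSpeciesReference:
    def test_central_values(self):
        tab = species_reference_density({"A": [2.8, 2.8, 2.8]})
        assert tab.loc["A", "rho_micro_ref"] == pytest.approx(2.8)
        assert tab.loc["A", "n"] == 3
        tab = species_reference_density({"A": [2.6, 2.8, 3.0]})
        assert tab.loc["A", "rho_micro_ref"] == pytest.approx(2.8)

    def test_median_mode(self):
        tab = species_reference_density({"A": [2.5, 2.8, 2.85]}, stat="median")
        assert tab.loc["A", "rho_micro_ref"] == pytest.approx(2.8)

    def test_empty_errors(self):
        with pytest.raises(DomainError):
            species_reference_density({})

    def test_physically_implausible_reference_rejected(self):
        with pytest.raises(DomainError, match="A"):
            species_reference_density({"A": [0.9, 0.95]})


class TestRecordValidation:
    def test_dry_must_exceed_wet(self):
        with pytest.raises(DomainError):
            BuoyantWeightRecord("x", "sp", wet_mass_g=2.0, dry_mass_g=1.0)

    def test_waxed_dry_at_least_dry(self):
        with pytest.raises(DomainError):
            BuoyantWeightRecord(
                "x", "sp", wet_mass_g=1.0, dry_mass_g=2.0, waxed_dry_mass_g=1.9
            )

    @pytest.mark.parametrize("kw", [{"salinity_psu": 50.0}, {"water_temp_C": 45.0}])
    def test_water_context_ranges(self, kw):
        with pytest.raises(DomainError):
            BuoyantWeightRecord("x", "sp", wet_mass_g=1.0, dry_mass_g=2.0, **kw)


class TestDeriveSkeletons:
    def test_measured_and_estimated_routes(self):
        rho_sw = seawater_density(25.0, 35.0)
        v, rho, por = 4.0, 2.6, 0.5
        v_bulk = v / (1 - por)
        v_wax = 0.03 * v_bulk
        dm = rho * v
        df = pd.DataFrame(
            [
                {
                    "specimen_id": "M1", "species": "sp",
                    "dry_mass_g": dm, "wet_mass_g": (rho - rho_sw) * v,
                    "water_temp_c": 25.0, "salinity_psu": 35.0,
                    "waxed_dry_mass_g": dm + 0.9 * v_wax,
                    "waxed_wet_mass_g": dm + 0.9 * v_wax - rho_sw * (v_bulk + v_wax),
                },
                {
                    "specimen_id": "A1", "species": "sp",
                    "dry_mass_g": np.nan, "wet_mass_g": (rho - rho_sw) * 2.0,
                    "water_temp_c": 25.0, "salinity_psu": 35.0,
                    "waxed_dry_mass_g": np.nan, "waxed_wet_mass_g": np.nan,
                },
            ]
        )
        out = derive_skeletons(df).set_index("specimen_id")
        assert out.loc["M1", "v_bio_cm3"] == pytest.approx(v, rel=1e-12)
        assert out.loc["M1", "rho_micro_g_cm3"] == pytest.approx(rho, rel=1e-12)
        assert out.loc["M1", "porosity_fraction"] == pytest.approx(por, rel=1e-12)
        assert out.loc["M1", "volume_provenance"] == "measured"
        # estimated route uses the species reference computed from the measured row
        assert out.loc["A1", "v_bio_cm3"] == pytest.approx(2.0, rel=1e-12)
        assert out.loc["A1", "volume_provenance"] == "estimated"

    def test_missing_required_column_named(self):
        with pytest.raises(SchemaError, match="wet_mass_g"):
            derive_skeletons(pd.DataFrame({"specimen_id": ["a"], "species": ["s"]}))

    def test_wax_volume_correction(self):
        # without the wax-shell correction the bulk volume would be overstated
        v_bulk = bulk_volume_from_wax(3.0, 0.5, 2.8, 1.0, wax_density=0.9)
        assert v_bulk == pytest.approx(2.5 - 0.2 / 0.9, rel=1e-12)
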