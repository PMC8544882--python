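"""Buoyant-weight densitometry for a single coral fragment.

A skeletal cross-section is weighed dry in air and suspended in seawater;
Archimedes' principle turns the mass deficit into the biomineral volume,
hence the microdensity. Wax-coated readings add the bulk volume, hence
the porosity.
"""

from coralith import (
    biomineral_volume,
    bulk_volume_from_wax,
    microdensity,
    porosity,
    seawater_density,
)

# water context: reef-flat seawater at 26.3 degC, salinity 35
rho_sw = seawater_density(26.3, 35.0)
print(f"seawater density        : {rho_sw:.6f} g/cm^3")

dry_mass = 11.2094      # g, in air
wet_mass = 7.0152       # g, suspended in seawater
waxed_dry = 11.3405     # g, after the paraffin dip
waxed_wet = 4.6086      # g, wax-coated and suspended

v_bio = biomineral_volume(dry_mass, wet_mass, rho_sw)
rho_micro = microdensity(dry_mass, v_bio)
v_bulk = bulk_volume_from_wax(waxed_dry, waxed_wet, dry_mass, rho_sw)
pore, frac = porosity(v_bulk, v_bio)

print(f"biomineral volume       : {v_bio:.3f} cm^3   (solid aragonite only)")
print(f"microdensity            : {rho_micro:.3f} g/cm^3 (density of the mineral itself)")
print(f"bulk volume             : {v_bulk:.3f} cm^3   (mineral + pore space)")
print(f"porosity                : {100 * frac:.1f} %     (void fraction of the bulk volume)")
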