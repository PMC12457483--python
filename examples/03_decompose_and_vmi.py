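"""Dual-energy material decomposition and 200 keV VMI synthesis.

Simulates the 80/120 kV pair of a zirconia phantom, inverts each sinogram
pixel into water/iron basis path lengths, and reconstructs the virtual
monochromatic image next to the routine 100 kV reconstruction.
"""
import numpy as np

import demar
from demar.recon import fbp_reconstruct, to_hounsfield, to_line_integrals

lib = demar.default_library()
water, iron = lib.basis_tables()
filtration = [("Al", 2.5), ("Cu", 0.2)]
s80 = demar.build_spectrum(80, 9, filtration, lib)
s100 = demar.build_spectrum(100, 18, filtration, lib)
s120 = demar.build_spectrum(120, 9, filtration, lib)

spec = [s for s in demar.default_study_phantoms() if s.name == "zirconia"][0]
geometry = demar.Geometry()
maps = demar.generate_phantom(spec, lib)
basis = demar.project_mass_density(maps, geometry)
sinos = {s.kvp: demar.simulate_polychromatic(basis, s, lib)
         for s in (s80, s100, s120)}

dec = demar.decompose_sinograms((sinos[80], sinos[120]), (s80, s120),
                                (water, iron))
print("decomposition residual (max):", f"{dec.residual.max():.2e}")
print("water path range:", round(dec.a_water.min(), 2), "to",
      round(dec.a_water.max(), 2), "g/cm^2")
print("iron-equivalent path range:", round(dec.a_iron.min(), 3), "to",
      round(dec.a_iron.max(), 2), "g/cm^2")

vmi = demar.synthesize_vmi(dec, 200.0, (water, iron))
vmi_img = to_hounsfield(fbp_reconstruct(vmi.line_integrals, geometry),
                        water.mu_linear(200.0, density=1.0))
mu_100 = demar.effective_mu(s100, water, density=1.0)
routine = to_hounsfield(
    fbp_reconstruct(to_line_integrals(sinos[100]), geometry), mu_100)

# gelatine patch on the opposite side of the cylinder from the inserts
rr, cc = np.ogrid[:256, :256]
gel = (np.sqrt((rr - 127.5) ** 2 + (cc - 90.0) ** 2) < 15)
print("gelatine HU, routine 100 kV:", round(routine.values[gel].mean(), 1))
print("gelatine HU, VMI 200 keV:  ", round(vmi_img.values[gel].mean(), 1))

print("""
On noiseless data the decomposition residual is at machine precision and
both reconstructions put gelatine near 0 HU, but the 100 kV image carries
beam hardening around the zirconia units that the monochromatic 200 keV
synthesis removes.""")
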