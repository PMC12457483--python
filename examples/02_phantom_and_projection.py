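"""Rasterize a study phantom and simulate a polychromatic acquisition.

Shows the forward chain: density maps -> projected mass density (g/cm^2)
-> energy-integrated detector intensities, and the beam-hardening effect
visible in the log-normalized data.
"""
import numpy as np

import demar

lib = demar.default_library()
spec = [s for s in demar.default_study_phantoms() if s.name == "titanium"][0]
maps = demar.generate_phantom(spec, lib)
print("phantom materials:", maps.materials())
print("titanium mass in a 1 cm slab:",
      round(maps.total_mass_g("titanium", 10.0), 2), "g")

geometry = demar.Geometry()
basis = demar.project_mass_density(maps, geometry)
print("max projected water path:",
      round(basis.sinograms["gelatine"].max(), 2), "g/cm^2")

spectrum = demar.build_spectrum(100, 18, [("Al", 2.5), ("Cu", 0.2)], lib)
sino = demar.simulate_polychromatic(basis, spectrum, lib)
li = -np.log(sino.normalized())
print("line-integral range:", round(li.min(), 3), "to", round(li.max(), 3))

noisy = demar.add_counting_noise(sino, photons_per_pixel_flat=1e5, seed=0)
flat = sino.intensity > 0.999 * sino.flat_field  # rays missing the object
rel = noisy.intensity[flat] / sino.intensity[flat] - 1
print("noise level on unattenuated rays:", round(float(rel.std()), 5))

print("""
The titanium insert adds a dense sinusoid band to the sinogram; counting
noise at a 1e5-photon flat-field budget perturbs unattenuated rays by
~0.3% per pixel and attenuated rays proportionally more — exactly the
regime where photon starvation behind metal drives streak artifacts.""")
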