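"""Inpainting-based metal artifact reduction on a noisy 100 kV scan.

Runs the full MAR chain (reconstruct, segment metal, forward-project the
mask into a trace, inpaint, reconstruct again, reinsert metal) on the
cobalt-chrome phantom and compares artifact scores before and after.
"""
import demar
from demar.recon import fbp_reconstruct, mar_pipeline, to_hounsfield, \
    to_line_integrals

lib = demar.default_library()
s100 = demar.build_spectrum(100, 18, [("Al", 2.5), ("Cu", 0.2)], lib)
mu_100 = demar.effective_mu(s100, lib.get("water"), density=1.0)
geometry = demar.Geometry()

specs = {s.name: s for s in demar.default_study_phantoms()}
images = {}
for name in ("cobalt_chrome", "uniformity"):
    maps = demar.generate_phantom(specs[name], lib)
    basis = demar.project_mass_density(maps, geometry)
    sino = demar.simulate_polychromatic(basis, s100, lib)
    noisy = demar.add_counting_noise(sino, 2e5, seed=5)
    li = to_line_integrals(noisy)
    images[name] = {
        "plain": to_hounsfield(fbp_reconstruct(li, geometry), mu_100),
        "mar": mar_pipeline(li, geometry, mu_100),
    }

rois = demar.auto_rois(specs["cobalt_chrome"])
for arm in ("plain", "mar"):
    score = demar.artifact_score(images["cobalt_chrome"][arm],
                                 images["uniformity"][arm], rois)
    print(f"{arm:5s} artifact score: {score:7.1f} HU")

print("""
The artifact score is the absolute HU deviation of four ROIs beside the
prosthesis from a gelatine-only reference; trace inpainting removes most
of the beam-hardening and starvation streaks between the metal units.
On metal-free data (the uniformity phantom) the pipeline returns the
plain reconstruction unchanged.""")
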