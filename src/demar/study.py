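"""Configuration-driven four-arm artifact-reduction study.

For each phantom and noise replicate the runner simulates the three
acquisitions (80 kV / 9 mAs, 100 kV / 18 mAs, 120 kV / 9 mAs behind
2.5 mm Al + 0.2 mm Cu), then reconstructs four arms:

1. ``routine_100kV`` — plain FBP of the 100 kV scan;
2. ``VMI``           — water/iron decomposition of the 80+120 kV pair,
                       monochromatic synthesis at 200 keV, FBP;
3. ``MAR``           — the inpainting pipeline on the 100 kV scan;
4. ``VMI_MAR``       — the inpainting pipeline on the VMI sinogram.

Every arm of every replicate is scored against the matching arm of an
insert-free uniformity phantom processed with the same noise seed, and
all pairwise paired t-tests are collected into a comparison matrix.
Runs are fully deterministic given the base seed; the manifest records
everything needed to reproduce an output.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .decomposition import SolverConfig, decompose_sinograms
from .materials import (MaterialLibrary, build_spectrum, default_library,
                        effective_mu)
from .metrics import (ARMS, ComparisonMatrix, artifact_score, auto_rois,
                      comparison_table, dap_match_check)
from .phantom import PhantomSpec, default_study_phantoms, generate_phantom
from .projector import (Geometry, add_counting_noise,
                        project_mass_density, simulate_polychromatic)
from .recon import (DEFAULT_METAL_THRESHOLD_HU, fbp_reconstruct, mar_pipeline,
                    to_hounsfield, to_line_integrals, vmi_mar_pipeline)
from .vmi import DEFAULT_VMI_ENERGY_KEV, synthesize_vmi

__all__ = ["Acquisition", "ExperimentConfig", "StudyResult", "run_study"]

log = logging.getLogger(__name__)

DEFAULT_FILTRATION = (("Al", 2.5), ("Cu", 0.2))

# scanner-reported dose-area products (mGy cm^2) for 80/100/120 kV
DEFAULT_DAP = (155.0, 541.0, 417.0)


@dataclass(frozen=True)
class Acquisition:
    """One tube setting of the protocol."""

    kvp: float
    mas: float
    filtration: tuple = DEFAULT_FILTRATION


@dataclass
class ExperimentConfig:
    """Everything the study runner needs; defaults mirror the protocol."""

    phantoms: list[PhantomSpec] | None = None  # None -> six defaults
    uniformity: PhantomSpec | None = None      # None -> default insert-free
    low: Acquisition = Acquisition(80.0, 9.0)
    routine: Acquisition = Acquisition(100.0, 18.0)
    high: Acquisition = Acquisition(120.0, 9.0)
    geometry: Geometry | None = None           # None -> phantom-matched default
    flat_photons_at_9mas: float = 1e5          # counting budget, scales with mAs
    n_replicates: int = 8
    base_seed: int = 0
    vmi_energy_kev: float = DEFAULT_VMI_ENERGY_KEV
    metal_threshold_hu: float = DEFAULT_METAL_THRESHOLD_HU
    solver: SolverConfig = field(default_factory=SolverConfig)
    roi_radius_px: float = 5.0
    roi_gap_px: float = 3.0
    uniformity_roi_radius_px: float = 8.0
    alpha: float = 0.01
    dap_mgy_cm2: tuple = DEFAULT_DAP

    def __post_init__(self):
        kvs = {self.low.kvp, self.routine.kvp, self.high.kvp}
        if len(kvs) != 3:
            raise ValueError("the dual-energy pair and the routine "
                             "acquisition must use three distinct voltages")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class StudyResult:
    """Scores, the pairwise comparison, and the provenance manifest."""

    scores: pd.DataFrame
    comparison: ComparisonMatrix
    manifest: dict
    images: dict | None = None


def _acq_seed(base: int, phantom_idx: int, replicate: int, acq_idx: int) -> int:
    ss = np.random.SeedSequence([int(base), phantom_idx, replicate, acq_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _simulate_clean(spec, geometry, spectra, library):
    maps = generate_phantom(spec, library)
    basis = project_mass_density(maps, geometry)
    return {name: simulate_polychromatic(basis, s, library)
            for name, s in spectra.items()}


def _reconstruct_arms(noisy, spectra, geometry, library, config):
    """All four arm reconstructions (HU) for one noisy measurement set."""
    water, iron = library.basis_tables()
    mu_ref_100 = effective_mu(spectra["routine"], water,
                              density=water.density or 1.0)
    li_100 = to_line_integrals(noisy["routine"])
    routine = to_hounsfield(
        fbp_reconstruct(li_100, geometry, arm="routine_100kV"), mu_ref_100)

    dec = decompose_sinograms((noisy["low"], noisy["high"]),
                              (spectra["low"], spectra["high"]),
                              (water, iron), config.solver)
    vmi_sino = synthesize_vmi(dec, config.vmi_energy_kev, (water, iron))
    mu_ref_vmi = water.mu_linear(config.vmi_energy_kev,
                                 density=water.density or 1.0)
    vmi_img = to_hounsfield(
        fbp_reconstruct(vmi_sino.line_integrals, geometry, arm="VMI"),
        mu_ref_vmi)

    mar = mar_pipeline(li_100, geometry, mu_ref_100,
                       config.metal_threshold_hu)
    vmi_mar = vmi_mar_pipeline(dec, config.vmi_energy_kev, geometry,
                               (water, iron), config.metal_threshold_hu)
    return {"routine_100kV": routine, "VMI": vmi_img, "MAR": mar,
            "VMI_MAR": vmi_mar}


def run_study(config: ExperimentConfig | None = None,
              library: MaterialLibrary | None = None,
              keep_images: bool = False,
              output_dir=None) -> StudyResult:
    """Run the full four-arm study and collect scores and statistics.

    Noiseless sinograms are simulated once per phantom; each replicate
    then draws fresh counting noise (all four arms see the same noisy
    measurements, preserving the paired structure of the comparison).
    """
    config = config or ExperimentConfig()
    lib = library or default_library()
    phantoms = config.phantoms if config.phantoms is not None \
        else default_study_phantoms()[:-1]
    uniformity = config.uniformity or default_study_phantoms(
        grid_size=phantoms[0].grid_size,
        pixel_spacing_mm=phantoms[0].pixel_spacing_mm)[-1]
    geometry = config.geometry or Geometry(
        image_size=phantoms[0].grid_size,
        pixel_spacing_mm=phantoms[0].pixel_spacing_mm)

    acqs = {"low": config.low, "routine": config.routine, "high": config.high}
    spectra = {name: build_spectrum(a.kvp, a.mas, a.filtration, lib)
               for name, a in acqs.items()}
    budgets = {name: config.flat_photons_at_9mas * a.mas / 9.0
               for name, a in acqs.items()}

    t0 = time.time()
    clean = {}
    for spec in [*phantoms, uniformity]:
        clean[spec.name] = _simulate_clean(spec, geometry, spectra, lib)
        log.info("simulated %-16s (%.1f s)", spec.name, time.time() - t0)

    rows = []
    images: dict = {}
    all_specs = [*phantoms, uniformity]
    for rep in range(config.n_replicates):
        arm_images = {}
        for p_idx, spec in enumerate(all_specs):
            noisy = {name: add_counting_noise(
                         clean[spec.name][name], budgets[name],
                         _acq_seed(config.base_seed, p_idx, rep, a_idx))
                     for a_idx, name in enumerate(acqs)}
            t1 = time.time()
            arm_images[spec.name] = _reconstruct_arms(
                noisy, spectra, geometry, lib, config)
            log.info("rep %d %-16s reconstructed in %.1f s", rep,
                     spec.name, time.time() - t1)
        for spec in phantoms:
            rois = auto_rois(spec, config.roi_radius_px, config.roi_gap_px,
                             config.uniformity_roi_radius_px)
            for arm in ARMS:
                score = artifact_score(arm_images[spec.name][arm],
                                       arm_images[uniformity.name][arm],
                                       rois)
                rows.append({"phantom": spec.name, "replicate": rep,
                             "arm": arm, "score": score})
        if keep_images:
            images[rep] = arm_images

    scores = pd.DataFrame(rows)
    comparison = comparison_table(scores, alpha=config.alpha)
    manifest = {
        "demar_version": __version__,
        "numpy_version": np.__version__,
        "base_seed": config.base_seed,
        "n_replicates": config.n_replicates,
        "phantoms": [s.name for s in phantoms],
        "grid_size": geometry.image_size,
        "n_views": geometry.n_views,
        "acquisitions": {n: {"kvp": a.kvp, "mas": a.mas,
                             "filtration": list(map(list, a.filtration))}
                         for n, a in acqs.items()},
        "flat_photons_at_9mas": config.flat_photons_at_9mas,
        "vmi_energy_kev": config.vmi_energy_kev,
        "metal_threshold_hu": config.metal_threshold_hu,
        "dap_percent_difference": dap_match_check(*config.dap_mgy_cm2),
        "runtime_s": round(time.time() - t0, 1),
    }
    result = StudyResult(scores=scores, comparison=comparison,
                         manifest=manifest,
                         images=images if keep_images else None)
    if output_dir is not None:
        _write_outputs(result, output_dir, config)
    return result


def _write_outputs(result: StudyResult, output_dir, config) -> None:
    import pathlib

    out = pathlib.Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.scores.to_csv(out / "scores.csv", index=False)
    result.comparison.p_values.to_csv(out / "comparison_p_values.csv")
    result.comparison.direction.to_csv(out / "comparison_direction.csv")
    result.comparison.formatted(config.alpha).to_csv(
        out / "comparison_formatted.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    if result.images:
        from .io import save_image_nifti
        for rep, by_phantom in result.images.items():
            for phantom, by_arm in by_phantom.items():
                for arm, img in by_arm.items():
                    save_image_nifti(
                        img, out / f"{phantom}_rep{rep}_{arm}.nii")
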