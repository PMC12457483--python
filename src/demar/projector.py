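"""Forward projection and polychromatic intensity simulation.

Parallel-beam geometry over 180 degrees is the working model: the
decomposition and artifact-reduction logic under test are geometry
agnostic, and parallel beams admit closed-form checks (chord lengths,
Beer-Lambert limits).  Line integrals are computed with
:func:`skimage.transform.radon`, whose detector has one channel per image
pixel plus diagonal padding (363 channels for the default 256 grid).

The detector model is an ideal energy-integrating one: each photon of
energy ``E`` contributes a signal proportional to ``E``.  The measured
signal for a ray with basis path lengths ``A_m`` (g/cm^2) is the
energy-bin sum of ``I_0(E) * E * exp(-sum_m mu_m(E) A_m)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import radon

from .materials import MaterialLibrary, Spectrum, default_library
from .phantom import BasisDensityMaps

__all__ = [
    "Geometry",
    "BasisSinograms",
    "IntensitySinogram",
    "project_mass_density",
    "project_image",
    "simulate_polychromatic",
    "add_counting_noise",
]


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry tied to a square image grid."""

    n_views: int = 360
    angular_range_deg: float = 180.0
    image_size: int = 256
    pixel_spacing_mm: float = 0.45

    def __post_init__(self):
        if self.n_views < 1:
            raise ValueError("need at least one view")
        if not 0 < self.angular_range_deg <= 360:
            raise ValueError("angular range must lie in (0, 360] degrees")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def thetas_deg(self) -> np.ndarray:
        return np.linspace(0.0, self.angular_range_deg, self.n_views,
                           endpoint=False)

    @property
    def n_channels(self) -> int:
        # skimage.radon pads the image to its diagonal
        return int(np.ceil(np.sqrt(2) * self.image_size))

    @property
    def channel_spacing_mm(self) -> float:
        return self.pixel_spacing_mm

    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_views, self.n_channels)


@dataclass
class BasisSinograms:
    """Projected mass density per material, g/cm^2, (views, channels)."""

    sinograms: dict[str, np.ndarray]
    geometry: Geometry

    def __post_init__(self):
        for name, s in self.sinograms.items():
            if s.shape != self.geometry.sinogram_shape():
                raise ValueError(
                    f"sinogram {name!r} shape {s.shape} does not match "
                    f"geometry {self.geometry.sinogram_shape()}")

    def materials(self) -> list[str]:
        return sorted(self.sinograms)


@dataclass
class IntensitySinogram:
    """Energy-integrated detector signal, (views, channels).

    ``flat_field`` is the signal of an unattenuated ray under the same
    spectrum (spatially uniform source model, so a scalar).
    """

    intensity: np.ndarray
    flat_field: float
    geometry: Geometry
    kvp: float
    mas: float

    def __post_init__(self):
        if self.intensity.shape != self.geometry.sinogram_shape():
            raise ValueError("intensity shape does not match geometry")
        if self.flat_field <= 0:
            raise ValueError("flat field must be positive")

    def normalized(self) -> np.ndarray:
        """I / I_flat, the quantity the decomposition solver consumes."""
        return self.intensity / self.flat_field


def project_image(image: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Line integrals of a 2D image; output units = image units * cm.

    The pixel-step line integral from ``radon`` is scaled by the pixel
    spacing converted to cm, so projecting a density map in g/cm^3 yields
    projected mass density in g/cm^2.
    """
    if image.shape != (geometry.image_size, geometry.image_size):
        raise ValueError(
            f"image shape {image.shape} does not match geometry grid "
            f"({geometry.image_size})")
    sino = radon(image, theta=geometry.thetas_deg, circle=False)
    return sino.T * (geometry.pixel_spacing_mm / 10.0)


def project_mass_density(maps: BasisDensityMaps,
                         geometry: Geometry) -> BasisSinograms:
    """Projected mass density A_m (g/cm^2) for every material map."""
    if maps.shape != (geometry.image_size, geometry.image_size):
        raise ValueError("density maps do not match the geometry grid")
    if abs(maps.pixel_spacing_mm - geometry.pixel_spacing_mm) > 1e-12:
        raise ValueError("density-map and geometry pixel spacings differ")
    sinos = {m: project_image(maps.maps[m], geometry)
             for m in maps.materials()}
    return BasisSinograms(sinograms=sinos, geometry=geometry)


def simulate_polychromatic(basis: BasisSinograms, spectrum: Spectrum,
                           library: MaterialLibrary | None = None
                           ) -> IntensitySinogram:
    """Polychromatic energy-integrating detector signal for each ray.

    Per sinogram pixel: ``sum_E S(E) E exp(-sum_m mu_m(E) A_m)`` with the
    flat field given by the same sum at zero path length.
    """
    lib = library or default_library()
    energies = spectrum.energies
    weights = spectrum.fluence * energies * spectrum.grid.width_kev
    flat = float(weights.sum())
    if flat <= 0:
        raise ValueError("spectrum carries no fluence")

    shape = basis.geometry.sinogram_shape()
    exponent = np.zeros((shape[0] * shape[1], energies.size))
    for material in basis.materials():
        mu = lib.get(material).mu(energies)  # cm^2/g
        exponent += basis.sinograms[material].reshape(-1, 1) * mu
    intensity = np.exp(-exponent) @ weights
    return IntensitySinogram(intensity=intensity.reshape(shape),
                             flat_field=flat, geometry=basis.geometry,
                             kvp=spectrum.kvp, mas=spectrum.mas)


def add_counting_noise(sino: IntensitySinogram,
                       photons_per_pixel_flat: float,
                       seed: int) -> IntensitySinogram:
    """Poisson counting noise at a given flat-field photon budget.

    The signal is scaled so an unattenuated ray collects
    ``photons_per_pixel_flat`` expected counts, an independent Poisson
    variate is drawn per pixel (floored at one count so logarithms stay
    finite), and the result is scaled back.  Deterministic for fixed seed.
    """
    if photons_per_pixel_flat <= 0:
        raise ValueError("photon budget must be positive")
    rng = np.random.default_rng(seed)
    expected = sino.normalized() * photons_per_pixel_flat
    counts = np.maximum(rng.poisson(expected), 1)
    noisy = counts / photons_per_pixel_flat * sino.flat_field
    return IntensitySinogram(intensity=noisy.astype(float),
                             flat_field=sino.flat_field,
                             geometry=sino.geometry,
                             kvp=sino.kvp, mas=sino.mas)
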