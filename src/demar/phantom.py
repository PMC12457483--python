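"""Digital 2D analogs of the gelatine-cylinder test phantoms.

The physical objects being emulated are gelatine-filled, 3D-printed PLA
cylinders (10 cm diameter) carrying one dental restorative or prosthetic
specimen each.  Here each phantom is a 2D axial slice: a PLA annulus, a
gelatine disc, and disc/ellipse inserts of surrogate dental materials.
Rasterization is deterministic pixel-center point sampling, which keeps
area and mass checks exact to state.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .materials import MaterialLibrary, default_library

__all__ = [
    "Insert",
    "PhantomSpec",
    "BasisDensityMaps",
    "generate_phantom",
    "default_study_phantoms",
]


@dataclass(frozen=True)
class Insert:
    """One insert: a disc or axis-aligned ellipse of a single material."""

    material: str
    center_mm: tuple[float, float]  # (x, y) from the phantom center
    radii_mm: tuple[float, float]   # (rx, ry); equal for a disc
    density: float                  # g/cm^3

    def __post_init__(self):
        if min(self.radii_mm) <= 0:
            raise ValueError("insert radii must be positive")
        if self.density <= 0:
            raise ValueError("insert density must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one simulated phantom slice."""

    name: str
    grid_size: int = 256
    pixel_spacing_mm: float = 0.45
    cylinder_diameter_mm: float = 100.0
    shell_material: str = "PLA"
    shell_thickness_mm: float = 2.0
    shell_density: float = 1.25
    fill_material: str = "gelatine"
    fill_density: float = 1.02
    inserts: tuple[Insert, ...] = ()

    def __post_init__(self):
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.cylinder_diameter_mm <= 0:
            raise ValueError("cylinder diameter must be positive")
        inner = self.cylinder_diameter_mm / 2 - self.shell_thickness_mm
        for ins in self.inserts:
            cx, cy = ins.center_mm
            if np.hypot(cx, cy) + max(ins.radii_mm) > inner:
                raise ValueError(
                    f"insert {ins.material!r} extends outside the cylinder")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        raw = yaml.safe_load(open(path))
        inserts = tuple(Insert(material=i["material"],
                               center_mm=tuple(i["center_mm"]),
                               radii_mm=tuple(i["radii_mm"]),
                               density=i["density"])
                        for i in raw.pop("inserts", ()))
        return cls(inserts=inserts, **raw)


@dataclass
class BasisDensityMaps:
    """Per-material mass-density images (g/cm^3) on one shared grid.

    Exactly one material occupies any pixel (no partial-volume mixing);
    ``labels`` records which, with '' for air/background.
    """

    maps: dict[str, np.ndarray]
    labels: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self):
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError("density maps must share one grid")
        for name, m in self.maps.items():
            if np.any(m < 0):
                raise ValueError(f"negative density in map {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def materials(self) -> list[str]:
        return sorted(self.maps)

    def total_mass_g(self, material: str, slice_thickness_mm: float = 1.0) -> float:
        """Integrated mass of one material over the slice (g)."""
        pix_area_cm2 = (self.pixel_spacing_mm / 10.0) ** 2
        return float(self.maps[material].sum() * pix_area_cm2
                     * slice_thickness_mm / 10.0)


def _pixel_coords_mm(n: int, spacing: float):
    c = (np.arange(n) - (n - 1) / 2.0) * spacing
    return np.meshgrid(c, c, indexing="xy")


def generate_phantom(spec: PhantomSpec,
                     library: MaterialLibrary | None = None) -> BasisDensityMaps:
    """Rasterize a phantom spec into per-material density maps.

    The gelatine disc fills the cylinder interior, the PLA shell forms an
    annulus at the rim, and inserts overwrite whatever lies under their
    footprint.  All materials must be registered in the library.
    """
    lib = library or default_library()
    for name in {spec.shell_material, spec.fill_material,
                 *(i.material for i in spec.inserts)}:
        lib.get(name)  # raises MaterialLookupError if missing

    n = spec.grid_size
    xx, yy = _pixel_coords_mm(n, spec.pixel_spacing_mm)
    rr = np.hypot(xx, yy)
    r_out = spec.cylinder_diameter_mm / 2.0
    r_in = r_out - spec.shell_thickness_mm

    labels = np.full((n, n), "", dtype=object)
    labels[rr <= r_out] = spec.shell_material
    labels[rr <= r_in] = spec.fill_material
    for ins in spec.inserts:
        cx, cy = ins.center_mm
        rx, ry = ins.radii_mm
        inside = (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2) <= 1.0
        labels[inside] = ins.material

    densities = {spec.shell_material: spec.shell_density,
                 spec.fill_material: spec.fill_density}
    for ins in spec.inserts:
        densities[ins.material] = ins.density

    maps = {}
    for material, rho in densities.items():
        m = np.zeros((n, n))
        m[labels == material] = rho
        maps[material] = m
    return BasisDensityMaps(maps=maps, labels=labels.astype(str),
                            pixel_spacing_mm=spec.pixel_spacing_mm)


# Default insert layouts, chosen to reflect the scale and structure of the
# corresponding restorations: fillings and the implant screw are single
# bodies a few mm across, while fixed dental prostheses are multi-unit
# bridges — three units on an arc, the configuration whose interleaved
# metal shadows make sinogram inpainting genuinely hard.  Inserts sit
# ~12 mm off the rotation axis: a specimen suspended in gelatine never
# coincides exactly with the scanner isocenter, and an exactly centered
# disc is a degenerate geometry whose metal trace is the same channel
# band in every view.
_ARC = ((9.2, -7.7), (12.0, 0.0), (9.2, 7.7))  # three units, 12 mm arc
_SINGLE = ((12.0, 0.0),)
_STUDY_INSERTS = {
    "amalgam": (_SINGLE, 4.0),          # occlusal filling in a molar
    "composite_resin": (_SINGLE, 4.0),  # resin filling
    "zirconia": (_ARC, 3.5),            # multi-unit fixed prosthesis
    "cobalt_chrome": (_ARC, 3.5),       # multi-unit fixed prosthesis
    "titanium": (_SINGLE, 3.0),         # implant screw body
    "high_gold": (_ARC, 3.5),           # multi-unit fixed prosthesis
}


def default_study_phantoms(grid_size: int = 256,
                           pixel_spacing_mm: float = 0.45,
                           library: MaterialLibrary | None = None
                           ) -> list[PhantomSpec]:
    """The six single-insert study phantoms plus one uniformity phantom.

    One phantom per dental material, insert centered in the cylinder, and a
    final insert-free phantom supplying the uniformity reference region for
    artifact scoring.
    """
    lib = library or default_library()
    specs = []
    for material, (centers, radius) in _STUDY_INSERTS.items():
        rho = lib.get(material).density
        inserts = tuple(Insert(material=material, center_mm=c,
                               radii_mm=(radius, radius), density=rho)
                        for c in centers)
        specs.append(PhantomSpec(
            name=material, grid_size=grid_size,
            pixel_spacing_mm=pixel_spacing_mm, inserts=inserts))
    specs.append(PhantomSpec(name="uniformity", grid_size=grid_size,
                             pixel_spacing_mm=pixel_spacing_mm))
    return specs
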