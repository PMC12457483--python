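"""X-ray spectra and energy-dependent mass attenuation coefficients.

A :class:`MaterialLibrary` bundles tabulated mass attenuation coefficients
``mu/rho(E)`` (cm^2/g) for elements, compounds and the dental-material
surrogates used by the study phantoms.  Absorption edges are encoded as
duplicate-energy rows (below-edge value first), and interpolation is
log-log and side-limited, so it never bridges an edge discontinuity.

Tube spectra use a Kramers-type bremsstrahlung shape filtered through
Beer-Lambert attenuation of the configured filtration layers.  The shape is
deliberately generic: the simulation and the decomposition solver share one
spectrum model, which is all the polychromatic inversion requires.  A CSV
import path (:meth:`Spectrum.from_csv`) allows substituting measured or
externally generated spectra to probe spectrum-mismatch sensitivity.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "EnergyGrid",
    "Spectrum",
    "AttenuationTable",
    "MaterialLibrary",
    "build_spectrum",
    "mass_attenuation_coefficient",
    "mixture_attenuation",
    "default_library",
]


class MaterialLookupError(KeyError):
    """Requested material is not registered in the library."""


class EnergyRangeError(ValueError):
    """Requested energy lies outside a table's tabulated range."""


@dataclass(frozen=True)
class EnergyGrid:
    """Energy bins in keV: centers plus a uniform bin width."""

    centers: np.ndarray
    width_kev: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("energy grid must be a non-empty 1-D array")
        if np.any(c <= 0):
            raise ValueError("all energies must be positive")
        if c.size > 1 and np.any(np.diff(c) <= 0):
            raise ValueError("energies must be strictly increasing")

    @property
    def e_max(self) -> float:
        return float(self.centers[-1])


@dataclass(frozen=True)
class Spectrum:
    """Incident fluence per energy bin for one acquisition.

    Fluence is in arbitrary units proportional to the current-time product
    (mAs); the decomposition and line-integral conversions only ever use
    flat-field-normalized quantities, so the absolute scale is free.
    """

    grid: EnergyGrid
    fluence: np.ndarray
    kvp: float
    mas: float = 1.0
    filtration: tuple = ()

    def __post_init__(self):
        f = np.asarray(self.fluence, dtype=float)
        object.__setattr__(self, "fluence", f)
        if f.shape != self.grid.centers.shape:
            raise ValueError("fluence and energy grid shapes differ")
        if np.any(f < 0):
            raise ValueError("fluence must be non-negative")
        if np.any(f[self.grid.centers > self.kvp] > 0):
            raise ValueError("fluence above the tube voltage must be zero")

    @property
    def energies(self) -> np.ndarray:
        return self.grid.centers

    def total_fluence(self) -> float:
        return float(self.fluence.sum() * self.grid.width_kev)

    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy in keV."""
        w = self.fluence.sum()
        if w <= 0:
            raise ValueError("spectrum has zero total fluence")
        return float((self.fluence * self.energies).sum() / w)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.grid, self.fluence * factor, self.kvp,
                        self.mas * factor, self.filtration)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["energy_keV", "fluence"])
            for e, f in zip(self.energies, self.fluence):
                w.writerow([f"{e:.6g}", f"{f:.8g}"])

    @classmethod
    def from_csv(cls, path, kvp: float | None = None) -> "Spectrum":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        e, f = rows[:, 0], rows[:, 1]
        width = float(np.median(np.diff(e))) if e.size > 1 else 1.0
        return cls(EnergyGrid(e, width), f, kvp=float(kvp or e[-1]))


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated mass attenuation coefficient for one material.

    Duplicate energies flag absorption edges; queries exactly at a
    duplicated knot resolve to the above-edge value, queries approaching
    from below interpolate toward the below-edge value.
    """

    material: str
    energies_kev: np.ndarray
    mu_over_rho: np.ndarray
    density: float | None = None
    composition: tuple = ()

    def __post_init__(self):
        e = np.asarray(self.energies_kev, dtype=float)
        m = np.asarray(self.mu_over_rho, dtype=float)
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "mu_over_rho", m)
        if e.shape != m.shape or e.ndim != 1:
            raise ValueError("energies and coefficients must be matching 1-D arrays")
        if np.any(np.diff(e) < 0):
            raise ValueError("table energies must be non-decreasing")
        if np.any(m <= 0):
            raise ValueError("attenuation coefficients must be positive")

    @property
    def e_min(self) -> float:
        return float(self.energies_kev[0])

    @property
    def e_max(self) -> float:
        return float(self.energies_kev[-1])

    def mu(self, energy_kev) -> np.ndarray | float:
        """Log-log interpolated mass attenuation coefficient (cm^2/g)."""
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.e_min) or np.any(e > self.e_max):
            raise EnergyRangeError(
                f"energy outside [{self.e_min}, {self.e_max}] keV for "
                f"{self.material!r}")
        out = np.exp(np.interp(np.log(e), np.log(self.energies_kev),
                               np.log(self.mu_over_rho)))
        return float(out) if np.isscalar(energy_kev) else out

    def mu_linear(self, energy_kev, density: float | None = None):
        """Linear attenuation coefficient (1/cm) at nominal density."""
        rho = density if density is not None else self.density
        if rho is None:
            raise ValueError(f"no density registered for {self.material!r}")
        return self.mu(energy_kev) * rho


def _load_table_csv(name: str, filename: str, density=None) -> AttenuationTable:
    ref = resources.files("demar.data.attenuation") / filename
    rows = np.loadtxt(str(ref), delimiter=",", skiprows=1, ndmin=2)
    return AttenuationTable(name, rows[:, 0], rows[:, 1], density=density)


class MaterialLibrary:
    """Registry of attenuation tables, with the two basis materials flagged."""

    def __init__(self, tables: dict[str, AttenuationTable],
                 basis: tuple[str, str] = ("water", "iron")):
        self._tables = dict(tables)
        for b in basis:
            if b not in self._tables:
                raise MaterialLookupError(f"basis material {b!r} not registered")
        self.basis = tuple(basis)

    def __contains__(self, name) -> bool:
        return name in self._tables

    def names(self) -> list[str]:
        return sorted(self._tables)

    def get(self, name: str) -> AttenuationTable:
        try:
            return self._tables[name]
        except KeyError:
            raise MaterialLookupError(f"unknown material {name!r}") from None

    def register(self, table: AttenuationTable) -> None:
        self._tables[table.material] = table

    def basis_tables(self) -> tuple[AttenuationTable, AttenuationTable]:
        return self.get(self.basis[0]), self.get(self.basis[1])

    def mixture_table(self, name: str, composition: dict[str, float],
                      density: float | None = None) -> AttenuationTable:
        """Build a mixture table on the union grid of its constituents.

        The mixture rule is the mass-fraction-weighted sum of constituent
        coefficients; edge duplicates of every constituent are preserved.
        """
        _check_fractions(composition.values())
        tables = {m: self.get(m) for m in composition}
        energies = np.unique(np.concatenate(
            [t.energies_kev for t in tables.values()]))
        lo = max(t.e_min for t in tables.values())
        hi = min(t.e_max for t in tables.values())
        energies = energies[(energies >= lo) & (energies <= hi)]
        # re-insert duplicate edge rows falling inside the clipped range
        dups = np.concatenate([
            t.energies_kev[:-1][np.diff(t.energies_kev) == 0]
            for t in tables.values()])
        dups = np.unique(dups[(dups > lo) & (dups < hi)])
        grid = np.sort(np.concatenate([energies, dups]))
        mu = np.zeros_like(grid)
        for i, e in enumerate(grid):
            # for the first of a duplicated pair take the below-edge limit
            is_below_side = i + 1 < grid.size and grid[i + 1] == e
            q = np.nextafter(e, 0.0) if is_below_side else e
            mu[i] = sum(frac * tables[m].mu(q)
                        for m, frac in composition.items())
        return AttenuationTable(name, grid, mu, density=density,
                                composition=tuple(sorted(composition.items())))

    @classmethod
    def from_registry(cls, path=None) -> "MaterialLibrary":
        """Load the packaged registry (or a user YAML of the same schema)."""
        if path is None:
            text = (resources.files("demar.data") / "materials.yaml").read_text()
        else:
            text = open(path).read()
        reg = yaml.safe_load(text)
        tables: dict[str, AttenuationTable] = {}
        for name, entry in reg.get("tables", {}).items():
            tables[name] = _load_table_csv(name, entry["file"],
                                           density=entry.get("density"))
        lib = cls(tables, basis=tuple(reg.get("basis", ("water", "iron"))))
        for name, entry in reg.get("mixtures", {}).items():
            lib.register(lib.mixture_table(name, entry["composition"],
                                           density=entry.get("density")))
        return lib


@lru_cache(maxsize=1)
def default_library() -> MaterialLibrary:
    """The packaged material library (cached singleton)."""
    return MaterialLibrary.from_registry()


def _check_fractions(fractions) -> None:
    fr = np.asarray(list(fractions), dtype=float)
    if np.any(fr < 0):
        raise ValueError("mass fractions must be non-negative")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"mass fractions must sum to 1 (got {fr.sum()!r})")


def mass_attenuation_coefficient(material: str, energy_kev,
                                 library: MaterialLibrary | None = None):
    """Mass attenuation coefficient (cm^2/g) of a registered material."""
    lib = library or default_library()
    return lib.get(material).mu(energy_kev)


def mixture_attenuation(composition, energy_kev,
                        library: MaterialLibrary | None = None):
    """Mass-fraction-weighted coefficient of a mixture at one energy.

    ``composition`` is a sequence of ``(material, mass_fraction)`` pairs;
    fractions must be non-negative and sum to one.
    """
    comp = list(composition)
    _check_fractions(f for _, f in comp)
    lib = library or default_library()
    return sum(frac * lib.get(m).mu(energy_kev) for m, frac in comp)


# filtration layer densities come from the registry tables


def build_spectrum(kvp: float, mas: float, filtration=(),
                   library: MaterialLibrary | None = None,
                   fluence_scale: float = 1.0) -> Spectrum:
    """Kramers-type filtered bremsstrahlung spectrum on a 1 keV grid.

    Parameters
    ----------
    kvp:
        Tube voltage in kV, limited to [40, 150].
    mas:
        Current-time product; total fluence scales linearly with it.
    filtration:
        Sequence of ``(material, thickness_mm)`` layers, attenuated by
        Beer-Lambert with each layer's linear attenuation coefficient.
    """
    if not 40 <= kvp <= 150:
        raise ValueError(f"tube voltage {kvp} kV outside supported [40, 150]")
    if mas <= 0:
        raise ValueError("mAs must be positive")
    lib = library or default_library()
    energies = np.arange(5.0, float(kvp) + 0.5, 1.0)
    grid = EnergyGrid(energies, 1.0)
    # unfiltered Kramers shape: N(E) ∝ (kVp - E)/E
    fluence = np.clip(kvp - energies, 0.0, None) / energies
    for material, thickness_mm in filtration:
        table = lib.get(material)
        mu_lin = table.mu_linear(energies)  # 1/cm at nominal density
        fluence = fluence * np.exp(-mu_lin * thickness_mm / 10.0)
    norm = fluence.sum()
    if norm <= 0:
        raise ValueError("filtration removed the entire spectrum")
    fluence = fluence / norm * mas * fluence_scale
    return Spectrum(grid, fluence, kvp=float(kvp), mas=float(mas),
                    filtration=tuple((m, float(t)) for m, t in filtration))


def effective_mu(spectrum: Spectrum, table: AttenuationTable,
                 density: float | None = None) -> float:
    """Energy-fluence-weighted linear attenuation coefficient (1/cm).

    The thin-object effective coefficient under an ideal energy-integrating
    detector; used as the Hounsfield water reference for polychromatic
    reconstructions.
    """
    w = spectrum.fluence * spectrum.energies
    mu = table.mu_linear(spectrum.energies, density=density)
    return float((w * mu).sum() / w.sum())
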