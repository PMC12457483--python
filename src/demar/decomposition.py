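"""Projection-domain dual-energy material decomposition.

Each sinogram pixel is measured twice, once per tube voltage.  The solver
recovers the two basis path lengths ``(A_water, A_iron)`` in g/cm^2 by
minimizing, per pixel, the l2 residual between the flat-field-normalized
measurements and the polychromatic forward model

    m_n(A) = sum_E w_n(E) exp(-mu_water(E) A_water - mu_iron(E) A_iron),

where ``w_n(E)`` are the normalized energy-fluence weights of spectrum
``n``.  The residual lives in the intensity domain (not log-transformed),
matching the model actually measured by an energy-integrating detector.

The iteration is a damped Gauss-Newton scheme: with two measurements and
two unknowns the linearized system is square, the Jacobian is analytic,
and each step is halved until the residual norm does not increase.  The
iteration starts from ``A = 0`` (the unattenuated-ray fixed point) and
runs a fixed budget of 200 iterations with an early exit once the step
norm is negligible; non-convergence surfaces through the residual map
rather than an exception.

Steps are projected onto a generous physical feasibility box (default
[-2, 50] g/cm^2 per basis).  Unconstrained, fully photon-starved rays —
where both measurements sit at the counting floor and are therefore
spectrally inconsistent — drive the fit down an unbounded
water-positive / iron-negative valley toward path lengths equivalent to
meters of water; the box keeps such rays at bounded, physically scaled
values while leaving every feasible ray (including small noise-driven
negative excursions) untouched.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import Spectrum
from .projector import Geometry

__all__ = [
    "SolverConfig",
    "DecomposedSinograms",
    "decompose_pixel",
    "decompose_sinograms",
]


class DegenerateSystemError(ValueError):
    """The two acquisitions cannot separate the two basis materials."""


@dataclass(frozen=True)
class SolverConfig:
    """Gauss-Newton controls.

    ``max_iter`` is the fixed iteration budget; ``step_tol`` triggers an
    early exit (pure optimization — results agree to well below every
    stated tolerance); ``max_halvings`` bounds the per-step damping loop.
    """

    max_iter: int = 200
    step_tol: float = 1e-12
    max_halvings: int = 30
    bounds: tuple[float, float] = (-2.0, 50.0)

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("need at least one iteration")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("solver bounds must be an increasing pair")


@dataclass
class DecomposedSinograms:
    """Water/iron basis sinograms (g/cm^2) plus the final residual map."""

    a_water: np.ndarray
    a_iron: np.ndarray
    residual: np.ndarray
    geometry: Geometry

    def __post_init__(self):
        if not (self.a_water.shape == self.a_iron.shape
                == self.residual.shape == self.geometry.sinogram_shape()):
            raise ValueError("decomposed sinogram shapes do not match geometry")
        if np.any(self.residual < 0):
            raise ValueError("residual norms cannot be negative")


def _spectrum_weights(spectrum: Spectrum, tables) -> tuple[np.ndarray, np.ndarray]:
    """Normalized energy-fluence weights and basis mu values per bin."""
    e = spectrum.energies
    w = spectrum.fluence * e * spectrum.grid.width_kev
    total = w.sum()
    if total <= 0:
        raise ValueError("spectrum carries no fluence")
    mu = np.stack([t.mu(e) for t in tables], axis=1)  # (E, 2)
    return w / total, mu


def _check_spectra_distinct(spectra) -> None:
    s1, s2 = spectra
    if (s1.kvp == s2.kvp and s1.fluence.shape == s2.fluence.shape
            and np.allclose(s1.fluence / s1.fluence.sum(),
                            s2.fluence / s2.fluence.sum())):
        raise DegenerateSystemError(
            "the two acquisitions use identical spectra; the basis "
            "materials cannot be separated")


def _gauss_newton(y: np.ndarray, weights, mus, config: SolverConfig):
    """Vectorized damped Gauss-Newton over P pixels.

    Parameters
    ----------
    y:
        (P, 2) flat-field-normalized measurements, one column per spectrum.
    weights, mus:
        Per-spectrum normalized weights (E_n,) and basis coefficients
        (E_n, 2).

    Returns (A, residual_norm) with A of shape (P, 2).
    """
    P = y.shape[0]
    A = np.zeros((P, 2))

    def model(A_sub):
        out = np.empty((A_sub.shape[0], 2))
        for n in range(2):
            t = np.exp(-(A_sub @ mus[n].T))       # (p, E_n)
            out[:, n] = t @ weights[n]
        return out

    def model_jac(A_sub):
        m = np.empty((A_sub.shape[0], 2))
        J = np.empty((A_sub.shape[0], 2, 2))      # J[:, n, k] = dm_n/dA_k
        for n in range(2):
            t = np.exp(-(A_sub @ mus[n].T))
            tw = t * weights[n]
            m[:, n] = tw.sum(axis=1)
            for k in range(2):
                J[:, n, k] = -(tw @ mus[n][:, k])
        return m, J

    rnorm = np.linalg.norm(y - model(A), axis=1)
    active = np.flatnonzero(rnorm > 1e-15)

    for _ in range(config.max_iter):
        if active.size == 0:
            break
        m, J = model_jac(A[active])
        ra = y[active] - m
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        ok = np.abs(det) > 1e-300
        dA = np.zeros_like(ra)
        dA[ok, 0] = (J[ok, 1, 1] * ra[ok, 0] - J[ok, 0, 1] * ra[ok, 1]) / det[ok]
        dA[ok, 1] = (-J[ok, 1, 0] * ra[ok, 0] + J[ok, 0, 0] * ra[ok, 1]) / det[ok]

        # damping: halve the step until the residual does not increase
        # (to a 1e-12 relative band, so rounding noise near the optimum
        # cannot trigger spurious halvings)
        lam = np.where(ok, 1.0, 0.0)
        rn_old = np.linalg.norm(ra, axis=1)
        lo, hi = config.bounds
        trial = np.clip(A[active] + lam[:, None] * dA, lo, hi)
        rn_new = np.linalg.norm(y[active] - model(trial), axis=1)
        pending = np.flatnonzero((rn_new > rn_old * (1 + 1e-12)) & (lam > 0))
        for _ in range(config.max_halvings):
            if pending.size == 0:
                break
            lam[pending] *= 0.5
            sub = np.clip(A[active[pending]] + lam[pending, None] * dA[pending],
                          lo, hi)
            rn_sub = np.linalg.norm(y[active[pending]] - model(sub), axis=1)
            better = rn_sub <= rn_old[pending] * (1 + 1e-12)
            trial[pending[better]] = sub[better]
            rn_new[pending[better]] = rn_sub[better]
            pending = pending[~better]
        if pending.size:  # no acceptable step: freeze these pixels
            lam[pending] = 0.0
            trial[pending] = A[active[pending]]
            rn_new[pending] = rn_old[pending]

        step = np.abs(trial - A[active]).max(axis=1)  # after box projection
        A[active] = trial
        rnorm[active] = rn_new
        keep = (step > config.step_tol) & (lam > 0) & (rn_new > 1e-15)
        active = active[keep]

    return A, rnorm


def decompose_pixel(measurements, spectra, basis_tables,
                    config: SolverConfig | None = None):
    """Decompose one sinogram pixel measured under two spectra.

    Parameters
    ----------
    measurements:
        Pair of flat-field-normalized intensities (I / I_flat), one per
        acquisition, both positive and finite.
    spectra:
        Pair of :class:`Spectrum`, matching the measurement order.
    basis_tables:
        Pair of :class:`AttenuationTable` (water, iron).

    Returns ``(a_water, a_iron, residual_norm)``.
    """
    config = config or SolverConfig()
    y = np.asarray(measurements, dtype=float).reshape(1, 2)
    if not np.all(np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("measurements must be positive and finite")
    _check_spectra_distinct(spectra)
    weights, mus = zip(*(_spectrum_weights(s, basis_tables) for s in spectra))
    A, rnorm = _gauss_newton(y, weights, mus, config)
    return float(A[0, 0]), float(A[0, 1]), float(rnorm[0])


def decompose_sinograms(sinograms, spectra, basis_tables,
                        config: SolverConfig | None = None
                        ) -> DecomposedSinograms:
    """Per-pixel decomposition of a dual-kV sinogram pair.

    Pixels are independent; the vectorized solve is exactly the per-pixel
    contract applied to every pixel.  Results are order-invariant under
    swapping the two acquisitions as long as spectra stay paired with
    their measurements.
    """
    config = config or SolverConfig()
    s1, s2 = sinograms
    if s1.geometry != s2.geometry:
        raise ValueError("the two acquisitions use different geometries")
    for s in (s1, s2):
        if not np.all(np.isfinite(s.intensity)) or np.any(s.intensity <= 0):
            raise ValueError("sinogram intensities must be positive and finite")
    _check_spectra_distinct(spectra)
    weights, mus = zip(*(_spectrum_weights(s, basis_tables) for s in spectra))

    shape = s1.geometry.sinogram_shape()
    y = np.stack([s1.normalized().ravel(), s2.normalized().ravel()], axis=1)
    A, rnorm = _gauss_newton(y, weights, mus, config)
    return DecomposedSinograms(a_water=A[:, 0].reshape(shape),
                               a_iron=A[:, 1].reshape(shape),
                               residual=rnorm.reshape(shape),
                               geometry=s1.geometry)
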