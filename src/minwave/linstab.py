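"""Linear stability analysis of the homogeneous steady state.

Linearizing the reaction-diffusion system around the uniform steady state
``u*`` with a plane-wave perturbation ``exp(sigma_q t) exp(i q x)`` yields
the eigenvalue problem ``A_q du_q = sigma_q du_q`` with
``A_q = A - D q^2``, where ``A`` is the 5x5 reaction Jacobian at ``u*`` and
``D`` the diagonal diffusion matrix.  A parameter set is a candidate for
pole-to-pole oscillation when the leading eigenvalue at the longest
domain-compatible wavelength (``q = pi / L``, wavelength ``2 L`` under
no-flux boundaries) has positive real part (growth, Turing-unstable in
space) and nonzero imaginary part (temporal oscillation, Hopf-unstable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    DiffusionCoefficients,
    KineticParameters,
    ProteinTotals,
    SteadyStateError,
    uniform_steady_state,
)

__all__ = ["LinearizedSystem", "StabilityVerdict", "build_jacobian", "classify_instability"]

#: |Im sigma| below this (relative to max(1, |Re|)) counts as real
IMAG_TOLERANCE = 1e-10


@dataclass(frozen=True)
class LinearizedSystem:
    """Steady state, reaction Jacobian, and wavenumber of one linearization."""

    u_star: np.ndarray
    A: np.ndarray
    D: np.ndarray  # diagonal entries of the diffusion matrix
    q: float

    @property
    def A_q(self) -> np.ndarray:
        return self.A - np.diag(self.D) * self.q**2


@dataclass(frozen=True)
class StabilityVerdict:
    """Leading eigenvalue and the oscillatory-divergence flag."""

    sigma: complex
    oscillatory_divergent: bool
    u_star: np.ndarray | None = None


def reaction_jacobian(u_star: np.ndarray, params: KineticParameters) -> np.ndarray:
    """Analytic 5x5 Jacobian of the reaction terms at a state ``u_star``.

    Species order: (c_DD, c_DT, c_E, c_d, c_de).
    """
    _, c_DT, c_E, c_d, _ = np.asarray(u_star, dtype=float)
    kD, kdD, kdE, kde, kA = (
        params.k_D,
        params.k_dD,
        params.k_dE,
        params.k_de,
        params.k_ADP_ATP,
    )
    return np.array(
        [
            [-kA, 0.0, 0.0, 0.0, kde],
            [kA, -kD - kdD * c_d, 0.0, -kdD * c_DT, 0.0],
            [0.0, 0.0, -kdE * c_d, -kdE * c_E, kde],
            [0.0, kD + kdD * c_d, -kdE * c_d, kdD * c_DT - kdE * c_E, 0.0],
            [0.0, 0.0, kdE * c_d, kdE * c_E, -kde],
        ]
    )


def build_jacobian(
    u_star: np.ndarray,
    params: KineticParameters,
    D: DiffusionCoefficients,
    q: float,
) -> np.ndarray:
    """``A_q = A - D q^2``: reaction Jacobian with diffusive damping."""
    return reaction_jacobian(u_star, params) - np.diag(D.as_array()) * q**2


def linearize(
    params: KineticParameters,
    D: DiffusionCoefficients,
    totals: ProteinTotals,
    length: float,
    q: float | None = None,
) -> LinearizedSystem:
    """Steady state and Jacobian for a cell of ``length`` um (q defaults to pi/L)."""
    u_star = uniform_steady_state(params, totals, length)
    if q is None:
        q = np.pi / length
    return LinearizedSystem(u_star, reaction_jacobian(u_star, params), D.as_array(), q)


def leading_eigenvalue(A_q: np.ndarray) -> complex:
    """Eigenvalue of largest real part; ties broken toward a complex pair.

    Breaking ties toward the complex eigenvalue makes the screen more
    permissive; the full nonlinear simulation downstream is the arbiter.
    """
    eig = np.linalg.eigvals(A_q)
    re_max = eig.real.max()
    near = eig[eig.real >= re_max - 1e-12 * max(1.0, abs(re_max))]
    imag = np.abs(near.imag)
    return complex(near[np.argmax(imag)])


def _is_oscillatory(sigma: complex) -> bool:
    return sigma.real > 0 and abs(sigma.imag) > IMAG_TOLERANCE * max(1.0, abs(sigma.real))


def classify_instability(
    params: KineticParameters,
    D: DiffusionCoefficients,
    totals: ProteinTotals,
    length: float,
    q: float | None = None,
    mode: str = "strict",
) -> StabilityVerdict:
    """Is the uniform state unstable to a growing oscillation?

    ``mode="strict"``: true iff the leading eigenvalue of ``A_q`` at
    ``q = pi / L`` has ``Re > 0`` and ``Im != 0`` (tested against a
    floating-point tolerance) — a single eigenvalue that grows and
    oscillates.

    ``mode="hopf_turing"``: true iff the leading eigenvalue at
    ``q = pi / L`` has ``Re > 0`` (the longest domain-compatible spatial
    mode grows: Turing-unstable in space) *and* the dispersion relation
    has an oscillatory unstable branch at some wavenumber (a complex
    leading eigenvalue with positive real part: Hopf-unstable in time).
    The two instabilities need not peak at the same wavenumber — for the
    reference parameter set the growing mode at ``q = pi / L`` is real
    while the oscillatory branch sits at small ``q`` — so the combined
    test is the one used as screening filter F1.

    A steady state with a negative component is unphysical and classified
    stable; steady-state solver failures propagate as
    :class:`SteadyStateError`.
    """
    if mode not in ("strict", "hopf_turing"):
        raise ValueError("mode must be 'strict' or 'hopf_turing'")
    system = linearize(params, D, totals, length, q)
    if np.any(system.u_star < -1e-12):
        return StabilityVerdict(sigma=0j, oscillatory_divergent=False, u_star=system.u_star)
    sigma = leading_eigenvalue(system.A_q)
    if mode == "strict":
        verdict = _is_oscillatory(sigma)
    else:
        verdict = sigma.real > 0 and (
            _is_oscillatory(sigma) or _has_oscillatory_branch(system, params, D)
        )
    return StabilityVerdict(sigma=sigma, oscillatory_divergent=verdict, u_star=system.u_star)


def _has_oscillatory_branch(
    system: LinearizedSystem,
    params: KineticParameters,
    D: DiffusionCoefficients,
    q_max: float | None = None,
    n_q: int = 80,
) -> bool:
    """Does any wavenumber carry a growing oscillatory mode?

    Scans the dispersion relation from long wavelengths up to the grid
    Nyquist scale (``q_max`` defaults to pi / 0.2 um).
    """
    if q_max is None:
        q_max = np.pi / 0.2
    A = system.A
    Dq = system.D
    for q in np.geomspace(1e-3, q_max, n_q):
        sigma = leading_eigenvalue(A - np.diag(Dq) * q**2)
        if _is_oscillatory(sigma):
            return True
    return False
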