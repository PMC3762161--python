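"""Closed-form perturbation solutions of the linearized capillary model.

Writing ``v = eps*w``, ``c = eps*xi``, ``f = 1 - eps*phi``,
``eta = 1 + eps*n`` and letting ``eps -> 0`` decouples the system:

* ``w(y,t) = theta(y) exp(-lambda t)``       (factor consumption),
* ``xi(y,t) = theta(y) (1 - exp(-lambda t))``  (protease production),
* ``phi`` solves ``phi_t + beta*phi = mu*theta*(1 - exp(-lambda t))``
  in closed form (fibronectin dip),
* ``n`` solves a forced Neumann heat equation whose large-time forcing is
  ``-D_eta*K*theta''(y)``; substituting away the particular solution
  ``K*theta(y)`` leaves a homogeneous cosine-series problem with
  coefficients ``C_n = -2K * integral theta(y) cos(n pi y) dy``.

The steady state of the cell perturbation is ``B + K*theta(y)``; the series
selects the stable constant ``B = C_0/2 = -K``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate

from .model import InitialProfile, ModelParams, PerturbationConfig

__all__ = [
    "NumericalError",
    "FourierSpectrum",
    "Fields",
    "solve_w",
    "solve_xi",
    "phi_bracket",
    "solve_phi",
    "fourier_spectrum",
    "quartic_coefficients",
    "series_n",
    "series_deviation_envelope",
    "assemble_fields",
    "steady_state",
    "stable_B",
]

#: relative threshold below which the beta ~= lambda confluent limit is used
CONFLUENT_THRESHOLD = 1e-6


class NumericalError(RuntimeError):
    """Quadrature or series evaluation failed to converge."""


def solve_w(y, t, theta: InitialProfile, lambda_: float):
    """Angiogenic-factor perturbation ``w(y,t) = theta(y) exp(-lambda t)``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be nonnegative")
    return theta(y) * np.exp(-lambda_ * t)


def solve_xi(y, t, theta: InitialProfile, lambda_: float):
    """Protease perturbation ``xi = theta(y)(1 - exp(-lambda t))``.

    Complementary to :func:`solve_w`: ``w + xi = theta`` identically, the
    pointwise conservation of factor plus enzyme.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be nonnegative")
    return theta(y) * -np.expm1(-lambda_ * t)


def phi_bracket(t, lambda_: float, beta: float):
    """Time factor of the fibronectin perturbation ``phi = mu*theta*bracket``.

    ``bracket(t) = 1/beta - exp(-lambda t)/(beta - lambda)
    + lambda exp(-beta t)/(beta (beta - lambda))``; it vanishes at ``t = 0``
    and tends to ``1/beta``.  Near the ``beta = lambda`` degeneracy the
    confluent (L'Hopital) limit
    ``(1 - exp(-beta t)(1 + beta t))/beta`` is used instead.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be nonnegative")
    if abs(beta - lambda_) <= CONFLUENT_THRESHOLD * abs(beta):
        return (1.0 - np.exp(-beta * t) * (1.0 + beta * t)) / beta
    return (
        1.0 / beta
        - np.exp(-lambda_ * t) / (beta - lambda_)
        + lambda_ * np.exp(-beta * t) / (beta * (beta - lambda_))
    )


def solve_phi(y, t, theta: InitialProfile, lambda_: float, beta: float, mu: float):
    """Fibronectin perturbation ``phi(y,t) = mu*theta(y)*bracket(t)``.

    ``phi(y,0) = 0`` exactly and ``phi -> mu*theta(y)/beta`` as
    ``t -> infinity`` (the asymptotic proteolytic dip in fibronectin).
    """
    return mu * theta(y) * phi_bracket(t, lambda_, beta)


@dataclass(frozen=True)
class FourierSpectrum:
    """Cosine coefficients ``C_0 ... C_N`` of the substituted heat problem.

    ``C_0 = -2K`` for any unit-mass profile; higher coefficients decay like
    ``n**-4`` for profiles with vanishing endpoint slopes.  ``tail_bound``
    estimates ``sum_{n>N} |C_n|`` from that decay.
    """

    K: float
    coefficients: np.ndarray
    N: int
    profile_label: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        if self.coefficients.shape != (self.N + 1,):
            raise ValueError(
                f"expected {self.N + 1} coefficients, got {self.coefficients.shape}"
            )

    @property
    def tail_bound(self) -> float:
        """Estimate of ``sum_{n>N} |C_n|`` assuming ``|C_n| ~ c n**-4``.

        The scale ``c`` is taken from the largest of the last two computed
        coefficients; the tail sum is bounded by ``c/(3 N**3)``.
        """
        if self.N < 2:
            return float("inf")
        scale = max(
            abs(self.coefficients[-1]) * self.N**4,
            abs(self.coefficients[-2]) * (self.N - 1) ** 4,
        )
        return scale / (3.0 * self.N**3)


def fourier_spectrum(
    theta: InitialProfile, K: float, N: int = 200
) -> FourierSpectrum:
    """Cosine spectrum ``C_n = -2K * integral theta(y) cos(n pi y) dy``.

    Computed by adaptive quadrature with an oscillatory (cosine-weight)
    rule; ``C_0 = -2K`` times the profile mass.
    """
    if N < 1:
        raise ValueError(f"truncation order N must be >= 1, got {N}")
    coeffs = np.empty(N + 1)
    coeffs[0] = -2.0 * K * theta.mass()
    for n in range(1, N + 1):
        val, err = integrate.quad(
            theta.evaluate,
            0.0,
            1.0,
            weight="cos",
            wvar=n * np.pi,
            epsabs=1e-12,
            epsrel=1e-12,
            limit=200,
        )
        if err > 1e-8:
            raise NumericalError(
                f"cosine quadrature for coefficient n={n} did not converge "
                f"(error estimate {err:g})"
            )
        coeffs[n] = -2.0 * K * val
    return FourierSpectrum(K=K, coefficients=coeffs, N=N, profile_label=theta.label)


def quartic_coefficients(N: int, K: float) -> np.ndarray:
    """Closed-form spectrum of the quartic bump ``theta = 30 y^2 (1-y)^2``.

    ``C_0 = -2K``; ``C_n = 1440 K / (n^4 pi^4)`` for even ``n`` and ``0``
    for odd ``n``.  Used as the independent cross-check of the quadrature
    route.
    """
    n = np.arange(N + 1)
    coeffs = np.zeros(N + 1)
    coeffs[0] = -2.0 * K
    even = (n >= 2) & (n % 2 == 0)
    coeffs[even] = 1440.0 * K / (n[even].astype(float) ** 4 * np.pi**4)
    return coeffs


def series_n(
    y,
    t,
    spectrum: FourierSpectrum,
    theta: InitialProfile,
    D_eta: float,
    K: float | None = None,
):
    """Cell-density perturbation from the truncated cosine series.

    ``n(y,t) = C_0/2 + sum_{n=1}^{N} C_n exp(-n^2 pi^2 D_eta t) cos(n pi y)
    + K theta(y)``.  ``y`` and ``t`` may be scalars or broadcastable arrays.
    The truncation error is bounded by ``spectrum.tail_bound``.
    """
    if K is None:
        K = spectrum.K
    if spectrum.profile_label != theta.label:
        raise ValueError(
            f"spectrum was built for profile {spectrum.profile_label!r}, "
            f"got {theta.label!r}"
        )
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be nonnegative")
    out_shape = np.broadcast_shapes(y.shape, t.shape)
    n_idx = np.arange(1, spectrum.N + 1)
    # sum over modes on the trailing axis
    decay = np.exp(
        -(n_idx**2) * np.pi**2 * D_eta * t[..., None]
    )  # (..., N)
    cosines = np.cos(n_idx * np.pi * y[..., None])  # (..., N)
    series = np.sum(spectrum.coefficients[1:] * decay * cosines, axis=-1)
    result = spectrum.coefficients[0] / 2.0 + series + K * theta(y)
    return np.broadcast_to(result, out_shape) if result.shape != out_shape else result


def series_deviation_envelope(spectrum: FourierSpectrum, D_eta: float, t):
    """Upper bound ``sum_n |C_n| exp(-n^2 pi^2 D_eta t)`` on the distance
    of the series solution from its steady state at time ``t``."""
    t = np.asarray(t, dtype=float)
    n_idx = np.arange(1, spectrum.N + 1)
    decay = np.exp(-(n_idx**2) * np.pi**2 * D_eta * t[..., None])
    return np.sum(np.abs(spectrum.coefficients[1:]) * decay, axis=-1)


class Fields(NamedTuple):
    """The four assembled densities at the evaluation points."""

    v: np.ndarray
    c: np.ndarray
    f: np.ndarray
    eta: np.ndarray


def assemble_fields(
    y,
    t,
    config: PerturbationConfig,
    params: ModelParams | None = None,
    D_eta: float | None = None,
    spectrum: FourierSpectrum | None = None,
    N: int = 200,
) -> Fields:
    """Assemble the physical densities from the perturbation solutions.

    ``v = eps*w``, ``c = eps*xi``, ``f = 1 - eps*phi``, ``eta = 1 + eps*n``.
    The identity ``v + c = eps*theta(y)`` holds pointwise.  A warning is
    emitted if ``eps`` is large enough that ``f`` or ``eta`` leaves the
    positive range anywhere requested (perturbation regime violated).
    """
    if params is None:
        params = ModelParams()
    if D_eta is None:
        D_eta = params.D_eta
    if spectrum is None:
        spectrum = fourier_spectrum(config.theta, config.K, N=N)
    eps = config.epsilon
    w = solve_w(y, t, config.theta, params.lambda_)
    xi = solve_xi(y, t, config.theta, params.lambda_)
    phi = solve_phi(y, t, config.theta, params.lambda_, params.beta, params.mu)
    n = series_n(y, t, spectrum, config.theta, D_eta, K=config.K)
    f = 1.0 - eps * phi
    eta = 1.0 + eps * n
    if np.any(f <= 0) or np.any(eta <= 0):
        warnings.warn(
            "fibronectin or cell density is nonpositive: epsilon is outside "
            "the perturbation regime for this profile",
            stacklevel=2,
        )
    return Fields(v=eps * w, c=eps * xi, f=f, eta=eta)


def steady_state(y, B: float, K: float, theta: InitialProfile):
    """Steady cell-density perturbation ``n_ss(y) = B + K*theta(y)``."""
    return B + K * theta(y)


def stable_B(spectrum: FourierSpectrum, K: float | None = None) -> float:
    """The constant making the steady state the attractor of the series.

    The series tends to ``C_0/2 + K*theta(y)`` as ``t -> infinity``, so the
    stable steady state has ``B = C_0/2``, which equals ``-K`` for any
    unit-mass profile.
    """
    B = float(spectrum.coefficients[0]) / 2.0
    if K is not None and abs(B + K) > 1e-8 * max(1.0, abs(K)):
        warnings.warn(
            f"C0/2 = {B!r} differs from -K = {-K!r}: profile is not "
            "unit-normalized?",
            stacklevel=2,
        )
    return B
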