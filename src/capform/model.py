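"""Model parameters, transition probability, and admissible initial profiles.

The model describes four densities along a capillary of (rescaled) unit
length: angiogenic factor ``v``, proteolytic enzyme ``c``, fibronectin ``f``
and endothelial cells ``eta``.  Stimulated endothelial cells perform a
reinforced random walk biased by the transition probability
``tau(c, f) = tau1(c) * tau2(f)`` — they prefer regions of high protease and
low fibronectin.  Everything here is deterministic, dimensionless time.

This module holds the parameter container with its ordering invariants, the
transition-probability function and its logarithmic derivatives, the lumped
sensitivity constants ``rho1``/``rho2`` and forcing constant ``K`` used by
the linearized theory, and the polynomial-bump family of initial
angiogenic-factor profiles ``theta_m(y) = A_m y^m (1-y)^m``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import integrate, special

__all__ = [
    "ParameterError",
    "ProfileError",
    "ModelParams",
    "InitialProfile",
    "PerturbationConfig",
    "compute_rho",
    "compute_K",
    "transition_probability",
    "log_tau_derivatives",
    "make_bump_profile",
    "constant_profile",
    "calibrate_exponents",
]

#: absolute tolerance for the unit-mass check of initial profiles.  Closed
#: forms exist for every built-in profile, so quadrature is only a cross-check.
NORMALIZATION_TOL = 1e-10


class ParameterError(ValueError):
    """A model parameter violates its ordering or positivity invariant."""


class ProfileError(ValueError):
    """An initial profile violates its admissibility requirements."""


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and transport constants of the full nonlinear system.

    Attributes
    ----------
    lambda_ : float
        Angiogenic-factor consumption rate (time^-1).
    nu : float
        Michaelis-type saturation constant of the factor kinetics
        (concentration^-1).
    beta : float
        Fibronectin logistic production rate (time^-1).
    mu : float
        Fibronectin proteolytic degradation rate (time^-1).
    D_eta : float
        Endothelial-cell diffusion coefficient in the capillary
        (length^2 time^-1, unit capillary length).
    eta0, f0 : float
        Reference (rest-state) endothelial-cell and fibronectin densities.
    alpha1, alpha2 : float
        Protease transition constants, ``0 < alpha1 < 1 < alpha2``.
    beta1, beta2 : float
        Fibronectin transition constants, ``beta1 > 1 > beta2 > 0``.
    gamma1, gamma2 : float
        Transition exponents (>= 0).  ``tau`` approximates
        ``c**gamma1 * f**-gamma2`` over a considerable range while staying
        finite at ``c = 0`` and ``f = 0``.
    """

    lambda_: float = 20.0
    nu: float = 1.0
    beta: float = 10.0
    mu: float = 5.0
    D_eta: float = 0.25
    eta0: float = 1.0
    f0: float = 1.0
    alpha1: float = 0.1
    alpha2: float = 10.0
    beta1: float = 2.0
    beta2: float = 0.5
    gamma1: float = 1.0
    gamma2: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ParameterError` naming the first violated inequality."""
        positive = {
            "lambda_": self.lambda_,
            "beta": self.beta,
            "mu": self.mu,
            "D_eta": self.D_eta,
            "eta0": self.eta0,
            "f0": self.f0,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ParameterError(f"{name} > 0 violated ({name}={value!r})")
        if self.nu < 0:
            raise ParameterError(f"nu >= 0 violated (nu={self.nu!r})")
        if not 0 < self.alpha1 < 1:
            raise ParameterError(
                f"0 < alpha1 < 1 violated (alpha1={self.alpha1!r})"
            )
        if not self.alpha2 > 1:
            raise ParameterError(f"alpha2 > 1 violated (alpha2={self.alpha2!r})")
        if not self.beta1 > 1:
            raise ParameterError(f"beta1 > 1 violated (beta1={self.beta1!r})")
        if not 0 < self.beta2 < 1:
            raise ParameterError(f"1 > beta2 > 0 violated (beta2={self.beta2!r})")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ParameterError(
                f"gamma1, gamma2 >= 0 violated "
                f"(gamma1={self.gamma1!r}, gamma2={self.gamma2!r})"
            )


def compute_rho(params: ModelParams) -> tuple[float, float]:
    """Lumped transition sensitivities of the linearized cell equation.

    ``rho1 = gamma1 (alpha2 - alpha1) / (alpha1 alpha2)`` is the logarithmic
    derivative of ``tau1`` at the rest protease level ``c = 0``;
    ``rho2 = gamma2 (beta2 - beta1) / ((beta1 + 1)(beta2 + 1))`` is that of
    ``tau2`` at the rest fibronectin level ``f = 1``.  Under the parameter
    ordering, ``rho1 > 0`` (chemoattraction) and ``rho2 < 0`` (fibronectin
    avoidance).
    """
    params.validate()
    rho1 = params.gamma1 * (params.alpha2 - params.alpha1) / (
        params.alpha1 * params.alpha2
    )
    rho2 = params.gamma2 * (params.beta2 - params.beta1) / (
        (params.beta1 + 1.0) * (params.beta2 + 1.0)
    )
    return rho1, rho2


def compute_K(rho1: float, rho2: float, mu: float, beta: float) -> float:
    """Lumped forcing constant ``K = rho1 - rho2 * mu / beta``.

    ``K`` multiplies ``theta''(y)`` in the large-time linearized cell
    equation.  Linearizing the cell flux with ``c = eps*xi`` and
    ``f = 1 - eps*phi`` (so ``f_y = -eps*phi_y``) gives the forcing
    ``rho1*xi_yy - rho2*phi_yy``: because ``rho2 < 0``, the fibronectin
    dip carved by the protease *reinforces* the protease attraction, and
    ``K = rho1 + |rho2|*mu/beta > rho1`` under the parameter ordering.
    """
    if beta == 0:
        raise ZeroDivisionError("beta must be nonzero to form K = rho1 - rho2*mu/beta")
    return rho1 - rho2 * mu / beta


def _check_nonnegative(c, f) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(c, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(c < 0):
        raise ValueError("protease concentration c must be nonnegative")
    if np.any(f < 0):
        raise ValueError("fibronectin concentration f must be nonnegative")
    return c, f


def transition_probability(c, f, params: ModelParams):
    """Transition probability ``tau(c,f)`` biasing the endothelial random walk.

    ``tau = ((alpha1+c)/(alpha2+c))**gamma1 * ((beta1+f)/(beta2+f))**gamma2``
    is strictly positive and finite for all ``c, f >= 0`` (no singularity at
    the origin), increasing in ``c`` and decreasing in ``f``.
    """
    c, f = _check_nonnegative(c, f)
    tau1 = ((params.alpha1 + c) / (params.alpha2 + c)) ** params.gamma1
    tau2 = ((params.beta1 + f) / (params.beta2 + f)) ** params.gamma2
    return tau1 * tau2


def log_tau_derivatives(c, f, params: ModelParams):
    """Logarithmic derivatives ``(d ln tau1/dc, d ln tau2/df)``.

    These are the taxis coefficients of the cell flux:
    ``gamma1 (alpha2-alpha1) / ((alpha1+c)(alpha2+c))`` and
    ``gamma2 (beta2-beta1) / ((beta1+f)(beta2+f))``.  At ``c=0`` and ``f=1``
    they reduce exactly to ``rho1`` and ``rho2``.
    """
    c, f = _check_nonnegative(c, f)
    d1 = params.gamma1 * (params.alpha2 - params.alpha1) / (
        (params.alpha1 + c) * (params.alpha2 + c)
    )
    d2 = params.gamma2 * (params.beta2 - params.beta1) / (
        (params.beta1 + f) * (params.beta2 + f)
    )
    return d1, d2


@dataclass(frozen=True)
class InitialProfile:
    """Initial angiogenic-factor shape ``theta(y)`` on the unit interval.

    Admissible profiles are nonnegative, integrate to one, and have vanishing
    endpoint derivatives (so the zero-flux condition of the linearized cell
    equation reduces to a plain Neumann condition).
    """

    evaluate: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]
    second_derivative: Callable[[np.ndarray], np.ndarray]
    label: str

    def __call__(self, y):
        return self.evaluate(np.asarray(y, dtype=float))

    def mass(self) -> float:
        """Quadrature of ``theta`` over [0, 1]."""
        val, _ = integrate.quad(self.evaluate, 0.0, 1.0, epsabs=1e-13, epsrel=1e-13)
        return val

    def validate(self, tol: float = NORMALIZATION_TOL) -> None:
        """Check unit mass, endpoint derivatives and nonnegativity on a grid."""
        m = self.mass()
        if abs(m - 1.0) > tol:
            raise ProfileError(
                f"profile {self.label!r} has mass {m!r}, expected 1 within {tol}"
            )
        d0 = float(self.derivative(np.array(0.0)))
        d1 = float(self.derivative(np.array(1.0)))
        if abs(d0) > tol or abs(d1) > tol:
            raise ProfileError(
                f"profile {self.label!r} has nonzero endpoint slope "
                f"(theta'(0)={d0!r}, theta'(1)={d1!r})"
            )
        grid = np.linspace(0.0, 1.0, 201)
        vals = self(grid)
        if np.any(vals < -tol):
            raise ProfileError(f"profile {self.label!r} is negative on [0, 1]")


def make_bump_profile(m: int) -> InitialProfile:
    """Unimodal bump ``theta_m(y) = A_m y^m (1-y)^m`` with unit integral.

    ``A_m = 1 / B(m+1, m+1)`` (Beta function), e.g. ``A_1 = 6``, ``A_2 = 30``,
    ``A_3 = 140``.  For ``m >= 2`` all endpoint derivatives up to order
    ``m - 1`` vanish.  ``m = 1`` is accepted with a warning: its endpoint
    slope is nonzero, so the reduction of the cell-equation boundary
    condition to a plain Neumann condition does not apply.
    """
    m = int(m)
    if m < 1:
        raise ProfileError(f"bump exponent m must be >= 1, got {m}")
    if m == 1:
        warnings.warn(
            "m = 1 bump has theta'(0) != 0; the Neumann reduction of the "
            "linearized boundary condition does not apply",
            stacklevel=2,
        )
    A = 1.0 / special.beta(m + 1, m + 1)

    def theta(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return A * (y * (1.0 - y)) ** m

    def dtheta(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return A * m * (y * (1.0 - y)) ** (m - 1) * (1.0 - 2.0 * y)

    def d2theta(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if m == 1:
            return np.full_like(y, -2.0 * A)
        # (m-1) factor kills the (m-2)-power term when m == 2; numpy's
        # 0.0**0 == 1.0 keeps the endpoints finite there.
        return A * m * (
            (m - 1) * (y * (1.0 - y)) ** (m - 2) * (1.0 - 2.0 * y) ** 2
            - 2.0 * (y * (1.0 - y)) ** (m - 1)
        )

    return InitialProfile(theta, dtheta, d2theta, label=f"bump(m={m})")


def constant_profile() -> InitialProfile:
    """The uniform profile ``theta(y) = 1`` (all cosine coefficients vanish)."""

    def one(y):
        return np.ones_like(np.asarray(y, dtype=float))

    def zero(y):
        return np.zeros_like(np.asarray(y, dtype=float))

    return InitialProfile(one, zero, zero, label="uniform")


@dataclass(frozen=True)
class PerturbationConfig:
    """Everything the linearized (perturbation) route needs.

    ``epsilon`` scales the initial angiogenic disturbance
    ``v(y, 0) = epsilon * theta(y)``; ``rho1``, ``rho2`` and ``K`` are the
    lumped constants of the linearized cell equation.
    """

    epsilon: float
    theta: InitialProfile
    rho1: float
    rho2: float
    K: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ParameterError(f"epsilon >= 0 violated (epsilon={self.epsilon!r})")

    @classmethod
    def from_params(
        cls, epsilon: float, theta: InitialProfile, params: ModelParams
    ) -> "PerturbationConfig":
        """Derive the lumped constants from a full parameter set."""
        rho1, rho2 = compute_rho(params)
        K = compute_K(rho1, rho2, params.mu, params.beta)
        return cls(epsilon=epsilon, theta=theta, rho1=rho1, rho2=rho2, K=K)

    @classmethod
    def from_lumped(
        cls,
        epsilon: float,
        theta: InitialProfile,
        K: float,
        rho_split: tuple[float, float] | None = None,
        mu: float | None = None,
        beta: float | None = None,
    ) -> "PerturbationConfig":
        """Build a config directly from the lumped constant ``K``.

        If the individual ``(rho1, rho2)`` split is not supplied the whole
        forcing is attributed to the protease channel (``rho1 = K``,
        ``rho2 = 0``); the closed-form route only ever uses ``K``.
        """
        if rho_split is None:
            rho1, rho2 = K, 0.0
        else:
            rho1, rho2 = rho_split
            if mu is not None and beta is not None:
                implied = compute_K(rho1, rho2, mu, beta)
                if abs(implied - K) > 1e-12 * max(1.0, abs(K)):
                    raise ParameterError(
                        f"rho split implies K={implied!r}, inconsistent with K={K!r}"
                    )
        return cls(epsilon=epsilon, theta=theta, rho1=rho1, rho2=rho2, K=K)


def calibrate_exponents(
    params: ModelParams, K_target: float, fibronectin_share: float = 0.5
) -> ModelParams:
    """Rescale ``gamma1`` and ``gamma2`` so the lumped constant equals
    ``K_target``.

    ``rho1`` is proportional to ``gamma1`` and ``-rho2*mu/beta`` to
    ``gamma2``, so splitting the target between the two taxis channels is a
    pair of linear solves: the fibronectin channel is assigned
    ``fibronectin_share * K_target`` and the protease channel the rest.
    """
    if not 0.0 <= fibronectin_share < 1.0:
        raise ParameterError(
            f"fibronectin_share must be in [0, 1), got {fibronectin_share!r}"
        )
    if K_target <= 0:
        raise ParameterError(f"K_target must be positive, got {K_target!r}")
    rho1, rho2 = compute_rho(params)
    if rho1 == 0:
        raise ParameterError("cannot calibrate: rho1 = 0 (gamma1 = 0?)")
    if rho2 == 0 and fibronectin_share > 0:
        raise ParameterError("cannot calibrate: rho2 = 0 (gamma2 = 0?)")
    new_gamma1 = params.gamma1 * (1.0 - fibronectin_share) * K_target / rho1
    if fibronectin_share == 0:
        new_gamma2 = 0.0  # switch the fibronectin channel off entirely
    else:
        new_gamma2 = params.gamma2 * fibronectin_share * K_target / (
            -rho2 * params.mu / params.beta
        )
    return replace(params, gamma1=new_gamma1, gamma2=new_gamma2)
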