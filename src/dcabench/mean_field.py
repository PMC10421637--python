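"""Closed-form mean-field theory: order parameters, critical temperatures,
and the mean-field f-divergence curve.

The Ising order parameter solves ``delta = tanh(lambda * delta / T)`` with
critical temperature ``Tc = lambda``. The q-state Potts order parameter is
the free-energy-selected root of ``s = (e^{beta lam s} - 1)/(e^{beta lam s}
+ q - 1)``; for q > 2 the transition is first order with jump
``(q - 2)/(q - 1)``. Both reduce consistently: a q=2 Potts model with
coupling strength J maps to an Ising model with coupling J/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DivergenceSpec",
    "MeanFieldCurve",
    "ising_order_parameter",
    "potts_order_parameter",
    "critical_temperature",
    "mf_f_divergence",
    "mean_field_curve",
    "JS_SECOND_DERIVATIVE_AT_ONE",
]

ROOT_TOL = 1e-10
JS_SECOND_DERIVATIVE_AT_ONE = 1.0 / (2.0 * np.log(2.0))  # f''(1) of the JS generator


@dataclass(frozen=True)
class DivergenceSpec:
    """Parameters of the small-coupling-difference divergence expansion."""

    generator_second_derivative_at_one: float = JS_SECOND_DERIVATIVE_AT_ONE
    l1_size: int = 1

    def __post_init__(self):
        if self.generator_second_derivative_at_one <= 0:
            raise ValueError("f''(1) must be positive")
        if self.l1_size < 0:
            raise ValueError("l1_size must be nonnegative")


def ising_order_parameter(T: float, mean_degree: float) -> float:
    """Largest nonnegative root of ``delta = tanh(mean_degree * delta / T)``.

    Returns 0 for T >= Tc = mean_degree (the tanh slope at the origin drops
    below 1); otherwise bracketed bisection to 1e-10 absolute tolerance.
    """
    if T <= 0 or mean_degree <= 0:
        raise ValueError("temperature and mean degree must be positive")
    if T >= mean_degree:
        return 0.0
    g = lambda d: np.tanh(mean_degree * d / T) - d
    # g > 0 just right of 0 in the ordered phase; g(1) < 0 always
    return float(brentq(g, 1e-12, 1.0, xtol=ROOT_TOL))


def _potts_free_energy(s: float, T: float, lam: float, q: int) -> float:
    """Mean-field variational free energy per site at order parameter s."""
    p = np.full(q, (1.0 - s) / q)
    p[0] = (1.0 + (q - 1) * s) / q
    entropy = -np.sum(np.where(p > 0, p * np.log(np.maximum(p, 1e-300)), 0.0))
    return float(-(lam / (2.0 * q)) * (1.0 + (q - 1) * s * s) - T * entropy)


def _potts_self_consistency_roots(T: float, lam: float, q: int) -> list[float]:
    beta = 1.0 / T
    g = lambda s: s - np.expm1(beta * lam * s) / (np.exp(beta * lam * s) + q - 1)
    roots = [0.0]
    grid = np.linspace(1e-9, 1.0 - 1e-12, 400)
    vals = np.array([g(s) for s in grid])
    for a, b, ga, gb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if ga == 0.0:
            roots.append(float(a))
        elif ga * gb < 0:
            roots.append(float(brentq(g, a, b, xtol=ROOT_TOL)))
    return roots


def potts_order_parameter(T: float, mean_degree: float, q: int) -> float:
    """Stable mean-field Potts order parameter ``(q * rho_max - 1)/(q - 1)``.

    Among the self-consistency roots, the one globally minimizing the
    mean-field free energy is returned; for q > 2 the curve jumps by
    ``(q - 2)/(q - 1)`` at the first-order transition.
    """
    if T <= 0 or mean_degree <= 0:
        raise ValueError("temperature and mean degree must be positive")
    if int(q) != q or q < 2:
        raise ValueError("q must be an integer >= 2")
    q = int(q)
    roots = _potts_self_consistency_roots(T, mean_degree, q)
    return float(min(roots, key=lambda s: _potts_free_energy(s, T, mean_degree, q)))


def critical_temperature(mean_degree: float, q: int = 2) -> float:
    """Order-disorder transition temperature of the mean-field theory.

    Ising (q=2): ``Tc = mean_degree`` exactly. Potts q > 2: the first-order
    transition located numerically as the temperature where the nontrivial
    free-energy minimum crosses the disordered one (closed form:
    ``lam (q-2) / (2 (q-1) ln(q-1))``).
    """
    if mean_degree <= 0:
        raise ValueError("mean degree must be positive")
    if int(q) != q or q < 2:
        raise ValueError("q must be an integer >= 2")
    q = int(q)
    if q == 2:
        return float(mean_degree)

    def free_energy_gap(T: float) -> float:
        roots = [s for s in _potts_self_consistency_roots(T, mean_degree, q) if s > 1e-8]
        if not roots:
            return 1.0  # only the disordered solution exists: above Tc
        best = min(_potts_free_energy(s, T, mean_degree, q) for s in roots)
        return best - _potts_free_energy(0.0, T, mean_degree, q)

    closed = mean_degree * (q - 2) / (2.0 * (q - 1) * np.log(q - 1))
    return float(brentq(free_energy_gap, 0.5 * closed, 1.5 * closed, xtol=ROOT_TOL))


def mf_f_divergence(
    T: float, mean_degree: float, spec: DivergenceSpec | None = None
) -> float:
    """Mean-field f-divergence between models differing in ``l1_size`` edges.

    ``0.5 * f''(1) * l1 * (1 - delta(T)^4) / T**2`` with the Ising mean-field
    order parameter; reduces to ``0.5 * f''(1) * l1 / T**2`` above Tc and
    peaks at T/Tc ~ 0.83.
    """
    spec = spec or DivergenceSpec()
    delta = ising_order_parameter(T, mean_degree)
    return float(
        0.5
        * spec.generator_second_derivative_at_one
        * spec.l1_size
        * (1.0 - delta**4)
        / T**2
    )


@dataclass
class MeanFieldCurve:
    """Tabulated order parameter and divergence curve on a temperature grid."""

    mean_degree: float
    num_states: int
    critical_temperature: float
    temperatures: np.ndarray
    order_parameter: np.ndarray
    divergence: np.ndarray | None = None

    @property
    def reduced_temperatures(self) -> np.ndarray:
        return self.temperatures / self.critical_temperature


def mean_field_curve(
    mean_degree: float,
    q: int = 2,
    t_min_rel: float = 0.3,
    t_max_rel: float = 3.0,
    points: int = 200,
    divergence_spec: DivergenceSpec | None = None,
) -> MeanFieldCurve:
    """Evaluate delta(T) (and the divergence curve for Ising) on a log grid.

    Temperatures are log-spaced over ``[t_min_rel, t_max_rel] * Tc``.
    """
    Tc = critical_temperature(mean_degree, q)
    temps = np.geomspace(t_min_rel * Tc, t_max_rel * Tc, points)
    if q == 2:
        delta = np.array([ising_order_parameter(T, mean_degree) for T in temps])
        div = np.array([mf_f_divergence(T, mean_degree, divergence_spec) for T in temps])
    else:
        delta = np.array([potts_order_parameter(T, mean_degree, q) for T in temps])
        div = None
    return MeanFieldCurve(
        mean_degree=mean_degree,
        num_states=int(q),
        critical_temperature=Tc,
        temperatures=temps,
        order_parameter=delta,
        divergence=div,
    )


def mf_divergence_argmax(
    mean_degree: float,
    t_min_rel: float = 0.5,
    t_max_rel: float = 1.5,
    points: int = 20_001,
) -> float:
    """Location (in units of Tc) of the mean-field divergence maximum."""
    Tc = critical_temperature(mean_degree, 2)
    temps = np.linspace(t_min_rel * Tc, t_max_rel * Tc, points)
    vals = np.array([mf_f_divergence(T, mean_degree) for T in temps])
    return float(temps[np.argmax(vals)] / Tc)
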