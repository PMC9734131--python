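"""Thermo-kinetic interpretation of fitted two-state exchange parameters.

Given the minor-state population p_B, the exchange rate k_ex = k_1 + k_-1
and the temperature, this module derives the microscopic rates, state
half-lives, the Gibbs free-energy gap between the states, and Eyring
activation free energies with transmission coefficient kappa = 1:

    k_1      = k_ex * p_B                (ground -> excited)
    k_-1     = k_ex * p_A                (excited -> ground)
    dG       = -R T ln(p_B / p_A)
    dG_dagger = -R T ln(k h / (kappa k_B T))
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exchange_model import ExchangeParameters

__all__ = [
    "R_GAS",
    "K_BOLTZMANN",
    "H_PLANCK",
    "KineticSummary",
    "rates_from_exchange",
    "populations_to_dG",
    "dG_to_populations",
    "eyring_dG",
    "eyring_rate",
    "summarize",
]

R_GAS = 8.314462618  # J mol^-1 K^-1
K_BOLTZMANN = 1.380649e-23  # J K^-1
H_PLANCK = 6.62607015e-34  # J s


@dataclass(frozen=True)
class KineticSummary:
    """Full thermo-kinetic picture of a two-state exchange process.

    Energies in J mol^-1; ``dG`` is excited minus ground, ``dG_forward`` /
    ``dG_reverse`` the barriers from ground / excited state to the
    transition state.
    """

    k1: float
    k_minus1: float
    t_half_ground: float
    t_half_excited: float
    dG: float
    dG_forward: float
    dG_reverse: float
    temperature: float
    kappa: float = 1.0

    @property
    def k_ex(self) -> float:
        return self.k1 + self.k_minus1


def rates_from_exchange(k_ex: float, p_excited: float) -> tuple[float, float]:
    """Microscopic rates (k_1, k_-1) from (k_ex, p_excited).

    Detailed balance for A <-> B gives k_1/k_-1 = p_B/p_A, hence
    k_1 = k_ex p_B and k_-1 = k_ex p_A.
    """
    if k_ex <= 0:
        raise ValueError(f"k_ex must be positive; got {k_ex}")
    if not 0.0 < p_excited < 1.0:
        raise ValueError(f"p_excited must lie strictly in (0, 1); got {p_excited}")
    return k_ex * p_excited, k_ex * (1.0 - p_excited)


def populations_to_dG(p_ground: float, p_excited: float, temperature: float) -> float:
    """Gibbs free-energy difference (excited minus ground) in J mol^-1."""
    if p_ground <= 0 or p_excited <= 0:
        raise ValueError(
            f"populations must be positive; got p_ground={p_ground}, "
            f"p_excited={p_excited}"
        )
    if p_ground + p_excited > 1.0 + 1e-6:
        raise ValueError("populations sum above 1")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive; got {temperature}")
    return -R_GAS * temperature * math.log(p_excited / p_ground)


def dG_to_populations(dG: float, temperature: float) -> tuple[float, float]:
    """Boltzmann inversion of :func:`populations_to_dG` (two-state)."""
    ratio = math.exp(-dG / (R_GAS * temperature))  # p_excited / p_ground
    p_ground = 1.0 / (1.0 + ratio)
    return p_ground, 1.0 - p_ground


def eyring_dG(rate: float, temperature: float, kappa: float = 1.0) -> float:
    """Activation free energy (J mol^-1) from a rate via the Eyring equation.

    Inverts ``k = kappa (k_B T / h) exp(-dG_dagger / R T)``.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive; got {rate}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive; got {temperature}")
    return -R_GAS * temperature * math.log(
        rate * H_PLANCK / (kappa * K_BOLTZMANN * temperature)
    )


def eyring_rate(dG_dagger: float, temperature: float, kappa: float = 1.0) -> float:
    """Inverse of :func:`eyring_dG`."""
    return (
        kappa
        * K_BOLTZMANN
        * temperature
        / H_PLANCK
        * math.exp(-dG_dagger / (R_GAS * temperature))
    )


def summarize(exch: ExchangeParameters, kappa: float = 1.0) -> KineticSummary:
    """Compose rates, half-lives, dG and Eyring barriers for one fit."""
    k1, km1 = rates_from_exchange(exch.k_ex, exch.p_excited)
    dG = populations_to_dG(exch.p_ground, exch.p_excited, exch.temperature)
    return KineticSummary(
        k1=k1,
        k_minus1=km1,
        t_half_ground=math.log(2.0) / k1,
        t_half_excited=math.log(2.0) / km1,
        dG=dG,
        dG_forward=eyring_dG(k1, exch.temperature, kappa),
        dG_reverse=eyring_dG(km1, exch.temperature, kappa),
        temperature=exch.temperature,
        kappa=kappa,
    )
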