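"""Two-state chemical-exchange forward models for CPMG relaxation dispersion.

Maps global exchange parameters (minor-state population ``p_excited`` and
exchange rate ``k_ex = k_1 + k_-1``) plus per-probe chemical-shift
differences onto effective transverse relaxation rates ``R2,eff`` measured
in constant-time CPMG experiments:

* ¹⁵N single-quantum (SQ) backbone-amide CPMG, and
* ¹³C–¹H multiple-quantum (MQ) methyl-TROSY CPMG, whose dispersion depends
  on both the carbon and the proton shift differences.

Both models are evaluated by exact numerical propagation of the 2x2 complex
Bloch–McConnell evolution blocks through an ideal-pulse echo train.  The
exchange-free baseline rate is assumed equal in the two states; it then
commutes with the evolution and enters only as an additive offset, so the
propagation below is carried out for the exchange contribution alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "NucleusMode",
    "ExchangeParameters",
    "ProbeParameters",
    "DispersionPoint",
    "CpmgSchedule",
    "GAMMA_RATIO",
    "r2eff_from_intensity",
    "intensity_from_r2eff",
    "sq_cpmg_r2eff",
    "mq_cpmg_r2eff",
    "exchange_contribution",
    "dw_ppm_to_rad",
    "pulse_count",
]


class NucleusMode(str, Enum):
    """Coherence type of a dispersion curve."""

    N15_SQ = "N15SQ"
    CH3_MQ = "CH3MQ"


#: magnitude of gamma_X / gamma_H for the heteronucleus of each mode
GAMMA_RATIO = {NucleusMode.N15_SQ: 0.10136, NucleusMode.CH3_MQ: 0.25144}

#: gamma_H / gamma_H, used for the proton dimension of MQ coherences
_GAMMA_H = 1.0


@dataclass(frozen=True)
class ExchangeParameters:
    """Global two-state exchange state: A (ground) <-> B (excited).

    Parameters
    ----------
    p_excited : float
        Fractional population of the minor (excited) state, in [0, 0.5].
    k_ex : float
        Exchange rate ``k_1 + k_-1`` in s^-1.
    temperature : float
        Sample temperature in kelvin.
    """

    p_excited: float
    k_ex: float
    temperature: float = 293.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_excited <= 0.5:
            raise ValueError(
                f"p_excited must lie in [0, 0.5] (minor state); got {self.p_excited}"
            )
        if self.k_ex <= 0:
            raise ValueError(f"k_ex must be positive; got {self.k_ex}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive; got {self.temperature}")

    @property
    def p_ground(self) -> float:
        return 1.0 - self.p_excited


@dataclass
class ProbeParameters:
    """Per-probe parameters of the dispersion model.

    ``dw_X`` is the absolute heteronucleus shift difference (|Δω_N| or
    |Δω_C|) in ppm; ``dw_H`` the proton one (zero for ¹⁵N SQ).
    ``relative_sign`` is the sign of Δω_H relative to Δω_X (MQ only); under
    the DQ/ZQ pathway average it does not change R2,eff but it does change
    the individual pathway signals.  ``r2_base`` maps the spectrometer ¹H
    frequency in MHz to the exchange-free rate R2,0 in s^-1.
    """

    probe_id: str
    nucleus_mode: NucleusMode
    dw_X: float
    dw_H: float = 0.0
    relative_sign: int = 1
    r2_base: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nucleus_mode = NucleusMode(self.nucleus_mode)
        if self.dw_X < 0 or self.dw_H < 0:
            raise ValueError(
                f"shift differences are absolute values (>= 0); got "
                f"dw_X={self.dw_X}, dw_H={self.dw_H} for {self.probe_id}"
            )
        if self.nucleus_mode is NucleusMode.N15_SQ and self.dw_H != 0.0:
            raise ValueError(f"dw_H must be 0 for N15_SQ probe {self.probe_id}")
        if self.relative_sign not in (-1, 1):
            raise ValueError("relative_sign must be +1 or -1")
        for f, r in self.r2_base.items():
            if r < 0:
                raise ValueError(f"r2_base[{f}] < 0 for {self.probe_id}")


@dataclass(frozen=True)
class DispersionPoint:
    """One measured R2,eff value."""

    field_MHz: float
    nu_cpmg: float
    r2eff: float
    sigma: float

    def __post_init__(self) -> None:
        if self.nu_cpmg <= 0:
            raise ValueError(f"nu_cpmg must be positive; got {self.nu_cpmg}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive; got {self.sigma}")


@dataclass(frozen=True)
class CpmgSchedule:
    """Constant-time CPMG acquisition schedule.

    ``nu_cpmg = n_pi / (2 * t_relax)`` with ``n_pi`` the even number of
    refocusing pulses in the relaxation period.
    """

    nucleus_mode: NucleusMode
    t_relax: float
    nu_list: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nucleus_mode", NucleusMode(self.nucleus_mode))
        if self.t_relax <= 0:
            raise ValueError("t_relax must be positive")
        for nu in self.nu_list:
            pulse_count(nu, self.t_relax)  # validates commensurability

    @classmethod
    def default_mq(cls) -> "CpmgSchedule":
        """16 frequencies spanning 66–2000 Hz in a 30 ms period."""
        n_pi = (4, 6, 8, 10, 12, 16, 20, 26, 32, 40, 50, 62, 76, 90, 104, 120)
        t = 0.030
        return cls(NucleusMode.CH3_MQ, t, tuple(n / (2 * t) for n in n_pi))

    @classmethod
    def default_n15(cls) -> "CpmgSchedule":
        """11 frequencies spanning 33–1000 Hz in a 60 ms period."""
        n_pi = (4, 6, 8, 12, 16, 22, 30, 44, 64, 90, 120)
        t = 0.060
        return cls(NucleusMode.N15_SQ, t, tuple(n / (2 * t) for n in n_pi))


def pulse_count(nu_cpmg: float, t_relax: float) -> int:
    """Even number of refocusing pulses implied by ``nu_cpmg`` and ``t_relax``.

    Raises if the frequency is not commensurate with an even pulse count.
    """
    n_float = 2.0 * t_relax * nu_cpmg
    n = int(round(n_float))
    if n < 2 or abs(n_float - n) > 1e-6 * max(1.0, n_float) or n % 2 != 0:
        raise ValueError(
            f"nu_cpmg={nu_cpmg} Hz does not correspond to an even pulse count "
            f"in t_relax={t_relax} s (n = {n_float:.6f})"
        )
    return n


def r2eff_from_intensity(i_nu: float, i_ref: float, t_relax: float) -> float:
    """R2,eff from the intensity ratio of a CPMG plane to the reference plane.

    ``R2,eff = -(1/t_relax) * ln(I(nu)/I_ref)``.
    """
    if i_nu <= 0:
        raise ValueError(f"intensity i_nu must be positive; got {i_nu}")
    if i_ref <= 0:
        raise ValueError(f"reference intensity must be positive; got {i_ref}")
    if t_relax <= 0:
        raise ValueError(f"t_relax must be positive; got {t_relax}")
    return -math.log(i_nu / i_ref) / t_relax


def intensity_from_r2eff(r2eff: float, i_ref: float, t_relax: float) -> float:
    """Inverse of :func:`r2eff_from_intensity`."""
    if i_ref <= 0:
        raise ValueError(f"reference intensity must be positive; got {i_ref}")
    if t_relax <= 0:
        raise ValueError(f"t_relax must be positive; got {t_relax}")
    return i_ref * math.exp(-r2eff * t_relax)


def dw_ppm_to_rad(dw_ppm: float, field_MHz: float, nucleus_ratio: float) -> float:
    """Convert a ppm shift difference to rad/s at the given ¹H field.

    The nucleus Larmor frequency is ``field_MHz * |gamma_X/gamma_H|`` MHz,
    so 1 ppm corresponds to that many Hz.
    """
    return 2.0 * math.pi * dw_ppm * field_MHz * nucleus_ratio


def _expm2(mat: np.ndarray) -> np.ndarray:
    """Matrix exponentials of a batch of 2x2 complex matrices, closed form."""
    a = mat[..., 0, 0]
    b = mat[..., 0, 1]
    c = mat[..., 1, 0]
    d = mat[..., 1, 1]
    tr = a + d
    disc = np.sqrt((a - d) ** 2 + 4 * b * c + 0j)
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    e1 = np.exp(lam1)
    e2 = np.exp(lam2)
    diff = lam1 - lam2
    # sinch handles the degenerate (equal-eigenvalue) limit
    small = np.abs(diff) < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(small, np.exp(lam2), (e1 - e2) / np.where(small, 1.0, diff))
    g = e1 - lam1 * f
    out = np.empty_like(mat)
    out[..., 0, 0] = f * a + g
    out[..., 0, 1] = f * b
    out[..., 1, 0] = f * c
    out[..., 1, 1] = f * d + g
    return out


def _echo_train_signal(
    omega_b: np.ndarray | float,
    k1: float,
    km1: float,
    n_pulses: np.ndarray,
    t_relax: float,
) -> np.ndarray:
    """Ground-state signal magnitude after an ideal even-pulse CPMG train.

    ``omega_b`` is the (signed) offset of state B relative to A in rad/s for
    the coherence considered; a refocusing pulse flips its sign.  The train
    is ``(tau - pi - tau)^n`` with ``tau = t_relax / (2 n)``.  The returned
    value is |M_A(T)| / p_A with M(0) = (p_A, p_B); exchange-free relaxation
    is excluded (it factors out when equal in both states).
    """
    omega_b, n_pulses = np.broadcast_arrays(
        np.asarray(omega_b, dtype=float), np.asarray(n_pulses)
    )
    shape = omega_b.shape
    if k1 == 0.0:
        # single-state: no dephasing of the observed ground-state line
        return np.ones(shape)
    p_a = km1 / (k1 + km1)
    p_b = 1.0 - p_a

    w = omega_b.ravel()
    n = n_pulses.ravel().astype(int)
    tau = (t_relax / (2 * n))[:, None, None]
    base = np.zeros(w.shape + (2, 2), dtype=complex)
    base[:, 0, 0] = -k1
    base[:, 0, 1] = km1
    base[:, 1, 0] = k1
    l_plus = base.copy()
    l_plus[:, 1, 1] = -km1 - 1j * w
    l_minus = base
    l_minus[:, 1, 1] = -km1 + 1j * w
    p_tau_p = _expm2(l_plus * tau)
    p_tau_m = _expm2(l_minus * tau)
    p2_p = p_tau_p @ p_tau_p
    p2_m = p_tau_m @ p_tau_m
    # train (even n, read right-to-left in time):
    #   tau(+) [2tau(+) 2tau(-)]^{n/2-1} 2tau(-) tau(+)
    block = p2_p @ p2_m
    exponent = n // 2 - 1
    acc = np.broadcast_to(np.eye(2, dtype=complex), block.shape).copy()
    sq = block
    e_max = int(exponent.max())
    bit = 0
    while (1 << bit) <= e_max:
        mask = (exponent >> bit) & 1 == 1
        if mask.any():
            acc[mask] = acc[mask] @ sq[mask]
        sq = sq @ sq
        bit += 1
    u = p_tau_p @ (p2_m @ (acc @ p_tau_p))
    m_a = u[:, 0, 0] * p_a + u[:, 0, 1] * p_b
    return (np.abs(m_a) / p_a).reshape(shape)


def exchange_contribution(
    exch: ExchangeParameters,
    probe: ProbeParameters,
    field_MHz: float,
    nu_cpmg: np.ndarray | float,
    t_relax: float,
) -> np.ndarray:
    """Exchange contribution Rex(nu) = R2,eff - R2,0 in s^-1.

    Vectorized over ``nu_cpmg``.  For MQ probes the double- and
    zero-quantum pathway signals are averaged before taking the log.
    """
    nu = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    n_pulses = np.array([pulse_count(v, t_relax) for v in nu])
    k1 = exch.k_ex * exch.p_excited
    km1 = exch.k_ex * exch.p_ground
    ratio = GAMMA_RATIO[probe.nucleus_mode]
    w_x = dw_ppm_to_rad(probe.dw_X, field_MHz, ratio)
    if probe.nucleus_mode is NucleusMode.N15_SQ:
        sig = _echo_train_signal(w_x, k1, km1, n_pulses, t_relax)
    else:
        w_h = probe.relative_sign * dw_ppm_to_rad(probe.dw_H, field_MHz, _GAMMA_H)
        sig_dq = _echo_train_signal(w_x + w_h, k1, km1, n_pulses, t_relax)
        sig_zq = _echo_train_signal(w_x - w_h, k1, km1, n_pulses, t_relax)
        sig = 0.5 * (sig_dq + sig_zq)
    rex = -np.log(sig) / t_relax
    return rex if np.ndim(nu_cpmg) else rex.reshape(())


def _r2eff(
    exch: ExchangeParameters,
    probe: ProbeParameters,
    field_MHz: float,
    nu_cpmg,
    t_relax: float,
) -> np.ndarray:
    try:
        base = probe.r2_base[field_MHz]
    except KeyError:
        raise KeyError(
            f"probe {probe.probe_id} has no r2_base entry for {field_MHz} MHz"
        ) from None
    return base + exchange_contribution(exch, probe, field_MHz, nu_cpmg, t_relax)


def sq_cpmg_r2eff(
    exch: ExchangeParameters,
    probe: ProbeParameters,
    field_MHz: float,
    nu_cpmg,
    t_relax: float = 0.060,
):
    """R2,eff for a ¹⁵N single-quantum CPMG experiment (s^-1)."""
    if probe.nucleus_mode is not NucleusMode.N15_SQ:
        raise ValueError(f"probe {probe.probe_id} is not an N15_SQ probe")
    return _r2eff(exch, probe, field_MHz, nu_cpmg, t_relax)


def mq_cpmg_r2eff(
    exch: ExchangeParameters,
    probe: ProbeParameters,
    field_MHz: float,
    nu_cpmg,
    t_relax: float = 0.030,
):
    """R2,eff for a ¹³C–¹H multiple-quantum methyl-TROSY CPMG experiment.

    The DQ and ZQ coherence pathways evolve with offsets Δω_C ± Δω_H; their
    signals are averaged and converted with -(1/T) ln.
    """
    if probe.nucleus_mode is not NucleusMode.CH3_MQ:
        raise ValueError(f"probe {probe.probe_id} is not a CH3_MQ probe")
    return _r2eff(exch, probe, field_MHz, nu_cpmg, t_relax)
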