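"""Transition-state-theory rate constants with tunneling corrections.

The per-channel rate model is conventional TST on a 1 M standard state,

    k = sigma * kappa * (k_B T / h) * exp(-dG_act / RT),

with sigma the reaction-path degeneracy and kappa a tunneling transmission
coefficient.  kappa may be supplied as data (the usual case when consuming
published tables), or computed from the imaginary frequency alone (Wigner)
or from an asymmetric Eckart barrier (forward/reverse barrier heights plus
imaginary frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate

from . import constants, medium
from .datamodel import Conditions, RateResult, ReactionChannel, ValidationError

__all__ = [
    "TunnelingSpec",
    "tst_rate",
    "wigner_kappa",
    "eckart_kappa",
    "eckart_transmission",
    "evaluate_channels",
]


@dataclass(frozen=True)
class TunnelingSpec:
    """How to obtain kappa for each channel.

    mode "supplied" uses the channel's kappa column; "wigner" needs
    nu_imag; "eckart" needs v_forward, v_reverse and nu_imag; "none"
    disables tunneling (kappa = 1).
    """

    mode: str = "supplied"

    _MODES = ("supplied", "wigner", "eckart", "none")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValidationError(f"unknown tunneling mode {self.mode!r}")


def tst_rate(delta_g_act: float, temperature: float = 298.15,
             sigma: int = 1, kappa: float = 1.0) -> float:
    """Conventional TST rate constant in M^-1 s^-1.

    Strictly decreasing in the barrier, linear in sigma and kappa;
    at dG_act = 0 with sigma = kappa = 1 it returns k_B T / h.
    """
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")
    if sigma < 1:
        raise ValidationError("sigma must be >= 1")
    if kappa < 0:
        raise ValidationError("kappa must be non-negative")
    if not math.isfinite(delta_g_act):
        raise ValidationError("delta_g_act must be finite")
    return sigma * kappa * constants.kbt_over_h(temperature) \
        * constants.boltzmann_factor(delta_g_act, temperature)


def wigner_kappa(nu_imag: float, temperature: float = 298.15) -> float:
    """Wigner tunneling correction kappa = 1 + u^2/24, u = h*c*nu/(k_B T).

    A small-curvature fallback when only the imaginary frequency is known.
    """
    if nu_imag < 0:
        raise ValidationError("imaginary frequency magnitude must be >= 0")
    u = constants.WAVENUMBER_TO_KELVIN * nu_imag / temperature
    return 1.0 + u * u / 24.0


# ---------------------------------------------------------------------------
# Eckart barrier
# ---------------------------------------------------------------------------

def _log_cosh(t: np.ndarray) -> np.ndarray:
    """log(cosh(t)), overflow-safe."""
    t = np.abs(t)
    return t + np.log1p(np.exp(-2.0 * t)) - math.log(2.0)


def eckart_transmission(energy_j: np.ndarray, v_forward_j: float,
                        v_reverse_j: float, nu_quantum_j: float) -> np.ndarray:
    """Transmission probability P(E) through an asymmetric Eckart barrier.

    Energies are per-molecule (J), measured from the reactant asymptote;
    ``nu_quantum_j`` is h*c*nu for the imaginary-mode wavenumber.  P(E) = 0
    below the product asymptote max(0, V_f - V_r).  The standard
    two-parameter closed form is evaluated in log space so that large
    barrier/low-frequency regimes do not overflow cosh.
    """
    energy = np.asarray(energy_j, dtype=float)
    alpha1 = 2.0 * math.pi * v_forward_j / nu_quantum_j
    alpha2 = 2.0 * math.pi * v_reverse_j / nu_quantum_j
    inv_sqrt = 1.0 / math.sqrt(alpha1) + 1.0 / math.sqrt(alpha2)

    xi = energy / v_forward_j
    open_channel = energy > max(0.0, v_forward_j - v_reverse_j)
    xi = np.where(open_channel, xi, np.nan)

    two_pi_a = 2.0 * np.sqrt(alpha1 * xi) / inv_sqrt
    two_pi_b = 2.0 * np.sqrt((xi - 1.0) * alpha1 + alpha2) / inv_sqrt
    d_arg = alpha1 * alpha2 - math.pi ** 2 / 4.0

    log_cosh_sum = _log_cosh(two_pi_a + two_pi_b)
    log_cosh_diff = _log_cosh(two_pi_a - two_pi_b)
    if d_arg >= 0.0:
        log_d = _log_cosh(np.asarray(2.0 * math.sqrt(d_arg)))
        m_num = np.maximum(log_cosh_diff, log_d)
        log_num = m_num + np.log(np.exp(log_cosh_diff - m_num) + np.exp(log_d - m_num))
        m_den = np.maximum(log_cosh_sum, log_d)
        log_den = m_den + np.log(np.exp(log_cosh_sum - m_den) + np.exp(log_d - m_den))
    else:
        cos_d = math.cos(2.0 * math.sqrt(-d_arg))  # |cos| <= 1
        log_num = log_cosh_diff + np.log1p(cos_d * np.exp(-log_cosh_diff))
        log_den = log_cosh_sum + np.log1p(cos_d * np.exp(-log_cosh_sum))

    prob = -np.expm1(log_num - log_den)
    return np.where(open_channel, prob, 0.0)


def eckart_kappa(v_forward: float, v_reverse: float, nu_imag: float,
                 temperature: float = 298.15, rel_tol: float = 1e-8) -> float:
    """Eckart tunneling correction.

    Boltzmann average of the asymmetric-Eckart transmission probability,
    normalized by the classical flux over the forward barrier:

        kappa = exp(V_f/RT)/(RT) * int_0^inf P(E) exp(-E/RT) dE

    with barriers in kcal mol^-1 and the imaginary frequency in cm^-1.
    Adaptive quadrature on E in [0, V_f + 40 RT] (the integrand decays as
    exp(-E/RT), so the truncated tail is ~exp(-40) of the classical flux).
    """
    if v_forward <= 0 or v_reverse <= 0 or nu_imag <= 0:
        raise ValidationError("Eckart barriers and imaginary frequency must be > 0")
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")

    kt = constants.BOLTZMANN_J_PER_K * temperature
    vf = constants.kcal_to_joule_per_molecule(v_forward)
    vr = constants.kcal_to_joule_per_molecule(v_reverse)
    nu_q = constants.wavenumber_to_joule(nu_imag)

    def integrand(e: float) -> float:
        return float(eckart_transmission(np.asarray(e), vf, vr, nu_q)) \
            * math.exp(-(e - vf) / kt)

    upper = vf + 40.0 * kt
    value, abserr = integrate.quad(integrand, 0.0, upper, points=[vf],
                                   epsrel=rel_tol, epsabs=0.0, limit=500)
    if not math.isfinite(value) or (value > 0 and abserr > 1e-4 * value):
        raise ValidationError(
            f"Eckart quadrature did not converge (value={value}, abserr={abserr})"
        )
    return value / kt


def resolve_kappa(channel: ReactionChannel, tunneling: TunnelingSpec,
                  temperature: float) -> float:
    if tunneling.mode == "none":
        return 1.0
    if tunneling.mode == "supplied":
        if channel.kappa is None:
            raise ValidationError(f"{channel.site_label}: no supplied kappa")
        return channel.kappa
    if tunneling.mode == "wigner":
        if channel.nu_imag is None:
            raise ValidationError(f"{channel.site_label}: wigner mode needs nu_imag")
        return wigner_kappa(channel.nu_imag, temperature)
    # eckart
    if channel.v_forward is None or channel.v_reverse is None or channel.nu_imag is None:
        raise ValidationError(
            f"{channel.site_label}: eckart mode needs v_forward, v_reverse and nu_imag"
        )
    return eckart_kappa(channel.v_forward, channel.v_reverse, channel.nu_imag, temperature)


def evaluate_channels(viable: Sequence[ReactionChannel], conditions: Conditions,
                      tunneling: TunnelingSpec = TunnelingSpec()) -> list[RateResult]:
    """Per-channel rate constants under the given conditions.

    In gas conditions k_app = k_act exactly (k_diff treated as infinite);
    in a solvent the Collins-Kimball diffusion correction is applied with
    the Stokes-Einstein/Smoluchowski encounter rate from the conditions.
    """
    k_diff: Optional[float] = None
    if not conditions.is_gas:
        spec = medium.diffusion_spec_from_conditions(conditions)
        k_diff = medium.smoluchowski_kd(spec, conditions.temperature)

    results = []
    for channel in viable:
        if channel.delta_g_act is None:
            raise ValidationError(
                f"{channel.site_label} ({channel.mechanism.value}): "
                "missing activation free energy"
            )
        kappa = resolve_kappa(channel, tunneling, conditions.temperature)
        k_tst = tst_rate(channel.delta_g_act, conditions.temperature)
        k_act = channel.sigma * kappa * k_tst
        k_app = k_act if k_diff is None else medium.collins_kimball(k_act, k_diff)
        results.append(RateResult(
            site_label=channel.site_label,
            mechanism=channel.mechanism,
            k_tst=k_tst, k_act=k_act, k_app=k_app, k_diff=k_diff,
        ))
    return results
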