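"""Closed-form free-energy and rate relations for bioenergetic modelling.

The functions here are the elementary vocabulary from which proton-pump
free-energy profiles are assembled:

* equilibrium constant ↔ ΔG (ΔG = −RT·ln K),
* redox potential difference → ΔG (ΔG = −n·F·ΔE),
* transition-state theory barrier ↔ rate (k = κ·(k_B·T/h)·e^(−ΔG‡/RT)),
* proton transfer between a bulk phase at some pH and a titratable site
  with a given pK_a (ΔG = 2.303·RT·(pH − pK_a)),
* perturbation of a charge-translocation step by a membrane potential
  assuming a linear potential drop across the membrane,
* a screened Coulomb interaction between two point charges.

Sign conventions: negative ΔG is exergonic; a positive charge moved from
the N-side towards the P-side against a positive pmf is destabilized
(positive ΔΔG).  All inputs/outputs are kcal/mol, mV, Å, s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import COULOMB_CONSTANT, EXACT, EnergySpec

__all__ = [
    "ChargeMove",
    "dg_from_equilibrium",
    "equilibrium_from_dg",
    "dg_from_redox",
    "tst_rate",
    "tst_barrier",
    "proton_transfer_dg",
    "proton_release_dg",
    "pmf_shift",
    "coulomb_interaction",
]


@dataclass(frozen=True)
class ChargeMove:
    """A (partial) charge translocation across the membrane.

    Parameters
    ----------
    charge : float
        Translocated charge in elementary charges; positive for a proton
        moving from the N-side towards the P-side.
    fraction : float
        Fraction z/L of the transmembrane potential drop crossed by the
        charge, in [0, 1].  A buried site halfway across the membrane has
        fraction 0.5; a completed translocation has fraction 1.0.
    """

    charge: float
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(
                f"fraction must be within [0, 1], got {self.fraction}"
            )
        if not math.isfinite(self.charge):
            raise ValueError("charge must be finite")


def dg_from_equilibrium(K: float, spec: EnergySpec = EXACT) -> float:
    """Free energy (kcal/mol) of a step with equilibrium constant ``K``.

    ΔG = −RT·ln K, evaluated as −(2.303·RT)·log10 K so that the rounded
    constant set reproduces printed 1.42·ΔpK arithmetic exactly.
    """
    if K <= 0:
        raise ValueError(f"equilibrium constant must be positive, got {K}")
    return -spec.ln10_RT * math.log10(K)


def equilibrium_from_dg(dg: float, spec: EnergySpec = EXACT) -> float:
    """Equilibrium constant of a step with free energy ``dg`` (kcal/mol)."""
    return 10.0 ** (-dg / spec.ln10_RT)


def dg_from_redox(delta_E_mv: float, n: int, spec: EnergySpec = EXACT) -> float:
    """Free energy (kcal/mol) of transferring ``n`` electrons down ΔE.

    ΔG = −n·F·ΔE with ΔE = E_m(acceptor) − E_m(donor) in mV.  A positive
    ΔE (electrons moving to a higher potential) is exergonic.
    """
    if not isinstance(n, int) or isinstance(n, bool) or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n!r}")
    return -n * spec.faraday_kcal * delta_E_mv / 1000.0


def tst_rate(barrier: float, kappa: float = 1.0, spec: EnergySpec = EXACT) -> float:
    """Transition-state-theory rate (s⁻¹) for a barrier in kcal/mol.

    k = κ·(k_B·T/h)·exp(−ΔG‡/RT).  κ is a transmission coefficient in
    (0, 1]; Kramers-type diffusive corrections enter as a user-supplied κ.
    """
    if barrier < 0:
        raise ValueError(f"barrier must be non-negative, got {barrier}")
    if not 0.0 < kappa <= 1.0:
        raise ValueError(f"kappa must be in (0, 1], got {kappa}")
    return kappa * spec.prefactor * math.exp(-barrier / spec.RT)


def tst_barrier(rate: float, kappa: float = 1.0, spec: EnergySpec = EXACT) -> float:
    """Barrier (kcal/mol) implied by a first-order rate (s⁻¹); inverse of
    :func:`tst_rate`."""
    if not 0.0 < kappa <= 1.0:
        raise ValueError(f"kappa must be in (0, 1], got {kappa}")
    ceiling = kappa * spec.prefactor
    if not 0.0 < rate <= ceiling:
        raise ValueError(
            f"rate must be in (0, kappa*prefactor={ceiling:.3g}], got {rate}"
        )
    return spec.RT * math.log(ceiling / rate)


def proton_transfer_dg(pH: float, pKa: float, spec: EnergySpec = EXACT) -> float:
    """ΔG (kcal/mol) of proton uptake from bulk at ``pH`` onto a site with
    ``pKa``: 2.303·RT·(pH − pK_a).  Exergonic when pK_a > pH."""
    return spec.ln10_RT * (pH - pKa)


def proton_release_dg(pH: float, pKa: float, spec: EnergySpec = EXACT) -> float:
    """ΔG (kcal/mol) of releasing the site's proton back to bulk at ``pH``;
    the negation of :func:`proton_transfer_dg`."""
    return -proton_transfer_dg(pH, pKa, spec)


def pmf_shift(move: ChargeMove, pmf_mv: float, spec: EnergySpec = EXACT) -> float:
    """Membrane-potential perturbation (kcal/mol) of a charge move.

    ΔΔG = q·F·pmf·(z/L), assuming a linear potential drop across the
    membrane.  Positive for a positive charge moving N→P against a
    positive pmf.  ``pmf_mv`` may be negative (reverse gradient).
    """
    return move.charge * spec.faraday_kcal * (pmf_mv / 1000.0) * move.fraction


def coulomb_interaction(r: float, epsilon: float, q1: float = 1.0, q2: float = 1.0) -> float:
    """Screened Coulomb interaction energy (kcal/mol) of two charges.

    ΔG = C·q1·q2/(ε·r) with C ≈ 332 kcal·Å·mol⁻¹·e⁻², ``r`` in Å and a
    uniform dielectric ε.  The crudest useful estimate of electrostatic
    coupling between titratable/redox sites in a protein.
    """
    if r <= 0:
        raise ValueError(f"distance must be positive, got {r}")
    if epsilon <= 0:
        raise ValueError(f"dielectric must be positive, got {epsilon}")
    return COULOMB_CONSTANT * q1 * q2 / (epsilon * r)
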