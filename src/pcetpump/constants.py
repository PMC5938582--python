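"""Physical-constant sets for bioenergetic free-energy arithmetic.

All energies in this package are kcal/mol, potentials in mV, distances in
Å and rates in s⁻¹ — the unit system in which essentially every number in
the bioenergetics literature is printed.  Two constant sets are provided:

``exact``
    CODATA-based constants evaluated at the requested temperature
    (default 310 K, mammalian physiological).

``rounded``
    The conventionally rounded values used in back-of-envelope
    bioenergetics arithmetic: RT = 0.61 kcal/mol, 2.303·RT = 1.42,
    F = 23.06 kcal·mol⁻¹·V⁻¹ and k_B·T/h = 6.4 ps⁻¹.  Pinning these lets
    published ladders of rounded numbers be reproduced digit for digit.

The two sets agree to ~1% for every operation in :mod:`pcetpump.thermo`.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

__all__ = [
    "EnergySpec",
    "EXACT",
    "ROUNDED",
    "KCAL_PER_EV",
    "COULOMB_CONSTANT",
    "get_spec",
]

#: Gas constant, kcal mol⁻¹ K⁻¹.
R_KCAL = 1.987204259e-3
#: Boltzmann constant, J K⁻¹ (exact, SI 2019).
KB_J = 1.380649e-23
#: Planck constant, J s (exact, SI 2019).
H_J = 6.62607015e-34
#: Faraday constant expressed as energy per volt, kcal mol⁻¹ V⁻¹.
FARADAY_KCAL_PER_V = 96485.33212 / 4184.0
#: 1 eV in kcal/mol; numerically identical to Faraday in kcal/(mol·V).
KCAL_PER_EV = FARADAY_KCAL_PER_V
#: Coulomb constant in kcal·Å·mol⁻¹·e⁻² (vacuum, point charges).
COULOMB_CONSTANT = 332.06


@dataclass(frozen=True)
class EnergySpec:
    """A coherent set of thermodynamic constants at one temperature.

    Attributes
    ----------
    temperature : float
        Absolute temperature, K.
    RT : float
        Thermal energy, kcal/mol.
    faraday_kcal : float
        Faraday constant as energy per volt, kcal mol⁻¹ V⁻¹.
    prefactor : float
        Transition-state-theory pre-exponential k_B·T/h, s⁻¹.
    ln10_RT : float
        2.303·RT, kcal/mol — the energy per pH (or pK_a) unit.
    mode : str
        ``"exact"`` or ``"rounded"``.
    """

    temperature: float
    RT: float
    faraday_kcal: float
    prefactor: float
    ln10_RT: float
    mode: str

    @classmethod
    def exact(cls, temperature: float = 310.0) -> "EnergySpec":
        """CODATA constants evaluated at ``temperature`` (K)."""
        if temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        rt = R_KCAL * temperature
        return cls(
            temperature=temperature,
            RT=rt,
            faraday_kcal=FARADAY_KCAL_PER_V,
            prefactor=KB_J * temperature / H_J,
            ln10_RT=math.log(10.0) * rt,
            mode="exact",
        )

    @classmethod
    def rounded(cls) -> "EnergySpec":
        """The conventionally rounded 310 K constant set (see module docs)."""
        return cls(
            temperature=310.0,
            RT=0.61,
            faraday_kcal=23.06,
            prefactor=6.4e12,
            ln10_RT=1.42,
            mode="rounded",
        )

    @property
    def RT_ev(self) -> float:
        """Thermal energy in eV (for electron-transfer expressions)."""
        return self.RT / KCAL_PER_EV

    def to_json(self) -> str:
        """Serialize the constant set for provenance records."""
        return json.dumps(asdict(self), sort_keys=True)


#: Module-level singletons; the default for every operation is ``EXACT``.
EXACT = EnergySpec.exact()
ROUNDED = EnergySpec.rounded()


def get_spec(mode: str) -> EnergySpec:
    """Return the constant set named ``mode`` (``"exact"`` | ``"rounded"``)."""
    if mode == "exact":
        return EXACT
    if mode == "rounded":
        return ROUNDED
    raise ValueError(f"unknown constants mode {mode!r}; expected 'exact' or 'rounded'")
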