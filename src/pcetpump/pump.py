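"""Multi-state models of redox-driven proton pumps.

The centrepiece is a declarative 17-state model of one catalytic cycle of
respiratory complex I (states I, IIa … VIIIb, IX), built from a handful
of thermodynamic parameters:

* the two-electron redox drop NADH → quinone (midpoint potentials of
  donor and acceptor) fixes the free energy of the end state IX — the
  cycle's boundary condition;
* quinone reduction (I → IIa) is treated as isoenergetic with a 13
  kcal/mol barrier (the ~100 µs electron-transfer step);
* proton uptake into the NuoH subunit (IIa → IIb) follows from the
  uptake pK_a (≈10) against the N-side pH;
* quinol motion down its channel (IIb → IIc) releases a configurable
  fraction (default 60%) of the redox drop — the pump's power stroke;
* three slightly exergonic lateral relay steps (≈ −1 kcal/mol each,
  alternating with isoenergetic Lys/Glu ion-pair openings) charge the
  antiporter-like subunits (IIc → … → Va);
* proton release to the P-side (pK_a ≈ 9 against P-side pH 7, ≈ +3
  kcal/mol) alternates with re-uptake from the N-side (≈ −3) through the
  backwave Va → Vb → … → VIIIb, release order NuoL, M, N, H;
* the final quinol-exchange step VIIIb → IX carries an *unknown* barrier
  (turnover limits it to ≈ 14 kcal/mol) and whatever free energy is
  required to close the cycle onto the redox boundary condition.

Each state records the cumulative charge translocated across the
membrane up to that point (uptake to a buried site counts the membrane
fraction crossed, default one half; P-side release completes the rest),
so that :func:`apply_pmf` can shift the whole ladder at an arbitrary
proton motive force by q·F·pmf·(z/L) per move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

from .constants import EXACT, EnergySpec
from .profile import FreeEnergyProfile
from .thermo import (
    ChargeMove,
    dg_from_redox,
    pmf_shift,
    proton_release_dg,
    proton_transfer_dg,
    tst_barrier,
)

__all__ = [
    "PumpState",
    "Transition",
    "PumpModel",
    "ComplexIParams",
    "ClosureError",
    "build_complex_i_model",
    "build_single_site_model",
    "apply_pmf",
    "single_site_pump_profile",
    "COMPLEX_I_LABELS",
]

#: Canonical state labels of the packaged complex I cycle.
COMPLEX_I_LABELS = (
    "I", "IIa", "IIb", "IIc",
    "IIIa", "IIIb", "IVa", "IVb",
    "Va", "Vb", "VIa", "VIb", "VIIa", "VIIb", "VIIIa", "VIIIb",
    "IX",
)

#: Maximum tolerated mismatch between an explicitly configured ladder and
#: the redox boundary condition, kcal/mol.
CLOSURE_TOL = 0.5


class ClosureError(ValueError):
    """Configured step energies violate the cycle's redox boundary."""


@dataclass(frozen=True)
class PumpState:
    """One node of the pumping cycle.

    ``dG0`` is the free energy relative to the first state at pmf = 0;
    ``moves`` is the cumulative record of charge translocations
    completed once this state is reached.
    """

    label: str
    dG0: float
    moves: tuple[ChargeMove, ...] = ()

    @property
    def translocated_charge(self) -> float:
        """Σ q·(z/L): total membrane-fraction-weighted charge moved."""
        return sum(m.charge * m.fraction for m in self.moves)


@dataclass(frozen=True)
class Transition:
    """One edge of the cycle; ``barrier`` is relative to the source
    state, or ``None`` when no data constrains it (rendered dashed)."""

    source: str
    target: str
    barrier: float | None
    mechanism: str = ""


@dataclass(frozen=True)
class PumpModel:
    """A linear sequence of states closed into a cycle by a substrate-
    exchange edge from the last state back to the first."""

    states: tuple[PumpState, ...]
    transitions: tuple[Transition, ...]
    spec: EnergySpec = EXACT
    unknown_barrier_ceiling: float = 14.0
    exchange_barrier: float = 14.0
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        if len(self.states) < 2:
            raise ValueError("a pump model needs at least two states")
        if abs(self.states[0].dG0) > 1e-12:
            raise ValueError("first state must have dG0 = 0 (reference)")
        if len(self.transitions) != len(self.states) - 1:
            raise ValueError("need exactly one transition per forward step")
        for i, t in enumerate(self.transitions):
            if (t.source, t.target) != (labels[i], labels[i + 1]):
                raise ValueError(
                    f"transition {i} must connect {labels[i]} -> {labels[i+1]}"
                )
            step = self.states[i + 1].dG0 - self.states[i].dG0
            if t.barrier is not None and t.barrier < max(0.0, step) - 1e-9:
                raise ValueError(
                    f"{t.source} -> {t.target}: barrier {t.barrier:.3g} below "
                    f"max(0, step dG = {step:.3g})"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    def state(self, label: str) -> PumpState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(f"no state labelled {label!r}")

    @property
    def total_translocated_charge(self) -> float:
        """Charge translocated over the full cycle (4.0 for complex I:
        four protons across the whole membrane)."""
        return self.states[-1].translocated_charge


@dataclass(frozen=True)
class ComplexIParams:
    """Thermodynamic parameters of the packaged complex I model.

    Energies kcal/mol, potentials mV, pK_a/pH in their own units.
    Defaults are the ubiquinone parameter set; for the menaquinone
    variant set ``acceptor_em_mv = -80``.
    """

    donor_em_mv: float = -320.0      # NADH/NAD+ couple
    acceptor_em_mv: float = 90.0     # ubiquinone in the membrane
    n_electrons: int = 2
    ph_n: float = 7.0
    ph_p: float = 7.0
    uptake_pka: float = 10.0         # NuoH titratable cluster after Q reduction
    release_pka: float = 9.0         # terminal residues / middle lysines
    q_motion_fraction: float = 0.6   # share of the redox drop released IIb->IIc
    relay_step_dg: float = -1.0      # lateral pT to each terminal residue
    q_reduction_barrier: float = 13.0
    q_motion_barrier: float = 4.0
    ion_pair_barrier: float = 4.0    # Lys/Glu ion-pair opening
    relay_barrier: float = 10.0      # lateral proton transfer, "<10"
    water_barrier: float = 10.0      # hydration-limited uptake/release (8-10)
    buried_fraction: float = 0.5     # membrane fraction of buried proton sites
    unknown_barrier_ceiling: float = 14.0
    exchange_barrier: float = 14.0
    final_step_dg: float | None = None  # explicit VIIIb->IX energy (checked)

    def validate(self) -> None:
        named = {
            "donor_em_mv": "donor midpoint potential (NADH couple)",
            "acceptor_em_mv": "acceptor midpoint potential (quinone couple)",
            "uptake_pka": "NuoH uptake pKa",
            "release_pka": "terminal-residue release pKa",
            "q_motion_fraction": "quinol-motion energy fraction",
        }
        for attr, desc in named.items():
            if getattr(self, attr) is None:
                raise ValueError(f"missing parameter {attr} ({desc})")
        if not 0.0 <= self.q_motion_fraction <= 1.0:
            raise ValueError("q_motion_fraction must be in [0, 1]")
        if not 0.0 <= self.buried_fraction <= 1.0:
            raise ValueError("buried_fraction must be in [0, 1]")
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")


def build_complex_i_model(
    params: ComplexIParams | None = None,
    spec: EnergySpec = EXACT,
) -> PumpModel:
    """Assemble the 17-state complex I pumping cycle at pmf = 0.

    The ladder is built step by step from the parameters (see module
    docs); the final quinol-exchange step VIIIb → IX is computed from
    the cycle-closure condition dG0(IX) = −n·F·ΔE.  If
    ``params.final_step_dg`` is supplied explicitly and disagrees with
    closure by more than 0.5 kcal/mol a :class:`ClosureError` is raised.
    """
    p = params or ComplexIParams()
    p.validate()
    delta_e = p.acceptor_em_mv - p.donor_em_mv
    dg_redox = dg_from_redox(delta_e, p.n_electrons, spec)
    uptake = proton_transfer_dg(p.ph_n, p.uptake_pka, spec)
    q_motion = p.q_motion_fraction * dg_redox
    release = proton_release_dg(p.ph_p, p.release_pka, spec)
    reuptake = proton_transfer_dg(p.ph_n, p.release_pka, spec)
    half = p.buried_fraction
    rest = 1.0 - half

    # (target label, step dG, barrier, mechanism, charge move completed)
    steps: list[tuple[str, float, float | None, str, ChargeMove | None]] = [
        ("IIa", 0.0, p.q_reduction_barrier,
         "two-electron quinone reduction via the FeS wire (~100 us)", None),
        ("IIb", uptake, p.water_barrier,
         "proton uptake from the N-side into NuoH (pKa shift on Q reduction)",
         ChargeMove(1.0, half)),
        ("IIc", q_motion, p.q_motion_barrier,
         "quinol motion down the Q channel (power stroke)", None),
        ("IIIa", p.relay_step_dg, p.relay_barrier,
         "lateral pT to terminal residues of the NuoH/N block", None),
        ("IIIb", 0.0, p.ion_pair_barrier,
         "NuoN terminal protonation opens the NuoM Lys/Glu ion pair", None),
        ("IVa", p.relay_step_dg, p.relay_barrier,
         "lateral pT from the NuoM middle lysine to its terminal residue", None),
        ("IVb", 0.0, p.ion_pair_barrier,
         "NuoM terminal protonation opens the NuoL Lys/Glu ion pair", None),
        ("Va", p.relay_step_dg, p.relay_barrier,
         "lateral pT from the NuoL middle lysine to its terminal residue", None),
        ("Vb", release, p.water_barrier,
         "proton release to the P-side from NuoL (backwave starts)",
         ChargeMove(1.0, rest)),
        ("VIa", reuptake, p.water_barrier,
         "NuoL ion-pair closure; middle-lysine re-uptake from the N-side",
         ChargeMove(1.0, half)),
        ("VIb", release, p.water_barrier,
         "proton release to the P-side from NuoM", ChargeMove(1.0, rest)),
        ("VIIa", reuptake, p.water_barrier,
         "NuoM ion-pair closure; middle-lysine re-uptake from the N-side",
         ChargeMove(1.0, half)),
        ("VIIb", release, p.water_barrier,
         "proton release to the P-side from NuoN", ChargeMove(1.0, rest)),
        ("VIIIa", reuptake, p.water_barrier,
         "NuoN ion-pair closure; middle-lysine re-uptake from the N-side",
         ChargeMove(1.0, half)),
        ("VIIIb", release, p.water_barrier,
         "proton release to the P-side from the NuoH/E-channel site",
         ChargeMove(1.0, rest)),
    ]

    states = [PumpState("I", 0.0, ())]
    transitions: list[Transition] = []
    for target, dg, barrier, mech, move in steps:
        prev = states[-1]
        moves = prev.moves + ((move,) if move is not None else ())
        states.append(PumpState(target, prev.dG0 + dg, moves))
        transitions.append(Transition(prev.label, target, barrier, mech))

    required_final = dg_redox - states[-1].dG0
    if p.final_step_dg is not None and abs(p.final_step_dg - required_final) > CLOSURE_TOL:
        raise ClosureError(
            f"configured VIIIb -> IX step ({p.final_step_dg:.3g} kcal/mol) "
            f"violates cycle closure onto -nF*dE = {dg_redox:.3g} "
            f"(requires {required_final:.3g}) by more than {CLOSURE_TOL} kcal/mol"
        )
    states.append(PumpState("IX", dg_redox, states[-1].moves))
    transitions.append(
        Transition(
            "VIIIb", "IX", None,
            "quinol release / Tyr-87, His-38 re-protonation (barrier unknown)",
        )
    )

    return PumpModel(
        states=tuple(states),
        transitions=tuple(transitions),
        spec=spec,
        unknown_barrier_ceiling=p.unknown_barrier_ceiling,
        exchange_barrier=p.exchange_barrier,
        provenance={
            "model": "complex_i",
            "constants_mode": spec.mode,
            "parameters": {
                k: getattr(p, k) for k in (
                    "donor_em_mv", "acceptor_em_mv", "n_electrons", "ph_n",
                    "ph_p", "uptake_pka", "release_pka", "q_motion_fraction",
                    "relay_step_dg", "buried_fraction",
                )
            },
            "dg_redox_kcal_mol": dg_redox,
        },
    )


def build_single_site_model(
    pKa: float,
    pH_N: float = 7.0,
    pH_P: float = 7.0,
    step_time: float = 1e-6,
    buried_fraction: float = 0.5,
    spec: EnergySpec = EXACT,
) -> PumpModel:
    """Three-state model of proton transfer across the membrane through a
    single buried site: N-side → bound (at ``buried_fraction`` depth) →
    P-side.  Barriers from the assumed uptake/release ``step_time``."""
    if step_time <= 0:
        raise ValueError("step_time must be positive (seconds)")
    barrier = tst_barrier(1.0 / step_time, spec=spec)
    bound = proton_transfer_dg(pH_N, pKa, spec)
    end = bound + proton_release_dg(pH_P, pKa, spec)
    states = (
        PumpState("N-side", 0.0, ()),
        PumpState("bound", bound, (ChargeMove(1.0, buried_fraction),)),
        PumpState("P-side", end,
                  (ChargeMove(1.0, buried_fraction),
                   ChargeMove(1.0, 1.0 - buried_fraction))),
    )
    transitions = (
        Transition("N-side", "bound", max(barrier, bound, 0.0),
                   "uptake from the N-side onto the buried site"),
        Transition("bound", "P-side", max(barrier, end - bound, 0.0),
                   "release from the buried site to the P-side"),
    )
    return PumpModel(
        states=states,
        transitions=transitions,
        spec=spec,
        provenance={
            "model": "single_site",
            "constants_mode": spec.mode,
            "parameters": {
                "pKa": pKa, "pH_N": pH_N, "pH_P": pH_P,
                "step_time_s": step_time, "buried_fraction": buried_fraction,
            },
        },
    )


def apply_pmf(
    model: PumpModel,
    pmf_mv: float,
    ts_position: float = 0.5,
) -> FreeEnergyProfile:
    """Free-energy profile of ``model`` at a proton motive force.

    Every state is shifted by the pmf cost of its cumulative charge
    moves (q·F·pmf·fraction per move).  Known barriers are shifted by
    ``ts_position`` times the step's shift difference — the transition
    state is assumed to sit partway (default midway) along the
    charge-transfer coordinate of its own step.  ``pmf_mv`` may be
    negative (reverse gradient).  At pmf = 0 the profile reproduces the
    model's dG0 ladder exactly.
    """
    if not 0.0 <= ts_position <= 1.0:
        raise ValueError("ts_position must be in [0, 1]")
    shifts = [
        sum(pmf_shift(m, pmf_mv, model.spec) for m in s.moves)
        for s in model.states
    ]
    dG = tuple(s.dG0 + sh for s, sh in zip(model.states, shifts))
    barriers: list[float | None] = []
    for i, t in enumerate(model.transitions):
        if t.barrier is None:
            barriers.append(None)
        else:
            shifted = t.barrier + ts_position * (shifts[i + 1] - shifts[i])
            step = dG[i + 1] - dG[i]
            barriers.append(max(shifted, step, 0.0))
    barriers.append(None)  # last state: no in-profile outgoing step
    return FreeEnergyProfile(
        labels=model.labels,
        dG=dG,
        barriers_out=tuple(barriers),
        pmf_mv=pmf_mv,
        spec=model.spec,
        provenance={**model.provenance, "ts_position": ts_position},
    )


def single_site_pump_profile(
    pKa: float,
    pH_N: float = 7.0,
    pH_P: float = 7.0,
    step_time: float = 1e-6,
    pmf_mv: float = 0.0,
    spec: EnergySpec = EXACT,
) -> FreeEnergyProfile:
    """Profile of the single-buried-site membrane proton transfer (see
    :func:`build_single_site_model`) at the given pmf."""
    return apply_pmf(
        build_single_site_model(pKa, pH_N, pH_P, step_time, spec=spec), pmf_mv
    )
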