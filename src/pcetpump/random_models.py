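"""Seeded generation of synthetic closed-cycle pump models.

These models are synthetic test articles: structurally they mimic a
redox-driven proton pump (a power stroke, then per-subunit uptake /
relay / release steps with partial charge translocations), but their
step energies and barriers are drawn from user-specified distributions
and then renormalized so that the ladder closes exactly onto the redox
boundary condition −n·F·ΔE.  They exist to exercise the profile,
pmf-shift and kinetics machinery across a wide family of
thermodynamically consistent cycles, not to represent any particular
enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import EnergySpec, get_spec
from .thermo import dg_from_redox, proton_transfer_dg

__all__ = ["RandomPumpSpec", "generate_random_pump"]


@dataclass(frozen=True)
class RandomPumpSpec:
    """Recipe for one synthetic pump model (reproducible per seed).

    ``n_subunits`` proton-relay subunits each contribute an uptake step
    (pK_a drawn from N(pka_mean, pka_sd)), a lateral relay step (ΔG from
    N(step_dg_mean, step_dg_sd)) and a release step; barriers are drawn
    uniformly from [barrier_low, barrier_high].  ``redox_delta_e_mv`` /
    ``n_electrons`` set the cycle's boundary condition.
    """

    n_subunits: int = 3
    pka_mean: float = 9.0
    pka_sd: float = 0.5
    step_dg_mean: float = -1.0
    step_dg_sd: float = 0.5
    barrier_low: float = 8.0
    barrier_high: float = 10.0
    seed: int = 0
    redox_delta_e_mv: float = 410.0
    n_electrons: int = 2
    ph: float = 7.0
    constants_mode: str = "exact"

    def validate(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("need at least one relay subunit")
        if self.pka_sd < 0 or self.step_dg_sd < 0:
            raise ValueError("distribution widths must be non-negative")
        if not self.barrier_low <= self.barrier_high:
            raise ValueError("barrier band must satisfy low <= high")


def generate_random_pump(spec: RandomPumpSpec) -> dict:
    """Draw one synthetic pump model; returns a ``custom``-kind model
    config mapping (see :func:`pcetpump.config.build_model`).

    Step energies are drawn, then shifted by a common constant so the
    full ladder sums exactly to −n·F·ΔE (cycle closure by
    construction).  Raises if the barrier band cannot accommodate the
    renormalized uphill steps.
    """
    spec.validate()
    espec: EnergySpec = get_spec(spec.constants_mode)
    rng = np.random.default_rng(spec.seed)
    dg_total = dg_from_redox(spec.redox_delta_e_mv, spec.n_electrons, espec)

    steps: list[tuple[str, float, float]] = []  # (label, dG, fraction move)
    steps.append(("loaded", float(rng.normal(0.4, 0.1)) * dg_total, 0.0))
    for s in range(1, spec.n_subunits + 1):
        pka_up = float(rng.normal(spec.pka_mean, spec.pka_sd))
        pka_rel = float(rng.normal(spec.pka_mean, spec.pka_sd))
        steps.append(
            (f"S{s}-up", proton_transfer_dg(spec.ph, pka_up, espec), 0.5)
        )
        steps.append(
            (f"S{s}-relay",
             float(rng.normal(spec.step_dg_mean, spec.step_dg_sd)), 0.0)
        )
        steps.append(
            (f"S{s}-rel", -proton_transfer_dg(spec.ph, pka_rel, espec), 0.5)
        )
    steps.append(("end", float(rng.normal(-1.0, 0.5)), 0.0))

    drawn = np.array([dg for _, dg, _ in steps])
    shift = (dg_total - drawn.sum()) / len(drawn)
    dgs = drawn + shift

    worst = float(np.max(np.maximum(dgs, 0.0)))
    if spec.barrier_high < worst:
        raise ValueError(
            f"infeasible spec: barrier band upper bound {spec.barrier_high} "
            f"kcal/mol below the largest uphill step ({worst:.3g})"
        )

    states = [{"label": "start", "dg0": 0.0, "moves": []}]
    transitions = []
    cum = 0.0
    moves: list[list[float]] = []
    for (label, _, frac), dg in zip(steps, dgs):
        low = max(spec.barrier_low, float(dg), 0.0)
        barrier = float(rng.uniform(low, spec.barrier_high))
        cum += float(dg)
        if frac > 0:
            moves = moves + [[1.0, frac]]
        states.append({"label": label, "dg0": cum, "moves": list(moves)})
        transitions.append(
            {"source": states[-2]["label"], "target": label,
             "barrier": barrier, "mechanism": "synthetic"}
        )

    return {
        "schema_version": 1,
        "name": f"random_pump_seed{spec.seed}",
        "kind": "custom",
        "constants_mode": spec.constants_mode,
        "states": states,
        "transitions": transitions,
        "unknown_barrier_ceiling": spec.barrier_high,
        "exchange_barrier": spec.barrier_high,
    }
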