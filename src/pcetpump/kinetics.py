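"""Cycle kinetics: from a free-energy profile to steady-state turnover.

A :class:`~pcetpump.profile.FreeEnergyProfile` is converted into a
single-cycle kinetic model by transition-state theory: the forward rate
out of state i is κ·(k_B·T/h)·exp(−ΔG‡/RT) and the backward rate uses
the same transition state seen from the product side (barrier − ΔG_step),
so detailed balance k_f/k_b = exp(−ΔG_step/RT) holds edge by edge by
construction.  The linear ladder is closed into a ring by a
substrate-exchange edge (last state → first state) that is treated as
isoenergetic: the thermodynamic driving force of the whole cycle is then
exactly the free energy of the end state, and the product of forward-to-
backward rate ratios around the ring telescopes to exp(−ΔG_cycle/RT).

Steady-state cycle flux is obtained by an exact linear solve of the
master equation on the ring; a seeded Gillespie simulator provides an
independent stochastic estimate of the mean cycle time for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import EXACT, EnergySpec
from .profile import FreeEnergyProfile
from .pump import PumpModel, apply_pmf
from .thermo import tst_rate

__all__ = [
    "KineticModel",
    "rates_from_profile",
    "steady_state_flux",
    "cycle_dg",
    "stall_pmf",
    "gillespie_cycle_times",
]


@dataclass(frozen=True)
class KineticModel:
    """Forward/backward rate constants on a ring of states.

    Edge i connects state i to state (i+1) mod n; ``k_fwd[i]`` and
    ``k_back[i]`` are its two directions in s⁻¹.
    """

    labels: tuple[str, ...]
    k_fwd: np.ndarray
    k_back: np.ndarray
    pmf_mv: float = 0.0
    spec: EnergySpec = EXACT

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.k_fwd) != n or len(self.k_back) != n:
            raise ValueError("one forward and one backward rate per ring edge")
        if np.any(self.k_fwd <= 0) or np.any(self.k_back <= 0):
            raise ValueError("all rates must be positive (connected ring)")

    def scaled(self, c: float) -> "KineticModel":
        """All rates multiplied by a transmission factor ``c`` (κ
        scaling; leaves every equilibrium constant unchanged)."""
        return KineticModel(self.labels, self.k_fwd * c, self.k_back * c,
                            self.pmf_mv, self.spec)


def rates_from_profile(
    profile: FreeEnergyProfile,
    kappa: float = 1.0,
    unknown_barrier: float = 14.0,
    exchange_barrier: float = 14.0,
) -> KineticModel:
    """TST rate constants for every edge of the cycle.

    Unknown (``None``) barriers take ``unknown_barrier``; the ring-closing
    substrate-exchange edge is isoenergetic with ``exchange_barrier``.
    Raises if any known barrier lies below max(0, ΔG_step).
    """
    spec = profile.spec
    n = len(profile)
    kf = np.empty(n)
    kb = np.empty(n)
    for i in range(n - 1):
        step = profile.step_dg(i)
        barrier = profile.barriers_out[i]
        if barrier is None:
            barrier = max(unknown_barrier, step, 0.0)
        if barrier < max(0.0, step) - 1e-9:
            raise ValueError(
                f"{profile.labels[i]} -> {profile.labels[i + 1]}: barrier "
                f"{barrier:.3g} kcal/mol below step dG {step:.3g}"
            )
        kf[i] = tst_rate(barrier, kappa, spec)
        kb[i] = tst_rate(barrier - step, kappa, spec)
    kf[n - 1] = kb[n - 1] = tst_rate(exchange_barrier, kappa, spec)
    return KineticModel(profile.labels, kf, kb, profile.pmf_mv, spec)


def cycle_dg(model: KineticModel) -> float:
    """Cycle free energy (kcal/mol) implied by the rates:
    −RT·Σ ln(k_f/k_b); negative drives forward turnover."""
    return -model.spec.RT * float(
        np.sum(np.log(model.k_fwd) - np.log(model.k_back))
    )


def steady_state_flux(model: KineticModel) -> float:
    """Net steady-state cycle flux (cycles/s, signed; positive =
    forward).

    Uses the exact closed-form steady state of the unicyclic master
    equation (Derrida's solution): the only cancellation is the factor
    1 − exp(ΔG_cycle/RT), so the flux is numerically clean arbitrarily
    close to stall, where a dense linear solve drowns in rounding (state
    populations span many orders of magnitude).  Agrees with the dense
    solve (:func:`_steady_state_flux_dense`) wherever the latter is
    well-conditioned.
    """
    n = len(model.labels)
    log_u = np.log(model.k_fwd)                      # rate i -> i+1
    log_w = np.log(np.roll(model.k_back, 1))         # rate i -> i-1
    # Gamma = prod_i (w_i / u_i) = exp(+dG_cycle / RT)
    log_ratio_edges = np.log(model.k_back) - np.log(model.k_fwd)
    gamma = math.exp(float(np.sum(log_ratio_edges)))
    denom = 0.0
    for s in range(n):
        # r_s = (1/u_s) * (1 + sum_{k=1}^{n-1} prod_{i=1}^{k} w_{s+i}/u_{s+i})
        idx = [(s + i) % n for i in range(1, n)]
        logs = np.cumsum(log_w[idx] - log_u[idx])
        r = (1.0 + float(np.sum(np.exp(logs)))) / model.k_fwd[s]
        denom += r
    return (1.0 - gamma) / denom


def _steady_state_flux_dense(model: KineticModel) -> float:
    """Dense linear-algebra solve of the ring master equation; used as an
    independent numerical cross-check of :func:`steady_state_flux` away
    from stall."""
    n = len(model.labels)
    scale = float(max(model.k_fwd.max(), model.k_back.max()))
    kf = model.k_fwd / scale
    kb = model.k_back / scale
    G = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        G[i, i] -= kf[i]
        G[j, i] += kf[i]
        G[j, j] -= kb[i]
        G[i, j] += kb[i]
    A = np.vstack([G[:-1, :], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        p = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular master equation (disconnected ring?)") from exc
    return float((p[n - 1] * kf[n - 1] - p[0] * kb[n - 1]) * scale)


def stall_pmf(model: PumpModel) -> float:
    """The pmf (mV) at which the cycle free energy vanishes and net
    turnover stalls.

    The end-state energy is linear in pmf, dG(end, pmf) = dG0(end) +
    q·F·pmf, with q the total translocated charge, so the stall point is
    the closed form −dG0(end)·1000/(q·F).
    """
    q = model.total_translocated_charge
    if q == 0:
        raise ValueError("no charge is translocated: the cycle cannot stall")
    return -model.states[-1].dG0 * 1000.0 / (q * model.spec.faraday_kcal)


def pmf_flux_curve(
    model: PumpModel,
    pmf_values: np.ndarray | list[float],
    kappa: float = 1.0,
) -> np.ndarray:
    """Steady-state flux (cycles/s) at each pmf in ``pmf_values``."""
    out = []
    for pmf in pmf_values:
        prof = apply_pmf(model, float(pmf))
        km = rates_from_profile(
            prof,
            kappa=kappa,
            unknown_barrier=model.unknown_barrier_ceiling,
            exchange_barrier=model.exchange_barrier,
        )
        out.append(steady_state_flux(km))
    return np.asarray(out)


def gillespie_cycle_times(
    model: KineticModel,
    n_cycles: int = 100,
    seed: int = 0,
    max_steps: int = 50_000_000,
) -> np.ndarray:
    """Durations of successive net forward cycles from a stochastic
    (Gillespie) trajectory on the ring.

    A cycle completes each time the net winding number reaches a new
    maximum; the returned durations are renewal intervals whose mean
    estimates 1/flux.  Deterministic for a given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = len(model.labels)
    kf = model.k_fwd
    kb = model.k_back
    state = 0
    t = 0.0
    winding = 0
    best = 0
    t_last = 0.0
    times: list[float] = []
    steps = 0
    while len(times) < n_cycles:
        if steps >= max_steps:
            raise RuntimeError(
                f"Gillespie exceeded {max_steps} steps with only "
                f"{len(times)}/{n_cycles} cycles; rates too disparate"
            )
        steps += 1
        back_edge = (state - 1) % n
        a_f = kf[state]
        a_b = kb[back_edge]
        total = a_f + a_b
        t += rng.exponential(1.0 / total)
        if rng.random() * total < a_f:
            if state == n - 1:
                winding += 1
            state = (state + 1) % n
        else:
            if state == 0:
                winding -= 1
            state = (state - 1) % n
        if winding > best:
            best = winding
            times.append(t - t_last)
            t_last = t
    return np.asarray(times)
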