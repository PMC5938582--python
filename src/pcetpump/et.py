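"""Electron-tunneling rates and a linear-wire hopping solver.

Biological electron transfer over 4–14 Å proceeds by non-adiabatic
tunneling.  Two standard rate expressions are implemented:

* the Marcus golden-rule rate, parameterized by the electronic coupling
  |H_ab|, the reorganization energy λ and the driving force ΔG;
* the empirical tunneling "ruler" of Page, Moser, Chen & Dutton, which
  replaces |H_ab| with the edge-to-edge distance r and the protein
  packing density ρ:

      log10 k = 13 − (1.2 − 0.8·ρ)·(r − 3.6) − 3.1·(ΔG + λ)²/λ

  (r in Å, ΔG and λ in eV; the exergonic form as published).

On a multi-center wire (e.g. the FMN → N3 → … → N2 iron–sulfur chain of
complex I) single electrons hop between neighbours.  Per-step forward and
backward rates are derived from the ruler with ΔG from midpoint-potential
differences; the uphill direction of each step is always obtained from
the downhill ruler rate via detailed balance, k_uphill = k_downhill ·
exp(−|ΔG|/RT), since the quadratic Franck–Condon term alone does not
satisfy microscopic reversibility.  The mean first-passage time of one
electron from the first to the last (absorbing) center then follows from
the birth–death master equation solved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import EXACT, EnergySpec

__all__ = [
    "ETCenter",
    "ETChain",
    "marcus_rate",
    "moser_dutton_log_rate",
    "chain_step_rates",
    "chain_passage_time",
    "read_chain",
]

#: ħ in eV·s.
HBAR_EV_S = 6.582119569e-16


def marcus_rate(
    Hab_ev: float,
    lambda_ev: float,
    dG_ev: float,
    spec: EnergySpec = EXACT,
) -> float:
    """Non-adiabatic (golden rule) electron-transfer rate, s⁻¹.

    k = (2π/ħ)·|H_ab|²·(4πλRT)^(−1/2)·exp(−(ΔG + λ)²/(4λRT)),
    everything in eV.  Maximal and activationless at ΔG = −λ.
    """
    if lambda_ev <= 0:
        raise ValueError(f"reorganization energy must be positive, got {lambda_ev}")
    rt = spec.RT_ev
    fc = math.exp(-((dG_ev + lambda_ev) ** 2) / (4.0 * lambda_ev * rt))
    return (2.0 * math.pi / HBAR_EV_S) * Hab_ev**2 * fc / math.sqrt(
        4.0 * math.pi * lambda_ev * rt
    )


def moser_dutton_log_rate(
    r: float, rho: float, dG_ev: float, lambda_ev: float
) -> float:
    """log10 of the empirical tunneling rate (rate in s⁻¹).

    Parameters: edge-to-edge distance ``r`` (Å), packing density ``rho``
    (dimensionless, ~0.76 in many proteins), driving force and
    reorganization energy in eV.  The single quadratic (exergonic) form
    is evaluated as printed; uphill steps of a wire are handled by
    detailed balance in :func:`chain_step_rates`, not here.
    """
    if r <= 0:
        raise ValueError(f"distance must be positive, got {r}")
    if not 0.0 < rho < 1.0:
        raise ValueError(f"packing density must be in (0, 1), got {rho}")
    if lambda_ev <= 0:
        raise ValueError(f"reorganization energy must be positive, got {lambda_ev}")
    return (
        13.0
        - (1.2 - 0.8 * rho) * (r - 3.6)
        - 3.1 * (dG_ev + lambda_ev) ** 2 / lambda_ev
    )


@dataclass(frozen=True)
class ETCenter:
    """A redox center on (or off) the wire.

    ``Em_mv`` is the midpoint potential vs NHE in mV; ``lambda_ev`` the
    reorganization energy; ``on_path`` marks whether the center carries
    wire current (off-path centers, e.g. the ~22 Å distant N7 cluster of
    complex I, are kept for bookkeeping but excluded from the wire).
    """

    label: str
    Em_mv: float
    lambda_ev: float = 0.7
    on_path: bool = True
    position_note: str = ""

    def __post_init__(self) -> None:
        if self.lambda_ev <= 0:
            raise ValueError(f"{self.label}: reorganization energy must be > 0")


@dataclass(frozen=True)
class ETChain:
    """An ordered wire of redox centers with pairwise edge-to-edge gaps.

    ``distances`` has one entry per step (len(centers) − 1), in Å.
    Off-path centers passed to :meth:`from_centers` are dropped before
    the wire is assembled.
    """

    centers: tuple[ETCenter, ...]
    distances: tuple[float, ...]
    rho: float = 0.76

    def __post_init__(self) -> None:
        if len(self.centers) < 2:
            raise ValueError("a chain needs at least 2 centers")
        if len(self.distances) != len(self.centers) - 1:
            raise ValueError(
                f"need {len(self.centers) - 1} distances for "
                f"{len(self.centers)} centers, got {len(self.distances)}"
            )
        if any(r <= 0 for r in self.distances):
            raise ValueError("all edge-to-edge distances must be positive")
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"packing density must be in (0, 1), got {self.rho}")
        if any(not c.on_path for c in self.centers):
            raise ValueError("off-path centers cannot be part of the wire")

    @classmethod
    def from_centers(
        cls,
        centers: Sequence[ETCenter],
        distances: Sequence[float],
        rho: float = 0.76,
    ) -> "ETChain":
        """Build a wire, silently dropping off-path centers.

        ``distances[i]`` is the gap from on-path center i to on-path
        center i+1 (off-path rows carry no wire distance).
        """
        on = [c for c in centers if c.on_path]
        return cls(tuple(on), tuple(float(d) for d in distances), rho)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.centers]


def chain_step_rates(
    chain: ETChain, spec: EnergySpec = EXACT
) -> pd.DataFrame:
    """Forward/backward tunneling rates for every step of the wire.

    ΔG of step i (in eV) is −(Em[i+1] − Em[i])/1000: hopping towards a
    higher midpoint potential is downhill.  λ of a step is the mean of
    the two centers' reorganization energies.  The downhill direction is
    rated with the ruler; the uphill direction follows from detailed
    balance so that k_f/k_b = exp(−ΔG/RT) holds exactly.

    Returns a DataFrame with columns donor, acceptor, r_A, dG_ev,
    log10_k_fwd, k_fwd, k_back.
    """
    rows = []
    rt = spec.RT_ev
    for i, r in enumerate(chain.distances):
        a, b = chain.centers[i], chain.centers[i + 1]
        dg = -(b.Em_mv - a.Em_mv) / 1000.0
        lam = 0.5 * (a.lambda_ev + b.lambda_ev)
        if dg <= 0:
            kf = 10.0 ** moser_dutton_log_rate(r, chain.rho, dg, lam)
            kb = kf * math.exp(dg / rt)
        else:
            kb = 10.0 ** moser_dutton_log_rate(r, chain.rho, -dg, lam)
            kf = kb * math.exp(-dg / rt)
        rows.append(
            {
                "donor": a.label,
                "acceptor": b.label,
                "r_A": r,
                "dG_ev": dg,
                "log10_k_fwd": math.log10(kf),
                "k_fwd": kf,
                "k_back": kb,
            }
        )
    return pd.DataFrame(rows)


def chain_passage_time(chain: ETChain, spec: EnergySpec = EXACT) -> float:
    """Mean first-passage time (s) of one electron from the first to the
    last center of the wire, the last center absorbing.

    Solves the birth–death mean-first-passage equations
    a_i·(T_{i+1} − T_i) + b_i·(T_{i−1} − T_i) = −1 exactly (reflecting
    first center, absorbing last).
    """
    rates = chain_step_rates(chain, spec)
    a = rates["k_fwd"].to_numpy()
    b = rates["k_back"].to_numpy()
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise ValueError("chain is disconnected: non-positive forward rate")
    n = len(a)  # transient states 0..n-1, absorbing state n
    # scale to O(1) for conditioning; MFPT scales inversely with rates
    scale = a.max()
    a_s, b_s = a / scale, b / scale
    M = np.zeros((n, n))
    rhs = -np.ones(n)
    for i in range(n):
        M[i, i] -= a_s[i]
        if i + 1 < n:
            M[i, i + 1] += a_s[i]
        if i > 0:
            M[i, i] -= b_s[i - 1]
            M[i, i - 1] += b_s[i - 1]
    T = np.linalg.solve(M, rhs)
    return float(T[0] / scale)


def read_chain(path: str | Path, rho: float = 0.76) -> ETChain:
    """Read a wire from a TSV table.

    Expected columns: ``label``, ``Em_mV``, ``r_to_next_A``,
    ``lambda_eV``; optional ``on_path`` (true/false, default true) and
    ``note``.  ``r_to_next_A`` of the last on-path row is ignored (may
    be blank).  Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "Em_mV", "r_to_next_A", "lambda_eV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chain table missing columns: {sorted(missing)}")
    if "on_path" in df.columns:
        flags = df["on_path"].astype(str).str.strip().str.lower()
        df = df[flags.isin({"true", "1", "yes"})]
    centers = []
    for row in df.itertuples(index=False):
        note = getattr(row, "note", "")
        centers.append(
            ETCenter(
                label=str(row.label),
                Em_mv=float(row.Em_mV),
                lambda_ev=float(row.lambda_eV),
                position_note="" if pd.isna(note) else str(note),
            )
        )
    distances = [float(x) for x in df["r_to_next_A"].to_numpy()[:-1]]
    return ETChain.from_centers(centers, distances, rho=rho)
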