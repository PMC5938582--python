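"""Free-energy profiles: the ordered (state, ΔG, outgoing barrier) ladder.

A :class:`FreeEnergyProfile` is the central artifact of the package: the
cumulative free energy of every state of a pumping cycle at one value of
the proton motive force, together with the forward barrier out of each
state.  Barriers that cannot be assigned from available data are carried
as ``None`` (serialized as an explicit ``null``, never as 0) and only
replaced by a configurable ceiling when rates are needed.

Profiles round-trip losslessly through TSV and JSON; every written table
carries a provenance comment block (constants mode, model hash,
parameter values).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterator

import pandas as pd

from .constants import EXACT, EnergySpec

__all__ = ["FreeEnergyProfile", "write_profile", "read_profile"]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Ordered free-energy ladder of a pumping cycle at a fixed pmf.

    ``barriers_out[i]`` is the forward barrier out of state i in
    kcal/mol relative to that state, or ``None`` when unknown; the last
    state has no in-profile outgoing transition (``None``).
    """

    labels: tuple[str, ...]
    dG: tuple[float, ...]
    barriers_out: tuple[float | None, ...]
    pmf_mv: float
    spec: EnergySpec = EXACT
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise ValueError("a profile needs at least two states")
        if len(self.dG) != n or len(self.barriers_out) != n:
            raise ValueError("labels, dG and barriers_out must have equal length")
        if len(set(self.labels)) != n:
            raise ValueError("state labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> float:
        """ΔG (kcal/mol) of the state named ``label``."""
        try:
            return self.dG[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no state labelled {label!r}") from None

    def __iter__(self) -> Iterator[tuple[str, float, float | None]]:
        return iter(zip(self.labels, self.dG, self.barriers_out))

    def step_dg(self, i: int) -> float:
        """ΔG of the forward step out of state i."""
        return self.dG[i + 1] - self.dG[i]

    def rounded(self) -> "FreeEnergyProfile":
        """Rendering with state energies rounded to integer kcal/mol.

        Reproduces the way qualitative published ladders are printed;
        use the unrounded profile for any computation.
        """
        return replace(self, dG=tuple(float(round(g)) for g in self.dG))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.labels,
                "dG_kcal_mol": self.dG,
                "barrier_kcal_mol": [
                    b if b is not None else None for b in self.barriers_out
                ],
                "pmf_mV": self.pmf_mv,
            }
        )

    # -- serialization ----------------------------------------------------

    def write(self, destination: str | Path) -> None:
        write_profile(self, destination)

    def isclose(self, other: "FreeEnergyProfile", tol: float = 1e-12) -> bool:
        if self.labels != other.labels:
            return False
        if abs(self.pmf_mv - other.pmf_mv) > tol:
            return False
        for a, b in zip(self.dG, other.dG):
            if abs(a - b) > tol:
                return False
        for a, b in zip(self.barriers_out, other.barriers_out):
            if (a is None) != (b is None):
                return False
            if a is not None and abs(a - b) > tol:
                return False
        return True


def _fmt(x: float | None) -> str:
    return "null" if x is None else _FLOAT_FMT % x


def write_profile(profile: FreeEnergyProfile, destination: str | Path) -> None:
    """Write a profile as TSV (default) or JSON (``.json`` suffix).

    Both formats embed the constant set and provenance map and
    round-trip through :func:`read_profile` to better than 1e-12.
    Unknown barriers are written as explicit ``null``.
    """
    dest = Path(destination)
    if dest.suffix == ".json":
        payload = {
            "format": "pcetpump-profile/1",
            "constants": json.loads(profile.spec.to_json()),
            "provenance": profile.provenance,
            "pmf_mV": profile.pmf_mv,
            "states": [
                {"state": s, "dG_kcal_mol": g, "barrier_kcal_mol": b}
                for s, g, b in profile
            ],
        }
        dest.write_text(json.dumps(payload, indent=1) + "\n")
        return
    lines = ["# pcetpump-profile/1"]
    lines.append("# constants: " + profile.spec.to_json())
    lines.append("# provenance: " + json.dumps(profile.provenance, sort_keys=True))
    lines.append("# pmf_mV: " + (_FLOAT_FMT % profile.pmf_mv))
    lines.append("state\tdG_kcal_mol\tbarrier_kcal_mol\tpmf_mV")
    for s, g, b in profile:
        lines.append(f"{s}\t{_fmt(g)}\t{_fmt(b)}\t{_fmt(profile.pmf_mv)}")
    dest.write_text("\n".join(lines) + "\n")


def read_profile(source: str | Path) -> FreeEnergyProfile:
    """Read a profile written by :func:`write_profile` (TSV or JSON)."""
    src = Path(source)
    if src.suffix == ".json":
        payload = json.loads(src.read_text())
        spec = EnergySpec(**payload["constants"])
        states = payload["states"]
        return FreeEnergyProfile(
            labels=tuple(s["state"] for s in states),
            dG=tuple(float(s["dG_kcal_mol"]) for s in states),
            barriers_out=tuple(
                None if s["barrier_kcal_mol"] is None else float(s["barrier_kcal_mol"])
                for s in states
            ),
            pmf_mv=float(payload["pmf_mV"]),
            spec=spec,
            provenance=payload.get("provenance", {}),
        )
    spec = EXACT
    provenance: dict[str, Any] = {}
    pmf = 0.0
    labels: list[str] = []
    dgs: list[float] = []
    barriers: list[float | None] = []
    header_seen = False
    for line in src.read_text().splitlines():
        if line.startswith("# constants: "):
            spec = EnergySpec(**json.loads(line[len("# constants: "):]))
        elif line.startswith("# provenance: "):
            provenance = json.loads(line[len("# provenance: "):])
        elif line.startswith("# pmf_mV: "):
            pmf = float(line[len("# pmf_mV: "):])
        elif line.startswith("#") or not line.strip():
            continue
        elif not header_seen:
            header_seen = True  # column header row
        else:
            state, g, b, _ = line.split("\t")
            labels.append(state)
            dgs.append(float(g))
            barriers.append(None if b == "null" else float(b))
    return FreeEnergyProfile(
        labels=tuple(labels),
        dG=tuple(dgs),
        barriers_out=tuple(barriers),
        pmf_mv=pmf,
        spec=spec,
        provenance=provenance,
    )
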