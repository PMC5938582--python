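# Methods

## Scope and units

`pcetpump` models the thermodynamics and desk-scale kinetics of
redox-driven proton pumps, parameterized for the long-range PCET cycle
of respiratory complex I. Everything is analytic or exactly solvable:
no structures, trajectories or fitted parameters enter. The internal
unit system is the one in which bioenergetic numbers are printed:
kcal/mol for energies, mV for potentials and pmf, Å for distances, s⁻¹
for rates, eV for electron-transfer quantities (converted at
23.060548 kcal·mol⁻¹·eV⁻¹, numerically the Faraday constant per volt).
All converters live in `EnergySpec`.

## Constant sets

Two selectable constant sets (`constants.EXACT`, `constants.ROUNDED`):

| quantity | exact (310 K) | rounded |
|---|---|---|
| RT | 0.61603 kcal/mol | 0.61 |
| 2.303·RT | 1.41847 kcal/mol | 1.42 |
| F | 23.0605 kcal·mol⁻¹·V⁻¹ | 23.06 |
| k_BT/h | 6.459×10¹² s⁻¹ | 6.4×10¹² |

The rounded set exists because the field's qualitative ladders are
printed with these rounded factors; pinning them makes such arithmetic
reproducible digit for digit (note the deliberate inconsistency carried
by the convention itself: 1.42 ≠ 2.303 × 0.61). Energy-valued
operations agree between the sets to well under 5%; exponentiated TST
rates inherit the RT difference amplified by ΔG‡/RT ≈ 20 e-folds, so
cross-set comparisons of rates are only meaningful on the log scale.
`dg_from_equilibrium` is evaluated as −(2.303·RT)·log₁₀K so both sets
use their printed per-decade factor; in exact mode this is identical to
−RT·ln K.

## Closed-form relations

Signs: negative ΔG is exergonic; moving positive charge N→P against a
positive pmf costs energy (`ChargeMove` encodes charge and the membrane
fraction z/L crossed, assuming a linear potential drop and uniform
dielectric). κ (transmission coefficient) defaults to 1 and is accepted
as a user multiplier — diffusive (Kramers-type) corrections are not
computed. The Coulomb constant is fixed at 332.06 kcal·Å·mol⁻¹·e⁻²; no
ionic-strength or activity corrections are applied anywhere.

A TST aside: with the 310 K prefactor, a 1 s⁻¹ process corresponds to
ΔG‡ ≈ 18.2 kcal/mol, slightly below the ≈ 20 kcal/mol sometimes quoted
for "seconds timescale"; the package consistently uses the computed
value.

## Electron tunneling and the wire solver

`marcus_rate` is the non-adiabatic golden-rule expression evaluated in
eV. `moser_dutton_log_rate` is the empirical ruler
log₁₀k = 13 − (1.2 − 0.8ρ)(r − 3.6) − 3.1(ΔG + λ)²/λ (r in Å, energies
in eV), the single exergonic quadratic form, with defaults λ = 0.7 eV
and ρ = 0.76. Because that quadratic alone does not satisfy microscopic
reversibility, wire steps always rate the downhill direction with the
ruler and obtain the uphill direction from detailed balance,
k_up = k_down·e^(−|ΔG|/RT) — the standard uphill prescription.

The wire is strictly single-occupancy and linear; electron–electron
interaction and the two-electron bookkeeping of the flavin site are out
of scope. Off-path centers (the ~22 Å distant N7) are carried in the
input table but excluded from the wire. The mean first-passage time
from the first to the (absorbing) last center solves the birth–death
MFPT equations exactly with one dense solve, after scaling rates to
O(1) for conditioning.

The packaged wire table (`data/fes_wire_complex_i.tsv`) is a synthetic
representative geometry: per-pair edge-to-edge distances are not
tabulated in the sources the parameters come from, so the file places
seven steps inside the structurally observed 9–14 Å range with the
N5→N6a bottleneck at 14 Å, all centers at −320 mV except N2 at
−160 mV. The resulting passage time (~1×10⁻⁴ s) is therefore checked
against a decade band (10⁻⁵–10⁻³ s), not a point value.

## The 17-state pumping cycle

`build_complex_i_model` assembles states I → IIa/b/c → IIIa/b → IVa/b →
Va/b → VIa/b → VIIa/b → VIIIa/b → IX from the parameters in
`ComplexIParams` (all configurable; defaults in parentheses):

- donor/acceptor Em (−320 / +90 mV; −80 mV for the menaquinone
  variant), n = 2: fixes the boundary condition dG0(IX) = −nFΔE;
- I → IIa quinone reduction isoenergetic, barrier 13 kcal/mol (the
  ~100 µs electron-transfer step via TST);
- IIa → IIb uptake from the N-side onto the pK_a-10 NuoH cluster:
  2.303RT(pH_N − 10) ≈ −4.3 kcal/mol;
- IIb → IIc quinol motion releasing `q_motion_fraction` (0.6) of the
  redox drop, barrier 4;
- three relay steps at `relay_step_dg` (−1) with barrier 10,
  alternating with isoenergetic Lys/Glu ion-pair openings (barrier 4);
- the backwave Va → VIIIb: P-side releases at
  −2.303RT(pH_P − 9) ≈ +2.8 alternating with N-side re-uptakes ≈ −2.8,
  release order NuoL, M, N, H; all barriers at the hydration-limited
  default 10 kcal/mol (the upper end of the 8–10 band, i.e. the ~1 µs
  end of the 100 ns–1 µs range);
- VIIIb → IX (quinol exchange / Q-site re-protonation) carries an
  explicit *unknown* barrier, defaulted to a 14 kcal/mol ceiling (the
  millisecond-turnover bound) only when rates are needed, and whatever
  step energy closes the ladder onto −nFΔE. If a final-step energy is
  supplied explicitly and misses closure by > 0.5 kcal/mol, a
  `ClosureError` is raised.

Charge bookkeeping: buried proton sites sit at `buried_fraction` (0.5)
of the membrane depth, so each uptake contributes +0.5 of a
translocation and each P-side release the remaining +0.5; lateral
relays carry no membrane-normal charge. One cycle translocates 4.0
charges, matching the two printed 200 mV costs (+2.3 per buried proton,
+4.6 per completed translocation). The E-channel/NuoH proton is counted
as the fourth pumped proton, released at VIIIb; lower-stoichiometry
variants are user edits, not defaults.

`apply_pmf` shifts each state by Σ q·F·pmf·(z/L) over its cumulative
moves. Known barriers shift by `ts_position` (default 0.5, the
transition state midway along its step's charge-transfer coordinate)
times the step's shift difference, clamped to stay ≥ max(0, ΔG_step);
at pmf = 0 the profile reproduces dG0 exactly. The
`FreeEnergyProfile.rounded()` rendering rounds state energies to
integer kcal/mol, reproducing the conventional printed ladder
(0, −4, −16, −17, −18, −19, …, −19); computations always use the
unrounded values. A recomputed aside: at 200 mV the four pumped protons
store 4·F·0.2 = 18.45 of the 18.91 kcal/mol redox drop, an efficiency
of ≈ 97.5% — a couple of points above the commonly quoted ≈ 95%.

Profiles serialize to TSV/JSON with a provenance header (constant set,
config hash, parameters); unknown barriers are written as explicit
`null`, never 0, and round-trip losslessly.

## Cycle kinetics

`rates_from_profile` builds TST rates per edge (k_b uses barrier −
ΔG_step, so detailed balance holds by construction and the cycle's rate
ratios telescope to e^(−ΔG_cycle/RT)). The linear ladder closes into a
ring through a substrate-exchange edge treated as isoenergetic with a
configurable barrier (default 14 kcal/mol, the quinone entry/exit
bound); the cycle affinity is then exactly −dG(IX, pmf).

Steady-state flux uses the exact closed-form solution of the unicyclic
master equation (Derrida's construction): all denominator terms are
positive, so the only cancellation is the physical factor
1 − e^(ΔG_cycle/RT) and the flux is numerically clean arbitrarily close
to stall — a dense nullspace solve (kept as an internal cross-check)
loses the sign near stall because state populations span ~13 orders of
magnitude. The stall pmf has the closed form −ΔG_redox·1000/(q·F) mV
(205 mV for the ubiquinone model: 410 mV × 2 e⁻ / 4 H⁺; 120 mV for
menaquinone) and is verified against root-finding on dG(IX, pmf).

`gillespie_cycle_times` is the independent stochastic oracle: a seeded
exact-SSA trajectory on the ring, returning renewal intervals between
new maxima of the winding number; their mean estimates 1/flux. No
absolute turnover number is targeted — none is well constrained — so
the solver and simulator are checked against *each other* (agreement
within three standard errors).

## Synthetic random pumps

`generate_random_pump` draws closed-cycle pump models (a power stroke,
then per-subunit uptake/relay/release with ±0.5 charge moves) with step
energies from user distributions, then shifts all increments by a
common constant so the ladder closes exactly onto −nFΔE; barriers are
drawn from a band after flooring at max(0, ΔG_step), and an infeasible
band raises. These models emulate the *structure* of a pump cycle
(closure, partial translocations, alternating uphill/downhill steps)
but none of the mechanistic correlations of a real enzyme; tests on
them demonstrate thermodynamic consistency of the machinery (closure,
detailed balance, pmf linearity, stall closed form) across a model
family, not biological accuracy. The Gillespie cross-checks use a
deliberately tight barrier band (11–13 kcal/mol) so that a trajectory's
jump count per cycle stays modest; the packaged complex I model spans
~7 orders of magnitude in rates, which an exact solver handles trivially
but a stochastic trajectory cannot traverse in reasonable event counts.

## Numerical choices and degenerate inputs

- Rates are scaled to O(1) before linear solves (MFPT, dense
  steady-state); products of rate ratios are accumulated in log space.
- Profile validation rejects barriers below max(0, ΔG_step), duplicate
  labels, and a nonzero reference state; chains reject non-positive
  distances, packing densities outside (0, 1), and fewer than two
  centers.
- `stall_pmf` raises when no charge is translocated (no stall exists);
  TST inversion rejects rates above κ·k_BT/h.
- Config validation (pydantic, `extra="forbid"`) rejects unknown keys
  and names the physical quantity behind a missing field; applied
  defaults are logged.

## Problem sizes

All packaged computations are desk-scale by design: 17-state ladders,
8-center wires, 100-model property sweeps, and stochastic cross-checks
of a few hundred cycles (~10⁵ events); the full test suite runs in a
few seconds.

## Known limitations

- The membrane potential profile is linear with a uniform dielectric;
  no Stern-layer or surface-potential structure.
- Barriers under pmf shift by a fixed transition-state position rather
  than a per-step coordinate model.
- The wire solver ignores electron–electron interaction and
  conformational gating; the empirical ruler's coefficients carry their
  published ~order-of-magnitude uncertainty (±0.2 eV in a midpoint
  potential moves a step rate ~10×).
- The pumping cycle is strictly sequential (no branching, no slip
  pathways), so lower-stoichiometry operation at high pmf can only be
  represented by editing the model, not predicted.
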