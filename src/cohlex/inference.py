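"""Inversion of biophysical measurements into reaction-network rates.

Given a candidate topology and the per-protein (copy number, bound fraction,
residence time) table, the wild-type populations of every cohesin state follow
directly from the bound fractions.  The 8 unknown transition rates are then
pinned by 8 linear constraints:

* for each regulator, its release flux equals its bound population divided by
  its residence time (Little's law; for a regulator bound in a single state
  this is exactly "total exit rate = 1/residence time");
* the cohesin unloading flux equals the loaded population divided by the
  cohesin residence time (the stationarity identity for the mean binding
  window);
* stationary flux balance at every loaded state.

The resulting linear system is solved numerically per topology; a rate that
comes out non-positive marks the topology as unphysical.  A second pruning
stage re-solves the nonlinear steady state under 90% single-regulator
depletions (intrinsic rate constants frozen, totals reduced) and keeps only
topologies reproducing the experimentally observed directional changes in the
cohesin bound fraction (down for ΔNIPBL, up for ΔPDS5 and ΔWAPL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .measurements import MeasurementSet, load_measurements
from .network import ReactionTopology, Transition

#: Rates at or below this threshold (per second) are treated as unphysical;
#: guards against sign flips from floating-point cancellation.
PHYSICALITY_TOL = 1e-12


class MeasurementInconsistencyError(ValueError):
    """The topology cannot host the measured populations (negative state)."""


class DegenerateTopologyError(ValueError):
    """The rate-mapping linear system is singular for this topology."""


def _released(t: Transition):
    if not t.released_species:
        return ()
    return tuple(t.released_species.split("+"))


def wt_populations(topology: ReactionTopology, measurements="hela_wt") -> dict:
    """Absolute wild-type populations of each state and free pool.

    Returns a dict with one entry per state label plus ``free_<species>``
    entries for the three regulators.  Raises
    :class:`MeasurementInconsistencyError` if the bound-fraction arithmetic
    implies a negative population for any state.
    """
    ms = load_measurements(measurements)
    loaded_total = ms["RAD21"].bound_copies
    loaded = topology.loaded_states
    n = len(loaded)

    # Linear system: per-regulator occupancy sums + total loaded population.
    regs = sorted({r for s in loaded for r in s.bound_regulators})
    rows, rhs = [], []
    for reg in regs:
        rows.append([1.0 if reg in s.bound_regulators else 0.0 for s in loaded])
        rhs.append(ms[reg].bound_copies)
    rows.append([1.0] * n)
    rhs.append(loaded_total)
    A, b = np.asarray(rows), np.asarray(rhs)
    sol, residual, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < n or (np.abs(A @ sol - b) > 1e-6 * max(1.0, loaded_total)).any():
        raise MeasurementInconsistencyError(
            f"{topology.name}: cannot assign measured bound populations to states"
        )
    pops = {s.label: float(x) for s, x in zip(loaded, sol)}
    if min(pops.values()) < 0:
        raise MeasurementInconsistencyError(
            f"{topology.name}: negative implied population {pops}"
        )
    pops["FREE"] = ms["RAD21"].copy_number - loaded_total
    for reg in ("NIPBL", "PDS5", "WAPL"):
        bound = sum(pops[s.label] for s in loaded if reg in s.bound_regulators)
        pops[f"free_{reg}"] = ms[reg].copy_number - bound
    return pops


@dataclass
class RateSet:
    """Inferred transition rates for one topology.

    ``effective_rates`` are first-order rates (1/s) evaluated at the wild-type
    steady state; ``intrinsic_rates`` divide out the wild-type free pool for
    order-2 transitions (per free molecule per second) and coincide with the
    effective rates for order-1 transitions.
    """

    topology: ReactionTopology
    effective_rates: dict  # (from, to) -> 1/s at WT
    intrinsic_rates: dict  # (from, to) -> 1/s or 1/(molecule s)
    wt_state_populations: dict = field(default_factory=dict)
    wt_free_pools: dict = field(default_factory=dict)

    @property
    def transitions(self) -> list:
        return self.topology.transitions

    def is_physical(self, tol: float = PHYSICALITY_TOL) -> bool:
        return all(v > tol for v in self.effective_rates.values())

    def effective_at(self, free_pools: dict) -> dict:
        """Effective first-order rates given free regulator pools (copies)."""
        out = {}
        for t in self.transitions:
            k = self.intrinsic_rates[t.key]
            if t.order == 2:
                k *= free_pools[t.consumed_species]
            out[t.key] = k
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for t in self.transitions:
            rows.append(
                {
                    "from": t.from_state,
                    "to": t.to_state,
                    "kind": t.kind,
                    "order": t.order,
                    "consumed": t.consumed_species,
                    "released": t.released_species,
                    "effective_per_s": self.effective_rates[t.key],
                    "intrinsic": self.intrinsic_rates[t.key],
                }
            )
        return pd.DataFrame(rows)


def solve_rates(topology: ReactionTopology, measurements="hela_wt") -> RateSet:
    """Solve the 8-constraint linear system for the transition rates.

    Negative rates are *returned*, not raised — physicality is decided by the
    pruning stage.  Raises :class:`DegenerateTopologyError` when the system is
    singular, and ``ValueError`` when the constraint and unknown counts differ.
    """
    ms = load_measurements(measurements)
    pops = wt_populations(topology, ms)
    trans = topology.transitions
    n = len(trans)
    loaded_labels = [s.label for s in topology.loaded_states]
    regs = sorted({r for s in topology.loaded_states for r in s.bound_regulators})
    n_constraints = len(regs) + 1 + len(loaded_labels)
    if n != n_constraints:
        raise ValueError(
            f"{topology.name}: {n} unknown rates but {n_constraints} constraints"
        )

    A = np.zeros((n, n))
    b = np.zeros(n)
    row = 0
    # Regulator release flux = bound population / residence time.
    for reg in regs:
        for j, t in enumerate(trans):
            if reg in _released(t):
                A[row, j] = pops[t.from_state]
        bound = sum(
            pops[s.label] for s in topology.loaded_states if reg in s.bound_regulators
        )
        b[row] = bound / ms[reg].residence_time
        row += 1
    # Cohesin unloading flux = loaded population / residence time.
    loaded_total = sum(pops[lbl] for lbl in loaded_labels)
    for j, t in enumerate(trans):
        if t.kind == "unload":
            A[row, j] = pops[t.from_state]
    b[row] = loaded_total / ms["RAD21"].residence_time
    row += 1
    # Stationary flux balance at every loaded state.
    for lbl in loaded_labels:
        for j, t in enumerate(trans):
            if t.to_state == lbl:
                A[row, j] += pops[t.from_state]
            if t.from_state == lbl:
                A[row, j] -= pops[lbl]
        row += 1

    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        raise DegenerateTopologyError(f"{topology.name}: {err}") from None
    if np.abs(A @ x - b).max() > 1e-6 * max(1.0, np.abs(b).max()):
        raise DegenerateTopologyError(f"{topology.name}: rate system is singular")

    effective = {t.key: float(k) for t, k in zip(trans, x)}
    intrinsic = {}
    for t in trans:
        k = effective[t.key]
        if t.order == 2:
            pool = pops[f"free_{t.consumed_species}"]
            if pool <= 0:
                raise MeasurementInconsistencyError(
                    f"{topology.name}: no free {t.consumed_species} at WT"
                )
            k = k / pool
        intrinsic[t.key] = k
    free_pools = {r: pops[f"free_{r}"] for r in ("NIPBL", "PDS5", "WAPL")}
    state_pops = {k: v for k, v in pops.items() if not k.startswith("free_")}
    return RateSet(topology, effective, intrinsic, state_pops, free_pools)


@dataclass
class PruningReport:
    """Outcome of the two-stage pruning for one candidate topology."""

    topology: ReactionTopology
    physical: bool
    qualitative_checks: dict = field(default_factory=dict)
    surviving: bool = False
    note: str = ""

    def as_row(self) -> dict:
        row = {"topology": self.topology.name, "physical": self.physical,
               "surviving": self.surviving}
        row.update({f"check_{k}": v for k, v in self.qualitative_checks.items()})
        row["note"] = self.note
        return row


#: Directional bound-fraction changes required of a surviving topology:
#: species -> True if the cohesin bound fraction must increase on depletion.
QUALITATIVE_DIRECTIONS = {"NIPBL": False, "PDS5": True, "WAPL": True}


def prune(topologies, measurements="hela_wt", depletion_level: float = 0.9) -> list:
    """Two-stage pruning of candidate topologies.

    Stage 1 rejects topologies whose inferred rates are not all strictly
    positive.  Stage 2 re-solves the nonlinear steady state under single
    regulator depletions (default 90%, matching RNAi efficiencies) and demands
    the observed directional changes of the cohesin bound fraction.
    """
    from .kinetics import solve_steady_state  # local import to avoid a cycle

    if not 0.0 < depletion_level < 1.0:
        raise ValueError("depletion level must lie in (0, 1)")
    ms = load_measurements(measurements)
    totals = {sp: m.copy_number for sp, m in ms.items()}
    reports = []
    for topo in topologies:
        try:
            rates = solve_rates(topo, ms)
        except (MeasurementInconsistencyError, DegenerateTopologyError) as err:
            reports.append(PruningReport(topo, False, {}, False, str(err)))
            continue
        if not rates.is_physical():
            reports.append(PruningReport(topo, False, {}, False,
                                         "non-positive rate"))
            continue
        wt = solve_steady_state(rates, totals)
        checks = {}
        for sp, must_increase in QUALITATIVE_DIRECTIONS.items():
            depleted = dict(totals)
            depleted[sp] = totals[sp] * (1.0 - depletion_level)
            ss = solve_steady_state(rates, depleted)
            went_up = ss.bound_fraction > wt.bound_fraction
            checks[f"d{sp}_bound_{'up' if must_increase else 'down'}"] = (
                went_up == must_increase
            )
        reports.append(
            PruningReport(topo, True, checks, all(checks.values()))
        )
    return reports
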