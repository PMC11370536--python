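"""Deterministic mass-action kinetics of the cohesin reaction network.

All second-order transitions couple to the instantaneous free pool of the
consumed regulator, so the stationary state of the network is the fixed point
of a nonlinear system: given free pools the cohesin chain is linear and its
stationary distribution follows from one linear solve; the free pools in turn
follow from conservation of each regulator's total.  A damped fixed-point
iteration on this pair converges rapidly in all regimes encountered here
(including 99% depletions); a general root finder is kept as fallback.

Depletion experiments are modelled by rescaling species totals while freezing
the intrinsic rate constants at their wild-type inference — all nonlinearity
of the depletion response enters through free-pool re-equilibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .inference import RateSet
from .measurements import load_measurements

REGULATORS = ("NIPBL", "PDS5", "WAPL")


class ConvergenceError(RuntimeError):
    """Steady-state iteration failed; carries the last residual."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


@dataclass
class SteadyState:
    """Stationary populations, pools and fluxes of the network."""

    populations: dict  # state label -> copies
    free_pools: dict  # species -> copies
    fluxes: dict  # (from, to) -> copies/s
    totals: dict  # species -> copies

    @property
    def loaded(self) -> float:
        return sum(v for k, v in self.populations.items() if k != "FREE")

    @property
    def bound_fraction(self) -> float:
        return self.loaded / self.totals["RAD21"]

    def regulator_bound_fraction(self, species: str, topology) -> float:
        bound = sum(
            self.populations[s.label]
            for s in topology.loaded_states
            if species in s.bound_regulators
        )
        return bound / self.totals[species]

    @property
    def active_to_loaded_ratio(self) -> float:
        """[RN] / ([RN]+[R]+[RP]+[RW]); the fraction of loaded cohesins that
        are actively extruding."""
        return self.populations.get("RN", 0.0) / self.loaded

    @property
    def loading_flux(self) -> float:
        return sum(v for k, v in self.fluxes.items() if k[0] == "FREE")

    @property
    def unloading_flux(self) -> float:
        return sum(v for k, v in self.fluxes.items() if k[1] == "FREE")

    @property
    def residence_time(self) -> float:
        """Mean cohesin binding window via the occupancy/flux identity."""
        return self.loaded / self.unloading_flux


def _free_pools(topology, pops: dict, totals: dict) -> dict:
    free = {}
    for sp in REGULATORS:
        bound = sum(
            pops[s.label] for s in topology.loaded_states if sp in s.bound_regulators
        )
        free[sp] = totals[sp] - bound
    return free


def _stationary_populations(topology, eff: dict, total_rad21: float) -> dict:
    """Stationary distribution of the state chain at fixed effective rates."""
    labels = topology.state_labels
    idx = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    M = np.zeros((n, n))
    for (a, b), k in eff.items():
        M[idx[b], idx[a]] += k
        M[idx[a], idx[a]] -= k
    M[0, :] = 1.0  # replace one balance row by the conservation constraint
    rhs = np.zeros(n)
    rhs[0] = total_rad21
    p = np.linalg.solve(M, rhs)
    return {lbl: float(p[idx[lbl]]) for lbl in labels}


def solve_steady_state(
    rates: RateSet,
    totals: dict | None = None,
    *,
    damping: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> SteadyState:
    """Solve the nonlinear stationary state of the network.

    Parameters
    ----------
    rates : RateSet
        Intrinsic rate constants (typically from the wild-type inference).
    totals : dict, optional
        Species totals (copies); defaults to the wild-type totals implied by
        the rate set.  Depletions are expressed by reducing entries here.
    """
    topology = rates.topology
    if totals is None:
        totals = dict(rates.wt_free_pools)
        for sp in REGULATORS:
            bound = sum(
                rates.wt_state_populations[s.label]
                for s in topology.loaded_states
                if sp in s.bound_regulators
            )
            totals[sp] += bound
        totals["RAD21"] = sum(rates.wt_state_populations.values())
    if min(totals.values()) <= 0:
        raise ValueError("species totals must be strictly positive")

    free = {sp: float(totals[sp]) for sp in REGULATORS}
    pops = None
    beta = damping
    for _ in range(max_iter):
        eff = rates.effective_at(free)
        new_pops = _stationary_populations(topology, eff, totals["RAD21"])
        new_free = _free_pools(topology, new_pops, totals)
        if any(v <= 0 for v in new_free.values()) or min(new_pops.values()) < 0:
            # over-shoot: regulator demand exceeded supply; clip and damp harder
            new_free = {sp: max(v, 1e-9 * totals[sp]) for sp, v in new_free.items()}
            beta = max(beta * 0.5, 1e-3)
        if pops is not None:
            delta = max(
                abs(new_pops[lbl] - pops[lbl]) for lbl in topology.state_labels
            )
            if delta < tol * totals["RAD21"]:
                pops, free = new_pops, new_free
                break
            new_free = {
                sp: beta * new_free[sp] + (1 - beta) * free[sp]
                for sp in new_free
            }
        pops, free = new_pops, new_free

    # Polish: one exact linear solve at the converged pools, then verify.
    eff = rates.effective_at(free)
    pops = _stationary_populations(topology, eff, totals["RAD21"])
    free = _free_pools(topology, pops, totals)
    residual = _net_flux_residual(rates, pops, free)
    state = _assemble(rates, pops, free, totals)
    if residual > 1e-10:
        state = _root_fallback(rates, totals, free)
        residual = _net_flux_residual(rates, state.populations, state.free_pools)
        if residual > 1e-8:
            raise ConvergenceError(
                f"steady state did not converge (residual {residual:.2e})",
                residual,
            )
    return state


def _net_flux_residual(rates, pops, free) -> float:
    """Max |net flux| per state relative to network throughput."""
    eff = rates.effective_at(free)
    net = {lbl: 0.0 for lbl in rates.topology.state_labels}
    through = 0.0
    for (a, b), k in eff.items():
        f = k * pops[a]
        net[a] -= f
        net[b] += f
        through += f
    return max(abs(v) for v in net.values()) / max(through, 1e-300)


def _root_fallback(rates, totals, free_guess) -> SteadyState:
    from scipy.optimize import least_squares

    topology = rates.topology
    scale = np.array([totals[sp] for sp in REGULATORS])

    def residual(free_vec):
        free = {sp: float(v) for sp, v in zip(REGULATORS, free_vec)}
        eff = rates.effective_at(free)
        pops = _stationary_populations(topology, eff, totals["RAD21"])
        new_free = _free_pools(topology, pops, totals)
        return [(new_free[sp] - free[sp]) / totals[sp] for sp in REGULATORS]

    x0 = np.clip([free_guess[sp] for sp in REGULATORS], 1e-9 * scale, scale)
    sol = least_squares(residual, x0, bounds=(np.zeros(3), scale),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    free = {sp: float(v) for sp, v in zip(REGULATORS, sol.x)}
    eff = rates.effective_at(free)
    pops = _stationary_populations(topology, eff, totals["RAD21"])
    free = _free_pools(topology, pops, totals)
    return _assemble(rates, pops, free, totals)


def _assemble(rates, pops, free, totals) -> SteadyState:
    eff = rates.effective_at(free)
    fluxes = {key: k * pops[key[0]] for key, k in eff.items()}
    return SteadyState(dict(pops), dict(free), fluxes, dict(totals))


# ---------------------------------------------------------------------------
# Time-dependent dynamics


def integrate_odes(rates: RateSet, totals: dict, initial: dict, t_grid) -> dict:
    """Integrate the nonlinear mass-action ODE system on a time grid.

    ``initial`` maps state label -> copies (must satisfy RAD21 conservation).
    Returns ``{"t": array, "<label>": array, ...}``.
    """
    topology = rates.topology
    labels = topology.state_labels
    y0 = np.array([float(initial[lbl]) for lbl in labels])
    if y0.min() < 0:
        raise ValueError("initial populations must be non-negative")
    if abs(y0.sum() - totals["RAD21"]) > 1e-6 * totals["RAD21"]:
        raise ValueError("initial populations must sum to the RAD21 total")
    idx = {lbl: i for i, lbl in enumerate(labels)}
    trans = topology.transitions

    def rhs(_, y):
        pops = {lbl: y[idx[lbl]] for lbl in labels}
        free = _free_pools(topology, pops, totals)
        dy = np.zeros_like(y)
        for t in trans:
            k = rates.intrinsic_rates[t.key]
            if t.order == 2:
                k *= free[t.consumed_species]
            f = k * y[idx[t.from_state]]
            dy[idx[t.from_state]] -= f
            dy[idx[t.to_state]] += f
        return dy

    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
        method="LSODA", rtol=1e-10, atol=1e-8 * totals["RAD21"],
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    out = {"t": sol.t}
    for lbl in labels:
        out[lbl] = sol.y[idx[lbl]]
    drift = np.abs(sol.y.sum(axis=0) - totals["RAD21"]).max() / totals["RAD21"]
    if drift > 1e-9:
        raise RuntimeError(f"conservation drift {drift:.2e} exceeds tolerance")
    return out


# ---------------------------------------------------------------------------
# Residence times and transition frequencies


def _entry_distribution(rates, steady) -> dict:
    loads = [t for t in rates.topology.load_transitions]
    flux = {t.to_state: steady.fluxes[t.key] for t in loads}
    total = sum(flux.values())
    if total <= 0:
        raise ValueError("no loading flux; entry distribution undefined")
    return {lbl: f / total for lbl, f in flux.items()}


def residence_time_mfpt(rates: RateSet, steady: SteadyState) -> float:
    """Mean first-passage time from loading entry to unloading (seconds).

    Computed by a linear solve over the loaded subnetwork with effective rates
    evaluated at the given steady state's free pools; the entry state
    distribution is weighted by loading fluxes.  At stationarity this equals
    the occupancy/flux identity ``loaded / unloading flux``.
    """
    topology = rates.topology
    eff = rates.effective_at(steady.free_pools)
    loaded = [s.label for s in topology.loaded_states]
    idx = {lbl: i for i, lbl in enumerate(loaded)}
    n = len(loaded)
    Q = np.zeros((n, n))
    for (a, b), k in eff.items():
        if a == "FREE":
            continue
        Q[idx[a], idx[a]] -= k
        if b != "FREE":
            Q[idx[a], idx[b]] += k
    if np.linalg.matrix_rank(Q) < n:
        raise ValueError("FREE state unreachable from part of the loaded network")
    tau = np.linalg.solve(Q, -np.ones(n))
    entry = _entry_distribution(rates, steady)
    return float(sum(w * tau[idx[lbl]] for lbl, w in entry.items()))


def transition_frequencies(rates: RateSet, steady: SteadyState) -> dict:
    """Per-minute entry frequency into each loaded state.

    For each loaded state: (total entry flux / loading flux) gives the mean
    number of entries per cohesin binding window; dividing by the residence
    time and converting to minutes gives the reported frequency.
    """
    loading = steady.loading_flux
    if loading <= 0:
        raise ValueError("zero loading flux; frequencies undefined")
    residence = steady.residence_time
    freqs = {}
    for s in rates.topology.loaded_states:
        entries = sum(
            f for (a, b), f in steady.fluxes.items() if b == s.label
        )
        freqs[s.label] = entries / loading / residence * 60.0
    return freqs


# ---------------------------------------------------------------------------
# In silico depletions


@dataclass(frozen=True)
class DepletionSpec:
    """Fractional depletion per species, e.g. ``{"WAPL": 0.9}``."""

    targets: dict = field(default_factory=dict)

    def __post_init__(self):
        for sp, frac in self.targets.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"depletion fraction for {sp} must be in [0, 1]")

    def apply(self, totals: dict) -> dict:
        out = dict(totals)
        for sp, frac in self.targets.items():
            out[sp] = totals[sp] * (1.0 - frac)
        return out


@dataclass
class ExtrusionPrediction:
    """Predicted extrusion kinetics under a depletion."""

    spec: DepletionSpec
    steady: SteadyState
    residence_time_s: float
    bound_fraction: float
    relative_extrusion_rate: float  # active-to-loaded ratio normalized to WT
    occupancies: dict  # state -> fraction of total cohesin
    transition_freqs_per_min: dict


def wild_type_totals(measurements="hela_wt") -> dict:
    ms = load_measurements(measurements)
    return {sp: m.copy_number for sp, m in ms.items()}


def predict_depletion(
    rates: RateSet, totals: dict, spec: DepletionSpec
) -> ExtrusionPrediction:
    """Steady-state extrusion kinetics with species totals rescaled.

    Intrinsic rate constants stay frozen at their (wild-type) inference; only
    the totals change, so the full response is carried by free-pool
    re-equilibration.
    """
    wt = solve_steady_state(rates, totals)
    depleted = solve_steady_state(rates, spec.apply(totals))
    occ = {
        lbl: depleted.populations[lbl] / depleted.totals["RAD21"]
        for lbl in rates.topology.state_labels
    }
    return ExtrusionPrediction(
        spec=spec,
        steady=depleted,
        residence_time_s=depleted.residence_time,
        bound_fraction=depleted.bound_fraction,
        relative_extrusion_rate=(
            depleted.active_to_loaded_ratio / wt.active_to_loaded_ratio
        ),
        occupancies=occ,
        transition_freqs_per_min=transition_frequencies(rates, depleted),
    )


def depletion_scan(rates, totals, species, levels) -> "pd.DataFrame":
    """Tabulate depletion predictions over a grid of levels (one species)."""
    import pandas as pd

    wt = solve_steady_state(rates, totals)
    rows = []
    for lev in levels:
        pred = predict_depletion(rates, totals, DepletionSpec({species: lev}))
        rows.append(
            {
                "species": species,
                "depletion": lev,
                "bound_fraction": pred.bound_fraction,
                "residence_s": pred.residence_time_s,
                "residence_fold": pred.residence_time_s / wt.residence_time,
                "relative_extrusion_rate": pred.relative_extrusion_rate,
                "loaded": pred.steady.loaded,
            }
        )
    return pd.DataFrame(rows)


def lattice_time_mapping(
    active_to_loaded_ratio: float,
    v_invitro: float = 1000.0,
    site_bp: float = 2500.0,
) -> float:
    """Physical duration (s) of one lattice step.

    The mean extrusion speed of a loaded extruder is ``v = 2 l / tau_1d *
    ratio`` (two legs each advancing one site of ``l`` bp per step while
    NIPBL-bound), so ``tau_1d = 2 l * ratio / v`` with the in vitro speed
    ``v`` (default 1 kb/s) and ``l`` = 2.5 kb per site.
    """
    if v_invitro <= 0:
        raise ValueError("in vitro extrusion speed must be > 0")
    if active_to_loaded_ratio <= 0:
        raise ValueError("active-to-loaded ratio is zero; time step undefined")
    return 2.0 * site_bp * active_to_loaded_ratio / v_invitro
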