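"""Seeded synthetic inputs for testing and validation.

All generators are pure functions of ``(kind, seed)`` so fixtures are
reproducible and need not be stored on disk.
"""

from __future__ import annotations

import numpy as np

from .inference import RateSet
from .measurements import MeasurementSet, ProteinMeasurement
from .network import builtin_topologies
from . import kinetics


def random_rateset(seed: int = 0, topology=None, totals=None) -> RateSet:
    """A random physical rate set on the five-state cycle (or given topology).

    Intrinsic rates are drawn log-uniformly in ranges bracketing the measured
    regime; effective rates are evaluated at the steady state of the
    wild-type totals, so the result is physical by construction.
    """
    topology = topology or builtin_topologies()["five_state"]
    totals = totals or kinetics.wild_type_totals()
    rng = np.random.default_rng(seed)
    intrinsic = {}
    for t in topology.transitions:
        if t.order == 1:
            intrinsic[t.key] = float(np.exp(rng.uniform(np.log(1e-3), np.log(3e-2))))
        else:
            intrinsic[t.key] = float(
                np.exp(rng.uniform(np.log(1e-8), np.log(3e-7)))
            )
    rates = RateSet(topology, {}, intrinsic)
    steady = kinetics.solve_steady_state(rates, totals)
    rates.effective_rates = rates.effective_at(steady.free_pools)
    rates.wt_state_populations = dict(steady.populations)
    rates.wt_free_pools = dict(steady.free_pools)
    return rates


def measurements_from_steady(steady, topology, totals) -> MeasurementSet:
    """Forward-model a measurement table from a steady state.

    The inverse of rate inference: bound fractions come from state
    occupancies, residence times from the occupancy/flux identity per
    species.  Feeding the result back through the rate solver must recover
    the generating rates (round-trip oracle).
    """
    entries = [
        ProteinMeasurement(
            "RAD21", totals["RAD21"], steady.bound_fraction, steady.residence_time
        )
    ]
    for sp in ("NIPBL", "PDS5", "WAPL"):
        bound = sum(
            steady.populations[s.label]
            for s in topology.loaded_states
            if sp in s.bound_regulators
        )
        release = sum(
            f
            for (a, b), f in steady.fluxes.items()
            for t in topology.transitions
            if t.key == (a, b)
            and t.released_species
            and sp in t.released_species.split("+")
        )
        entries.append(
            ProteinMeasurement(sp, totals[sp], bound / totals[sp], bound / release)
        )
    return MeasurementSet(entries)


def toy_lattice(kind: str = "jam", seed: int = 0):
    """Small prescribed lattice states with known collision structure.

    Kinds: ``"jam"`` (all loaded extruders in one contiguous traffic jam;
    percolation score 1), ``"spread"`` (well separated; all singleton
    clusters), ``"pair"`` (exactly two adjacent extruders).
    """
    from .lattice import LatticeConfig, LatticeState
    from .measurements import HELA_WT
    from .inference import solve_rates

    rates = solve_rates(builtin_topologies()["five_state"], HELA_WT)
    cfg = LatticeConfig(
        n_sites=100, n_extruders=8, rates=rates, seed=seed, init="unloaded",
        n_steps=1, burn_in_steps=0,
    )
    st = LatticeState(cfg)
    placements = {
        "jam": [(10 + 2 * i, 11 + 2 * i) for i in range(8)],
        "spread": [(10 * i + 3, 10 * i + 5) for i in range(8)],
        "pair": [(10, 20), (21, 30)],
    }
    if kind not in placements:
        raise ValueError(f"unknown toy lattice kind {kind!r}")
    for e, (lt, rt) in enumerate(placements[kind]):
        st.state[e] = st.entry_state
        st.left[e], st.right[e] = lt, rt
        st.owner[lt] = st.owner[rt] = e
    return st


def paired_rasters(correlation: str = "identical", seed: int = 0, n: int = 24):
    """Raster pairs with known Pearson structure for the microscopy oracle."""
    rng = np.random.default_rng(seed)
    a = rng.poisson(3.0, size=(n, n, n)).astype(float)
    if correlation == "identical":
        return a, a.copy()
    if correlation == "independent":
        return a, rng.poisson(3.0, size=(n, n, n)).astype(float)
    if correlation == "anticorrelated":
        return a, a.max() - a
    raise ValueError(f"unknown raster correlation {correlation!r}")


def toy_polymer(seed: int = 0, n: int = 50):
    """A short random-walk chain conformation for brute-force P(s) oracles."""
    from .polymer import PolymerConformation

    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return PolymerConformation(coords, np.empty((0, 2), dtype=np.int64), 0.0)


def make_fixtures(kind: str, seed: int = 0):
    """Dispatch table over the fixture kinds."""
    if kind == "random_rateset":
        return random_rateset(seed)
    if kind == "toy_lattice":
        return toy_lattice("jam", seed)
    if kind == "toy_polymer":
        return toy_polymer(seed)
    if kind == "paired_rasters":
        return paired_rasters("identical", seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
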