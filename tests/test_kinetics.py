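"""Steady states, ODE dynamics, residence times and in silico depletions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohlex import (
    DepletionSpec,
    HELA_WT,
    depletion_scan,
    integrate_odes,
    lattice_time_mapping,
    predict_depletion,
    residence_time_mfpt,
    solve_steady_state,
    transition_frequencies,
)
from cohlex.fixtures import random_rateset
from cohlex.kinetics import REGULATORS


def test_wt_closure_reproduces_measurement_inputs(five_state, wt_rates, wt_steady):
    """The inferred rates reproduce every measured bound fraction and
    residence time at the wild-type steady state."""
    assert wt_steady.bound_fraction == pytest.approx(0.65, rel=1e-6)
    for sp, phi in [("NIPBL", 0.40), ("PDS5", 0.45), ("WAPL", 0.35)]:
        assert wt_steady.regulator_bound_fraction(sp, five_state) == pytest.approx(
            phi, rel=1e-6
        )
    assert wt_steady.residence_time == pytest.approx(822.0, rel=1e-6)
    # regulator residence times: bound population / release flux
    for sp, tau in [("NIPBL", 72.0), ("PDS5", 70.0), ("WAPL", 45.0)]:
        bound = sum(
            wt_steady.populations[s.label]
            for s in five_state.loaded_states
            if sp in s.bound_regulators
        )
        release = sum(
            wt_steady.fluxes[t.key]
            for t in five_state.transitions
            if t.released_species and sp in t.released_species.split("+")
        )
        assert bound / release == pytest.approx(tau, rel=1e-6)


def test_conservation_laws_hold(five_state, wt_steady, wt_totals):
    assert sum(wt_steady.populations.values()) == pytest.approx(
        wt_totals["RAD21"], rel=1e-9
    )
    for sp in REGULATORS:
        bound = sum(
            wt_steady.populations[s.label]
            for s in five_state.loaded_states
            if sp in s.bound_regulators
        )
        assert bound + wt_steady.free_pools[sp] == pytest.approx(
            wt_totals[sp], rel=1e-9
        )


def test_mfpt_equals_occupancy_over_flux(wt_rates, wt_steady):
    """Mean first-passage from RN to FREE matches loaded/unloading-flux."""
    mfpt = residence_time_mfpt(wt_rates, wt_steady)
    identity = wt_steady.loaded / wt_steady.unloading_flux
    assert mfpt == pytest.approx(identity, rel=1e-8)
    assert mfpt == pytest.approx(822.0, rel=1e-6)


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_mfpt_identity_for_random_cycles(seed):
    """The stationarity identity holds for arbitrary physical rate sets."""
    rates = random_rateset(seed)
    steady = solve_steady_state(rates)
    mfpt = residence_time_mfpt(rates, steady)
    assert mfpt == pytest.approx(steady.loaded / steady.unloading_flux, rel=1e-8)


def test_single_loaded_state_mfpt_closed_form():
    """A single loaded state with exit rate k has residence 1/k."""
    from cohlex.inference import solve_rates
    from cohlex.network import make_cycle

    rates = solve_rates(make_cycle(["R"]), HELA_WT)
    steady = solve_steady_state(rates, {sp: m.copy_number for sp, m in HELA_WT.items()})
    k_exit = rates.effective_rates[("R", "FREE")]
    assert residence_time_mfpt(rates, steady) == pytest.approx(1.0 / k_exit)
    freqs = transition_frequencies(rates, steady)
    assert freqs["R"] == pytest.approx(60.0 / steady.residence_time)


def test_ode_from_unloaded_reaches_steady_state(wt_rates, wt_totals, wt_steady):
    """Starting fully unloaded, loading proceeds monotonically to the fixed
    point; the long-horizon endpoint matches the algebraic steady state."""
    initial = {lbl: 0.0 for lbl in wt_rates.topology.state_labels}
    initial["FREE"] = wt_totals["RAD21"]
    traj = integrate_odes(wt_rates, wt_totals, initial, np.linspace(0, 50_000, 200))
    loaded = wt_totals["RAD21"] - traj["FREE"]
    assert (np.diff(loaded) > -1e-6 * wt_totals["RAD21"]).all()
    for lbl, target in wt_steady.populations.items():
        assert traj[lbl][-1] == pytest.approx(target, abs=1e-6 * wt_totals["RAD21"])


def test_ode_fixed_point_is_constant(wt_rates, wt_totals, wt_steady):
    traj = integrate_odes(
        wt_rates, wt_totals, wt_steady.populations, np.linspace(0, 5000, 20)
    )
    for lbl, target in wt_steady.populations.items():
        assert np.allclose(traj[lbl], target, rtol=1e-6)


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_ode_endpoint_matches_steady_state_for_random_rates(seed):
    rates = random_rateset(seed)
    totals = {"RAD21": 264_000.0, "NIPBL": 111_000.0, "WAPL": 65_000.0,
              "PDS5": 164_000.0}
    steady = solve_steady_state(rates, totals)
    initial = {lbl: 0.0 for lbl in rates.topology.state_labels}
    initial["FREE"] = totals["RAD21"]
    t_end = 40.0 * steady.residence_time
    traj = integrate_odes(rates, totals, initial, [0.0, t_end])
    for lbl, target in steady.populations.items():
        assert traj[lbl][-1] == pytest.approx(target, abs=2e-6 * totals["RAD21"])


def test_rn_entry_frequency_in_printed_range(wt_rates, wt_steady):
    """Loaded cohesins re-enter the actively-extruding state a few tenths of
    a time per minute (flux-based evaluation)."""
    freqs = transition_frequencies(wt_rates, wt_steady)
    assert 0.15 <= freqs["RN"] <= 0.45
    assert all(v >= 0 for v in freqs.values())


def test_zero_depletion_returns_wild_type(wt_rates, wt_totals, wt_steady):
    pred = predict_depletion(wt_rates, wt_totals, DepletionSpec({}))
    assert pred.bound_fraction == pytest.approx(wt_steady.bound_fraction)
    assert pred.relative_extrusion_rate == pytest.approx(1.0)
    assert pred.residence_time_s == pytest.approx(wt_steady.residence_time)


@pytest.mark.parametrize(
    "species, expect",
    [
        ("WAPL", dict(bf="up", residence="up")),
        ("PDS5", dict(bf="up", residence="up")),
        ("NIPBL", dict(bf="down", rate="down", residence="mild")),
    ],
)
def test_depletion_directions(wt_rates, wt_totals, wt_steady, species, expect):
    """Directional responses to 90% single-regulator depletion."""
    pred = predict_depletion(wt_rates, wt_totals, DepletionSpec({species: 0.9}))
    if expect.get("bf") == "up":
        assert pred.bound_fraction > wt_steady.bound_fraction
    elif expect.get("bf") == "down":
        assert pred.bound_fraction < wt_steady.bound_fraction
    if expect.get("residence") == "up":
        assert pred.residence_time_s > wt_steady.residence_time
    if expect.get("residence") == "mild":
        assert 0.5 < pred.residence_time_s / wt_steady.residence_time < 1.5
    if expect.get("rate") == "up":
        assert pred.relative_extrusion_rate > 1.0
    if expect.get("rate") == "down":
        assert pred.relative_extrusion_rate < 1.0


def test_rad21_depletion_mostly_changes_absolute_numbers(wt_rates, wt_totals,
                                                         wt_steady):
    """Cohesin depletion lowers the loaded count but barely shifts bound
    fraction or residence time (regulator pools become relatively richer)."""
    pred = predict_depletion(wt_rates, wt_totals, DepletionSpec({"RAD21": 0.9}))
    assert pred.steady.loaded < 0.2 * wt_steady.loaded
    assert abs(pred.bound_fraction - wt_steady.bound_fraction) < 0.15
    assert 0.8 < pred.residence_time_s / wt_steady.residence_time < 1.2


def test_pds5_scan_extrusion_rate_is_non_monotone(wt_rates, wt_totals):
    """Extrusion rate rises at moderate PDS5 depletion then falls at very
    high depletion levels."""
    levels = np.arange(0.0, 0.991, 0.033)
    df = depletion_scan(wt_rates, wt_totals, "PDS5", levels)
    rate = df["relative_extrusion_rate"].to_numpy()
    peak = rate.argmax()
    assert 0 < peak < len(rate) - 1
    assert rate[peak] > rate[0] and rate[peak] > rate[-1]


def test_wapl_nipbl_codepletion_preserves_loop_balance(wt_rates, wt_totals,
                                                       wt_steady):
    """Stoichiometric WAPL+NIPBL co-depletion keeps occupancy ratios near the
    unperturbed state while slowing individual extruders."""
    pred = predict_depletion(
        wt_rates, wt_totals, DepletionSpec({"WAPL": 0.9, "NIPBL": 0.9})
    )
    assert pred.residence_time_s > 2.0 * wt_steady.residence_time
    assert pred.relative_extrusion_rate < 0.7
    # loop-relevant balance: loop size ~ extrusion rate x residence stays
    # within a factor ~2 of wild type, unlike single WAPL depletion
    growth = pred.relative_extrusion_rate * (
        pred.residence_time_s / wt_steady.residence_time
    )
    single = predict_depletion(wt_rates, wt_totals, DepletionSpec({"WAPL": 0.9}))
    growth_single = single.relative_extrusion_rate * (
        single.residence_time_s / wt_steady.residence_time
    )
    assert 0.5 < growth < 2.5
    assert growth_single > growth


def test_lattice_time_mapping_arithmetic():
    assert lattice_time_mapping(0.25, 1000.0, 2500.0) == pytest.approx(1.25)
    assert lattice_time_mapping(0.25, 500.0, 2500.0) == pytest.approx(2.5)
    with pytest.raises(ValueError):
        lattice_time_mapping(0.0)


def test_wt_time_mapping_near_1_25_s(wt_steady):
    tau = lattice_time_mapping(wt_steady.active_to_loaded_ratio)
    assert 1.19 <= tau <= 1.31
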