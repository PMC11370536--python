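"""Discrete-time kinetic Monte Carlo engine."""

import numpy as np
import pytest

from cohlex import (
    HELA_WT,
    KmcConfig,
    integrate_odes,
    sample_residence_times,
    simulate_population,
    solve_steady_state,
)
from cohlex.inference import RateSet, solve_rates
from cohlex.network import make_cycle


def test_identical_seeds_give_identical_event_logs(wt_rates, wt_totals):
    cfg = KmcConfig(timestep=1.0, horizon=300, seed=42, n_complexes=500)
    a = simulate_population(wt_rates, wt_totals, cfg)
    b = simulate_population(wt_rates, wt_totals, cfg)
    assert np.array_equal(a.events, b.events)
    assert np.array_equal(a.states, b.states)
    c = simulate_population(wt_rates, wt_totals,
                            KmcConfig(timestep=1.0, horizon=300, seed=43,
                                      n_complexes=500))
    assert not np.array_equal(a.events, c.events)


def test_timestep_bound_enforced(wt_rates, wt_totals):
    with pytest.raises(ValueError, match="timestep too large"):
        simulate_population(
            wt_rates, wt_totals, KmcConfig(timestep=5.0, horizon=10.0)
        )


def test_zero_rates_produce_no_events(five_state, wt_totals):
    dead = RateSet(
        five_state,
        {t.key: 0.0 for t in five_state.transitions},
        {t.key: 0.0 for t in five_state.transitions},
    )
    # all mass stays FREE; steady solve is degenerate, so seed populations
    dead.wt_state_populations = {lbl: 0.0 for lbl in five_state.state_labels}
    dead.wt_state_populations["FREE"] = wt_totals["RAD21"]
    dead.wt_free_pools = {sp: wt_totals[sp] for sp in ("NIPBL", "PDS5", "WAPL")}
    traj = simulate_population(
        dead, wt_totals, KmcConfig(timestep=1.0, horizon=50, n_complexes=100)
    )
    assert traj.events.shape[0] == 0
    assert (traj.states == 0).all()


def test_two_state_bound_fraction_matches_closed_form():
    """FREE <-> R toy: phi = k_on / (k_on + k_off) within sampling error."""
    rates = solve_rates(make_cycle(["R"]), HELA_WT)
    totals = {sp: m.copy_number for sp, m in HELA_WT.items()}
    k_on = rates.effective_rates[("FREE", "R")]
    k_off = rates.effective_rates[("R", "FREE")]
    phi = k_on / (k_on + k_off)
    n = 20_000
    cfg = KmcConfig(timestep=20.0, horizon=30_000, seed=11, n_complexes=n,
                    record_stride=100)
    traj = simulate_population(rates, totals, cfg, initial="steady")
    occ = traj.occupancy()["R"][10:]
    se = np.sqrt(phi * (1 - phi) / n)
    assert abs(occ.mean() - phi) < 3 * se


def test_ensemble_matches_ode_within_3_se(wt_rates, wt_totals):
    """Equilibration from a fully unloaded population: the KMC ensemble
    tracks the mass-action ODE at every recorded time (shared pools)."""
    n = 5000
    cfg = KmcConfig(timestep=1.0, horizon=3000, seed=3, n_complexes=n,
                    record_stride=200, coupling="shared_pools")
    traj = simulate_population(wt_rates, wt_totals, cfg, initial="unloaded")
    occ = traj.occupancy()
    initial = {lbl: 0.0 for lbl in traj.labels}
    initial["FREE"] = wt_totals["RAD21"]
    ode = integrate_odes(wt_rates, wt_totals, initial, traj.times)
    for lbl in traj.labels:
        p = ode[lbl] / wt_totals["RAD21"]
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
        assert (np.abs(occ[lbl] - p) <= 3 * np.maximum(se, 1e-9)).all()


def test_frozen_and_shared_pools_agree_at_steady_state(wt_rates, wt_totals):
    """Starting at the steady state, pool drift is negligible and the two
    couplings give statistically indistinguishable occupancies."""
    n = 4000
    kw = dict(timestep=1.0, horizon=1500, n_complexes=n, record_stride=100)
    frozen = simulate_population(
        wt_rates, wt_totals, KmcConfig(seed=5, coupling="frozen_rates", **kw),
        initial="steady",
    )
    shared = simulate_population(
        wt_rates, wt_totals, KmcConfig(seed=6, coupling="shared_pools", **kw),
        initial="steady",
    )
    for lbl in frozen.labels:
        a = frozen.occupancy()[lbl][5:].mean()
        b = shared.occupancy()[lbl][5:].mean()
        assert abs(a - b) < 4 * np.sqrt(0.25 / n)


def test_dwell_times_are_geometric_per_state(wt_rates, wt_steady):
    """Single-exit states dwell geometrically; mean matches 1/k_tot."""
    eff = wt_rates.effective_at(wt_steady.free_pools)
    k_tot = sum(v for (a, b), v in eff.items() if a == "RN")
    tau = 1.0
    p_step = -np.expm1(-k_tot * tau)
    rng = np.random.default_rng(0)
    n = 5000
    draws = rng.geometric(p_step, size=n) * tau
    # discrete-time mean is tau / p_step; continuous-time limit is 1/k_tot
    assert draws.mean() == pytest.approx(tau / p_step, rel=5 / np.sqrt(n))
    assert tau / p_step == pytest.approx(1.0 / k_tot, rel=k_tot * tau)


def test_residence_sampling_matches_table_value(wt_rates, wt_steady):
    """Mean sampled binding window reproduces the 822 s cohesin residence."""
    samp = sample_residence_times(wt_rates, wt_steady, n=4000, seed=5,
                                  timestep=1.0)
    m = samp.dwell_times.mean()
    se = samp.dwell_times.std() / np.sqrt(len(samp.dwell_times))
    assert abs(m - 822.0) < 3 * se + 1.0  # +tau covers discretization bias


def test_sampled_entry_frequency_matches_flux_calculation(wt_rates, wt_steady):
    from cohlex import transition_frequencies

    samp = sample_residence_times(wt_rates, wt_steady, n=4000, seed=7,
                                  timestep=1.0)
    flux = transition_frequencies(wt_rates, wt_steady)
    for lbl in ("RN", "RW"):
        sampled = samp.entry_frequency_per_min(lbl)
        assert sampled == pytest.approx(flux[lbl], rel=0.1)


def test_single_loaded_state_dwell_mean(five_state):
    """One loaded state with exit rate k: sampled mean ~ 1/k."""
    rates = solve_rates(make_cycle(["R"]), HELA_WT)
    totals = {sp: m.copy_number for sp, m in HELA_WT.items()}
    steady = solve_steady_state(rates, totals)
    samp = sample_residence_times(rates, steady, n=3000, seed=1, timestep=10.0)
    k = rates.effective_rates[("R", "FREE")]
    se = samp.dwell_times.std() / np.sqrt(3000)
    assert abs(samp.dwell_times.mean() - 1.0 / k) < 3 * se + 10.0
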