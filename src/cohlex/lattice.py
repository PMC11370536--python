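"""1D lattice simulation of multi-state loop extruders.

Chromatin is a lattice of sites (2.5 kb each by default); an extruder is a
pair of legs occupying two sites plus a biochemical state from the reaction
network.  Each timestep every extruder first undergoes a discrete-time KMC
biochemical update (loading places both legs on a uniformly chosen free
adjacent site pair; unloading clears them), then every leg of every
NIPBL-bound (RN) extruder advances one site outward provided the target site
is unoccupied.  Legs move independently — a blocked leg does not stop its
partner — and extruders in non-RN loaded states are immobile but still block,
so encounters are collisions without bypass.

Transition rates are homogeneous across sites and frozen at the effective
first-order rates of the simulated condition's deterministic steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import RateSet
from . import kinetics
from .kmc import _transition_matrix

DEFAULT_SITE_BP = 2500.0


@dataclass
class LatticeConfig:
    """Configuration of a lattice extrusion run."""

    n_sites: int
    n_extruders: int
    rates: RateSet
    totals: dict | None = None  # species totals of the simulated condition
    site_bp: float = DEFAULT_SITE_BP
    tau_1d: float | None = None  # seconds per step; derived from rates if None
    n_steps: int = 5000
    burn_in_steps: int = 1000
    seed: int = 0
    record_stride: int = 20
    n_chains: int = 1
    boundary: str = "chain_ends_reflecting"  # or "ring"
    init: str = "steady"  # or "unloaded"
    max_load_tries: int = 64

    def __post_init__(self):
        if 2 * self.n_extruders > self.n_sites:
            raise ValueError("more extruder legs than lattice sites")
        if self.boundary not in ("chain_ends_reflecting", "ring"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.boundary == "ring" and self.n_chains != 1:
            raise ValueError("ring boundary requires a single chain")
        if self.n_sites % self.n_chains:
            raise ValueError("n_sites must divide evenly into chains")


@dataclass
class LatticeObservables:
    """Per-frame 1D structural observables."""

    loaded_density_per_mb: float
    loop_sizes_bp: np.ndarray
    loop_coverage: float
    collided_fraction: float
    percolation: float
    occupancy: dict  # state label -> count


class LatticeState:
    """Mutable state of a lattice extrusion simulation."""

    def __init__(self, cfg: LatticeConfig):
        self.cfg = cfg
        self.topology = cfg.rates.topology
        self.labels = self.topology.state_labels
        self.idx = {lbl: i for i, lbl in enumerate(self.labels)}
        if any(v > 0 for v in cfg.rates.intrinsic_rates.values()):
            steady = kinetics.solve_steady_state(cfg.rates, cfg.totals)
            free_pools = steady.free_pools
        else:  # degenerate network: nothing ever loads
            if cfg.totals is None:
                raise ValueError("totals required when all rates vanish")
            pops = {lbl: 0.0 for lbl in self.topology.state_labels}
            pops["FREE"] = cfg.totals["RAD21"]
            free_pools = {sp: cfg.totals[sp] for sp in kinetics.REGULATORS}
            steady = kinetics.SteadyState(
                pops, free_pools,
                {t.key: 0.0 for t in self.topology.transitions}, dict(cfg.totals),
            )
        self.steady = steady
        tau = cfg.tau_1d
        if tau is None:
            tau = kinetics.lattice_time_mapping(
                steady.active_to_loaded_ratio, site_bp=cfg.site_bp
            )
        self.tau_1d = tau
        eff = cfg.rates.effective_at(free_pools)
        self.P_cum = np.cumsum(_transition_matrix(self.topology, eff, tau), axis=1)
        self.entry_state = self.idx[self.topology.load_transitions[0].to_state]
        self.active_state = self.idx.get("RN", -1)

        self.rng = np.random.default_rng(cfg.seed)
        n = cfg.n_extruders
        self.state = np.zeros(n, dtype=np.int8)  # 0 == FREE
        self.left = np.full(n, -1, dtype=np.int64)
        self.right = np.full(n, -1, dtype=np.int64)
        self.owner = np.full(cfg.n_sites, -1, dtype=np.int64)
        self.chain_len = cfg.n_sites // cfg.n_chains
        self.t_step = 0
        if cfg.init == "steady":
            self._init_from_steady()
        elif cfg.init != "unloaded":
            raise ValueError(f"unknown init {cfg.init!r}")

    # -- helpers ---------------------------------------------------------------
    def _chain_of(self, site):
        return site // self.chain_len

    def _init_from_steady(self):
        p = np.array([self.steady.populations[lbl] for lbl in self.labels])
        drawn = self.rng.choice(len(self.labels), size=self.cfg.n_extruders,
                                p=p / p.sum()).astype(np.int8)
        for e in np.nonzero(drawn != 0)[0]:
            if self._try_load(e):
                self.state[e] = drawn[e]

    def _try_load(self, e) -> bool:
        """Place both legs on a uniformly chosen free adjacent site pair.

        Rejection sampling from uniform site draws is uniform over valid
        pairs; after ``max_load_tries`` failures the attempt is deferred to
        the next step.
        """
        cfg = self.cfg
        ring = cfg.boundary == "ring"
        for _ in range(cfg.max_load_tries):
            s = int(self.rng.integers(cfg.n_sites))
            s2 = (s + 1) % cfg.n_sites if ring else s + 1
            if not ring:
                if s2 >= cfg.n_sites or self._chain_of(s) != self._chain_of(s2):
                    continue
            if self.owner[s] == -1 and self.owner[s2] == -1:
                self.left[e], self.right[e] = s, s2
                self.owner[s] = self.owner[s2] = e
                return True
        return False

    def _unload(self, e):
        self.owner[self.left[e]] = -1
        self.owner[self.right[e]] = -1
        self.left[e] = self.right[e] = -1
        self.state[e] = 0

    # -- dynamics --------------------------------------------------------------
    def step(self) -> "LatticeState":
        """Advance one lattice timestep (biochemistry, then extrusion)."""
        cfg = self.cfg
        n = cfg.n_extruders
        u = self.rng.random(n)
        new = np.empty_like(self.state)
        for s in range(len(self.labels)):
            mask = self.state == s
            if mask.any():
                new[mask] = np.searchsorted(self.P_cum[s], u[mask], side="right")
        # loading attempts (sequential, in random order, to respect exclusion)
        loaders = np.nonzero((self.state == 0) & (new != 0))[0]
        self.rng.shuffle(loaders)
        for e in loaders:
            if self._try_load(e):
                self.state[e] = new[e]
            # else: deferred, stays FREE
        # unloading and plain state changes
        unloaders = np.nonzero((self.state != 0) & (new == 0))[0]
        for e in unloaders:
            self._unload(e)
        others = (self.state != 0) & (new != 0)
        self.state[others] = new[others]

        # extrusion moves: RN legs step outward, random order, no bypass
        if self.active_state >= 0:
            active = np.nonzero(self.state == self.active_state)[0]
            self.rng.shuffle(active)
            ring = cfg.boundary == "ring"
            for e in active:
                lt = self.left[e]
                tgt = (lt - 1) % cfg.n_sites if ring else lt - 1
                if (
                    tgt >= 0
                    and (ring or self._chain_of(tgt) == self._chain_of(lt))
                    and self.owner[tgt] == -1
                    and tgt != self.right[e]
                ):
                    self.owner[lt] = -1
                    self.owner[tgt] = e
                    self.left[e] = tgt
                rt = self.right[e]
                tgt = (rt + 1) % cfg.n_sites if ring else rt + 1
                if (
                    tgt < cfg.n_sites
                    and (ring or self._chain_of(tgt) == self._chain_of(rt))
                    and self.owner[tgt] == -1
                    and tgt != self.left[e]
                ):
                    self.owner[rt] = -1
                    self.owner[tgt] = e
                    self.right[e] = tgt
        self.t_step += 1
        return self

    # -- observables -----------------------------------------------------------
    @property
    def loaded(self) -> np.ndarray:
        return np.nonzero(self.state != 0)[0]

    def check_exclusion(self):
        occupied = np.nonzero(self.owner >= 0)[0]
        legs = np.concatenate(
            [self.left[self.loaded], self.right[self.loaded]]
        )
        assert len(set(legs.tolist())) == legs.size, "two legs share a site"
        assert set(occupied.tolist()) == set(legs.tolist())

    def loop_intervals(self) -> np.ndarray:
        """Loaded loops as (left, right) site pairs (ring loops unwrapped)."""
        ld = self.loaded
        return np.column_stack([self.left[ld], self.right[ld]])

    def collided_mask(self) -> np.ndarray:
        """Per loaded extruder: does any leg touch another extruder's leg."""
        ld = self.loaded
        out = np.zeros(ld.size, dtype=bool)
        ring = self.cfg.boundary == "ring"
        ns = self.cfg.n_sites
        for i, e in enumerate(ld):
            for s in (self.left[e], self.right[e]):
                for d in (-1, 1):
                    q = (s + d) % ns if ring else s + d
                    if 0 <= q < ns and self.owner[q] not in (-1, e):
                        if ring or self._chain_of(q) == self._chain_of(s):
                            out[i] = True
        return out

    def percolation_score(self) -> float:
        """Fraction of loaded extruders in the largest collided cluster."""
        ld = self.loaded
        if ld.size == 0:
            raise ValueError("no loaded extruders; percolation undefined")
        index = {int(e): i for i, e in enumerate(ld)}
        parent = list(range(ld.size))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

        ring = self.cfg.boundary == "ring"
        ns = self.cfg.n_sites
        for s in np.nonzero(self.owner >= 0)[0]:
            q = (s + 1) % ns if ring else s + 1
            if q >= ns or (not ring and self._chain_of(q) != self._chain_of(s)):
                continue
            a, b = self.owner[s], self.owner[q]
            if a >= 0 and b >= 0 and a != b:
                union(index[int(a)], index[int(b)])
        sizes = np.bincount([find(i) for i in range(ld.size)])
        return sizes.max() / ld.size

    def observables(self) -> LatticeObservables:
        cfg = self.cfg
        ld = self.loaded
        mb = cfg.n_sites * cfg.site_bp / 1e6
        sizes = (self.right[ld] - self.left[ld])
        if cfg.boundary == "ring":
            sizes = sizes % cfg.n_sites
        cover = np.zeros(cfg.n_sites + 1, dtype=np.int64)
        for e in ld:
            lt, rt = self.left[e], self.right[e]
            if rt >= lt:
                cover[lt] += 1
                cover[rt + 1] -= 1
            else:  # wrapped ring loop
                cover[lt] += 1
                cover[cfg.n_sites] -= 1
                cover[0] += 1
                cover[rt + 1] -= 1
        covered = (np.cumsum(cover[:-1]) > 0).mean()
        collided = self.collided_mask()
        occ = {lbl: int((self.state == i).sum()) for i, lbl in enumerate(self.labels)}
        return LatticeObservables(
            loaded_density_per_mb=ld.size / mb,
            loop_sizes_bp=sizes * cfg.site_bp,
            loop_coverage=float(covered),
            collided_fraction=float(collided.mean()) if ld.size else 0.0,
            percolation=self.percolation_score() if ld.size else float("nan"),
            occupancy=occ,
        )


@dataclass
class LatticeRun:
    """Result of a lattice run: frame records plus time-averaged observables."""

    cfg: LatticeConfig
    tau_1d: float
    times: np.ndarray  # recorded step indices
    frames: list  # list of dicts with state/left/right snapshots
    series: "pd.DataFrame" = None
    warning: str = ""

    def mean(self, column: str) -> float:
        """Time-average of an observable column after burn-in."""
        sel = self.series[self.series["step"] >= self.cfg.burn_in_steps]
        return float(sel[column].mean())

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["tau_1d"] = self.tau_1d
            f.create_dataset("steps", data=self.times)
            f.create_dataset(
                "state", data=np.stack([fr["state"] for fr in self.frames])
            )
            f.create_dataset(
                "left", data=np.stack([fr["left"] for fr in self.frames])
            )
            f.create_dataset(
                "right", data=np.stack([fr["right"] for fr in self.frames])
            )


def run(cfg: LatticeConfig) -> LatticeRun:
    """Run a lattice simulation, recording frames every ``record_stride``."""
    import pandas as pd

    sim = LatticeState(cfg)
    warning = ""
    if cfg.n_steps <= cfg.burn_in_steps:
        warning = "horizon does not exceed burn-in; averages are empty"
    times, frames, rows = [], [], []
    for step in range(1, cfg.n_steps + 1):
        sim.step()
        if step % cfg.record_stride == 0:
            obs = sim.observables()
            times.append(step)
            frames.append(
                {
                    "state": sim.state.copy(),
                    "left": sim.left.copy(),
                    "right": sim.right.copy(),
                }
            )
            row = {
                "step": step,
                "t_s": step * sim.tau_1d,
                "loaded_density_per_mb": obs.loaded_density_per_mb,
                "loop_coverage": obs.loop_coverage,
                "collided_fraction": obs.collided_fraction,
                "percolation": obs.percolation,
                "mean_loop_bp": float(obs.loop_sizes_bp.mean())
                if obs.loop_sizes_bp.size
                else 0.0,
            }
            row.update({f"n_{k}": v for k, v in obs.occupancy.items()})
            rows.append(row)
    return LatticeRun(cfg, sim.tau_1d, np.asarray(times), frames,
                      pd.DataFrame(rows), warning)


def loops_to_bed(state: LatticeState, chrom_prefix="chain") -> str:
    """Loaded loops as BED lines (0-based half-open, site coordinates x l bp)."""
    lines = []
    bp = state.cfg.site_bp
    for e in state.loaded:
        lt, rt = int(state.left[e]), int(state.right[e])
        c = state._chain_of(lt)
        off = c * state.chain_len
        lines.append(
            f"{chrom_prefix}{c}\t{int((lt - off) * bp)}\t{int((rt - off + 1) * bp)}"
            f"\textruder_{e}\t{state.labels[state.state[e]]}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
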