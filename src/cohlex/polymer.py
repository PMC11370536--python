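"""Coarse-grained bead-spring polymer dynamics driven by lattice extruders.

One lattice site maps to one bead of b = 50 nm (2.5 kb of chromatin).  The
chain carries harmonic backbone springs, a bounded polynomial soft
excluded-volume repulsion (chain crossings are rare but not forbidden, as
appropriate for interphase chromatin at this resolution), and one harmonic
bond per loaded extruder connecting the two monomers its legs occupy; the
extruder bonds are refreshed from the 1D lattice trajectory every
``steps_per_lattice_update`` integration steps.

Integration uses overdamped Brownian (Langevin) dynamics in a periodic box
sized to a 20% monomer volume fraction.  Times are dimensionless in units of
the integration step; the physical value of the step is obtained post hoc by
matching the simulated monomer mean-squared-displacement power law to
experimental chromatin diffusion coefficients (:func:`calibrate_time`).  The
default friction is set so the free-chain Rouse MSD coefficient is ~0.3
b^2 per sqrt(step), which makes the calibrated step land near 5 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class PolymerConfig:
    """Parameters of the bead-spring chain and its integrator."""

    n_monomers: int
    volume_fraction: float = 0.20
    bead_nm: float = 50.0
    bead_bp: float = 2500.0
    repulsion_amplitude: float = 6.0  # kT; bounded overlap energy
    repulsion_range: float = 1.0  # b
    bond_stiffness: float = 20.0  # kT / b^2 (backbone and extruder bonds)
    bond_rest_length: float = 1.0  # b
    dt: float = 0.005  # dimensionless integration step
    friction: float = 0.27  # sets monomer mobility (see module docstring)
    kT: float = 1.0
    steps_per_lattice_update: int = 250
    seed: int = 0
    max_step_displacement: float = 0.35  # b; per-step clamp for stability
    neighbor_rebuild: int = 5
    neighbor_skin: float = 0.6

    @property
    def box_length(self) -> float:
        """Cubic periodic box edge (in b) at the target volume fraction."""
        v_bead = np.pi / 6.0  # sphere of diameter b
        return (self.n_monomers * v_bead / self.volume_fraction) ** (1.0 / 3.0)


@dataclass
class PolymerConformation:
    """A single frame: unwrapped coordinates (units of b) plus extruder bonds."""

    coords: np.ndarray  # (n, 3)
    bonds: np.ndarray  # (m, 2) monomer index pairs
    time: float  # dimensionless (integration steps x dt)


@dataclass
class TimeMapping:
    """Experimental anchors for the simulation-to-physical time mapping."""

    rouse_exponent: float = 0.5
    rouse_coefficient_um2: float = 0.01  # um^2 / s^0.5
    extrusion_exponent: float = 0.675
    extrusion_coefficient_um2: float = 0.0075  # um^2 / s^0.675
    bead_um: float = 0.05


class IntegrationError(RuntimeError):
    def __init__(self, message, last_frame=None):
        super().__init__(message)
        self.last_frame = last_frame


class PolymerSimulation:
    """Brownian dynamics of one chain in a periodic box."""

    def __init__(self, cfg: PolymerConfig, coords=None):
        self.cfg = cfg
        self.L = cfg.box_length
        self.rng = np.random.default_rng(cfg.seed)
        if coords is None:
            coords = self._random_walk_init()
        self.x = np.asarray(coords, dtype=float).copy()
        if self.x.shape != (cfg.n_monomers, 3):
            raise ValueError("coords shape mismatch")
        self.extruder_bonds = np.empty((0, 2), dtype=np.int64)
        self._pairs = None
        self._steps_since_rebuild = 10**9
        self.n_steps_done = 0

    def _random_walk_init(self):
        steps = self.rng.normal(size=(self.cfg.n_monomers - 1, 3))
        steps *= self.cfg.bond_rest_length / np.linalg.norm(
            steps, axis=1, keepdims=True
        )
        x = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        return x - x.mean(axis=0)

    def set_extruder_bonds(self, bonds) -> None:
        b = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
        if b.size and (b.min() < 0 or b.max() >= self.cfg.n_monomers):
            raise ValueError("extruder bond index out of range")
        self.extruder_bonds = b
        # fresh bonds can change the local force landscape; refresh neighbors
        self._steps_since_rebuild = 10**9

    def _min_image(self, d):
        return d - self.L * np.round(d / self.L)

    def _forces(self):
        cfg = self.cfg
        f = np.zeros_like(self.x)
        # backbone + extruder harmonic bonds
        i = np.arange(cfg.n_monomers - 1)
        pairs = np.vstack(
            [np.column_stack([i, i + 1]), self.extruder_bonds]
        )
        d = self._min_image(self.x[pairs[:, 1]] - self.x[pairs[:, 0]])
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 1e-12)
        fb = (cfg.bond_stiffness * (r - cfg.bond_rest_length) / r)[:, None] * d
        np.add.at(f, pairs[:, 0], fb)
        np.add.at(f, pairs[:, 1], -fb)
        # soft excluded volume: U = A (1 - (r/rc)^2)^3 for r < rc
        if self._steps_since_rebuild >= cfg.neighbor_rebuild or self._pairs is None:
            wrapped = np.mod(self.x, self.L)
            tree = cKDTree(wrapped, boxsize=self.L)
            self._pairs = tree.query_pairs(
                cfg.repulsion_range + cfg.neighbor_skin, output_type="ndarray"
            )
            self._steps_since_rebuild = 0
        if self._pairs.size:
            p = self._pairs
            d = self._min_image(self.x[p[:, 1]] - self.x[p[:, 0]])
            r2 = (d * d).sum(axis=1)
            rc2 = cfg.repulsion_range**2
            inside = r2 < rc2
            if inside.any():
                pi, di, r2i = p[inside], d[inside], r2[inside]
                s = 1.0 - r2i / rc2
                # F = -dU/dr * rhat = 6 A (r/rc^2) s^2 * rhat (repulsive)
                coef = 6.0 * cfg.repulsion_amplitude * s**2 / rc2
                fr = -coef[:, None] * di
                np.add.at(f, pi[:, 0], fr)
                np.add.at(f, pi[:, 1], -fr)
        return f

    def step(self, n: int = 1) -> None:
        cfg = self.cfg
        amp = np.sqrt(2.0 * cfg.kT * cfg.dt / cfg.friction)
        for _ in range(n):
            f = self._forces()
            dx = f * (cfg.dt / cfg.friction)
            # clamp the deterministic drift only (blow-up guard); thermal
            # noise must stay unclamped or diffusion is biased
            norm = np.linalg.norm(dx, axis=1)
            over = norm > cfg.max_step_displacement
            if over.any():
                dx[over] *= (cfg.max_step_displacement / norm[over])[:, None]
            dx += amp * self.rng.standard_normal(self.x.shape)
            self.x += dx
            self._steps_since_rebuild += 1
            self.n_steps_done += 1
            if not np.isfinite(self.x).all():
                raise IntegrationError(
                    "non-finite coordinates (force blow-up)",
                    last_frame=self.frame(),
                )

    def frame(self) -> PolymerConformation:
        return PolymerConformation(
            self.x.copy(), self.extruder_bonds.copy(), self.n_steps_done * self.cfg.dt
        )


def _lattice_bonds(frame: dict, offset: int = 0) -> np.ndarray:
    """Extruder bonds (monomer index pairs) from a recorded lattice frame."""
    loaded = frame["state"] != 0
    return np.column_stack(
        [frame["left"][loaded] - offset, frame["right"][loaded] - offset]
    )


def run_polymer(
    cfg: PolymerConfig,
    lattice_run=None,
    n_relax_steps: int = 2000,
    burn_in_frames: int = 0,
    record_every_frames: int = 1,
    frames: int | None = None,
) -> list:
    """Integrate the chain, refreshing extruder bonds from a lattice run.

    Parameters
    ----------
    lattice_run : LatticeRun, optional
        Recorded lattice trajectory; each recorded lattice frame drives
        ``steps_per_lattice_update`` integration steps.  When omitted, a free
        chain is integrated for ``frames`` blocks instead.
    n_relax_steps : int
        Initial relaxation steps before any extruder bonds are applied.
    burn_in_frames : int
        Number of leading lattice frames discarded from the output ensemble
        (still simulated, so the conformation equilibrates under extrusion).
    """
    sim = PolymerSimulation(cfg)
    sim.step(n_relax_steps)
    out = []
    if lattice_run is None:
        for k in range(frames or 10):
            sim.step(cfg.steps_per_lattice_update)
            if k >= burn_in_frames and (k % record_every_frames) == 0:
                out.append(sim.frame())
        return out
    for k, fr in enumerate(lattice_run.frames):
        if fr["state"].max() >= 1 and fr["left"].max() >= cfg.n_monomers:
            raise ValueError("lattice is larger than the polymer chain")
        sim.set_extruder_bonds(_lattice_bonds(fr))
        sim.step(cfg.steps_per_lattice_update)
        if k >= burn_in_frames and (k % record_every_frames) == 0:
            out.append(sim.frame())
    return out


def monomer_msd(frames: list, max_lag: int | None = None) -> tuple:
    """Monomer MSD (b^2) vs lag (dimensionless time), frame-resolution lags."""
    coords = np.stack([f.coords for f in frames])
    times = np.array([f.time for f in frames])
    n = len(frames)
    max_lag = max_lag or n - 1
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(lags.size)
    for j, lag in enumerate(lags):
        d = coords[lag:] - coords[:-lag]
        msd[j] = (d**2).sum(axis=2).mean()
    return (times[lags] - times[0]), msd


def fit_power_law(t, y, window=None) -> tuple:
    """Least-squares fit of y = C t^alpha in log-log space -> (C, alpha)."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, y = t[sel], y[sel]
    if t.size < 2:
        raise ValueError("not enough points in fit window")
    alpha, logc = np.polyfit(np.log(t), np.log(y), 1)
    return float(np.exp(logc)), float(alpha)


def calibrate_time(
    msd_t,
    msd_values,
    mapping: TimeMapping | None = None,
    regime: str = "rouse",
    window=None,
    exponent_tolerance: float = 0.15,
) -> dict:
    """Physical duration of one integration step from an MSD curve.

    Fits ``MSD = C * t^alpha`` (t in units of the integration step, MSD in
    b^2), then equates the simulated and experimental coefficients:
    ``C * b_um^2 * t^alpha = D_exp * (t * tau)^alpha`` gives
    ``tau = (C * b_um^2 / D_exp)^(1/alpha)`` seconds per step.

    Returns a dict with ``tau_s``, the fitted ``coefficient`` and
    ``exponent``, a ``warning`` string when the fitted exponent deviates from
    the reference beyond ``exponent_tolerance``, and the implied lattice
    coupling ``n_3d_per_1d`` for a 1.25 s lattice step.
    """
    mapping = mapping or TimeMapping()
    if regime == "rouse":
        ref_alpha, d_exp = mapping.rouse_exponent, mapping.rouse_coefficient_um2
    elif regime == "extrusion":
        ref_alpha, d_exp = (
            mapping.extrusion_exponent,
            mapping.extrusion_coefficient_um2,
        )
    else:
        raise ValueError(f"unknown regime {regime!r}")
    _, alpha = fit_power_law(msd_t, msd_values, window)
    warning = ""
    if abs(alpha - ref_alpha) > exponent_tolerance:
        warning = (
            f"fitted exponent {alpha:.3f} deviates from reference "
            f"{ref_alpha:.3f}; coefficient comparison may be biased"
        )
    # coefficient with the exponent pinned at the reference power law
    t = np.asarray(msd_t, float)
    y = np.asarray(msd_values, float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, y = t[sel], y[sel]
    C = float(np.exp(np.mean(np.log(y) - ref_alpha * np.log(t))))
    tau = (C * mapping.bead_um**2 / d_exp) ** (1.0 / ref_alpha)
    return {
        "tau_s": float(tau),
        "coefficient": C,
        "exponent": alpha,
        "warning": warning,
        "n_3d_per_1d": 1.25 / tau,
    }


def save_conformations(frames: list, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset(
            "coords", data=np.stack([fr.coords for fr in frames]),
            compression="gzip",
        )
        f.create_dataset("times", data=np.array([fr.time for fr in frames]))
        grp = f.create_group("bonds")
        for i, fr in enumerate(frames):
            grp.create_dataset(str(i), data=fr.bonds)


def frame_to_text(frame: PolymerConformation) -> str:
    """Minimal xyz-style text export of one conformation (b units)."""
    lines = [str(len(frame.coords)), f"t={frame.time}"]
    for i, (x, y, z) in enumerate(frame.coords):
        lines.append(f"M{i} {x:.4f} {y:.4f} {z:.4f}")
    return "\n".join(lines) + "\n"
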