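"""Structural observables: contact scaling, goodness-of-fit, in silico microscopy.

``contacts_and_ps`` turns an ensemble of polymer conformations into a contact
frequency versus genomic distance curve P(s): monomer pairs closer than a
capture radius (default 2.3 b ~ 115 nm, the typical Hi-C capture distance)
count as contacts, and contact probability is averaged within log-spaced
genomic separation bins.  ``r_squared`` scores a model curve against a
reference curve as 1 - SS_res/SS_tot with the mean taken over the reference,
evaluated on the reference grid over a stated genomic range (default
[50 kb, 10 Mb]).

``vermicelli_score`` emulates confocal imaging: DNA (all monomers) and
cohesin (loaded-extruder midpoints plus uniformly scattered diffusive
complexes matching the unloaded population) are rasterized into a 3D voxel
grid, blurred with a Gaussian approximating the point spread function, and
scored by the Pearson correlation of the two diffracted channels.  High
scores indicate chromatin organized around cohesin-rich axial cores
(vermicelli); near-zero scores indicate no colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

DEFAULT_CONTACT_RADIUS = 2.3  # b ~ 115 nm
DEFAULT_RANGE_BP = (5e4, 1e7)
DEFAULT_N_BINS = 4950


@dataclass
class PsCurve:
    """Contact probability versus genomic separation."""

    s_bp: np.ndarray  # bin centers (geometric), bp
    p: np.ndarray
    edges_bp: np.ndarray
    contact_radius: float = DEFAULT_CONTACT_RADIUS

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"s_bp": self.s_bp, "P": self.p})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        df = pd.read_csv(path)
        s = df.iloc[:, 0].to_numpy(float)
        p = df.iloc[:, 1].to_numpy(float)
        edges = np.sqrt(s[:-1] * s[1:])
        edges = np.concatenate([[s[0] ** 2 / edges[0]], edges,
                                [s[-1] ** 2 / edges[-1]]])
        return cls(s, p, edges)

    def interpolate(self, s_bp) -> np.ndarray:
        """Log-log interpolation onto another genomic grid."""
        valid = self.p > 0
        return np.exp(
            np.interp(
                np.log(s_bp), np.log(self.s_bp[valid]), np.log(self.p[valid])
            )
        )


def contacts_and_ps(
    frames,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
    n_bins: int = 60,
    site_bp: float = 2500.0,
    s_range_bp=None,
) -> PsCurve:
    """P(s) from an ensemble of conformations.

    Contacts are monomer pairs within ``contact_radius`` (b units, same frame);
    the diagonal is excluded and each unordered pair counts once.  Contact
    probability is normalized per valid pair per log-spaced bin, so system
    size cancels to leading order.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty conformation ensemble")
    n = len(frames[0].coords)
    if s_range_bp is None:
        s_range_bp = (site_bp, n * site_bp)
    edges_sites = np.geomspace(
        max(s_range_bp[0] / site_bp, 1.0), s_range_bp[1] / site_bp, n_bins + 1
    )
    counts = np.zeros(n_bins)
    for fr in frames:
        pairs = cKDTree(fr.coords).query_pairs(contact_radius, output_type="ndarray")
        if pairs.size:
            sep = np.abs(pairs[:, 1] - pairs[:, 0])
            counts += np.histogram(sep, bins=edges_sites)[0]
    # pairs at separation k in a chain of n monomers: n - k
    seps = np.arange(1, n)
    pair_counts = np.histogram(seps, bins=edges_sites, weights=(n - seps))[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(pair_counts > 0, counts / (pair_counts * len(frames)), np.nan)
    centers = np.sqrt(edges_sites[:-1] * edges_sites[1:]) * site_bp
    keep = pair_counts > 0
    return PsCurve(centers[keep], p[keep], edges_sites * site_bp, contact_radius)


def contact_map(frames, contact_radius=DEFAULT_CONTACT_RADIUS) -> np.ndarray:
    """Dense symmetric contact-count matrix summed over frames."""
    frames = list(frames)
    n = len(frames[0].coords)
    m = np.zeros((n, n))
    for fr in frames:
        pairs = cKDTree(fr.coords).query_pairs(contact_radius, output_type="ndarray")
        for i, j in pairs:
            m[i, j] += 1
            m[j, i] += 1
    return m


def r_squared(model: PsCurve, reference: PsCurve, s_range_bp=DEFAULT_RANGE_BP) -> float:
    """Goodness of fit of a model P(s) against a reference curve.

    ``R^2 = 1 - sum[(Pref - P)^2] / sum[(Pref - mean(Pref))^2]`` with sum and
    mean over the reference-grid points inside ``s_range_bp``.  The model is
    interpolated onto the reference grid in log-log space.
    """
    sel = (reference.s_bp >= s_range_bp[0]) & (reference.s_bp <= s_range_bp[1])
    sel &= np.isfinite(reference.p)
    if not sel.any():
        raise ValueError("reference curve does not overlap the genomic range")
    s = reference.s_bp[sel]
    if s.min() < model.s_bp.min() / 1.5 or s.max() > model.s_bp.max() * 1.5:
        raise ValueError("model curve does not cover the comparison range")
    pref = reference.p[sel]
    pmod = model.interpolate(s)
    ss_res = np.sum((pref - pmod) ** 2)
    ss_tot = np.sum((pref - pref.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


@dataclass
class MicroscopyConfig:
    """In silico confocal imaging parameters."""

    voxel_nm: float = 100.0
    n_voxels: int = 50  # per axis; 50 x 100 nm = 5 um field of view
    sigma_nm: float = 250.0  # Gaussian PSF standard deviation
    bead_nm: float = 50.0

    def __post_init__(self):
        if min(self.voxel_nm, self.n_voxels, self.sigma_nm, self.bead_nm) <= 0:
            raise ValueError("microscopy dimensions must be positive")

    @property
    def field_nm(self) -> float:
        return self.voxel_nm * self.n_voxels


def _rasterize(points_nm: np.ndarray, cfg: MicroscopyConfig) -> np.ndarray:
    edges = np.linspace(0.0, cfg.field_nm, cfg.n_voxels + 1)
    raster, _ = np.histogramdd(points_nm, bins=(edges, edges, edges))
    return raster


def raster_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two equally shaped rasters."""
    a, b = a.ravel(), b.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance channel; Pearson score undefined")
    return float(np.corrcoef(a, b)[0, 1])


def vermicelli_score(
    frames,
    unloaded_count: int,
    cfg: MicroscopyConfig | None = None,
    seed: int = 0,
) -> float:
    """Pearson colocalization of diffracted cohesin and DNA signal.

    The cohesin channel holds the midpoint of each loaded extruder's two leg
    monomers plus ``unloaded_count`` diffusive complexes placed uniformly in
    the field of view; the DNA channel holds every monomer.  Both channels
    are blurred with the Gaussian PSF before correlating; the returned score
    averages over frames.
    """
    cfg = cfg or MicroscopyConfig()
    rng = np.random.default_rng(seed)
    frames = list(frames)
    if not frames:
        raise ValueError("empty conformation ensemble")
    sigma_vox = cfg.sigma_nm / cfg.voxel_nm
    scores = []
    for fr in frames:
        xyz = fr.coords * cfg.bead_nm
        center = xyz.mean(axis=0)
        xyz = xyz - center + cfg.field_nm / 2.0
        dna = _rasterize(xyz, cfg)
        if len(fr.bonds):
            mid = 0.5 * (
                fr.coords[fr.bonds[:, 0]] + fr.coords[fr.bonds[:, 1]]
            ) * cfg.bead_nm - center + cfg.field_nm / 2.0
        else:
            mid = np.empty((0, 3))
        diffusive = rng.uniform(0.0, cfg.field_nm, size=(unloaded_count, 3))
        cohesin = _rasterize(np.vstack([mid, diffusive]), cfg)
        scores.append(
            raster_pearson(
                gaussian_filter(dna, sigma_vox), gaussian_filter(cohesin, sigma_vox)
            )
        )
    return float(np.mean(scores))
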