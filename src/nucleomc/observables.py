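"""Estimators over trajectories: chain size measures, size distributions,
radial distribution functions in spherical confinement, condensed-counterion
effective charges, and sub-batch uncertainties.

Two radius-of-gyration estimators coexist deliberately:

* :func:`radius_of_gyration` — the mean distance of the monomers to the chain
  center of mass, (1/N)Σ|ri−rCM|.  This is the quantity behind the size
  distributions P(RG).
* :func:`radius_of_gyration_rms` — the textbook root-mean-square form,
  sqrt((1/N)Σ|ri−rCM|²), used only for the Ree/Rg shape ratio.

RDFs are normalized by the analytic pair-distance density of two independent
uniform points in the confining sphere, so a non-interacting system gives
g(r)=1 at every r by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import bjerrum_length  # noqa: F401  (public re-export)
from .model_core import ParticleKind
from .sampler import Trajectory

__all__ = [
    "radius_of_gyration",
    "radius_of_gyration_rms",
    "end_to_end",
    "rg_series",
    "ree_series",
    "ree_rg_rms_ratio",
    "intra_dimer_separation",
    "HistogramSeries",
    "prg_histogram",
    "RdfCurve",
    "rdf",
    "effective_crowder_charge",
    "subbatch_errors",
    "bjerrum_length",
    "sphere_pair_distance_cdf",
]


def radius_of_gyration(coords: np.ndarray) -> float:
    """Mean distance of the monomers to their center of mass (Å)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 1:
        raise ValueError("need an (N, 3) coordinate array with N >= 1")
    com = coords.mean(axis=0)
    return float(np.mean(np.linalg.norm(coords - com, axis=1)))


def radius_of_gyration_rms(coords: np.ndarray) -> float:
    """Root-mean-square radius of gyration (Å)."""
    coords = np.asarray(coords, dtype=float)
    com = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - com) ** 2, axis=1))))


def end_to_end(coords: np.ndarray) -> float:
    """Distance between the first and last monomer (Å)."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 monomers")
    return float(np.linalg.norm(coords[0] - coords[-1]))


def _chain_members(traj: Trajectory, chain: int) -> np.ndarray:
    return np.array(traj.chains[chain].members, dtype=np.int64)


def rg_series(traj: Trajectory, chain: int = 0, rms: bool = False) -> np.ndarray:
    """Per-frame radius of gyration of one chain."""
    m = _chain_members(traj, chain)
    coords = traj.positions[:, m, :]
    com = coords.mean(axis=1, keepdims=True)
    d2 = np.sum((coords - com) ** 2, axis=2)
    if rms:
        return np.sqrt(d2.mean(axis=1))
    return np.sqrt(d2).mean(axis=1)


def ree_series(traj: Trajectory, chain: int = 0) -> np.ndarray:
    """Per-frame end-to-end distance of one chain."""
    m = _chain_members(traj, chain)
    return np.linalg.norm(
        traj.positions[:, m[0], :] - traj.positions[:, m[-1], :], axis=1
    )


def ree_rg_rms_ratio(traj: Trajectory, chain: int = 0) -> float:
    """RMS(Ree) / RMS(Rg): the chain-shape ratio (√12 ≈ 3.46 for a rod,
    √6 ≈ 2.45 for an ideal coil)."""
    ree2 = ree_series(traj, chain) ** 2
    rg2 = rg_series(traj, chain, rms=True) ** 2
    return float(math.sqrt(ree2.mean() / rg2.mean()))


def intra_dimer_separation(traj: Trajectory) -> tuple[float, float]:
    """Trajectory average (and sub-batch error) of the bonded monomer-monomer
    distance within every 2-member chain (protein dimer)."""
    pairs = [c.members for c in traj.chains if c.n_members == 2]
    if not pairs:
        raise ValueError("no dimers in this system")
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    d = np.linalg.norm(traj.positions[:, i, :] - traj.positions[:, j, :], axis=2)
    per_frame = d.mean(axis=1)
    return subbatch_errors(per_frame, traj.n_subbatches)


def subbatch_errors(series: np.ndarray, n_batches: int) -> tuple[float, float]:
    """Mean and standard error from block (sub-batch) averages of a
    correlated series: mean of batch means, std of batch means / √B."""
    series = np.asarray(series, dtype=float)
    if n_batches < 2:
        raise ValueError("need at least 2 sub-batches")
    if len(series) % n_batches != 0:
        raise ValueError(
            f"series length {len(series)} not divisible by {n_batches} batches"
        )
    bm = series.reshape(n_batches, -1).mean(axis=1)
    return float(bm.mean()), float(bm.std(ddof=1) / math.sqrt(n_batches))


# ---------------------------------------------------------------------------
# histograms


@dataclass
class HistogramSeries:
    """Normalized density histogram with per-bin sub-batch standard errors."""

    bin_edges: np.ndarray
    density: np.ndarray
    errors: np.ndarray
    batch_densities: np.ndarray  # (B, nbins)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mean(self) -> float:
        return float(np.sum(self.bin_centers * self.density) * self.bin_width)


def histogram_series(
    samples: np.ndarray, n_batches: int, bin_width: float,
    r_min: float = 0.0, r_max: float | None = None,
) -> HistogramSeries:
    """Density histogram of a scalar series, normalized to unit integral, with
    per-bin errors from sub-batch histograms."""
    samples = np.asarray(samples, dtype=float)
    if r_max is None:
        r_max = float(samples.max()) + bin_width
    edges = np.arange(r_min, r_max + bin_width, bin_width)
    batches = samples.reshape(n_batches, -1)
    dens = np.empty((n_batches, len(edges) - 1))
    for b in range(n_batches):
        counts, _ = np.histogram(batches[b], bins=edges)
        norm = counts.sum() * bin_width
        dens[b] = counts / norm if norm > 0 else 0.0
    density = dens.mean(axis=0)
    errors = dens.std(axis=0, ddof=1) / math.sqrt(n_batches)
    return HistogramSeries(edges, density, errors, dens)


def prg_histogram(
    traj: Trajectory, chain: int = 0, bin_width: float = 2.0
) -> HistogramSeries:
    """P(RG): probability distribution of the mean-distance radius of
    gyration of one chain, with sub-batch errors."""
    return histogram_series(rg_series(traj, chain), traj.n_subbatches, bin_width)


# ---------------------------------------------------------------------------
# radial distribution functions


def sphere_pair_distance_cdf(r: np.ndarray, r_cell: float) -> np.ndarray:
    """CDF of the distance between two independent uniform points in a sphere
    of radius ``r_cell`` (the ideal-gas reference for confined RDFs)."""
    x = np.clip(np.asarray(r, dtype=float) / r_cell, 0.0, 2.0)
    return x**3 - (9.0 / 16.0) * x**4 + x**6 / 32.0


@dataclass
class RdfCurve:
    """g(r) with the ideal-reference pair counts used for normalization."""

    r: np.ndarray
    g: np.ndarray
    g_err: np.ndarray
    ref_counts: np.ndarray  # expected ideal pairs per bin over all frames

    def as_table(self) -> np.ndarray:
        return np.column_stack([self.r, self.g, self.g_err])


def _pair_distances(frame: np.ndarray, ia: np.ndarray, ib: np.ndarray,
                    same: bool) -> np.ndarray:
    a = frame[ia]
    b = frame[ib]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    if same:
        iu = np.triu_indices(len(ia), k=1)
        return d[iu]
    return d.ravel()


def rdf(
    traj: Trajectory,
    kind_a: ParticleKind,
    kind_b: ParticleKind,
    bin_width: float = 0.25,
    r_max: float | None = None,
) -> RdfCurve:
    """Radial distribution function between two particle kinds, normalized by
    the analytic ideal-gas pair histogram for the same counts uniformly
    distributed in the confining sphere.  A=B pairs are counted once."""
    ia = traj.kind_indices(kind_a)
    ib = traj.kind_indices(kind_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(
            f"no particles of kind {kind_a!r} and/or {kind_b!r} in trajectory"
        )
    same = int(kind_a) == int(kind_b)
    if same and len(ia) < 2:
        raise ValueError("need at least 2 particles for a same-kind RDF")
    n_pairs = len(ia) * (len(ia) - 1) // 2 if same else len(ia) * len(ib)
    if r_max is None:
        r_max = 2.0 * traj.r_cell
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    cdf = sphere_pair_distance_cdf(edges, traj.r_cell)
    ref_per_frame = n_pairs * np.diff(cdf)

    n_frames = traj.n_frames
    n_batches = traj.n_subbatches if n_frames % traj.n_subbatches == 0 else 1
    per_batch = n_frames // n_batches
    g_batches = np.empty((n_batches, len(edges) - 1))
    total_counts = np.zeros(len(edges) - 1)
    valid = ref_per_frame > 0
    for b in range(n_batches):
        counts = np.zeros(len(edges) - 1)
        for f in range(b * per_batch, (b + 1) * per_batch):
            dist = _pair_distances(traj.positions[f], ia, ib, same)
            c, _ = np.histogram(dist, bins=edges)
            counts += c
        total_counts += counts
        with np.errstate(invalid="ignore", divide="ignore"):
            g_batches[b] = np.where(valid, counts / (per_batch * ref_per_frame), 0.0)
    g = g_batches.mean(axis=0)
    if n_batches > 1:
        g_err = g_batches.std(axis=0, ddof=1) / math.sqrt(n_batches)
    else:
        g_err = np.zeros_like(g)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdfCurve(centers[valid], g[valid], g_err[valid],
                    (n_frames * ref_per_frame)[valid])


# ---------------------------------------------------------------------------
# effective crowder charge


def effective_crowder_charge(
    traj: Trajectory, shell: float = 7.0
) -> tuple[float, float]:
    """Effective charge per crowder from the Bjerrum-shell criterion.

    Per frame, every positive counterion whose center lies within
    (crowder radius + ``shell``) of a crowder center is condensed, assigned to
    its nearest qualifying crowder (counted once; argmin breaks ties by lower
    index).  Zeff = Zcrow + ⟨condensed ions⟩/Ncrow, averaged over frames with
    sub-batch errors.
    """
    ic = traj.kind_indices(ParticleKind.CROWDER)
    ip = traj.kind_indices(ParticleKind.COUNTERION_POS)
    if len(ic) == 0:
        raise ValueError("no crowders in this system")
    if len(ip) == 0:
        raise ValueError("no positive counterions in this system")
    z_crow = float(traj.valences[ic[0]])
    cutoff = float(traj.radii[ic[0]]) + shell
    counts = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        p = traj.positions[f]
        d = np.linalg.norm(p[ip][:, None, :] - p[ic][None, :, :], axis=2)
        dmin = d.min(axis=1)
        counts[f] = np.count_nonzero(dmin <= cutoff)
    per_crowder = counts / len(ic)
    mean, err = subbatch_errors(per_crowder, traj.n_subbatches)
    return z_crow + mean, err
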