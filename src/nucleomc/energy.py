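"""Potential-energy model: primitive-model electrostatics with hard-sphere
cores, Lennard-Jones self-association between protein monomers, harmonic
bonds, angular stiffness of the DNA chain, and hard spherical confinement.

All energies are returned in kT.  Hard-core overlap and escape from the cell
are reported through the ``math.inf`` sentinel, decided geometrically before
any potential is evaluated (no floating-point overflow paths).

The functions here are the plain-numpy reference implementations; the MC
sampler uses compiled kernels (:mod:`nucleomc._kernels`) that are
cross-validated against these in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import ForceField, ParticleKind, SystemState

__all__ = [
    "EnergyBreakdown",
    "pair_electrostatic_hs",
    "lj_pair",
    "bond_energy",
    "angle_energy",
    "angle_deg",
    "total_energy",
    "move_energy_delta",
]

INF = math.inf


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy decomposition in kT; ``u_total`` is always the component sum."""

    u_elec_hs: float
    u_lj: float
    u_bond: float
    u_angle: float
    u_ext: float

    @property
    def u_total(self) -> float:
        return self.u_elec_hs + self.u_lj + self.u_bond + self.u_angle + self.u_ext

    @property
    def finite(self) -> bool:
        return math.isfinite(self.u_total)


def pair_electrostatic_hs(
    zi: float, zj: float, ri: float, rj: float, rij: float, lb: float
) -> float:
    """Coulomb interaction of two charged hard spheres in the dielectric
    continuum: infinity inside contact, lB·zi·zj/rij beyond."""
    if rij <= 0:
        raise ValueError("rij must be positive")
    if rij < ri + rj:
        return INF
    if zi == 0 or zj == 0:
        return 0.0
    return lb * zi * zj / rij


def lj_pair(rij: float, eps: float, sigma: float) -> float:
    """Lennard-Jones 12-6 potential, 4ε((σ/r)¹²−(σ/r)⁶), no cutoff."""
    if rij <= 0:
        raise ValueError("rij must be positive")
    if eps == 0.0:
        return 0.0
    x6 = (sigma / rij) ** 6
    return 4.0 * eps * (x6 * x6 - x6)


def bond_energy(rij: float, k: float, r0: float) -> float:
    """Harmonic bond, (k/2)(r−r0)²."""
    if rij <= 0:
        raise ValueError("rij must be positive")
    return 0.5 * k * (rij - r0) ** 2


def angle_energy(alpha: float, k: float, alpha0: float) -> float:
    """Harmonic angle term, (k/2)(α−α0)², angles in degrees."""
    return 0.5 * k * (alpha - alpha0) ** 2


def angle_deg(r_prev: np.ndarray, r_mid: np.ndarray, r_next: np.ndarray) -> float:
    """Chain angle in degrees at ``r_mid``: the angle between the bond vectors
    r_next−r_mid and r_prev−r_mid (180° for a straight chain)."""
    a = np.asarray(r_prev, dtype=float) - np.asarray(r_mid, dtype=float)
    b = np.asarray(r_next, dtype=float) - np.asarray(r_mid, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("degenerate (zero-length) bond vector")
    c = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _lj_pair_mask(state: SystemState, ff: ForceField) -> np.ndarray:
    """Boolean (N,N) mask of pairs subject to the protein self-association LJ
    term: all protein-monomer pairs, minus intra-dimer pairs if disabled."""
    is_hns = state.kinds == int(ParticleKind.HNS_MONOMER)
    mask = np.logical_and.outer(is_hns, is_hns)
    np.fill_diagonal(mask, False)
    if not ff.lj_intra:
        cid = state.chain_id_per_particle
        same_chain = (cid[:, None] == cid[None, :]) & (cid[:, None] >= 0)
        mask &= ~same_chain
    return mask


def total_energy(state: SystemState, ff: ForceField) -> EnergyBreakdown:
    """Full energy decomposition: electrostatics+hard spheres over all pairs,
    LJ over protein-monomer pairs, bonds, DNA angles, confinement."""
    pos = state.positions
    n = state.n_particles
    u_ext = 0.0
    if np.any(np.linalg.norm(pos, axis=1) >= state.r_cell):
        u_ext = INF

    u_elec = 0.0
    u_lj = 0.0
    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        iu = np.triu_indices(n, k=1)
        dij = d[iu]
        contact = (state.radii[:, None] + state.radii[None, :])[iu]
        if np.any(dij < contact):
            u_elec = INF
        else:
            q = state.valences.astype(float)
            qq = np.outer(q, q)[iu]
            nz = qq != 0
            u_elec = ff.bjerrum * float(np.sum(qq[nz] / dij[nz]))
        if ff.eps_pp > 0:
            ljm = _lj_pair_mask(state, ff)[iu]
            if np.any(ljm):
                x6 = (ff.sigma_pp / dij[ljm]) ** 6
                u_lj = 4.0 * ff.eps_pp * float(np.sum(x6 * x6 - x6))

    u_bond = 0.0
    u_angle = 0.0
    for ch in state.chains:
        for i, j in ch.bonds:
            u_bond += bond_energy(
                float(np.linalg.norm(pos[i] - pos[j])), ff.k_bond, ff.r0
            )
        for i, j, k in ch.angle_triples:
            u_angle += angle_energy(
                angle_deg(pos[i], pos[j], pos[k]), ff.k_ang, ff.alpha0
            )
    return EnergyBreakdown(u_elec, u_lj, u_bond, u_angle, u_ext)


def _partial_energy(
    state: SystemState, ff: ForceField, moved: np.ndarray, pos: np.ndarray
) -> float:
    """Sum of all energy terms that involve at least one moved particle,
    evaluated at coordinates ``pos``.  moved×moved pairs counted once."""
    moved_set = set(int(i) for i in moved)
    n = state.n_particles
    lb = ff.bjerrum
    q = state.valences.astype(float)
    rad = state.radii
    lj_mask = _lj_pair_mask(state, ff)

    u = 0.0
    for i in moved_set:
        if np.linalg.norm(pos[i]) >= state.r_cell:
            return INF
    for i in moved_set:
        for j in range(n):
            if j == i or (j in moved_set and j < i):
                continue
            rij = float(np.linalg.norm(pos[i] - pos[j]))
            if rij < rad[i] + rad[j]:  # geometric test first: covers rij == 0
                return INF
            if q[i] != 0 and q[j] != 0:
                u += lb * q[i] * q[j] / rij
            if ff.eps_pp > 0 and lj_mask[i, j]:
                u += lj_pair(rij, ff.eps_pp, ff.sigma_pp)
    for ch in state.chains:
        for i, j in ch.bonds:
            if i in moved_set or j in moved_set:
                u += bond_energy(
                    float(np.linalg.norm(pos[i] - pos[j])), ff.k_bond, ff.r0
                )
        for i, j, k in ch.angle_triples:
            if i in moved_set or j in moved_set or k in moved_set:
                u += angle_energy(
                    angle_deg(pos[i], pos[j], pos[k]), ff.k_ang, ff.alpha0
                )
    return u


def move_energy_delta(
    state: SystemState,
    ff: ForceField,
    moved: np.ndarray,
    new_positions: np.ndarray,
) -> float:
    """ΔU (kT) of displacing the particle subset ``moved`` to
    ``new_positions``, computing only terms that involve moved particles.

    Agrees with the brute-force total-energy difference to machine precision
    on finite states; ``inf`` propagates (the move will be rejected).
    """
    moved = np.atleast_1d(np.asarray(moved, dtype=np.int64))
    new_positions = np.atleast_2d(np.asarray(new_positions, dtype=float))
    if new_positions.shape != (len(moved), 3):
        raise ValueError("new_positions must have shape (len(moved), 3)")
    u_old = _partial_energy(state, ff, moved, state.positions)
    trial = state.positions.copy()
    trial[moved] = new_positions
    u_new = _partial_energy(state, ff, moved, trial)
    if u_new == INF:
        return INF
    if u_old == INF:
        # moving out of an invalid state; treat as strongly favorable
        return -INF
    return u_new - u_old
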