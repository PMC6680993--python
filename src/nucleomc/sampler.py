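"""Canonical-ensemble Metropolis Monte Carlo.

Three trial-move types: single-particle translations (attempted 100× more
often than the others), rigid translations of whole chains, and a slither
(reptation) move for the polymer chain in which a randomly chosen end monomer
is regrown at the opposite end with bond length and chain angle drawn from
their Boltzmann densities.  With that generation bias the bond and angle
Boltzmann factors cancel from the acceptance rule exactly, leaving only the
nonbonded and confinement energy in the Metropolis exponent.

A run is an equilibration phase (with optional amplitude auto-tuning toward
30–50% acceptance), followed by a production phase with frozen amplitudes,
sampled at a fixed stride and divided into sub-batches for uncertainties.
Runs are reproducible given the schedule seed; chunk seeds are derived from
it with a counter so a checkpointed run resumes bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernels
from .model_core import ChainTopology, ForceField, McSchedule, SystemState

__all__ = [
    "MoveSet",
    "Trajectory",
    "RunResult",
    "BookkeepingError",
    "metropolis_accept",
    "single_particle_move",
    "chain_translate_move",
    "slither_move",
    "SlitherProposal",
    "run_mc",
    "save_checkpoint",
    "load_checkpoint",
]

INF = math.inf

#: amplitude auto-tuning acceptance window and multipliers
_TUNE_LO, _TUNE_HI = 0.30, 0.50
_TUNE_UP, _TUNE_DOWN = 1.15, 0.85


class BookkeepingError(RuntimeError):
    """Accumulated-delta energy diverged from the recomputed total."""


@dataclass
class MoveSet:
    """Move amplitudes (Å), attempt weights and attempt/accept counters.

    Default weights 100:1:1 (single-particle : chain translation : slither).
    Single-particle moves carry two amplitudes: ``amp_monomer`` for chain
    monomers (bond constraints cap the useful step near the bond length) and
    ``amp_single`` for free particles (ions, crowders); each is tuned against
    its own acceptance rate.  Counters are a (4, 2) array
    [single-monomer, single-free, chain translation, slither] ×
    [attempted, accepted].
    """

    amp_single: float = 4.0
    amp_monomer: float = 2.0
    amp_chain: float = 10.0
    w_single: float = 100.0
    w_chain: float = 1.0
    w_slither: float = 1.0
    counters: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 2), dtype=np.int64)
    )

    def __post_init__(self) -> None:
        if min(self.w_single, self.w_chain, self.w_slither) < 0:
            raise ValueError("move weights must be non-negative")

    def acceptance_rates(self) -> np.ndarray:
        att = np.maximum(self.counters[:, 0], 1)
        return self.counters[:, 1] / att

    def probabilities(self, has_chains: bool, has_polymer: bool) -> tuple[float, float]:
        """(p_single, p_chain) after zeroing inapplicable move types; the
        slither probability is the remainder."""
        wc = self.w_chain if has_chains else 0.0
        ws = self.w_slither if has_polymer else 0.0
        total = self.w_single + wc + ws
        if total <= 0:
            raise ValueError("no applicable move type")
        return self.w_single / total, wc / total


def metropolis_accept(du: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis rule: accept with probability min(1, exp(−ΔU/kT));
    an infinite ΔU is always rejected."""
    if du == INF:
        return False
    if du <= 0.0:
        return True
    if du > 500.0:
        return False
    return rng.random() < math.exp(-du)


def single_particle_move(
    state: SystemState, particle: int, amplitude: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Propose a uniform displacement in a cube of side 2·amplitude
    (symmetric proposal).  Returns (moved indices, new positions)."""
    disp = rng.uniform(-amplitude, amplitude, size=3)
    return (
        np.array([particle], dtype=np.int64),
        state.positions[particle][None, :] + disp,
    )


def chain_translate_move(
    state: SystemState, chain: int, amplitude: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Propose one rigid displacement of every member of a chain; internal
    (bond/angle/intra-chain) terms are invariant under the move."""
    disp = rng.uniform(-amplitude, amplitude, size=3)
    members = np.array(state.chains[chain].members, dtype=np.int64)
    return members, state.positions[members] + disp


@dataclass(frozen=True)
class SlitherProposal:
    """Slither reconfiguration: end monomer ``removed`` regrown at position
    ``new_position`` on the opposite end.  ``new_chain_positions`` is the
    resulting ordered coordinate block of the chain.  ``gen_log_bias`` is the
    log of the generation-probability ratio; by construction it equals the
    bond+angle energy change, so the acceptance exponent reduces to
    −ΔU(nonbonded + confinement)."""

    removed: int
    new_position: np.ndarray
    new_chain_positions: np.ndarray
    from_head: bool
    bond_length: float
    chain_angle: float
    gen_log_bias: float


def slither_move(
    state: SystemState, chain: int, ff: ForceField, rng: np.random.Generator
) -> SlitherProposal:
    """Propose a slither move for a polymer chain of length ≥ 3.

    Trial bond length ~ p(r) ∝ r²·exp(−k_bond(r−r0)²/2); trial chain angle
    ~ p(α) ∝ sinα·exp(−k_ang(α−α0)²/2); azimuth uniform.
    """
    ch = state.chains[chain]
    if ch.n_members < 3:
        raise ValueError("slither requires a chain of length >= 3")
    members = np.array(ch.members, dtype=np.int64)
    pos = state.positions
    from_head = bool(rng.integers(2) == 0)
    if from_head:
        i_rm = members[0]
        anchor, anchor2 = members[-1], members[-2]
        old_nb, old_ang_m = members[1], members[1]
    else:
        i_rm = members[-1]
        anchor, anchor2 = members[0], members[1]
        old_nb, old_ang_m = members[-2], members[-2]

    u = pos[anchor] - pos[anchor2]
    u = u / np.linalg.norm(u)
    r = _draw_bond_length_py(ff.k_bond, ff.r0, rng)
    if ch.has_angles:
        alpha = _draw_chain_angle_py(ff.k_ang, ff.alpha0, rng)
    else:
        alpha = math.degrees(math.acos(rng.uniform(-1.0, 1.0)))
    theta = math.radians(180.0 - alpha)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    d = math.cos(theta) * u + math.sin(theta) * (
        math.cos(phi) * e1 + math.sin(phi) * e2
    )
    new_pos = pos[anchor] + r * d

    # generation log-bias == bond+angle energy change (analytic cancellation)
    from .energy import angle_deg, angle_energy, bond_energy

    r_old = float(np.linalg.norm(pos[i_rm] - pos[old_nb]))
    bias = bond_energy(r, ff.k_bond, ff.r0) - bond_energy(r_old, ff.k_bond, ff.r0)
    if ch.has_angles:
        a_old = angle_deg(pos[old_ang_m - 1], pos[old_ang_m], pos[old_ang_m + 1])
        bias += angle_energy(alpha, ff.k_ang, ff.alpha0) - angle_energy(
            a_old, ff.k_ang, ff.alpha0
        )

    block = pos[members].copy()
    if from_head:
        block[:-1] = block[1:]
        block[-1] = new_pos
    else:
        block[1:] = block[:-1]
        block[0] = new_pos
    return SlitherProposal(
        removed=int(i_rm),
        new_position=new_pos,
        new_chain_positions=block,
        from_head=from_head,
        bond_length=r,
        chain_angle=alpha,
        gen_log_bias=bias,
    )


def _draw_bond_length_py(k_bond: float, r0: float, rng: np.random.Generator) -> float:
    sigma = 1.0 / math.sqrt(k_bond)
    cap = r0 + 5.0 * sigma
    for _ in range(10000):
        r = r0 + rng.normal() * sigma
        if r <= 0.0:
            continue
        w = 1.0 if r >= cap else (r / cap) ** 2
        if rng.random() < w:
            return r
    return r0


def _draw_chain_angle_py(k_ang: float, alpha0: float, rng: np.random.Generator) -> float:
    if k_ang * 8100.0 < 1e-12:
        return math.degrees(math.acos(rng.uniform(-1.0, 1.0)))
    sigma = 1.0 / math.sqrt(k_ang)
    for _ in range(10000):
        a = alpha0 - abs(rng.normal() * sigma)
        if 0.0 <= a <= 180.0 and rng.random() < math.sin(math.radians(a)):
            return a
    return alpha0 - sigma


# ---------------------------------------------------------------------------
# run driver


@dataclass
class Trajectory:
    """Sampled production frames plus the static particle description."""

    positions: np.ndarray  # (F, N, 3)
    sweeps: np.ndarray  # (F,)
    energies: np.ndarray  # (F, 5): elec_hs, lj, bond, angle, ext
    kinds: np.ndarray
    valences: np.ndarray
    radii: np.ndarray
    chains: list[ChainTopology]
    r_cell: float
    n_subbatches: int

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def u_total(self) -> np.ndarray:
        return self.energies.sum(axis=1)

    def kind_indices(self, kind) -> np.ndarray:
        return np.flatnonzero(self.kinds == int(kind))


@dataclass
class RunResult:
    trajectory: Trajectory
    final_state: SystemState
    moveset: MoveSet
    schedule: McSchedule
    u_final: float
    max_drift: float


def _chunk_seed(master_seed: int, counter: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF,
                                spawn_key=(counter,))
    return int(ss.generate_state(1)[0] % (2**31))


def _kernel_energy(pos, ka, ff, r_cell):
    terms = _kernels.total_energy_arrays(
        pos, ka["charge"], ka["radius"], ka["chain_id"], ka["chain_start"],
        ka["chain_len"], ka["chain_has_angles"], ka["is_hns"], r_cell,
        ff.bjerrum, ff.eps_pp, ff.sigma_pp, ff.lj_intra,
        ff.k_bond, ff.r0, ff.k_ang, ff.alpha0,
    )
    return np.array(terms)


def run_mc(
    state: SystemState,
    ff: ForceField,
    schedule: McSchedule,
    moveset: MoveSet | None = None,
    checkpoint_path: str | None = None,
    restart: dict | None = None,
    drift_abort: float = 1e-3,
    log=None,
) -> RunResult:
    """Equilibrate, then run production sampling at the schedule's stride.

    The input ``state`` is not modified.  ``restart`` is a checkpoint dict
    from :func:`load_checkpoint`; the run resumes its remaining schedule and
    reproduces the uninterrupted run bit for bit.
    """
    if moveset is None:
        moveset = MoveSet()
    work = state.copy()
    ka = work.kernel_arrays()
    pos = work.positions
    n = work.n_particles
    has_chains = len(work.chains) > 0
    polymer = next(
        (c.chain_id for c in work.chains if c.has_angles and c.n_members >= 3), -1
    )
    p_single, p_chain = moveset.probabilities(has_chains, polymer >= 0)

    counters = moveset.counters
    u_acc = np.zeros(1)
    chunk_counter = 0
    equil_done = 0
    prod_done = 0
    if restart is not None:
        pos[:] = restart["positions"]
        u_acc[0] = restart["u_acc"]
        counters[:] = restart["counters"]
        chunk_counter = int(restart["chunk_counter"])
        equil_done = int(restart["equil_sweeps_done"])
        prod_done = int(restart["prod_sweeps_done"])
        moveset.amp_single = float(restart["amp_single"])
        moveset.amp_monomer = float(restart["amp_monomer"])
        moveset.amp_chain = float(restart["amp_chain"])
    else:
        e0 = _kernel_energy(pos, ka, ff, work.r_cell)
        if not np.isfinite(e0.sum()):
            raise ValueError("initial state has infinite energy")
        u_acc[0] = e0.sum()

    def _run(n_sweeps: int, amp_m: float, amp_s: float, amp_c: float) -> None:
        nonlocal chunk_counter
        _kernels.run_chunk(
            pos, ka["charge"], ka["radius"], ka["chain_id"], ka["chain_start"],
            ka["chain_len"], ka["chain_has_angles"], ka["is_hns"], work.r_cell,
            ff.bjerrum, ff.eps_pp, ff.sigma_pp, ff.lj_intra,
            ff.k_bond, ff.r0, ff.k_ang, ff.alpha0,
            n_sweeps * n, amp_m, amp_s, amp_c, p_single, p_chain, polymer,
            _chunk_seed(schedule.seed, chunk_counter), counters, u_acc,
        )
        chunk_counter += 1

    def _ckpt(path: str) -> None:
        save_checkpoint(
            path, work, u_acc[0], counters, chunk_counter,
            equil_done, prod_done, moveset, schedule,
        )

    # --- equilibration with optional amplitude tuning
    tune_chunk = max(10, schedule.equil_sweeps // 20)
    while equil_done < schedule.equil_sweeps:
        todo = min(tune_chunk, schedule.equil_sweeps - equil_done)
        before = counters.copy()
        _run(todo, moveset.amp_monomer, moveset.amp_single, moveset.amp_chain)
        equil_done += todo
        if schedule.tune_amplitudes:
            delta = counters - before
            for t, attr in ((0, "amp_monomer"), (1, "amp_single"),
                            (2, "amp_chain")):
                if delta[t, 0] == 0:
                    continue
                rate = delta[t, 1] / delta[t, 0]
                amp = getattr(moveset, attr)
                if rate > _TUNE_HI:
                    amp *= _TUNE_UP
                elif rate < _TUNE_LO:
                    amp *= _TUNE_DOWN
                setattr(moveset, attr, min(max(amp, 0.05), work.r_cell))

    # amplitudes are frozen from here on
    amp_monomer = moveset.amp_monomer
    amp_single = moveset.amp_single
    amp_chain = moveset.amp_chain

    # re-baseline the energy books after equilibration (production drift is
    # what the invariant constrains; equilibration already verified finiteness)
    e_eq = _kernel_energy(pos, ka, ff, work.r_cell)
    if not np.isfinite(e_eq.sum()):  # pragma: no cover - guarded by kernels
        raise BookkeepingError("infinite energy after equilibration")
    u_acc[0] = e_eq.sum()

    stride = schedule.sample_stride
    n_frames = schedule.prod_sweeps // stride if schedule.prod_sweeps else 1
    frames = np.empty((n_frames, n, 3))
    frame_sweeps = np.empty(n_frames, dtype=np.int64)
    frame_energies = np.empty((n_frames, 5))
    max_drift = 0.0

    if schedule.prod_sweeps == 0:
        frames[0] = pos
        frame_sweeps[0] = 0
        frame_energies[0] = e_eq
    else:
        f = prod_done // stride
        while prod_done < schedule.prod_sweeps:
            _run(stride, amp_monomer, amp_single, amp_chain)
            prod_done += stride
            e = _kernel_energy(pos, ka, ff, work.r_cell)
            drift = abs(e.sum() - u_acc[0])
            max_drift = max(max_drift, drift)
            if not np.isfinite(e.sum()) or drift > drift_abort:
                if checkpoint_path:
                    _ckpt(checkpoint_path)
                raise BookkeepingError(
                    f"energy bookkeeping drift {drift:.3e} kT at sweep "
                    f"{prod_done} (checkpoint dumped)"
                )
            frames[f] = pos
            frame_sweeps[f] = prod_done
            frame_energies[f] = e
            f += 1
            if (
                checkpoint_path
                and schedule.checkpoint_interval
                and prod_done % schedule.checkpoint_interval == 0
            ):
                _ckpt(checkpoint_path)
            if log is not None and f % max(1, n_frames // schedule.n_subbatches) == 0:
                rates = moveset.acceptance_rates()
                log(
                    f"sweep {prod_done}/{schedule.prod_sweeps} "
                    f"U={u_acc[0]:.2f} kT "
                    f"acc(monomer/free/chain/slither)="
                    f"{rates[0]:.2f}/{rates[1]:.2f}/{rates[2]:.2f}/"
                    f"{rates[3]:.2f}"
                )

    if checkpoint_path:
        _ckpt(checkpoint_path)

    if restart is not None:
        # only the resumed tail of the production was sampled here
        first = restart["prod_sweeps_done"] // stride
        frames = frames[first:]
        frame_sweeps = frame_sweeps[first:]
        frame_energies = frame_energies[first:]

    traj = Trajectory(
        positions=frames,
        sweeps=frame_sweeps,
        energies=frame_energies,
        kinds=work.kinds,
        valences=work.valences,
        radii=work.radii,
        chains=work.chains,
        r_cell=work.r_cell,
        n_subbatches=schedule.n_subbatches,
    )
    work.validate()
    return RunResult(
        trajectory=traj,
        final_state=work,
        moveset=moveset,
        schedule=schedule,
        u_final=float(u_acc[0]),
        max_drift=max_drift,
    )


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(
    path: str,
    state: SystemState,
    u_acc: float,
    counters: np.ndarray,
    chunk_counter: int,
    equil_sweeps_done: int,
    prod_sweeps_done: int,
    moveset: MoveSet,
    schedule: McSchedule,
) -> None:
    """Self-describing HDF5 checkpoint: coordinates, counters, RNG chunk
    counter, amplitudes and a schedule echo."""
    chain_meta = [
        {"chain_id": c.chain_id, "members": list(map(int, c.members)),
         "has_angles": c.has_angles}
        for c in state.chains
    ]
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=state.positions)
        f.create_dataset("kinds", data=state.kinds)
        f.create_dataset("valences", data=state.valences)
        f.create_dataset("radii", data=state.radii)
        f.create_dataset("counters", data=counters)
        f.attrs["u_acc"] = u_acc
        f.attrs["chunk_counter"] = chunk_counter
        f.attrs["equil_sweeps_done"] = equil_sweeps_done
        f.attrs["prod_sweeps_done"] = prod_sweeps_done
        f.attrs["amp_single"] = moveset.amp_single
        f.attrs["amp_monomer"] = moveset.amp_monomer
        f.attrs["amp_chain"] = moveset.amp_chain
        f.attrs["r_cell"] = state.r_cell
        f.attrs["seed"] = schedule.seed
        f.attrs["chains"] = json.dumps(chain_meta)
        f.attrs["schedule"] = json.dumps(
            {
                "equil_sweeps": schedule.equil_sweeps,
                "prod_sweeps": schedule.prod_sweeps,
                "n_subbatches": schedule.n_subbatches,
                "sample_stride": schedule.sample_stride,
                "seed": schedule.seed,
                "checkpoint_interval": schedule.checkpoint_interval,
            }
        )


def load_checkpoint(path: str) -> dict:
    """Load a checkpoint into the dict form accepted by ``run_mc(restart=)``."""
    with h5py.File(path, "r") as f:
        out = {
            "positions": f["positions"][...],
            "kinds": f["kinds"][...],
            "valences": f["valences"][...],
            "radii": f["radii"][...],
            "counters": f["counters"][...],
            "u_acc": float(f.attrs["u_acc"]),
            "chunk_counter": int(f.attrs["chunk_counter"]),
            "equil_sweeps_done": int(f.attrs["equil_sweeps_done"]),
            "prod_sweeps_done": int(f.attrs["prod_sweeps_done"]),
            "amp_single": float(f.attrs["amp_single"]),
            "amp_monomer": float(f.attrs["amp_monomer"]),
            "amp_chain": float(f.attrs["amp_chain"]),
            "r_cell": float(f.attrs["r_cell"]),
            "seed": int(f.attrs["seed"]),
            "chains": json.loads(f.attrs["chains"]),
            "schedule": json.loads(f.attrs["schedule"]),
        }
    return out
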