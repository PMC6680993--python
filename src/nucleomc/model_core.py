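"""Domain types and construction of valid initial systems.

The model cell is a sphere of radius ``r_cell`` containing, in the fully loaded
case: one bead-and-spring DNA chain (negatively charged hard-sphere monomers
with harmonic bonds and an angular stiffness), a number of protein dimers
(two positively charged monomers joined by one harmonic bond, mimicking the
DNA-binding sites of an H-NS dimer), spherical crowders with an optional
negative surface charge, and explicit monovalent counterions.  The solvent
enters only through its relative permittivity.

Counterion counts are never taken from user input: they are derived from the
fixed charges so that the cell is exactly electroneutral.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ALPHA0_DEFAULT,
    EPS_R_WATER,
    K_ANG_DEFAULT,
    K_BOND_DEFAULT,
    R0_DEFAULT,
    T_ROOM,
    bjerrum_length,
)

__all__ = [
    "ParticleKind",
    "ParticleSpec",
    "ChainTopology",
    "SystemState",
    "ForceField",
    "SystemConfig",
    "McSchedule",
    "build_system",
    "insert_free_particles",
    "topology_from_config",
    "charge_from_surface_density",
    "surface_density_from_charge",
    "crowder_count_from_volume_fraction",
    "PackingError",
]


class PackingError(RuntimeError):
    """Raised when random sequential insertion cannot place all particles."""


class ParticleKind(enum.IntEnum):
    DNA_MONOMER = 0
    HNS_MONOMER = 1
    CROWDER = 2
    COUNTERION_POS = 3
    COUNTERION_NEG = 4


#: Allowed valence signs per kind (DNA may be 0 for the neutral reference chain).
_VALENCE_SIGN = {
    ParticleKind.DNA_MONOMER: (-1, 0),
    ParticleKind.HNS_MONOMER: (1,),
    ParticleKind.CROWDER: (-1, 0),
    ParticleKind.COUNTERION_POS: (1,),
    ParticleKind.COUNTERION_NEG: (-1,),
}


@dataclass(frozen=True)
class ParticleSpec:
    """Immutable per-particle description: kind, hard-sphere radius (Å) and
    integer valence (units of e)."""

    kind: ParticleKind
    radius: float
    valence: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        sign = 0 if self.valence == 0 else int(math.copysign(1, self.valence))
        if sign not in _VALENCE_SIGN[self.kind]:
            raise ValueError(
                f"valence {self.valence} has wrong sign for kind {self.kind.name}"
            )


@dataclass(frozen=True)
class ChainTopology:
    """One linear chain: ordered, contiguous particle indices.

    Bonds connect consecutive members; angle triples (i-1, i, i+1) exist only
    for chains with ``has_angles`` (the DNA chain).  A protein dimer is a
    2-member chain with one bond and no angles.
    """

    chain_id: int
    members: tuple[int, ...]
    has_angles: bool = False

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a chain needs at least 2 members")
        diffs = np.diff(self.members)
        if not np.all(diffs == 1):
            raise ValueError("chain members must be contiguous ascending indices")
        if self.has_angles and len(self.members) < 3:
            raise ValueError("angle terms require at least 3 members")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def bonds(self) -> list[tuple[int, int]]:
        m = self.members
        return [(m[i], m[i + 1]) for i in range(len(m) - 1)]

    @property
    def angle_triples(self) -> list[tuple[int, int, int]]:
        if not self.has_angles:
            return []
        m = self.members
        return [(m[i - 1], m[i], m[i + 1]) for i in range(1, len(m) - 1)]


@dataclass
class ForceField:
    """All interaction parameters in internal units (kT, Å, deg).

    The Bjerrum length is always recomputed from ``eps_r`` and ``temperature``;
    it is deliberately not a stored field.  ``eps_pp`` is the depth (kT) of the
    Lennard-Jones self-association between protein monomers and ``sigma_pp``
    its size parameter; ``lj_intra`` controls whether the bonded intra-dimer
    pair also feels the LJ term.
    """

    k_bond: float = K_BOND_DEFAULT
    r0: float = R0_DEFAULT
    k_ang: float = K_ANG_DEFAULT
    alpha0: float = ALPHA0_DEFAULT
    eps_r: float = EPS_R_WATER
    temperature: float = T_ROOM
    eps_pp: float = 0.0
    sigma_pp: float = 5.8
    lj_intra: bool = True

    def __post_init__(self) -> None:
        if self.eps_pp < 0:
            raise ValueError("eps_pp must be >= 0")
        if self.eps_r <= 0 or self.temperature <= 0:
            raise ValueError("eps_r and temperature must be positive")

    @property
    def bjerrum(self) -> float:
        """Bjerrum length in Å, derived from eps_r and temperature."""
        return bjerrum_length(self.eps_r, self.temperature)

    @classmethod
    def from_config(cls, config: "SystemConfig") -> "ForceField":
        return cls(
            k_bond=config.k_bond,
            r0=config.r0,
            k_ang=config.k_ang,
            alpha0=config.alpha0,
            eps_r=config.eps_r,
            temperature=config.temperature,
            eps_pp=config.eps_pp,
            sigma_pp=config.sigma_pp,
            lj_intra=config.lj_intra,
        )


@dataclass
class SystemState:
    """Coordinates plus the static description of every particle.

    positions: (N, 3) Cartesian Å, origin at the cell center.
    kinds/valences/radii: per-particle arrays aligned with positions.
    chains: chain topologies over contiguous index ranges.
    """

    positions: np.ndarray
    kinds: np.ndarray
    valences: np.ndarray
    radii: np.ndarray
    chains: list[ChainTopology]
    r_cell: float

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def kind_indices(self, kind: ParticleKind) -> np.ndarray:
        return np.flatnonzero(self.kinds == int(kind))

    @property
    def chain_id_per_particle(self) -> np.ndarray:
        cid = np.full(self.n_particles, -1, dtype=np.int64)
        for ch in self.chains:
            cid[list(ch.members)] = ch.chain_id
        return cid

    def kernel_arrays(self) -> dict[str, np.ndarray]:
        """Flat array view of the topology for the compiled MC kernels."""
        n_chains = len(self.chains)
        start = np.zeros(n_chains, dtype=np.int64)
        length = np.zeros(n_chains, dtype=np.int64)
        has_ang = np.zeros(n_chains, dtype=np.bool_)
        for i, ch in enumerate(self.chains):
            if ch.chain_id != i:
                raise ValueError("chain ids must be 0..n_chains-1 in order")
            start[i] = ch.members[0]
            length[i] = ch.n_members
            has_ang[i] = ch.has_angles
        return {
            "chain_id": self.chain_id_per_particle,
            "chain_start": start,
            "chain_len": length,
            "chain_has_angles": has_ang,
            "is_hns": self.kinds == int(ParticleKind.HNS_MONOMER),
            "charge": self.valences.astype(np.float64),
            "radius": self.radii.astype(np.float64),
        }

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            kinds=self.kinds.copy(),
            valences=self.valences.copy(),
            radii=self.radii.copy(),
            chains=list(self.chains),
            r_cell=self.r_cell,
        )

    def validate(self, overlap_tol: float = 1e-9) -> None:
        """Assert the hard invariants: confinement of every center, exact
        electroneutrality, and no hard-sphere overlap."""
        r = np.linalg.norm(self.positions, axis=1)
        if np.any(r >= self.r_cell):
            worst = int(np.argmax(r))
            raise ValueError(
                f"particle {worst} outside the cell: |r|={r[worst]:.3f} >= "
                f"Rcell={self.r_cell}"
            )
        if int(self.valences.sum()) != 0:
            raise ValueError(
                f"system is not electroneutral: total valence {self.valences.sum()}"
            )
        n = self.n_particles
        if n > 1:
            d = np.linalg.norm(
                self.positions[:, None, :] - self.positions[None, :, :], axis=-1
            )
            contact = self.radii[:, None] + self.radii[None, :]
            iu = np.triu_indices(n, k=1)
            bad = d[iu] < contact[iu] - overlap_tol
            if np.any(bad):
                k = int(np.flatnonzero(bad)[0])
                i, j = iu[0][k], iu[1][k]
                raise ValueError(
                    f"hard-sphere overlap between particles {i} and {j}: "
                    f"d={d[i, j]:.4f} < {contact[i, j]:.4f}"
                )


@dataclass
class McSchedule:
    """Monte Carlo schedule in sweeps (1 sweep = N trial moves, N = particle
    count, matching the 'trial moves per particle' accounting)."""

    equil_sweeps: int = 1000
    prod_sweeps: int = 5000
    n_subbatches: int = 10
    sample_stride: int = 10
    seed: int = 0
    checkpoint_interval: int = 0  # sweeps; 0 disables periodic checkpoints
    tune_amplitudes: bool = True

    def __post_init__(self) -> None:
        if self.n_subbatches < 1:
            raise ValueError("need at least one sub-batch")
        if self.prod_sweeps > 0:
            block = self.sample_stride * self.n_subbatches
            if self.prod_sweeps % block != 0:
                raise ValueError(
                    f"prod_sweeps={self.prod_sweeps} must be divisible by "
                    f"sample_stride*n_subbatches={block}"
                )


@dataclass
class SystemConfig:
    """Fully resolved description of one system plus its MC schedule.

    Defaults are the reference cell: Rcell=100 Å, 120 DNA monomers of valence
    −1 and radius 2 Å, harmonic bonds (0.4 N/m, r0=5 Å) and angular stiffness
    (3.4e−24 J/deg², α0=180°), protein dimers of valence +1 per monomer,
    crowders of radius 10 Å, counterion radius 2 Å.
    """

    r_cell: float = 100.0
    seed: int = 0
    # DNA chain
    n_dna: int = 120
    dna_radius: float = 2.0
    dna_valence: int = -1
    # protein dimers
    n_hns: int = 0
    hns_radius: float = 2.0
    hns_valence: int = 1
    eps_pp: float = 0.0
    sigma_pp: float = 5.8
    lj_intra: bool = True
    # crowders
    n_crow: int = 0
    crow_radius: float = 10.0
    z_crow: int = 0
    # counterions
    ct_radius: float = 2.0
    # force field
    eps_r: float = EPS_R_WATER
    temperature: float = T_ROOM
    k_bond: float = K_BOND_DEFAULT
    r0: float = R0_DEFAULT
    k_ang: float = K_ANG_DEFAULT
    alpha0: float = ALPHA0_DEFAULT
    # schedule
    mc: McSchedule = field(default_factory=McSchedule)
    # observables
    prg_bin: float = 2.0
    rdf_bin: float = 0.25
    zeff_shell: float = 7.0

    def counterion_counts(self) -> tuple[int, int]:
        """(N+, N−) derived from electroneutrality: positive ions neutralize
        DNA and crowder charge, negative ions neutralize the protein charge."""
        n_pos = abs(self.n_dna * self.dna_valence) + abs(self.n_crow * self.z_crow)
        n_neg = self.n_hns * 2 * self.hns_valence
        return n_pos, n_neg

    def replace(self, **kw) -> "SystemConfig":
        return dataclasses.replace(self, **kw)


def insert_free_particles(
    state: SystemState,
    additions: list[tuple[ParticleKind, int, float, int]],
    seed: int,
    max_attempts: int = 20000,
) -> SystemState:
    """Insert free (chain-less) particles into an existing configuration.

    ``additions`` is a list of (kind, count, radius, valence) groups, placed
    by random sequential insertion without overlap.  The combined particle
    set is reordered into the canonical kind order (chain particles keep
    their indices; free particles are sorted by kind), so estimators and
    kernels see the same layout as a freshly built system.  Useful for
    staging protocols, e.g. adding crowders to a pre-formed complex.
    """
    rng = np.random.default_rng(seed)
    n_new = sum(count for _, count, _, _ in additions)
    n_old = state.n_particles
    ins = _Inserter(n_old + n_new, state.r_cell)
    ins.pos[:n_old] = state.positions
    ins.rad[:n_old] = state.radii
    ins.count = n_old
    kinds = list(state.kinds)
    valences = list(state.valences)
    radii = list(state.radii)
    for kind, count, radius, valence in additions:
        for _ in range(count):
            for _ in range(max_attempts):
                p = _random_point_in_sphere(rng, state.r_cell)
                if ins.ok(p, radius):
                    ins.add(p, radius)
                    break
            else:
                raise PackingError(
                    f"could not insert a {ParticleKind(kind).name}; achieved "
                    f"{ins.count}/{n_old + n_new} particles"
                )
            kinds.append(int(kind))
            valences.append(valence)
            radii.append(radius)

    in_chain = np.zeros(n_old + n_new, dtype=bool)
    for ch in state.chains:
        in_chain[list(ch.members)] = True
    free = np.flatnonzero(~in_chain)
    kinds_arr = np.array(kinds, dtype=np.int8)
    order = np.concatenate(
        [np.flatnonzero(in_chain),
         free[np.argsort(kinds_arr[free], kind="stable")]]
    )
    new_state = SystemState(
        positions=ins.pos[order].copy(),
        kinds=kinds_arr[order],
        valences=np.array(valences, dtype=np.int64)[order],
        radii=np.array(radii, dtype=np.float64)[order],
        chains=list(state.chains),
        r_cell=state.r_cell,
    )
    new_state.validate()
    return new_state


def charge_from_surface_density(sigma: float, radius: float) -> int:
    """Integer valence of a sphere with surface charge density ``sigma``
    (e/nm²) and radius in Å: round(sigma · 4π(radius/10)²)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return int(np.rint(sigma * 4.0 * math.pi * (radius / 10.0) ** 2))


def surface_density_from_charge(valence: int, radius: float) -> float:
    """Inverse map: surface charge density in e/nm² for an integer valence."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return valence / (4.0 * math.pi * (radius / 10.0) ** 2)


def crowder_count_from_volume_fraction(
    phi: float, r_crow: float, r_cell: float
) -> int:
    """Number of crowders occupying volume fraction ``phi`` of the cell:
    round(phi · (r_cell/r_crow)³)."""
    if not 0 <= phi < 0.3:
        raise ValueError("phi must be in [0, 0.3)")
    if r_crow <= 0 or r_cell <= 0:
        raise ValueError("radii must be positive")
    return int(np.rint(phi * (r_cell / r_crow) ** 3))


# ---------------------------------------------------------------------------
# system construction


def _random_point_in_sphere(rng: np.random.Generator, r_max: float) -> np.ndarray:
    while True:
        p = rng.uniform(-r_max, r_max, size=3)
        if p @ p < r_max * r_max:
            return p


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _sample_chain_angle(rng: np.random.Generator, k_ang: float, alpha0: float) -> float:
    """Draw a chain angle (deg) from p(α) ∝ sinα · exp(−k_ang(α−α0)²/2)."""
    if k_ang * 90.0**2 < 1e-12:  # effectively free angle
        return math.degrees(math.acos(rng.uniform(-1.0, 1.0)))
    sigma = 1.0 / math.sqrt(k_ang)
    for _ in range(10000):
        alpha = alpha0 - abs(rng.normal(0.0, sigma))
        if not 0.0 <= alpha <= 180.0:
            continue
        if rng.random() < math.sin(math.radians(alpha)):
            return alpha
    return alpha0 - sigma  # pathological parameters; any valid angle works


def _direction_at_angle(
    rng: np.random.Generator, prev_dir: np.ndarray, alpha: float
) -> np.ndarray:
    """Unit vector making chain angle ``alpha`` (deg) with the previous bond
    (α=180° means straight continuation), uniform azimuth."""
    theta = math.radians(180.0 - alpha)  # polar angle from prev_dir
    phi = rng.uniform(0.0, 2.0 * math.pi)
    a = np.array([1.0, 0.0, 0.0]) if abs(prev_dir[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(prev_dir, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(prev_dir, e1)
    return (
        math.cos(theta) * prev_dir
        + math.sin(theta) * (math.cos(phi) * e1 + math.sin(phi) * e2)
    )


class _Inserter:
    """Random sequential insertion bookkeeping with O(N) overlap checks."""

    def __init__(self, n_total: int, r_cell: float):
        self.pos = np.empty((n_total, 3))
        self.rad = np.empty(n_total)
        self.count = 0
        self.r_cell = r_cell

    def ok(self, p: np.ndarray, radius: float) -> bool:
        if p @ p >= self.r_cell**2:
            return False
        if self.count == 0:
            return True
        d2 = np.sum((self.pos[: self.count] - p) ** 2, axis=1)
        contact = self.rad[: self.count] + radius
        return bool(np.all(d2 >= contact * contact))

    def add(self, p: np.ndarray, radius: float) -> None:
        self.pos[self.count] = p
        self.rad[self.count] = radius
        self.count += 1

    def pop(self, n: int) -> None:
        self.count -= n


def _grow_chain(
    inserter: _Inserter,
    rng: np.random.Generator,
    n_mon: int,
    radius: float,
    r0: float,
    k_ang: float,
    alpha0: float,
    max_restarts: int = 200,
    tries_per_monomer: int = 200,
) -> np.ndarray | None:
    """Grow a non-overlapping connected walk inside the cell.

    Bond lengths are fixed at r0; directions are drawn from the angular
    Boltzmann weight (straight-chain bias) and relaxed to uniform after
    repeated boundary/overlap failures.  Equilibration erases the initial
    conformation, so only validity matters here.
    """
    for _ in range(max_restarts):
        placed = 0
        start = _random_point_in_sphere(rng, inserter.r_cell * 0.9)
        if not inserter.ok(start, radius):
            continue
        inserter.add(start, radius)
        placed = 1
        prev_dir = _random_unit_vector(rng)
        failed = False
        while placed < n_mon:
            here = inserter.pos[inserter.count - 1]
            success = False
            for attempt in range(tries_per_monomer):
                if placed == 1:
                    d = _random_unit_vector(rng)
                elif attempt < tries_per_monomer // 2:
                    alpha = _sample_chain_angle(rng, k_ang, alpha0)
                    d = _direction_at_angle(rng, prev_dir, alpha)
                else:  # relax the stiffness bias near the wall
                    d = _random_unit_vector(rng)
                p = here + r0 * d
                if inserter.ok(p, radius):
                    inserter.add(p, radius)
                    prev_dir = d
                    placed += 1
                    success = True
                    break
            if not success:
                failed = True
                break
        if not failed:
            return inserter.pos[inserter.count - n_mon : inserter.count].copy()
        inserter.pop(placed)
    return None


def topology_from_config(
    config: SystemConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[ChainTopology]]:
    """(kinds, valences, radii, chains) implied by a config, in the canonical
    particle order: DNA chain, protein dimers, crowders, positive counterions,
    negative counterions.  Counterion counts derive from electroneutrality."""
    n_pos, n_neg = config.counterion_counts()
    n_total = config.n_dna + 2 * config.n_hns + config.n_crow + n_pos + n_neg
    kinds = np.empty(n_total, dtype=np.int8)
    valences = np.empty(n_total, dtype=np.int64)
    radii = np.empty(n_total, dtype=np.float64)
    chains: list[ChainTopology] = []
    cursor = 0
    chain_id = 0
    if config.n_dna > 0:
        idx = range(cursor, cursor + config.n_dna)
        kinds[idx] = ParticleKind.DNA_MONOMER
        valences[idx] = config.dna_valence
        radii[idx] = config.dna_radius
        chains.append(ChainTopology(chain_id, tuple(idx), has_angles=True))
        chain_id += 1
        cursor += config.n_dna
    for _ in range(config.n_hns):
        idx = range(cursor, cursor + 2)
        kinds[idx] = ParticleKind.HNS_MONOMER
        valences[idx] = config.hns_valence
        radii[idx] = config.hns_radius
        chains.append(ChainTopology(chain_id, tuple(idx), has_angles=False))
        chain_id += 1
        cursor += 2
    for count, radius, kind, valence in (
        (config.n_crow, config.crow_radius, ParticleKind.CROWDER, config.z_crow),
        (n_pos, config.ct_radius, ParticleKind.COUNTERION_POS, 1),
        (n_neg, config.ct_radius, ParticleKind.COUNTERION_NEG, -1),
    ):
        idx = range(cursor, cursor + count)
        kinds[idx] = kind
        valences[idx] = valence
        radii[idx] = radius
        cursor += count
    return kinds, valences, radii, chains


def build_system(config: SystemConfig) -> SystemState:
    """Construct a valid initial :class:`SystemState` from a config.

    Particle order: DNA chain, protein dimers, crowders, positive counterions,
    negative counterions.  Counterion counts are derived from electroneutrality.
    Placement is random sequential insertion (the DNA grown as a connected
    walk); deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_pos, n_neg = config.counterion_counts()
    radii_by_group = [
        (config.n_dna, config.dna_radius),
        (config.n_hns * 2, config.hns_radius),
        (config.n_crow, config.crow_radius),
        (n_pos, config.ct_radius),
        (n_neg, config.ct_radius),
    ]
    n_total = sum(n for n, _ in radii_by_group)
    if n_total == 0:
        raise ValueError("empty system")
    largest = max(r for n, r in radii_by_group if n > 0)
    if config.r_cell <= largest:
        raise ValueError(
            f"cell radius {config.r_cell} Å not larger than the largest "
            f"particle radius {largest} Å"
        )

    ins = _Inserter(n_total, config.r_cell)
    kinds, valences, radii, chains = topology_from_config(config)

    def _fail(what: str) -> None:
        frac = ins.count / n_total
        raise PackingError(
            f"could not insert {what}; achieved packing fraction "
            f"{frac:.1%} of {n_total} particles"
        )

    if config.n_dna > 0:
        coords = _grow_chain(
            ins, rng, config.n_dna, config.dna_radius, config.r0,
            config.k_ang, config.alpha0,
        )
        if coords is None:
            _fail("the DNA chain")

    for _ in range(config.n_hns):
        coords = _grow_chain(
            ins, rng, 2, config.hns_radius, config.r0, 0.0, config.alpha0
        )
        if coords is None:
            _fail("a protein dimer")

    free_groups = [
        (config.n_crow, config.crow_radius, "a crowder"),
        (n_pos, config.ct_radius, "a positive counterion"),
        (n_neg, config.ct_radius, "a negative counterion"),
    ]
    for count, radius, label in free_groups:
        for _ in range(count):
            for _ in range(20000):
                p = _random_point_in_sphere(rng, config.r_cell)
                if ins.ok(p, radius):
                    ins.add(p, radius)
                    break
            else:
                _fail(label)

    state = SystemState(
        positions=ins.pos,
        kinds=kinds,
        valences=valences,
        radii=radii,
        chains=chains,
        r_cell=config.r_cell,
    )
    state.validate()
    return state
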