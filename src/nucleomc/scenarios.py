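"""Programmatic generator of every studied system composition.

Every scenario resolves to a fully specified :class:`SystemConfig` built from
the reference cell (Rcell=100 Å, 120 DNA monomers, 60 protein dimers at
charge-ratio unity, crowders of radius 10 Å at volume fraction 0.06, explicit
monovalent counterions).  Scale ``"full"`` carries the full-length MC
schedule (2×10⁶ equilibration + 6×10⁶ production sweeps); scale ``"reduced"``
shrinks only the sampling length — never the composition or the physics — to
desk-scale runs with correspondingly larger error bars.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

from .model_core import (
    McSchedule,
    SystemConfig,
    charge_from_surface_density,
    crowder_count_from_volume_fraction,
)

__all__ = [
    "SCENARIO_TAGS",
    "SIGMA_CROW_GRID",
    "PHI_CROW_GRID",
    "EPS_PP_GRID",
    "ScenarioId",
    "reference_scenario",
    "scenario_grid",
    "scenario_seed",
]

#: crowder surface charge densities, e/nm² (−0.04 and −0.08 both studied)
SIGMA_CROW_GRID = (0.0, -0.04, -0.08, -0.40, -0.80, -1.20)
#: crowder volume fractions
PHI_CROW_GRID = (0.0, 0.06, 0.16, 0.20)
#: protein self-association strengths, kT
EPS_PP_GRID = (0.0, 1.0, 2.0)

SCENARIO_TAGS = (
    "dna_only",
    "dna_neutral_reference",
    "dna_crowders",
    "dna_hns",
    "dna_hns_crowders",
    "hns_only",
    "hns_crowders",
    "crowder_radius_variant",
)

_FULL = dict(equil_sweeps=2_000_000, prod_sweeps=6_000_000,
             n_subbatches=10, sample_stride=100)
_REDUCED = dict(equil_sweeps=2000, prod_sweeps=20_000,
                n_subbatches=10, sample_stride=10)


@dataclass(frozen=True)
class ScenarioId:
    """A scenario tag with its physical variations."""

    tag: str
    eps_pp: float = 0.0
    sigma_crow: float = 0.0
    phi_crow: float = 0.06
    r_crow: float = 10.0

    def __post_init__(self) -> None:
        if self.tag not in SCENARIO_TAGS:
            raise ValueError(
                f"unknown scenario tag {self.tag!r}; known: {SCENARIO_TAGS}"
            )

    def label(self) -> str:
        parts = [self.tag]
        if "crowder" in self.tag or "crowders" in self.tag:
            parts.append(f"phi={self.phi_crow:g}")
            parts.append(f"sigma={self.sigma_crow:g}")
            if self.r_crow != 10.0:
                parts.append(f"Rcrow={self.r_crow:g}")
        if "hns" in self.tag:
            parts.append(f"epp={self.eps_pp:g}")
        return ",".join(parts)


def scenario_seed(label: str) -> int:
    """Deterministic seed for a scenario: first 4 bytes of sha256(label)."""
    h = hashlib.sha256(label.encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def reference_scenario(sid: ScenarioId | str, scale: str = "reduced",
                       seed: int | None = None) -> SystemConfig:
    """Resolve a scenario id to a fully specified :class:`SystemConfig`.

    ``scale`` is "full" (full-length schedule) or "reduced"
    (desk-scale schedule, identical composition).
    """
    if isinstance(sid, str):
        sid = ScenarioId(sid)
    if scale not in ("full", "reduced"):
        raise ValueError("scale must be 'full' or 'reduced'")
    sched_kw = dict(_FULL if scale == "full" else _REDUCED)
    if seed is None:
        seed = scenario_seed(sid.label())
    sched = McSchedule(seed=seed, **sched_kw)

    cfg = SystemConfig(seed=seed, mc=sched)
    tag = sid.tag
    with_dna = tag.startswith("dna") or tag == "crowder_radius_variant"
    with_hns = "hns" in tag
    with_crow = "crowders" in tag or tag == "crowder_radius_variant"

    if not with_dna:
        cfg = cfg.replace(n_dna=0)
    if tag == "dna_neutral_reference":
        cfg = cfg.replace(dna_valence=0)
    if with_hns:
        cfg = cfg.replace(n_hns=60, eps_pp=sid.eps_pp)
    if with_crow:
        n_crow = crowder_count_from_volume_fraction(
            sid.phi_crow, sid.r_crow, cfg.r_cell
        )
        z = charge_from_surface_density(sid.sigma_crow, sid.r_crow)
        cfg = cfg.replace(n_crow=n_crow, crow_radius=sid.r_crow, z_crow=z)
    return cfg


def scenario_grid(
    tags: tuple[str, ...] | None = None,
    eps_pp: tuple[float, ...] | None = None,
    sigma_crow: tuple[float, ...] | None = None,
    phi_crow: tuple[float, ...] | None = None,
    scale: str = "reduced",
) -> list[SystemConfig]:
    """Cartesian grid of scenarios, deduplicated, each with its deterministic
    derived seed.  Filters restrict each axis; None means the full grid."""
    tags = tags or ("dna_crowders", "dna_hns", "dna_hns_crowders",
                    "hns_only", "hns_crowders")
    eps_grid = eps_pp or EPS_PP_GRID
    sig_grid = sigma_crow or SIGMA_CROW_GRID
    phi_grid = phi_crow or PHI_CROW_GRID
    seen: set[tuple] = set()
    out: list[SystemConfig] = []
    for tag in tags:
        has_crow = "crowders" in tag or tag == "crowder_radius_variant"
        has_hns = "hns" in tag
        eps_axis = eps_grid if has_hns else (0.0,)
        sig_axis = sig_grid if has_crow else (0.0,)
        phi_axis = phi_grid if has_crow else (0.0,)
        for e, s, p in itertools.product(eps_axis, sig_axis, phi_axis):
            if has_crow and p == 0.0:
                continue  # no crowders: covered by the crowder-free tag
            sid = ScenarioId(tag, eps_pp=e, sigma_crow=s, phi_crow=p)
            cfg = reference_scenario(sid, scale=scale)
            # dedupe on the resolved composition: nearby surface charge
            # densities can round to the same integer valence
            key = (cfg.n_dna, cfg.dna_valence, cfg.n_hns, cfg.eps_pp,
                   cfg.n_crow, cfg.z_crow, cfg.crow_radius)
            if key in seen:
                continue
            seen.add(key)
            out.append(cfg)
    return out
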