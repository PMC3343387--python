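"""Displaced-solvent scoring of ligand poses against a hydration-site map.

The binding free-energy estimate is the sum, over hydration sites displaced
by the ligand, of each site's water-transfer free energy:

    dG_bind = sum_s  w_s * dG_transfer,s

where the displacement weight ``w_s`` depends on the minimum distance
``d_min`` from the site center to any used ligand atom and the cutoff
``Rco`` (default 2.24 A):

* ``step``  (default): w = 1 if d_min < Rco else 0 — the Heaviside reading;
* ``ramp``: w = max(0, 1 - d_min / Rco) — a linear taper to the cutoff.

A site displaced by several atoms contributes once (the weight is capped at
1): the sum runs over sites, not atom-site pairs.  By default only heavy
ligand atoms count, since hydration sites are oxygen-position clusters and
hydrogen positions in typical input structures are modeled rather than
observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hydration_cluster import HydrationSite

logger = logging.getLogger("solvsite")

DEFAULT_RCO = 2.24


@dataclass(frozen=True)
class LigandPose:
    """Heavy-atom (plus optional hydrogen) coordinates of one ligand pose."""

    name: str
    atoms: tuple[tuple[str, tuple[float, float, float]], ...]  # (element, xyz)

    def __post_init__(self):
        if not any(el != "H" for el, _ in self.atoms):
            raise ValueError(f"pose {self.name!r} has no heavy atoms")

    def positions(self, atoms_used: str = "heavy") -> np.ndarray:
        if atoms_used == "heavy":
            pts = [p for el, p in self.atoms if el != "H"]
        elif atoms_used == "all":
            pts = [p for _, p in self.atoms]
        else:
            raise ValueError(f"atoms_used must be 'heavy' or 'all', got {atoms_used!r}")
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    @classmethod
    def from_structure(cls, structure, name: str,
                       res_name: str | None = None) -> "LigandPose":
        atoms = structure.atoms if res_name is None else \
            [a for a in structure.atoms if a.res_name == res_name]
        return cls(name=name,
                   atoms=tuple((a.element, a.position) for a in atoms))


@dataclass(frozen=True)
class DisplacementConfig:
    Rco: float = DEFAULT_RCO
    functional: str = "step"     # "step" | "ramp"
    atoms_used: str = "heavy"    # "heavy" | "all"

    def __post_init__(self):
        if self.Rco <= 0:
            raise ValueError("Rco must be positive")
        if self.functional not in ("step", "ramp"):
            raise ValueError(f"unknown functional {self.functional!r}")
        if self.atoms_used not in ("heavy", "all"):
            raise ValueError(f"unknown atoms_used {self.atoms_used!r}")


@dataclass
class SiteContribution:
    site_index: int
    d_min: float
    weight: float
    dG_transfer: float

    @property
    def contribution(self) -> float:
        return self.weight * self.dG_transfer


@dataclass
class DisplacementResult:
    """Per-site displacement table and the summed binding free energy."""

    ligand: str
    per_site: list[SiteContribution]
    config: DisplacementConfig

    @property
    def dG_bind(self) -> float:
        return float(sum(c.contribution for c in self.per_site))

    def displaced_sites(self) -> list[int]:
        return [c.site_index for c in self.per_site if c.weight > 0]

    def as_records(self) -> list[dict]:
        return [{
            "site_index": c.site_index,
            "d_min": c.d_min,
            "weight": c.weight,
            "dG_transfer": c.dG_transfer,
            "contribution": c.contribution,
        } for c in self.per_site]


def displaced_weight(site: HydrationSite, ligand: LigandPose,
                     cfg: DisplacementConfig = DisplacementConfig()
                     ) -> tuple[float, float]:
    """Minimum site-to-atom distance and the displacement weight in [0, 1]."""
    pts = ligand.positions(cfg.atoms_used)
    d_min = float(np.min(np.linalg.norm(pts - np.asarray(site.center), axis=1)))
    if cfg.functional == "step":
        weight = 1.0 if d_min < cfg.Rco else 0.0
    else:
        weight = max(0.0, 1.0 - d_min / cfg.Rco)
    return d_min, weight


def score_ligand(sites: Sequence[HydrationSite], ligand: LigandPose,
                 cfg: DisplacementConfig = DisplacementConfig()
                 ) -> DisplacementResult:
    """Score one pose: per-site weights, contributions, and their sum."""
    per_site = []
    for i, site in enumerate(sites):
        if site.thermo is None:
            raise ValueError(f"site {i} lacks thermodynamics")
        d_min, weight = displaced_weight(site, ligand, cfg)
        per_site.append(SiteContribution(
            site_index=i, d_min=d_min, weight=weight,
            dG_transfer=site.thermo.dG_transfer))
    result = DisplacementResult(ligand=ligand.name, per_site=per_site,
                                config=cfg)
    logger.info("score_ligand(%s): dG_bind = %.3f kcal/mol over %d sites "
                "(%d displaced)", ligand.name, result.dG_bind, len(sites),
                len(result.displaced_sites()))
    return result


def compare_ligands(sites: Sequence[HydrationSite],
                    ligand_poses: Sequence[LigandPose],
                    cfg: DisplacementConfig = DisplacementConfig()) -> dict:
    """Score a panel of poses; pairwise ddG and the displaced/not matrix."""
    if len(ligand_poses) < 2:
        raise ValueError("need at least 2 poses to compare")
    names = [p.name for p in ligand_poses]
    if len(set(names)) != len(names):
        raise ValueError("duplicate pose names")
    results = {p.name: score_ligand(sites, p, cfg) for p in ligand_poses}
    ddG = {(a, b): results[a].dG_bind - results[b].dG_bind
           for a in names for b in names if a != b}
    displaced = {name: [c.weight > 0 for c in results[name].per_site]
                 for name in names}
    return {"results": results, "ddG": ddG, "displaced": displaced}
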