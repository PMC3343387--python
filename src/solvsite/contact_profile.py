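"""Geometric interaction typology for protein-ligand complexes.

Detects the interaction classes seen in bisphosphonate binding sites:
conventional and bifurcated hydrogen bonds, weak CH-O hydrogen bonds, salt
bridges, metal coordination (with an octahedral-geometry check for the
trinuclear Mg cluster motif), parallel / T-shaped pi-pi stacking, and
hydrophobic carbon-carbon contacts.

All geometric thresholds live in :class:`ContactCriteria` and are
literature-conventional defaults; every one is overridable.  Distances are
tested with strict inequality on the open side (``d < max``) and angles with
``angle >= min``.  Hydrogens are used when present; when neither partner of a
candidate N/O hydrogen bond carries a hydrogen, the angle test is skipped and
distance-only detection applies (flagged ``no-H`` in the contact detail).
CH-O hydrogen bonds always require an explicit hydrogen, since the C-H
direction is part of their definition.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .io_formats import Atom, Structure

logger = logging.getLogger("solvsite")


class ContactType(enum.Enum):
    HBOND = "HBOND"
    BIFURCATED_HBOND = "BIFURCATED_HBOND"
    CHO_HBOND = "CHO_HBOND"
    SALT_BRIDGE = "SALT_BRIDGE"
    METAL_COORD = "METAL_COORD"
    PI_PI = "PI_PI"
    HYDROPHOBIC = "HYDROPHOBIC"


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric thresholds (angstrom / degrees) for contact detection."""

    hbond_max_da: float = 3.35
    hbond_min_angle: float = 120.0
    cho_max_co: float = 3.7
    cho_min_angle: float = 110.0
    salt_max: float = 4.0
    metal_max: float = 2.6
    octahedral_tol: float = 20.0
    pipi_max_centroid: float = 5.5
    pipi_parallel_max_tilt: float = 30.0
    pipi_tshaped_min_tilt: float = 60.0
    hydrophobic_max: float = 3.9

    def __post_init__(self):
        for name in ("hbond_max_da", "cho_max_co", "salt_max", "metal_max",
                     "pipi_max_centroid", "hydrophobic_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_min_angle", "cho_min_angle", "octahedral_tol",
                     "pipi_parallel_max_tilt", "pipi_tshaped_min_tilt"):
            if not 0.0 < getattr(self, name) <= 180.0:
                raise ValueError(f"{name} must be in (0, 180]")


@dataclass(frozen=True)
class Ring:
    """A planar aromatic ring: member atoms, centroid and unit normal."""

    atoms: tuple[Atom, ...]
    centroid: tuple[float, float, float]
    normal: tuple[float, float, float]

    @property
    def centroid_arr(self) -> np.ndarray:
        return np.asarray(self.centroid)

    @property
    def residue_id(self):
        return self.atoms[0].residue_id


@dataclass
class Contact:
    """One typed protein-ligand interaction with its geometry."""

    contact_type: ContactType
    partner_a: Atom | Ring          # ligand-side partner (or metal's ligand atom)
    partner_b: Atom | Ring          # protein/metal-side partner
    distance: float
    angle: float | None = None
    detail: str = ""
    members: tuple = ()             # supporting atoms or member contacts

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")


# ---------------------------------------------------------------------------
# connectivity helpers
# ---------------------------------------------------------------------------

_HEAVY_BOND_MAX = 1.9
_H_BOND_MAX = 1.2

#: protein side-chain atoms carrying a formal charge (metal ions excluded)
_CATIONIC_PROTEIN = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"),
                     ("ARG", "NH2"), ("HIS", "ND1"), ("HIS", "NE2")}
_ANIONIC_PROTEIN = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"),
                    ("GLU", "OE2")}


class _Connectivity:
    """Distance-derived bonds, attached hydrogens and polarity typing."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms = list(atoms)
        pos = np.array([a.position for a in self.atoms]).reshape(-1, 3)
        self.pos = pos
        tree = cKDTree(pos)
        self.attached_h: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
        self.bonded_heavy: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
        for i, j in tree.query_pairs(_HEAVY_BOND_MAX):
            ei, ej = self.atoms[i].element, self.atoms[j].element
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if ei == "H" and ej != "H" and d < _H_BOND_MAX:
                self.attached_h[j].append(i)
            elif ej == "H" and ei != "H" and d < _H_BOND_MAX:
                self.attached_h[i].append(j)
            elif ei != "H" and ej != "H":
                self.bonded_heavy[i].append(j)
                self.bonded_heavy[j].append(i)

    def is_apolar_carbon(self, i: int) -> bool:
        if self.atoms[i].element != "C":
            return False
        return not any(self.atoms[j].element in ("N", "O", "P", "S")
                       for j in self.bonded_heavy[i])

    def is_anionic(self, i: int, is_ligand: bool) -> bool:
        a = self.atoms[i]
        if a.element != "O":
            return False
        if not is_ligand:
            return (a.res_name, a.name) in _ANIONIC_PROTEIN
        # ligand oxygens bound to phosphorus (phosphonate / phosphate)
        return any(self.atoms[j].element == "P" for j in self.bonded_heavy[i])

    def is_cationic(self, i: int, is_ligand: bool) -> bool:
        a = self.atoms[i]
        if a.element != "N":
            return False
        if not is_ligand:
            return (a.res_name, a.name) in _CATIONIC_PROTEIN
        return len(self.attached_h[i]) >= 3  # protonated amine


def _angle_deg(p_vertex: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - p_vertex
    v2 = p2 - p_vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


# ---------------------------------------------------------------------------
# ring perception
# ---------------------------------------------------------------------------

def find_rings(structure: Structure, planarity_tol: float = 0.3) -> list[Ring]:
    """Detect planar 5- and 6-membered aromatic-capable rings.

    Bonds are inferred from distances (heavy-heavy < 1.9 A, H < 1.2 A).
    Candidate atoms are sp2-capable C/N: at most 3 total bonds (a saturated
    ring carbon carries 4 and is excluded, so cyclohexane is rejected even
    when its pucker happens to fall inside the planarity tolerance).
    Candidate cycles come from the bond graph's cycle basis and are kept when
    every atom lies within ``planarity_tol`` of the best-fit plane.
    """
    conn = _Connectivity(structure.atoms)
    idx = [i for i, a in enumerate(structure.atoms)
           if a.element in ("C", "N")
           and len(conn.bonded_heavy[i]) + len(conn.attached_h[i]) <= 3]
    if len(idx) < 5:
        return []
    pos = structure.positions[idx]
    tree = cKDTree(pos)
    g = nx.Graph()
    g.add_nodes_from(range(len(idx)))
    g.add_edges_from(tree.query_pairs(_HEAVY_BOND_MAX))
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        pts = pos[cycle]
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        _, _, vt = np.linalg.svd(centered)
        normal = vt[2]
        if np.max(np.abs(centered @ normal)) >= planarity_tol:
            continue
        rings.append(Ring(
            atoms=tuple(structure.atoms[idx[c]] for c in cycle),
            centroid=tuple(map(float, centroid)),
            normal=tuple(map(float, normal))))
    rings.sort(key=lambda r: min(a.serial for a in r.atoms))
    return rings


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_contacts(structure: Structure,
                    ligand_selection: str | Callable[[Atom], bool],
                    criteria: ContactCriteria = ContactCriteria()
                    ) -> list[Contact]:
    """Detect all typed contacts between the ligand and its environment.

    ``ligand_selection`` is a residue name (e.g. ``"LIG"`` or ``"MIN"``) or a
    predicate over atoms.  Metal ions (HETATM with a metal element) outside
    the ligand are treated as coordination centers, everything else outside
    the ligand as environment (protein + waters).
    """
    if isinstance(ligand_selection, str):
        resname = ligand_selection
        select = lambda a: a.res_name == resname  # noqa: E731
    else:
        select = ligand_selection

    conn = _Connectivity(structure.atoms)
    n = len(structure.atoms)
    lig_idx = [i for i in range(n) if select(structure.atoms[i])]
    if not lig_idx:
        raise ValueError("ligand selection matched no atoms")
    lig_set = set(lig_idx)
    metal_idx = [i for i in range(n)
                 if i not in lig_set and structure.atoms[i].is_metal
                 and structure.atoms[i].hetero]
    metal_set = set(metal_idx)
    env_idx = [i for i in range(n)
               if i not in lig_set and i not in metal_set
               and structure.atoms[i].element != "H"]

    atoms = structure.atoms
    pos = conn.pos
    contacts: list[Contact] = []

    # atoms coordinating each metal (either side); used to veto phantom
    # hydrogen bonds between ligands of the same metal cluster
    coordinators: dict[int, set[int]] = {}
    for m in metal_idx:
        near = [i for i in range(n)
                if i != m and atoms[i].element in ("N", "O")
                and np.linalg.norm(pos[i] - pos[m]) < criteria.metal_max]
        coordinators[m] = set(near)

    def share_metal(i: int, j: int) -> bool:
        return any(i in c and j in c for c in coordinators.values())

    # --- hydrogen bonds -----------------------------------------------------
    hbonds: list[tuple[Contact, int | None]] = []  # (contact, donor index)
    for li in lig_idx:
        if atoms[li].element not in ("N", "O"):
            continue
        for ei in env_idx:
            if atoms[ei].element not in ("N", "O"):
                continue
            d = float(np.linalg.norm(pos[li] - pos[ei]))
            if not d < criteria.hbond_max_da or share_metal(li, ei):
                continue
            candidates = []
            for donor, acceptor in ((li, ei), (ei, li)):
                for h in conn.attached_h[donor]:
                    ang = _angle_deg(pos[h], pos[donor], pos[acceptor])
                    if ang >= criteria.hbond_min_angle:
                        candidates.append((donor, ang))
            has_any_h = conn.attached_h[li] or conn.attached_h[ei]
            if candidates:
                donor, ang = max(candidates, key=lambda c: c[1])
                side = "ligand-donor" if donor == li else "protein-donor"
                hbonds.append((Contact(
                    ContactType.HBOND, atoms[li], atoms[ei], d, ang,
                    detail=side), donor))
            elif not has_any_h:
                hbonds.append((Contact(
                    ContactType.HBOND, atoms[li], atoms[ei], d, None,
                    detail="no-H"), None))
    contacts.extend(c for c, _ in hbonds)

    # --- bifurcated hydrogen bonds ------------------------------------------
    by_shared: dict[int, list[Contact]] = {}
    for contact, donor in hbonds:
        li = next(i for i in lig_idx if atoms[i] is contact.partner_a)
        ei = next(i for i in env_idx if atoms[i] is contact.partner_b)
        if donor is not None:
            shared = [donor]
        else:
            shared = [li, ei]
        for s in shared:
            by_shared.setdefault(s, []).append(contact)
    for s, group in sorted(by_shared.items()):
        partners = {(id(c.partner_a), id(c.partner_b)) for c in group}
        if len(group) >= 2 and len(partners) >= 2:
            group = sorted(group, key=lambda c: c.distance)
            contacts.append(Contact(
                ContactType.BIFURCATED_HBOND,
                group[0].partner_a, group[0].partner_b,
                distance=group[0].distance,
                detail=f"shared atom {atoms[s].name} ({len(group)} H-bonds)",
                members=tuple(group)))

    # --- CH-O hydrogen bonds ------------------------------------------------
    for ci_pool, oi_pool, label in ((lig_idx, env_idx, "ligand C-H"),
                                    (env_idx, lig_idx, "protein C-H")):
        for ci in ci_pool:
            if atoms[ci].element != "C" or not conn.attached_h[ci]:
                continue
            for oi in oi_pool:
                if atoms[oi].element != "O":
                    continue
                d = float(np.linalg.norm(pos[ci] - pos[oi]))
                if not d < criteria.cho_max_co:
                    continue
                best = None
                for h in conn.attached_h[ci]:
                    ang = _angle_deg(pos[h], pos[ci], pos[oi])
                    if ang >= criteria.cho_min_angle:
                        best = max(best or 0.0, ang)
                if best is not None:
                    a_lig = atoms[ci] if label == "ligand C-H" else atoms[oi]
                    a_env = atoms[oi] if label == "ligand C-H" else atoms[ci]
                    contacts.append(Contact(
                        ContactType.CHO_HBOND, a_lig, a_env, d, best,
                        detail=label))

    # --- salt bridges -------------------------------------------------------
    for li in lig_idx:
        for ei in env_idx:
            d = float(np.linalg.norm(pos[li] - pos[ei]))
            if not d < criteria.salt_max:
                continue
            lig_anion = conn.is_anionic(li, True)
            lig_cation = conn.is_cationic(li, True)
            env_anion = conn.is_anionic(ei, False)
            env_cation = conn.is_cationic(ei, False)
            if (lig_anion and env_cation) or (lig_cation and env_anion):
                contacts.append(Contact(
                    ContactType.SALT_BRIDGE, atoms[li], atoms[ei], d,
                    detail="anion-cation" if lig_anion else "cation-anion"))

    # --- metal coordination -------------------------------------------------
    for m in metal_idx:
        ligating = sorted(coordinators[m])
        lig_ligating = [i for i in ligating if i in lig_set]
        if not lig_ligating:
            continue
        dists = [float(np.linalg.norm(pos[i] - pos[m])) for i in ligating]
        octa = False
        if len(ligating) == 6:
            cis = []
            for a in range(6):
                for b in range(a + 1, 6):
                    ang = _angle_deg(pos[m], pos[ligating[a]], pos[ligating[b]])
                    if ang < 135.0:
                        cis.append(ang)
            octa = all(abs(ang - 90.0) <= criteria.octahedral_tol
                       for ang in cis)
        contacts.append(Contact(
            ContactType.METAL_COORD, atoms[lig_ligating[0]], atoms[m],
            distance=float(np.mean(dists)),
            detail=f"coordination={len(ligating)} octahedral={octa}",
            members=tuple(atoms[i] for i in ligating)))

    # --- pi-pi stacking -----------------------------------------------------
    rings = find_rings(structure)
    lig_rings = [r for r in rings
                 if all(any(a is atoms[i] for i in lig_idx) for a in r.atoms)]
    env_rings = [r for r in rings
                 if all(any(a is atoms[i] for i in env_idx) for a in r.atoms)]
    pipi_pairs: list[tuple[Ring, Ring]] = []
    for lr in lig_rings:
        for er in env_rings:
            d = float(np.linalg.norm(lr.centroid_arr - er.centroid_arr))
            if not d < criteria.pipi_max_centroid:
                continue
            cost = abs(float(np.dot(lr.normal, er.normal)))
            tilt = math.degrees(math.acos(min(1.0, cost)))
            if tilt <= criteria.pipi_parallel_max_tilt:
                shape = "parallel"
            elif tilt >= criteria.pipi_tshaped_min_tilt:
                shape = "T-shaped"
            else:
                shape = "inclined"
            contacts.append(Contact(
                ContactType.PI_PI, lr, er, d, tilt, detail=shape))
            pipi_pairs.append((lr, er))

    # --- hydrophobic contacts -----------------------------------------------
    stacked = {(id(a), id(b)) for lr, er in pipi_pairs
               for a in lr.atoms for b in er.atoms}
    for li in lig_idx:
        if not conn.is_apolar_carbon(li):
            continue
        for ei in env_idx:
            if not conn.is_apolar_carbon(ei):
                continue
            if (id(atoms[li]), id(atoms[ei])) in stacked:
                continue
            d = float(np.linalg.norm(pos[li] - pos[ei]))
            if d < criteria.hydrophobic_max:
                contacts.append(Contact(
                    ContactType.HYDROPHOBIC, atoms[li], atoms[ei], d))

    logger.info("detect_contacts: %d contacts (%s)", len(contacts),
                ", ".join(f"{t.name}={sum(c.contact_type is t for c in contacts)}"
                          for t in ContactType
                          if any(c.contact_type is t for c in contacts)))
    return contacts


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _partner_residues(contact: Contact):
    out = []
    for p in (contact.partner_a, contact.partner_b):
        rid = p.residue_id
        out.append(rid)
    return out


def contact_report(contacts: Sequence[Contact],
                   structure: Structure | None = None) -> dict:
    """Summarize contacts: counts per type and a per-residue breakdown.

    Residues are sorted by (chain, residue number); ordering is deterministic.
    """
    del structure  # residue identity travels with the contacts themselves
    counts = {t.name: 0 for t in ContactType}
    per_residue: dict[tuple[str, str, int], list[str]] = {}
    for c in sorted(contacts,
                    key=lambda c: (c.contact_type.name, c.distance)):
        counts[c.contact_type.name] += 1
        for rid in _partner_residues(c):
            per_residue.setdefault(rid, []).append(c.contact_type.name)
    residues = [{
        "chain": rid[0], "res_name": rid[1], "res_seq": rid[2],
        "contacts": sorted(types),
    } for rid, types in sorted(per_residue.items(),
                               key=lambda kv: (kv[0][0], kv[0][2]))]
    return {
        "schema_version": "1",
        "counts": {k: v for k, v in counts.items() if v},
        "n_contacts": len(contacts),
        "residues": residues,
    }
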