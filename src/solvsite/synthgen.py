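"""Synthetic-data generators with known ground truth.

Every test input of the pipeline is generated here: pocket water trajectories
with planted hydration-site occupancy, positional spread, orientational
concentration and interaction-energy distributions; bulk reference
trajectories; toy protein-ligand complexes realizing planted contact
geometries exactly; and pair-interaction-energy tables with planted
residue-potency covariance.  Each generator is deterministic under its seed
and echoes the planted parameters so estimators can be scored against truth.

The water generators stand in for an explicit-solvent molecular-dynamics run:
sites are independent Bernoulli/Gaussian emitters and bulk waters are
re-drawn independently every frame (ideal-gas-like), which makes the bulk
translational excess entropy exactly zero by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import vonmises_fisher

from .contact_profile import ContactType
from .io_formats import Atom, Structure, Trajectory, WaterObservation

#: ambient-condition number density of liquid water, waters per cubic angstrom
BULK_WATER_DENSITY = 0.0334

#: exclusion radius used when checking that planted sites do not overlap
SITE_SPHERE_RADIUS = 1.0

IDENTITY_QUAT = (1.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSpec:
    """A planted hydration site.

    ``occupancy_p`` is the per-frame probability that the site holds a water;
    positions are isotropic Gaussian around ``center`` with standard deviation
    ``sigma_pos`` (angstrom); orientations follow a von Mises-Fisher
    distribution on the unit quaternion sphere with concentration ``kappa``
    about ``ref_orientation`` (kappa = 0 is exactly uniform); energies are
    Gaussian(energy_mean, energy_sd**2) kcal/mol.
    """

    center: tuple[float, float, float]
    occupancy_p: float = 1.0
    sigma_pos: float = 0.25
    kappa: float = 0.0
    ref_orientation: tuple[float, float, float, float] = IDENTITY_QUAT
    energy_mean: float = -22.0
    energy_sd: float = 1.5

    def __post_init__(self):
        if not 0.0 <= self.occupancy_p <= 1.0:
            raise ValueError(f"occupancy_p must be in [0, 1], got {self.occupancy_p}")
        if self.sigma_pos <= 0:
            raise ValueError("sigma_pos must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.energy_sd < 0:
            raise ValueError("energy_sd must be >= 0")
        norm = math.sqrt(sum(c * c for c in self.ref_orientation))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError("ref_orientation must be a unit quaternion")


@dataclass(frozen=True)
class BulkSpec:
    """A rectangular bulk-water region filled at a fixed number density."""

    box_min: tuple[float, float, float]
    box_max: tuple[float, float, float]
    density: float = BULK_WATER_DENSITY
    energy_mean: float = -22.0
    energy_sd: float = 1.5

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.volume <= 0:
            raise ValueError("bulk box must have positive volume")

    @property
    def volume(self) -> float:
        lo = np.asarray(self.box_min, dtype=float)
        hi = np.asarray(self.box_max, dtype=float)
        return float(np.prod(hi - lo))


@dataclass(frozen=True)
class PlantedContact:
    """One contact geometry to realize in a toy complex.

    ``params`` overrides the per-type defaults (distances in angstrom, angles
    in degrees); see :data:`CONTACT_DEFAULTS` for the recognized keys.
    """

    contact_type: ContactType
    params: Mapping[str, float] = field(default_factory=dict)

    def resolved(self) -> dict[str, float]:
        out = dict(CONTACT_DEFAULTS[self.contact_type])
        unknown = set(self.params) - set(out)
        if unknown:
            raise ValueError(
                f"unknown parameters {sorted(unknown)} for {self.contact_type.name}")
        out.update(self.params)
        for key, val in out.items():
            if key.startswith("distance") and val <= 0:
                raise ValueError(f"{self.contact_type.name}: {key} must be > 0")
            if key.startswith("angle") and not 0.0 <= val <= 180.0:
                raise ValueError(f"{self.contact_type.name}: {key} out of [0, 180]")
        return out


CONTACT_DEFAULTS: dict[ContactType, dict[str, float]] = {
    ContactType.HBOND: {"distance": 2.9, "angle": 165.0},
    ContactType.BIFURCATED_HBOND: {"distance1": 2.8, "distance2": 3.0,
                                   "angle1": 150.0, "angle2": 150.0},
    ContactType.CHO_HBOND: {"distance": 3.3, "angle": 140.0},
    ContactType.SALT_BRIDGE: {"distance": 3.5},
    ContactType.METAL_COORD: {"distance": 2.1, "perturb_deg": 0.0},
    ContactType.PI_PI: {"distance": 4.0, "angle": 0.0},
    ContactType.HYDROPHOBIC: {"distance": 3.6},
}


# ---------------------------------------------------------------------------
# orientations
# ---------------------------------------------------------------------------

def sample_orientations(n: int, kappa: float, ref: Sequence[float],
                        rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` unit quaternions; kappa = 0 reduces exactly to uniform."""
    if kappa == 0.0:
        q = rng.normal(size=(n, 4))
    else:
        q = np.atleast_2d(vonmises_fisher(np.asarray(ref, dtype=float), kappa)
                          .rvs(n, random_state=rng))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# water trajectories
# ---------------------------------------------------------------------------

def _check_site_overlap(site_specs: Sequence[SiteSpec]) -> None:
    for i in range(len(site_specs)):
        for j in range(i + 1, len(site_specs)):
            d = np.linalg.norm(np.asarray(site_specs[i].center, float)
                               - np.asarray(site_specs[j].center, float))
            if d < 2.0 * SITE_SPHERE_RADIUS:
                raise ValueError(
                    f"site spheres {i} and {j} overlap "
                    f"(center distance {d:.3f} A < {2 * SITE_SPHERE_RADIUS} A)")


def gen_water_trajectory(
        site_specs: Sequence[SiteSpec],
        bulk: BulkSpec | None,
        n_frames: int,
        seed: int) -> tuple[Trajectory, dict]:
    """Generate a pocket water trajectory with planted sites (+ optional bulk).

    Site waters keep a stable ``water_id`` equal to the site index; bulk
    waters get ids starting at ``len(site_specs)`` within each frame.
    Returns the trajectory and a ground-truth record echoing every planted
    parameter.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    _check_site_overlap(site_specs)
    rng = np.random.default_rng(seed)
    frames: list[list[WaterObservation]] = []
    site_counts = [0] * len(site_specs)
    for f in range(n_frames):
        frame: list[WaterObservation] = []
        for i, spec in enumerate(site_specs):
            if rng.random() >= spec.occupancy_p:
                continue
            site_counts[i] += 1
            pos = np.asarray(spec.center, float) + rng.normal(
                scale=spec.sigma_pos, size=3)
            quat = sample_orientations(1, spec.kappa, spec.ref_orientation, rng)[0]
            energy = spec.energy_mean + (
                rng.normal(scale=spec.energy_sd) if spec.energy_sd > 0 else 0.0)
            frame.append(WaterObservation(
                frame=f, water_id=i, position=tuple(pos),
                orientation=tuple(quat), energy=float(energy)))
        if bulk is not None:
            frame.extend(_bulk_frame(bulk, f, len(site_specs), rng))
        frames.append(frame)
    ground_truth = {
        "sites": [{
            "center": list(spec.center),
            "occupancy_p": spec.occupancy_p,
            "sigma_pos": spec.sigma_pos,
            "kappa": spec.kappa,
            "ref_orientation": list(spec.ref_orientation),
            "energy_mean": spec.energy_mean,
            "energy_sd": spec.energy_sd,
            "realized_occupancy": site_counts[i] / n_frames,
        } for i, spec in enumerate(site_specs)],
        "bulk": None if bulk is None else {
            "box_min": list(bulk.box_min), "box_max": list(bulk.box_max),
            "density": bulk.density, "energy_mean": bulk.energy_mean,
            "energy_sd": bulk.energy_sd,
        },
        "n_frames": n_frames,
        "seed": seed,
    }
    return Trajectory(frames=frames), ground_truth


def _bulk_frame(bulk: BulkSpec, frame_idx: int, id_offset: int,
                rng: np.random.Generator) -> list[WaterObservation]:
    lo = np.asarray(bulk.box_min, float)
    hi = np.asarray(bulk.box_max, float)
    count = rng.poisson(bulk.density * bulk.volume)
    positions = rng.uniform(lo, hi, size=(count, 3))
    quats = sample_orientations(count, 0.0, IDENTITY_QUAT, rng) if count else \
        np.empty((0, 4))
    energies = bulk.energy_mean + (
        rng.normal(scale=bulk.energy_sd, size=count) if bulk.energy_sd > 0
        else np.zeros(count))
    return [WaterObservation(
        frame=frame_idx, water_id=id_offset + j, position=tuple(positions[j]),
        orientation=tuple(quats[j]), energy=float(energies[j]))
        for j in range(count)]


def gen_bulk_reference(bulk: BulkSpec, n_frames: int, seed: int) -> Trajectory:
    """Generate a pure-bulk trajectory: uniform positions and orientations."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = [_bulk_frame(bulk, f, 0, rng) for f in range(n_frames)]
    return Trajectory(frames=frames)


# ---------------------------------------------------------------------------
# toy complexes with planted contacts
# ---------------------------------------------------------------------------

def _place_hbond_acceptor(donor: np.ndarray, h: np.ndarray, d_da: float,
                          angle_deg: float, out_of_plane: float = 0.0
                          ) -> np.ndarray:
    """Acceptor position realizing donor..acceptor distance and D-H-A angle.

    The acceptor is placed in the xz-plane through the D-H axis (rotated by
    ``out_of_plane`` degrees about that axis for bifurcated geometries).
    """
    alpha = math.radians(angle_deg)
    d_dh = float(np.linalg.norm(h - donor))
    disc = d_da ** 2 - (d_dh * math.sin(alpha)) ** 2
    if disc < 0:
        raise ValueError(
            f"hydrogen-bond geometry unsatisfiable: distance {d_da:.2f} A "
            f"with angle {angle_deg:.1f} deg")
    t = d_dh * math.cos(alpha) + math.sqrt(disc)
    axis = (h - donor) / d_dh
    perp = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(axis, perp)) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    perp = perp - np.dot(perp, axis) * axis
    perp /= np.linalg.norm(perp)
    phi = math.radians(out_of_plane)
    perp2 = np.cross(axis, perp)
    direction = (-math.cos(alpha)) * axis + math.sin(alpha) * (
        math.cos(phi) * perp + math.sin(phi) * perp2)
    # direction makes angle alpha with -axis, i.e. D-H-A angle = alpha
    return h + t * direction


class _Builder:
    """Accumulates atoms for one toy complex and assigns serials."""

    def __init__(self):
        self.atoms: list[Atom] = []
        self._serial = 0
        self._lig_counter: dict[str, int] = {}
        self._res_counter = 99

    def next_residue(self) -> int:
        self._res_counter += 1
        return self._res_counter

    def add(self, name: str, element: str, pos: np.ndarray, *,
            res_name: str, res_seq: int, chain: str, hetero: bool) -> Atom:
        self._serial += 1
        atom = Atom(serial=self._serial, name=name, element=element,
                    res_name=res_name, res_seq=res_seq, chain=chain,
                    position=tuple(float(v) for v in pos), hetero=hetero)
        self.atoms.append(atom)
        return atom

    def lig(self, element: str, pos: np.ndarray) -> Atom:
        n = self._lig_counter.get(element, 0) + 1
        self._lig_counter[element] = n
        return self.add(f"{element}{n}", element, pos, res_name="LIG",
                        res_seq=1, chain="L", hetero=True)

    def prot(self, name: str, element: str, pos: np.ndarray,
             res_name: str, res_seq: int) -> Atom:
        return self.add(name, element, pos, res_name=res_name,
                        res_seq=res_seq, chain="A", hetero=False)


def _manifest_entry(ctype: ContactType, lig_atoms, prot_atoms, **geometry):
    return {
        "contact_type": ctype.name,
        "ligand_atoms": [a.serial for a in lig_atoms],
        "protein_atoms": [a.serial for a in prot_atoms],
        "geometry": geometry,
    }


def _build_hbond(b: _Builder, origin: np.ndarray, p: dict) -> list[dict]:
    donor_pos = origin
    h_pos = origin + np.array([1.0, 0.0, 0.0])
    acc_pos = _place_hbond_acceptor(donor_pos, h_pos, p["distance"], p["angle"])
    donor = b.lig("N", donor_pos)
    b.lig("H", h_pos)
    res = b.next_residue()
    acc = b.prot("OG1", "O", acc_pos, "THR", res)
    return [_manifest_entry(ContactType.HBOND, [donor], [acc],
                            distance=p["distance"], angle=p["angle"])]


def _build_bifurcated(b: _Builder, origin: np.ndarray, p: dict) -> list[dict]:
    donor_pos = origin
    h_pos = origin + np.array([1.0, 0.0, 0.0])
    acc1_pos = _place_hbond_acceptor(donor_pos, h_pos, p["distance1"],
                                     p["angle1"], out_of_plane=0.0)
    acc2_pos = _place_hbond_acceptor(donor_pos, h_pos, p["distance2"],
                                     p["angle2"], out_of_plane=180.0)
    donor = b.lig("N", donor_pos)
    b.lig("H", h_pos)
    res1, res2 = b.next_residue(), b.next_residue()
    acc1 = b.prot("OG1", "O", acc1_pos, "THR", res1)
    acc2 = b.prot("O", "O", acc2_pos, "LYS", res2)
    return [
        _manifest_entry(ContactType.HBOND, [donor], [acc1],
                        distance=p["distance1"], angle=p["angle1"]),
        _manifest_entry(ContactType.HBOND, [donor], [acc2],
                        distance=p["distance2"], angle=p["angle2"]),
        _manifest_entry(ContactType.BIFURCATED_HBOND, [donor], [acc1, acc2],
                        distance=min(p["distance1"], p["distance2"])),
    ]


def _build_cho(b: _Builder, origin: np.ndarray, p: dict) -> list[dict]:
    c_pos = origin
    h_pos = origin + np.array([1.09, 0.0, 0.0])
    o_pos = _place_hbond_acceptor(c_pos, h_pos, p["distance"], p["angle"])
    # carbonyl carbon 1.23 A beyond the oxygen, pointing away from the ligand
    away = (o_pos - c_pos) / np.linalg.norm(o_pos - c_pos)
    cc_pos = o_pos + 1.23 * away
    donor = b.lig("C", c_pos)
    b.lig("H", h_pos)
    res = b.next_residue()
    acc = b.prot("O", "O", o_pos, "PHE", res)
    b.prot("C", "C", cc_pos, "PHE", res)
    return [_manifest_entry(ContactType.CHO_HBOND, [donor], [acc],
                            distance=p["distance"], angle=p["angle"])]


def _build_salt_bridge(b: _Builder, origin: np.ndarray, p: dict) -> list[dict]:
    p_pos = origin
    o_pos = origin + np.array([1.5, 0.0, 0.0])
    nz_pos = o_pos + np.array([p["distance"], 0.0, 0.0])
    b.lig("P", p_pos)
    o = b.lig("O", o_pos)
    res = b.next_residue()
    nz = b.prot("NZ", "N", nz_pos, "LYS", res)
    return [_manifest_entry(ContactType.SALT_BRIDGE, [o], [nz],
                            distance=p["distance"])]


def _build_metal(b: _Builder, origin: np.ndarray, p: dict) -> list[dict]:
    mg = b.add("MG", "MG", origin, res_name="MG",
               res_seq=b.next_residue(), chain="M", hetero=True)
    axes = [np.array(v, float) for v in
            ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))]
    if p["perturb_deg"]:
        # rotate the +x oxygen toward +y by the requested amount
        ang = math.radians(p["perturb_deg"])
        axes[0] = np.array([math.cos(ang), math.sin(ang), 0.0])
    oxygens = [b.lig("O", origin + p["distance"] * ax) for ax in axes]
    return [_manifest_entry(ContactType.METAL_COORD, oxygens, [mg],
                            distance=p["distance"], n_coord=6,
                            perturb_deg=p["perturb_deg"])]


_RING_RADIUS = 1.39  # benzene C-C bond length equals the circumradius


def _hexagon(center: np.ndarray, normal_axis: int = 2) -> list[np.ndarray]:
    pts = []
    for k in range(6):
        ang = math.pi / 3.0 * k
        offset = np.zeros(3)
        in_plane = [i for i in range(3) if i != normal_axis]
        offset[in_plane[0]] = _RING_RADIUS * math.cos(ang)
        offset[in_plane[1]] = _RING_RADIUS * math.sin(ang)
        pts.append(center + offset)
    return pts


def _build_pipi(b: _Builder, origin: np.ndarray, p: dict) -> list[dict]:
    lig_ring = [b.lig("C", pt) for pt in _hexagon(origin)]
    tilt = math.radians(p["angle"])
    center2 = origin + np.array([0.0, 0.0, p["distance"]])
    res = b.next_residue()
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    rot = np.array([[1, 0, 0],
                    [0, math.cos(tilt), -math.sin(tilt)],
                    [0, math.sin(tilt), math.cos(tilt)]])
    prot_ring = [b.prot(nm, "C", center2 + rot @ (pt - origin), "PHE", res)
                 for nm, pt in zip(names, _hexagon(origin))]
    return [_manifest_entry(ContactType.PI_PI, lig_ring, prot_ring,
                            distance=p["distance"], angle=p["angle"])]


def _build_hydrophobic(b: _Builder, origin: np.ndarray, p: dict) -> list[dict]:
    c = b.lig("C", origin)
    res = b.next_residue()
    cd1 = b.prot("CD1", "C", origin + np.array([p["distance"], 0.0, 0.0]),
                 "LEU", res)
    return [_manifest_entry(ContactType.HYDROPHOBIC, [c], [cd1],
                            distance=p["distance"])]


_BUILDERS = {
    ContactType.HBOND: _build_hbond,
    ContactType.BIFURCATED_HBOND: _build_bifurcated,
    ContactType.CHO_HBOND: _build_cho,
    ContactType.SALT_BRIDGE: _build_salt_bridge,
    ContactType.METAL_COORD: _build_metal,
    ContactType.PI_PI: _build_pipi,
    ContactType.HYDROPHOBIC: _build_hydrophobic,
}

_MOTIF_SPACING = 25.0  # A between planted motifs; no cross-motif contacts


def gen_complex_structure(contacts: Sequence[PlantedContact], seed: int = 0
                          ) -> tuple[Structure, list[dict]]:
    """Build a toy complex realizing each planted contact exactly.

    Motifs are laid out on a widely spaced grid so contacts cannot interfere.
    The manifest lists every contact the detector is expected to report
    (a planted bifurcated hydrogen bond expands to its two member hydrogen
    bonds plus the bifurcation record).  Construction is exact to well below
    0.01 A / 0.5 deg.  A steric clash between non-bonded heavy atoms closer
    than 1.5 A raises an error naming the offending pair.
    """
    del seed  # construction is deterministic; kept for interface uniformity
    b = _Builder()
    manifest: list[dict] = []
    for k, planted in enumerate(contacts):
        origin = np.array([_MOTIF_SPACING * k, 0.0, 0.0])
        entries = _BUILDERS[planted.contact_type](b, origin, planted.resolved())
        manifest.extend(entries)
    _check_steric(b.atoms)
    return Structure(atoms=b.atoms), manifest


def _check_steric(atoms: Sequence[Atom]) -> None:
    heavy = [a for a in atoms if a.element != "H"]
    for i in range(len(heavy)):
        for j in range(i + 1, len(heavy)):
            a, bb = heavy[i], heavy[j]
            if a.residue_id == bb.residue_id:
                continue
            d = float(np.linalg.norm(a.pos - bb.pos))
            if d < 1.5 and not ({a.element, bb.element} & {"MG"}):
                raise ValueError(
                    f"steric clash: atoms {a.serial} ({a.name}) and "
                    f"{bb.serial} ({bb.name}) at {d:.2f} A")


# ---------------------------------------------------------------------------
# PIE tables with planted statistical structure
# ---------------------------------------------------------------------------

def gen_pie_table(fragment_count: int,
                  ligand_names: Sequence[str],
                  signal_fragments: Mapping[int | str, float],
                  noise_sd: float,
                  pic50: Sequence[float],
                  seed: int):
    """Generate a PIE matrix with planted fragment-potency covariance.

    Signal fragments follow ``PIE = slope * pIC50 + noise``; all others are a
    per-fragment constant plus noise.  ``signal_fragments`` maps a fragment
    index (or its generated ``F###`` label) to its slope in kcal/mol per
    pIC50 unit.  Returns (PIEMatrix, ground_truth).
    """
    from .pie_stats import PIEMatrix
    import pandas as pd

    if len(set(ligand_names)) != len(ligand_names):
        raise ValueError("duplicate ligand names")
    if len(pic50) != len(ligand_names):
        raise ValueError("pic50 length must match ligand_names")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fragments = [f"F{i:03d}" for i in range(fragment_count)]
    slopes = np.zeros(fragment_count)
    for key, slope in signal_fragments.items():
        idx = key if isinstance(key, int) else fragments.index(key)
        if not 0 <= idx < fragment_count:
            raise ValueError(f"signal fragment {key!r} out of range")
        slopes[idx] = slope

    rng = np.random.default_rng(seed)
    baselines = rng.uniform(-10.0, 0.0, size=fragment_count)
    pic50_arr = np.asarray(pic50, dtype=float)
    values = np.empty((fragment_count, len(ligand_names)))
    for i in range(fragment_count):
        signal = (slopes[i] * pic50_arr if slopes[i] != 0.0
                  else np.full(len(ligand_names), baselines[i]))
        noise = (rng.normal(scale=noise_sd, size=len(ligand_names))
                 if noise_sd > 0 else 0.0)
        values[i] = signal + noise

    total = pd.DataFrame(values, index=fragments, columns=list(ligand_names))
    matrix = PIEMatrix(
        fragments=fragments, ligands=list(ligand_names), total=total,
        pieda=None,
        pic50=pd.Series(pic50_arr, index=list(ligand_names)))
    ground_truth = {
        "slopes": {fragments[i]: float(slopes[i]) for i in range(fragment_count)
                   if slopes[i] != 0.0},
        "baselines": {fragments[i]: float(baselines[i])
                      for i in range(fragment_count) if slopes[i] == 0.0},
        "noise_sd": noise_sd,
        "pic50": {lig: float(v) for lig, v in zip(ligand_names, pic50_arr)},
        "seed": seed,
    }
    return matrix, ground_truth
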