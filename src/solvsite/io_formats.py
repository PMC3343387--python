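"""Readers and writers for the on-disk artifacts of the pipeline.

Formats handled: single- and multi-MODEL PDB structures, per-frame XYZ
trajectories, CSV energy/orientation sidecars, JSON hydration-site maps and
versioned reports, and long-format CSV pair-interaction-energy (PIE) tables.

Conventions fixed here and relied on everywhere else:

* coordinates are Cartesian angstroms exactly as found in the file — no
  recentering, no unit autodetection;
* PDB residue numbers are 1-based and preserved verbatim; internal frame and
  list indices are 0-based;
* energies are kcal/mol throughout;
* water residues are identified by residue name ``HOH`` or ``WAT``;
* alternate locations: altloc ``'A'`` or blank is kept, everything else is
  dropped (the number of discarded records is logged).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("solvsite")

SCHEMA_VERSION = "1"

#: residue names recognised as water
WATER_RESNAMES = {"HOH", "WAT"}

#: elements treated as metal ions when they appear in HETATM records
METAL_ELEMENTS = {"MG", "ZN", "MN", "CA", "NA", "K", "FE", "CU", "NI", "CO"}

SIDECAR_COLUMNS = [
    "frame", "water_id", "x", "y", "z", "qw", "qx", "qy", "qz",
    "energy_kcal_mol",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom record of a structure (PDB conventions)."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    position: tuple[float, float, float]
    altloc: str = ""
    hetero: bool = False

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def is_metal(self) -> bool:
        return self.element.upper() in METAL_ELEMENTS

    @property
    def residue_id(self) -> tuple[str, str, int]:
        return (self.chain, self.res_name, self.res_seq)


@dataclass
class Structure:
    """A single-model structure: a flat list of atoms plus metal bookkeeping."""

    atoms: list[Atom] = field(default_factory=list)

    @property
    def metals(self) -> list[Atom]:
        return [a for a in self.atoms if a.hetero and a.is_metal]

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def select(self, res_name: str | None = None,
               hetero: bool | None = None) -> list[Atom]:
        out = self.atoms
        if res_name is not None:
            out = [a for a in out if a.res_name == res_name]
        if hetero is not None:
            out = [a for a in out if a.hetero == hetero]
        return out

    def __len__(self) -> int:
        return len(self.atoms)


def _validate_pdb_lines(path: Path) -> None:
    """Reject truncated ATOM/HETATM records before handing off to the parser."""
    with open(path, encoding="utf-8") as fh:
        n_records = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n_records += 1
                if len(line.rstrip("\n")) < 54:
                    raise FormatError(
                        f"{path}: truncated ATOM/HETATM record on line {lineno}")
    if n_records == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records found")


def read_structure(path: str | Path) -> Structure:
    """Read a (single-model) PDB file into a :class:`Structure`.

    Altloc policy: keep blank or 'A'; discards are counted and logged.
    Malformed or empty files raise :class:`FormatError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    discarded = 0
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                if at.altloc not in ("", "A", "\x00"):
                    discarded += 1
                    continue
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name.upper(),
                    res_name=res.name,
                    res_seq=res.seqid.num,
                    chain=chain.name,
                    position=(at.pos.x, at.pos.y, at.pos.z),
                    altloc="" if at.altloc == "\x00" else at.altloc,
                    hetero=het,
                ))
    if discarded:
        logger.info("read_structure(%s): discarded %d non-'A' altloc records",
                    path, discarded)
    logger.info("read_structure(%s): %d atoms, %d metal ions",
                path, len(atoms), sum(a.is_metal and a.hetero for a in atoms))
    return Structure(atoms=atoms)


def _format_atom_line(a: Atom) -> str:
    record = "HETATM" if a.hetero else "ATOM"
    name = a.name
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    x, y, z = a.position
    return (f"{record:<6}{a.serial:>5} {name:<4}{a.altloc or ' ':1}"
            f"{a.res_name:>3} {a.chain:1}{a.res_seq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2}")


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file (fixed-width ATOM/HETATM records)."""
    lines = [_format_atom_line(a) for a in structure.atoms]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# water trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterObservation:
    """One water molecule in one frame (oxygen position + rigid-body state)."""

    frame: int
    water_id: int
    position: tuple[float, float, float]
    orientation: tuple[float, float, float, float] | None = None
    energy: float | None = None

    def __post_init__(self):
        if self.orientation is not None:
            norm = math.sqrt(sum(c * c for c in self.orientation))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError(
                    f"orientation of water {self.water_id} frame {self.frame} "
                    f"is not a unit quaternion (|q| = {norm:.8f})")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("non-finite water position")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def quat(self) -> np.ndarray | None:
        if self.orientation is None:
            return None
        return np.asarray(self.orientation, dtype=float)

    @property
    def key(self) -> tuple[int, int]:
        return (self.frame, self.water_id)


@dataclass
class Trajectory:
    """An ordered list of frames, each a list of :class:`WaterObservation`."""

    frames: list[list[WaterObservation]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def observations(self) -> Iterable[WaterObservation]:
        for frame in self.frames:
            yield from frame

    def __len__(self) -> int:
        return len(self.frames)


# rigid 3-site water geometry used when frames are written as PDB: O at the
# origin, the two H at the experimental gas-phase geometry (0.9572 A, 104.52
# deg), rotated by the observation quaternion.
_WATER_OH = 0.9572
_WATER_HOH_DEG = 104.52
_half = math.radians(_WATER_HOH_DEG / 2.0)
WATER_SITES = np.array([
    [0.0, 0.0, 0.0],
    [_WATER_OH * math.sin(_half), 0.0, _WATER_OH * math.cos(_half)],
    [-_WATER_OH * math.sin(_half), 0.0, _WATER_OH * math.cos(_half)],
])


def quat_to_matrix(q: Sequence[float]) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def write_trajectory(traj: Trajectory, coords_path: str | Path,
                     sidecar_path: str | Path | None = None,
                     fmt: str = "pdb") -> None:
    """Write a trajectory as multi-MODEL PDB or per-frame XYZ, plus sidecar.

    The PDB form emits a rigid 3-site water (O, H1, H2) per observation, the
    hydrogens placed by the observation quaternion; only the oxygen position
    is authoritative.  The sidecar CSV carries full-precision positions,
    quaternions and energies keyed by (frame, water_id).
    """
    coords_path = Path(coords_path)
    if fmt == "pdb":
        lines: list[str] = []
        for i, frame in enumerate(traj.frames):
            lines.append(f"MODEL     {i + 1:>4}")
            serial = 1
            for obs in frame:
                rot = (quat_to_matrix(obs.orientation)
                       if obs.orientation is not None else np.eye(3))
                sites = obs.pos + WATER_SITES @ rot.T
                for name, el, p in zip(("O", "H1", "H2"), ("O", "H", "H"), sites):
                    lines.append(_format_atom_line(Atom(
                        serial=serial, name=name, element=el, res_name="HOH",
                        res_seq=obs.water_id, chain="W",
                        position=tuple(p), hetero=True)))
                    serial += 1
            lines.append("ENDMDL")
        lines.append("END")
        coords_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "xyz":
        chunks = []
        for i, frame in enumerate(traj.frames):
            chunks.append(f"{len(frame)}")
            chunks.append(f"frame {i}")
            for obs in frame:
                x, y, z = obs.position
                chunks.append(f"O {x:.6f} {y:.6f} {z:.6f} {obs.water_id}")
        coords_path.write_text("\n".join(chunks) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown trajectory format: {fmt!r}")
    if sidecar_path is not None:
        write_sidecar(traj, sidecar_path)


def write_sidecar(traj: Trajectory, path: str | Path) -> None:
    rows = []
    for obs in traj.observations():
        q = obs.orientation if obs.orientation is not None else (
            float("nan"),) * 4
        rows.append((obs.frame, obs.water_id, *obs.position, *q,
                     float("nan") if obs.energy is None else obs.energy))
    df = pd.DataFrame(rows, columns=SIDECAR_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def _read_pdb_frames(path: Path) -> list[list[tuple[int, np.ndarray]]]:
    _validate_pdb_lines(path)
    st = gemmi.read_pdb(str(path))
    frames = []
    for model in st:
        frame = []
        for chain in model:
            for res in chain:
                if res.name not in WATER_RESNAMES:
                    continue
                for at in res:
                    if at.element.name.upper() == "O":
                        frame.append((res.seqid.num,
                                      np.array([at.pos.x, at.pos.y, at.pos.z])))
        frames.append(frame)
    return frames


def _read_xyz_frames(path: Path) -> list[list[tuple[int, np.ndarray]]]:
    """Parse per-frame XYZ.

    A fifth column carries the water id; with ids present, frames may differ
    in size (partially occupied sites).  Plain 4-column XYZ identifies waters
    positionally, so there inconsistent frame sizes are an error, as is a
    frame shorter than its declared atom count.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    frames = []
    i = 0
    n_atoms_ref = None
    has_ids = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}: bad XYZ atom count on line {i + 1}") from exc
        frame = []
        for j in range(n):
            if i + 2 + j >= len(lines) or len(lines[i + 2 + j].split()) < 4:
                raise FormatError(
                    f"{path}: frame starting line {i + 1} declares {n} atoms "
                    f"but ends early at line {i + 2 + j}")
            parts = lines[i + 2 + j].split()
            if len(parts) > 4:
                wid = int(parts[4])
            else:
                has_ids = False
                wid = j
            frame.append((wid, np.array([float(parts[1]), float(parts[2]),
                                         float(parts[3])])))
        if n_atoms_ref is None:
            n_atoms_ref = n
        elif n != n_atoms_ref and not has_ids:
            raise FormatError(
                f"{path}: inconsistent atom count across XYZ frames "
                f"({n} vs {n_atoms_ref} on line {i + 1}) and no water-id "
                f"column to disambiguate")
        frames.append(frame)
        i += 2 + n
    return frames


def read_trajectory(coords_path: str | Path,
                    sidecar_path: str | Path | None = None) -> Trajectory:
    """Read a water trajectory, joining sidecar data by (frame, water_id).

    Without a sidecar, observations carry positions only.  With one, the
    sidecar's full-precision positions replace the coordinate file's rounded
    values (after a consistency check at PDB precision), and orientations and
    energies are attached.  A sidecar row whose (frame, water_id) key does not
    occur in the coordinate file is an error.
    """
    coords_path = Path(coords_path)
    suffix = coords_path.suffix.lower()
    raw = (_read_xyz_frames(coords_path) if suffix == ".xyz"
           else _read_pdb_frames(coords_path))
    if not raw:
        raise FormatError(f"{coords_path}: no frames")

    side: dict[tuple[int, int], pd.Series] = {}
    if sidecar_path is not None:
        df = pd.read_csv(sidecar_path, float_precision="round_trip")
        missing = {"frame", "water_id"} - set(df.columns)
        if missing:
            raise FormatError(f"{sidecar_path}: missing columns {sorted(missing)}")
        keys_in_coords = {(f, wid) for f, frame in enumerate(raw)
                          for wid, _ in frame}
        for _, row in df.iterrows():
            key = (int(row["frame"]), int(row["water_id"]))
            if key not in keys_in_coords:
                raise FormatError(
                    f"{sidecar_path}: orphan row (frame={key[0]}, "
                    f"water_id={key[1]}) not present in {coords_path}")
            side[key] = row

    frames: list[list[WaterObservation]] = []
    for f, frame_raw in enumerate(raw):
        frame = []
        for wid, pos in frame_raw:
            orientation = None
            energy = None
            if (f, wid) in side:
                row = side[(f, wid)]
                if {"x", "y", "z"} <= set(row.index):
                    exact = np.array([row["x"], row["y"], row["z"]], dtype=float)
                    if np.max(np.abs(exact - pos)) > 2e-3:
                        raise FormatError(
                            f"sidecar position for (frame={f}, water_id={wid}) "
                            f"disagrees with coordinate file")
                    pos = exact
                if {"qw", "qx", "qy", "qz"} <= set(row.index):
                    q = np.array([row["qw"], row["qx"], row["qy"], row["qz"]],
                                 dtype=float)
                    if np.all(np.isfinite(q)):
                        orientation = tuple(q)
                if "energy_kcal_mol" in row.index and np.isfinite(
                        row["energy_kcal_mol"]):
                    energy = float(row["energy_kcal_mol"])
            frame.append(WaterObservation(
                frame=f, water_id=wid, position=tuple(pos),
                orientation=orientation, energy=energy))
        frames.append(frame)
    n_obs = sum(len(fr) for fr in frames)
    logger.info("read_trajectory(%s): %d frames, %d observations",
                coords_path, len(frames), n_obs)
    return Trajectory(frames=frames)


# ---------------------------------------------------------------------------
# hydration-site maps
# ---------------------------------------------------------------------------

_THERMO_FIELDS = ["dH", "minus_T_dS_trans", "minus_T_dS_orient",
                  "dG_site", "dG_transfer", "T"]


def write_site_map(sites: Sequence, path: str | Path,
                   metadata: dict | None = None) -> None:
    """Serialize hydration sites (with thermodynamics, if present) to JSON."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "metadata": metadata or {},
        "sites": [],
    }
    for s in sites:
        entry = {
            "center": list(map(float, s.center)),
            "occupancy_fraction": float(s.occupancy_fraction),
            "n_frames": int(s.n_frames),
            "members": [[int(f), int(w)] for f, w in s.member_keys()],
        }
        if s.thermo is not None:
            t = s.thermo
            entry["thermo"] = {k: float(getattr(t, k)) for k in _THERMO_FIELDS}
            entry["thermo"]["labels"] = sorted(t.labels)
        payload["sites"].append(entry)
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def read_site_map(path: str | Path):
    """Read a JSON site map back into :class:`HydrationSite` objects.

    A schema_version other than the current one, or a thermo block missing a
    required field, is an error.
    """
    from .hydration_cluster import HydrationSite
    from .site_thermo import SiteThermo

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: schema_version {payload.get('schema_version')!r} "
            f"!= expected {SCHEMA_VERSION!r}")
    sites = []
    for entry in payload["sites"]:
        site = HydrationSite(
            center=np.array(entry["center"], dtype=float),
            members=[],
            occupancy_fraction=float(entry["occupancy_fraction"]),
            n_frames=int(entry["n_frames"]),
            member_keys_cache=[tuple(m) for m in entry["members"]],
        )
        if "thermo" in entry:
            t = entry["thermo"]
            missing = set(_THERMO_FIELDS) - set(t)
            if missing:
                raise FormatError(
                    f"{path}: thermo block missing fields {sorted(missing)}")
            site.thermo = SiteThermo(
                dH=t["dH"], minus_T_dS_trans=t["minus_T_dS_trans"],
                minus_T_dS_orient=t["minus_T_dS_orient"], T=t["T"],
                labels=frozenset(t.get("labels", [])))
        sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# PIE tables
# ---------------------------------------------------------------------------

PIEDA_COLUMNS = ["ES", "EX", "CTmix", "DI"]


def _decimals(text: str) -> int:
    """Number of printed decimal places of a literal like '-2.5' or '23'."""
    text = text.strip()
    if "e" in text.lower():
        mantissa = text.lower().split("e")[0]
        return _decimals(mantissa)
    return len(text.split(".")[1]) if "." in text else 0


def read_pie_table(path: str | Path):
    """Read a long-format PIE CSV into a :class:`~solvsite.pie_stats.PIEMatrix`.

    Required columns: fragment, ligand, total.  Optional: the PIEDA terms
    ES, EX, CTmix, DI (all present or all absent), dQ, and a per-ligand pic50
    column (must be constant within each ligand).  The printed decimal places
    of total and PIEDA entries are recorded for rounding-aware validation.
    """
    from .pie_stats import PIEMatrix

    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    required = {"fragment", "ligand", "total"}
    if not required <= set(raw.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(raw.columns))}")
    pieda_present = [c for c in PIEDA_COLUMNS if c in raw.columns]
    if pieda_present and len(pieda_present) != len(PIEDA_COLUMNS):
        raise FormatError(
            f"{path}: ragged PIEDA columns — found {pieda_present}, "
            f"need all of {PIEDA_COLUMNS} or none")

    dup = raw.duplicated(subset=["fragment", "ligand"])
    if dup.any():
        first = raw.loc[dup.idxmax()]
        raise FormatError(
            f"{path}: duplicate row for fragment={first['fragment']!r} "
            f"ligand={first['ligand']!r}")

    fragments = list(dict.fromkeys(raw["fragment"]))
    ligands = list(dict.fromkeys(raw["ligand"]))
    for f in fragments:
        for lig in ligands:
            if not ((raw["fragment"] == f) & (raw["ligand"] == lig)).any():
                raise FormatError(
                    f"{path}: missing cell fragment={f!r} ligand={lig!r}")

    def pivot(col: str, as_str: bool = False) -> pd.DataFrame:
        t = raw.pivot(index="fragment", columns="ligand", values=col)
        t = t.reindex(index=fragments, columns=ligands)
        return t if as_str else t.astype(float)

    total = pivot("total")
    decimals = {"total": pivot("total", as_str=True).map(_decimals)}
    pieda = None
    if pieda_present:
        pieda = {c: pivot(c) for c in PIEDA_COLUMNS}
        for c in PIEDA_COLUMNS:
            decimals[c] = pivot(c, as_str=True).map(_decimals)
        if "dQ" in raw.columns:
            pieda["dQ"] = pivot("dQ")

    pic50 = None
    if "pic50" in raw.columns:
        by_lig = raw.dropna(subset=["pic50"]).groupby("ligand")["pic50"]
        if by_lig.nunique().gt(1).any():
            raise FormatError(f"{path}: pic50 not constant within a ligand")
        pic50 = by_lig.first().astype(float).reindex(ligands)
        if pic50.isna().any():
            raise FormatError(f"{path}: pic50 missing for some ligands")

    logger.info("read_pie_table(%s): %d fragments x %d ligands, pieda=%s",
                path, len(fragments), len(ligands), bool(pieda))
    return PIEMatrix(fragments=fragments, ligands=ligands, total=total,
                     pieda=pieda, pic50=pic50, decimals=decimals)


def load_example_pie_table():
    """Load the packaged FPPS/bisphosphonate PIEDA example table.

    Pair interaction energies (kcal/mol) between the side chains of six
    nitrogen-containing bisphosphonates and the FPPS fragments Phe99, Leu100
    and Thr201, decomposed into electrostatic (ES), exchange-repulsion (EX),
    charge-transfer-plus-mixed (CTmix) and dispersion (DI) terms, with the
    charge transferred (dQ, a.u.).
    """
    return read_pie_table(Path(__file__).parent / "data" / "fpps_pieda.csv")
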