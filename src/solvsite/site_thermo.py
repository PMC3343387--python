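"""Per-site hydration thermodynamics.

For every hydration site the module computes, relative to bulk water:

* enthalpy ``dH`` — the mean interaction energy of the site's member waters
  minus the bulk per-water mean;
* translational excess-entropy penalty ``-T dS_trans`` — from the first-order
  (one-body) term of the inhomogeneous-solvation entropy expansion,
  ``-T dS = kB T <ln(rho(r)/rho_bulk)>``, with the one-body density
  ``rho(r) = m p(r)`` (``m`` = mean occupying waters per frame, ``p`` the
  member-position density) estimated by a nearest-neighbor differential
  entropy estimator;
* orientational excess-entropy penalty ``-T dS_orient`` — the analogous
  one-body term relative to the uniform distribution over orientation space
  (total measure 8 pi^2), using the geodesic metric on unit quaternions with
  antipodal identification;
* the site free energy in both sign conventions:
  ``dG_site = dH + (-T dS_trans) + (-T dS_orient)`` (site minus bulk) and
  ``dG_transfer = -dG_site`` (site water transferred to bulk).  Both are
  always reported, because sign conventions for hydration-site maps are a
  recurring source of confusion.

A physics-based nonbonded energy (Lennard-Jones + Coulomb with plain cutoff
truncation) is available as a fallback when observations carry no energies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .hydration_cluster import HydrationSite

logger = logging.getLogger("solvsite")

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872

#: default simulation temperature, K
DEFAULT_T = 300.0

#: Coulomb constant, kcal A / (mol e^2)
COULOMB_K = 332.06

#: Euler-Mascheroni constant (nearest-neighbor estimator bias correction)
EULER_GAMMA = float(np.euler_gamma)

#: total measure of rigid-body orientation space (Euler-angle convention)
ORIENT_MEASURE = 8.0 * math.pi ** 2

#: below this member count the estimators are flagged unreliable
MIN_MEMBERS = 10

ENTHALPY_UNFAVOURABLE = "ENTHALPY_UNFAVOURABLE"
HIGH_MAGNITUDE_DG = "HIGH_MAGNITUDE_DG"


@dataclass(frozen=True)
class BulkReference:
    """Bulk-water baseline: per-water mean energy, number density, temperature."""

    E_bulk: float
    rho_bulk: float
    T: float = DEFAULT_T

    def __post_init__(self):
        if self.rho_bulk <= 0:
            raise ValueError("rho_bulk must be positive")
        if self.T <= 0:
            raise ValueError("T must be positive")


def bulk_reference_from_trajectory(traj, box_volume: float,
                                   T: float = DEFAULT_T) -> BulkReference:
    """Derive the bulk baseline from a bulk trajectory: mean energy + density."""
    energies = [o.energy for o in traj.observations()]
    if any(e is None for e in energies):
        raise ValueError("bulk trajectory has observations without energies")
    if box_volume <= 0:
        raise ValueError("box_volume must be positive")
    n_per_frame = sum(len(f) for f in traj.frames) / traj.n_frames
    return BulkReference(E_bulk=float(np.mean(energies)),
                         rho_bulk=n_per_frame / box_volume, T=T)


@dataclass(frozen=True)
class SiteThermo:
    """Thermodynamic summary of one hydration site (kcal/mol; T in K)."""

    dH: float
    minus_T_dS_trans: float
    minus_T_dS_orient: float
    T: float = DEFAULT_T
    labels: frozenset[str] = frozenset()

    @property
    def dG_site(self) -> float:
        return self.dH + self.minus_T_dS_trans + self.minus_T_dS_orient

    @property
    def dG_transfer(self) -> float:
        return -self.dG_site


@dataclass(frozen=True)
class EntropyEstimate:
    """An excess-entropy penalty with reliability bookkeeping."""

    minus_T_dS: float
    reliable: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# enthalpy
# ---------------------------------------------------------------------------

def compute_enthalpy(site: HydrationSite, bulk: BulkReference) -> float:
    """Site-minus-bulk mean interaction energy (kcal/mol per water)."""
    energies = []
    for obs in site.members:
        if obs.energy is None:
            raise ValueError(
                f"member (frame={obs.frame}, water_id={obs.water_id}) "
                f"has no energy")
        energies.append(obs.energy)
    if not energies:
        raise ValueError("site has no members")
    return float(np.mean(energies)) - bulk.E_bulk


# ---------------------------------------------------------------------------
# nearest-neighbor entropy estimators
# ---------------------------------------------------------------------------

def _kl_differential_entropy(log_ball_measures: np.ndarray, n: int) -> float:
    """Kozachenko-Leonenko estimate (nats) from per-sample log ball measures."""
    return float(np.mean(log_ball_measures)) + EULER_GAMMA + math.log(n - 1)


def entropy_trans(site: HydrationSite, bulk: BulkReference) -> EntropyEstimate:
    """First-order translational excess-entropy penalty, kcal/mol.

    ``-T dS = kB T ( ln m - H[p] - ln rho_bulk )`` with ``m`` the mean number
    of occupying waters per frame and ``H[p]`` the differential entropy of
    the member-position density, estimated by the first-nearest-neighbor
    estimator with Euler-Mascheroni bias correction.  Uniform members at bulk
    density give zero by construction; localized distributions give a
    positive penalty up to estimator noise.
    """
    pos = np.array([o.position for o in site.members]).reshape(-1, 3)
    n = len(pos)
    if n < 2:
        return EntropyEstimate(0.0, reliable=False, note="fewer than 2 members")
    tree = cKDTree(pos)
    dist, _ = tree.query(pos, k=2)
    eps = dist[:, 1]
    if np.any(eps <= 0):
        # coincident points saturate the estimator instead of raising
        eps = np.maximum(eps, 1e-12)
        note = "saturated: coincident member positions"
        reliable = False
    else:
        note = ""
        reliable = n >= MIN_MEMBERS
        if not reliable:
            note = f"unreliable: only {n} members (< {MIN_MEMBERS})"
    v3 = 4.0 / 3.0 * math.pi
    h = _kl_differential_entropy(np.log(v3 * eps ** 3), n)
    m = n / site.n_frames
    value = KB * bulk.T * (math.log(m) - h - math.log(bulk.rho_bulk))
    return EntropyEstimate(value, reliable=reliable, note=note)


def quat_geodesic_distances(quats: np.ndarray) -> np.ndarray:
    """Pairwise rotation angles (radians) with q = -q identified."""
    dots = np.abs(quats @ quats.T)
    np.clip(dots, -1.0, 1.0, out=dots)
    return 2.0 * np.arccos(dots)


def so3_ball_measure(r: np.ndarray | float) -> np.ndarray | float:
    """Measure of a geodesic ball of radius r in SO(3), total 8 pi^2.

    Under the Haar measure, the fraction of rotations within angle r of a
    given one is (r - sin r)/pi; the full space (r = pi) has measure 8 pi^2.
    """
    return 8.0 * math.pi * (np.asarray(r) - np.sin(r))


def entropy_orient(site: HydrationSite, T: float = DEFAULT_T) -> EntropyEstimate:
    """First-order orientational excess-entropy penalty, kcal/mol.

    ``-T dS = kB T ( ln(8 pi^2) - H[p] )`` with ``H[p]`` the differential
    entropy of the member orientation density over SO(3), estimated by the
    nearest-neighbor estimator using exact geodesic-ball measures (which
    accounts for the curvature of orientation space at large radii).
    Uniform orientations give zero up to estimator noise.
    """
    if any(o.orientation is None for o in site.members):
        missing = next(o for o in site.members if o.orientation is None)
        raise ValueError(
            f"member (frame={missing.frame}, water_id={missing.water_id}) "
            f"has no orientation")
    quats = np.array([o.orientation for o in site.members])
    n = len(quats)
    if n < 2:
        return EntropyEstimate(0.0, reliable=False, note="fewer than 2 members")
    d = quat_geodesic_distances(quats)
    np.fill_diagonal(d, np.inf)
    eps = d.min(axis=1)
    reliable = n >= MIN_MEMBERS
    note = "" if reliable else f"unreliable: only {n} members (< {MIN_MEMBERS})"
    if np.any(eps <= 0):
        eps = np.maximum(eps, 1e-9)
        reliable = False
        note = "saturated: coincident orientations"
    h = _kl_differential_entropy(np.log(so3_ball_measure(eps)), n)
    value = KB * T * (math.log(ORIENT_MEASURE) - h)
    return EntropyEstimate(value, reliable=reliable, note=note)


# ---------------------------------------------------------------------------
# free energy and classification
# ---------------------------------------------------------------------------

def site_free_energy(dH: float, minus_T_dS_trans: float,
                     minus_T_dS_orient: float, T: float = DEFAULT_T
                     ) -> SiteThermo:
    """Assemble the site free energy; both sign conventions are exposed."""
    for name, v in (("dH", dH), ("minus_T_dS_trans", minus_T_dS_trans),
                    ("minus_T_dS_orient", minus_T_dS_orient)):
        if not math.isfinite(v):
            raise ValueError(f"{name} is not finite")
    return SiteThermo(dH=dH, minus_T_dS_trans=minus_T_dS_trans,
                      minus_T_dS_orient=minus_T_dS_orient, T=T)


def classify_sites(sites: Sequence[HydrationSite],
                   dG_threshold: float = 3.0) -> list[frozenset[str]]:
    """Label sites: enthalpically unfavourable (dH > 0) and |dG| >= threshold.

    The magnitude test is convention-free: it flags sites whose displacement
    matters regardless of which sign convention a reader assumes.
    """
    labels_per_site = []
    for site in sites:
        if site.thermo is None:
            raise ValueError("site thermodynamics not populated")
        labels = set()
        if site.thermo.dH > 0:
            labels.add(ENTHALPY_UNFAVOURABLE)
        if abs(site.thermo.dG_site) >= dG_threshold:
            labels.add(HIGH_MAGNITUDE_DG)
        labels_per_site.append(frozenset(labels))
        site.thermo = SiteThermo(
            dH=site.thermo.dH,
            minus_T_dS_trans=site.thermo.minus_T_dS_trans,
            minus_T_dS_orient=site.thermo.minus_T_dS_orient,
            T=site.thermo.T, labels=frozenset(labels))
    return labels_per_site


def attach_thermodynamics(sites: Sequence[HydrationSite],
                          bulk: BulkReference,
                          dG_threshold: float = 3.0) -> None:
    """Compute and attach dH, both entropy terms, dG and labels to each site."""
    for site in sites:
        dH = compute_enthalpy(site, bulk)
        ts = entropy_trans(site, bulk)
        to = entropy_orient(site, T=bulk.T)
        site.thermo = site_free_energy(dH, ts.minus_T_dS, to.minus_T_dS,
                                       T=bulk.T)
    classify_sites(sites, dG_threshold=dG_threshold)


# ---------------------------------------------------------------------------
# fallback nonbonded energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NonbondedParams:
    """Per-element Lennard-Jones parameters and point charges.

    ``lj`` maps element symbol to (epsilon kcal/mol, sigma A); ``charge``
    maps atom name (takes precedence) or element symbol to charge in e.
    Lorentz-Berthelot combining rules; plain cutoff truncation, no switching,
    no periodic images.
    """

    lj: Mapping[str, tuple[float, float]]
    charge: Mapping[str, float] = field(default_factory=dict)
    cutoff: float = 9.0

    def __post_init__(self):
        for el, (eps, sig) in self.lj.items():
            if eps < 0 or sig <= 0:
                raise ValueError(f"bad LJ parameters for {el}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def lookup_lj(self, element: str) -> tuple[float, float]:
        if element not in self.lj:
            raise KeyError(f"no Lennard-Jones parameters for element {element!r}")
        return self.lj[element]

    def lookup_charge(self, name: str, element: str) -> float:
        if name in self.charge:
            return self.charge[name]
        return self.charge.get(element, 0.0)


def pair_energy(pos_a: np.ndarray, el_a: str, q_a: float,
                pos_b: np.ndarray, el_b: str, q_b: float,
                params: NonbondedParams) -> float:
    r = float(np.linalg.norm(pos_a - pos_b))
    if r >= params.cutoff or r == 0.0:
        return 0.0
    eps_a, sig_a = params.lookup_lj(el_a)
    eps_b, sig_b = params.lookup_lj(el_b)
    eps = math.sqrt(eps_a * eps_b)
    sig = 0.5 * (sig_a + sig_b)
    sr6 = (sig / r) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    coulomb = COULOMB_K * q_a * q_b / r
    return lj + coulomb


def compute_interaction_energy(
        water_atoms: Sequence[tuple[str, str, np.ndarray]],
        environment_atoms: Sequence[tuple[str, str, np.ndarray]],
        params: NonbondedParams) -> float:
    """Nonbonded water-environment interaction energy (kcal/mol).

    Atoms are (name, element, position) triples; the water is the 3-site
    rigid model (O, H1, H2).  The sum runs over all water-environment pairs
    within the cutoff; the pairwise form makes it symmetric under exchanging
    the roles of two waters.
    """
    total = 0.0
    for name_w, el_w, pos_w in water_atoms:
        q_w = params.lookup_charge(name_w, el_w)
        for name_e, el_e, pos_e in environment_atoms:
            q_e = params.lookup_charge(name_e, el_e)
            total += pair_energy(np.asarray(pos_w), el_w, q_w,
                                 np.asarray(pos_e), el_e, q_e, params)
    return total
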