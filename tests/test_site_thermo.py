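"""Thermodynamics: enthalpy, entropy estimators vs quadrature, identities."""

import math

import numpy as np
import pytest

from solvsite import (
    ENTHALPY_UNFAVOURABLE, HIGH_MAGNITUDE_DG, KB, BulkReference,
    HydrationSite, NonbondedParams, SiteSpec, WaterObservation,
    classify_sites, compute_enthalpy, compute_interaction_energy,
    entropy_orient, entropy_trans, gen_water_trajectory, sample_orientations,
    site_free_energy,
)
from solvsite.site_thermo import pair_energy

RHO_BULK = 0.0334
T = 300.0
BULK = BulkReference(E_bulk=-22.0, rho_bulk=RHO_BULK, T=T)


def make_site(positions, orientations=None, energies=None, n_frames=None):
    n = len(positions)
    members = [WaterObservation(
        frame=i, water_id=0, position=tuple(positions[i]),
        orientation=None if orientations is None else tuple(orientations[i]),
        energy=None if energies is None else float(energies[i]))
        for i in range(n)]
    return HydrationSite(center=np.mean(positions, axis=0), members=members,
                         occupancy_fraction=1.0,
                         n_frames=n_frames or n)


# ---------------------------------------------------------------------------
# quadrature oracles (independent of the nearest-neighbor estimators)
# ---------------------------------------------------------------------------

def quadrature_trans(sigma, m=1.0, rho=RHO_BULK, half_width=6.0, npts=161):
    """Grid quadrature of kB T * int p ln(m p / rho) for an isotropic Gaussian."""
    g = np.linspace(-half_width * sigma, half_width * sigma, npts)
    dx = g[1] - g[0]
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    p = np.exp(-(X ** 2 + Y ** 2 + Z ** 2) / (2 * sigma ** 2)) \
        / (2 * math.pi * sigma ** 2) ** 1.5
    integrand = np.where(p > 0, p * np.log(np.maximum(m * p / rho, 1e-300)), 0.0)
    return KB * T * float(np.sum(integrand)) * dx ** 3


def quadrature_orient(kappa):
    """1-D quadrature of the orientational KL divergence for the vMF model.

    The antipodally-identified von Mises-Fisher density depends only on the
    rotation angle theta to the reference; under the Haar measure the angle
    density is (2/pi) sin^2(theta/2), reducing the SO(3) integral to 1-D.
    """
    from scipy.integrate import quad
    f = lambda th: (2 / math.pi) * math.sin(th / 2) ** 2  # noqa: E731
    c0, _ = quad(lambda th: f(th) * math.cosh(kappa * math.cos(th / 2)),
                 0, math.pi)
    g = lambda th: math.cosh(kappa * math.cos(th / 2)) / c0  # noqa: E731
    d, _ = quad(lambda th: f(th) * g(th) * math.log(g(th)), 0, math.pi)
    return KB * T * d


# ---------------------------------------------------------------------------
# enthalpy
# ---------------------------------------------------------------------------

class TestEnthalpy:
    def test_bulk_equal_energies_give_zero(self):
        site = make_site(np.zeros((20, 3)) + np.arange(20)[:, None] * 0.01,
                         energies=np.full(20, -22.0))
        assert compute_enthalpy(site, BULK) == 0.0

    def test_constant_offset(self):
        site = make_site(np.random.default_rng(0).normal(size=(15, 3)),
                         energies=np.full(15, -25.0))
        assert compute_enthalpy(site, BULK) == pytest.approx(-3.0)

    def test_sample_mean_recovery(self, rng):
        # mean of 1000 N(-18, 1) draws: 3-sigma band is 4.0 +/- 0.095
        energies = rng.normal(-18.0, 1.0, size=1000)
        site = make_site(rng.normal(size=(1000, 3)) * 0.2, energies=energies)
        dh = compute_enthalpy(site, BULK)
        assert dh == pytest.approx(4.0, abs=3 / math.sqrt(1000))

    def test_missing_energy_names_member(self):
        site = make_site(np.zeros((3, 3)) + np.eye(3))
        with pytest.raises(ValueError, match=r"frame=0.*water_id=0"):
            compute_enthalpy(site, BULK)


# ---------------------------------------------------------------------------
# translational entropy
# ---------------------------------------------------------------------------

class TestEntropyTrans:
    def test_uniform_at_bulk_density_is_null(self, rng):
        # ~2000 points uniform in a sphere, one frame holding rho*V waters
        radius = 5.0
        volume = 4 / 3 * math.pi * radius ** 3
        per_frame = RHO_BULK * volume
        n_frames = int(round(2000 / per_frame))
        n = int(round(n_frames * per_frame))
        pts = []
        while len(pts) < n:
            p = rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(p) <= radius:
                pts.append(p)
        site = make_site(np.array(pts), n_frames=n_frames)
        est = entropy_trans(site, BULK)
        assert est.reliable
        assert abs(est.minus_T_dS) < 0.1

    @pytest.mark.parametrize("sigma", [0.15, 0.25, 0.35])
    def test_matches_quadrature_within_5pct(self, sigma, rng):
        pts = rng.normal(scale=sigma, size=(2000, 3))
        site = make_site(pts)
        est = entropy_trans(site, BULK).minus_T_dS
        oracle = quadrature_trans(sigma)
        assert abs(est - oracle) / abs(oracle) < 0.05

    def test_tighter_distribution_larger_penalty(self, rng):
        tight = make_site(rng.normal(scale=0.15, size=(2000, 3)))
        loose = make_site(rng.normal(scale=0.35, size=(2000, 3)))
        assert entropy_trans(tight, BULK).minus_T_dS > \
            entropy_trans(loose, BULK).minus_T_dS

    def test_occupancy_enters_density(self, rng):
        # same spread, half occupancy -> local density halves: penalty drops
        # by exactly kB T ln 2
        pts = rng.normal(scale=0.25, size=(1000, 3))
        full = make_site(pts, n_frames=1000)
        half = make_site(pts, n_frames=2000)
        diff = (entropy_trans(full, BULK).minus_T_dS
                - entropy_trans(half, BULK).minus_T_dS)
        assert diff == pytest.approx(KB * T * math.log(2), abs=1e-9)

    def test_few_members_flagged_unreliable(self):
        site = make_site(np.random.default_rng(1).normal(size=(5, 3)))
        est = entropy_trans(site, BULK)
        assert not est.reliable
        assert "unreliable" in est.note

    def test_coincident_members_saturate_not_raise(self):
        site = make_site(np.zeros((50, 3)))
        est = entropy_trans(site, BULK)
        assert not est.reliable
        assert "saturated" in est.note
        assert math.isfinite(est.minus_T_dS)


# ---------------------------------------------------------------------------
# orientational entropy
# ---------------------------------------------------------------------------

class TestEntropyOrient:
    def test_uniform_is_null(self, rng):
        q = sample_orientations(2000, 0.0, (1, 0, 0, 0), rng)
        site = make_site(np.zeros((2000, 3)), orientations=q)
        est = entropy_orient(site, T=T)
        assert est.reliable
        assert abs(est.minus_T_dS) < 0.1

    def test_larger_kappa_larger_penalty(self, rng):
        qa = sample_orientations(2000, 5.0, (1, 0, 0, 0), rng)
        qb = sample_orientations(2000, 20.0, (1, 0, 0, 0), rng)
        a = entropy_orient(make_site(np.zeros((2000, 3)), orientations=qa), T=T)
        b = entropy_orient(make_site(np.zeros((2000, 3)), orientations=qb), T=T)
        assert b.minus_T_dS > a.minus_T_dS > 0

    @pytest.mark.parametrize("kappa", [5.0, 20.0])
    def test_matches_quadrature_within_5pct(self, kappa, rng):
        q = sample_orientations(2000, kappa, (1, 0, 0, 0), rng)
        site = make_site(np.zeros((2000, 3)), orientations=q)
        est = entropy_orient(site, T=T).minus_T_dS
        oracle = quadrature_orient(kappa)
        assert abs(est - oracle) / abs(oracle) < 0.05

    def test_antipodal_quaternions_identified(self, rng):
        q = sample_orientations(500, 10.0, (1, 0, 0, 0), rng)
        flipped = q * np.where(rng.random(500) < 0.5, -1.0, 1.0)[:, None]
        a = entropy_orient(make_site(np.zeros((500, 3)), orientations=q), T=T)
        b = entropy_orient(make_site(np.zeros((500, 3)), orientations=flipped),
                           T=T)
        assert a.minus_T_dS == pytest.approx(b.minus_T_dS, abs=1e-9)

    def test_missing_orientation_rejected(self):
        site = make_site(np.zeros((12, 3)))
        with pytest.raises(ValueError, match="no orientation"):
            entropy_orient(site)


# ---------------------------------------------------------------------------
# free energy, classification, identities
# ---------------------------------------------------------------------------

class TestFreeEnergy:
    def test_all_zero(self):
        t = site_free_energy(0.0, 0.0, 0.0)
        assert t.dG_site == 0.0 and t.dG_transfer == 0.0

    def test_hand_arithmetic(self):
        t = site_free_energy(-2.0, 3.0, 2.0)
        assert t.dG_site == 3.0
        assert t.dG_transfer == -3.0

    def test_enthalpy_only(self):
        assert site_free_energy(1.2, 0.0, 0.0).dG_site == 1.2

    def test_identities_exact_on_generated_run(self, three_site_run):
        for s in three_site_run["sites"]:
            t = s.thermo
            assert t.dG_site == t.dH + t.minus_T_dS_trans + t.minus_T_dS_orient
            assert t.dG_transfer == -t.dG_site

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="dH"):
            site_free_energy(float("nan"), 0.0, 0.0)


class TestClassification:
    def _site_with(self, dH, ts, to):
        s = HydrationSite(center=np.zeros(3), members=[],
                          occupancy_fraction=1.0, n_frames=1)
        s.thermo = site_free_energy(dH, ts, to)
        return s

    def test_positive_enthalpy_flagged(self):
        s = self._site_with(0.5, 0.0, 0.0)
        labels = classify_sites([s])[0]
        assert ENTHALPY_UNFAVOURABLE in labels

    def test_dg_magnitude_boundary(self):
        below = self._site_with(2.9, 0.0, 0.0)
        at = self._site_with(3.0, 0.0, 0.0)
        assert HIGH_MAGNITUDE_DG not in classify_sites([below])[0]
        assert HIGH_MAGNITUDE_DG in classify_sites([at])[0]

    def test_favourable_high_magnitude(self):
        s = self._site_with(-7.5, 2.0, 2.3)  # dG_site = -3.2
        labels = classify_sites([s])[0]
        assert HIGH_MAGNITUDE_DG in labels
        assert ENTHALPY_UNFAVOURABLE not in labels


# ---------------------------------------------------------------------------
# fallback nonbonded energy
# ---------------------------------------------------------------------------

class TestNonbonded:
    PARAMS = NonbondedParams(lj={"O": (0.15, 3.15), "H": (0.0, 1.0),
                                 "X": (0.2, 3.0)},
                             charge={"O": -0.8, "H": 0.4}, cutoff=9.0)

    def test_lj_zero_at_sigma(self):
        params = NonbondedParams(lj={"X": (0.2, 3.0)}, charge={})
        e = pair_energy(np.zeros(3), "X", 0.0, np.array([3.0, 0, 0]), "X",
                        0.0, params)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_coulomb_hand_value(self):
        params = NonbondedParams(lj={"Q": (0.0, 1.0)}, charge={})
        e = pair_energy(np.zeros(3), "Q", 1.0, np.array([3.32, 0, 0]), "Q",
                        -1.0, params)
        assert e == pytest.approx(-332.06 / 3.32, rel=1e-9)
        assert e == pytest.approx(-100.0, abs=0.05)

    def test_beyond_cutoff_is_zero(self):
        e = pair_energy(np.zeros(3), "O", -0.8, np.array([9.5, 0, 0]), "O",
                        -0.8, self.PARAMS)
        assert e == 0.0

    def test_water_pair_symmetric(self):
        w1 = [("O", "O", np.array([0.0, 0, 0])),
              ("H1", "H", np.array([0.96, 0, 0])),
              ("H2", "H", np.array([-0.24, 0.93, 0]))]
        w2 = [(n, el, p + np.array([3.0, 0.5, 0.2])) for n, el, p in w1]
        e12 = compute_interaction_energy(w1, w2, self.PARAMS)
        e21 = compute_interaction_energy(w2, w1, self.PARAMS)
        assert e12 == pytest.approx(e21, rel=1e-12)
        assert e12 != 0.0

    def test_missing_element_named(self):
        with pytest.raises(KeyError, match="ZN"):
            compute_interaction_energy(
                [("O", "O", np.zeros(3))],
                [("ZN", "ZN", np.array([2.0, 0, 0]))], self.PARAMS)


class TestEnthalpyRecoveryOnTrajectories:
    def test_planted_energy_mean_recovered(self, three_site_run):
        sites = three_site_run["sites"]
        truth = three_site_run["truth"]
        for planted in truth["sites"]:
            center = np.array(planted["center"])
            nearest = min(sites,
                          key=lambda s: np.linalg.norm(s.center - center))
            expected = planted["energy_mean"] - BULK.E_bulk
            n = nearest.n_members
            band = 3 * planted["energy_sd"] / math.sqrt(n)
            assert abs(nearest.thermo.dH - expected) <= band
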