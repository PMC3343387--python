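"""Ring perception and contact detection on planted geometries."""

import math
from collections import Counter

import numpy as np
import pytest

from solvsite import (
    Atom, ContactCriteria, ContactType, PlantedContact, Structure,
    contact_report, detect_contacts, find_rings, gen_complex_structure,
)


def _atom(serial, name, element, pos, res_name="LIG", res_seq=1, chain="L",
          hetero=True):
    return Atom(serial=serial, name=name, element=element, res_name=res_name,
                res_seq=res_seq, chain=chain, position=tuple(pos),
                hetero=hetero)


def benzene(center=(0, 0, 0), z=0.0):
    pts = []
    for k in range(6):
        ang = math.pi / 3 * k
        pts.append((center[0] + 1.39 * math.cos(ang),
                    center[1] + 1.39 * math.sin(ang), center[2] + z))
    return pts


class TestFindRings:
    def test_benzene_single_ring(self):
        atoms = [_atom(i + 1, f"C{i + 1}", "C", p)
                 for i, p in enumerate(benzene())]
        rings = find_rings(Structure(atoms=atoms))
        assert len(rings) == 1
        np.testing.assert_allclose(rings[0].centroid, (0, 0, 0), atol=1e-9)
        assert np.linalg.norm(rings[0].normal) == pytest.approx(1.0)

    def test_cyclohexane_chair_rejected(self):
        # realistic chair: +-0.23 A pucker passes planarity numerically,
        # so rejection must come from the sp3 (4-bond) carbon filter
        atoms = []
        serial = 0
        for k in range(6):
            ang = math.pi / 3 * k
            z = 0.23 if k % 2 == 0 else -0.23
            c = np.array([1.46 * math.cos(ang), 1.46 * math.sin(ang), z])
            serial += 1
            atoms.append(_atom(serial, f"C{k + 1}", "C", c))
            radial = np.array([math.cos(ang), math.sin(ang), 0.0])
            for h_off in (1.09 * radial, np.array([0, 0, math.copysign(1.09, z)])):
                serial += 1
                atoms.append(_atom(serial, f"H{serial}", "H", c + h_off))
        assert find_rings(Structure(atoms=atoms)) == []

    def test_fused_bicyclic_two_rings(self):
        # 6-ring fused to a regular planar 5-ring across one bond
        # (imidazopyridine-like)
        hexa = benzene()
        a_v, b_v = np.array(hexa[0]), np.array(hexa[1])
        mid = (a_v + b_v) / 2
        out = mid / np.linalg.norm(mid)  # away from the hexagon center
        apothem = 1.39 / (2 * math.tan(math.pi / 5))
        c5 = mid + apothem * out
        # rotate A about the pentagon center in 72 deg steps toward B's side
        def rot(v, ang):
            c, s = math.cos(ang), math.sin(ang)
            return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])
        step = 2 * math.pi / 5
        sign = 1 if np.allclose(c5 + rot(a_v - c5, step), b_v, atol=1e-6) \
            else -1
        extra = [c5 + rot(a_v - c5, sign * step * k) for k in (2, 3, 4)]
        atoms = [_atom(i + 1, f"C{i + 1}", "C", p)
                 for i, p in enumerate(hexa)]
        atoms += [_atom(7, "N1", "N", extra[0]),
                  _atom(8, "C7", "C", extra[1]),
                  _atom(9, "N2", "N", extra[2])]
        rings = find_rings(Structure(atoms=atoms))
        assert len(rings) == 2
        members = [frozenset(a.serial for a in r.atoms) for r in rings]
        assert len(members[0] & members[1]) == 2


class TestDetectionExamples:
    def test_single_planted_hbond_only(self):
        structure, _ = gen_complex_structure(
            [PlantedContact(ContactType.HBOND,
                            {"distance": 2.9, "angle": 165.0})])
        contacts = detect_contacts(structure, "LIG")
        assert [c.contact_type for c in contacts] == [ContactType.HBOND]
        assert contacts[0].distance == pytest.approx(2.9, abs=1e-6)
        assert contacts[0].angle == pytest.approx(165.0, abs=0.01)

    def test_bifurcated_motif(self):
        structure, _ = gen_complex_structure(
            [PlantedContact(ContactType.BIFURCATED_HBOND,
                            {"distance1": 2.8, "distance2": 3.0})])
        counts = Counter(c.contact_type for c in
                         detect_contacts(structure, "LIG"))
        assert counts[ContactType.HBOND] == 2
        assert counts[ContactType.BIFURCATED_HBOND] == 1

    @pytest.mark.parametrize("perturb,expect_octa", [
        (0.0, True), (10.0, True), (25.0, False),
    ])
    def test_octahedral_flag_tolerance(self, perturb, expect_octa):
        structure, _ = gen_complex_structure(
            [PlantedContact(ContactType.METAL_COORD,
                            {"distance": 2.1, "perturb_deg": perturb})])
        contacts = detect_contacts(structure, "LIG")
        metal = [c for c in contacts
                 if c.contact_type is ContactType.METAL_COORD]
        assert len(metal) == 1
        assert "coordination=6" in metal[0].detail
        assert f"octahedral={expect_octa}" in metal[0].detail

    @pytest.mark.parametrize("tilt,shape", [
        (0.0, "parallel"), (25.0, "parallel"), (45.0, "inclined"),
        (80.0, "T-shaped")])
    def test_pipi_shape_classification(self, tilt, shape):
        structure, _ = gen_complex_structure(
            [PlantedContact(ContactType.PI_PI,
                            {"distance": 4.4, "angle": tilt})])
        pipi = [c for c in detect_contacts(structure, "LIG")
                if c.contact_type is ContactType.PI_PI]
        assert len(pipi) == 1
        assert pipi[0].detail == shape
        assert pipi[0].angle == pytest.approx(tilt, abs=0.5)

    @pytest.mark.parametrize("d,found", [(3.34, True), (3.36, False)])
    def test_hbond_distance_boundary(self, d, found):
        # strict inequality on the open side, probed at the default 3.35
        structure, _ = gen_complex_structure(
            [PlantedContact(ContactType.HBOND, {"distance": d})])
        hbonds = [c for c in detect_contacts(structure, "LIG")
                  if c.contact_type is ContactType.HBOND]
        assert bool(hbonds) is found

    @pytest.mark.parametrize("angle,found", [(120.5, True), (119.5, False)])
    def test_hbond_angle_boundary(self, angle, found):
        structure, _ = gen_complex_structure(
            [PlantedContact(ContactType.HBOND,
                            {"distance": 2.9, "angle": angle})])
        hbonds = [c for c in detect_contacts(structure, "LIG")
                  if c.contact_type is ContactType.HBOND]
        assert bool(hbonds) is found

    def test_no_hydrogen_distance_only_mode(self):
        # donor without hydrogens: distance-only detection, flagged no-H
        atoms = [_atom(1, "N1", "N", (0, 0, 0)),
                 _atom(2, "OG1", "O", (2.9, 0, 0), res_name="THR",
                       res_seq=100, chain="A", hetero=False)]
        contacts = detect_contacts(Structure(atoms=atoms), "LIG")
        assert len(contacts) == 1
        assert contacts[0].detail == "no-H"
        assert contacts[0].angle is None

    def test_role_swap_preserves_geometry(self):
        # same pair detected from either side: identical distance and angle
        structure, _ = gen_complex_structure(
            [PlantedContact(ContactType.HBOND)])
        fwd = detect_contacts(structure, "LIG")
        swapped = detect_contacts(structure, lambda a: a.res_name != "LIG")
        assert len(fwd) == len(swapped) == 1
        assert fwd[0].distance == pytest.approx(swapped[0].distance)
        assert fwd[0].angle == pytest.approx(swapped[0].angle)


class TestManifestAgreement:
    def test_perfect_recall_and_precision(self, planted_complex):
        structure, manifest = planted_complex
        detected = detect_contacts(structure, "LIG")
        expected = Counter(m["contact_type"] for m in manifest)
        got = Counter(c.contact_type.name for c in detected)
        assert got == expected

    def test_bifurcated_supported_by_member_hbonds(self, planted_complex):
        structure, _ = planted_complex
        contacts = detect_contacts(structure, "LIG")
        for c in contacts:
            if c.contact_type is ContactType.BIFURCATED_HBOND:
                assert len(c.members) >= 2
                assert all(m.contact_type is ContactType.HBOND
                           for m in c.members)
                shared = {id(m.partner_a) for m in c.members}
                assert len(shared) == 1  # one donor shared by all members


class TestContactReport:
    def test_empty(self):
        rep = contact_report([])
        assert rep["counts"] == {}
        assert rep["n_contacts"] == 0

    def test_counts_per_type(self, planted_complex):
        structure, manifest = planted_complex
        rep = contact_report(detect_contacts(structure, "LIG"))
        expected = Counter(m["contact_type"] for m in manifest)
        assert rep["counts"] == dict(expected)
        assert rep["residues"] == sorted(
            rep["residues"], key=lambda r: (r["chain"], r["res_seq"]))

    def test_richer_profile_dominates(self):
        # bifurcated + many hydrophobic vs single H-bond + few hydrophobic:
        # the richer ligand's counts strictly dominate
        rich, _ = gen_complex_structure(
            [PlantedContact(ContactType.BIFURCATED_HBOND)]
            + [PlantedContact(ContactType.HYDROPHOBIC)] * 6)
        poor, _ = gen_complex_structure(
            [PlantedContact(ContactType.HBOND),
             PlantedContact(ContactType.HYDROPHOBIC),
             PlantedContact(ContactType.HYDROPHOBIC)])
        rep_rich = contact_report(detect_contacts(rich, "LIG"))["counts"]
        rep_poor = contact_report(detect_contacts(poor, "LIG"))["counts"]
        assert rep_rich["HYDROPHOBIC"] > rep_poor["HYDROPHOBIC"]
        assert rep_rich.get("BIFURCATED_HBOND", 0) > \
            rep_poor.get("BIFURCATED_HBOND", 0)
        assert rep_rich["HBOND"] > rep_poor["HBOND"]


class TestCriteriaValidation:
    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            ContactCriteria(hbond_max_da=0.0)

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ValueError):
            ContactCriteria(hbond_min_angle=200.0)
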