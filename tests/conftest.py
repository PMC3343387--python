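import numpy as np
import pytest

from solvsite import (
    BulkReference, ClusterParams, PlantedContact, ContactType, RegionSpec,
    SiteSpec, attach_thermodynamics, cluster_sites, gen_complex_structure,
    gen_water_trajectory, pool_observations,
)

#: the three-site pocket used across the clustering / pipeline tests:
#: well-separated sites with distinct occupancies and energies
THREE_SITE_SPECS = [
    SiteSpec(center=(0.0, 0.0, 0.0), occupancy_p=1.0, sigma_pos=0.2,
             energy_mean=-25.0, energy_sd=1.0),
    SiteSpec(center=(5.0, 0.0, 0.0), occupancy_p=0.8, sigma_pos=0.2,
             energy_mean=-18.0, energy_sd=1.0, kappa=20.0),
    SiteSpec(center=(0.0, 6.0, 0.0), occupancy_p=0.6, sigma_pos=0.2,
             energy_mean=-22.0, energy_sd=1.0),
]

BULK = BulkReference(E_bulk=-22.0, rho_bulk=0.0334, T=300.0)

ALL_CONTACT_TYPES = [
    PlantedContact(ContactType.HBOND),
    PlantedContact(ContactType.BIFURCATED_HBOND),
    PlantedContact(ContactType.CHO_HBOND),
    PlantedContact(ContactType.SALT_BRIDGE),
    PlantedContact(ContactType.METAL_COORD),
    PlantedContact(ContactType.PI_PI),
    PlantedContact(ContactType.HYDROPHOBIC),
]


@pytest.fixture(scope="session")
def three_site_run():
    """Planted 3-site trajectory (500 frames), clustered, with thermo."""
    traj, truth = gen_water_trajectory(THREE_SITE_SPECS, None, 500, seed=11)
    obs = pool_observations(traj, RegionSpec(
        kind="box", box_min=(-5, -5, -5), box_max=(10, 11, 5)))
    # claiming radius ~7.5 sigma_pos so occupancy recovery is limited by
    # Bernoulli sampling, not positional tail truncation
    sites = cluster_sites(obs, ClusterParams(site_radius=1.5,
                                             min_center_separation=3.0),
                          traj.n_frames)
    attach_thermodynamics(sites, BULK)
    return {"traj": traj, "truth": truth, "sites": sites, "bulk": BULK}


@pytest.fixture(scope="session")
def planted_complex():
    structure, manifest = gen_complex_structure(ALL_CONTACT_TYPES, seed=0)
    return structure, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
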