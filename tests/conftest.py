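"""Shared fixtures.

Heavy simulation fixtures are session-scoped so the thermostat, stability and
mobility analyses all read from the same runs.
"""

import numpy as np
import pytest

from coacwet import dynamics, engine, synth
from coacwet.model import SPECIES, PairTable, SimProtocol


@pytest.fixture(scope="session")
def patch128_production():
    """128-lipid patch taken through the published protocol.

    Build + strong-coupling thermalization + published equilibration, then a
    1e5-step production run (dt*=0.005, T*=1.1, damping 50).
    """
    state = synth.equilibrated_patch(128, seed=1)
    return engine.langevin_run(
        state,
        SimProtocol(dt_star=0.005, n_steps=100_000, dump_interval=10_000, seed=3),
        temp_stride=10,
    )


def wetted_patch_run(eps_pl: float, seed: int = 1):
    """512-lipid patch with an adsorbed 60-chain droplet, production frames.

    Returns (times, head positions, per-frame contact labels, mean counts).
    """
    pt = PairTable.default(eps_pl=eps_pl, omega_tt=1.70)
    state = synth.gen_small_cg_fixtures("patch512+droplet", seed=seed, pair_table=pt)
    th = engine.langevin_run(state, SimProtocol(
        dt_star=0.002, n_steps=12_000, dump_interval=12_000, seed=seed + 10,
        damping=2.0))
    prod = engine.langevin_run(th.state, SimProtocol(
        dt_star=0.005, n_steps=30_000, dump_interval=50, seed=seed + 20))
    times, pos = dynamics.head_trajectory(prod)
    labels = dynamics.contact_labels_over_time(prod, cutoff=1.5)
    return times, pos, labels


@pytest.fixture(scope="session")
def wetted_mobility_curves():
    """Displacement-ratio plateaus at weak and strong membrane adhesion."""
    out = {}
    for eps_pl in (0.7, 1.3):
        times, pos, labels = wetted_patch_run(eps_pl)
        out[eps_pl] = dynamics.displacement_ratio(times, pos, labels, n_boot=200)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_lipid_cluster(n_lipids=16, n_free_heads=2, box=30.0, seed=7):
    """~50-bead open-boundary cluster: a tiny bilayer disc plus free heads."""
    from coacwet.builders import _add_lipid, _state

    rng = np.random.default_rng(seed)
    species, mol, pos, bonds = [], [], [], []
    bead = 0
    mol_id = 0
    side = int(np.ceil(np.sqrt(n_lipids // 2)))
    a = 1.1
    for z_head, dirz in [(box / 2 + 2.4, -1.0), (box / 2 - 2.4, 1.0)]:
        cnt = 0
        for ix in range(side):
            for iy in range(side):
                if cnt >= n_lipids // 2:
                    break
                head = np.array([box / 2 + ix * a, box / 2 + iy * a, z_head])
                bead = _add_lipid(species, mol, pos, bonds, head,
                                  np.array([0.0, 0.0, dirz]), mol_id, bead)
                mol_id += 1
                cnt += 1
    for _ in range(n_free_heads):
        species.append(SPECIES["H"])
        mol.append(mol_id)
        mol_id += 1
        pos.append(rng.uniform(box / 2 + 6, box / 2 + 8, size=3))
        bead += 1
    s = _state(box, species, mol, pos, bonds, PairTable.default(), 0.0, rng)
    return engine.minimize(s, n_iter=200)
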