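"""System builders: polymer droplets, vesicles, flat bilayer patches.

All builders are deterministic under (parameters, seed) and return states with
Maxwell-Boltzmann velocities at the default target temperature T* = 1.1.
"""

from __future__ import annotations

import numpy as np

from coacwet import engine
from coacwet.model import (
    BOND_FENE,
    BOND_HARMONIC,
    PairTable,
    SPECIES,
    SystemState,
)

CHAIN_LEN = 10
LIPID_LEN = 3
HARMONIC_K = 50.0
HARMONIC_REQ = 0.548
FENE_K = 30.0
FENE_RINF = 1.5

# head-surface area per lipid used when laying out vesicles; chosen so the
# published build (diameter 50, two leaflets) carries ~9500 lipids
VESICLE_APL = 1.36
# initial area per lipid for flat patches (fluid-phase three-bead lipids)
PATCH_APL = 1.20


class CapacityError(RuntimeError):
    """Geometry cannot accommodate the requested bead count."""


def _state(box, species, mol, pos, bonds, pair_table, T_star, rng):
    species = np.asarray(species, dtype=np.int64)
    mol = np.asarray(mol, dtype=np.int64)
    pos = np.asarray(pos, dtype=float)
    if bonds:
        bi, bj, bs, bk, br = (np.asarray(x) for x in zip(*bonds))
    else:
        bi = bj = bs = np.empty(0, dtype=np.int64)
        bk = br = np.empty(0)
    return SystemState(
        box_length=float(box),
        species=species,
        mol=mol,
        positions=pos,
        velocities=engine.maxwell_velocities(len(species), T_star, rng),
        bond_i=bi.astype(np.int64),
        bond_j=bj.astype(np.int64),
        bond_style=bs.astype(np.int64),
        bond_k=bk.astype(float),
        bond_r0=br.astype(float),
        pair_table=pair_table,
    )


def build_polymer_droplet(n_chains_per_species: int, box_length: float = 40.0,
                          seed: int = 0, pair_table: PairTable | None = None,
                          T_star: float = 1.1, minimize_iters: int = 200,
                          max_tries: int = 50,
                          region_radius: float | None = None,
                          relax: bool = True) -> SystemState:
    """Equal numbers of A10 and B10 chains placed at random in a cubic box.

    Chains are laid down as short random walks with the harmonic equilibrium
    bond length; the state is then energy-minimized until no two beads sit
    closer than 0.8 sigma_AA.  The published droplet uses 1000 chains per
    species in a (40)^3 box.  ``region_radius`` confines chain starts to a
    central ball (compact pre-droplet for assembly fixtures).
    """
    if n_chains_per_species < 1:
        raise ValueError("need at least one chain per species")
    pt = pair_table or PairTable.default()
    rng = np.random.default_rng(seed)
    n_chains = 2 * n_chains_per_species
    species, mol, pos, bonds = [], [], [], []
    bead = 0
    for c in range(n_chains):
        sp = SPECIES["A"] if c < n_chains_per_species else SPECIES["B"]
        if region_radius is not None:
            while True:
                u = rng.uniform(-region_radius, region_radius, size=3)
                if np.linalg.norm(u) <= region_radius:
                    break
            start = np.full(3, box_length / 2.0) + u
        else:
            start = rng.uniform(0, box_length, size=3)
        p = start.copy()
        for k in range(CHAIN_LEN):
            if k > 0:
                step = rng.normal(size=3)
                step *= HARMONIC_REQ / np.linalg.norm(step)
                p = p + step
                bonds.append((bead - 1, bead, BOND_HARMONIC, HARMONIC_K, HARMONIC_REQ))
            species.append(sp)
            mol.append(c)
            pos.append(p.copy())
            bead += 1
    state = _state(box_length, species, mol, pos, bonds, pt, T_star, rng)
    if not relax:
        return state
    sigma_aa = float(pt.sigma[SPECIES["A"], SPECIES["A"]])
    for attempt in range(max_tries):
        state = engine.minimize(state, n_iter=minimize_iters)
        if _min_separation(state) >= 0.8 * sigma_aa:
            return state
    raise CapacityError("could not resolve bead overlaps after bounded retries")


def _min_separation(state: SystemState) -> float:
    from scipy.spatial import cKDTree

    pos = state.wrapped_positions()
    tree = cKDTree(pos, boxsize=state.box_length)
    d, _ = tree.query(pos, k=2)
    return float(d[:, 1].min())


def _fibonacci_sphere(n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """n near-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _add_lipid(species, mol, pos, bonds, head, direction, mol_id, bead0, spacing=0.96):
    """Append one H-T-T lipid starting at ``head`` pointing along ``direction``."""
    species.extend([SPECIES["H"], SPECIES["T"], SPECIES["T"]])
    mol.extend([mol_id] * 3)
    for k in range(3):
        pos.append(head + k * spacing * direction)
    bonds.append((bead0, bead0 + 1, BOND_FENE, FENE_K, FENE_RINF))
    bonds.append((bead0 + 1, bead0 + 2, BOND_FENE, FENE_K, FENE_RINF))
    return bead0 + 3


def build_vesicle(diameter: float = 50.0, box_length: float = 70.0, seed: int = 0,
                  pair_table: PairTable | None = None, T_star: float = 1.1,
                  apl: float = VESICLE_APL) -> SystemState:
    """Unilamellar vesicle: two concentric spherical leaflets of H-T-T lipids.

    Outer-leaflet heads sit at radius ``diameter/2`` pointing outward,
    inner-leaflet heads 3 sigma further in pointing inward; lipid counts
    follow leaflet head-surface area / ``apl``.  The default density gives
    ~9500 lipids at diameter 50.
    """
    r_out = diameter / 2.0
    r_in = r_out - 5.0  # inner head surface; tails meet near r_out - 2.5
    if diameter + 4 >= box_length:
        raise CapacityError("vesicle does not fit in the box")
    if r_in <= 2.0:
        raise CapacityError("diameter too small for two leaflets")
    pt = pair_table or PairTable.default()
    rng = np.random.default_rng(seed)
    n_outer = int(round(4.0 * np.pi * r_out**2 / apl))
    n_inner = int(round(4.0 * np.pi * r_in**2 / apl))
    species, mol, pos, bonds = [], [], [], []
    bead = 0
    mol_id = 0
    center = np.full(3, box_length / 2.0)
    for u in _fibonacci_sphere(n_outer):
        bead = _add_lipid(species, mol, pos, bonds, center + r_out * u, -u, mol_id, bead)
        mol_id += 1
    for u in _fibonacci_sphere(n_inner):
        bead = _add_lipid(species, mol, pos, bonds, center + r_in * u, +u, mol_id, bead)
        mol_id += 1
    state = _state(box_length, species, mol, pos, bonds, pt, T_star, rng)
    return engine.minimize(state, n_iter=50)


def build_bilayer_patch(n_lipids: int = 128, box_xy: float | None = None, seed: int = 0,
                        pair_table: PairTable | None = None, T_star: float = 1.1,
                        box_z: float | None = None, apl: float = PATCH_APL) -> SystemState:
    """Flat periodic bilayer patch, equal leaflet occupancy, normal along z.

    ``box_xy`` defaults to the area holding ``n_lipids/2`` lipids per leaflet
    at the fluid-phase area per lipid.  The box is cubic-periodic; the z
    extent simply leaves vacuum above and below the membrane.
    """
    if n_lipids % 2:
        raise ValueError("n_lipids must be even")
    del box_z  # the box is cubic; z clearance follows from box_xy
    per_leaflet = n_lipids // 2
    side = int(np.ceil(np.sqrt(per_leaflet)))
    if box_xy is None:
        box_xy = float(np.sqrt(per_leaflet * apl))
    a = box_xy / side
    if a * a < 0.8:
        raise CapacityError("area too small for requested lipid count")
    box = float(box_xy)  # cubic box; membrane spans x-y, vacuum above/below
    if box - 4.8 < 2.7:
        raise CapacityError("box too small to isolate the bilayer from its z image")
    pt = pair_table or PairTable.default()
    rng = np.random.default_rng(seed)
    species, mol, pos, bonds = [], [], [], []
    bead = 0
    mol_id = 0
    z_mid = box / 2.0
    placed = 0
    for leaflet, (z_head, dirz) in enumerate([(z_mid + 2.4, -1.0), (z_mid - 2.4, 1.0)]):
        cnt = 0
        for ix in range(side):
            for iy in range(side):
                if cnt >= per_leaflet:
                    break
                jitter = rng.uniform(-0.05, 0.05, size=2)
                head = np.array([((ix + 0.25 + 0.5 * leaflet) * a + jitter[0]) % box,
                                 ((iy + 0.25 + 0.5 * leaflet) * a + jitter[1]) % box,
                                 z_head])
                bead = _add_lipid(species, mol, pos, bonds, head,
                                  np.array([0.0, 0.0, dirz]), mol_id, bead)
                mol_id += 1
                cnt += 1
                placed += 1
    assert placed == n_lipids
    state = _state(box, species, mol, pos, bonds, pt, T_star, rng)
    return engine.minimize(state, n_iter=50)


def subset_state(state: SystemState, keep: np.ndarray) -> SystemState:
    """New state restricted to the beads where ``keep`` is True.

    Bonds with either partner removed are dropped; bead indices are remapped.
    """
    keep = np.asarray(keep, dtype=bool)
    idx = np.flatnonzero(keep)
    remap = -np.ones(state.n_beads, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    bsel = keep[state.bond_i] & keep[state.bond_j]
    return SystemState(
        box_length=state.box_length,
        species=state.species[idx].copy(),
        mol=state.mol[idx].copy(),
        positions=state.positions[idx].copy(),
        velocities=state.velocities[idx].copy(),
        bond_i=remap[state.bond_i[bsel]],
        bond_j=remap[state.bond_j[bsel]],
        bond_style=state.bond_style[bsel].copy(),
        bond_k=state.bond_k[bsel].copy(),
        bond_r0=state.bond_r0[bsel].copy(),
        pair_table=state.pair_table,
        step=state.step,
    )


def assemble_droplet_on_patch(patch: SystemState, droplet: SystemState,
                              gap: float = 1.0, membrane_z: float = 4.5) -> SystemState:
    """Place a pre-formed droplet above a bilayer patch with a ``gap``.

    The patch is shifted so its midplane sits at ``membrane_z``, leaving the
    rest of the (periodic) box free for the droplet, which is recentred over
    the patch with its lowest bead ``gap`` above the highest patch bead
    (published protocol: preformed droplet placed outside the membrane, then
    equilibrated).
    """
    ppos = patch.positions + np.array([0.0, 0.0, membrane_z - patch.positions[:, 2].mean()])
    dpos = droplet.positions - droplet.positions.mean(axis=0)
    top = ppos[:, 2].max()
    shift = np.array([patch.box_length / 2.0, patch.box_length / 2.0,
                      top + gap - dpos[:, 2].min()])
    dpos = dpos + shift
    if dpos[:, 2].max() > patch.box_length - 1.0:
        raise CapacityError("droplet does not fit above the patch in this box")
    nb = patch.n_beads
    return SystemState(
        box_length=patch.box_length,
        species=np.concatenate([patch.species, droplet.species]),
        mol=np.concatenate([patch.mol, droplet.mol + patch.mol.max() + 1]),
        positions=np.concatenate([ppos, dpos]),
        velocities=np.concatenate([patch.velocities, droplet.velocities]),
        bond_i=np.concatenate([patch.bond_i, droplet.bond_i + nb]),
        bond_j=np.concatenate([patch.bond_j, droplet.bond_j + nb]),
        bond_style=np.concatenate([patch.bond_style, droplet.bond_style]),
        bond_k=np.concatenate([patch.bond_k, droplet.bond_k]),
        bond_r0=np.concatenate([patch.bond_r0, droplet.bond_r0]),
        pair_table=patch.pair_table,
    )


def assemble_droplet_on_vesicle(vesicle: SystemState, droplet: SystemState,
                                gap: float = 1.0) -> SystemState:
    """Place a pre-formed droplet outside a vesicle along +z with a ``gap``."""
    vpos = vesicle.positions
    center = vpos.mean(axis=0)
    r_out = np.max(np.linalg.norm(vpos - center, axis=1))
    dpos = droplet.positions - droplet.positions.mean(axis=0)
    d_half = (dpos[:, 2].max() - dpos[:, 2].min()) / 2.0
    dpos = dpos + center + np.array([0.0, 0.0, r_out + gap + d_half])
    nb = vesicle.n_beads
    return SystemState(
        box_length=vesicle.box_length,
        species=np.concatenate([vesicle.species, droplet.species]),
        mol=np.concatenate([vesicle.mol, droplet.mol + vesicle.mol.max() + 1]),
        positions=np.concatenate([vpos, dpos]),
        velocities=np.concatenate([vesicle.velocities, droplet.velocities]),
        bond_i=np.concatenate([vesicle.bond_i, droplet.bond_i + nb]),
        bond_j=np.concatenate([vesicle.bond_j, droplet.bond_j + nb]),
        bond_style=np.concatenate([vesicle.bond_style, droplet.bond_style]),
        bond_k=np.concatenate([vesicle.bond_k, droplet.bond_k]),
        bond_r0=np.concatenate([vesicle.bond_r0, droplet.bond_r0]),
        pair_table=vesicle.pair_table,
    )
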