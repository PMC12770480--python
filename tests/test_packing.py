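"""Area-per-lipid, leaflet assignment, tail order, de-mixing, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coacwet import packing, synth
from coacwet.packing import (
    Membrane,
    apl_contour_map,
    area_per_lipid,
    assign_leaflets,
    cluster_sizes,
    contact_counts,
    demix_fraction,
    periodic_voronoi_areas,
    tail_order,
)


class TestLeafletAssignment:
    def test_flat_bilayer_exact_split(self):
        mem, _ = synth.gen_lattice_leaflet("square", spacing=1.1, n=8)
        asg = assign_leaflets(mem)
        n = mem.n_lipids // 2
        assert len(asg.indices("upper")) == n
        assert len(asg.indices("lower")) == n

    def test_flipping_a_lipid_flips_assignment(self):
        mem, _ = synth.gen_lattice_leaflet("square", spacing=1.1, n=8)
        asg0 = assign_leaflets(mem)
        mem.tail_ends[0] = mem.heads[0] + (mem.heads[0] - mem.tail_ends[0])
        asg1 = assign_leaflets(mem)
        assert asg0.leaflet[0] != asg1.leaflet[0]
        assert np.all(asg0.leaflet[1:] == asg1.leaflet[1:])

    def test_vesicle_outer_exceeds_inner(self):
        from coacwet.builders import build_vesicle

        v = build_vesicle(diameter=20.0, box_length=36.0, seed=1)
        mem = Membrane.from_state(v)
        assert mem.geometry == "vesicle"
        asg = assign_leaflets(mem)
        assert len(asg.indices("upper")) > len(asg.indices("lower"))


class TestAreaPerLipid:
    def test_square_lattice_exact(self):
        mem, gt = synth.gen_lattice_leaflet("square", spacing=1.1, n=8)
        apl = area_per_lipid(mem)
        for leaf in ("upper", "lower"):
            assert np.allclose(apl.apl[leaf], 1.21, atol=1e-9)

    def test_hexagonal_lattice_exact(self):
        pts, box, expected = synth.gen_hex_leaflet_periodic(spacing=1.1, n=10)
        areas = periodic_voronoi_areas(pts, box)
        assert np.allclose(areas, expected, atol=1e-9)

    def test_area_conservation_under_jitter(self):
        mem, _ = synth.gen_lattice_leaflet("square", spacing=1.1, n=10,
                                           jitter=0.35, seed=3)
        apl = area_per_lipid(mem)
        box_area = (10 * 1.1) ** 2
        for leaf in ("upper", "lower"):
            assert apl.total_area(leaf) == pytest.approx(box_area, rel=0.01)

    def test_local_method_on_sphere(self):
        """Tangent-plane Voronoi cells tile a sphere area approximately."""
        from coacwet.builders import _fibonacci_sphere

        n, r = 500, 10.0
        pts = r * _fibonacci_sphere(n)
        areas = packing.local_voronoi_areas(pts, k=12)
        expected = 4 * np.pi * r**2 / n
        med = np.nanmedian(areas)
        assert med == pytest.approx(expected, rel=0.1)

    def test_min_leaflet_size_enforced(self):
        mem, _ = synth.gen_lattice_leaflet("square", spacing=1.1, n=3)
        with pytest.raises(ValueError):
            area_per_lipid(mem)


class TestTailOrder:
    def test_aligned_and_inplane_limits(self):
        mem, _ = synth.gen_lattice_leaflet("square", spacing=1.1, n=8)
        of = tail_order(mem)
        assert np.allclose(of.p2, 1.0)  # lattice tails parallel to z
        flat = Membrane(heads=mem.heads,
                        tail_ends=mem.heads + np.array([1.0, 0, 0]),
                        box=mem.box, geometry="patch")
        assert np.allclose(tail_order(flat).p2, -0.5)

    def test_isotropic_orientations_average_zero(self, rng):
        n = 100_000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        heads = rng.uniform(0, 50, size=(n, 3))
        mem = Membrane(heads=heads, tail_ends=heads - u, box=50.0,
                       geometry="patch")
        of = tail_order(mem)
        assert np.mean(of.p2) == pytest.approx(0.0, abs=0.005)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_order_parameter_bounds(self, seed):
        r = np.random.default_rng(seed)
        n = 50
        heads = r.uniform(0, 20, size=(n, 3))
        tails = heads + r.normal(size=(n, 3))
        mem = Membrane(heads=heads, tail_ends=tails, box=20.0, geometry="patch")
        p2 = tail_order(mem).p2
        ok = np.isfinite(p2)
        assert np.all(p2[ok] >= -0.5 - 1e-12) and np.all(p2[ok] <= 1.0 + 1e-12)


class TestDemix:
    def _leaflet(self, n=400, frac_contact_region=0.3, seed=0, demixed=False):
        rng = np.random.default_rng(seed)
        leaflet = np.array(["upper"] * n, dtype=object)
        species = np.array(["DOPC"] * n, dtype=object)
        anion = rng.choice(n, size=n // 5, replace=False)
        species[anion] = "DOPS"
        contact = np.array(["far"] * n, dtype=object)
        k = int(frac_contact_region * n)
        if demixed:
            contact[anion[: min(len(anion), k)]] = "contact"
            rest = np.setdiff1d(np.arange(n), anion)
            contact[rest[: k - min(len(anion), k)]] = "contact"
        else:
            contact[rng.choice(n, size=k, replace=False)] = "contact"
        return species, leaflet, contact

    def test_uniform_mixing_matches_area_fraction(self):
        fracs = []
        for seed in range(30):
            sp, lf, ct = self._leaflet(seed=seed)
            rep = demix_fraction(sp, lf, ct, "DOPS")
            fracs.append(rep.fraction_in_contact)
        assert np.mean(fracs) == pytest.approx(0.30, abs=0.02)

    def test_fully_demixed_species(self):
        sp, lf, ct = self._leaflet(demixed=True)
        rep = demix_fraction(sp, lf, ct, "DOPS")
        assert rep.fraction_in_contact == 1.0
        assert rep.enrichment > 2.0

    def test_no_contact_region(self):
        sp, lf, ct = self._leaflet(frac_contact_region=0.0)
        rep = demix_fraction(sp, lf, ct, "DOPS")
        assert rep.fraction_in_contact == 0.0

    def test_absent_species_rejected(self):
        sp, lf, ct = self._leaflet()
        with pytest.raises(ValueError):
            demix_fraction(sp, lf, ct, "POPC")

    def test_null_enrichment_tends_to_one(self):
        """Binomial null: enrichment -> 1 with tight CI as frames grow."""
        reps = []
        for seed in range(40):
            sp, lf, ct = self._leaflet(n=1000, seed=seed)
            reps.append(demix_fraction(sp, lf, ct, "DOPS").enrichment)
        m = np.mean(reps)
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(m - 1.0) < 3 * se + 0.02


class TestContactsAndClusters:
    def test_pair_at_cutoff_boundary(self):
        a = np.array([[1.0, 1.0, 1.0]])
        b = np.array([[1.0, 1.0, 2.0]])
        assert contact_counts(a, b, cutoff=1.0 + 1e-9, box=10.0) == 1
        assert contact_counts(a, b, cutoff=1.0 - 1e-9, box=10.0) == 0

    def test_constructed_pairs_counted(self, rng):
        k = 7
        a = rng.uniform(2, 8, size=(k, 3))
        b = a + 0.3
        far = rng.uniform(20, 28, size=(5, 3))
        n = contact_counts(a, np.vstack([b, far]), cutoff=0.6, box=30.0)
        brute = sum(np.linalg.norm(x - y) <= 0.6 for x in a
                    for y in np.vstack([b, far]))
        assert n == brute == k

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            contact_counts(np.empty((0, 3)), np.ones((1, 3)), 1.0)

    def test_overlapping_chains_one_cluster(self):
        state = synth.gen_small_cg_fixtures("droplet200", seed=1)
        sizes = cluster_sizes(state)
        assert sizes[0] > 0.8 * sizes.sum()

    def test_separated_groups_two_clusters(self):
        from coacwet.builders import build_polymer_droplet, subset_state

        s = build_polymer_droplet(4, box_length=40.0, seed=0, relax=False,
                                  region_radius=2.0)
        s.positions[s.mol >= 4] += 15.0  # move B chains far away
        sizes = cluster_sizes(s, cutoff=1.0)
        assert len(sizes) >= 2
        assert sizes[0] < s.mol.max() + 1

    def test_dilute_placement_stays_dispersed(self, rng):
        from coacwet.builders import build_polymer_droplet

        s = build_polymer_droplet(25, box_length=60.0, seed=4, relax=False)
        sizes = cluster_sizes(s, cutoff=0.75)
        # brute-force oracle on chain centroid graph
        assert sizes[0] < 50 * 0.5


class TestContourMap:
    def test_uniform_lattice_flat_map(self):
        mem, _ = synth.gen_lattice_leaflet("square", spacing=1.1, n=8)
        asg = assign_leaflets(mem)
        apl = area_per_lipid(mem, asg)
        up = asg.indices("upper")
        sub = Membrane(heads=mem.heads[up], tail_ends=mem.tail_ends[up],
                       box=mem.box, geometry="patch")
        m = apl_contour_map(sub, apl.apl["upper"], grid=4)
        assert np.nanmax(m) - np.nanmin(m) < 1e-9

    def test_compressed_disc_depresses_center(self):
        rng = np.random.default_rng(0)
        box = 20.0
        outer = rng.uniform(0, box, size=(300, 2))
        r = np.linalg.norm(outer - box / 2, axis=1)
        outer = outer[r > 5.0]
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        rr = 4.0 * np.sqrt(rng.uniform(0.1, 1, 200))
        inner = np.column_stack([box / 2 + rr * np.cos(t),
                                 box / 2 + rr * np.sin(t)])
        pts = np.vstack([outer, inner])
        heads = np.column_stack([pts, np.full(len(pts), 2.0)])
        mem = Membrane(heads=heads, tail_ends=heads - [0, 0, 1.5],
                       box=box, geometry="patch")
        areas = periodic_voronoi_areas(pts, box)
        m = apl_contour_map(mem, areas, grid=5)
        center = m[2, 2]
        edge = np.nanmean([m[0, 0], m[0, 4], m[4, 0], m[4, 4]])
        assert center < edge

    def test_sparse_bins_masked(self):
        mem, _ = synth.gen_lattice_leaflet("square", spacing=1.1, n=8)
        asg = assign_leaflets(mem)
        up = asg.indices("upper")
        sub = Membrane(heads=mem.heads[up][:10], tail_ends=mem.tail_ends[up][:10],
                       box=mem.box, geometry="patch")
        with pytest.warns(UserWarning):
            m = apl_contour_map(sub, np.ones(10), grid=8)
        assert np.isnan(m).any()
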