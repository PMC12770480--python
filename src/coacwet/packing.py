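"""Membrane packing and composition analyses.

Per-leaflet area per lipid (APL) by Voronoi construction (periodic 2D
tessellation for flat patches, local tangent-plane Voronoi cells for curved
membranes), lipid tail orientational order (P2 against the local normal),
anionic-lipid de-mixing at the condensate contact region, residue-lipid
contact counting, and chain-level cluster analysis of coacervation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi, cKDTree

from coacwet.dynamics import CONTACT
from coacwet.model import SPECIES, SystemState

UPPER, LOWER = "upper", "lower"


class TopologyError(RuntimeError):
    pass


@dataclasses.dataclass
class LeafletAssignment:
    leaflet: np.ndarray  # per lipid: UPPER (outer/+normal) or LOWER (inner)
    method: str

    def indices(self, which: str) -> np.ndarray:
        return np.flatnonzero(self.leaflet == which)


@dataclasses.dataclass
class Membrane:
    """Head/tail coordinates per lipid extracted from a frame or user arrays."""

    heads: np.ndarray       # (n_lipids, 3)
    tail_ends: np.ndarray   # (n_lipids, 3) terminal tail bead
    box: float | None       # periodic box for flat patches; None = open
    geometry: str           # "patch" | "vesicle"
    species: np.ndarray | None = None  # per-lipid species label (optional)

    @classmethod
    def from_state(cls, state: SystemState, geometry: str = "auto") -> "Membrane":
        heads, tails = [], []
        lipid_mols = np.unique(state.mol[state.species == SPECIES["H"]])
        for m in lipid_mols:
            idx = np.flatnonzero(state.mol == m)
            sp = state.species[idx]
            heads.append(state.positions[idx[sp == SPECIES["H"]][0]])
            tails.append(state.positions[idx[sp == SPECIES["T"]][-1]])
        heads = np.array(heads)
        tails = np.array(tails)
        if geometry == "auto":
            # flat patches have a head z spread far below their x-y extent
            span = heads.max(axis=0) - heads.min(axis=0)
            geometry = "patch" if span[2] < 0.5 * max(span[0], span[1]) else "vesicle"
        return cls(heads=heads, tail_ends=tails, box=state.box_length,
                   geometry=geometry)

    @property
    def n_lipids(self) -> int:
        return len(self.heads)


def local_normals(mem: Membrane) -> np.ndarray:
    """Outward-oriented local normal per lipid.

    Patches use +z; vesicles use the radial direction from the head centroid.
    """
    if mem.geometry == "patch":
        return np.tile([0.0, 0.0, 1.0], (mem.n_lipids, 1))
    c = mem.heads.mean(axis=0)
    v = mem.heads - c
    n = np.linalg.norm(v, axis=1, keepdims=True)
    return v / np.maximum(n, 1e-12)


def assign_leaflets(mem: Membrane) -> LeafletAssignment:
    """Assign lipids to leaflets by the head-minus-tail projection on the normal.

    UPPER collects lipids whose head lies along +normal of their tail (outer
    leaflet of a vesicle; +z leaflet of a patch).
    """
    normals = local_normals(mem)
    proj = np.einsum("ij,ij->i", mem.heads - mem.tail_ends, normals)
    leaflet = np.where(proj > 0, UPPER, LOWER)
    if mem.n_lipids and (np.all(leaflet == UPPER) or np.all(leaflet == LOWER)):
        if mem.geometry == "vesicle":
            raise TopologyError("single-leaflet assignment: membrane not intact?")
    return LeafletAssignment(leaflet=leaflet, method=f"normal-projection/{mem.geometry}")


@dataclasses.dataclass
class AplDistribution:
    apl: dict            # leaflet -> (n,) APL values (NaN = degenerate cell)
    mean: dict
    frac_below: dict
    threshold: float
    units: str

    def total_area(self, which: str) -> float:
        v = self.apl[which]
        return float(np.nansum(v))


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def periodic_voronoi_areas(points2d: np.ndarray, box) -> np.ndarray:
    """Voronoi cell area per point on a 2D torus (square side or (bx, by)).

    Built from the 3x3 image tiling; areas tile the box exactly, so they sum
    to the box area up to floating-point error.
    """
    bx, by = (box, box) if np.isscalar(box) else box
    n = len(points2d)
    pts = np.mod(points2d, [bx, by])
    images = []
    for ox in (-1, 0, 1):
        for oy in (-1, 0, 1):
            images.append(pts + np.array([ox * bx, oy * by]))
    allpts = np.vstack(images)
    vor = Voronoi(allpts)
    center_offset = 4 * n  # (0,0) tile is the 5th of the 9 appended blocks
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[center_offset + i]]
        if -1 in region or len(region) < 3:
            areas[i] = np.nan
        else:
            areas[i] = _polygon_area(vor.vertices[region])
    return areas


def local_voronoi_areas(points3d: np.ndarray, k: int = 12) -> np.ndarray:
    """APL on a curved surface by per-lipid tangent-plane Voronoi cells.

    For each head bead: take the k nearest head neighbors, fit the local
    plane by PCA, project the neighborhood, and measure the central point's
    2D Voronoi cell.  Unbounded or degenerate cells give NaN.
    """
    n = len(points3d)
    k = min(k, n - 1)
    tree = cKDTree(points3d)
    _, nbr = tree.query(points3d, k=k + 1)
    areas = np.full(n, np.nan)
    for i in range(n):
        group = points3d[nbr[i]]
        centered = group - group.mean(axis=0)
        try:
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
        except np.linalg.LinAlgError:
            continue
        plane = centered @ vt[:2].T  # (k+1, 2); row 0 is the central lipid
        if np.linalg.matrix_rank(plane - plane[0]) < 2:
            warnings.warn("degenerate (collinear) neighborhood; APL set to NaN")
            continue
        try:
            vor = Voronoi(plane)
        except Exception:
            continue
        region = vor.regions[vor.point_region[0]]
        if -1 in region or len(region) < 3:
            continue
        areas[i] = _polygon_area(vor.vertices[region])
    return areas


def area_per_lipid(mem: Membrane, assignment: LeafletAssignment | None = None,
                   threshold: float = 0.5, k: int = 12,
                   units: str = "sigma^2") -> AplDistribution:
    """Per-leaflet APL distributions (periodic tessellation for patches,
    local tangent-plane Voronoi for vesicles)."""
    assignment = assignment or assign_leaflets(mem)
    apl, mean, frac = {}, {}, {}
    for which in (UPPER, LOWER):
        idx = assignment.indices(which)
        if len(idx) < 16:
            raise ValueError(f"need >= 16 lipids per leaflet, got {len(idx)} in {which}")
        heads = mem.heads[idx]
        if mem.geometry == "patch" and mem.box is not None:
            v = periodic_voronoi_areas(heads[:, :2], mem.box)
        else:
            v = local_voronoi_areas(heads, k=k)
        apl[which] = v
        mean[which] = float(np.nanmean(v))
        frac[which] = float(np.nanmean(v < threshold))
    return AplDistribution(apl=apl, mean=mean, frac_below=frac,
                           threshold=threshold, units=units)


@dataclasses.dataclass
class OrderField:
    p2: np.ndarray                 # per lipid
    region_means: dict             # region label -> (mean, se, n)


def tail_order(mem: Membrane, regions: np.ndarray | None = None) -> OrderField:
    """Nematic order P2 = <(3 cos^2 theta - 1)/2> of head-to-tail vectors.

    theta is measured against the outward local normal; fully aligned tails
    give +1, in-plane tails -1/2, isotropic orientations 0.
    """
    vec = mem.tail_ends - mem.heads
    norms = np.linalg.norm(vec, axis=1)
    ok = norms > 1e-12
    if not np.all(ok):
        warnings.warn("zero-length tail vectors excluded from order parameter")
    normals = local_normals(mem)
    cos = np.full(mem.n_lipids, np.nan)
    cos[ok] = np.einsum("ij,ij->i", vec[ok], normals[ok]) / norms[ok]
    p2 = 0.5 * (3.0 * cos**2 - 1.0)
    region_means = {}
    if regions is not None:
        regions = np.asarray(regions, dtype=object)
        for r in np.unique(regions):
            v = p2[(regions == r) & np.isfinite(p2)]
            if len(v):
                se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
                region_means[r] = (float(v.mean()), float(se), int(len(v)))
    return OrderField(p2=p2, region_means=region_means)


@dataclasses.dataclass
class DemixReport:
    species: str
    leaflet: str
    fraction_in_contact: float
    area_fraction: float
    enrichment: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def demix_fraction(species_labels: np.ndarray, leaflet: np.ndarray,
                   contact: np.ndarray, species: str, which: str = UPPER,
                   frames_axis: bool = False, n_boot: int = 1000,
                   seed: int = 0) -> DemixReport:
    """Fraction of a lipid species in the facing leaflet that touches the
    condensate, against the contact region's share of that leaflet.

    ``species_labels``, ``leaflet`` and ``contact`` are per-lipid arrays
    (optionally stacked over frames as (F, n)); ``contact`` holds the
    contact/buffer/far labels.  Enrichment ~1 means a well-mixed leaflet,
    >1 local accumulation at the contact region.
    """
    sl = np.atleast_2d(np.asarray(species_labels, dtype=object))
    lf = np.atleast_2d(np.asarray(leaflet, dtype=object))
    ct = np.atleast_2d(np.asarray(contact, dtype=object))
    if not frames_axis and sl.shape[0] != ct.shape[0]:
        sl = np.broadcast_to(sl, ct.shape)
        lf = np.broadcast_to(lf, ct.shape)
    if not np.any(sl == species):
        raise ValueError(f"species {species!r} absent")

    def stats(frames):
        fr, af = [], []
        for f in frames:
            in_leaf = lf[f] == which
            sp = in_leaf & (sl[f] == species)
            if sp.sum() == 0 or in_leaf.sum() == 0:
                continue
            fr.append(np.mean(ct[f][sp] == CONTACT))
            af.append(np.mean(ct[f][in_leaf] == CONTACT))
        return (np.mean(fr) if fr else np.nan, np.mean(af) if af else np.nan)

    n_frames = ct.shape[0]
    frac, area = stats(range(n_frames))
    rng = np.random.default_rng(seed)
    boots = []
    if n_frames > 1:
        for _ in range(n_boot):
            f, a = stats(rng.integers(0, n_frames, n_frames))
            if np.isfinite(f) and a and a > 0:
                boots.append(f / a)
    enrich = frac / area if area and area > 0 else np.nan
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return DemixReport(species=species, leaflet=which,
                       fraction_in_contact=float(frac), area_fraction=float(area),
                       enrichment=float(enrich), ci_low=float(lo), ci_high=float(hi))


def contact_counts(positions_a: np.ndarray, positions_b: np.ndarray,
                   cutoff: float, box: float | None = None) -> int:
    """Number of (a, b) pairs within ``cutoff`` (periodic-aware)."""
    if len(positions_a) == 0 or len(positions_b) == 0:
        raise ValueError("empty selection")
    if box is not None:
        positions_a = np.mod(positions_a, box)
        positions_b = np.mod(positions_b, box)
    ta = cKDTree(positions_a, boxsize=box)
    tb = cKDTree(positions_b, boxsize=box)
    return int(ta.count_neighbors(tb, cutoff))


def contact_count_series(traj, select_a, select_b, cutoff: float) -> np.ndarray:
    """Per-frame contact counts between two bead selections of a trajectory."""
    state = traj.state
    ia = np.flatnonzero(select_a(state)) if callable(select_a) else np.asarray(select_a)
    ib = np.flatnonzero(select_b(state)) if callable(select_b) else np.asarray(select_b)
    out = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        out[f] = contact_counts(traj.positions[f][ia], traj.positions[f][ib],
                                cutoff, box=state.box_length)
    return out


def cluster_sizes(state: SystemState, cutoff: float = 0.75) -> np.ndarray:
    """Chain-level single-linkage cluster sizes of the polymers, descending.

    Two chains join a cluster when any inter-chain bead pair sits within
    ``cutoff`` (default 1.5 sigma_AA).  The largest-cluster fraction is the
    standard summary of phase separation.
    """
    poly = np.isin(state.species, [SPECIES["A"], SPECIES["B"]])
    if not np.any(poly):
        return np.array([], dtype=int)
    idx = np.flatnonzero(poly)
    pos = np.mod(state.positions[idx], state.box_length)
    mols = state.mol[idx]
    chain_ids, chain_inv = np.unique(mols, return_inverse=True)
    tree = cKDTree(pos, boxsize=state.box_length)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        ci = chain_inv[pairs[:, 0]]
        cj = chain_inv[pairs[:, 1]]
        keep = ci != cj
        n = len(chain_ids)
        adj = coo_matrix((np.ones(keep.sum()), (ci[keep], cj[keep])), shape=(n, n))
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(len(chain_ids))
    sizes = np.bincount(comp)
    return np.sort(sizes)[::-1]


def largest_cluster_mask(state: SystemState, cutoff: float = 0.75) -> np.ndarray:
    """Boolean bead mask of the largest polymer-chain cluster (plus all
    non-polymer beads)."""
    poly = np.isin(state.species, [SPECIES["A"], SPECIES["B"]])
    mask = np.ones(state.n_beads, dtype=bool)
    if not np.any(poly):
        return mask
    idx = np.flatnonzero(poly)
    pos = np.mod(state.positions[idx], state.box_length)
    mols = state.mol[idx]
    chain_ids, chain_inv = np.unique(mols, return_inverse=True)
    tree = cKDTree(pos, boxsize=state.box_length)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    n = len(chain_ids)
    if len(pairs):
        ci = chain_inv[pairs[:, 0]]
        cj = chain_inv[pairs[:, 1]]
        keep = ci != cj
        adj = coo_matrix((np.ones(keep.sum()), (ci[keep], cj[keep])), shape=(n, n))
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(n)
    big = np.argmax(np.bincount(comp))
    mask[idx] = comp[chain_inv] == big
    return mask


def apl_contour_map(mem: Membrane, apl_values: np.ndarray, grid: int = 8):
    """Grid-binned mean APL over a flat patch; empty bins are NaN."""
    if mem.geometry != "patch":
        raise ValueError("contour map requires a flat patch")
    box = mem.box
    xy = np.mod(mem.heads[:, :2], box)
    if mem.n_lipids / grid**2 < 2:
        warnings.warn("fewer than 2 lipids per bin on average; map will be noisy")
    ix = np.minimum((xy[:, 0] / box * grid).astype(int), grid - 1)
    iy = np.minimum((xy[:, 1] / box * grid).astype(int), grid - 1)
    out = np.full((grid, grid), np.nan)
    for gx in range(grid):
        for gy in range(grid):
            v = apl_values[(ix == gx) & (iy == gy)]
            v = v[np.isfinite(v)]
            if len(v):
                out[gx, gy] = v.mean()
    return out
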