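"""Synthetic-data generators with recorded ground truth.

Every input the analysis stages consume can be generated here with known
parameters: two-state LAURDAN-like hyperspectral stacks, 2D Brownian walkers
with class-dependent diffusion constants, hyperbolic FRAP recovery curves,
cross-section images of a droplet wetting a vesicle at a prescribed
intrinsic angle, lattice leaflets with exact Voronoi areas, and small
pre-relaxed simulation fixtures.  A single global seed fans out to stable
per-generator substreams, so adding generators never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any

import numpy as np
from scipy import ndimage

from coacwet import builders, engine
from coacwet.dynamics import FrapCurve, frap_model
from coacwet.model import SPECIES, PairTable, SimProtocol, SystemState
from coacwet.packing import Membrane
from coacwet.phasor import HyperspectralStack
from coacwet.wetting import CrossSectionImage


@dataclasses.dataclass
class GroundTruth:
    """Generator provenance: (name, seed, params) regenerate the artifact."""

    generator: str
    seed: int
    params: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=_jsonify)


def _jsonify(x: Any):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(type(x))


def substream(seed: int, name: str) -> np.random.Generator:
    """Stable per-generator RNG derived from the global seed by hashing."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


# ---------------------------------------------------------------------------
# hyperspectral stacks

LAMBDA_MIN, LAMBDA_MAX, N_CHANNELS = 416.0, 728.0, 30
PACKED_CENTER, FLUID_CENTER, BASIS_WIDTH = 440.0, 490.0, 25.0


def basis_spectra(channels: np.ndarray, packed_center: float = PACKED_CENTER,
                  fluid_center: float = FLUID_CENTER, width: float = BASIS_WIDTH):
    """Gaussian packed/fluid basis emission spectra on the channel grid."""
    packed = np.exp(-0.5 * ((channels - packed_center) / width) ** 2)
    fluid = np.exp(-0.5 * ((channels - fluid_center) / width) ** 2)
    return packed, fluid


def default_channels(n: int = N_CHANNELS, lo: float = LAMBDA_MIN,
                     hi: float = LAMBDA_MAX) -> np.ndarray:
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def gen_hyperspectral(shape=(64, 64), mixing="two-region", m_values=(0.8, 0.2),
                      noise_photons: float = 0.0, intensity: float = 1000.0,
                      packed_center: float = PACKED_CENTER,
                      fluid_center: float = FLUID_CENTER,
                      width: float = BASIS_WIDTH, seed: int = 0):
    """Two-state stack: per-pixel spectrum m*packed + (1-m)*fluid.

    ``mixing`` is "constant" (m = m_values[0]), "two-region" (left half
    m_values[0] = wetted/packed, right half m_values[1] = bare/fluid) or
    "gradient" (m sweeps m_values linearly along x).  Optional Poisson shot
    noise with ``noise_photons`` expected counts at unit intensity.
    Returns (stack, mixing field, region masks, GroundTruth).
    """
    if not (LAMBDA_MIN < packed_center < LAMBDA_MAX
            and LAMBDA_MIN < fluid_center < LAMBDA_MAX):
        raise ValueError("basis centers must lie inside the wavelength range")
    rng = substream(seed, "hyperspectral")
    channels = default_channels()
    packed, fluid = basis_spectra(channels, packed_center, fluid_center, width)
    h, w = shape
    xs = np.linspace(0, 1, w)[None, :] * np.ones((h, 1))
    if mixing == "constant":
        m = np.full(shape, float(m_values[0]))
        masks = {}
    elif mixing == "two-region":
        m = np.where(xs < 0.5, float(m_values[0]), float(m_values[1]))
        masks = {"wetted": xs < 0.5, "bare": xs >= 0.5}
    elif mixing == "gradient":
        m = m_values[0] + (m_values[1] - m_values[0]) * xs
        masks = {}
    else:
        raise ValueError(f"unknown mixing field {mixing!r}")
    spec = m[..., None] * packed + (1.0 - m[..., None]) * fluid
    spec = intensity * spec
    if noise_photons > 0:
        spec = rng.poisson(spec * noise_photons) / noise_photons
    stack = HyperspectralStack(intensity=spec.astype(float), lambda_min=LAMBDA_MIN,
                               lambda_max=LAMBDA_MAX, channels=channels)
    gt = GroundTruth("hyperspectral", seed, {
        "shape": list(shape), "mixing": mixing, "m_values": list(m_values),
        "noise_photons": noise_photons, "packed_center": packed_center,
        "fluid_center": fluid_center, "width": width})
    return stack, m, masks, gt


# ---------------------------------------------------------------------------
# Brownian walkers (displacement-ratio oracle)


def gen_brownian_walkers(n_per_class: int = 200, d_wet: float = 1.0,
                         d_bare: float = 2.0, n_steps: int = 500,
                         dt: float = 0.25, seed: int = 0):
    """2D Brownian trajectories in two mobility classes.

    Steps are Gaussian with variance 2 D dt per axis; class labels are fixed
    (contact = wet/slow, far = bare/fast).  Returns (times, positions
    (F, n, 2), labels, GroundTruth).
    """
    if d_wet <= 0 or d_bare <= 0:
        raise ValueError("diffusion constants must be positive")
    rng = substream(seed, "brownian")
    n = 2 * n_per_class
    steps = rng.normal(size=(n_steps, n, 2))
    d = np.array([d_wet] * n_per_class + [d_bare] * n_per_class)
    steps *= np.sqrt(2.0 * d * dt)[None, :, None]
    pos = np.concatenate([np.zeros((1, n, 2)), np.cumsum(steps, axis=0)], axis=0)
    labels = np.array(["contact"] * n_per_class + ["far"] * n_per_class, dtype=object)
    times = dt * np.arange(n_steps + 1)
    gt = GroundTruth("brownian", seed, {
        "n_per_class": n_per_class, "D_wet": d_wet, "D_bare": d_bare,
        "ratio": d_bare / d_wet, "n_steps": n_steps, "dt": dt})
    return times, pos, labels, gt


# ---------------------------------------------------------------------------
# FRAP curves


def gen_frap_curve(I0: float = 0.2, Imax: float = 1.0, tau_half: float = 5.0,
                   t_max: float = 60.0, n_points: int = 100,
                   noise: float = 0.0, region: str = "", seed: int = 0):
    """Hyperbolic recovery curve with optional Gaussian noise."""
    if tau_half <= 0:
        raise ValueError("tau_half must be positive")
    rng = substream(seed, "frap")
    t = np.linspace(0.0, t_max, n_points)
    y = frap_model(t, I0, Imax, tau_half)
    if noise > 0:
        y = y + rng.normal(scale=noise, size=y.shape)
    gt = GroundTruth("frap", seed, {"I0": I0, "Imax": Imax, "tau_half": tau_half,
                                    "t_max": t_max, "n_points": n_points,
                                    "noise": noise})
    return FrapCurve(time=t, intensity=y, region=region), gt


# ---------------------------------------------------------------------------
# wetting cross-sections


class GeometryError(ValueError):
    pass


def wetting_circles(theta_in: float, vesicle_radius: float, footprint_deg: float = 40.0):
    """Analytic droplet-on-vesicle cross-section geometry.

    The membrane is the circle of radius R_v at the origin; the droplet free
    surface is the circle through the two contact points (at polar angles
    +/- footprint from the +x axis) whose tangent there makes the intrinsic
    angle ``theta_in`` with the membrane tangent, measured through the
    condensate.  Returns (condensate center (2,), condensate radius,
    contact points (2, 2)).
    """
    if not 0.0 < theta_in < 180.0:
        raise GeometryError("theta_in must lie in (0, 180) degrees")
    beta = np.radians(footprint_deg)
    th = np.radians(theta_in)
    rv = vesicle_radius
    p = np.array([rv * np.cos(beta), rv * np.sin(beta)])
    t_wet = np.array([np.sin(beta), -np.cos(beta)])  # toward the footprint
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t_ce = rot @ t_wet
    n_ce = np.array([-t_ce[1], t_ce[0]])
    if abs(n_ce[1]) < 1e-9:
        raise GeometryError("degenerate droplet surface (flat interface)")
    s = -p[1] / n_ce[1]  # center on the symmetry (x) axis
    center = p + s * n_ce
    radius = abs(s)
    if center[0] <= 0 or radius > 4 * rv:
        raise GeometryError("infeasible arc combination for this footprint")
    p2 = np.array([p[0], -p[1]])
    return center, radius, np.array([p, p2])


def auto_footprint(theta_in: float, footprint_deg: float = 40.0) -> float:
    """Nudge the footprint away from the straight-interface degeneracy.

    The droplet surface straightens as theta_in + footprint approaches
    180 deg (and inverts beyond), so strong wetting needs a narrower
    footprint for an outward-bulging arc.
    """
    return float(max(10.0, min(footprint_deg, 165.0 - theta_in)))


def gen_wetting_snapshot(theta_in: float, vesicle_radius: float = 30.0,
                         footprint_deg: float | None = None, pixel_size: float = 0.25,
                         image_size: int | None = None, blur_px: float = 2.0,
                         membrane_width: float = 0.8, noise: float = 0.0,
                         seed: int = 0):
    """Rendered cross-section of a droplet wetting a vesicle at ``theta_in``.

    Membrane channel: Gaussian ridge along the vesicle circle; condensate
    channel: filled region outside the vesicle and inside the droplet circle,
    edge-blurred.  Returns (CrossSectionImage, GroundTruth).
    """
    if footprint_deg is None:
        footprint_deg = auto_footprint(theta_in)
    center, radius, contacts = wetting_circles(theta_in, vesicle_radius, footprint_deg)
    rng = substream(seed, "wetting")
    pad = 8.0
    if image_size is None:
        half = max(vesicle_radius, center[0] + radius) + pad
        image_size = int(np.ceil(2 * half / pixel_size))
    n = image_size
    ax = (np.arange(n) + 0.5) * pixel_size - n * pixel_size / 2.0
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    r_ves = np.hypot(X, Y)
    mem = np.exp(-0.5 * ((r_ves - vesicle_radius) / membrane_width) ** 2)
    r_con = np.hypot(X - center[0], Y - center[1])
    con = ((r_con <= radius) & (r_ves >= vesicle_radius)).astype(float)
    con = ndimage.gaussian_filter(con, blur_px)
    if noise > 0:
        mem = np.clip(mem + rng.normal(scale=noise, size=mem.shape), 0, None)
        con = np.clip(con + rng.normal(scale=noise, size=con.shape), 0, None)
    img = CrossSectionImage(membrane=mem, condensate=con, pixel_size=pixel_size)
    gt = GroundTruth("wetting", seed, {
        "theta_in": theta_in, "vesicle_radius": vesicle_radius,
        "footprint_deg": footprint_deg, "pixel_size": pixel_size,
        "condensate_center": center, "condensate_radius": radius,
        "contacts": contacts, "noise": noise})
    return img, gt


# ---------------------------------------------------------------------------
# lattice leaflets (APL oracle)


def gen_lattice_leaflet(kind: str = "square", spacing: float = 1.1, n: int = 16,
                        jitter: float = 0.0, seed: int = 0):
    """Membrane whose upper-leaflet heads sit on a periodic 2D lattice.

    ``n`` is the repeat count per axis; the square lattice has APL a^2 per
    lipid, the hexagonal (triangular) lattice (sqrt(3)/2) a^2.  A matching
    lower leaflet mirrors the upper one.  Returns (Membrane, GroundTruth).
    """
    rng = substream(seed, "lattice")
    a = spacing
    if kind == "square":
        xs, ys = np.meshgrid(np.arange(n) * a, np.arange(n) * a, indexing="ij")
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        box = n * a
        apl = a * a
    elif kind == "hexagonal":
        rows = []
        for j in range(n):
            x = np.arange(n) * a + (a / 2.0 if j % 2 else 0.0)
            y = np.full(n, j * a * np.sqrt(3) / 2.0)
            rows.append(np.column_stack([x, y]))
        pts = np.vstack(rows)
        box = n * a  # valid torus only in x; use for even n with y period n*a*sqrt(3)/2
        box = None
        apl = np.sqrt(3) / 2.0 * a * a
    else:
        raise ValueError("kind must be 'square' or 'hexagonal'")
    if jitter > 0:
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    n_pts = len(pts)
    heads_u = np.column_stack([pts, np.full(n_pts, 2.0)])
    tails_u = np.column_stack([pts, np.full(n_pts, 0.5)])
    heads_l = np.column_stack([pts, np.full(n_pts, -2.0)])
    tails_l = np.column_stack([pts, np.full(n_pts, -0.5)])
    mem = Membrane(heads=np.vstack([heads_u, heads_l]),
                   tail_ends=np.vstack([tails_u, tails_l]),
                   box=box, geometry="patch")
    gt = GroundTruth("lattice", seed, {"kind": kind, "spacing": spacing, "n": n,
                                       "jitter": jitter, "apl": apl,
                                       "box": box if box else 0.0})
    return mem, gt


def gen_hex_leaflet_periodic(spacing: float = 1.1, n: int = 12, jitter: float = 0.0,
                             seed: int = 0):
    """Hexagonal upper-leaflet head coordinates on a rectangular torus.

    Returns (points2d, (box_x, box_y), apl).  Used where exact periodic
    tiling of the triangular lattice is required (n even).
    """
    if n % 2:
        raise ValueError("n must be even for a periodic hexagonal tiling")
    rng = substream(seed, "hexper")
    a = spacing
    rows = []
    for j in range(n):
        x = np.arange(n) * a + (a / 2.0 if j % 2 else 0.0)
        y = np.full(n, j * a * np.sqrt(3) / 2.0)
        rows.append(np.column_stack([x, y]))
    pts = np.vstack(rows)
    if jitter > 0:
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return pts, (n * a, n * a * np.sqrt(3) / 2.0), np.sqrt(3) / 2.0 * a * a


# ---------------------------------------------------------------------------
# small CG fixtures


def equilibrated_patch(n_lipids: int = 128, seed: int = 0,
                       pair_table: PairTable | None = None) -> SystemState:
    """Bilayer patch taken through build, thermalization and equilibration.

    Strong-coupling Langevin (damping 2.0) thermalizes the freshly built
    lattice while it melts into the fluid phase; the published equilibration
    protocol (dt*=0.002, damping 50) then hands over a state ready for
    production runs.
    """
    pt = pair_table or PairTable.default()
    state = builders.build_bilayer_patch(n_lipids, seed=seed, pair_table=pt)
    th = engine.langevin_run(state, SimProtocol(
        dt_star=0.002, n_steps=30000, dump_interval=30000, seed=seed + 1,
        damping=2.0))
    eq = engine.langevin_run(th.state, SimProtocol.equilibration(
        n_steps=20000, seed=seed + 2, dump_interval=20000))
    return eq.state


def gen_small_cg_fixtures(preset: str, seed: int = 0,
                          pair_table: PairTable | None = None) -> SystemState:
    """Deterministic desk-scale simulation fixtures.

    * ``patch128`` / ``patch512``: relaxed flat bilayer patches;
    * ``droplet200``: 100 + 100 chains condensed into a droplet;
    * ``patch512+droplet``: droplet adsorbed on a 512-lipid patch.
    """
    pt = pair_table or PairTable.default()
    if preset == "patch128":
        state = builders.build_bilayer_patch(128, seed=seed, pair_table=pt)
        tr = engine.langevin_run(state, SimProtocol(
            dt_star=0.002, n_steps=2000, dump_interval=2000, seed=seed, damping=5.0))
        return tr.state
    if preset == "patch512":
        state = builders.build_bilayer_patch(512, seed=seed, pair_table=pt)
        tr = engine.langevin_run(state, SimProtocol(
            dt_star=0.002, n_steps=2000, dump_interval=2000, seed=seed, damping=5.0))
        return tr.state
    if preset == "droplet200":
        state = builders.build_polymer_droplet(100, box_length=14.0, seed=seed,
                                               pair_table=pt, region_radius=5.0)
        tr = engine.langevin_run(state, SimProtocol(
            dt_star=0.002, n_steps=4000, dump_interval=4000, seed=seed, damping=5.0))
        return tr.state
    if preset == "droplet60":
        state = builders.build_polymer_droplet(30, box_length=14.0, seed=seed,
                                               pair_table=pt, region_radius=3.2)
        tr = engine.langevin_run(state, SimProtocol(
            dt_star=0.002, n_steps=4000, dump_interval=4000, seed=seed, damping=5.0))
        return tr.state
    if preset == "patch512+droplet":
        from coacwet.packing import largest_cluster_mask

        patch = gen_small_cg_fixtures("patch512", seed=seed, pair_table=pt)
        droplet = gen_small_cg_fixtures("droplet60", seed=seed, pair_table=pt)
        # keep the condensed phase only; stray evaporated chains would
        # inflate the droplet bounding box past the patch box
        droplet = builders.subset_state(droplet, largest_cluster_mask(droplet))
        combo = builders.assemble_droplet_on_patch(patch, droplet)
        tr = engine.langevin_run(combo, SimProtocol(
            dt_star=0.002, n_steps=4000, dump_interval=4000, seed=seed, damping=5.0))
        return tr.state
    raise ValueError(f"unknown preset {preset!r}")
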