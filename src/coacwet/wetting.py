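"""Wetting geometry: apparent angles, geometric factor, intrinsic angle.

At the micron scale a condensate sitting on a vesicle defines three apparent
contact angles at the contact line -- theta_e (opening toward the external
solution), theta_c (toward the condensate) and theta_v (toward the vesicle
interior), summing to 360 degrees.  The membrane affinity is summarized by
the geometric factor

    Phi = (sin theta_e - sin theta_c) / sin theta_v = cos theta_in,

where theta_in is the intrinsic (nanoscale, material) contact angle between
the smoothly curved membrane and the condensate interface.  This module also
extracts theta_in directly from two-channel cross-section images (simulated
density maps or micrographs) by Canny edge detection and circular-arc
regression of the two interfaces.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from coacwet.model import SPECIES, SystemState


class DegenerateGeometryError(ValueError):
    pass


class InconsistencyError(ValueError):
    pass


class ExtractionError(RuntimeError):
    pass


@dataclasses.dataclass
class ApparentAngles:
    """Microscopic (apparent) contact angles in degrees; sum to 360."""

    theta_e: float
    theta_c: float
    theta_v: float

    def __post_init__(self):
        for t in (self.theta_e, self.theta_c, self.theta_v):
            if not (0.0 < t < 360.0):
                raise ValueError("apparent angles must lie in (0, 360) degrees")
        if abs(self.theta_e + self.theta_c + self.theta_v - 360.0) > 1.0:
            raise InconsistencyError("apparent angles must sum to 360 deg (tol 1 deg)")


@dataclasses.dataclass
class WettingResult:
    phi: float
    theta_in: float  # degrees
    dewetted: bool = False
    complete_wetting: bool = False


@dataclasses.dataclass
class TensionTriangle:
    """Interfacial tension of the droplet surface and the two membrane segments."""

    sigma_ce: float
    sigma_vc: float
    sigma_ve: float

    def __post_init__(self):
        if min(self.sigma_ce, self.sigma_vc, self.sigma_ve) <= 0:
            raise ValueError("tensions must be positive")


@dataclasses.dataclass
class CrossSectionImage:
    """Two-channel cross-section through the droplet-vesicle symmetry axis."""

    membrane: np.ndarray    # 2D intensity, lipid-head channel
    condensate: np.ndarray  # 2D intensity, polymer channel
    pixel_size: float       # length units per pixel

    def __post_init__(self):
        if self.membrane.shape != self.condensate.shape:
            raise ValueError("channel shapes differ")
        if np.any(self.membrane < 0) or np.any(self.condensate < 0):
            raise ValueError("intensities must be non-negative")


def geometric_factor(angles: ApparentAngles) -> float:
    """Phi = (sin theta_e - sin theta_c)/sin theta_v, clamped to [-1, 1]."""
    tv = math.radians(angles.theta_v)
    if abs(math.sin(tv)) < 1e-12:
        raise DegenerateGeometryError("sin(theta_v) = 0")
    phi = (math.sin(math.radians(angles.theta_e))
           - math.sin(math.radians(angles.theta_c))) / math.sin(tv)
    if abs(phi) > 1.0 + 1e-6:
        raise InconsistencyError(f"geometric factor {phi} outside [-1, 1]")
    return float(min(1.0, max(-1.0, phi)))


def intrinsic_angle(phi: float) -> float:
    """theta_in in degrees from Phi = cos(theta_in)."""
    if not -1.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [-1, 1]")
    return float(math.degrees(math.acos(phi)))


def tension_triangle_residual(tensions: TensionTriangle, angles: ApparentAngles) -> float:
    """Norm of the vector force balance at the contact line.

    The three tensions pull along their interfaces; with the condensate
    surface direction at polar angle 0, the bare-membrane direction opens by
    theta_e and the wetted-membrane direction by -theta_c.  Zero for a
    consistent (sine-rule) triple.
    """
    te = math.radians(angles.theta_e)
    tc = math.radians(angles.theta_c)
    u_ce = np.array([1.0, 0.0])
    u_ve = np.array([math.cos(te), math.sin(te)])
    u_vc = np.array([math.cos(tc), -math.sin(tc)])
    res = (tensions.sigma_ce * u_ce + tensions.sigma_ve * u_ve
           + tensions.sigma_vc * u_vc)
    return float(np.linalg.norm(res))


def tensions_from_angles(angles: ApparentAngles, scale: float = 1.0) -> TensionTriangle:
    """Sine-rule-consistent tensions for given apparent angles."""
    return TensionTriangle(
        sigma_ce=scale * math.sin(math.radians(angles.theta_v)),
        sigma_vc=scale * math.sin(math.radians(angles.theta_e)),
        sigma_ve=scale * math.sin(math.radians(angles.theta_c)),
    )


def render_cross_section(state: SystemState, slab_thickness: float = 4.0,
                         axis: int = 1, pixel_size: float = 0.25,
                         blur_sigma_px: float = 2.0) -> CrossSectionImage:
    """Binned bead-density image of a slab containing the symmetry axis.

    The slab is centered on the system centroid along ``axis`` (the direction
    normal to the imaging plane); lipid heads fill the membrane channel,
    polymer beads the condensate channel, both Gaussian-smoothed.
    """
    pos = state.positions
    centroid = pos.mean(axis=0)
    sel_slab = np.abs(pos[:, axis] - centroid[axis]) <= slab_thickness / 2.0
    if not np.any(sel_slab):
        raise ValueError("empty slab")
    keep_axes = [a for a in range(3) if a != axis]
    xy = pos[np.ix_(sel_slab, keep_axes)]
    is_head = state.species[sel_slab] == SPECIES["H"]
    is_poly = np.isin(state.species[sel_slab],
                      [SPECIES["A"], SPECIES["B"]])
    n_px = int(np.ceil(state.box_length / pixel_size))
    edges = np.arange(n_px + 1) * pixel_size
    mem, _, _ = np.histogram2d(xy[is_head, 0], xy[is_head, 1], bins=(edges, edges))
    con, _, _ = np.histogram2d(xy[is_poly, 0], xy[is_poly, 1], bins=(edges, edges))
    mem = ndimage.gaussian_filter(mem, blur_sigma_px)
    con = ndimage.gaussian_filter(con, blur_sigma_px)
    return CrossSectionImage(membrane=mem, condensate=con, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# snapshot angle extraction


def _canny_points(channel: np.ndarray, sigma: float, low: float, high: float):
    """Canny edge pixels of an intensity-normalized channel.

    Thresholds are absolute gradient magnitudes on the max-normalized image,
    which keeps weak noise-induced edges (flat interiors, empty background)
    below the hysteresis band while real interface gradients pass.
    """
    from skimage import feature

    img = channel.astype(float)
    if img.max() > 0:
        img = img / img.max()
    edges = feature.canny(img, sigma=sigma, low_threshold=low, high_threshold=high)
    return np.argwhere(edges).astype(float)  # (n, 2) row, col


def fit_circle(points: np.ndarray):
    """Algebraic (Kasa) least-squares circle fit; returns (center(2,), radius)."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx * cx + cy * cy, 0.0))
    return np.array([cx, cy]), r


def _circle_intersections(c1, r1, c2, r2):
    d = np.linalg.norm(c2 - c1)
    if d <= 1e-12 or d >= r1 + r2 or d <= abs(r1 - r2):
        return None
    a = (r1 * r1 - r2 * r2 + d * d) / (2 * d)
    h2 = r1 * r1 - a * a
    if h2 < 0:
        return None
    h = math.sqrt(h2)
    u = (c2 - c1) / d
    mid = c1 + a * u
    perp = np.array([-u[1], u[0]])
    return mid + h * perp, mid - h * perp


def _angle_at_contact(p, c_mem, c_con, other_p):
    """Intrinsic angle at contact point ``p`` between fitted circles.

    Measured through the condensate: between the membrane tangent pointing
    along the wetted segment (toward the other contact point) and the
    condensate-surface tangent pointing away from the membrane.
    """
    r1 = p - c_mem
    n_out = r1 / np.linalg.norm(r1)  # outward membrane normal
    t_m = np.array([-n_out[1], n_out[0]])
    if np.dot(t_m, other_p - p) < 0:
        t_m = -t_m  # wetted-side direction
    r2 = p - c_con
    t_c = np.array([-r2[1], r2[0]])
    t_c /= np.linalg.norm(t_c)
    if np.dot(t_c, n_out) < 0:
        t_c = -t_c  # away from the membrane, along the droplet surface
    return math.degrees(math.atan2(np.dot(t_c, n_out), np.dot(t_c, t_m)))


@dataclasses.dataclass
class AngleMeasurement:
    theta_in: float
    uncertainty: float
    side: str  # "left" / "right"


@dataclasses.dataclass
class ExtractionResult:
    angles: list
    dewetted: bool = False
    complete_wetting: bool = False

    def values(self):
        return [a.theta_in for a in self.angles]


def extract_intrinsic_angle(image: CrossSectionImage, canny_sigma: float = 2.0,
                            low_threshold: float = 0.05, high_threshold: float = 0.15,
                            margin_px: float = 3.0, n_boot: int = 20,
                            seed: int = 0) -> ExtractionResult:
    """Measure theta_in at both contact points of a cross-section image.

    Canny edges are detected per channel; the membrane interface and the
    droplet free surface are each fitted with a least-squares circular arc
    (the regression window spans the detected chain), the fitted circles are
    intersected to locate the two contact points, and the angle between the
    interface tangents -- measured through the condensate -- is reported with
    a bootstrap uncertainty over edge pixels.
    """
    mem_pts = _canny_points(image.membrane, canny_sigma, low_threshold, high_threshold)
    con_pts = _canny_points(image.condensate, canny_sigma, low_threshold, high_threshold)
    if len(mem_pts) < 8:
        raise ExtractionError("membrane channel has no detectable boundary")
    if len(con_pts) < 8:
        return ExtractionResult(angles=[], dewetted=True)
    c_mem, r_mem = fit_circle(mem_pts)
    # droplet free surface: condensate edges clear of the membrane ring
    d = np.linalg.norm(con_pts - c_mem, axis=1)
    free = con_pts[d > r_mem + margin_px]
    if len(free) < 8:
        # droplet boundary never leaves the membrane: complete wetting
        return ExtractionResult(angles=[], complete_wetting=True)
    c_con, r_con = fit_circle(free)

    def measure(mp, fp):
        cm, rm = fit_circle(mp)
        cc, rc = fit_circle(fp)
        inter = _circle_intersections(cm, rm, cc, rc)
        if inter is None:
            return None
        p1, p2 = inter
        return (_angle_at_contact(p1, cm, cc, p2),
                _angle_at_contact(p2, cm, cc, p1))

    base = measure(mem_pts, free)
    if base is None:
        return ExtractionResult(angles=[], dewetted=True)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        mp = mem_pts[rng.integers(0, len(mem_pts), len(mem_pts))]
        fp = free[rng.integers(0, len(free), len(free))]
        m = measure(mp, fp)
        if m is not None:
            boots.append(m)
    boots = np.array(boots) if boots else np.array([base])
    ses = boots.std(axis=0, ddof=1) if len(boots) > 1 else np.zeros(2)
    angles = [
        AngleMeasurement(theta_in=float(base[0]), uncertainty=float(ses[0]), side="left"),
        AngleMeasurement(theta_in=float(base[1]), uncertainty=float(ses[1]), side="right"),
    ]
    return ExtractionResult(angles=angles)


def wetting_from_angles(angles: ApparentAngles) -> WettingResult:
    phi = geometric_factor(angles)
    return WettingResult(phi=phi, theta_in=intrinsic_angle(phi))
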