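"""Lipid mobility estimators: FRAP recovery fits and displacement ratios.

Experimentally, recovery after photobleaching is fitted with

    y(x) = (I0 + Imax (x/tau_half)) / (1 + x/tau_half),

whose half-time gives the apparent diffusion constant D_app = r0^2 nu /
(4 tau_half).  Ratios of half-times between wetted and bare membrane regions
equal the inverse ratio of diffusion constants, with spot geometry (r0, nu)
cancelling.

On the simulation side, absolute diffusion constants are meaningless
(coarse-grained time has no physical calibration) and residence times at the
contact region are short, so the bare/wet mobility ratio is estimated from
mean squared head-bead displacements over short windows Delta t* (grid
0.25-3.0 in reduced time), classifying each lipid as contact/far at the
window start and reading the plateau from the largest windows.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from coacwet.model import SPECIES, SystemState


class FitError(RuntimeError):
    pass


class EstimationError(RuntimeError):
    pass


@dataclasses.dataclass
class FrapCurve:
    """Normalized post-bleach recovery trace."""

    time: np.ndarray
    intensity: np.ndarray
    region: str = ""  # "wetted" | "bare" | ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if len(self.time) != len(self.intensity):
            raise ValueError("time/intensity length mismatch")


@dataclasses.dataclass
class FrapFit:
    I0: float
    Imax: float
    tau_half: float
    covariance: np.ndarray
    residual_rms: float

    def __call__(self, x):
        return frap_model(np.asarray(x, float), self.I0, self.Imax, self.tau_half)


def frap_model(x, I0, Imax, tau_half):
    u = x / tau_half
    return (I0 + Imax * u) / (1.0 + u)


def fit_frap(curve: FrapCurve) -> FrapFit:
    """Nonlinear least squares of the hyperbolic recovery function.

    Requires at least 5 points; refuses fits whose half-time exceeds ten
    observation windows (unconstrained recovery).
    """
    t, y = curve.time, curve.intensity
    if len(t) < 5:
        raise ValueError("need at least 5 post-bleach points")
    span = t[-1] - t[0]
    p0 = (float(y[0]), float(y.max()), max(float(span) / 4.0, 1e-6))
    try:
        popt, pcov = optimize.curve_fit(frap_model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"FRAP fit did not converge: {exc}") from exc
    resid = y - frap_model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if not np.all(np.isfinite(pcov)):
        raise FitError(f"non-finite covariance (residual rms {rms:.3g})")
    if popt[2] > 10.0 * span:
        raise FitError(
            f"tau_half {popt[2]:.3g} exceeds 10x the observation window {span:.3g}")
    return FrapFit(I0=float(popt[0]), Imax=float(popt[1]), tau_half=float(popt[2]),
                   covariance=pcov, residual_rms=rms)


def d_apparent(r0: float, nu: float, tau_half: float) -> float:
    """Apparent diffusion constant D_app = r0^2 nu / (4 tau_half)."""
    if r0 <= 0 or nu <= 0 or tau_half <= 0:
        raise ValueError("r0, nu, tau_half must be positive")
    return r0 * r0 * nu / (4.0 * tau_half)


def frap_ratio(tau_wet: float, tau_bare: float) -> float:
    """D_bare/D_wet from half-times: tau_wet/tau_bare (geometry cancels)."""
    if tau_wet <= 0 or tau_bare <= 0:
        raise ValueError("half-times must be positive")
    return tau_wet / tau_bare


CONTACT, BUFFER, FAR = "contact", "buffer", "far"


def classify_contact_lipids(frame: SystemState, cutoff: float = 1.5) -> np.ndarray:
    """Label each lipid contact/buffer/far by head-polymer proximity.

    A lipid is ``contact`` when its head bead lies within ``cutoff`` of any
    polymer bead, ``far`` beyond ``2 * cutoff``; the annulus in between is a
    ``buffer`` excluded from both classes.  Returns an array of labels
    indexed by lipid (molecule) order.
    """
    head_idx = np.flatnonzero(frame.species == SPECIES["H"])
    poly_idx = np.flatnonzero(np.isin(frame.species, [SPECIES["A"], SPECIES["B"]]))
    labels = np.full(len(head_idx), FAR, dtype=object)
    if len(poly_idx) == 0:
        return labels
    box = frame.box_length
    heads = np.mod(frame.positions[head_idx], box)
    poly = np.mod(frame.positions[poly_idx], box)
    tree = cKDTree(poly, boxsize=box)
    d, _ = tree.query(heads, k=1)
    labels[d <= cutoff] = CONTACT
    labels[(d > cutoff) & (d <= 2 * cutoff)] = BUFFER
    return labels


@dataclasses.dataclass
class MobilityRatioCurve:
    """D_bare/D_wet estimates over the Delta t* grid with a plateau summary."""

    dt_star: np.ndarray
    ratio: np.ndarray
    msd_contact: np.ndarray
    msd_far: np.ndarray
    plateau: float
    plateau_se: float


def default_dt_grid(n: int = 12) -> np.ndarray:
    return np.linspace(0.25, 3.0, n)


def displacement_ratio(times: np.ndarray, positions: np.ndarray,
                       labels: np.ndarray, dt_star_grid: np.ndarray | None = None,
                       in_plane: tuple = (0, 1), min_per_class: int = 20,
                       n_boot: int = 1000, seed: int = 0) -> MobilityRatioCurve:
    """Ratio of mean squared displacements of far vs contact lipids.

    ``positions`` is (frames, lipids, d) of unwrapped head coordinates,
    ``labels`` either (lipids,) fixed labels or (frames, lipids) per-frame
    labels evaluated at each window start.  For every Delta t* in the grid,
    the squared in-plane displacement is averaged over all (lipid, window)
    pairs of each class; the plateau is the mean over the largest-window
    third of the grid with a bootstrap standard error over lipids.
    """
    times = np.asarray(times, float)
    if dt_star_grid is None:
        dt_star_grid = default_dt_grid()
    frame_dt = float(times[1] - times[0])
    n_frames, n_lipids = positions.shape[:2]
    labels = np.asarray(labels, dtype=object)
    per_frame = labels.ndim == 2
    xy = positions[..., list(in_plane)]

    # per-lipid sums of squared displacement per dt, for bootstrap over lipids
    sums_c = np.zeros((len(dt_star_grid), n_lipids))
    cnts_c = np.zeros((len(dt_star_grid), n_lipids))
    sums_f = np.zeros((len(dt_star_grid), n_lipids))
    cnts_f = np.zeros((len(dt_star_grid), n_lipids))
    for k, dt in enumerate(dt_star_grid):
        w = int(round(dt / frame_dt))
        if w < 1 or abs(w * frame_dt - dt) > 1e-9 * max(1.0, dt):
            raise ValueError(f"frame spacing {frame_dt} does not divide dt* {dt}")
        if w >= n_frames:
            raise ValueError(f"dt* {dt} exceeds trajectory span")
        disp2 = np.sum((xy[w:] - xy[:-w]) ** 2, axis=-1)  # (starts, lipids)
        lab = labels[: n_frames - w] if per_frame else np.broadcast_to(labels, disp2.shape)
        is_c = lab == CONTACT
        is_f = lab == FAR
        sums_c[k] = np.sum(np.where(is_c, disp2, 0.0), axis=0)
        cnts_c[k] = is_c.sum(axis=0)
        sums_f[k] = np.sum(np.where(is_f, disp2, 0.0), axis=0)
        cnts_f[k] = is_f.sum(axis=0)

    n_class_c = int((cnts_c.sum(axis=0) > 0).sum())
    n_class_f = int((cnts_f.sum(axis=0) > 0).sum())
    if n_class_c < min_per_class:
        raise EstimationError(f"contact class starved ({n_class_c} lipids)")
    if n_class_f < min_per_class:
        raise EstimationError(f"far class starved ({n_class_f} lipids)")

    msd_c = sums_c.sum(axis=1) / np.maximum(cnts_c.sum(axis=1), 1)
    msd_f = sums_f.sum(axis=1) / np.maximum(cnts_f.sum(axis=1), 1)
    ratio = msd_f / msd_c

    top = len(dt_star_grid) - max(1, len(dt_star_grid) // 3)
    plateau = float(np.mean(ratio[top:]))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_lipids, n_lipids)
        mc = sums_c[top:, pick].sum(axis=1) / np.maximum(cnts_c[top:, pick].sum(axis=1), 1)
        mf = sums_f[top:, pick].sum(axis=1) / np.maximum(cnts_f[top:, pick].sum(axis=1), 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boots[b] = np.mean(np.where(mc > 0, mf / mc, np.nan))
    boots = boots[np.isfinite(boots)]
    se = float(boots.std(ddof=1)) if len(boots) > 1 else float("nan")
    return MobilityRatioCurve(dt_star=np.asarray(dt_star_grid, float), ratio=ratio,
                              msd_contact=msd_c, msd_far=msd_f,
                              plateau=plateau, plateau_se=se)


def head_trajectory(traj, unwrapped: bool = True):
    """(times, head positions (F, n_lipids, 3)) from an engine Trajectory."""
    head_idx = np.flatnonzero(traj.state.species == SPECIES["H"])
    pos = traj.positions[:, head_idx, :]
    return traj.times, pos


def contact_labels_over_time(traj, cutoff: float = 1.5) -> np.ndarray:
    """Per-frame contact/buffer/far labels for every lipid of a trajectory."""
    out = []
    for f in range(traj.n_frames):
        out.append(classify_contact_lipids(traj.frame_state(f), cutoff=cutoff))
    return np.array(out, dtype=object)
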