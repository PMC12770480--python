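"""Spectral phasor analysis of hyperspectral image stacks.

Each pixel's emission spectrum I(lambda) maps to the first-harmonic Fourier
pair

    G = sum I(l) cos(2 pi n (l - l_min)/(l_max - l_min)) / sum I(l)
    S = sum I(l) sin(2 pi n (l - l_min)/(l_max - l_min)) / sum I(l)

so pure spectral species become points on the phasor plane and mixtures fall
on the straight segment between them (linear-combination rule), with weights
proportional to their integrated intensities.  Two-cursor analysis projects
pixels onto the segment between a fluid-extreme and a packed-extreme cursor;
the resulting fluidity-fraction histogram (normalized to unit mass) is
summarized by its center of mass CM = sum_i i F_i / sum_i F_i.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np


@dataclasses.dataclass
class HyperspectralStack:
    """Pixels x wavelength channels, with the wavelength axis metadata."""

    intensity: np.ndarray          # (..., n_channels), non-negative
    lambda_min: float
    lambda_max: float
    channels: np.ndarray           # channel center wavelengths (nm)
    harmonic: int = 1
    mask: np.ndarray | None = None  # True = pixel excluded

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.intensity.shape[-1] != len(self.channels):
            raise ValueError("channel count mismatch")
        if len(self.channels) < 3:
            raise ValueError("need at least 3 spectral channels")
        if self.lambda_min >= self.lambda_max:
            raise ValueError("lambda_min must be < lambda_max")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.harmonic < 1:
            raise ValueError("harmonic must be >= 1")


@dataclasses.dataclass
class PhasorPoint:
    G: float
    S: float

    def as_array(self):
        return np.array([self.G, self.S])


@dataclasses.dataclass
class CursorPair:
    """cursor1 = fluid extreme, cursor2 = packed extreme."""

    cursor1: PhasorPoint
    cursor2: PhasorPoint

    def __post_init__(self):
        if np.allclose(self.cursor1.as_array(), self.cursor2.as_array()):
            raise ValueError("cursors must be distinct")


@dataclasses.dataclass
class FluidityHistogram:
    bin_centers: np.ndarray
    counts: np.ndarray   # normalized, sums to 1
    cm: float            # center of mass on [0, 1]
    n_pixels: int


def phasor_transform(stack: HyperspectralStack, floor_frac: float = 0.0):
    """Per-pixel (G, S) arrays; all-zero (or sub-floor) pixels become NaN.

    ``floor_frac`` masks pixels whose integrated intensity is below that
    fraction of the maximum before transforming.
    """
    I = stack.intensity
    phase = (2.0 * np.pi * stack.harmonic * (stack.channels - stack.lambda_min)
             / (stack.lambda_max - stack.lambda_min))
    tot = I.sum(axis=-1)
    masked = tot <= 0
    if floor_frac > 0 and tot.size:
        masked = masked | (tot < floor_frac * tot.max())
    if stack.mask is not None:
        masked = masked | stack.mask
    with np.errstate(invalid="ignore", divide="ignore"):
        G = (I * np.cos(phase)).sum(axis=-1) / tot
        S = (I * np.sin(phase)).sum(axis=-1) / tot
    G = np.where(masked, np.nan, G)
    S = np.where(masked, np.nan, S)
    return G, S


def phasor_of_spectrum(spectrum, stack_meta: HyperspectralStack) -> PhasorPoint:
    s = HyperspectralStack(intensity=np.asarray(spectrum, float)[None, :],
                           lambda_min=stack_meta.lambda_min,
                           lambda_max=stack_meta.lambda_max,
                           channels=stack_meta.channels,
                           harmonic=stack_meta.harmonic)
    G, S = phasor_transform(s)
    return PhasorPoint(G=float(G[0]), S=float(S[0]))


def linear_combination_check(spec_a: np.ndarray, spec_b: np.ndarray,
                             alpha: float, meta: HyperspectralStack) -> float:
    """Deviation between the mixed spectrum's phasor and the weighted
    combination of the component phasors (zero analytically)."""
    spec_a = np.asarray(spec_a, float)
    spec_b = np.asarray(spec_b, float)
    mixed = alpha * spec_a + (1.0 - alpha) * spec_b
    p_mix = phasor_of_spectrum(mixed, meta).as_array()
    pa = phasor_of_spectrum(spec_a, meta).as_array()
    pb = phasor_of_spectrum(spec_b, meta).as_array()
    wa = alpha * spec_a.sum()
    wb = (1.0 - alpha) * spec_b.sum()
    expected = (wa * pa + wb * pb) / (wa + wb)
    return float(np.linalg.norm(p_mix - expected))


def two_cursor_fraction(G: np.ndarray, S: np.ndarray, cursors: CursorPair) -> np.ndarray:
    """Normalized position of each phasor along the cursor segment.

    Orthogonal projection onto the cursor1->cursor2 segment, 0 at cursor 1
    and 1 at cursor 2, clamped to [0, 1]; NaN phasors propagate.
    """
    p1 = cursors.cursor1.as_array()
    p2 = cursors.cursor2.as_array()
    seg = p2 - p1
    denom = float(seg @ seg)
    t = ((np.asarray(G, float) - p1[0]) * seg[0]
         + (np.asarray(S, float) - p1[1]) * seg[1]) / denom
    return np.clip(t, 0.0, 1.0)


def fluidity_histogram(fractions: np.ndarray, n_bins: int = 100) -> FluidityHistogram:
    """Normalized histogram of fractions on [0, 1] and its center of mass."""
    f = np.asarray(fractions, float).ravel()
    f = f[np.isfinite(f)]
    if len(f) == 0:
        raise ValueError("no unmasked pixels")
    counts, edges = np.histogram(f, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    F = counts / counts.sum()
    cm = float(np.sum(centers * F) / np.sum(F))
    return FluidityHistogram(bin_centers=centers, counts=F, cm=cm, n_pixels=len(f))


def fluidity_fraction(G, S, cursors: CursorPair) -> np.ndarray:
    """Fluidity fraction per pixel: 1 at the fluid cursor, 0 at the packed one."""
    return 1.0 - two_cursor_fraction(G, S, cursors)


def segment_membrane_regions(stack: HyperspectralStack, cursors: CursorPair,
                             masks: dict, n_bins: int = 100,
                             floor_frac: float = 0.01) -> dict:
    """Per-region fluidity histograms and CM values.

    ``masks`` maps region names (e.g. "wetted", "bare") to boolean pixel
    masks (True = pixel belongs to the region); masks must be disjoint.
    Returns region -> FluidityHistogram; regions with no usable pixels are
    skipped with a warning.
    """
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"region masks {a!r} and {b!r} overlap")
    G, S = phasor_transform(stack, floor_frac=floor_frac)
    frac = fluidity_fraction(G, S, cursors)
    out = {}
    for name, m in masks.items():
        vals = frac[m]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"region {name!r} has no unmasked pixels; skipped")
            continue
        out[name] = fluidity_histogram(vals, n_bins=n_bins)
    return out
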