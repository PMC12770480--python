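"""Model definition for the generic coarse-grained coacervate-membrane system.

Reduced (Lennard-Jones) units throughout: sigma is the unit of length
(1 sigma ~ 6.93 A for this parameterization), epsilon the unit of energy,
k_B = 1 and all beads carry unit mass.  Four bead species:

* ``H``/``T`` -- head and tail beads of three-bead (H-T-T) lipids; heads are
  WCA-repulsive, tails attract through a flat-bottomed cos^2-tailed well of
  range ``omega_TT`` on top of a WCA core, and successive lipid beads are
  bonded by FENE springs (k=30, r_inf=1.5).
* ``A``/``B`` -- ten-bead polyelectrolyte chains (the K10/D10 analogues);
  self-repulsive (WCA), heterotypically attractive (truncated LJ,
  eps_PP=1.5, sigma=0.5), harmonically bonded (k=50, r_eq=0.548).

The two tunable couplings of the model are the polymer-head attraction
``eps_PL`` (A-H and B-H, truncated LJ) and the tail-tail attraction range
``omega_TT``, which together set the wetting affinity and bilayer fluidity.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np

# species codes used in all engine arrays
SPECIES = {"H": 0, "T": 1, "A": 2, "B": 3}
SPECIES_NAMES = {v: k for k, v in SPECIES.items()}
N_SPECIES = 4

# pair-style codes
STYLE_NONE = 0
STYLE_WCA = 1
STYLE_LJ = 2
STYLE_TAIL = 3  # WCA core (sigma_TT) + flat/cos^2 attraction of range omega_c

SIGMA_ANGSTROM = 6.93  # 1 sigma in Angstrom for this parameterization

WCA_CUT = 2.0 ** (1.0 / 6.0)
LJ_CUT = 2.5

# bond-style codes
BOND_HARMONIC = 0
BOND_FENE = 1


def u_wca(r, epsilon=1.0, sigma=1.0):
    """Weeks-Chandler-Andersen potential: purely repulsive, shifted LJ.

    ``4 eps [(s/r)^12 - (s/r)^6 + 1/4]`` for ``r <= 2^(1/6) s``, zero beyond;
    the +1/4 shift makes it continuous at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or epsilon <= 0 or sigma <= 0:
        raise ValueError("u_wca requires r, epsilon, sigma > 0")
    sr6 = (sigma / r) ** 6
    u = 4.0 * epsilon * (sr6 * sr6 - sr6 + 0.25)
    out = np.where(r <= WCA_CUT * sigma, u, 0.0)
    return float(out) if out.ndim == 0 else out


def u_lj(r, epsilon=1.0, sigma=1.0):
    """Truncated (unshifted) Lennard-Jones potential, cutoff 2.5 sigma."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or epsilon <= 0 or sigma <= 0:
        raise ValueError("u_lj requires r, epsilon, sigma > 0")
    sr6 = (sigma / r) ** 6
    u = 4.0 * epsilon * (sr6 * sr6 - sr6)
    out = np.where(r <= LJ_CUT * sigma, u, 0.0)
    return float(out) if out.ndim == 0 else out


def u_tail(r, epsilon=1.0, r_c=WCA_CUT, omega_c=1.5):
    """Attractive part of the tail-tail interaction.

    Flat well ``-eps`` below ``r_c``, then a ``-eps cos^2`` ramp of width
    ``omega_c``, zero beyond ``r_c + omega_c``.  The repulsive core below
    contact is handled separately (WCA with sigma_TT); this function is the
    broadened attraction that controls bilayer fluidity.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or epsilon <= 0 or omega_c <= 0:
        raise ValueError("u_tail requires r, epsilon, omega_c > 0")
    ramp = -epsilon * np.cos(np.pi * (r - r_c) / (2.0 * omega_c)) ** 2
    out = np.where(r < r_c, -epsilon, np.where(r <= r_c + omega_c, ramp, 0.0))
    return float(out) if out.ndim == 0 else out


def v_fene(r, k=30.0, r_inf=1.5):
    """FENE bond energy ``-(k/2) r_inf^2 ln[1 - (r/r_inf)^2]``.

    Diverges at ``r_inf``; extensions at or beyond it raise
    :class:`BondOverextensionError` (the bond is broken and the run invalid).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("v_fene requires r >= 0")
    if np.any(r >= r_inf):
        raise BondOverextensionError(f"FENE extension r >= r_inf = {r_inf}")
    out = -0.5 * k * r_inf**2 * np.log(1.0 - (r / r_inf) ** 2)
    return float(out) if out.ndim == 0 else out


def u_harmonic(r, k=50.0, r_eq=0.548):
    """Harmonic bond ``(k/2)(r - r_eq)^2`` (half-prefactor convention)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("u_harmonic requires r >= 0")
    out = 0.5 * k * (r - r_eq) ** 2
    return float(out) if out.ndim == 0 else out


class BondOverextensionError(RuntimeError):
    """A FENE bond reached or exceeded its maximum extension."""


class ConfigurationError(ValueError):
    """Unknown species pair or otherwise inconsistent model configuration."""


@dataclasses.dataclass
class PairTable:
    """Symmetric tables of pair interactions for the four species.

    Arrays are indexed ``[species_i, species_j]``; ``style`` selects the
    functional form, ``cutoff`` is the WCA/LJ cutoff or the TAIL plateau edge
    r_c, and ``omega`` the TAIL ramp width (zero elsewhere).
    """

    style: np.ndarray
    eps: np.ndarray
    sigma: np.ndarray
    cutoff: np.ndarray
    omega: np.ndarray

    @property
    def max_cutoff(self) -> float:
        return float(np.max(self.cutoff + self.omega))

    @classmethod
    def default(cls, eps_pl: float = 0.7625, omega_tt: float = 1.70,
                eps_pp: float = 1.5, eps_tt: float = 1.0) -> "PairTable":
        """Paper-default interaction matrix with tunable (eps_PL, omega_TT)."""
        style = np.zeros((N_SPECIES, N_SPECIES), dtype=np.int64)
        eps = np.ones((N_SPECIES, N_SPECIES))
        sig = np.ones((N_SPECIES, N_SPECIES))
        H, T, A, B = SPECIES["H"], SPECIES["T"], SPECIES["A"], SPECIES["B"]

        def set_pair(i, j, st, e, s):
            style[i, j] = style[j, i] = st
            eps[i, j] = eps[j, i] = e
            sig[i, j] = sig[j, i] = s

        # lipid-lipid
        set_pair(H, H, STYLE_WCA, 1.0, 0.95)
        set_pair(H, T, STYLE_WCA, 1.0, 0.95)
        set_pair(T, T, STYLE_TAIL, eps_tt, 1.00)
        # polymer-polymer: self-repulsive, heterotypically attractive
        set_pair(A, A, STYLE_WCA, 1.0, 0.5)
        set_pair(B, B, STYLE_WCA, 1.0, 0.5)
        set_pair(A, B, STYLE_LJ, eps_pp, 0.5)
        # polymer-lipid: attractive to heads, repulsive to tails
        # (Lorentz arithmetic-mean mixing for the cross sigmas)
        sig_ah = 0.5 * (0.95 + 0.5)
        sig_at = 0.5 * (1.00 + 0.5)
        set_pair(A, H, STYLE_LJ, eps_pl, sig_ah)
        set_pair(B, H, STYLE_LJ, eps_pl, sig_ah)
        set_pair(A, T, STYLE_WCA, 1.0, sig_at)
        set_pair(B, T, STYLE_WCA, 1.0, sig_at)

        cut = np.where(style == STYLE_LJ, LJ_CUT * sig, WCA_CUT * sig)
        cut[style == STYLE_NONE] = 0.0
        omega = np.zeros_like(cut)
        omega[T, T] = omega_tt
        return cls(style=style, eps=eps, sigma=sig, cutoff=cut, omega=omega)


# Optimized couplings for the membrane-composition analogues.  The 5% DOPS
# pair is the published one; the other three compositions carry estimated
# values (monotone wetting strength with anionic-lipid content) and are so
# flagged -- see coacwet/data/presets.toml for provenance notes.
PRESETS: dict[str, dict] = {
    "dopc": {"eps_pl": 0.700, "omega_tt": 1.72, "provenance": "estimated"},
    "dops5": {"eps_pl": 0.7625, "omega_tt": 1.70, "provenance": "published"},
    "dops10": {"eps_pl": 0.850, "omega_tt": 1.66, "provenance": "estimated"},
    "dops20": {"eps_pl": 0.950, "omega_tt": 1.60, "provenance": "estimated"},
    "droplet-only": {"eps_pl": 0.0, "omega_tt": 1.70, "provenance": "construction"},
}


def preset_pair_table(name: str) -> PairTable:
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[name]
    eps_pl = p["eps_pl"] if p["eps_pl"] > 0 else 1e-12  # droplet-only: no lipids anyway
    return PairTable.default(eps_pl=eps_pl, omega_tt=p["omega_tt"])


@dataclasses.dataclass
class SystemState:
    """Complete bead system: positions, velocities, bonds, box, interactions.

    Positions are stored unwrapped (displacement analyses need continuous
    coordinates); ``wrapped_positions`` gives the in-box view.  ``mol`` groups
    beads into molecules (3 beads per lipid, 10 per chain).
    """

    box_length: float
    species: np.ndarray          # (N,) int
    mol: np.ndarray              # (N,) int molecule id
    positions: np.ndarray        # (N, 3) float
    velocities: np.ndarray       # (N, 3) float
    bond_i: np.ndarray           # (Nb,) int
    bond_j: np.ndarray           # (Nb,) int
    bond_style: np.ndarray       # (Nb,) int
    bond_k: np.ndarray           # (Nb,) float
    bond_r0: np.ndarray          # (Nb,) float: r_eq (harmonic) or r_inf (FENE)
    pair_table: PairTable
    step: int = 0

    @property
    def n_beads(self) -> int:
        return len(self.species)

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.positions, self.box_length)

    def copy(self) -> "SystemState":
        return SystemState(
            box_length=self.box_length,
            species=self.species.copy(),
            mol=self.mol.copy(),
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            bond_i=self.bond_i.copy(),
            bond_j=self.bond_j.copy(),
            bond_style=self.bond_style.copy(),
            bond_k=self.bond_k.copy(),
            bond_r0=self.bond_r0.copy(),
            pair_table=self.pair_table,
            step=self.step,
        )

    def select(self, species: Iterable[str]) -> np.ndarray:
        codes = [SPECIES[s] for s in species]
        return np.isin(self.species, codes)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        n = self.n_beads
        if len(self.bond_i) and (self.bond_i.max() >= n or self.bond_j.max() >= n):
            raise ValueError("bond partner out of range")
        fene = self.bond_style == BOND_FENE
        if np.any(fene):
            d = self.positions[self.bond_i[fene]] - self.positions[self.bond_j[fene]]
            d -= self.box_length * np.round(d / self.box_length)
            r = np.linalg.norm(d, axis=1)
            if np.any(r >= self.bond_r0[fene]):
                raise BondOverextensionError("FENE bond at or beyond r_inf in state")


@dataclasses.dataclass
class SimProtocol:
    """Langevin run protocol in reduced units.

    Defaults follow the published protocol: equilibration dt*=0.002 for 1e5
    steps, production dt*=0.005 for 1e7 steps, T*=1.1, damping timescale 50.0,
    coordinates dumped every 1e4 steps.  Desk-scale runs shorten ``n_steps``.
    """

    dt_star: float = 0.005
    n_steps: int = 10_000_000
    T_star: float = 1.1
    damping: float = 50.0
    dump_interval: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.dt_star <= 0:
            raise ValueError("dt_star must be positive")

    @classmethod
    def equilibration(cls, n_steps: int = 100_000, seed: int = 0, **kw) -> "SimProtocol":
        return cls(dt_star=0.002, n_steps=n_steps, seed=seed, **kw)


def pair_force(r_vec: np.ndarray, pair_table: PairTable, species_i: str | int,
               species_j: str | int) -> np.ndarray:
    """Force on bead i from bead j at separation ``r_vec = r_i - r_j``.

    Analytic gradient ``F = -dU/dr r_hat`` of the configured pair style.
    """
    si = SPECIES[species_i] if isinstance(species_i, str) else int(species_i)
    sj = SPECIES[species_j] if isinstance(species_j, str) else int(species_j)
    style = int(pair_table.style[si, sj])
    if style == STYLE_NONE:
        raise ConfigurationError(f"no pair style for species pair ({species_i}, {species_j})")
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r <= 0:
        raise ValueError("zero separation")
    eps = float(pair_table.eps[si, sj])
    sig = float(pair_table.sigma[si, sj])
    dudr = 0.0
    if style == STYLE_WCA:
        if r <= WCA_CUT * sig:
            sr6 = (sig / r) ** 6
            dudr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    elif style == STYLE_LJ:
        if r <= LJ_CUT * sig:
            sr6 = (sig / r) ** 6
            dudr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    elif style == STYLE_TAIL:
        r_c = float(pair_table.cutoff[si, sj])
        omega = float(pair_table.omega[si, sj])
        # WCA core
        if r <= WCA_CUT * sig:
            sr6 = (sig / r) ** 6
            dudr += 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        # cos^2 ramp (flat well contributes no force)
        if r_c <= r <= r_c + omega:
            x = math.pi * (r - r_c) / (2.0 * omega)
            dudr += eps * math.pi / (2.0 * omega) * math.sin(2.0 * x)
    return -dudr * r_vec / r
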