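"""Langevin / NVE dynamics for the generic coarse-grained model.

The integrator is BAOAB-split Langevin dynamics (velocity Verlet when the
friction is switched off), with Verlet neighbor lists rebuilt from cell lists
whenever any bead has moved more than half the skin.  All hot loops are numba
kernels over flat arrays; :class:`~coacwet.model.SystemState` is unpacked at
the boundary.  k_B = 1, unit masses.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from coacwet.model import (
    BOND_FENE,
    BOND_HARMONIC,
    STYLE_LJ,
    STYLE_NONE,
    STYLE_TAIL,
    BondOverextensionError,
    SimProtocol,
    SystemState,
)

DEFAULT_SKIN = 0.3

STATUS_OK = 0
STATUS_FENE = 1
STATUS_NONFINITE = 2
STATUS_NEIGH_OVERFLOW = 3


class IntegrationError(RuntimeError):
    pass


@njit(cache=True, fastmath=True)
def _build_neighbors(pos, box, rlist, maxn, neigh, nneigh):
    """Half neighbor list (j > i) within rlist, via cell binning.

    Returns 0 on success, -1 on per-bead overflow of ``maxn``.
    """
    n = pos.shape[0]
    inv_box = 1.0 / box
    nneigh[:] = 0
    nc = int(box / rlist)
    if nc < 3:
        # small box: direct O(N^2)
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= box * np.rint(dx * inv_box)
                dy -= box * np.rint(dy * inv_box)
                dz -= box * np.rint(dz * inv_box)
                if dx * dx + dy * dy + dz * dz < rlist * rlist:
                    if nneigh[i] >= maxn:
                        return -1
                    neigh[i, nneigh[i]] = j
                    nneigh[i] += 1
        return 0
    cell = box / nc
    ncell = nc * nc * nc
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cidx = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] % box) / cell) % nc
        cy = int((pos[i, 1] % box) / cell) % nc
        cz = int((pos[i, 2] % box) / cell) % nc
        c = (cx * nc + cy) * nc + cz
        cidx[i] = c
        nxt[i] = head[c]
        head[c] = i
    r2max = rlist * rlist
    for i in range(n):
        c = cidx[i]
        cz = c % nc
        cy = (c // nc) % nc
        cx = c // (nc * nc)
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                for oz in range(-1, 2):
                    cc = (((cx + ox) % nc) * nc + ((cy + oy) % nc)) * nc + ((cz + oz) % nc)
                    j = head[cc]
                    while j >= 0:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= box * np.rint(dx * inv_box)
                            dy -= box * np.rint(dy * inv_box)
                            dz -= box * np.rint(dz * inv_box)
                            if dx * dx + dy * dy + dz * dz < r2max:
                                if nneigh[i] >= maxn:
                                    return -1
                                neigh[i, nneigh[i]] = j
                                nneigh[i] += 1
                        j = nxt[j]
    return 0


@njit(cache=True, fastmath=True)
def _forces(pos, species, box, neigh, nneigh, p_style, p_eps, p_sig, p_cut, p_omega,
            bond_i, bond_j, bond_style, bond_k, bond_r0, forces):
    """Fill ``forces``; return (potential energy, status)."""
    n = pos.shape[0]
    inv_box = 1.0 / box
    forces[:] = 0.0
    energy = 0.0
    for i in range(n):
        si = species[i]
        pix = pos[i, 0]
        piy = pos[i, 1]
        piz = pos[i, 2]
        fix = 0.0
        fiy = 0.0
        fiz = 0.0
        for m in range(nneigh[i]):
            j = neigh[i, m]
            sj = species[j]
            st = p_style[si, sj]
            if st == STYLE_NONE:
                continue
            dx = pix - pos[j, 0]
            dy = piy - pos[j, 1]
            dz = piz - pos[j, 2]
            dx -= box * np.rint(dx * inv_box)
            dy -= box * np.rint(dy * inv_box)
            dz -= box * np.rint(dz * inv_box)
            r2 = dx * dx + dy * dy + dz * dz
            rc_tot = p_cut[si, sj] + p_omega[si, sj]
            if r2 >= rc_tot * rc_tot or r2 <= 0.0:
                continue
            # all in r^2 where possible: f = (-dU/dr)/r, force = f * dr_vec
            eps = p_eps[si, sj]
            sig = p_sig[si, sj]
            f = 0.0
            if st == STYLE_LJ:
                s2 = sig * sig / r2
                s6 = s2 * s2 * s2
                energy += 4.0 * eps * (s6 * s6 - s6)
                f = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
            else:
                # WCA core (also the core of the TAIL style)
                if r2 <= 1.259921049894873 * sig * sig:  # (2^(1/6) sig)^2
                    s2 = sig * sig / r2
                    s6 = s2 * s2 * s2
                    energy += 4.0 * eps * (s6 * s6 - s6 + 0.25)
                    f = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                if st == STYLE_TAIL:
                    rc = p_cut[si, sj]
                    if r2 < rc * rc:
                        energy += -eps
                    else:
                        omega = p_omega[si, sj]
                        r = np.sqrt(r2)
                        c2 = np.cos(np.pi * (r - rc) / omega)
                        energy += -0.5 * eps * (1.0 + c2)
                        s2r = np.sqrt(max(0.0, 1.0 - c2 * c2))
                        f -= eps * np.pi / (2.0 * omega) * s2r / r
            fix += f * dx
            fiy += f * dy
            fiz += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.rint(dx / box)
        dy -= box * np.rint(dy / box)
        dz -= box * np.rint(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if bond_style[b] == BOND_HARMONIC:
            energy += 0.5 * bond_k[b] * (r - bond_r0[b]) ** 2
            dudr = bond_k[b] * (r - bond_r0[b])
        else:  # FENE
            rinf = bond_r0[b]
            if r >= rinf:
                return energy, STATUS_FENE
            x2 = (r / rinf) ** 2
            energy += -0.5 * bond_k[b] * rinf * rinf * np.log(1.0 - x2)
            dudr = bond_k[b] * r / (1.0 - x2)
        if r > 0:
            f = -dudr / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
    return energy, STATUS_OK


@njit(cache=True, fastmath=True)
def _run(pos, vel, species, box, p_style, p_eps, p_sig, p_cut, p_omega,
         bond_i, bond_j, bond_style, bond_k, bond_r0,
         dt, n_steps, T, gamma, seed, dump_interval, temp_stride,
         rlist, maxn, frames_pos, frames_vel, temps, energies):
    """BAOAB Langevin (gamma > 0) or velocity Verlet (gamma == 0) loop.

    Returns (status, step_at_failure, n_frames, n_temps).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    neigh = np.empty((n, maxn), dtype=np.int64)
    nneigh = np.empty(n, dtype=np.int64)
    forces = np.empty((n, 3))
    pos_ref = pos.copy()
    skin = DEFAULT_SKIN

    if _build_neighbors(pos, box, rlist, maxn, neigh, nneigh) < 0:
        return STATUS_NEIGH_OVERFLOW, 0, 0, 0
    e, st = _forces(pos, species, box, neigh, nneigh, p_style, p_eps, p_sig,
                    p_cut, p_omega, bond_i, bond_j, bond_style, bond_k, bond_r0, forces)
    if st != STATUS_OK:
        return st, 0, 0, 0

    c1 = np.exp(-gamma * dt) if gamma > 0.0 else 1.0
    c2 = np.sqrt(T * (1.0 - c1 * c1)) if gamma > 0.0 else 0.0

    nf = 0
    nt = 0
    for step in range(1, n_steps + 1):
        # B
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d]
        # A
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        # O
        if gamma > 0.0:
            for i in range(n):
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + c2 * np.random.standard_normal()
        # A
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        # neighbor refresh check
        max_d2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - pos_ref[i, 0]
            dy = pos[i, 1] - pos_ref[i, 1]
            dz = pos[i, 2] - pos_ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > max_d2:
                max_d2 = d2
        if max_d2 > (0.5 * skin) ** 2:
            if _build_neighbors(pos, box, rlist, maxn, neigh, nneigh) < 0:
                return STATUS_NEIGH_OVERFLOW, step, nf, nt
            pos_ref[:] = pos
        e, st = _forces(pos, species, box, neigh, nneigh, p_style, p_eps, p_sig,
                        p_cut, p_omega, bond_i, bond_j, bond_style, bond_k, bond_r0, forces)
        if st != STATUS_OK:
            return st, step, nf, nt
        # B
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d]
        if not np.isfinite(pos[0, 0]):
            return STATUS_NONFINITE, step, nf, nt
        if temp_stride > 0 and step % temp_stride == 0:
            ke = 0.0
            for i in range(n):
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            temps[nt] = ke / (3.0 * n)
            nt += 1
        if dump_interval > 0 and step % dump_interval == 0:
            frames_pos[nf] = pos
            frames_vel[nf] = vel
            ke = 0.0
            for i in range(n):
                ke += 0.5 * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            energies[nf] = e + ke
            nf += 1
    return STATUS_OK, n_steps, nf, nt


@njit(cache=True)
def _minimize(pos, species, box, p_style, p_eps, p_sig, p_cut, p_omega,
              bond_i, bond_j, bond_style, bond_k, bond_r0,
              n_iter, max_disp, rlist, maxn):
    """Displacement-capped steepest descent; returns final energy.

    Returns NaN when the neighbor list capacity is exceeded (caller retries
    with a larger ``maxn``).
    """
    n = pos.shape[0]
    neigh = np.empty((n, maxn), dtype=np.int64)
    nneigh = np.empty(n, dtype=np.int64)
    forces = np.empty((n, 3))
    step = 1e-4
    e_prev = 1e300
    for it in range(n_iter):
        if _build_neighbors(pos, box, rlist, maxn, neigh, nneigh) < 0:
            return np.nan
        e, st = _forces(pos, species, box, neigh, nneigh, p_style, p_eps, p_sig,
                        p_cut, p_omega, bond_i, bond_j, bond_style, bond_k, bond_r0, forces)
        if st != STATUS_OK:
            # FENE overextension during minimization: shrink toward partner
            for b in range(bond_i.shape[0]):
                if bond_style[b] == BOND_FENE:
                    i = bond_i[b]
                    j = bond_j[b]
                    for d in range(3):
                        mid = 0.5 * (pos[i, d] + pos[j, d])
                        pos[i, d] = mid + 0.45 * (pos[i, d] - mid)
                        pos[j, d] = mid + 0.45 * (pos[j, d] - mid)
            continue
        if e > e_prev:
            step *= 0.5
        else:
            step *= 1.1
        e_prev = e
        for i in range(n):
            for d in range(3):
                dd = step * forces[i, d]
                if dd > max_disp:
                    dd = max_disp
                elif dd < -max_disp:
                    dd = -max_disp
                pos[i, d] += dd
    return e_prev


def _pack(state: SystemState):
    pt = state.pair_table
    return (pt.style, pt.eps, pt.sigma, pt.cutoff, pt.omega)


def _rlist(state: SystemState) -> float:
    """Neighbor-list radius from the pair cutoffs of the species present."""
    pt = state.pair_table
    present = np.unique(state.species)
    total = pt.cutoff + pt.omega
    rmax = 0.0
    for si in present:
        for sj in present:
            if pt.style[si, sj] != STYLE_NONE:
                rmax = max(rmax, float(total[si, sj]))
    return (rmax if rmax > 0 else pt.max_cutoff) + DEFAULT_SKIN


@dataclasses.dataclass
class Trajectory:
    """Frames from a run: unwrapped positions/velocities at dump steps."""

    times: np.ndarray          # (F,) reduced time of each frame
    positions: np.ndarray      # (F, N, 3)
    velocities: np.ndarray     # (F, N, 3)
    total_energy: np.ndarray   # (F,)
    temps: np.ndarray          # instantaneous T* trace (stride recorded)
    temp_stride_time: float
    state: SystemState         # final state

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame_state(self, f: int) -> SystemState:
        s = self.state.copy()
        s.positions = self.positions[f].copy()
        s.velocities = self.velocities[f].copy()
        return s

    def mean_temperature(self, n_blocks: int = 20):
        """Block-averaged mean instantaneous T* and its standard error."""
        t = self.temps
        nb = min(n_blocks, max(1, len(t) // 10))
        m = len(t) // nb
        blocks = t[: nb * m].reshape(nb, m).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(nb) if nb > 1 else np.nan
        return float(t.mean()), float(se)


def _run_state(state: SystemState, protocol: SimProtocol, gamma: float,
               temp_stride: int, maxn: int = 128) -> Trajectory:
    s = state.copy()
    n = s.n_beads
    if n == 0:
        raise ValueError("empty state")
    n_frames = protocol.n_steps // protocol.dump_interval if protocol.dump_interval > 0 else 0
    n_temps = protocol.n_steps // temp_stride if temp_stride > 0 else 0
    frames_pos = np.empty((max(n_frames, 1), n, 3))
    frames_vel = np.empty((max(n_frames, 1), n, 3))
    energies = np.empty(max(n_frames, 1))
    temps = np.empty(max(n_temps, 1))
    while True:
        pos = s.positions.copy()
        vel = s.velocities.copy()
        status, step, nf, nt = _run(
            pos, vel, s.species, s.box_length, *_pack(s),
            s.bond_i, s.bond_j, s.bond_style, s.bond_k, s.bond_r0,
            protocol.dt_star, protocol.n_steps, protocol.T_star, gamma,
            protocol.seed, protocol.dump_interval, temp_stride,
            _rlist(s), maxn, frames_pos, frames_vel, temps, energies)
        if status == STATUS_NEIGH_OVERFLOW and maxn < 4096:
            maxn *= 2
            continue
        break
    if status == STATUS_FENE:
        raise BondOverextensionError(f"FENE bond broke at step {step}")
    if status == STATUS_NONFINITE:
        raise IntegrationError(f"non-finite coordinates at step {step}")
    if status == STATUS_NEIGH_OVERFLOW:
        raise IntegrationError("neighbor list overflow")
    s.positions = pos
    s.velocities = vel
    s.step += protocol.n_steps
    times = protocol.dt_star * protocol.dump_interval * np.arange(1, nf + 1)
    return Trajectory(
        times=times,
        positions=frames_pos[:nf],
        velocities=frames_vel[:nf],
        total_energy=energies[:nf],
        temps=temps[:nt],
        temp_stride_time=protocol.dt_star * temp_stride,
        state=s,
    )


def langevin_run(state: SystemState, protocol: SimProtocol,
                 temp_stride: int = 10) -> Trajectory:
    """Integrate ``state`` under the Langevin thermostat of ``protocol``.

    Same seed and inputs give an identical trajectory.  The instantaneous
    reduced temperature is recorded every ``temp_stride`` steps for the
    thermostat contract (time-averaged T* within statistical error of the
    target).
    """
    gamma = 1.0 / protocol.damping
    return _run_state(state, protocol, gamma, temp_stride)


def nve_run(state: SystemState, dt_star: float, n_steps: int,
            dump_interval: int = 100) -> Trajectory:
    """Thermostat-free velocity-Verlet run (energy-conservation checks)."""
    protocol = SimProtocol(dt_star=dt_star, n_steps=n_steps, T_star=0.0,
                           damping=np.inf, dump_interval=dump_interval, seed=0)
    return _run_state(state, protocol, 0.0, temp_stride=0)


def minimize(state: SystemState, n_iter: int = 500, max_disp: float = 0.05) -> SystemState:
    """Relax overlaps by displacement-capped steepest descent (on a copy)."""
    s = state.copy()
    maxn = 128
    e = np.nan
    while maxn <= 4096:
        pos = s.positions.copy()
        e = _minimize(pos, s.species, s.box_length, *_pack(s),
                      s.bond_i, s.bond_j, s.bond_style, s.bond_k, s.bond_r0,
                      n_iter, max_disp, _rlist(s), maxn)
        if not np.isnan(e):
            break
        maxn *= 2
    if np.isnan(e):
        raise IntegrationError("neighbor list overflow during minimization")
    s.positions = pos
    return s


def measure_temperature(state: SystemState) -> float:
    """Equipartition readout: T* = 2<KE>/(3N) with k_B = 1, unit masses."""
    if state.n_beads == 0:
        raise ValueError("empty state")
    v2 = np.sum(state.velocities**2)
    return float(v2 / (3.0 * state.n_beads))


def total_energy(state: SystemState, maxn: int = 256) -> float:
    """Potential + kinetic energy of a state (diagnostics)."""
    n = state.n_beads
    neigh = np.empty((n, maxn), dtype=np.int64)
    nneigh = np.empty(n, dtype=np.int64)
    forces = np.empty((n, 3))
    if _build_neighbors(state.positions, state.box_length, _rlist(state), maxn,
                        neigh, nneigh) < 0:
        raise IntegrationError("neighbor list overflow")
    e, st = _forces(state.positions, state.species, state.box_length, neigh, nneigh,
                    *_pack(state), state.bond_i, state.bond_j, state.bond_style,
                    state.bond_k, state.bond_r0, forces)
    if st != STATUS_OK:
        raise BondOverextensionError("FENE bond at or beyond r_inf")
    return float(e + 0.5 * np.sum(state.velocities**2))


def maxwell_velocities(n: int, T_star: float, rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities at T*, zero total momentum."""
    v = rng.normal(scale=np.sqrt(T_star), size=(n, 3))
    return v - v.mean(axis=0)
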