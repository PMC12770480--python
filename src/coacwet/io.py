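"""Readers, writers and configuration.

Trajectories of the generic model travel as LAMMPS-dump text (``ITEM:``
blocks with ``id type mol x y z``); externally produced MARTINI trajectories
are ingested from GRO/XTC via MDAnalysis.  Configuration uses TOML
([system]/[pairs]/[protocol] sections); a small nonbonded-table utility
applies the published 1.20 rescaling of polyelectrolyte/lipid-head
interactions while leaving charged-head (DOPS) rows untouched.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from coacwet.model import PairTable, SystemState


class ParseError(ValueError):
    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


def write_dump(path, states, append: bool = False) -> None:
    """Write frames in the LAMMPS-dump text dialect (id type mol x y z).

    Coordinates are emitted with 17 significant digits so a read round-trips
    bit-exactly.
    """
    if isinstance(states, SystemState):
        states = [states]
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for s in states:
            fh.write("ITEM: TIMESTEP\n%d\n" % s.step)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % s.n_beads)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write("%.17g %.17g\n" % (0.0, s.box_length))
            fh.write("ITEM: ATOMS id type mol x y z\n")
            for i in range(s.n_beads):
                fh.write("%d %d %d %.17g %.17g %.17g\n" % (
                    i + 1, s.species[i] + 1, s.mol[i],
                    s.positions[i, 0], s.positions[i, 1], s.positions[i, 2]))


def read_dump(path, pair_table: PairTable | None = None) -> Iterator[SystemState]:
    """Stream frames from a LAMMPS-dump text file.

    Bonds are not part of the dump format; returned states carry empty bond
    tables (the analyses operating on dumps only need species/mol/positions).
    """
    pt = pair_table or PairTable.default()
    with open(path) as fh:
        lineno = 0

        def next_line():
            nonlocal lineno
            line = fh.readline()
            lineno += 1
            if not line:
                raise EOFError
            return line.rstrip("\n")

        while True:
            try:
                header = fh.readline()
                lineno += 1
                if not header:
                    return
                if header.strip() != "ITEM: TIMESTEP":
                    raise ParseError(f"expected ITEM: TIMESTEP, got {header.strip()!r}",
                                     lineno)
                step = int(next_line())
                if next_line() != "ITEM: NUMBER OF ATOMS":
                    raise ParseError("expected ITEM: NUMBER OF ATOMS", lineno)
                n = int(next_line())
                if not next_line().startswith("ITEM: BOX BOUNDS"):
                    raise ParseError("expected ITEM: BOX BOUNDS", lineno)
                lo, hi = (float(x) for x in next_line().split())
                box = hi - lo
                next_line()
                next_line()
                cols = next_line()
                if not cols.startswith("ITEM: ATOMS"):
                    raise ParseError("expected ITEM: ATOMS", lineno)
                species = np.empty(n, dtype=np.int64)
                mol = np.empty(n, dtype=np.int64)
                pos = np.empty((n, 3))
                for k in range(n):
                    parts = next_line().split()
                    if len(parts) != 6:
                        raise ParseError("expected 6 columns in ATOMS record", lineno)
                    idx = int(parts[0]) - 1
                    if not 0 <= idx < n:
                        raise ParseError(f"atom id {idx + 1} out of range", lineno)
                    species[idx] = int(parts[1]) - 1
                    mol[idx] = int(parts[2])
                    pos[idx] = [float(parts[3]), float(parts[4]), float(parts[5])]
                yield SystemState(
                    box_length=box, species=species, mol=mol, positions=pos,
                    velocities=np.zeros((n, 3)),
                    bond_i=np.empty(0, dtype=np.int64),
                    bond_j=np.empty(0, dtype=np.int64),
                    bond_style=np.empty(0, dtype=np.int64),
                    bond_k=np.empty(0), bond_r0=np.empty(0),
                    pair_table=pt, step=step)
            except EOFError:
                raise ParseError("truncated file", lineno) from None


def read_gro_xtc(structure_path, trajectory_path=None, species_map: dict | None = None):
    """Iterate frames of an externally produced (e.g. MARTINI) trajectory.

    Positions are returned in nm together with per-atom species labels
    resolved through ``species_map`` (residue name -> label).  Unmapped
    residue names raise a mapping error listing the offenders.
    """
    import MDAnalysis as mda

    u = (mda.Universe(str(structure_path), str(trajectory_path))
         if trajectory_path else mda.Universe(str(structure_path)))
    resnames = u.atoms.resnames
    labels = None
    if species_map is not None:
        unknown = sorted(set(resnames) - set(species_map))
        if unknown:
            raise KeyError(f"unmapped residue names: {unknown}")
        labels = np.array([species_map[r] for r in resnames], dtype=object)
    for ts in u.trajectory:
        yield {
            "time": float(ts.time),
            "positions_nm": ts.positions / 10.0,  # MDAnalysis uses Angstrom
            "box_nm": ts.dimensions[:3] / 10.0 if ts.dimensions is not None else None,
            "resnames": resnames,
            "labels": labels,
        }


# ---------------------------------------------------------------------------
# nonbonded table rescaling (MARTINI refinement utility)


def make_nonbonded_table(rows) -> pd.DataFrame:
    """Rows of (type_a, type_b, epsilon, sigma[, charged_head])."""
    df = pd.DataFrame(rows, columns=["type_a", "type_b", "epsilon", "sigma",
                                     "charged_head"][: len(rows[0])])
    if "charged_head" not in df:
        df["charged_head"] = False
    key = df.apply(lambda r: tuple(sorted((r.type_a, r.type_b))), axis=1)
    if key.duplicated().any():
        raise ValueError("duplicate unordered type pairs in table")
    if (df.epsilon <= 0).any() or (df.sigma <= 0).any():
        raise ValueError("epsilon and sigma must be positive")
    return df


def scale_nonbonded(table: pd.DataFrame, pairs, factor: float) -> pd.DataFrame:
    """Scale epsilon by ``factor`` on the selected pairs, sigma untouched.

    ``pairs`` is an iterable of (type_a, type_b) tuples (order-insensitive)
    or a boolean mask.  Rows flagged ``charged_head`` (e.g. DOPS head beads,
    which already interact Coulombically) are never scaled.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    out = table.copy()
    if isinstance(pairs, (pd.Series, np.ndarray, list)) and (
            len(pairs) == len(table) and np.asarray(pairs).dtype == bool):
        sel = np.asarray(pairs, dtype=bool)
    else:
        wanted = {tuple(sorted(p)) for p in pairs}
        sel = table.apply(
            lambda r: tuple(sorted((r.type_a, r.type_b))) in wanted, axis=1).to_numpy()
    sel = sel & ~table["charged_head"].to_numpy()
    if not sel.any():
        raise ValueError("selection resolves to no scalable rows")
    out.loc[sel, "epsilon"] = out.loc[sel, "epsilon"] * factor
    return out


# ---------------------------------------------------------------------------
# TOML configuration


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float, np.integer, np.floating)):
        return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_config(config: dict, path) -> None:
    """Minimal TOML writer for one level of sections of scalar/list values."""
    lines = []
    scalars = {k: v for k, v in config.items() if not isinstance(v, dict)}
    for k, v in scalars.items():
        lines.append(f"{k} = {_toml_value(v)}")
    for section, values in config.items():
        if not isinstance(values, dict):
            continue
        lines.append("")
        lines.append(f"[{section}]")
        for k, v in values.items():
            lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_config(preset: str = "dops5", seed: int = 0) -> dict:
    """Paper-default run configuration, ready to serialize."""
    from coacwet.model import PRESETS

    p = PRESETS[preset]
    return {
        "system": {
            "preset": preset,
            "eps_pl": p["eps_pl"],
            "omega_tt": p["omega_tt"],
            "eps_pp": 1.5,
            "provenance": p["provenance"],
            "droplet_box": 40.0,
            "vesicle_box": 70.0,
            "vesicle_diameter": 50.0,
            "chains_per_species": 1000,
        },
        "pairs": {
            "sigma_aa": 0.5, "sigma_bb": 0.5,
            "sigma_hh": 0.95, "sigma_ht": 0.95, "sigma_tt": 1.0,
            "harmonic_k": 50.0, "harmonic_req": 0.548,
            "fene_k": 30.0, "fene_rinf": 1.5,
            "harmonic_half_prefactor": True,
        },
        "protocol": {
            "equil_dt": 0.002, "equil_steps": 100000,
            "prod_dt": 0.005, "prod_steps": 10000000,
            "T_star": 1.1, "damping": 50.0,
            "dump_interval": 10000, "seed": seed,
        },
    }
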