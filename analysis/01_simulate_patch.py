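#!/usr/bin/env python
"""Desk-scale generic-model run: thermostat check and bilayer stability.

Builds a 128-lipid three-bead bilayer patch, takes it through
thermalization + the published equilibration protocol, then runs a 1e5-step
production window (dt* = 0.005, T* = 1.1, damping 50) and reports the
measured mean reduced temperature and lipid retention.  Writes
results/01_thermostat.json and the production trajectory as a LAMMPS-style
dump.
"""

import json
from pathlib import Path

import numpy as np

from coacwet import engine, io, synth
from coacwet.model import SimProtocol

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 1):
    state = synth.equilibrated_patch(128, seed=seed)
    prod = engine.langevin_run(state, SimProtocol(
        dt_star=0.005, n_steps=100_000, dump_interval=10_000, seed=seed + 3))
    mean_T, se_T = prod.mean_temperature()
    z = prod.state.positions[:, 2]
    retention = float(np.mean(np.abs(z - np.median(z)) < 5.0))
    io.write_dump(OUT / "01_patch128.dump",
                  [prod.frame_state(f) for f in range(prod.n_frames)])
    report = {"mean_T": mean_T, "se_T": se_T, "target_T": 1.1,
              "retention": retention, "n_lipids": 128,
              "production_steps": 100_000}
    (OUT / "01_thermostat.json").write_text(json.dumps(report, indent=2))
    print(f"mean T* = {mean_T:.4f} +/- {se_T:.4f} (target 1.1); "
          f"lipid retention {retention:.3f}")


if __name__ == "__main__":
    main()
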