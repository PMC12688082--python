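"""Construct an assembly-phase simulation system and its run parameters.

Places unimers in a box at the 2:1:1:1 chain ratio, inserts DiI cargo
outside the solute, reports solvation bookkeeping, and emits the
production MDP text.
"""

import numpy as np

from cgkit.sysbuild import (emit_run_parameters, insert_cargo, place_unimers,
                            solvation_counts)
from cgkit.topology import assign_bonded_parameters, build_dii_topology

frame = place_unimers(20, box=[120.0, 120.0, 120.0], seed=7)
n_mols = frame.atoms["molid"].nunique()
print(f"placed {n_mols} unimers ({frame.n_beads} beads) in a 12 nm box")

dii = assign_bonded_parameters(build_dii_topology())
loaded = insert_cargo(frame, dii, 5, seed=8)
print(f"inserted {(loaded.atoms['molname'] == 'DII').sum() // 21} DiI "
      "molecules outside the solute region")

solv = solvation_counts(loaded)
print(f"solvation bookkeeping: {solv['W']} water beads, "
      f"{solv['CL']} Cl- to neutralise the +{loaded.total_charge:.0f} charge")

rp, mdp = emit_run_parameters("production")
print(f"\nproduction protocol: dt {rp.timestep_fs} fs, cutoffs "
      f"{rp.lj_cutoff_nm} nm, eps_r {rp.epsilon_r}, T {rp.temperature_K} K")
print(mdp)
# These initial configurations are MD inputs; the engine equilibrates the
# solvent and relaxes the grown conformations.
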