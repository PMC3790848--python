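"""Salt-bridge detection and the one-call stability profile.

Builds a small two-frame ensemble containing a glutamate/lysine pair that is
bonded in one frame and separated in the other (occupancy 0.5), then runs the
full per-structure profile on a synthetic helix.  Pass a PDB path as the
first argument to profile a real structure instead, e.g. a p53-family
DNA-binding domain.
"""

import sys

import numpy as np

from corestab import salt_bridges
from corestab.structure_io import AtomRecord, Structure, Ensemble
from corestab.profiler import profile
from corestab.synthetic_data import make_helix

atoms = [
    AtomRecord(1, "N", "N", "GLU", 10, "", "A", (0, 5, 0)),
    AtomRecord(2, "CA", "C", "GLU", 10, "", "A", (1.5, 5, 0)),
    AtomRecord(3, "OE1", "O", "GLU", 10, "", "A", (0.0, 0.0, 0.0)),
    AtomRecord(4, "N", "N", "LYS", 30, "", "A", (8, 5, 0)),
    AtomRecord(5, "CA", "C", "LYS", 30, "", "A", (7, 5, 0)),
    AtomRecord(6, "NZ", "N", "LYS", 30, "", "A", (3.2, 0.0, 0.0)),
]
pair = Structure(atoms, "glu-lys")
apart = pair.coords().copy()
apart[5] += np.array([6.0, 0.0, 0.0])        # move NZ away in frame 2
ensemble = Ensemble(pair, np.stack([pair.coords(), apart]))

for record in salt_bridges(ensemble, cutoff=4.0):
    print(f"salt bridge {record.acidic_name}{record.acidic_residue[1]} - "
          f"{record.basic_name}{record.basic_residue[1]}: "
          f"min distance {record.distance:.1f} Å, occupancy {record.occupancy:.0%}")
# occupancy is the fraction of frames in which the charged atoms come within
# the 4 Å cutoff — 50% here by construction.

target = sys.argv[1] if len(sys.argv) > 1 else make_helix(12)[0]
report = profile(target, chain="A")
print("\nstability profile:")
for key, value in report.summary().items():
    if key != "parameters":
        print(f"  {key}: {value}")
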