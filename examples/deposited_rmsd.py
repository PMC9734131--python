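"""Region-RMSD comparisons against deposited structural ensembles.

This analysis needs externally fetched coordinate files (not shipped):

    data/deposited/8B7I.pdb      open-state ensemble (20 models)
    data/deposited/8B7J.pdb      closed-state ensemble (20 models)
    data/deposited/7L7J_ntd.pdb  N-terminal domain extracted from the
                                 full-length dimer structure

e.g. from the RCSB:  https://files.rcsb.org/download/8B7I.pdb

It then measures (i) the mobile-segment backbone RMSD between the
representative open and closed models after superposing on the rigid
scaffold (residues 11-97 + 137-223) — expected ~20 A — and (ii) the
lid Ca RMSD between the closed state and the full-length-dimer
reference — expected ~4.1 A.
"""

import sys
from pathlib import Path

from lidex.ensemble_geometry import Selection, region_rmsd, representative_model
from lidex.io import read_multimodel_pdb

base = Path(__file__).resolve().parent.parent / "data" / "deposited"
paths = {name: base / name for name in ("8B7I.pdb", "8B7J.pdb", "7L7J_ntd.pdb")}
missing = [n for n, p in paths.items() if not p.exists()]
if missing:
    sys.exit(f"missing {', '.join(missing)} under {base}; "
             "fetch the deposited structures first (see module docstring)")

ens_open = read_multimodel_pdb(paths["8B7I.pdb"])
ens_closed = read_multimodel_pdb(paths["8B7J.pdb"])
fit = Selection(((11, 97), (137, 223)), "backbone")
measure = Selection(((98, 136),), "backbone")
rep_open = ens_open.model(representative_model(ens_open, fit))
rep_closed = ens_closed.model(representative_model(ens_closed, fit))
r = region_rmsd(rep_open, rep_closed, fit, measure)
print(f"open vs closed mobile-segment backbone RMSD: {r:.1f} A (expect ~20)")

ref = read_multimodel_pdb(paths["7L7J_ntd.pdb"])
lid_ca = Selection(((98, 136),), "CA_only")
r_lid = region_rmsd(rep_closed, ref.model(0), lid_ca, lid_ca)
print(f"closed state vs full-length-dimer lid Ca RMSD: {r_lid:.1f} A "
      f"(expect ~4.1)")
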