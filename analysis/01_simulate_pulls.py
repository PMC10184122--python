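#!/usr/bin/env python
"""Generate paired steered-pull work ensembles: glue-shielded vs exposed bond.

Runs the three-stage protocol (restrained equilibration, approach to 2.5 Å,
stiff-spring pull to 5.0 Å at 0.5 Å/ns) 100 times per condition on the model
H-bond landscape, with water entry blocked (shielding = 1, the ternary-complex
condition) or free (shielding = 0, the binary complex).  Writes coarsened work
profiles under results/ for the downstream PMF step.

Finding: with water blocked, every pull pays close to the full reversible
rupture work; with water free, trajectories where a water caps the opening
acceptor come out several kcal/mol cheaper, and the work distribution grows a
low tail.
"""

import sys
import time
from pathlib import Path

from glueforce.io import write_work_profiles
from glueforce.landscape import LandscapeModel
from glueforce.simulate import PullingProtocol, generate_work_ensemble

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2023


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    protocol = PullingProtocol(rate=0.5, n_traj=100, seed=SEED)
    for shielding, tag in ((1.0, "shielded"), (0.0, "unshielded")):
        t0 = time.time()
        model = LandscapeModel(shielding=shielding)
        ensemble = generate_work_ensemble(model, protocol)
        out = RESULTS / f"work_{tag}.tsv"
        write_work_profiles(
            out, ensemble, meta={"seed": SEED, "shielding": shielding}, coarsen=100
        )
        w_end = ensemble.works[:, -1]
        print(
            f"{tag:11s}: N={ensemble.n_traj}  W(5.0) mean {w_end.mean():6.3f}  "
            f"min {w_end.min():6.3f}  max {w_end.max():6.3f} kcal/mol  "
            f"-> {out.name}  [{time.time() - t0:.0f} s]"
        )
    return 0


if __name__ == "__main__":
    sys.exit(main())
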