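#!/usr/bin/env python
"""Saturation-binding fits and the ΣPMF vs ΔG_bin regression path.

The published titration data behind the per-complex K_D values are
supplementary material not bundled here, so this driver demonstrates the
identical computational path on synthetic affinities: one-site titration
curves with 2% signal noise are fitted with the Y_max of the reference
complex held fixed, K_D is transformed to ΔG_bin = RT ln K_D, and the
resulting free energies are regressed against the recomputed per-complex
ΣPMF totals.

Finding: K_D is recovered within a few percent at 2% noise, and the
synthetic-affinity regression machinery reports slope/intercept/R² that match
a hand-computed Pearson calculation.
"""

import sys
from pathlib import Path

import pandas as pd

from glueforce.affinity import fit_saturation, kd_to_deltaG, synthetic_titration
from glueforce.energetics import (
    build_energetics_table,
    correlate_with_affinity,
    load_reference_endpoints,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2023

# synthetic per-complex dissociation constants (M), tighter for more robust
# H-bond networks; stand-ins for the unbundled supplementary measurements
TRUE_KD = {
    "wt_LEN": 2e-8,
    "wt_noLEN": 3e-6,
    "I35G": 8e-8,
    "I37E": 1.5e-7,
    "N39G": 9e-7,
    "G40N": 2.5e-6,
}
Y_MAX = 2.0  # saturated signal of the reference complex, fixed in every fit


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    table = build_energetics_table(load_reference_endpoints(), reference="wt_LEN")
    totals = table.totals["sum_pmf_kcal_mol"]
    rows = []
    for i, (label, kd) in enumerate(TRUE_KD.items()):
        curve = synthetic_titration(
            k_d=kd, y_max=Y_MAX, noise_sd=0.02 * Y_MAX, seed=SEED + i, label=label
        )
        fit = fit_saturation(curve, y_max=Y_MAX)
        rows.append(
            {
                "complex": label,
                "true_kd_molar": kd,
                "fit_kd_molar": fit.k_d,
                "dg_bin_kcal_mol": kd_to_deltaG(fit.k_d),
                "sum_pmf_kcal_mol": totals[label],
            }
        )
        print(
            f"{label:9s}: K_D fit {fit.k_d:9.3e} M (true {kd:9.3e})  "
            f"ΔG_bin {rows[-1]['dg_bin_kcal_mol']:7.2f} kcal/mol"
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "affinity_fits.tsv", sep="\t", index=False)
    result = correlate_with_affinity(
        frame.set_index("complex")["sum_pmf_kcal_mol"],
        frame.set_index("complex")["dg_bin_kcal_mol"],
    )
    print(
        f"\nΣPMF vs ΔG_bin (synthetic affinities): slope {result.slope:.3f} "
        f"kcal/kcal, intercept {result.intercept:.3f}, R² {result.r_squared:.3f}, "
        f"n {result.n}"
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
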