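# glueforce

Hydrogen-bond robustness analysis for molecular-glue ternary complexes.

Molecular glues such as lenalidomide stabilize protein–protein complexes — in
the flagship case, the E3-ligase substrate receptor CRBN and the kinase CK1α —
without adding any remarkable direct interactions.  The working explanation is
*hydrophobic shielding*: the glue blocks water from the interfacial
protein–protein hydrogen bonds, and because incoming waters catalyze H-bond
rupture (they cap the acceptor carbonyl as the bond opens), a dry H-bond is a
robust H-bond.  Bond robustness is measured by steered pulling: drag the
donor–acceptor distance from 2.5 to 5.0 Å with a stiff spring, record the
nonequilibrium work `W_i` over `N` repeats, and Boltzmann-average via the
Jarzynski equality

    PMF(λ) = −RT ln (1/N) Σᵢ exp(−Wᵢ(λ)/RT)

whose endpoint at 5.0 Å is the rupture free energy, with errors from
bootstrap resampling of the work profiles.  Summed over the three interface
bonds, ΣPMF tracks the measured stability of the complex: ΔG_bin = RT ln K_D
from one-site saturation fits of titration data.

This package implements that entire analysis chain in a controlled
one-dimensional setting:

* `glueforce.landscape` / `glueforce.simulate` — a Brownian-dynamics engine
  over a model H-bond landscape with an explicit two-state water-occupancy
  coordinate and a shielding parameter (1 = glue blocks water entry),
  reproducing the three-stage protocol: flat-bottom restrained equilibration
  (2.5–3.5 Å, 60 kcal·mol⁻¹·Å⁻²), 1 ns approach to 2.5 Å, and a 0.5 Å/ns
  stiff-spring pull (k = 500 kcal·mol⁻¹·Å⁻², work recorded every 0.0005 Å);
  plus synthetic solvent-shell frames with a tunable exclusion zone.
* `glueforce.pmf` — pointwise Jarzynski estimation, trajectory-level
  bootstrap errors, subsampling convergence, second-cumulant cross-check.
* `glueforce.solvation` — water RDF (0–10 Å, 0.1 Å bins, per-frame bulk
  normalization), shielding contrast, distance-series co-dependence,
  centre-of-mass distances.
* `glueforce.energetics` — per-complex ΣPMF with linear error propagation,
  relative values against the wild-type ternary complex, printed-total
  consistency flags, and the ΣPMF vs ΔG_bin regression.  The published
  per-bond endpoints for the six CRBN–CK1α variants ship with the package.
* `glueforce.affinity` — one-site saturation K_D fits (optionally with a
  constrained maximum signal) and ΔG_bin = RT ln K_D.
* `glueforce.io` / `config` / `pipeline` / `cli` — TSV/XYZ formats with
  provenance headers, flat-text run configs, a deterministic end-to-end
  driver, and the `glueforce` command-line tool.

## Worked example

The numbered drivers under `analysis/` run the study end to end and write
their tables under `results/`.  The shielding experiment
(`analysis/01_simulate_pulls.py` then `02_estimate_pmf.py`) pulls the same
model bond 100 times with water blocked and 100 times with water free:

```text
$ python analysis/01_simulate_pulls.py
shielded   : N=100  W(5.0) mean  5.412  min  5.191  max  5.647 kcal/mol  -> work_shielded.tsv
unshielded : N=100  W(5.0) mean  3.045  min  1.541  max  5.425 kcal/mol  -> work_unshielded.tsv

$ python analysis/02_estimate_pmf.py
reversible work (quadrature, water blocked): 5.414 kcal/mol
shielded   : endpoint PMF  5.405 ± 0.012 kcal/mol  (max subsampling drift 0.014)
unshielded : endpoint PMF  2.507 ± 0.069 kcal/mol  (max subsampling drift 0.117)
```

Read: with water blocked the Jarzynski endpoint reproduces the exact
reversible rupture work (5.41 kcal/mol) to ~0.01 kcal/mol; letting water in
cuts the apparent rupture cost by ~2.9 kcal/mol and inflates both the work
spread and the finite-sample drift — the signature of water-catalyzed
rupture.  `analysis/03_solvation_rdf.py` shows the matching solvation
picture (near-probe RDF exactly 0 under full shielding vs ~1 exposed, and a
narrower equilibrium H-bond length distribution when shielded), and
`analysis/04_energetics_table.py` re-adds the published per-bond endpoints:

```text
per-complex ΣPMF (recomputed, kcal/mol):
          sum_pmf_kcal_mol  sd_kcal_mol  rel_kcal_mol  rel_sd_kcal_mol
wt_LEN                28.0          0.7           0.0              1.4
wt_noLEN              12.5          1.1         -15.5              1.8
I35G                  24.5          0.7          -3.5              1.4
I37E                  22.7          0.8          -5.3              1.5
N39G                  17.0          1.1         -11.0              1.8
G40N                  11.6          2.5         -16.4              3.2

flagged printed-total mismatches: wt_noLEN, N39G, G40N
```

i.e. removing the glue costs ~15.6 kcal/mol of cumulative H-bond robustness,
and three published totals disagree with their own components at one decimal
— flagged, never silently corrected.  `analysis/05_affinity_correlation.py`
demonstrates the K_D → ΔG_bin → regression path on clearly-labelled synthetic
affinities (the measured titrations are supplementary material not bundled
here).

The same steps are available as shell commands (`glueforce simulate-pull`,
`pmf`, `rdf`, `energetics`, `fit-kd`, `correlate`, `run`); see
`glueforce --help`.

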