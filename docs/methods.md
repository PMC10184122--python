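# Methods

`glueforce` studies one question in a minimal, fully controlled setting: how
does blocking water access to a protein–protein hydrogen bond change the free
energy needed to break it?  The package provides (i) a one-dimensional
Brownian-dynamics model of H-bond rupture with explicit water catalysis, (ii)
nonequilibrium work analysis via the Jarzynski equality with bootstrap errors,
(iii) solvation-shell (RDF) analysis, (iv) the per-complex energetics
arithmetic used to aggregate per-bond rupture free energies, and (v)
saturation-binding K_D fits and their conversion to binding free energies.

## The model landscape

The donor–acceptor distance x (Å) of a single interfacial H-bond moves on

    U(x, n) = U0(x) − n · c · g(x)

* **Bare bond** — a Morse well `U0(x) = D[(1 − e^{−a(x−x_eq)})² − 1]` with
  depth `D = 10` kcal/mol at `x_eq = 2.9` Å and range `a = 0.9` Å⁻¹.  The
  depth is deliberately at the strong end for an H-bond because it stands for
  the bond *plus* its local environment (packing, cooperative neighbours);
  what matters downstream is only that the rupture work is several kcal/mol,
  comfortably above the thermal and bootstrap noise.  The soft range parameter
  keeps the compressed start of the pull (2.5 Å) inside the well, so the
  pull's endpoint free-energy difference is a meaningful "rupture cost".
* **Water occupancy** — a two-state Markov coordinate n ∈ {0, 1}.  When a
  water occupies the interface (n = 1) the landscape is lowered by
  `c·g(x)` with `c = 4.5` kcal/mol and `g` a logistic switch centred at
  `x_c = 3.2` Å with softness `w = 0.15` Å.  The switch form encodes the
  mechanism this package exists to probe: an incoming water hydrogen-bonds
  the acceptor that the protein partner is leaving, so it stabilizes the
  *opening and open* interface (g → 1), not a narrow window around some
  transition distance.  A bump-shaped weight that vanishes on both ends of
  the pull provably cannot produce a shielding effect in this setting: each
  entry/exit cycle then contributes `c·(g_entry − g_exit)` to the work, and
  with entries gated by interface openness that contribution is positive —
  water would *raise* the measured rupture work, inverting the physics.
* **Shielding** — the bound molecular glue is a single dimensionless
  parameter s ∈ [0, 1] multiplying the water entry rate by (1 − s).  Entry is
  additionally weighted by g(x) (water cannot reach a closed interface);
  the exit rate is constant.  Defaults: entry 8 ns⁻¹ (at g = 1, s = 0), exit
  2 ns⁻¹ — fast enough that a 5 ns pull sees entry events, slow enough that a
  capping water survives the passage of the rupture region.  Note the gated
  jump process deliberately breaks detailed balance (each catalytic cycle
  extracts energy from the bond region); it is a model of an open system in
  which bulk water is an energy reservoir.  All *frozen-occupancy* analyses
  (s = 1 starting from n = 0, or entry/exit rates zero) are strict
  equilibrium systems for which Boltzmann statistics and reversible-work
  oracles hold exactly; these are the configurations used for quantitative
  parameter-recovery checks.

## Simulation protocol

The integrator is overdamped (Brownian) Euler–Maruyama:
`dx = −μ U'(x,n) dt + √(2 μ k_B T dt) ξ` with mobility `μ = D_c / (k_B·298 K)`
and diffusion coefficient `D_c = 100` Å²/ns.  `k_B = 0.0019872`
kcal·mol⁻¹·K⁻¹ everywhere.  Temperature enters only the noise amplitude, so
T → 0 yields deterministic descent with unchanged friction — the limit used
by several oracle tests.  Time steps are chosen against the stiffest force
constant in play (`k·dt·D_c/k_BT < 0.1`): 1e-6 ns during pulls (guide spring
k = 500 kcal·mol⁻¹·Å⁻²) and 4e-6 ns during restrained equilibration.  A step
moving the particle more than 0.5 Å raises an instability warning.

Each pulled trajectory runs three stages, seeded `seed + 16·i` per trajectory
with consecutive stage sub-seeds, bit-reproducible end to end:

1. **Restrained equilibration** — flat-bottom window 2.5–3.5 Å, force
   constant 60 kcal·mol⁻¹·Å⁻² (energy `k(x−bound)²` outside the window, the
   restrained-MD convention).  Stand-alone equilibrium analyses default to
   10 ns × 100 replicas; inside ensemble generation the per-trajectory
   equilibration is shortened to 2 ns, which is ~5 decades longer than the
   position relaxation time of this 1-D model (~1e-3 ns) and therefore fully
   decorrelates replicas at a fraction of the cost.
2. **Approach** — a 1 ns guided pull bringing x to the start distance 2.5 Å.
   If the arrival snapshot happens to sit > 0.1 Å from the start (a ≥3σ
   thermal fluctuation under the stiff spring), a 0.01 ns static-guide settle
   is repeated; this only redraws the arrival state.
3. **Pull** — guide centre moving 2.5 → 5.0 Å at 0.5 Å/ns, spring k = 500
   kcal·mol⁻¹·Å⁻² (stiff-spring regime: lag beyond 0.2 Å flags the profile),
   work accumulated as `dW = k·v·(λ − x)·dt` and recorded every 0.0005 Å
   (5001 grid points).  The default ensemble is 100 trajectories and runs in
   about a minute per condition on one CPU.

## Free-energy estimation

The rupture PMF at each grid distance is the Jarzynski average
`ΔF = −RT ln⟨e^{−W/RT}⟩_N`, evaluated with a log-sum-exp shift.  Errors are
the sd over 10 bootstrap resamples of *whole trajectories* (resampling whole
pulls preserves the correlation of work values along a profile; the
pointwise sd of those trajectory-level resamples is what is reported at each
distance).  n_boot = 10 is kept as the default for comparability with the
bundled published table, but it is statistically thin and configurable.
Convergence is assessed by subsampling (default sizes 10/25/50/75/100)
with bootstrap errors per size.  Two facts about the estimator shape the
tests: it is bounded between min(W) and mean(W) (Jensen), and its finite-N
bias is strictly upward, so endpoint estimates drift *down* toward the true
ΔF as the ensemble grows.  A second-cumulant estimate `mean(W) −
var(W)/2RT` is provided as a cross-check for near-Gaussian work.

The quantitative oracle for the frozen-occupancy landscape is the exact
stiff-spring reversible work `F(λ=5.0) − F(λ=2.5)` with
`F(λ) = −RT ln ∫ e^{−β[U(x,n) + ½k(x−λ)²]} dx` by quadrature.  This is
preferred over the T → 0 shorthand `U0(5) − U0(x*)` because it is exact at
finite temperature and does not spend tolerance on the start-state spring
energy (~0.1–0.4 kcal/mol here).  At the default rate the 100-pull shielded
ensemble reproduces it to ~0.01 kcal/mol — the protocol is essentially
quasi-static for this landscape, which is the point: the several-kcal/mol
shielded/unshielded endpoint difference is carried by water catalysis, not
by dissipation artifacts.

## Solvation analysis

Synthetic solvent frames place water oxygens uniformly in a spherical box
(radius 12 Å, bulk density 0.0334 Å⁻³) around a probe at the origin; the
bound glue is modelled as an exclusion zone (default radius 5 Å) in which
particles are removed with probability equal to the shielding.  The RDF is
binned 0–10 Å at 0.1 Å with exact spherical-shell volumes and normalized per
frame by that frame's own particle count over the box volume — this
convention makes g → 1 exact for the uniform generator by construction, which
is what the normalization tests assert.  The shielding contrast is the
difference of mean g below 5 Å between two profiles (first and second
hydration shells).  Co-dependence between bonds is quantified as the Pearson
correlation of their distance series — a pragmatic proxy; constant series
are reported as 0 with a warning rather than NaN.

What the generator does *not* emulate: solvent structure (no layering, no
first-shell peak), orientation, or coupling between the RDF frames and the
1-D pulling coordinate.  Passing RDF tests therefore validate the estimator's
normalization and the exclusion-zone bookkeeping, not any claim about real
water structure.

## Energetics aggregation

Per-complex totals are plain sums of the three per-bond endpoint PMFs
(justified when bond ruptures are not co-dependent).  Error propagation is
**linear** — sd values add — because that is the only rule consistent with
the published totals this package re-derives (e.g. 0.3+0.3+0.1 = 0.7;
1.1+0.7 = 1.8 on the relative row); quadrature addition is available behind a
flag.  Printed totals are re-added from their components; disagreements at
one decimal are flagged and the recomputed values are authoritative — three
of the six bundled columns disagree (12.4 vs 12.5, 16.9 vs 17.0, 12.4 vs
11.6), which the package surfaces rather than resolves.

## Binding affinity

One-site saturation `y = Y_max·c/(K_D + c)` is fitted by multi-start
least squares (log-spaced K_D starts, dense log-grid fallback on
non-convergence), optionally with Y_max fixed to the reference complex's
saturated signal; the K_D standard error comes from the fit's local
curvature.  ΔG_bin = RT ln(K_D/1 M) at a 1 M standard state (the reference
concentration is a convention; nothing downstream depends on it because only
differences across complexes matter).  At 2% signal noise over 12 log-spaced
points spanning K_D/100–100·K_D, the median K_D recovery error is a few
percent.

## Problem sizes and limitations

Default study sizes — 100 pulls per condition, 2 ns per-pull equilibration,
20 ns equilibrium replicas, 500 RDF frames, 100 titration curves — were
chosen so the full analysis reruns from scratch in a few minutes on one CPU
while keeping every statistical margin (bootstrap sd, Poisson bands, TV
distance) several-fold below its test threshold.

Known limitations: the landscape is one-dimensional, so inter-bond coupling
cannot be represented (per-bond independence is an input assumption, not a
result); the water coordinate is a single two-state site with
detailed-balance-breaking gated entry — adequate for the mechanism, not for
kinetics of real hydration shells; absolute PMF magnitudes are set by model
parameters and are not comparable to all-atom values, only the shielded vs
unshielded *contrast* and the estimator properties are meaningful; and the
bundled affinity demonstration uses synthetic K_D values (clearly labelled),
since the measured titrations are not distributed with the package.
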