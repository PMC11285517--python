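# Methods

## Model

The network is a two-gene mutual-repression motif with fully explicit
molecular bookkeeping. For each gene *i* (with *j* the other gene), the
elementary processes and default rate constants (all s⁻¹; association
rates per molecule at unit volume) are:

| process | reaction | rate (default) |
|---|---|---|
| transcription | pro_i → pro_i + rna_i | λ₂ (0.0067) |
| translation | rna_i → rna_i + p_i | λ₃ (0.0474) |
| dimerization / dissociation | 2 p_i ⇌ pp_i | ca₁ / cd₁ (0.0023 / 0.00023) |
| regulator–promoter binding / unbinding | pro_j + pp_i ⇌ propp_i | ca₂ / cd₂ (0.1038 / 1.04) |
| mRNA degradation | rna_i → ∅ | γ₂ (0.00023) |
| protein degradation | p_i → ∅ | γ₃ (0.00077) |
| oligomer degradation | pp_i → ∅ | γ₄ (0.00058) |

Transcription is driven by a constitutive transcription factor held at
unit level (z_i ≡ 1, folded into the transcription rate, not a dynamic
species). Each gene starts with exactly one promoter copy, giving the
conservation laws pro₁ + propp₂ = 1 and pro₂ + propp₁ = 1 (promoter 1
is either free or occupied by gene 2's regulator).

**Oligomer-order variants.** The regulator that binds the opposing
promoter is the oligomer of order *n* ∈ {1, 2, 3, 4}. Assembly is
stepwise (P + P ⇌ PP, P + PP ⇌ PPP, P + PPP ⇌ PPPP) with every step at
ca₁/cd₁ and every free oligomer degraded at γ₄; only the top oligomer
binds the promoter. *n* = 1 has no oligomer species at all. *n* plays
the microscopic role of a Hill coefficient: it sets the nonlinearity of
the repressive interaction.

**ATP coupling.** Energy status is a dimensionless multiplier `atp`
applied linearly to rates selected by `atp_mode`: `both` (default)
scales λ₂ and λ₃; `transcription` / `translation` scale one of them;
`both_plus_degradation` additionally scales γ₃. The linear scaling is a
deliberate approximation to the centre of the sigmoidal dependence of
expression rates on ATP concentration. In the degradation-coupled mode
only the monomer degradation rate γ₃ is scaled — mRNA and oligomer
turnover (γ₂, γ₄) are dominated by nucleases and complex disassembly
rather than ATP-dependent proteolysis, so they are left unscaled; this
is a modelling choice, and either behaviour can be obtained by scaling
those rates explicitly.

**Bound complexes are protected.** Degradation channels act only on
free species; a promoter-bound oligomer is neither degraded nor
dissociated except through the cd₂ unbinding channel. Promoter
conservation is therefore exact by construction.

## Deterministic / stochastic correspondence

The model is compiled once into a reaction list and shared by both
engines, at unit volume so concentrations and copy numbers share units.
Deterministic mass-action flux of a reaction is k·∏(reactant
concentrations), giving e.g. −2·ca₁·p² in the monomer equation and
+ca₁·p² in the dimer equation. The matching stochastic propensity for
homodimerization is ca₁·x·(x−1) — **not** halved — so the large-count
drift of the jump process reproduces the ODE coefficients exactly;
higher assembly steps are ordinary hetero-bimolecular channels (k·x·y).
A property test asserts the drift/RHS agreement at large counts, and
the linear (no-feedback) submodel is checked against the ODE ensemble
mean and against an analytic pure-death expectation.

## Numerical integration and the false-convergence trap

The system is awkward: from most initial conditions it collapses
quickly (minutes to hours of model time) onto a slow manifold and then
drifts for 10⁵–10⁷ s, sometimes non-monotonically with coincident
turning points in all variables. An instantaneous-derivative or
short-horizon stationarity test stops at this "false convergence" long
before the true attractor.

All solvers therefore use a **windowed** convergence criterion: the run
is converged only when the largest per-species excursion (max − min)
across an entire trailing window of length `window` falls below `tol`.
Defaults: window = 10⁵ s, tol = 10⁻⁶ molecules, hard cap t_max = 10⁷ s.
The window length is two orders of magnitude above the slowest default
relaxation time (1/γ₂ ≈ 4.3 × 10³ s), and a regression test verifies
that the default window lands on the same attractor as a 10× longer
window in the slow γ₃-scaled regime. Runs that reach t_max unconverged
are returned flagged and are excluded from attractor clustering, never
silently treated as attractors.

Three schemes share this criterion:

* **Forward Euler** (reference), default dt = 0.01 s — resolving the
  fastest default process, promoter unbinding at cd₂ = 1.04 s⁻¹.
  Negative overshoots are clipped to zero and counted; any state beyond
  10¹² aborts with a step-size diagnostic. In strongly-expressing
  regimes (high ATP) the promoter-binding rate ca₂·pp can reach
  10²–10³ s⁻¹ and a fixed explicit step becomes unstable; the abort is
  deliberate rather than silent error accumulation.
* **Classical RK4** at the same step, used as the independent
  cross-check (`cross_check` reports terminal-state deviations; the
  suite requires < 1% agreement in the protein coordinates and 10⁻⁶
  agreement on an analytically solvable pure-decay submodel).
* **LSODA** (adaptive stiff/non-stiff, rtol 10⁻⁹ / atol 10⁻¹²),
  continued across windows without restarts. This is the workhorse for
  basin mapping: it takes large steps on the slow manifold while the
  windowed criterion still guards against premature convergence
  declarations, and it remains stable in the high-ATP regimes where
  fixed explicit steps fail.

## Stochastic simulation and switching statistics

Gillespie's direct method (one uniform draw for the waiting time, one
for the channel) over the compiled channels; with at most ~30 channels
there is no benefit to next-reaction machinery. The state is recorded
on a uniform time grid (default 100 s; 200 s for the long switching
ensembles) — exact, since the state is constant between events — which
bounds memory on 10⁶–10⁷ s trajectories. If total propensity reaches
zero the absorbing state is flagged and frozen to the end of the grid.

**Switching times.** The dominant protein is sign(p₁ − p₂) with a
symmetric hysteresis band: a switch is recorded only when the
previously dominant protein *trails* by more than `threshold` (default
10 molecules — large against single-molecule chatter at ties, small
against the tens-to-hundreds separation of dominance states). Dwell
intervals run from trajectory start (or the previous switch) to each
switch; the final censored interval is dropped. Switching experiments
start from the standard initial condition with a discarded burn-in
(default 10⁵ s). Summaries report the count, median, a log₁₀ histogram,
and the short-time transient mass (fraction of dwells below 10³ s)
that makes the distribution bimodal when trajectories chatter around a
switch.

## Attractor basins, clustering and scans

Basin maps relax every point of a grid of initial protein levels
(default ip₁, ip₂ ∈ [0, 50], 21 × 21 points — spanning well below and
above the default balanced state near p ≈ 6) with all other species at
the standard initial condition (optionally overridden initial mRNA).
Terminal (p₁, p₂) coordinates of converged points are clustered by
single-linkage agglomeration with a Euclidean threshold of 1.0 molecule
— far below the inter-attractor separations (≈ 5–15 molecules) in the
multistable regimes, far above solver noise (≤ 10⁻⁴). Cluster labels
are relabelled by sorted centroid so they are stable under input
permutation; a cluster is *asymmetric* when its centroid has
|p₁ − p₂| > tol. Because the network is symmetric under exchange of
gene labels, the terminal state of (b, a) is the coordinate swap of
that of (a, b); basin maps exploit this and integrate only one
triangle of the grid (disabled automatically when asymmetric initial
mRNA breaks the symmetry, and verified against the full computation in
the suite).

Parameter scans scale one or two of the nine rates by given factors
(defaults: {10⁻², 10⁻¹, 1, 10, 10²} singly; all 36 unordered pairs over
{1/10, 10} or {1/2, 2} pairwise) and record attractor counts and
coordinates per scan member. ATP bifurcation scans sweep the ATP
multiplier (default 15 points, geometric, 0.2–5) and additionally
record the separation between the asymmetric centroids and the
central-basin width (fraction of converged grid points in a symmetric
cluster); a pitchfork appears as the cluster count stepping 1 → 3 at a
finite ATP threshold with separation growing above it.

## Problem sizes used in the tests and acceptance script

Deterministic scans run at the standard 21 × 21 grid. ATP bifurcation
sweeps use 9 × 9 grids over six ATP values per regime, and the
oligomer-order comparison uses 7 × 7 grids — the attractor counts in
these regimes are grid-robust well below that resolution. Stochastic
calibrations use 2000 pure-death replicates and 200 linear-submodel
replicates; switching ensembles pool 20 seeded 5 × 10⁶ s trajectories
per ATP level. The γ₃ re-entrance scan extends one decade above the
standard factor set (to 10³) because the return to monostability under
fast turnover lies above 10².

## Known limitations

* Explicit fixed-step schemes are unstable in strongly-expressing
  regimes (high ATP, high λ₂/λ₃); use the adaptive scheme there. The
  instability is detected and reported, not worked around.
* Attractor detection is grid-based: basins narrower than the grid
  spacing, or attractors outside the sampled initial-condition range,
  are not found; there is no continuation or eigenvalue stability
  analysis, and basin boundaries are resolved only to grid resolution.
* Switching statistics are computed on the sampled series; dominance
  excursions shorter than the sampling interval are invisible. Dwell
  medians from finite trajectories are right-censoring-biased when
  dwells approach the trajectory length.
* The variant in which dimerization occurs on the DNA-bound monomer is
  not included; user-defined reaction lists can be compiled through the
  same machinery (`ModelSpec` arrays) as a plug-in point.
* Heterodimers, more than two genes, translation delay, and SBML
  import/export are out of scope.
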