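# Methods

## Models

### Minimal incorporation scheme

Single-nucleotide incorporation by a B-family replicative polymerase is
modelled as the reversible four-step mechanism

    DNA_n + Pol ⇌(k1/k−1) DNA_n·Pol ⇌(k2/k−2) DNA_n·Pol·dNTP
    ⇌(k3/k−3) DNA_n·Pol*·dNTP ⇌(k4/k−4) DNA_{n+1}·Pol*·PPi

with second-order k1, k2 (nM⁻¹s⁻¹) and first-order k3 (open→closed
conformational change) and k4 (chemistry). The simulator integrates the
mass-action ODEs with LSODA (stiff-capable, relative tolerance 1e-8,
absolute 1e-12): the rates in these assays span ~1–500 s⁻¹ first order plus
second-order binding, so stiffness is routine. dNTP is held constant
(pseudo-first-order) by default because burst assays use saturating dNTP
(250 μM against tens of nM complex); a flag enables explicit depletion.
DNA and polymerase totals are conserved by construction and verified to
1e-9 relative in tests. The observed burst rate approaches min(k3, k4)
when the two differ by ≥100× and earlier steps are pre-equilibrated —
the regime used to argue which step a clamp accelerates.

The second polymerase molecule of the 2:1 polymerase:DNA complex is given
no kinetic role: burst experiments are analyzed in the saturated regime
where the complex acts as a single catalytic unit. Assay temperature
(30 °C vs 12 °C) is a label on parameter sets, not a model — no activation
energies are available to interpolate between them.

### Processive-extension chain

Multi-nucleotide extension over an n-residue homopolymeric run is a chain
of identical irreversible steps at `k_step` (s⁻¹ per nucleotide; nucleotide
incorporation and translocation folded together, since the two cannot be
separated by these observables) competing with polymerase dissociation at
`k_off`. With a polymerase trap (heparin) active, dissociation is absorbing:
the DNA is stranded at its current length, and the model tracks that stalled
mass per length so distributions always sum to 1. Without the trap,
rebinding proceeds at `rebind_rate × free_pol_nM` (pseudo-first order; the
free-polymerase concentration must be supplied because the chain model is
per-molecule and linear).

For `k_off = 0` the occupancy has the censored-Poisson closed form
`P(j) = (k_step t)^j e^{−k_step t}/j!` for `j < n` with all run-off mass
accumulated at the full length n (run-off censoring matches how a finished
template run accumulates full-length product on a gel). Otherwise the chain
ODE (2n+1 states) is integrated at tolerance 1e-10. A per-molecule
stochastic simulator (exact exponential jumps, seeded) serves as the
independent Monte-Carlo oracle for both.

Unextended-primer survival among bound molecules is exactly
`e^{−(k_step+k_off)t}` (competing exponentials), which is why the primer
band gives a processivity-independent minimal catalytic rate. The *band*
fraction additionally contains molecules that dissociated before the first
incorporation; as t→∞ that stalled mass is `k_off/(k_step+k_off)`. The
primer-disappearance fit therefore uses `A(1 − e^{−kt})` with free
amplitude: the amplitude absorbs the stalled mass and the rate estimates
`k_step + k_off` without bias (it reduces to `k_step` when `k_off = 0`).

### Burst-phase fitting

Time courses are fit by bounded nonlinear least squares
(`scipy.optimize.least_squares`, amplitude in [0,1], rates ≥ 0). Initial
guesses: the rate from the reciprocal of the time to half-maximal signal,
the amplitude from the signal at three times that point — robust across the
three-decade rate range the assays span. Points are unweighted by default
(replicate errors are rarely available for quench-flow data); a per-point σ
column is honored when present. Phases are labelled by magnitude so
`k_fast ≥ k_slow` always holds. When a two-phase fit converges with
`k_fast/k_slow < 3` the phases are not experimentally resolvable; the
one-phase fit is reported with an explicit flag rather than returning two
ill-determined rates. A slow rate pinned at the zero bound is flagged, not
silently accepted. Standard errors come from the Jacobian at the optimum.

With `fixed_k_fast`, the fast rate determined at saturating enzyme is held
and only the amplitude and slow rate are refit; the amplitude is then the
fraction of DNA in the preformed productive complex, which is how
subsaturating burst amplitudes are converted into bound-DNA fractions.

### Two-site equilibrium and stoichiometry

Sequential macroscopic binding (`D + E ⇌ DE` at K1, `DE + E ⇌ DE₂` at K2)
is used rather than site-specific microscopic constants: the available
observables cannot distinguish DNA-end binding of a second polymerase from
protein-mediated dimerization, and the macroscopic model is agnostic to
that. Free enzyme is the unique root of the enzyme mass balance (a cubic),
bracketed on [0, E_total] and solved by Brent's method, so mass balances
hold to ~1e-10 even at sub-pM constants. Note that equal macroscopic
constants make the 1:1 point a mixed D/DE/DE₂ population (mass action
enforces DE² = D·DE₂·K2/K1); complete first-site filling before the second
requires K1 ≪ K2.

Predicted anisotropy is the fluorescence-weighted average of species
anisotropies (weights ∝ mole fraction × relative yield), the physically
correct combination when binding quenches the label; a mole-fraction mode
exists for comparison. Relative intensity is the yield-weighted species
average.

Segmented fits are continuous piecewise-linear least squares; breakpoints
are profiled over every midpoint between consecutive titration points
(resolution-matched to the data) and then refined by Nelder–Mead. The
stoichiometry estimate is the final breakpoint over the DNA concentration.
Breakpoints at the range edge, or fits no better than one fewer segment
(RSS reduction ≤20%, or a simpler model already explaining all but a
millionth of the variance), are flagged unresolved. Because quench
weighting makes the anisotropy channel a ratio of functions linear in bound
enzyme, its tight-binding curve is slightly convex and a two-segment fit
overestimates the breakpoint by roughly the quench depth times a small
factor (+2% at 10% quench, +8% at 40%, measured on noiseless curves); the
intensity channel with equal per-site quench is exactly piecewise linear.
`stoichiometry_from_titration` therefore averages the two channels' resolved
breakpoints, mirroring how stoichiometry is read off titrations that report
both observables.

## Synthetic data

The generators are pure functions of (truth, grid, σ, seed) and emulate the
study conditions end to end:

- **Burst time courses** — fraction extended on 25 log-spaced quench times,
  1 ms–2 s at 30 °C or 2 ms–1 s at 12 °C, from the two-exponential model
  (or the full scheme ODE), plus additive Gaussian noise σ = 0.02 clipped
  to [−0.05, 1.05]. σ = 0.02 is a conventional quench-flow quantification
  error; the true experimental noise is unpublished, so every recovery
  report states the σ used.
- **Titrations** — 16-point linear enzyme grids from 0 to 8× the DNA
  concentration (saturation at 2× plus margin, matching 0–400 nM ranges
  used at 50 nM DNA), additive Gaussian σ = 0.002 on both channels.
  Signal levels are generator conventions chosen as realistic
  fluorescein-label values: anisotropy 0.06 (free DNA), 0.13 (1:1), 0.20
  (2:1); relative yields 0.9 and 0.8 (20% quench at saturation, equal
  per-site decrements). Tight-binding truth uses K1 = K2 = 0.01 nM.
- **Gel lanes** — 12 log-spaced quench times (default 1–100 ms) from the
  chain occupancy (or the stochastic simulator at finite molecule count),
  scaled to an arbitrary lane intensity with multiplicative log-normal band
  noise (σ = 0.05 log-scale): phosphorimager error grows with band
  intensity, unlike the additive error of fraction-type observables.

What the generators do *not* emulate: gel-resolution blurring between
adjacent bands, baseline/background subtraction, sequence-dependent step
rates, pipetting-level concentration errors, and instrument drift.
Recovery tests therefore demonstrate estimator correctness and precision
under the stated noise model, not robustness to every artifact of real
gels and fluorimeters.

## Recovery experiments and problem sizes

Each headline rate is reproduced as the ground truth of a seeded recovery
experiment: 20 replicate data sets per condition, refit from scratch, with
the median estimate reported (median/IQR summaries are robust to the
occasional skewed replicate fit). Replicate seeds derive from one master
seed via a PCG64 stream. The defaults (20 replicates, 25-point grids,
20 000-molecule stochastic checks) keep any single experiment under a few
seconds while leaving Monte-Carlo error well below the tolerances of
interest for rates with well-separated phases.

One protocol-level caveat, measured by Monte Carlo: for the slowest
condition (6 s⁻¹ fast phase with amplitude 0.5 over a 1.5 s⁻¹ slow phase —
a rate ratio of only 4), the two-exponential refit is unbiased but noisy
enough that the 20-replicate median itself has ~7% standard deviation; the
one-phase saturating protocol recovers the same rate with ~0.5% median
scatter. Rate *ratios* quoted from the panel (≈30-fold wild-type clamp
stimulation, ≈9-fold for the partially defective mutant clamp) are computed
from recovered medians, not asserted.

## Numerical choices and degenerate inputs

- Integrators: LSODA, rtol 1e-8/atol 1e-12 (scheme), rtol 1e-10/atol 1e-14
  (chain); failures raise a numerical error carrying the offending
  parameters.
- Fits reject constant signals, too few points (5 for one phase, 7 for
  two), and all-primer lane series as contract errors rather than
  returning meaningless parameters.
- Poisson-mode ties: at k·t exactly integer the masses at k·t−1 and k·t are
  equal; the modal length breaks ties toward the shorter product and sets a
  tie flag.
- Peak normalization is idempotent and scale invariant; all-zero lanes are
  rejected at construction.

## Known limitations

- The eight scheme rate constants are not jointly identifiable from burst
  observables; no global scheme fitting is provided by design.
- Absolute K1/K2 cannot be estimated from tight-binding titrations (only
  bounds); the package estimates stoichiometry, not affinity, in that
  regime.
- The chain model assumes identical, sequence-independent step rates and
  folds translocation into k_step; real homopolymer runs approximate this,
  arbitrary sequences do not.
- Exonuclease proofreading is absent (the assays this emulates use an
  exonuclease-dead polymerase).
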