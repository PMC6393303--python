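# prekin

Pre-steady-state kinetics of clamp-stimulated DNA polymerases: burst-phase
fitting of quench-flow time courses, processive-extension chain models,
tight-binding titration/stoichiometry analysis, and seeded synthetic-data
generation for parameter-recovery experiments.

## The scientific problem

Replicative B-family DNA polymerases such as yeast DNA polymerase δ are slow
on their own but are held on DNA — and, for Pol δ, accelerated — by the
sliding clamp PCNA. Measuring the true catalytic rate requires
single-turnover (burst-phase) conditions: the polymerase is pre-bound to a
template/primer, the reaction is started by adding the complementary dNTP,
and product formation is sampled on millisecond quench-flow grids. Product
formation follows

    [Product](t) = A (1 − e^{−k_fast t}) + (1 − A)(1 − e^{−k_slow t})

where `k_fast` is catalysis by the preformed polymerase–DNA complex and the
amplitude `A` is the fraction of DNA in that complex; at saturating enzyme
`A = 1` and a single exponential suffices. Burst amplitudes are only
interpretable if the DNA really is saturated, so the package also models the
equilibrium titration used to establish saturation: two polymerase molecules
bind each template/primer sequentially (`D + E ⇌ DE`, `DE + E ⇌ DE₂`), and
in the tight-binding regime the anisotropy/intensity titration is piecewise
linear with its final breakpoint at (stoichiometry × [DNA]). Multi-nucleotide
extension over a homopolymeric run is modelled as a chain of identical
exponential steps (rate `k_step`) competing with dissociation (`k_off`);
with no dissociation the product-length distribution is the censored Poisson
`P(j) = (k t)^j e^{−kt}/j!`, and unextended-primer survival
`e^{−(k_step+k_off)t}` gives a processivity-independent minimal catalytic
rate.

The package is for kineticists who want these analyses as tested,
composable pieces: a mass-action simulator for the minimal four-step
incorporation scheme (binding k1, dNTP binding k2, conformational change k3,
chemistry k4), exponential burst fitting, two-site equilibrium and segmented
stoichiometry fits, gel-lane quantification, and generators that emulate
quench-flow and fluorimeter output with stated ground truths.

## Worked example

```python
from prekin import (GeneratorConfig, default_time_grid, make_burst_timecourse,
                    fit_exponential)

cfg = GeneratorConfig(kind="burst", truth={"A": 1.0, "k_fast": 40.0},
                      grid=default_time_grid(), sigma=0.02, seed=7)
(tc,) = make_burst_timecourse(cfg)
fit = fit_exponential(tc, n_phases=1)
print(f"k_pol = {fit.k_fast:.1f} /s")
```

prints `k_pol = 39.8 /s`: a saturating-enzyme time course generated from a
40 /s truth with realistic quench-flow noise refits to within an error well
inside the fitted standard error (±0.8 /s). The `examples/` directory has
one narrative script per capability — burst fitting and bound-fraction
amplitudes (`01`), titration stoichiometry (`02`, prints the ~100 nM
breakpoint of a 50 nM DNA titration, i.e. stoichiometry ≈ 2), processive
extension and product distributions (`03`, the 500 nt/s complex reaches
full-length 20-mer product by 40 ms and peaks around 4–5 nt at 10 ms while
a 150 /s complex peaks at 1–2 nt), and primer-disappearance rates (`04`).

A thin CLI mirrors the library:

```sh
prekin simulate --kind burst --config truth.yaml --seed 1 --out data.csv
prekin fit-burst data.csv --phases 1
prekin fit-titration titration.csv --dna-nM 50 --segments 2
prekin recover --config recovery.yaml --seed 1 --out report.csv
```

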