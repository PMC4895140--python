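# adoptspread

Threshold-driven social contagion with spontaneous adopters and unconcerned
individuals: a Monte Carlo simulator, the matching approximate-master-equation
(AME) theory, and structural analytics for adoption cascades.

## The problem

Online services (and products generally) spread through social networks, but
not the way classic cascade models predict. In the Watts threshold model a
single seed either triggers an instantaneous global cascade or nothing
happens; real service adoption instead unfolds over years, reaches only part
of the network, and is fed by a steady trickle of people who adopt without
any adopting friends. `adoptspread` implements a threshold model that
captures this phenomenology and the measurement machinery used to confront it
with adoption event logs:

* each node has degree *k* drawn from a lognormal law
  (*μ*<sub>D</sub>, *σ*<sub>D</sub>, *k*<sub>min</sub>) and a fractional
  adoption threshold *φ* ∈ (0, 1] drawn from a lognormal truncated to the
  unit interval (*μ*<sub>T</sub>, *σ*<sub>T</sub>), independent of degree;
* a fraction *r* of nodes is **immune** (never adopts);
* susceptible non-immune nodes adopt **spontaneously** at rate
  *p*<sub>r</sub> = *p*<sub>n</sub>/(1 − *r*) per iteration (so the innovator
  flux per network node is *p*<sub>n</sub>), and **socially** as soon as a
  fraction ≥ *φ* of their neighbours has adopted;
* adoption is absorbing: the dynamics freezes at *ρ*(∞) = 1 − *r*.

The default parameterisation is the empirical one for a large voice-over-IP
service: *μ*<sub>D</sub> = 1.09, *σ*<sub>D</sub> = 1.39,
*k*<sub>min</sub> = 1 (mean degree *z* ≈ 8.6), *μ*<sub>T</sub> = −2,
*σ*<sub>T</sub> = 1 (mean threshold *w* = 0.19), *p*<sub>n</sub> = 0.00019
per node per month, and an 89-month observation window.

## Theory

Writing *s*<sub>(k,c),m</sub> for the susceptible fraction of nodes with
degree *k*, threshold type *c* and *m* adopting neighbours, the AME system
for this monotone dynamics collapses under the binomial ansatz
*s*<sub>(k,c),m</sub> = B<sub>k,m</sub>(ν) e<sup>−p<sub>r</sub>t</sup>
(sub-threshold *m*) onto two ODEs:

    ρ' = h(ν, t) − ρ + p_r (1 − r − h)
    ν' = g(ν, t) − ν + p_r (1 − r − g)

where *ρ* is the adopter fraction, *ν* the probability that a random
neighbour of a susceptible node has adopted, and

    h(ν, t) = (1 − r) [1 − e^{−p_r t} Σ_k P(k) Σ_c P(c) BinCDF(M_kc − 1; k, ν)]

with *M*<sub>kc</sub> = ⌈k φ<sub>c</sub>⌉ the integer trigger count and *g*
the same mixture over the edge-weighted (excess-degree) law. The innovator
fraction obeys ρ₀' = p<sub>r</sub>(1 − r − ρ). The full
*s*<sub>(k,c),m</sub> system is also implemented and serves as the oracle for
the reduced pair (they agree to ~10⁻⁷ on regular single-type substrates).

Scanning the immune fraction reveals three regimes: rapid global cascades
(small *r*), a crossover where adoption is slowest (*r*<sub>c</sub> ≈ 0.8 for
the default parameters, marked by maximal half-adoption time *t*<sub>c</sub>
and a near-coincident maximum of the final innovator fraction), and a
fragmented regime (*r* ≳ 0.9) with no global diffusion.

## Worked example

```python
import numpy as np
from adoptspread import *

rng = np.random.default_rng(42)
deg = DegreeModel(1.09, 1.39, k_min=1)
thr = ThresholdModel(-2.0, 1.0)

pop = build_population(deg, thr, 100_000, r=0.73, rng=rng)
sim, log = simulate(pop, p_n=0.00019, t_max=89, rng=rng)
print(f"adopters after 89 months: {len(log)} ({100*len(log)/pop.n:.1f}% of the network)")

cls = classify(pop, log)
print(cls["cls"].value_counts().to_dict())

stats = component_stats(build_adoption_network(pop, log), n_total=pop.n)
trees, _ = vulnerable_forest(pop, log)
print(f"adoption-network LC: {stats.lc} nodes ({100*stats.rel_lc:.1f}% of N); "
      f"vulnerable trees: {len(trees)}, max depth {trees['depth'].max()}")

params = AMEParams.from_models(deg, thr, r=0.73, p_n=0.00019)
out = integrate_reduced(params, t_grid=np.arange(0.0, 90.0))
print(f"AME rho(89) = {out['rho'].iloc[-1]:.4f} vs MC {sim.rho[-1]:.4f}")
```

prints

```
adopters after 89 months: 5273 (5.3% of the network)
{'vulnerable': 3234, 'innovator': 1341, 'stable': 698}
adoption-network LC: 4010 nodes (4.0% of N); vulnerable trees: 834, max depth 11
AME rho(89) = 0.0662 vs MC 0.0527
```

At the crossover-regime immune fraction *r* = 0.73 the service reaches ~5% of
the network in 89 months. Adopters decompose into innovators (no adopting
neighbour at adoption), vulnerable nodes (exactly one) and stable nodes (two
or more); the adoption network — substrate edges between adopters with
distinct adoption times — has a giant component holding most adopters, glued
together by many small, shallow innovator-rooted vulnerable trees rather than
by one percolating vulnerable cluster. The mean-field AME curve tracks the
single Monte Carlo run within ~0.01.

A CLI mirrors the library (`adoptspread simulate|ame|crossover|phase|analyze|
estimate|fixtures`, each with `--seed` and a YAML config).

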