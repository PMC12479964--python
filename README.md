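# circuitevo

Host-aware simulation and design of genetic feedback controllers that slow
the evolutionary loss of synthetic gene-circuit function in bacteria.

Engineered circuits consume their host's ribosomes and anabolites; the
resulting growth defect ("burden") puts circuit-carrying cells at a
selective disadvantage, so loss-of-function mutants sweep serial-passage
populations and circuit output decays over days to weeks.  `circuitevo`
couples three scales to study this quantitatively and to design
countermeasures:

1. **Cell** — a mechanistic resource-allocation model of bacterial gene
   expression in which translation elongation saturates in the anabolite
   pool, `gamma(e) = gamma_max e / (K_gamma + e)`, and growth emerges as
   `lambda = gamma(e) * sum_x c_x / M` over all mRNA–ribosome translation
   complexes `c_x`.  Circuit expression competes for the same ribosomes and
   energy, so burden is predicted, not assumed.
2. **Mutation** — each mutable promoter takes functional levels
   {100, 67, 33, 0}% of its designed transcription rate; strains are level
   tuples (4, 16 or 64 states) connected by function-reducing,
   single-promoter transition rates.
3. **Population** — strains compete for one substrate bolus per 24-h batch
   (`dN_i/dt = lambda_i N_i + mutation transfer`), with daily dilution to
   1000 cells, replicating laboratory serial passage.

The population output `P = sum_i N_i p_A_i` is scored by its initial value
`P0`, the time `tau_pm10` it stays within ±10% of `P0`, the functional
half-life `tau_50`, and the cumulative production
`Q = sum_i \int T_{L_A,i} N_i dt`.  A library of controller topologies —
intra-circuit negative autoregulation, growth-(burden-)sensing feedback,
population sensing, sRNA-mediated post-transcriptional silencing, and
multi-input combinations — can be attached to the process gene, optimised
by a tri-objective NSGA-II (`maximise (P0, tau_pm10, tau_50)`), compared
against open-loop designs of equal initial output, and stress-tested under
parametric perturbation.  See `docs/methods.md` for the full model.

## Worked example

Simulate the nominal open-loop process (a single reporter-like gene at
`omega_A = 5` mc/min) under fast test-scale mutation for three batch days,
then attach an intra-circuit feedback controller at the same process
strength:

```python
import circuitevo as ce

toy = ce.fixture_toy_system()          # OL, 3 days, fast mutation
trace = toy.run()
m = ce.design_metrics(trace)
print("day-end P:", [f"{p:.3g}" for p in trace.day_end_P])
print(f"P0={m.P0:.3g} mc  tau_pm10={m.tau_pm10:.0f} min  Q={m.Q:.3g} mc")

ctl = ce.RunConfig(topology="PHEN_PA",
                   design={"omega_A": 5.0, "k_A": 2000.0},
                   mutation={"base_rate": 2e-4},
                   protocol={"max_days": 3, "samples_per_day": 12})
ctrace = ctl.run()
mc = ce.design_metrics(ctrace)
loss = 1.0 - ctrace.day_end_P[-1] / mc.P0
print(f"controlled: P0={mc.P0:.3g} mc  3-day loss={loss:.1%} "
      f"(open loop: {1 - trace.day_end_P[-1] / m.P0:.1%})")
```

Output:

```
day-end P: ['4.44e+07', '3.79e+07', '3.2e+07']
P0=4.44e+07 mc  tau_pm10=2421 min  Q=1.06e+08 mc
controlled: P0=1.58e+07 mc  3-day loss=18.1% (open loop: 27.9%)
```

Read: the ancestral population's standing output is 4.4e7 molecules at the
end of day 1; by day 3 faster-growing loss-of-function mutants have eroded
it to 3.2e7 (the output leaves the ±10% band after 2421 min ≈ 1.7 days at
this test-scale mutation rate).  Attaching negative feedback lowers `P0`
(the controller throttles expression) but slows the decay — the
output/longevity trade-off the design tools quantify.

The same pipeline is scriptable from the shell:

```sh
circuitevo simulate  --config run.yaml --out results/
circuitevo reference --config run.yaml --out ref/          # open-loop frontier
circuitevo metrics   --trace results/trace.csv --compare ref/reference.csv --out m.json
circuitevo optimize  --config run.yaml --out front/        # NSGA-II Pareto front
circuitevo robustness --config run.yaml --front front/front.csv --out rob/
```

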