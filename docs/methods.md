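# Methods

`circuitevo` simulates the evolutionary erosion of synthetic gene-circuit
function in bacterial populations and the genetic feedback controllers
designed to slow it.  This note records the model, its parameters, the
numerical choices, and what the package's synthetic study conditions do and
do not capture.

## The multi-scale model

### Host cell

Each cell is described by the coarse-grained resource-allocation model of
bacterial gene expression and growth: four endogenous gene classes
(nutrient transporter, metabolic enzyme, ribosomal, housekeeping) transcribe
into mRNAs that bind free ribosomes `R` to form translation complexes;
translation elongation consumes a pooled anabolite/energy species `e` at the
saturating rate

    gamma(e) = gamma_max * e / (K_gamma + e),

and the growth rate is the total translation flux normalised by cell mass,

    lambda = gamma(e) * (sum of all translation complexes) / M.

All species are diluted at `lambda`.  Host parameter defaults are the
published fitted values of this model family for *E. coli* (e.g.
`gamma_max = 1260 aa/min`, `M = 1e8 aa`, `n_r = 7549 aa`,
`d_m = 0.1 /min`); the circuit-free baseline reproduces a doubling time of
about 27 min under saturating substrate.  Units are molecules/cell (mc)
and minutes everywhere.

A circuit adds its own transcripts, complexes, proteins and sRNAs to the
same pools.  Because circuit translation competes for `R` and `e`, circuit
expression lowers `lambda` — the burden phenomenon — without any ad hoc
fitness penalty.  Circuit transcription carries the same anabolite
saturation factor `e/(theta_nr + e)` as the non-ribosomal host genes, so
starved (stationary-phase) cells stop transcribing; without this factor
cells would accumulate transcripts overnight and burst-translate at the
next dilution, which distorts the daily output endpoints.

An optional transcription-energy extension charges `tx_cost` anabolites per
transcribed nucleotide (host and circuit; gene length approximated as
3 nt/aa, sRNA length explicit).  It is off by default, reflecting the
assumption that translational demand dominates bacterial burden.

### Controllers

Regulation uses quasi-steady-state Hill laws with coefficient 2 by default
(configurable): repression `k^h/(k^h + x^h)`, activation `x^h/(k^h + x^h)`.
The library covers:

* phenomenological single-input laws — process output per cell (`PHEN_PA`),
  growth rate (`PHEN_LAMBDA`), population-wide output (`PHEN_POP`), and the
  product of the first two (`PHEN_DUAL`);
* mechanistic intra-circuit controllers: `CLpATX` (co-transcribed repressor
  inhibits the shared promoter) and `CLpATL` (co-transcribed activator
  drives an sRNA that sequesters the circuit mRNAs);
* mechanistic growth-based controllers: `CLlamTX`, `CLlamTL`, and the
  protein-free `CLlamPF`, where a stress-/growth-sensitive promoter
  (modelled as repression by the instantaneous `lambda`, no sensing delay)
  drives the regulator or the sRNA directly;
* five multi-input combinations (`CLpATXlamTL`, `CLpATLlamTX`,
  `CLpATLlamTL`, `CLpATXlamTX`, `CLpATLlamPF`) composing the two inputs
  per-promoter;
* `QS_POP`, population sensing implemented as the quasi-steady-state
  reduction of a fast quorum-sensing signal pool, which collapses to
  repression by the population output `P`.

sRNA sequestration is irreversible bimolecular co-degradation (rate
`seq_rate * m * r`, default `1e-2 /mc/min`; both molecules removed), the
simplest mass-balanced reading of sRNA silencing.  Where the process and a
regulator are co-transcribed they are modelled as two independently
ribosome-binding mRNA species produced at the same promoter rate, keeping
their binding rates independently tunable; in the intra-circuit sRNA
topologies the sRNA targets both co-transcribed mRNAs, in growth-based
topologies only the process mRNA.

Default kinetics (`circuits.DEFAULTS`) are the nominal study conditions: a
moderate process (`omega_A = 5 mc/min`), regulator length 300 aa (a typical
bacterial transcription factor; 1 and 600 aa probe the controller-burden
extremes), abundant cheap sRNA (`omega_C = 50 mc/min`), and growth sensing
at `k_lambda = 0.01 /min` (between the phenomenological and mechanistic
optima).

### Mutation

Each mutable promoter has four functional levels {100, 67, 33, 0}% of its
designed maximal transcription rate; a strain is a tuple of levels, so
topologies with 1/2/3 mutable promoters have 4/16/64 strains.  Transitions
are continuous first-order transfers: only function-reducing single-promoter
steps are allowed, at `base_rate * attenuation^(levels skipped - 1)`.
Defaults: `base_rate = 1e-5 /min`, `attenuation = 0.1`.  The base rate was
fixed once on two grounds: (i) pure mutational drift (no growth differences)
then halves the population's expected functional level only on a ~4-month
timescale, so selection — not mutational supply — dominates takeover, as in
the modelled phenomenon; (ii) serial-passage experiments on engineered
constructs lose function over one to a few weeks, which the nominal process
reproduces (tau_50 ≈ 5 weeks at `omega_A = 5`, faster for more burdensome
designs).  The fully non-functional strain is absorbing.

### Population and batch protocol

Strains share one external substrate pool; per-strain intracellular states,
strain abundances `N_i`, the substrate, and a cumulative-production
integral are integrated jointly as one stacked stiff ODE system:

    dN_i/dt  = lambda_i N_i + sum_j (N_j M[j,i] - N_i M[i,j])
    ds_X/dt  = - sum_i N_i * import_i

The serial-batch protocol mirrors laboratory evolution experiments: 24-h
days, substrate reset to `1e12` molecules, dilution to a representative
sample of 1000 cells (deterministic proportional rescaling by default — the
expectation of the sample — with seeded multinomial sampling available).
Within a day the population grows until the substrate is exhausted
(~2.5 doublings under the default parameterisation) and then sits in
stationary phase.  Runs stop when the daily-endpoint output falls below 1%
of its initial value or after `max_days` (default 60).

The day-0 population is 100% fully functional cells.  Intracellular states
start at the nutrient-replete steady state and are then carried through two
mutation-free batch cycles so the population enters day 1 at the periodic
state of the serial-passage map; without this equilibration the day-1
endpoint is biased by ~0.5% against later days, which contaminates the
band-exit metric.  Under zero mutation the daily endpoints are then
constant to ~1e-5 relative.

## Metrics

The continuous population output `P(t) = sum_i N_i p_A_i` is a daily
sawtooth (dilution resets the census), so longevity is scored on the
daily-endpoint series with linear interpolation between endpoints:

* `P0` — endpoint of day 1 (the ancestral population; the mutant fraction
  after one day is ~1e-3 and negligible);
* `tau_pm10` — first exit from `[0.9 P0, 1.1 P0]` (either boundary; an
  upper exit is flagged and implies `tau_pm10 != tau_90`);
* `tau_90`, `tau_50` — first drop below 90% and 50% of `P0`;
* `P_max` — maximum endpoint output;
* `Q` — cumulative production `sum_i \int T_L_A_i N_i dt` up to the time
  output falls below 1% of `P0`.

`Q` is integrated by the ODE solver as an auxiliary state rather than by
quadrature of the stored trace: the within-day production burst is too
sharp for any practical stored grid (trapezoid estimates scatter by several
percent with sampling density, while the solver-integrated value is
sampling-independent to ~1e-7).  Traces lacking the channel fall back to
trapezoid.

Controllers are compared against an *open-loop system of equal initial
output*: a sweep of uncontrolled designs over `omega_A` in [0.1, 1000]
mc/min yields the output/longevity frontier; designs past the interior `P0`
maximum are overburdened (output and longevity both fall) and are removed,
and the retained branch is linearly interpolated in `P0`.  Queries outside
the retained range raise rather than extrapolate.

## Design optimisation and robustness

Controller design maximises `(P0, tau_pm10, tau_50)` over box-bounded
kinetic parameters.  The solver is an in-package NSGA-II (fast
non-dominated sort, crowding distance, simulated binary crossover eta 15,
polynomial mutation eta 20) — no multi-objective library is a dependency.
Rate-like variables are searched in log10 space because bounds span
decades.  Full preset: population 250, Pareto fraction 0.4; the
scaled-down preset (population 40, 30 generations) is the desk-scale
default.  `tau` objectives not reached within the horizon enter capped at
the horizon and flagged; failed evaluations receive worst fitness;
evaluations are cached and everything is seeded.

Robustness analysis perturbs each optimised parameter uniformly within
±X% (X = 10, 25), clips to the optimisation bounds (mass lands exactly on
the boundary), re-simulates, and reports mean/std of the %-change of five
metrics against the stored baselines, plus the fraction of replicates that
lose `tau_pm10 = tau_90`.  Designs whose baseline already has
`tau_pm10 != tau_90` are excluded; "not reached" replicate metrics are
excluded from that metric's statistics and counted.

## Numerics

* Integrator: implicit BDF (stiff) with `rtol 1e-6`; absolute tolerances
  `1e-8` mc for intracellular species, `1e-6` cells for `N_i`, `1e-2`
  molecules for the substrate, 1 molecule for cumulative production.
  A finite-difference Jacobian with an explicit sparsity pattern (strain
  blocks plus substrate/census/population-output couplings) keeps the
  stacked systems (up to 64 strains × ~21 species) tractable.
* Non-negativity is enforced structurally: every consumption flux is
  proportional to the species consumed, so trajectories cannot cross zero
  except by solver roundoff; excursions are checked against `-1e-3` mc and
  clamped only at day boundaries.
* Steady-state initialisation integrates to `t = 1e5` min and polishes
  with a hybrid-Powell root solve if the scaled residual exceeds `1e-6`.
* "Not reached" metrics are `inf` sentinels with flags, never horizon
  values (except inside the optimiser's objective, where they are capped
  and flagged).

## Problem sizes

Default runs use 48 stored samples/day, a 60-day horizon, and the
open-loop reference sweep uses log-spaced designs (8 in the acceptance
script, configurable up to the 5000-design full preset).  The test suite
uses a miniature fixture (fast mutation `2e-4 /min`, 3-day horizon) that
preserves every qualitative feature — batch growth to exhaustion, mutant
takeover, monotone endpoint decay — in a few seconds per run.

## What the synthetic conditions do not capture

* Absolute scales (`P0`, `Q`, cell yields per batch) follow from the host
  parameterisation above; a different host transcription would shift them
  together.  Comparative statements (controller vs equal-output open loop)
  are the robust outputs.
* Mutation acts continuously in time, including stationary phase, and only
  on promoter strength; ribosome-binding-site or coding mutations, and
  per-division discrete mutation, are not modelled.
* Deterministic continuum populations: no demographic noise, no extinction
  threshold (strains persist at arbitrarily small `N_i`), and deterministic
  dilution by default.
* Single-cell chemistry is deterministic and unstructured (no cell cycle,
  no spatial effects); growth sensing is instantaneous.
* The quorum-sensing topology is a quasi-steady-state reduction, not an
  explicit AHL synthesis/diffusion model.
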