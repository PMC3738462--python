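# homeofront

Pareto-front analysis of integral-feedback homeostasis circuits in
*parameter space*.

The package studies the minimal rescaled integral-feedback loop

```
y(t) = u(t) - z(t)          # fast output balance
dz/dt = k (y(t) - y0)       # slow integral feedback
```

driven by a square input pulse (ambient level `I0` for a duration
`t_amb`, step to `I1` for one activation interval).  Each parameter point
`(k, y0)` — responsiveness and set-point — is scored by two time-averaged
costs: *effectiveness* (mean squared output, the damage carried) and
*economy* (mean squared internal variable, the protein burden).  The set
of best-compromise circuits is a curve in parameter space connecting the
two single-task archetypes, computed here three ways:

* **Analytically** (`front_analytic`): the contour-tangency condition is
  solved in closed form at any ambient interval; in the rare-input limit
  the front is `y0 = I0 (1-(2k+1)e^{-2k}) / (4 (1-(k+1)e^{-k}))`, falling
  from the economy archetype `(k=0, y0=I0)` to a plateau `y0 = I0/4`
  before the jump to the effectiveness archetype at infinite
  responsiveness.  Tangency points are classified (externally tangent /
  locally-but-not-globally optimal / internally tangent), cost extrema
  are located and Hessian-classified, and the two critical ambient
  durations where the regime changes are found by bisection.
* **By brute-force dominance** (`front_numeric`): exact non-dominated
  subsets of parameter grids, used as the validation oracle.
* **By evolutionary simulation** (`front_numeric.evolve_population`): a
  population is repeatedly dominance-filtered, perturbed by shrinking
  noise, and re-evaluated; survivors collapse onto the analytic front.

Because optimal circuits occupy a one-dimensional manifold, measuring a
subset of `(k, y0, I0)` pins down the rest (`inference`).  Three worked
case studies ship with the package: the E. coli heat-shock system
(ambient unfolded-protein load without a heat-shock system, about 2e5
proteins or 10% of total protein), the SOS DNA-repair system (ambient
damage 0.44 double-stranded breaks), and calcium homeostasis in dairy
cows.

## Command line

```sh
homeofront simulate --k 2 --y0 0.3 --i0 1 --i1 3 --t-amb 5 --out run/
homeofront performance --grid 100 --t-amb 5 --out perf/
homeofront front --i0 1 --rare --out front/            # rare-input limit
homeofront front --i0 1 --t-amb 0.2 --out front/       # finite interval + regime report
homeofront evolve --n 10000 --iters 60 --seed 1 --out evo/
homeofront infer --case dna_repair --out inf/
homeofront fixtures --out fixtures/
```

Every output directory records the exact `run_config.json` (including
the seed) that produced it; all numeric artifacts are CSV/JSON.

## Layout

```
src/homeofront/
  core_model.py      # dynamics: closed forms, ODE variants, rescaling
  performance.py     # cost functionals, closed forms, gradients/Hessians
  front_analytic.py  # tangency locus, classification, extrema, critical durations
  front_numeric.py   # dominance filter, grid oracle, evolutionary simulation
  inference.py       # front inversion + packaged case studies
  cli.py             # subcommands, fixtures, run configs
tests/               # unit, property and acceptance suites
scripts/acceptance.py
```
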