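# mphpk

Site-of-absorption pharmacokinetics of modified-release methylphenidate.

Evening-dosed delayed-release/extended-release methylphenidate (DR/ER-MPH) is
designed to carry its payload past the upper gastrointestinal tract and
release it in the proximal colon, where absorption is slower. Moving the
release site along the gut — small intestine (SI), proximal colon (PC),
distal colon (DC) — reshapes the entire plasma profile: a later, lower peak,
a longer apparent terminal half-life, and lower bioavailability the more
distal the site. `mphpk` is a toolkit for studying exactly that: it is aimed
at pharmacometricians and formulation scientists who want a compact,
fully-tested pipeline from simulated (or real) crossover concentration data
through noncompartmental analysis, convolution-model fitting, formulation
comparison, and in vitro dissolution analysis.

## The model

Plasma kinetics follow a convolution one-compartment model. The amount of
drug in the body A(t) obeys

    dA/dt = Dose · f(t) − kel · A,        A(0) = 0,

where f(t) = dr/dt is the in vivo input rate, the derivative of a cumulative
release function r(t), and kel is the first-order elimination rate.
Concentration is C = A / (V/F), with one apparent volume scaling amount to
ng/mL (bioavailability and volume are confounded, so a single amplitude
parameter suffices). Two release families are implemented:

* **sigmoid (Hill / Emax-type)** — r(t) = t^ga / (EC^ga + t^ga), where EC is
  the time to release 50% of the dose and ga sets the steepness; a
  monophasic input suited to delayed/extended-release beads;
* **double Weibull** — a weighted mixture of two Weibull CDFs, the standard
  biphasic input for an osmotic system with an immediate-release overcoat.

Around the model sit: an NCA engine with positional BLQ substitution rules
(values below the 0.02 ng/mL LLOQ before the first quantifiable
concentration become 0; BLQ or missing values after it are excluded), a
synthetic 18-subject three-way crossover generator with lognormal
between-subject variability and LLOQ censoring, pooled and two-stage
least-squares estimation, release-clock synchronization plus dose-linear
scaling for cross-formulation comparisons, and degradation-corrected
dissolution-profile analysis (parent drug + erythro isomer + related
compound A) with release-onset detection.

## Worked example

Simulate a default crossover cohort, run NCA, and compare formulations:

```python
from mphpk import (CohortSpec, generate_crossover_dataset, run_dataset_nca,
                   summarize_cohort, percent_difference)
from mphpk.formulation_comparison import round_percent

ds = generate_crossover_dataset(CohortSpec(seed=1))
summary = summarize_cohort(run_dataset_nca(ds)).set_index("formulation")
print(summary.loc[["SI", "PC", "DC"],
                  ["cmax_mean", "tmax_median", "auc_0_inf_mean", "t_half_mean"]].round(2))
auc = summary["auc_0_inf_mean"]
print("SI vs PC bioavailability:",
      f"{round_percent(percent_difference(auc['SI'], auc['PC'])):+d}%")
```

prints

```
             cmax_mean  tmax_median  auc_0_inf_mean  t_half_mean
formulation
SI               27.55         10.0          281.34         4.70
PC               15.98         14.0          226.41         5.21
DC               10.15         16.0          188.36         6.59
SI vs PC bioavailability: +24%
```

Reading the table: as the release site moves distally (SI → PC → DC), peak
concentration falls, the peak arrives later, total exposure (AUC0-∞) drops,
and the apparent terminal half-life stretches — the half-life effect is
"flip-flop" kinetics (absorption outlasting elimination), not a change in
the drug's intrinsic clearance, which is shared across formulations in the
simulator. The exact numbers vary with the seed; the orderings do not.

The same operations are exposed on the command line:

```sh
mphpk simulate --seed 1 --out cohort.csv
mphpk nca cohort.csv --out-summary summary.csv
mphpk fit cohort.csv --formulation SI --mode pooled --out si.yaml
mphpk compare si.yaml pc.yaml --offset -4 --offset 0 --out comparison.csv
mphpk dissolution --fixture PC --threshold 1.0 --out dissolution.csv
```

## Layout

| module | contents |
| --- | --- |
| `mphpk.io_datasets` | concentration/dissolution CSV and YAML config I/O, column semantics |
| `mphpk.release_models` | sigmoid and double-Weibull release functions and analytic input rates |
| `mphpk.convolution_pk` | ODE solution of the convolution model, concentration scaling, profile metrics |
| `mphpk.synthetic_cohort` | crossover study generator and packaged typical parameters |
| `mphpk.nca` | BLQ preprocessing, Cmax/tmax, trapezoid AUC, λz, cohort summaries |
| `mphpk.model_fitting` | pooled and two-stage least-squares estimation, prediction |
| `mphpk.formulation_comparison` | synchronization, dose scaling, percent differences, reports |
| `mphpk.dissolution_analysis` | media schedules, degradation correction, onset detection, fixtures |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
their provenance, and known limitations.
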