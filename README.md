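# tmddpk

Population pharmacokinetic/pharmacodynamic modelling and interspecies
translation for a high-affinity anti-α4β7 monoclonal antibody (IgG2,
~144 kDa) developed for inflammatory bowel disease. The package answers a
concrete translational question: given cynomolgus-monkey PK/PD, what is a
safe and pharmacologically sensible first-in-human (FIH) starting dose and
escalation scheme?

## What it does

* **Structural models** — two-compartment disposition with target-mediated
  drug disposition (TMDD). The default is the quasi-equilibrium (QE)
  approximation with constant total target: binding to the α4β7 receptor
  is collapsed into the dissociation constant *K*<sub>d</sub> and the free
  concentration is the positive root of

  *C*<sub>f</sub> = ½[(*C*<sub>tot</sub> − *R*<sub>tot</sub> − *K*<sub>d</sub>) +
  √((*C*<sub>tot</sub> − *R*<sub>tot</sub> − *K*<sub>d</sub>)² +
  4 *K*<sub>d</sub> *C*<sub>tot</sub>)].

  The full kinetic TMDD system (k<sub>on</sub>/k<sub>off</sub>, receptor
  turnover) and a parallel linear + Michaelis–Menten comparator are
  provided as oracles/alternatives.
* **Synthetic monkey program** — a generator that emulates a five-study
  preclinical program (119 treated animals, 0.01–80 mg/kg IV/SC, single to
  24 weekly doses) with lognormal between-animal variability, proportional
  + additive residual error, assay censoring (LLOQ 2 or 20 ng/mL) and
  anti-drug-antibody (ADA) contamination with a reproducible two-step
  exclusion filter.
* **Estimation** — naive-pooled maximum likelihood for typical values, a
  MAP/EM mixed-effects stage for between-animal variability, and an
  inhibitory E<sub>max</sub> fit (E = E₀(1 − E<sub>max</sub>·C/(EC₅₀+C)))
  for receptor-occupancy PD, with ECp = EC₅₀·p/(100−p).
* **Translation** — allometric scaling to a 70 kg human
  (CL ∝ BW<sup>0.75</sup>, V<sub>c</sub> ∝ BW<sup>1</sup>,
  K₁₂/K₂₁ ∝ BW<sup>−0.25</sup>), human exposure simulation, NOAEL-based
  safety margins, FDA MRSD arithmetic and MABEL-style occupancy coverage.

## Worked example

```python
from tmddpk import allometric_scale, exposure_margins, predict_human_exposures
from tmddpk.params import monkey_parameters, human_parameters

human = allometric_scale(monkey_parameters())
print(human.cl, human.vc)        # 144.22638454873643 2900.0  (mL/day, mL)

rows = predict_human_exposures(human_parameters(), [420, 210, 0.7],
                               ["IV", "SC", "SC"])
for r in rows:
    m = exposure_margins(r["cmax"], r["auc"])
    print(f"{r['dose_mg']:>6} mg {r['route']}: Cmax {r['cmax']:.4g} ug/mL, "
          f"AUC {r['auc']:.5g} ug*h/mL, AUC margin {m['auc_margin']:.4g}")
```

prints

```
 420.0 mg IV: Cmax 143.5 ug/mL, AUC 66977 ug*h/mL, AUC margin 7.241
 210.0 mg SC: Cmax 42.8 ug/mL, AUC 32298 ug*h/mL, AUC margin 15.02
   0.7 mg SC: Cmax 0.0008813 ug/mL, AUC 0.99264 ug*h/mL, AUC margin 4.886e+05
```

i.e. a single 420 mg IV dose in a 70 kg human is predicted to peak at
~143 µg/mL with a ~7-fold AUC margin to the monkey no-adverse-effect
exposure, while the 0.7 mg SC starting dose carries a ~490,000-fold margin
and a peak near the EC₁₀ of receptor occupancy — the MABEL rationale for
starting there.

The same pipeline is exposed on the command line:

```bash
tmddpk generate --design A,B,C,D,E --seed 1 --out program.csv
tmddpk scale
tmddpk dose-select --doses 0.7,2.1,7,21,70,210,420
```

## Layout

| Module | Contents |
|---|---|
| `tmddpk.units` | domain types, mass↔molar conversion, regimen building |
| `tmddpk.models` | QE/QSS, full TMDD and Michaelis–Menten right-hand sides |
| `tmddpk.simulate` | event-driven ODE simulation, exposure metrics, NCA |
| `tmddpk.synthetic` | study designs, IIV/error/LLOQ/ADA generator, VPC |
| `tmddpk.estimate` | pooled ML, mixed-effects stage, Emax fit, ECp |
| `tmddpk.translate` | allometric scaling, margins, MRSD, dose selection |
| `tmddpk.io` / `tmddpk.cli` | NONMEM-style CSV, YAML configs, CLI |

See `docs/methods.md` for the modelling assumptions and numerical choices.
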