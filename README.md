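# voridial

Voriconazole pharmacokinetics in critically ill patients on continuous
renal replacement therapy (RRT): an integrated dialysis pharmacometric
model with hemofilter adsorption, bedside clearance estimators, a
synthetic-trial generator, desk-scale estimation, and a Monte-Carlo
probability-of-target-attainment (PTA) engine for weight-based dosing.

## The problem

Voriconazole is first-line therapy against invasive aspergillosis.  In
ICU patients on continuous veno-venous hemodialysis/hemofiltration
(CVVHD/CVVH) the drug is cleared both by the body (hepatic metabolism,
CL_body) and by the extracorporeal circuit (CL_RRT) — and part of the
circuit clearance is not diffusion into the effluent but adsorption onto
the hemofilter membrane.  Whether such patients attain the accepted
exposure targets (trough 0.5–3 mg/L; AUC₂₄ₕ/MIC > 32) under label
dosing is a simulation question once the population parameters are known.

## The model

Two-compartment disposition with linear elimination.  With C₁ = A₁/V₁:

    dA1/dt    = R_inf(t) − (CL_body + Q + CL_dial + CL_ads(t))·C1 + (Q/V2)·A2
    dA2/dt    = Q·C1 − (Q/V2)·A2
    dA_ads/dt = CL_ads(t)·C1                      (irreversible, capacity-limited)
    CL_dial   = (1 − F_ADS)·CL_RRT
    CL_ads(t) = F_ADS·CL_RRT·max(0, 1 − A_ads/ADS_MAX)

Typical values (defaults): CL_body 4.70 L/h, V1 80.6 L, Q 62.1 L/h,
V2 106 L, CL_RRT 1.46 L/h, F_ADS 0.23, ADS_MAX 69.2 mg, red-cell-to-
plasma ratio RBCtP 2.13; log-normal interindividual variability on all
six structural parameters, interoccasion variability on CL_body (83.8
%CV per 12-h dosing interval), proportional residual error per measured
stream.  The bedside estimators relate paired pre-filter, post-filter
and effluent concentrations to the circuit clearance:

    Q_blood,adj = Q_blood·(1 − Hct + Hct·RBCtP)
    CL_pre-post = Q_blood,adj·(C_pre − C_post,corr)/C_pre,
                  C_post,corr = C_post,meas·(Q_blood,adj − Q_FRR)/Q_blood,adj
    CL_pre-effl = Q_effl·C_effl/C_pre,   Q_effl = Q_dial + Q_RF,pre + Q_FRR

A persistent gap between the two estimators quantifies adsorption; the
effluent-to-plasma ratio C_effl/C_pre is the saturation coefficient
S_eff.  See `docs/methods.md` for numerics, design choices and
limitations.

## Worked example

```python
from voridial.pta import STANDARD, run_report, report_tables

report = run_report(STANDARD, n=2000, seed=7)   # 6/4 mg/kg q12h, continuous RRT
day1, steady = report_tables([report])
print(day1.to_string(index=False))
print(steady.to_string(index=False))
print(f"PTA (AUC24/MIC > 32) at MIC 1 mg/L: day 1 {100*report.pta_day1[1.0]:.1f}%, "
      f"steady state {100*report.pta_ss[1.0]:.1f}%")
```

prints

```
             Scenario  Cmin < 0.5 mg/L  Cmin 0.5-3 mg/L  Cmin > 3 mg/L  Cmin > 4 mg/L
recommended 6/4 mg/kg                8               76             16              7
             Scenario  Cmin < 0.5 mg/L  Cmin 0.5-3 mg/L  Cmin > 3 mg/L  Cmin > 4 mg/L
recommended 6/4 mg/kg                6               43             50             35
PTA (AUC24/MIC > 32) at MIC 1 mg/L: day 1 91.2%, steady state 92.5%
```

Read: under the recommended regimen, 76% of simulated patients are in
the 0.5–3 mg/L target band on day 1, but by day 6 half exceed the
3 mg/L hepatotoxicity threshold — the maintenance dose, not the loading
dose, is the problem.  The AUC/MIC efficacy target is met by >90% of
patients for MIC ≤ 1 mg/L.

A CLI wraps the stages (`voridial generate`, `rrt-clearance`, `fit`,
`compare-groups`, `pta`, `run-all`); `voridial run-all --seed 1` executes
the full generate → clearance → estimate → compare → simulate pipeline
and writes a reproducibility manifest.

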