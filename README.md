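# oculogas

Risk estimation of intravitreous gas/air expansion and intraocular-pressure
(IOP) elevation for altitude travel after vitrectomy.

After pars plana vitrectomy, many eyes are left with a gas or air tamponade.
The bubble is buoyant and sits in the superior vitreous cavity, separated
from intraocular fluid by a horizontal fluid/gas interface. If the patient
travels to a higher altitude, ambient pressure falls and — by Boyle's law,
P₁V₁ = P₂V₂ — the bubble tends to expand inside a semirigid eyeball, which
can elevate IOP enough to threaten vision. `oculogas` implements the
computational core of a clinical calculator for this scenario, for
vitreoretinal surgeons and their patients:

- **Geometry.** The vitreous cavity is an oblate spheroid of total volume
  V = 4.5 ml. If the gas occupies the top fraction *h* of the vertical
  diameter (judged in percent, by the surgeon through the dilated pupil or
  by the patient from their own visual field), the gas volume is
  V₁ = V · h²(3 − 2h) — the spheroid-cap fraction, exact for any aspect
  ratio.
- **Atmosphere.** Altitude maps to ambient pressure through the
  International Standard Atmosphere troposphere formula
  P(z) = P₀(1 − Lz/T₀)^5.25588 with P₀ = 101.325 kPa, L = 0.0065 K/m,
  T₀ = 288.15 K (valid −500 m to 11 000 m; all constants configurable).
- **Expansion and risk.** V₂ = V₁·P₁/P₂ is the unconstrained Boyle volume at
  the destination; ΔV = V₂ − V₁; the risk ratio r = ΔV / V_AC against the
  normal anterior-chamber volume (default 0.20 ml) drives an ordered
  categorical report (none / low / moderate / high).
- **Interobserver agreement.** Bland–Altman bias and 95% limits of
  agreement (bias ± 1.96·SD of surgeon − patient differences), the Wilcoxon
  matched-pairs signed-rank test (exact null enumeration for ≤ 25 nonzero
  differences, normal approximation with continuity and tie correction
  above), median (range) summaries, and 5-point Likert tabulation.
- **Cohort I/O and simulation.** Validated cohort CSV reading/writing, a
  per-patient risk table, the patient-facing interface chart (SVG), and a
  synthetic-cohort generator with the study's statistical structure for
  fully reproducible testing.

Eyewall compensation (choroidal compression, scleral expansion, aqueous
outflow) is deliberately out of scope: the model assumes immediate, direct
travel.

## Worked example

A patient whose bubble fills the top 75% of the cavity travels from
Guangzhou (10 m) to Lhasa (3490 m):

```bash
oculogas risk --interface-pct 75 --from-alt 10 --to-alt 3490
```

```json
{
  "inputs": {"interface_pct": 75.0, "origin_altitude_m": 10.0,
             "destination_altitude_m": 3490.0},
  "pressures_kpa": {"origin": 101.20492618214062,
                    "destination": 65.84876129076738},
  "volumes_ml": {"initial_gas": 3.796875,
                 "expanded_gas": 5.835530487825477,
                 "delta": 2.0386554878254772},
  "risk": {"ratio": 10.193277439127385, "category": "high"},
  "model": {"total_volume_ml": 4.5, "anterior_chamber_ml": 0.2,
            "thresholds": [0.5, 1.0]}
}
```

Reading: 75% fill holds 3.80 ml of gas (84.4% of the cavity). Ambient
pressure drops from 101.2 kPa to 65.8 kPa, so the unconstrained bubble
would grow to 5.84 ml — an excess of 2.04 ml, more than ten anterior
chambers' worth of fluid displacement, hence a high IOP-elevation risk.
The same pipeline runs over whole cohorts:

```bash
oculogas simulate --n 50 --seed 1 --out cohort.csv
oculogas cohort --in cohort.csv --out report.json --agreement --plots figs/
oculogas chart --interface-pct 40 --out chart.svg
```

The Python API mirrors the CLI (`oculogas.assess`, `oculogas.bland_altman`,
`oculogas.generate`, ...), and all model constants can be overridden via a
YAML/JSON file passed with `--config`.

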