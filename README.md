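# ferrovol

Measurement of circulating plasma and total blood volume by **ferumoxytol
tracer dilution** from serial cardiac MR T1 relaxometry, with the
carbon-monoxide rebreathing reference calculation and Monte Carlo tools
for designing abbreviated acquisition protocols.

Quantitative blood volume matters in heart failure (the hallmark of
decompensation is volume overload), yet the classical tracer methods —
radiolabels, Evans blue, CO rebreathing — are rarely practical.
Ferumoxytol is a superparamagnetic iron-oxide blood-pool agent with a
long intravascular half-life; a small dose plus a handful of blood-pool
T1 maps turns a routine CMR exam into a dilution experiment.  This
package is for imaging scientists and physiologists who want to analyze
such data, validate against CO rebreathing, or simulate how few T1
measurements a protocol can get away with.

## The model

A dose of `n_Fe` mmol of iron with relaxivity `r1` (mM⁻¹ s⁻¹) raises the
blood relaxation rate `R1 = 1/T1` above its native value `R1,∅` in
proportion to concentration:

    R1(t) = R1,∅ + r1 · [CA](t)

Since `[CA] = n_Fe / V`, each post-contrast T1 measurement yields an
apparent distribution volume

    V′(t) = r1 · n_Fe / ΔR1(t),   ΔR1(t) = R1(t) − R1,∅   [units: L]

which grows as the tracer is eliminated, `V′(t) = V_plasma · exp(t/τ)`.
Ordinary least squares on `log V′(t) = log V_plasma + t/τ` gives the
plasma volume from the intercept (extrapolation to the end of infusion)
and the elimination half-life `t½ = τ·ln 2` from the slope.  Hematocrit
converts plasma to total blood volume, `V_blood = V_plasma / (1 − Hct)`.

The CO rebreathing reference uses
`V_blood = V_CO · K · 100 / ([Hb] · Δ%COHb · n_H)` with Hüfner's number
`n_H = 1.31 ml/g`, after correcting the administered CO volume for
hemoglobin-affinity loss (1%), apparatus remnant gas, and CO expired
during the measurement.

## Worked example

Generate a synthetic single-subject study (noise 0.6% CV on T1, the
measured in vivo repeatability of the mapping sequence) and fit it:

```python
from ferrovol import (StudyDesign, generate_study, DoseRecord,
                      SubjectRecord, DilutionModel)

study = generate_study(StudyDesign(n_subjects=1, seed=7))
row = study.truths.iloc[0]
model = DilutionModel(study.series[1, 1],
                      DoseRecord(row["dose_ml"]),
                      subject=SubjectRecord(row["weight_kg"], row["hematocrit"]))
print(model.fit().summary())
```

```
Ferumoxytol dilution fit
============================================
compartment            LV
fit window [min]       20 - 60
n points               21
V_plasma [L]           2.8036
  95% CI half-width    0.93%
tau [min]              277.43
half-life [h]          3.205
r^2                    0.9816
positive elimination   True
V_blood [L]            4.1400
V_blood [ml/kg]        94.62
```

The fit recovers this subject's generated truth (V_plasma 2.8119 L,
half-life 3.161 h) to within the noise-limited precision: 21 T1 maps
between 20 and 60 min, log-linear fit, plasma volume from the intercept,
then hematocrit and weight normalization.  `r^2` is the goodness of the
log-linear fit and the CI half-width is the delta-method 95% interval
from the intercept standard error.

The same machinery answers design questions.  How precise is an
abbreviated "human" protocol sampling only at 2, 4 and 6 min?

```python
import ferrovol as fv
s = fv.simulate_protocol(fv.human_protocol(6.0), fv.ForwardModelParams(seed=7))
print(s.sigma_vplasma_pct)   # 1.074  (% SD of plasma volume over 10,000 reps)
```

From the shell the same operations are available as
`ferrovol calibrate | fit-bv | co-bv | simulate | sweep | repeatability |
make-synthetic` (see `ferrovol --help`).

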