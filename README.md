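# isfextract

Minimally invasive blood-glucose monitoring can work by extracting a few
microlitres of interstitial fluid (ISF) through ultrasound-permeabilised skin
into a buffer and assaying the diluted sample — but only if the *volume* of
extracted ISF is known, and that volume is too small to meter directly.
`isfextract` implements a resistance-based solution: the longitudinal
resistance of the epidermis at the extraction site indicates skin
permeability, so a single calibrated constant turns a skin-resistance reading
into an ISF volume, and the dilution mass balance turns the diluted assay
into a blood-glucose estimate.

The package is for instrumentation and biomedical-modelling work: it provides
the circuit model of the three-electrode sensor used to measure that
resistance *in vivo*, the estimation chain from resistance to glucose, a
synthetic measurement simulator (no public human datasets exist for this
protocol), and the validation statistics for the whole pipeline.

## The model

**Dilution mass balance.** With ISF glucose *CI*, extracted volume *x* (μL),
buffer volume *V* (μL), and diluted-sample glucose *CS* (all glucose in
mmol/L), conservation of glucose gives *CB·x = k·CI·x = k·(V + x)·CS*, where
*CB* is blood glucose and *k* the subject's blood↔ISF proportionality.

**Resistance → volume.** The ISF permeation rate is proportional to skin
conductance per unit area, so *x = C1·G = C1/R* with a lumped constant
*C1* (μL·kΩ) fixed by one reference extraction in which *CB* is also read
from a blood-glucose meter. Prediction is then

&nbsp;&nbsp;&nbsp;&nbsp;*CB = k·(1 + V·R / C1)·CS*

**Three-electrode sensor.** *R* must be the longitudinal epidermal
resistance under the extraction site, not contaminated by lateral surface
paths. With electrodes A, B, C in a line (B on the site) and pairwise
measurements *R_AB*, *R_BC*, *R_AC* taken with the third electrode switched
out, the lateral terms cancel:

&nbsp;&nbsp;&nbsp;&nbsp;*R_B = (R_AB + R_BC − R_AC) / 2*

The package models the full seven-resistor network (exact when lateral paths
are finite), the series-sum limit (in which the inversion above is exact),
the static (before/after) and dynamic (five samples during extraction)
measurement protocols including electrolyte-infiltration drift, and
Monte-Carlo propagation of resistance, assay, and meter noise.

## Worked example

```python
from isfextract import (CalibrationRecord, ExtractionConfig,
                        calibrate_c1, predict_blood_glucose,
                        volume_from_resistance)

cfg = ExtractionConfig()  # V=50 μL, t=10 min, A=0.785 cm², k=1
rec = CalibrationRecord(cb_ref=5.5, cs=0.5, r_skin=100.0)
c1 = calibrate_c1(rec, cfg)
x = volume_from_resistance(c1, 125.0)
cb = predict_blood_glucose(0.42, 125.0, c1, cfg)
print(c1, x, cb)
```

Running `python examples/calibrate_and_predict.py` prints:

```
implied extracted ISF volume: 5.000 μL
calibration constant C1:      500.0 μL·kΩ
later extraction: R=125.0 kΩ → x=4.000 μL → blood glucose 5.67 mmol/L
```

The reference extraction (meter 5.5 mmol/L, diluted assay 0.5 mmol/L, 100 kΩ)
implies 5 μL of ISF were extracted, fixing C1 = 500 μL·kΩ. A later
extraction at 125 kΩ therefore yielded 4 μL, and its 0.42 mmol/L assay scales
back up to 5.67 mmol/L blood glucose — no meter involved the second time.

The other scripts in `examples/` each demonstrate one capability: the
network inversion and its bias, protocol simulation with drift and noise,
the end-to-end synthetic-cohort pipeline, and the error budget / linearity
validation.

## Command line

```
isfextract simulate --config sim.yaml --seed 7 --out sessions.csv
isfextract rb sessions.csv --out reduced.csv
isfextract calibrate --cb-ref 5.5 --cs 0.5 --r-skin 100 --out calib.yaml
isfextract predict sessions.csv --calibration calib.yaml --out pred.csv
isfextract validate sessions.csv --predictions pred.csv --out report
```

The sessions CSV schema and the YAML config/calibration formats are
documented in `isfextract.io`.

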