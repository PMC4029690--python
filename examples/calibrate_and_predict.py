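"""One-point calibration of the resistance→volume constant C1, then blood
glucose prediction from a later extraction's resistance and diluted assay."""

from isfextract import (
    CalibrationRecord, ExtractionConfig, calibrate_c1, isf_volume_from_mass_balance,
    predict_blood_glucose, volume_from_resistance,
)

cfg = ExtractionConfig()  # V=50 μL, t=10 min, A=0.785 cm², k=1

# Reference extraction: meter reads 5.5 mmol/L, the diluted sample assays at
# 0.5 mmol/L, and the reduced longitudinal skin resistance was 100 kΩ.
rec = CalibrationRecord(cb_ref=5.5, cs=0.5, r_skin=100.0)
x_cal = isf_volume_from_mass_balance(rec, cfg)
c1 = calibrate_c1(rec, cfg)
print(f"implied extracted ISF volume: {x_cal:.3f} μL")
print(f"calibration constant C1:      {c1:.1f} μL·kΩ")

# A later extraction on the same site: 125 kΩ and a 0.42 mmol/L assay.
r, cs = 125.0, 0.42
x = volume_from_resistance(c1, r)
cb = predict_blood_glucose(cs, r, c1, cfg)
print(f"later extraction: R={r} kΩ → x={x:.3f} μL → blood glucose {cb:.2f} mmol/L")
# The prediction scales the diluted assay back up by the dilution factor
# (V + x)/x inferred from the skin resistance alone — no meter needed.
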