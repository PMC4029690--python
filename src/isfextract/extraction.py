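"""Dilution mass balance and resistance-based ISF volume / glucose estimation.

A small volume ``x`` (μL) of interstitial fluid (ISF) is extracted through
permeabilised skin into ``V`` μL of buffer over ``t`` minutes through area
``A`` cm².  Conservation of glucose across the dilution gives

    CB·x = k·CI·x = k·(V + x)·CS

where CB is blood glucose, CI = CB/k is ISF glucose, CS the diluted-sample
glucose (all mmol/L), and k the subject-specific blood↔ISF proportionality.

The permeation rate of ISF is proportional to skin conductance per unit area,
so the extracted volume is inversely proportional to the longitudinal skin
resistance R:

    x = C1·G = C1 / R

with a lumped constant C1 (μL·kΩ) fixed by a single reference extraction in
which CB is also read from a blood-glucose meter.  Once C1 is known, blood
glucose is predicted from a resistance measurement and the diluted-sample
assay alone:

    CB = k·(1 + V·R/C1)·CS

Units: μL, min, cm², kΩ, mmol/L; C1 therefore carries μL·kΩ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ExtractionConfig",
    "SkinPermeability",
    "CalibrationRecord",
    "ExtractionSession",
    "extraction_area",
    "volume_from_resistance",
    "volume_from_conductance",
    "permeation_rate",
    "diluted_concentration",
    "isf_volume_from_mass_balance",
    "calibrate_c1",
    "predict_blood_glucose",
    "predict_blood_glucose_high_dilution",
]


def _check_positive(**values: float) -> None:
    for name, value in values.items():
        if not (math.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class ExtractionConfig:
    """Physical constants of one extraction setup.

    Defaults are the chamber of the standard protocol: 50 μL of buffer, a
    10 min vacuum extraction through a 10 mm diameter chamber (0.785 cm²),
    and unit blood↔ISF glucose proportionality.
    """

    v_buffer: float = 50.0   # buffer volume V (μL)
    t_extract: float = 10.0  # extraction time t (min)
    area: float = 0.785      # extraction area A (cm²)
    k: float = 1.0           # blood-to-ISF glucose coefficient (dimensionless)

    def __post_init__(self) -> None:
        _check_positive(v_buffer=self.v_buffer, t_extract=self.t_extract,
                        area=self.area, k=self.k)


@dataclass(frozen=True)
class SkinPermeability:
    """Lumped skin permeability constants.

    ``c1 = C·t`` (μL·kΩ) is the calibration constant actually used downstream;
    the pore constant C, conductivity sigma and stratum-corneum thickness dx
    are optional physical decomposition, never required by the pipeline.
    """

    c1: float                       # lumped calibration constant C1 (μL·kΩ)
    c_pore: float | None = None     # pore constant C of the permeation law
    sigma: float | None = None      # skin conductivity
    dx: float | None = None         # stratum-corneum thickness

    def __post_init__(self) -> None:
        _check_positive(c1=self.c1)
        for name in ("c_pore", "sigma", "dx"):
            value = getattr(self, name)
            if value is not None:
                _check_positive(**{name: value})


@dataclass(frozen=True)
class CalibrationRecord:
    """One reference extraction used to fix C1.

    Requires ``cb_ref > k·cs`` (the implied ISF volume must be positive);
    this is validated where ``k`` becomes known, in
    :func:`isf_volume_from_mass_balance`.
    """

    cb_ref: float  # meter-read blood glucose CB (mmol/L)
    cs: float      # diluted-sample glucose CS (mmol/L)
    r_skin: float  # reduced longitudinal skin resistance R (kΩ)

    def __post_init__(self) -> None:
        _check_positive(cb_ref=self.cb_ref, cs=self.cs, r_skin=self.r_skin)


@dataclass
class ExtractionSession:
    """One extraction with its observables and (if synthetic) ground truth."""

    r_skin: float                       # reduced longitudinal resistance R_i (kΩ)
    cs: float                           # diluted-sample glucose CS_i (mmol/L)
    session_id: str = ""
    mode: str = "static"
    g_skin: float = field(default=0.0)  # conductance G_i = 1/R_i (kΩ⁻¹)
    x_isf: float | None = None          # extracted ISF volume x_i (μL)
    ci: float | None = None             # ISF glucose CI_i (mmol/L), synthetic truth
    cb_true: float | None = None        # true blood glucose (mmol/L), synthetic truth
    cb_pred: float | None = None        # predicted blood glucose (mmol/L)
    p_rate: float | None = None         # permeation rate P_i (μL·min⁻¹·cm⁻²)
    series: object | None = None        # MeasurementSeries that produced r_skin

    def __post_init__(self) -> None:
        _check_positive(r_skin=self.r_skin, cs=self.cs)
        if not self.g_skin:
            self.g_skin = 1.0 / self.r_skin


def extraction_area(diameter_mm: float) -> float:
    """Extraction area (cm²) of a circular chamber of given diameter (mm)."""
    _check_positive(diameter_mm=diameter_mm)
    radius_cm = diameter_mm / 2.0 / 10.0
    return math.pi * radius_cm**2


def volume_from_resistance(c1: float, r_skin: float) -> float:
    """Extracted ISF volume x = C1 / R (μL)."""
    _check_positive(c1=c1, r_skin=r_skin)
    return c1 / r_skin


def volume_from_conductance(c1: float, g_skin: float) -> float:
    """Extracted ISF volume x = C1 · G (μL); dual of :func:`volume_from_resistance`."""
    _check_positive(c1=c1, g_skin=g_skin)
    return c1 * g_skin


def permeation_rate(x_isf: float, cfg: ExtractionConfig) -> float:
    """Permeation rate P = x / (t·A) (μL·min⁻¹·cm⁻²); P=0 for x=0."""
    if x_isf < 0 or not math.isfinite(x_isf):
        raise ValueError(f"x_isf must be non-negative and finite, got {x_isf!r}")
    return x_isf / (cfg.t_extract * cfg.area)


def diluted_concentration(ci: float, x_isf: float, cfg: ExtractionConfig) -> float:
    """Diluted-sample glucose CS = CI·x/(V + x) — forward dilution chemistry."""
    _check_positive(ci=ci)
    if x_isf < 0 or not math.isfinite(x_isf):
        raise ValueError(f"x_isf must be non-negative and finite, got {x_isf!r}")
    return ci * x_isf / (cfg.v_buffer + x_isf)


def isf_volume_from_mass_balance(rec: CalibrationRecord, cfg: ExtractionConfig) -> float:
    """ISF volume implied by a reference extraction: x = k·V·CS/(CB − k·CS).

    Raises ``ValueError`` when ``cb_ref <= k·cs`` (calibration infeasible:
    the diluted sample cannot be more concentrated than undiluted ISF).
    """
    denom = rec.cb_ref - cfg.k * rec.cs
    if denom <= 0:
        raise ValueError(
            f"calibration infeasible: cb_ref={rec.cb_ref} must exceed "
            f"k*cs={cfg.k * rec.cs}"
        )
    return cfg.k * cfg.v_buffer * rec.cs / denom


def calibrate_c1(rec: CalibrationRecord, cfg: ExtractionConfig) -> float:
    """Fix the lumped constant C1 = x·R from one reference extraction (μL·kΩ)."""
    return isf_volume_from_mass_balance(rec, cfg) * rec.r_skin


def predict_blood_glucose(cs: float, r_skin: float, c1: float,
                          cfg: ExtractionConfig) -> float:
    """Predict blood glucose CB = k·(1 + V·R/C1)·CS (mmol/L).

    Equivalent to k·(1 + V/x)·CS with x = C1/R, i.e. the dilution mass
    balance with the resistance-derived ISF volume substituted in.
    """
    _check_positive(cs=cs, r_skin=r_skin, c1=c1)
    return cfg.k * (1.0 + cfg.v_buffer * r_skin / c1) * cs


def predict_blood_glucose_high_dilution(cs: float, p_rate: float,
                                        cfg: ExtractionConfig, *,
                                        include_k: bool = True) -> float:
    """High-dilution (V ≫ x) approximation CB ≈ k·V·CS/(P·t·A).

    Its relative difference from the exact prediction is exactly x/(V + x).
    ``include_k=False`` drops the blood↔ISF coefficient from the
    approximation for compatibility with formulations that absorb k into
    the calibration.
    """
    _check_positive(cs=cs, p_rate=p_rate)
    k = cfg.k if include_k else 1.0
    return k * cfg.v_buffer * cs / (p_rate * cfg.t_extract * cfg.area)
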