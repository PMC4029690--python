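"""Static and dynamic measurement protocols and synthetic-cohort generation.

Two measurement protocols reduce a series of pairwise-resistance triples to a
single longitudinal resistance per extraction:

* **static** — one triple immediately before and one immediately after the
  extraction; the reduced value is the mean of the two inversions.  The skin
  partially recovers between measurements, modelled by a multiplicative
  ``recovery_factor`` on the central longitudinal resistance.
* **dynamic** — five triples at 2-minute intervals during the 10-minute
  extraction, averaged.  With the central electrode sitting in electrolyte,
  the electrolyte infiltrates the epidermis and the resistance under the
  electrode falls quickly; this drift is modelled as a single-exponential
  relaxation from ``r_start`` to ``r_floor`` with time constant ``tau``.

Measurement noise is multiplicative lognormal per pairwise value (resistances
are positive and errors scale with magnitude): each measured resistance is
multiplied by ``exp(sigma_rel · z)`` with ``z`` standard normal, so
``sigma_rel`` is the standard deviation of the log-resistance (≈ the relative
error for small values).

:func:`generate_cohort` ties the pieces together into fully synthetic
extraction sessions carrying both the observables (resistance triples,
diluted-sample glucose) and the ground truth (ISF volume, ISF and blood
glucose), so every downstream estimation stage can be tested without human
data.  All simulation is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .extraction import ExtractionConfig, ExtractionSession, SkinPermeability, diluted_concentration
from .network import ElectrodeNetwork, PairwiseResistances, estimate_rb, pairwise_full

__all__ = [
    "DriftParams",
    "NoiseParams",
    "MeasurementSeries",
    "rb_trajectory",
    "simulate_static_session",
    "simulate_dynamic_session",
    "generate_cohort",
    "flag_gross_errors",
    "DYNAMIC_SAMPLE_TIMES",
]

#: Dynamic-mode sample times (min): five samples at 2-min intervals within a
#: 10-min extraction, first sample at 2 min.
DYNAMIC_SAMPLE_TIMES: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class DriftParams:
    """Exponential-relaxation model of within-extraction resistance decay.

    ``r_start`` is the longitudinal resistance under the central electrode at
    the start of extraction, ``r_floor`` the asymptote after electrolyte
    infiltration, ``tau`` the relaxation time constant (min).
    """

    r_start: float
    r_floor: float
    tau: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.r_floor) and self.r_floor > 0):
            raise ValueError(f"r_floor must be positive, got {self.r_floor!r}")
        if not (math.isfinite(self.r_start) and self.r_start >= self.r_floor):
            raise ValueError("r_start must be finite and >= r_floor")
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau!r}")

    def scaled(self, factor: float) -> "DriftParams":
        """Drift curve with both levels multiplied by ``factor`` (same shape)."""
        return DriftParams(self.r_start * factor, self.r_floor * factor, self.tau)


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative lognormal measurement noise on each pairwise resistance."""

    sigma_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0 or not math.isfinite(self.sigma_rel):
            raise ValueError(f"sigma_rel must be >= 0, got {self.sigma_rel!r}")


@dataclass(frozen=True)
class MeasurementSeries:
    """A reduced measurement series: triples, times, and the protocol reduction."""

    mode: str                                 # "static" | "dynamic"
    times: tuple[float, ...]                  # sample times (min)
    triples: tuple[PairwiseResistances, ...]  # one noisy triple per sample
    reduced_r: float                          # protocol-reduced R (kΩ); NaN if invalid
    n_invalid: int                            # flagged non-positive inversions
    valid: bool                               # at least one usable inversion


def rb_trajectory(drift: DriftParams, time_min: float) -> float:
    """Longitudinal resistance under the central electrode at ``time_min``.

    ``r_floor + (r_start - r_floor)·exp(-t/tau)`` — monotone non-increasing.
    """
    if time_min < 0:
        raise ValueError(f"time must be non-negative, got {time_min!r}")
    return drift.r_floor + (drift.r_start - drift.r_floor) * math.exp(-time_min / drift.tau)


def _noisy_triple(net: ElectrodeNetwork, sigma_rel: float,
                  rng: np.random.Generator) -> PairwiseResistances:
    clean = pairwise_full(net)
    factors = np.exp(sigma_rel * rng.standard_normal(3))
    return PairwiseResistances(
        r_ab=clean.r_ab * factors[0],
        r_bc=clean.r_bc * factors[1],
        r_ac=clean.r_ac * factors[2],
    )


def _reduce(mode: str, times: tuple[float, ...],
            triples: tuple[PairwiseResistances, ...]) -> MeasurementSeries:
    estimates = [estimate_rb(t) for t in triples]
    usable = [e.r_b_hat for e in estimates if e.valid]
    n_invalid = len(estimates) - len(usable)
    if usable:
        return MeasurementSeries(mode, times, triples, float(np.mean(usable)),
                                 n_invalid, True)
    return MeasurementSeries(mode, times, triples, float("nan"), n_invalid, False)


def simulate_static_session(net: ElectrodeNetwork, noise: NoiseParams,
                            recovery_factor: float = 1.0, *,
                            t_extract: float = 10.0,
                            rng: np.random.Generator | None = None) -> MeasurementSeries:
    """Simulate a static (before/after) measurement pair.

    The pre-extraction triple uses the network as given; the post-extraction
    triple uses the central longitudinal resistance scaled by
    ``recovery_factor`` (skin recovery is incomplete, so typically < 1).
    The reduced value is the mean of the valid inversions of the two triples.
    """
    if recovery_factor <= 0 or not math.isfinite(recovery_factor):
        raise ValueError(f"recovery_factor must be positive, got {recovery_factor!r}")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    pre = _noisy_triple(net, noise.sigma_rel, rng)
    post = _noisy_triple(net.with_rb(net.r_b * recovery_factor), noise.sigma_rel, rng)
    return _reduce("static", (0.0, t_extract), (pre, post))


def simulate_dynamic_session(net: ElectrodeNetwork, drift: DriftParams,
                             noise: NoiseParams, *,
                             times: tuple[float, ...] = DYNAMIC_SAMPLE_TIMES,
                             rng: np.random.Generator | None = None) -> MeasurementSeries:
    """Simulate a dynamic (five samples during extraction) measurement series.

    At each sample time the central longitudinal resistance is replaced by
    the drift-curve value; invalid inversions are excluded from the mean and
    counted in ``n_invalid``.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    triples = tuple(
        _noisy_triple(net.with_rb(rb_trajectory(drift, t)), noise.sigma_rel, rng)
        for t in times
    )
    return _reduce("dynamic", tuple(times), triples)


def _trajectory_mean(drift: DriftParams, times: tuple[float, ...]) -> float:
    return float(np.mean([rb_trajectory(drift, t) for t in times]))


def generate_cohort(n_sessions: int,
                    cfg: ExtractionConfig,
                    skin: SkinPermeability,
                    drift: DriftParams | None = None,
                    noise: NoiseParams | None = None,
                    cb_true_range: tuple[float, float] = (4.0, 10.0),
                    *,
                    mode: str = "static",
                    base_net: ElectrodeNetwork | None = None,
                    rb_median: float = 100.0,
                    rb_sigma_log: float = 0.25,
                    recovery_factor: float = 1.0,
                    seed: int | None = None) -> list[ExtractionSession]:
    """Generate fully synthetic extraction sessions with ground truth.

    Per session: a true blood glucose is drawn uniformly from
    ``cb_true_range`` (mmol/L), ISF glucose is ``cb/k``, the site's
    longitudinal resistance is drawn lognormally around ``rb_median`` (kΩ,
    log-sd ``rb_sigma_log``), the extracted volume follows ``x = C1/r_b``,
    and the diluted-sample glucose follows the forward dilution chemistry.
    The measurement series is then simulated in the requested mode; in
    dynamic mode the drift curve is rescaled per session so its noiseless
    five-sample mean equals the drawn resistance, keeping ground truth and
    protocol reduction consistent.

    Deterministic given ``seed`` (falling back to ``noise.seed``).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    lo, hi = cb_true_range
    if not (0 < lo <= hi):
        raise ValueError(f"cb_true_range must be positive with lo <= hi, got {cb_true_range!r}")
    if rb_median <= 0 or rb_sigma_log < 0:
        raise ValueError("rb_median must be positive and rb_sigma_log non-negative")
    if mode not in ("static", "dynamic"):
        raise ValueError(f"mode must be 'static' or 'dynamic', got {mode!r}")
    if mode == "dynamic" and drift is None:
        raise ValueError("dynamic mode requires drift parameters")

    noise = noise if noise is not None else NoiseParams()
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    if base_net is None:
        # generic permeabilised-forearm site; lateral paths absent
        base_net = ElectrodeNetwork(r_a=100.0, r_b=100.0, r_c=100.0, r_1=20.0, r_2=20.0)

    sessions: list[ExtractionSession] = []
    for i in range(n_sessions):
        cb = float(rng.uniform(lo, hi))
        ci = cb / cfg.k
        r_b = float(rb_median * np.exp(rb_sigma_log * rng.standard_normal()))
        x = skin.c1 / r_b
        cs = diluted_concentration(ci, x, cfg)
        if not cs < ci:
            raise RuntimeError(
                f"infeasible session: diluted concentration {cs} not below ISF glucose {ci}"
            )
        net = base_net.with_rb(r_b)
        if mode == "static":
            series = simulate_static_session(net, noise, recovery_factor,
                                             t_extract=cfg.t_extract, rng=rng)
        else:
            assert drift is not None
            scale = r_b / _trajectory_mean(drift, DYNAMIC_SAMPLE_TIMES)
            series = simulate_dynamic_session(net, drift.scaled(scale), noise, rng=rng)
        if not series.valid:
            raise RuntimeError(f"session {i}: all inversions flagged invalid")
        sessions.append(ExtractionSession(
            r_skin=series.reduced_r,
            cs=cs,
            session_id=f"s{i:04d}",
            mode=mode,
            x_isf=x,
            ci=ci,
            cb_true=cb,
            series=series,
        ))
    return sessions


def flag_gross_errors(values, n_mads: float = 3.0) -> np.ndarray:
    """Flag replicate reduced values deviating more than ``n_mads`` MADs.

    A simple median-absolute-deviation screen for gross errors among
    replicate reduced resistances; with zero MAD (all-but-one identical)
    any deviation from the median is flagged.
    """
    arr = np.asarray(values, dtype=float)
    med = np.median(arr)
    mad = np.median(np.abs(arr - med))
    if mad == 0:
        return np.abs(arr - med) > 0
    return np.abs(arr - med) > n_mads * mad
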