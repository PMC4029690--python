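"""Three-electrode skin resistance network: forward model and inversion.

The skin under and between three surface electrodes (A, B, C) is treated as a
pure-resistance network of seven elements:

* ``r_a``, ``r_b``, ``r_c`` — longitudinal epidermal resistances under each
  electrode (current crossing the epidermis into deeper tissue);
* ``r_1``, ``r_2`` — subepidermal tissue resistances between B–C and A–B;
* ``r_3``, ``r_4`` — lateral epidermal resistances along the skin surface
  between B–C and A–B.

Measuring the resistance between each pair of electrodes (with the third
electrode switched out) gives three observables R_AB, R_BC, R_AC.  Because the
lateral epidermal resistances are very large, each pairwise measurement is
approximately the series sum of the two longitudinal branches plus the
subepidermal link, and the longitudinal resistance under the central electrode
B is recovered as

    R_B = (R_AB + R_BC - R_AC) / 2

This module implements the exact two-branch (series || lateral) forward model,
the large-lateral approximation, the inversion above, and the signed bias of
the inversion when the lateral paths are finite.

Units: kilo-ohms (kΩ) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ElectrodeNetwork",
    "PairwiseResistances",
    "LongitudinalEstimate",
    "pairwise_full",
    "pairwise_approx",
    "estimate_rb",
    "estimator_bias",
]


def _require_positive_finite(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class ElectrodeNetwork:
    """Seven-resistor skin model under and between electrodes A, B, C.

    ``r_3`` / ``r_4`` set to ``None`` flag an absent (effectively infinite)
    lateral path; this is an explicit flag, not a numeric sentinel, so the
    approximate and full forward models stay distinguishable.
    """

    r_a: float
    r_b: float
    r_c: float
    r_1: float
    r_2: float
    r_3: float | None = None
    r_4: float | None = None

    def __post_init__(self) -> None:
        for name in ("r_a", "r_b", "r_c", "r_1", "r_2"):
            _require_positive_finite(name, getattr(self, name))
        for name in ("r_3", "r_4"):
            value = getattr(self, name)
            if value is not None:
                _require_positive_finite(name, value)

    @property
    def lateral_infinite(self) -> bool:
        """True when both lateral epidermal paths are flagged absent."""
        return self.r_3 is None and self.r_4 is None

    def with_rb(self, r_b: float) -> "ElectrodeNetwork":
        """Copy of this network with the central longitudinal resistance replaced."""
        return ElectrodeNetwork(self.r_a, r_b, self.r_c, self.r_1, self.r_2, self.r_3, self.r_4)


@dataclass(frozen=True)
class PairwiseResistances:
    """The three measurable electrode-pair resistances (kΩ)."""

    r_ab: float
    r_bc: float
    r_ac: float

    def __post_init__(self) -> None:
        for name in ("r_ab", "r_bc", "r_ac"):
            _require_positive_finite(name, getattr(self, name))


@dataclass(frozen=True)
class LongitudinalEstimate:
    """Result of inverting pairwise measurements to the resistance under B.

    ``valid`` is False when the (R_AB + R_BC - R_AC)/2 combination is
    non-positive — possible for noisy field triples — so downstream code can
    drop flagged estimates instead of handling exceptions.
    """

    r_b_hat: float
    valid: bool


def _parallel(p: float, q: float) -> float:
    return p * q / (p + q)


def pairwise_approx(net: ElectrodeNetwork) -> PairwiseResistances:
    """Pairwise resistances in the large-lateral-resistance limit.

    Each measurement is the plain series sum of its longitudinal branch:
    R_AB = R_A + R_2 + R_B, R_BC = R_B + R_1 + R_C,
    R_AC = R_A + R_2 + R_1 + R_C.  These satisfy
    R_AB + R_BC - R_AC = 2 R_B exactly, so the inversion is exact.
    """
    return PairwiseResistances(
        r_ab=net.r_a + net.r_2 + net.r_b,
        r_bc=net.r_b + net.r_1 + net.r_c,
        r_ac=net.r_a + net.r_2 + net.r_1 + net.r_c,
    )


def pairwise_full(net: ElectrodeNetwork) -> PairwiseResistances:
    """Pairwise resistances with finite lateral epidermal paths.

    During each pairwise measurement the third electrode is switched out, so
    its longitudinal branch carries no current and the circuit reduces to the
    deep series branch in parallel with the lateral surface path:

        R_AB = (R_A + R_2 + R_B) || R_4
        R_BC = (R_B + R_1 + R_C) || R_3
        R_AC = (R_A + R_2 + R_1 + R_C) || (R_3 + R_4)

    Networks with both lateral paths flagged absent fall back to
    :func:`pairwise_approx` (parallel with an open path is the identity).
    """
    if net.lateral_infinite:
        return pairwise_approx(net)
    if net.r_3 is None or net.r_4 is None:
        raise ValueError("r_3 and r_4 must both be finite or both flagged absent")
    return PairwiseResistances(
        r_ab=_parallel(net.r_a + net.r_2 + net.r_b, net.r_4),
        r_bc=_parallel(net.r_b + net.r_1 + net.r_c, net.r_3),
        r_ac=_parallel(net.r_a + net.r_2 + net.r_1 + net.r_c, net.r_3 + net.r_4),
    )


def estimate_rb(meas: PairwiseResistances) -> LongitudinalEstimate:
    """Invert pairwise measurements to the longitudinal resistance under B.

    Computes (R_AB + R_BC - R_AC)/2.  A non-positive result is returned
    flagged invalid rather than raised: noisy triples can violate the
    triangle-like constraint and consumers must be able to drop them.
    """
    r_b_hat = (meas.r_ab + meas.r_bc - meas.r_ac) / 2.0
    return LongitudinalEstimate(r_b_hat=r_b_hat, valid=r_b_hat > 0)


def estimator_bias(net: ElectrodeNetwork) -> float:
    """Signed bias (kΩ) of the series-sum inversion under finite lateral paths.

    Returns ``estimate_rb(pairwise_full(net)).r_b_hat - net.r_b``; zero when
    the lateral paths are flagged absent.
    """
    return estimate_rb(pairwise_full(net)).r_b_hat - net.r_b
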