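"""Dry-matter carbon isotope composition and discrimination.

The 13C/12C composition of plant material is expressed relative to the Pee
Dee Belemnite (PDB) standard, delta_p = Rp/Rs - 1, where Rp and Rs are the
molar 13C/12C abundance ratios of the plant sample and the standard.
Discrimination against 13C during carbon fixation is

    Delta = Ra/Rp - 1 = (delta_a - delta_p) / (1 + delta_p)

with Ra the ratio in air and delta_a the composition of free atmospheric
CO2 on the PDB scale (about -8 permil).  Delta is a diagnostic of the
carbon-fixation pathway: C4 leaves discriminate far less than C3 leaves.

All API values are dimensionless fractions; use :func:`permil` /
:func:`from_permil` at the boundary to avoid the classic 1000x error.
"""

from __future__ import annotations

DELTA_A_DEFAULT = -0.008  # atmospheric CO2 composition on the PDB scale


class IsotopeError(ValueError):
    pass


def permil(fraction: float) -> float:
    """Fraction -> permil (presentation only)."""
    return fraction * 1000.0


def from_permil(value_permil: float) -> float:
    """Permil -> fraction."""
    return value_permil / 1000.0


def delta_from_ratio(rp: float, rs: float) -> float:
    """Isotopic composition delta_p = Rp/Rs - 1 (dimensionless fraction)."""
    if rp <= 0 or rs <= 0:
        raise IsotopeError("molar abundance ratios must be positive")
    return rp / rs - 1.0


def ratio_from_delta(delta: float, rs: float) -> float:
    """Inverse of :func:`delta_from_ratio`: Rp = (1 + delta) * Rs."""
    if rs <= 0:
        raise IsotopeError("molar abundance ratios must be positive")
    if delta <= -1.0:
        raise IsotopeError("delta must exceed -1")
    return (1.0 + delta) * rs


def discrimination(delta_a: float, delta_p: float) -> float:
    """Carbon isotope discrimination Delta = (delta_a - delta_p)/(1 + delta_p).

    Algebraically identical to Ra/Rp - 1 when both deltas are expressed
    against the same standard.  Inputs and output are fractions.
    """
    if delta_p <= -1.0 or delta_a <= -1.0:
        raise IsotopeError("delta values must exceed -1")
    return (delta_a - delta_p) / (1.0 + delta_p)
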