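"""Phenotype-side statistics: fluorescence parameters, the Fv/Fm phenotype
cutoff, Mendelian segregation testing, and the analytic pooled
allele-frequency expectations for a selfed-F1 (BC1F2) design.

The mapping population is produced by backcrossing a homozygous recessive
mutant to wild type and selfing the F1.  At the causal locus the BC1F2
segregates 1 mm : 2 Mm : 1 MM, so the recessive phenotype appears in 1/4 of
the progeny, a phenotype-selected mutant bulk is fixed for the mutant
allele, and a bulk of non-mutant segregants (the "azygous" pool: 1 MM : 2
Mm) carries the mutant allele at frequency 1/3.  For a marker at
recombination fraction r from the causal locus these expectations become
1 - r (mutant pool) and (1 + r)/3 (azygous pool); a wild-type pool carries
the mutant allele at frequency 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps


class ValidationError(ValueError):
    """An input violated a stated invariant; the message names the field."""


# ---------------------------------------------------------------------------
# Chlorophyll fluorescence parameters
# ---------------------------------------------------------------------------

@dataclass
class FluorRecord:
    """Raw fluorescence intensities (arbitrary units).

    Dark-adapted: minimal ``fo`` and maximal ``fm``.
    Light-adapted: steady-state ``fp`` (F'), minimal ``fop`` (Fo') and
    maximal ``fmp`` (Fm').  Any subset may be present; each derived
    parameter is computed only when its inputs are.
    """

    fo: float | None = None
    fm: float | None = None
    fp: float | None = None
    fop: float | None = None
    fmp: float | None = None

    def validate(self) -> None:
        if self.fo is not None and self.fm is not None:
            if not self.fm > self.fo > 0:
                raise ValidationError("fm must exceed fo and both be positive")
        if self.fop is not None and self.fmp is not None:
            if not self.fmp > self.fop > 0:
                raise ValidationError("fmp must exceed fop and both be positive")
        if self.fp is not None and self.fmp is not None:
            if self.fp > self.fmp:
                raise ValidationError("fp must not exceed fmp")


def fluorescence_params(rec: FluorRecord) -> dict[str, float]:
    """Standard PSII parameters from raw F-values.

    fvfm       = (Fm - Fo)/Fm       maximum quantum efficiency of PSII
    fvfm_prime = (Fm' - Fo')/Fm'    maximum PSII efficiency in the light
    phi_psii   = (Fm' - F')/Fm'     PSII operating efficiency
    qP         = (Fm' - F')/(Fm' - Fo')   photochemical quenching
    npq        = Fm/Fm' - 1         non-photochemical quenching
    """
    rec.validate()
    out: dict[str, float] = {}
    if rec.fo is not None and rec.fm is not None:
        out["fvfm"] = (rec.fm - rec.fo) / rec.fm
    if rec.fop is not None and rec.fmp is not None:
        out["fvfm_prime"] = (rec.fmp - rec.fop) / rec.fmp
    if rec.fp is not None and rec.fmp is not None:
        out["phi_psii"] = (rec.fmp - rec.fp) / rec.fmp
    if rec.fp is not None and rec.fop is not None and rec.fmp is not None:
        out["qP"] = (rec.fmp - rec.fp) / (rec.fmp - rec.fop)
    if rec.fm is not None and rec.fmp is not None:
        out["npq"] = rec.fm / rec.fmp - 1.0
    return out


def classify_phenotype(fvfm: float, cutoff: float = 0.6) -> str:
    """Classify an individual as ``"mutant"`` or ``"wildtype-like"``.

    The mutant class is strictly below the cutoff; an individual exactly at
    the boundary is called wild-type-like (the mutant phenotype is a
    *reduced* Fv/Fm).
    """
    if not 0.0 < fvfm < 1.0:
        raise ValidationError("fvfm must lie in (0, 1)")
    return "mutant" if fvfm < cutoff else "wildtype-like"


# ---------------------------------------------------------------------------
# Mendelian segregation
# ---------------------------------------------------------------------------

@dataclass
class SegregationResult:
    n_mutant: int
    n_total: int
    observed_fraction: float
    chi_square: float
    p_value: float


def segregation_test(
    n_mutant: int,
    n_total: int,
    expected_fraction: float = 0.25,
    yates: bool = False,
) -> SegregationResult:
    """Pearson chi-square test of a segregation ratio (1 df).

    Tests observed mutant counts against the two-class expectation
    (expected_fraction, 1 - expected_fraction); the default 0.25 is the
    single-recessive-locus ratio.  No continuity correction by default
    (population scale n ~ 300); set ``yates=True`` to apply it.  The
    p-value is the upper tail of the 1-df chi-square distribution
    (``scipy.stats.chi2.sf``, the regularized incomplete gamma function).
    """
    if not 0 <= n_mutant <= n_total or n_total < 1:
        raise ValidationError("need 0 <= n_mutant <= n_total and n_total >= 1")
    expected = (expected_fraction * n_total, (1 - expected_fraction) * n_total)
    observed = (n_mutant, n_total - n_mutant)
    chi2 = 0.0
    for obs, exp in zip(observed, expected):
        diff = abs(obs - exp)
        if yates:
            diff = max(diff - 0.5, 0.0)
        chi2 += diff * diff / exp
    return SegregationResult(
        n_mutant=n_mutant,
        n_total=n_total,
        observed_fraction=n_mutant / n_total,
        chi_square=chi2,
        p_value=float(sps.chi2.sf(chi2, df=1)),
    )


# ---------------------------------------------------------------------------
# Analytic pooled allele-frequency expectations
# ---------------------------------------------------------------------------

def expected_pool_af(pool: str, r: float = 0.0) -> float:
    """Expected mutant-allele frequency in a phenotype-selected pool.

    ``pool`` is one of ``"mutant"`` (homozygous-mutant bulk), ``"azygous"``
    (non-mutant segregant bulk) or ``"wildtype"``; ``r`` is the
    recombination fraction between the scored marker and the causal locus.
    Assumes a selfed F1 carrying the mutant haplotype in coupling, a single
    recessive causal locus and perfect phenotype selection.

    mutant   -> 1 - r
    azygous  -> (1 + r)/3
    wildtype -> 0
    """
    if not 0.0 <= r <= 0.5:
        raise ValidationError("recombination fraction r must lie in [0, 0.5]")
    if pool == "mutant":
        return 1.0 - r
    if pool == "azygous":
        return (1.0 + r) / 3.0
    if pool == "wildtype":
        return 0.0
    raise ValidationError(f"unknown pool {pool!r}")
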