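"""Omics-derived rate-constant formulas for gene-expression modules.

These four closed forms tie measured abundances (mRNA copies per cell,
protein concentration) and turnover (half-lives) to the first-order
rate constants of a transcription/translation/degradation module, such
that the measured state is the analytic steady state of the module:

* degradation rates are ``ln 2 / half-life``;
* the basal transcription rate compensates mRNA degradation at the
  measured mRNA count, given the equilibrium active-gene fraction;
* the translation rate compensates protein degradation at the measured
  protein concentration, given the measured mRNA concentration.

Half-lives are supplied in hours and converted to per-second rates at
this boundary; everything downstream runs in seconds.
"""

from __future__ import annotations

import math

from .units import SECONDS_PER_HOUR

LN2 = math.log(2.0)


def mrna_degradation_rate(half_life_h: float) -> float:
    """First-order mRNA degradation rate kTCd (1/s) from a half-life in hours."""
    if not half_life_h > 0:
        raise ValueError(f"mRNA half-life must be positive, got {half_life_h}")
    return LN2 / (half_life_h * SECONDS_PER_HOUR)


def protein_degradation_rate(half_life_h: float) -> float:
    """First-order protein degradation rate kTLd (1/s) from a half-life in hours.

    An infinite half-life (a protein treated as stable) maps to rate 0.
    """
    if not half_life_h > 0:
        raise ValueError(f"protein half-life must be positive, got {half_life_h}")
    if math.isinf(half_life_h):
        return 0.0
    return LN2 / (half_life_h * SECONDS_PER_HOUR)


def basal_transcription_rate(
    kTCd: float, mRNA_count: float, kG_in: float, kG_ac: float, gene_copy_number: float
) -> float:
    """Basal transcription rate kTC_basal (molecules/s per active gene copy).

    ``kTC_basal = (kTCd * mRNA_count) * (kG_in + kG_ac) / (kG_ac * GCN)``.

    With the gene on/off process at its equilibrium fraction
    ``kG_ac/(kG_ac+kG_in)``, the mRNA ODE
    ``dm/dt = kTC_basal * g_active - kTCd * m`` then has fixed point
    ``m* = mRNA_count`` exactly.
    """
    if kG_ac <= 0:
        raise ValueError("kG_ac must be > 0 (division by zero in basal rate)")
    if gene_copy_number <= 0:
        raise ValueError("gene copy number must be > 0")
    return (kTCd * mRNA_count) * (kG_in + kG_ac) / (kG_ac * gene_copy_number)


def translation_rate(
    protein_conc_nm: float,
    kTLd: float,
    mrna_conc_nm: float,
    mrna_floor_nm: float | None = None,
) -> float:
    """Translation rate kTL (1/s) = protein_conc * kTLd / mRNA_conc.

    Guarantees protein steady state equals ``protein_conc_nm`` when mRNA
    sits at ``mrna_conc_nm``.  A zero protein concentration gives kTL=0.
    Zero mRNA is a hard error unless ``mrna_floor_nm`` explicitly
    permits flooring (to avoid a silently infinite rate).
    """
    if protein_conc_nm == 0:
        return 0.0
    if mrna_conc_nm <= 0:
        if mrna_floor_nm is None:
            raise ValueError(
                f"mRNA concentration must be > 0 to set a translation rate "
                f"(got {mrna_conc_nm}); pass mrna_floor_nm to floor instead"
            )
        mrna_conc_nm = mrna_floor_nm
    return protein_conc_nm * kTLd / mrna_conc_nm
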