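"""Allelic-skew quantification at heterozygous candidate sites.

At a heterozygous site, RNA reads should split roughly 50:50 between
alleles; a strong departure (e.g. 97% of reads from one allele) is
evidence of nonsense-mediated decay or transcriptional silencing of the
other allele.  Skew is reported toward whichever allele dominates — the
caller annotates which allele carries the candidate variant — with an
exact two-sided binomial test against 0.5 (depths are small, so no normal
approximation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy.stats import binomtest

from rnadx.formats import AlleleCountRecord

MIN_DEPTH = 20


@dataclass(frozen=True)
class AlleleSkew:
    record: AlleleCountRecord
    total_depth: int
    ref_fraction: Optional[float]
    skew: Optional[float]  # max(ref_fraction, 1 - ref_fraction); in [0.5, 1]
    skewed_allele: Optional[str]  # "ref" or "alt"
    p_value: Optional[float]  # exact two-sided binomial vs 0.5
    passes_depth: bool


def allele_skew(record: AlleleCountRecord, min_depth: int = MIN_DEPTH) -> AlleleSkew:
    """Quantify allelic imbalance at one site.

    Zero total depth yields undefined skew and ``passes_depth`` False.
    Equal counts report the ref allele as "skewed" by convention
    (skew = 0.5, p = 1).
    """
    total = record.ref_reads + record.alt_reads
    if total == 0:
        return AlleleSkew(record, 0, None, None, None, None, False)
    ref_fraction = record.ref_reads / total
    # computed from the dominant count so that swapping ref/alt is exact
    skew = max(record.ref_reads, record.alt_reads) / total
    skewed = "ref" if ref_fraction >= 0.5 else "alt"
    p = binomtest(record.ref_reads, total, 0.5, alternative="two-sided").pvalue
    return AlleleSkew(
        record=record,
        total_depth=total,
        ref_fraction=ref_fraction,
        skew=skew,
        skewed_allele=skewed,
        p_value=float(p),
        passes_depth=total >= min_depth,
    )
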