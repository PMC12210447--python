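"""Per-sample splice-junction usage scores.

The usage score of a junction is the ratio of reads mapping to it over all
junction reads sharing its donor (or acceptor) splice site.  Both the
donor- and acceptor-normalized ratios are computed; the primary ``score``
is their minimum, the most conservative usage estimate — a junction is
low-usage as soon as either of its splice sites has a dominant competitor.

Denominators are always computed on the *unfiltered* junction set of the
sample; the minimum-read filter only gates which junctions are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from rnadx.formats import SpliceJunction

logger = logging.getLogger("rnadx")

MIN_UNIQUE_READS = 5  # junctions with >= 5 uniquely mapped reads are considered


@dataclass(frozen=True)
class JunctionScore:
    junction_key: tuple[str, int, int, str]
    donor_score: Optional[float]  # None when the donor-site total is 0
    acceptor_score: Optional[float]
    score: float  # min of the defined side scores
    donor_total_reads: int
    acceptor_total_reads: int
    unique_reads: int
    annotated: bool

    @property
    def donor_site(self) -> tuple[str, int, str]:
        chrom, start, end, strand = self.junction_key
        return (chrom, start if strand != "-" else end, strand)

    @property
    def acceptor_site(self) -> tuple[str, int, str]:
        chrom, start, end, strand = self.junction_key
        return (chrom, end if strand != "-" else start, strand)


def filter_junctions(
    junctions: Iterable[SpliceJunction], min_unique: int = MIN_UNIQUE_READS
) -> list[SpliceJunction]:
    """Keep junctions with at least ``min_unique`` uniquely mapped reads."""
    if min_unique < 0:
        raise ValueError("min_unique must be >= 0")
    return [j for j in junctions if j.unique_reads >= min_unique]


def site_totals(
    junctions: Iterable[SpliceJunction],
) -> tuple[dict[tuple[str, int, str], int], dict[tuple[str, int, str], int]]:
    """Total unique reads at each donor and each acceptor splice site."""
    donor: dict[tuple[str, int, str], int] = {}
    acceptor: dict[tuple[str, int, str], int] = {}
    for j in junctions:
        donor[j.donor_site] = donor.get(j.donor_site, 0) + j.unique_reads
        acceptor[j.acceptor_site] = acceptor.get(j.acceptor_site, 0) + j.unique_reads
    return donor, acceptor


def score_junctions(
    junctions: list[SpliceJunction],
    min_unique: int = MIN_UNIQUE_READS,
) -> list[JunctionScore]:
    """Compute usage scores for one sample's junctions.

    ``min_unique`` gates which junctions get a reported score; the
    donor/acceptor totals in the denominators always use every junction
    passed in.  A junction whose both site totals are zero (possible only
    when its own read count is zero) is dropped with a warning.
    """
    donor_tot, acceptor_tot = site_totals(junctions)
    scores: list[JunctionScore] = []
    for j in filter_junctions(junctions, min_unique):
        dt = donor_tot[j.donor_site]
        at = acceptor_tot[j.acceptor_site]
        ds = j.unique_reads / dt if dt > 0 else None
        as_ = j.unique_reads / at if at > 0 else None
        defined = [s for s in (ds, as_) if s is not None]
        if not defined:
            logger.warning("junction %s has zero site totals; dropped", j.key)
            continue
        scores.append(
            JunctionScore(
                junction_key=j.key,
                donor_score=ds,
                acceptor_score=as_,
                score=min(defined),
                donor_total_reads=dt,
                acceptor_total_reads=at,
                unique_reads=j.unique_reads,
                annotated=j.annotated,
            )
        )
    return scores
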