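"""Classification of junction Z-records and hypothesis-driven region queries.

A junction with |Z| >= 3 against the control cohort is *aberrant* and falls
into exactly one of three classes:

* ``novel`` — unannotated, essentially undetected in controls, usage
  increased (a patient-specific junction);
* ``missing`` — annotated junction whose usage is strongly decreased;
* ``outlier`` — any other significant deviation (annotated-with-increase,
  or an unannotated junction controls do use, in either direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from rnadx.cohort import JunctionZ
from rnadx.expression import ExpressionOutlier
from rnadx.formats import CandidateRegion, GeneModel

Z_MIN = 3.0
NOVEL_DETECTION_MAX = 0.05  # below this cohort detection fraction = "not detected"
REGION_FLANK = 500  # bp beyond the candidate region; splice effects can land one exon away

CLASSES = ("novel", "missing", "outlier")


@dataclass(frozen=True)
class AberrantJunction:
    junction_z: JunctionZ
    klass: str  # novel | missing | outlier
    direction: str  # increased | decreased
    gene_ids: tuple[str, ...] = ()

    @property
    def junction_key(self):
        return self.junction_z.junction_key

    @property
    def z(self) -> float:
        return self.junction_z.z

    @property
    def patient_score(self) -> float:
        return self.junction_z.patient_score


def classify_junctions(
    zs: Iterable[JunctionZ],
    z_min: float = Z_MIN,
    novel_detection_max: float = NOVEL_DETECTION_MAX,
    genes: Optional[Sequence[GeneModel]] = None,
) -> list[AberrantJunction]:
    """Apply the novel/missing/outlier rule table to Z-records.

    Records with |z| < z_min are not emitted; every emitted record receives
    exactly one class.  When ``genes`` is given, each aberrant junction is
    tagged with the genes whose span contains it.
    """
    out: list[AberrantJunction] = []
    for rec in zs:
        if abs(rec.z) < z_min:
            continue
        direction = "increased" if rec.z > 0 else "decreased"
        if (
            not rec.annotated
            and rec.stats.detection_fraction < novel_detection_max
            and direction == "increased"
        ):
            klass = "novel"
        elif rec.annotated and direction == "decreased":
            klass = "missing"
        else:
            klass = "outlier"
        gene_ids = tuple(g.gene_id for g in genes_containing(rec.junction_key, genes)) if genes else ()
        out.append(AberrantJunction(rec, klass, direction, gene_ids))
    return out


def genes_containing(
    junction_key: tuple[str, int, int, str], genes: Sequence[GeneModel]
) -> list[GeneModel]:
    """Genes whose genomic span contains the junction (coordinates only).

    Strand-undefined junctions match genes on either strand.
    """
    chrom, start, end, strand = junction_key
    hits = []
    for g in genes:
        lo, hi = g.span
        if g.chrom != chrom or lo > hi:
            continue
        if strand != "." and g.strand != strand:
            continue
        if lo <= start and end <= hi:
            hits.append(g)
    return hits


class UnknownGeneError(KeyError):
    pass


@dataclass
class RegionReport:
    """Everything the hypothesis-driven review of one candidate region needs."""

    case: CandidateRegion
    aberrant: list[AberrantJunction]
    all_z: list[JunctionZ]  # every junction Z in the region, incl. sub-threshold
    expression: Optional[ExpressionOutlier]
    events: list = field(default_factory=list)  # SplicingEvent records, wired by the caller
    flank: int = REGION_FLANK


def _in_region(key: tuple[str, int, int, str], case: CandidateRegion, flank: int) -> bool:
    chrom, start, end, _ = key
    return (
        chrom == case.chrom
        and start <= case.region_end + flank
        and end >= case.region_start - flank
    )


def region_report(
    case: CandidateRegion,
    aberrant: Iterable[AberrantJunction],
    all_z: Iterable[JunctionZ],
    expression: Iterable[ExpressionOutlier] = (),
    genes: Optional[Mapping[str, GeneModel]] = None,
    flank: int = REGION_FLANK,
    events: Optional[list] = None,
) -> RegionReport:
    """Collect aberrant junctions, all junction Zs and the gene's expression
    status within ``region +/- flank``.

    ``genes``, when provided, is used to verify the case gene is annotated;
    an unknown gene raises :class:`UnknownGeneError` naming the gene_id.
    ``events`` are downstream splicing-event calls for the region (see
    :mod:`rnadx.events`), passed through for reporting.
    """
    if genes is not None and case.gene_id not in genes:
        raise UnknownGeneError(f"gene {case.gene_id} absent from annotation")
    region_aberrant = [a for a in aberrant if _in_region(a.junction_key, case, flank)]
    region_z = [z for z in all_z if _in_region(z.junction_key, case, flank)]
    expr = next((e for e in expression if e.gene_id == case.gene_id), None)
    return RegionReport(
        case=case,
        aberrant=region_aberrant,
        all_z=region_z,
        expression=expr,
        events=list(events or []),
        flank=flank,
    )
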