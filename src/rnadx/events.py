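"""Splicing-event inference and transcript-consequence calls.

Aberrant junctions are translated into concrete splicing events on the
gene's canonical transcript (longest CDS, overridable): exon skipping,
exon extension into an intron, exon truncation, intron retention, novel
exons and tandem-duplication back-junctions.  Coding consequences follow
from coordinate arithmetic: the event's net change in CDS length
(``delta_nt``, counting CDS-overlapping bases only) decides in-frame vs
frameshift by the mod-3 rule, and a premature termination codon found by
conceptual translation of the edited CDS feeds the 55-nt
nonsense-mediated-decay rule.

Coordinate conventions
----------------------
Junctions are 1-based closed intervals over the intron (STAR).  Exon and
intron indices reported in events are 1-based in *transcription* order.
A tandem-duplication back-junction — the split-read junction joining the
donor of the last duplicated exon to the acceptor of the first — is
represented as the junction whose interval runs from one base before the
first duplicated exon's genomic start to one base past the last duplicated
exon's genomic end; this representation is identical for + and - strand
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from rnadx.aberrance import AberrantJunction
from rnadx.formats import CoverageInterval, GeneModel, SpliceJunction, Transcript

logger = logging.getLogger("rnadx")

MIN_DUP_SUPPORT = 5
RETENTION_THRESHOLD = 0.1
NMD_RULE_NT = 55  # PTC > 55 nt upstream of the last exon-exon junction triggers NMD

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

EVENT_TYPES = (
    "exon_skip",
    "exon_extension",
    "exon_truncation",
    "intron_retention",
    "novel_exon",
    "tandem_dup_backjunction",
    "isoform_switch_candidate",
    "unclassified",
)


@dataclass(frozen=True)
class SplicingEvent:
    event_type: str
    gene_id: str
    affected_exons: tuple[int, ...]  # 1-based, transcription order
    delta_nt: int  # signed CDS-length change
    aberrant_fraction: float  # junction usage score of the event junction
    frame: str  # in_frame | frameshift | noncoding
    nmd_predicted: bool = False
    junction: Optional[tuple[str, int, int, str]] = None
    note: str = ""


@dataclass(frozen=True)
class FrameCall:
    frame: str  # in_frame | frameshift | noncoding
    ptc_position: Optional[int] = None  # 0-based, spliced-transcript coords


@dataclass(frozen=True)
class DupCall:
    gene_id: str
    dup_exon_first: int  # transcription order, 1-based
    dup_exon_last: int
    backjunction_key: tuple[str, int, int]
    split_read_support: int
    in_tandem: bool
    in_frame: bool


@dataclass(frozen=True)
class SwitchCandidate:
    gene_id: str
    lost_isoforms: tuple[tuple[str, float], ...]  # (isoform_id, z <= -z_min)
    gained_isoforms: tuple[tuple[str, float], ...]  # (isoform_id, z >= +z_min)

    @property
    def max_abs_z(self) -> float:
        zs = [abs(z) for _, z in self.lost_isoforms + self.gained_isoforms]
        return max(zs) if zs else 0.0


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------


def _tx_index(transcript: Transcript, strand: str, genomic_exon_idx: int) -> int:
    """1-based transcription-order index of a genomically ordered exon."""
    n = len(transcript.exons)
    return genomic_exon_idx + 1 if strand != "-" else n - genomic_exon_idx


def edited_retained_blocks(
    transcript: Transcript, junction: tuple[int, int]
) -> list[tuple[int, int]]:
    """Genomic blocks retained in the mature transcript that uses ``junction``.

    The novel junction removes its own interval from the pre-mRNA.
    Canonical introns disjoint from it are spliced as usual; the parts of
    canonical introns that the junction overlaps but does not cover are
    retained (that is what an exon extension is).
    """
    js, je = junction
    span = (transcript.exons[0][0], transcript.exons[-1][1])
    removed: list[tuple[int, int]] = [(max(js, span[0]), min(je, span[1]))]
    for s, e in transcript.introns():
        if e < js or s > je:  # disjoint canonical intron: spliced out
            removed.append((s, e))
    removed.sort()
    blocks: list[tuple[int, int]] = []
    pos = span[0]
    for s, e in removed:
        if s > pos:
            blocks.append((pos, s - 1))
        pos = max(pos, e + 1)
    if pos <= span[1]:
        blocks.append((pos, span[1]))
    return blocks


def _overlap_len(blocks: Iterable[tuple[int, int]], lo: int, hi: int) -> int:
    total = 0
    for s, e in blocks:
        a, b = max(s, lo), min(e, hi)
        if a <= b:
            total += b - a + 1
    return total


def cds_delta_nt(transcript: Transcript, junction: tuple[int, int]) -> int:
    """Signed CDS-length change of the transcript that uses ``junction``."""
    if not transcript.coding:
        return 0
    lo, hi = transcript.cds_start, transcript.cds_end
    edited = _overlap_len(edited_retained_blocks(transcript, junction), lo, hi)
    canonical = _overlap_len(transcript.exons, lo, hi)
    return edited - canonical


# ---------------------------------------------------------------------------
# event inference
# ---------------------------------------------------------------------------


def infer_events(
    aberrant: Sequence[AberrantJunction],
    model: GeneModel,
    transcript_id: Optional[str] = None,
    retention_ratios: Optional[Mapping[int, float]] = None,
    retention_threshold: float = RETENTION_THRESHOLD,
) -> list[SplicingEvent]:
    """Pattern-match aberrant junctions onto the canonical transcript.

    ``retention_ratios`` maps transcription-order intron index to the
    intron-retention coverage ratio (see :func:`intron_retention_ratio`);
    a *missing* annotated junction whose intron exceeds the threshold
    becomes an intron_retention event.  Junctions that fit no pattern are
    emitted as ``unclassified`` with an explanatory note.
    """
    tx = model.canonical_transcript(transcript_id)
    strand = model.strand
    exons = tx.exons
    introns = tx.introns()
    # genomic coordinate -> genomic intron index
    intron_start_idx = {s: i for i, (s, e) in enumerate(introns)}
    intron_end_idx = {e: i for i, (s, e) in enumerate(introns)}
    exon_start_idx = {s: i for i, (s, e) in enumerate(exons)}
    exon_end_idx = {e: i for i, (s, e) in enumerate(exons)}

    def exon_at(pos: int) -> Optional[int]:
        for i, (s, e) in enumerate(exons):
            if s <= pos <= e:
                return i
        return None

    def intron_at(pos: int) -> Optional[int]:
        for i, (s, e) in enumerate(introns):
            if s <= pos <= e:
                return i
        return None

    def frame_of(delta: int, junction: tuple[int, int]) -> str:
        if not tx.coding:
            return "noncoding"
        touches_cds = delta != 0 or _overlap_len(
            [junction], tx.cds_start, tx.cds_end
        ) > 0
        if not touches_cds:
            return "noncoding"
        return "in_frame" if delta % 3 == 0 else "frameshift"

    events: list[SplicingEvent] = []
    for ab in aberrant:
        chrom, js, je, jstrand = ab.junction_key
        fraction = min(max(ab.patient_score, 0.0), 1.0)
        if chrom != model.chrom:
            events.append(
                SplicingEvent(
                    "unclassified", model.gene_id, (), 0, fraction, "noncoding",
                    junction=ab.junction_key, note="junction on another chromosome",
                )
            )
            continue

        gi_start = intron_start_idx.get(js)
        gi_end = intron_end_idx.get(je)

        # exact annotated intron of the canonical transcript
        if gi_start is not None and gi_start == gi_end:
            tx_intron = _tx_intron_index(tx, strand, gi_start)
            ratio = (retention_ratios or {}).get(tx_intron)
            if ab.klass == "missing" and ratio is not None and ratio > retention_threshold:
                delta = _overlap_len([introns[gi_start]], tx.cds_start or 0, tx.cds_end or -1) if tx.coding else 0
                events.append(
                    SplicingEvent(
                        "intron_retention", model.gene_id,
                        _flanking_exons(tx, strand, gi_start),
                        delta, min(ratio, 1.0),
                        frame_of(delta, (js, je)),
                        junction=ab.junction_key,
                        note=f"intron {tx_intron} retained (ratio {ratio:.2f})",
                    )
                )
            else:
                events.append(
                    SplicingEvent(
                        "unclassified", model.gene_id,
                        _flanking_exons(tx, strand, gi_start), 0, fraction,
                        "noncoding", junction=ab.junction_key,
                        note=f"annotated junction usage {ab.klass}/{ab.direction}",
                    )
                )
            continue

        # tandem-duplication back-junction: ends sit one base *outside*
        # exon boundaries, inverted relative to a normal intron
        ei_after = exon_start_idx.get(js + 1)
        ei_before = exon_end_idx.get(je - 1)
        if ei_after is not None and ei_before is not None and ei_after <= ei_before:
            dup = exons[ei_after : ei_before + 1]
            delta = (
                sum(_overlap_len([ex], tx.cds_start, tx.cds_end) for ex in dup)
                if tx.coding
                else 0
            )
            idxs = sorted(
                _tx_index(tx, strand, i) for i in range(ei_after, ei_before + 1)
            )
            events.append(
                SplicingEvent(
                    "tandem_dup_backjunction", model.gene_id, tuple(idxs),
                    delta, fraction, frame_of(delta, (js, je)),
                    junction=ab.junction_key,
                    note="back-junction consistent with a tandem duplication",
                )
            )
            continue

        # exon skip: both ends on annotated splice sites of different introns
        if gi_start is not None and gi_end is not None and gi_end > gi_start:
            skipped = range(gi_start + 1, gi_end + 1)  # genomic exon indices
            delta = -(
                sum(
                    _overlap_len([exons[i]], tx.cds_start, tx.cds_end)
                    for i in skipped
                )
                if tx.coding
                else 0
            )
            idxs = sorted(_tx_index(tx, strand, i) for i in skipped)
            events.append(
                SplicingEvent(
                    "exon_skip", model.gene_id, tuple(idxs), delta, fraction,
                    frame_of(delta, (js, je)), junction=ab.junction_key,
                )
            )
            continue

        # one end annotated, the other inside an intron or exon
        if gi_start is not None or gi_end is not None:
            if gi_start is not None:  # junction start matches intron gi_start
                gi = gi_start
                novel = je
            else:
                gi = gi_end
                novel = js
            delta = cds_delta_nt(tx, (js, je))
            in_intron = intron_at(novel) == gi
            if in_intron:
                # the exon beyond the novel end extends into the intron
                ex_g = gi + 1 if gi_start is not None else gi
                events.append(
                    SplicingEvent(
                        "exon_extension", model.gene_id,
                        (_tx_index(tx, strand, ex_g),), delta, fraction,
                        frame_of(delta, (js, je)), junction=ab.junction_key,
                    )
                )
                continue
            ex_idx = exon_at(novel)
            if ex_idx is not None:
                events.append(
                    SplicingEvent(
                        "exon_truncation", model.gene_id,
                        (_tx_index(tx, strand, ex_idx),), delta, fraction,
                        frame_of(delta, (js, je)), junction=ab.junction_key,
                    )
                )
                continue

        # both ends novel inside the same intron: a novel exon boundary pair
        ii_s, ii_e = intron_at(js), intron_at(je)
        if ii_s is not None and ii_s == ii_e:
            delta = cds_delta_nt(tx, (js, je))
            events.append(
                SplicingEvent(
                    "novel_exon", model.gene_id,
                    _flanking_exons(tx, strand, ii_s), delta, fraction,
                    frame_of(delta, (js, je)), junction=ab.junction_key,
                    note="novel splice sites within one intron",
                )
            )
            continue

        events.append(
            SplicingEvent(
                "unclassified", model.gene_id, (), 0, fraction, "noncoding",
                junction=ab.junction_key,
                note="junction not attributable to the canonical transcript",
            )
        )
    return events


def _tx_intron_index(tx: Transcript, strand: str, genomic_intron_idx: int) -> int:
    n = len(tx.introns())
    return genomic_intron_idx + 1 if strand != "-" else n - genomic_intron_idx


def _flanking_exons(tx: Transcript, strand: str, genomic_intron_idx: int) -> tuple[int, ...]:
    return tuple(
        sorted(
            (
                _tx_index(tx, strand, genomic_intron_idx),
                _tx_index(tx, strand, genomic_intron_idx + 1),
            )
        )
    )


# ---------------------------------------------------------------------------
# frame consequence and NMD
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _spliced_cds(
    tx: Transcript,
    strand: str,
    blocks: Sequence[tuple[int, int]],
    chrom_seq: str,
) -> str:
    """CDS nucleotides of the transcript built from genomic ``blocks``."""
    parts = []
    for s, e in blocks:
        lo, hi = max(s, tx.cds_start), min(e, tx.cds_end)
        if lo <= hi:
            parts.append(chrom_seq[lo - 1 : hi])
    seq = "".join(parts)
    return _revcomp(seq) if strand == "-" else seq


def frame_consequence(
    model: GeneModel,
    event: SplicingEvent,
    transcript_id: Optional[str] = None,
    genome: Optional[Mapping[str, str]] = None,
) -> FrameCall:
    """In-frame / frameshift / noncoding call for a splicing event.

    ``delta_nt`` counts CDS-overlapping bases only, so the mod-3 rule
    applies directly; events entirely in the UTR are noncoding.  When a
    genome sequence is supplied and the event carries its junction, the
    premature stop of the shifted frame is located by conceptually
    translating the edited spliced CDS (position reported 0-based in
    edited spliced-transcript coordinates).
    """
    tx = model.canonical_transcript(transcript_id)
    if not tx.coding or event.frame == "noncoding":
        return FrameCall("noncoding")
    frame = "in_frame" if event.delta_nt % 3 == 0 else "frameshift"
    ptc = None
    if frame == "frameshift" and genome is not None and event.junction is not None:
        chrom_seq = genome.get(model.chrom)
        if chrom_seq is not None:
            _, js, je, _ = event.junction
            blocks = edited_retained_blocks(tx, (js, je))
            cds = _spliced_cds(tx, model.strand, blocks, chrom_seq)
            for i in range(0, len(cds) - 2, 3):
                if cds[i : i + 3].upper() in STOP_CODONS:
                    # offset of the CDS start within the edited transcript
                    utr5 = _transcript_offset_of_cds(tx, model.strand, blocks)
                    ptc = utr5 + i
                    break
    return FrameCall(frame, ptc)


def _transcript_offset_of_cds(
    tx: Transcript, strand: str, blocks: Sequence[tuple[int, int]]
) -> int:
    """Length of the 5' UTR in the edited spliced transcript."""
    if strand != "-":
        return _overlap_len(blocks, blocks[0][0], tx.cds_start - 1)
    return _overlap_len(blocks, tx.cds_end + 1, blocks[-1][1])


def nmd_rule(
    model: GeneModel,
    ptc_position: Optional[int],
    transcript_id: Optional[str] = None,
) -> bool:
    """55-nt rule: NMD is predicted when the premature stop lies more than
    55 nt upstream of the transcript's last exon-exon junction.

    ``ptc_position`` is 0-based in spliced-transcript coordinates.
    Single-exon transcripts never trigger NMD.
    """
    if ptc_position is None:
        return False
    tx = model.canonical_transcript(transcript_id)
    if len(tx.exons) < 2:
        return False
    lengths = [e - s + 1 for s, e in tx.exons]
    if model.strand == "-":
        lengths = lengths[::-1]
    last_junction = sum(lengths[:-1])  # spliced coordinate of the final junction
    return last_junction - ptc_position > NMD_RULE_NT


# ---------------------------------------------------------------------------
# tandem duplications
# ---------------------------------------------------------------------------


def detect_tandem_dup(
    junctions: Sequence[SpliceJunction],
    model: GeneModel,
    dup_region: tuple[int, int],
    min_support: int = MIN_DUP_SUPPORT,
    transcript_id: Optional[str] = None,
) -> DupCall:
    """Confirm a candidate duplication as tandem via its back-junction.

    The back-junction joins the donor of the 3'-most duplicated exon to the
    acceptor of the 5'-most duplicated exon (transcription order); in
    genomic coordinates it runs "backwards", so it is stored as the
    interval [first dup exon start - 1, last dup exon end + 1] — a
    representation independent of gene strand.
    """
    tx = model.canonical_transcript(transcript_id)
    lo, hi = dup_region
    dup = [(i, ex) for i, ex in enumerate(tx.exons) if lo <= ex[0] and ex[1] <= hi]
    if not dup:
        raise ValueError(
            f"duplication region {model.chrom}:{lo}-{hi} covers no complete exon "
            f"of {tx.transcript_id}"
        )
    g_first, g_last = dup[0][0], dup[-1][0]
    bj_start = tx.exons[g_first][0] - 1
    bj_end = tx.exons[g_last][1] + 1
    support = sum(
        j.unique_reads
        for j in junctions
        if j.chrom == model.chrom and j.intron_start == bj_start and j.intron_end == bj_end
    )
    if tx.coding:
        dup_cds = sum(_overlap_len([ex], tx.cds_start, tx.cds_end) for _, ex in dup)
    else:
        dup_cds = 0
    idxs = sorted(_tx_index(tx, model.strand, i) for i, _ in dup)
    return DupCall(
        gene_id=model.gene_id,
        dup_exon_first=idxs[0],
        dup_exon_last=idxs[-1],
        backjunction_key=(model.chrom, bj_start, bj_end),
        split_read_support=support,
        in_tandem=support >= min_support,
        in_frame=dup_cds % 3 == 0,
    )


def backjunction_for_dup(
    model: GeneModel, dup_region: tuple[int, int], transcript_id: Optional[str] = None
) -> tuple[str, int, int]:
    """The back-junction key a tandem duplication of ``dup_region`` implies."""
    tx = model.canonical_transcript(transcript_id)
    lo, hi = dup_region
    dup = [ex for ex in tx.exons if lo <= ex[0] and ex[1] <= hi]
    if not dup:
        raise ValueError("duplication region covers no complete exon")
    return (model.chrom, dup[0][0] - 1, dup[-1][1] + 1)


# ---------------------------------------------------------------------------
# intron retention
# ---------------------------------------------------------------------------


def _median_coverage(
    records: Sequence[CoverageInterval], chrom: str, start: int, end: int
) -> Optional[float]:
    """Median per-base coverage over the 1-based closed interval."""
    length = end - start + 1
    if length <= 0:
        return None
    cov = np.zeros(length)
    seen = False
    for r in records:
        if r.chrom != chrom:
            continue
        # bedGraph is 0-based half-open
        lo = max(r.start + 1, start)
        hi = min(r.end, end)
        if lo <= hi:
            cov[lo - start : hi - start + 1] = r.value
            seen = True
    if not seen:
        return 0.0
    return float(np.median(cov))


def intron_retention_ratio(
    coverage: Sequence[CoverageInterval],
    model: GeneModel,
    intron_index: int,
    transcript_id: Optional[str] = None,
) -> Optional[float]:
    """Median intron coverage over the mean of the flanking exons' medians.

    ``intron_index`` is 1-based in transcription order.  The ratio is
    truncated to [0, 1] for reporting.  Returns None (logged) when both
    flanking exons have zero coverage.
    """
    tx = model.canonical_transcript(transcript_id)
    introns = tx.introns()
    n = len(introns)
    if not 1 <= intron_index <= n:
        raise ValueError(f"intron index {intron_index} out of range 1..{n}")
    gi = intron_index - 1 if model.strand != "-" else n - intron_index
    intron = introns[gi]
    left, right = tx.exons[gi], tx.exons[gi + 1]
    med_i = _median_coverage(coverage, model.chrom, *intron)
    med_l = _median_coverage(coverage, model.chrom, *left)
    med_r = _median_coverage(coverage, model.chrom, *right)
    exon_mean = ((med_l or 0.0) + (med_r or 0.0)) / 2
    if exon_mean == 0:
        logger.warning(
            "%s intron %d: zero flanking-exon coverage; retention undefined",
            model.gene_id, intron_index,
        )
        return None
    return min((med_i or 0.0) / exon_mean, 1.0)


# ---------------------------------------------------------------------------
# isoform switches
# ---------------------------------------------------------------------------


def isoform_switch_screen(
    patient_isoform_pcts: Mapping[str, Mapping[str, float]],
    control_isoform_pcts: Mapping[str, pd.DataFrame],
    z_min: float = 3.0,
    sd_floor: float = 0.01,
) -> list[SwitchCandidate]:
    """Genes whose patient isoform usage swaps relative to controls.

    Inputs are per-gene isoform *fractions* (summing to ~1): the patient's
    as a mapping isoform -> fraction, the controls' as an isoform x sample
    DataFrame.  A gene is a switch candidate when at least one isoform
    drops below -z_min and at least one rises above +z_min; candidates are
    ranked by their largest |z|.  Single-isoform genes are skipped.
    """
    candidates = []
    for gene_id in sorted(patient_isoform_pcts):
        patient = patient_isoform_pcts[gene_id]
        controls = control_isoform_pcts.get(gene_id)
        if controls is None or len(patient) < 2:
            continue
        lost, gained = [], []
        for iso, frac in patient.items():
            if iso not in controls.index:
                continue
            row = controls.loc[iso].to_numpy(dtype=float)
            z = (frac - row.mean()) / max(row.std(ddof=1), sd_floor)
            if z <= -z_min:
                lost.append((iso, float(z)))
            elif z >= z_min:
                gained.append((iso, float(z)))
        if lost and gained:
            candidates.append(
                SwitchCandidate(gene_id, tuple(sorted(lost)), tuple(sorted(gained)))
            )
    return sorted(candidates, key=lambda c: (-c.max_abs_z, c.gene_id))
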