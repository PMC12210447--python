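"""Readers and writers for the external formats the pipeline touches.

All splice-junction coordinates are 1-based closed over the *intron*
(STAR's ``SJ.out.tab`` convention).  Conversion to exonic coordinates
happens only in :mod:`rnadx.events`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger("rnadx")

STRAND_DECODE = {"0": ".", "1": "+", "2": "-"}
STRAND_ENCODE = {v: k for k, v in STRAND_DECODE.items()}

#: STAR intron motif codes.
MOTIF_NAMES = {
    0: "non-canonical",
    1: "GT/AG",
    2: "CT/AC",
    3: "GC/AG",
    4: "CT/GC",
    5: "AT/AC",
    6: "GT/AT",
}

VARIANT_CLASSES = frozenset(
    {
        "intronic",
        "synonymous",
        "missense",
        "canonical_splice",
        "cnv_duplication",
        "cnv_deletion",
        "utr_regulatory",
    }
)

AUTOLYSIS_GRADES = ("none", "mild", "moderate", "severe")


class ParseError(ValueError):
    """Malformed line in an input file (message names the line number)."""


class ValidationError(ValueError):
    """Structurally valid input with semantically invalid values."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpliceJunction:
    """One intron-spanning junction with read support and annotation flags."""

    chrom: str
    intron_start: int  # 1-based first intronic base
    intron_end: int  # 1-based last intronic base
    strand: str  # "+", "-" or "." (undefined)
    motif: int  # 0..6, see MOTIF_NAMES
    annotated: bool
    unique_reads: int
    multi_reads: int = 0
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("junction chrom must be non-empty")
        if self.intron_start > self.intron_end:
            raise ValidationError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.unique_reads < 0 or self.multi_reads < 0 or self.max_overhang < 0:
            raise ValidationError("read counts and overhang must be non-negative")
        if self.strand not in STRAND_ENCODE:
            raise ValidationError(f"strand must be one of +, -, . (got {self.strand!r})")
        if not 0 <= self.motif <= 6:
            raise ValidationError(f"motif code must be 0..6 (got {self.motif})")

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Unique key within one sample: (chrom, intron_start, intron_end, strand)."""
        return (self.chrom, self.intron_start, self.intron_end, self.strand)

    @property
    def donor_site(self) -> tuple[str, int, str]:
        """Genomic donor splice site.

        The donor is the ``intron_start`` side for + and undefined strand,
        the ``intron_end`` side for the - strand.
        """
        pos = self.intron_start if self.strand != "-" else self.intron_end
        return (self.chrom, pos, self.strand)

    @property
    def acceptor_site(self) -> tuple[str, int, str]:
        pos = self.intron_end if self.strand != "-" else self.intron_start
        return (self.chrom, pos, self.strand)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # 1-based closed, sorted genomically
    cds_start: Optional[int] = None  # genomic, inclusive
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValidationError(
                    f"{self.transcript_id}: exon start {start} > end {end}"
                )
            if prev_end is not None and start <= prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted at {start}"
                )
            prev_end = end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(f"{self.transcript_id}: partial CDS interval")
        if self.cds_start is not None:
            covered = any(
                s <= self.cds_start <= e for s, e in self.exons
            ) and any(s <= self.cds_end <= e for s, e in self.exons)
            if not covered:
                raise ValidationError(
                    f"{self.transcript_id}: CDS boundaries outside exon union"
                )

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals, 1-based closed, genomic order."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def cds_length(self) -> int:
        if not self.coding:
            return 0
        total = 0
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                total += hi - lo + 1
        return total


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.exons[0][0] for t in self.transcripts if t.exons]
        ends = [t.exons[-1][1] for t in self.transcripts if t.exons]
        if not starts:
            return (0, -1)
        return (min(starts), max(ends))

    def canonical_transcript(
        self, transcript_id: Optional[str] = None
    ) -> Transcript:
        """Longest-CDS transcript, or an explicit override by id."""
        if not self.transcripts:
            raise ValidationError(f"{self.gene_id}: no transcripts")
        if transcript_id is not None:
            for t in self.transcripts:
                if t.transcript_id == transcript_id:
                    return t
            raise ValidationError(f"{self.gene_id}: no transcript {transcript_id}")
        return max(
            self.transcripts,
            key=lambda t: (t.cds_length(), sum(e - s + 1 for s, e in t.exons), t.transcript_id),
        )

    def annotated_junction_keys(self) -> set[tuple[str, int, int, str]]:
        keys = set()
        for t in self.transcripts:
            for s, e in t.introns():
                keys.add((self.chrom, s, e, self.strand))
        return keys


@dataclass
class TpmMatrix:
    """Gene x sample TPM values (non-negative reals)."""

    values: pd.DataFrame  # index gene_id, columns sample_id

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("TPM matrix labels must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("TPM matrix must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SampleQc:
    sample_id: str
    rin: float
    mapping_rate: float
    intergenic_rate: float
    rrna_pct: float
    autolysis_grade: str = "none"

    def __post_init__(self) -> None:
        if not 0 <= self.mapping_rate <= 1 or not 0 <= self.intergenic_rate <= 1:
            raise ValidationError(f"{self.sample_id}: rates must lie in [0, 1]")
        if not 0 <= self.rrna_pct <= 100:
            raise ValidationError(f"{self.sample_id}: rRNA % must lie in [0, 100]")
        if self.autolysis_grade not in AUTOLYSIS_GRADES:
            raise ValidationError(
                f"{self.sample_id}: unknown autolysis grade {self.autolysis_grade!r}"
            )


@dataclass(frozen=True)
class AlleleCountRecord:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    ref_reads: int
    alt_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValidationError("allele read counts must be non-negative")


@dataclass(frozen=True)
class CandidateRegion:
    case_id: str
    gene_id: str
    chrom: str
    region_start: int
    region_end: int  # 1-based closed
    variant_description: str
    variant_class: str

    def __post_init__(self) -> None:
        if self.region_start > self.region_end:
            raise ValidationError("region_start > region_end")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant_class {self.variant_class!r}")


@dataclass(frozen=True)
class CoverageInterval:
    """One bedGraph record: 0-based half-open interval with a coverage value."""

    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    value: float


# ---------------------------------------------------------------------------
# SJ.out.tab
# ---------------------------------------------------------------------------


def read_sj_tab(path: str | Path) -> list[SpliceJunction]:
    """Parse a STAR ``SJ.out.tab`` file (9 tab-separated columns, no header)."""
    junctions: list[SpliceJunction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand = STRAND_DECODE.get(fields[3])
                if strand is None:
                    raise ValueError(f"bad strand code {fields[3]!r}")
                motif = int(fields[4])
                annotated = fields[5] == "1"
                unique, multi, overhang = (
                    int(fields[6]),
                    int(fields[7]),
                    int(fields[8]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                junctions.append(
                    SpliceJunction(
                        chrom, start, end, strand, motif, annotated, unique, multi, overhang
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return junctions


def write_sj_tab(junctions: Iterable[SpliceJunction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                "\t".join(
                    (
                        j.chrom,
                        str(j.intron_start),
                        str(j.intron_end),
                        STRAND_ENCODE[j.strand],
                        str(j.motif),
                        "1" if j.annotated else "0",
                        str(j.unique_reads),
                        str(j.multi_reads),
                        str(j.max_overhang),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF subset (exon / CDS features)
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_subset(path: str | Path) -> list[GeneModel]:
    """Parse exon/CDS records of a GTF into :class:`GeneModel` objects.

    Only ``gene_id``, ``gene_name`` and ``transcript_id`` attributes are
    required; quoted and unquoted attribute values are both accepted.
    Genes with no exon records (e.g. a GTF of bare ``gene`` lines) yield
    models with empty transcript lists and a logged warning.
    """
    # gene_id -> {"name":..., "chrom":..., "strand":..., "tx": {tx_id: {...}}}
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_text = fields
            attrs = _parse_gtf_attributes(attr_text)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: record lacks gene_id")
            entry = genes.setdefault(
                gene_id,
                {
                    "name": attrs.get("gene_name", gene_id),
                    "chrom": chrom,
                    "strand": strand,
                    "tx": {},
                },
            )
            if attrs.get("gene_name"):
                entry["name"] = attrs["gene_name"]
            if feature not in ("exon", "CDS"):
                continue
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise ParseError(f"{path}:{lineno}: {feature} record lacks transcript_id")
            start, end = int(start_s), int(end_s)
            tx = entry["tx"].setdefault(tx_id, {"exons": [], "cds": []})
            if feature == "exon":
                tx["exons"].append((start, end))
            else:
                tx["cds"].append((start, end))

    models: list[GeneModel] = []
    for gene_id, entry in genes.items():
        transcripts = []
        for tx_id, tx in sorted(entry["tx"].items()):
            exons = tuple(sorted(tx["exons"]))
            cds_start = cds_end = None
            if tx["cds"]:
                cds_start = min(s for s, _ in tx["cds"])
                cds_end = max(e for _, e in tx["cds"])
            try:
                transcripts.append(Transcript(tx_id, exons, cds_start, cds_end))
            except ValidationError as exc:
                raise ValidationError(f"{path}: transcript {tx_id}: {exc}") from exc
        if not transcripts:
            logger.warning("gene %s has no exon records; empty transcript list", gene_id)
        models.append(
            GeneModel(
                gene_id,
                entry["name"],
                entry["chrom"],
                entry["strand"],
                tuple(transcripts),
            )
        )
    return models


def write_gtf(models: Iterable[GeneModel], path: str | Path, source: str = "rnadx") -> None:
    """Write gene models as exon/CDS GTF records (inverse of read_gtf_subset)."""
    with open(path, "w") as fh:
        for gene in models:
            for tx in gene.transcripts:
                attr = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_name "{gene.gene_name}";'
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t{attr}\n"
                    )
                if tx.coding:
                    for s, e in tx.exons:
                        lo, hi = max(s, tx.cds_start), min(e, tx.cds_end)
                        if lo <= hi:
                            fh.write(
                                f"{gene.chrom}\t{source}\tCDS\t{lo}\t{hi}\t.\t{gene.strand}\t.\t{attr}\n"
                            )


# ---------------------------------------------------------------------------
# TPM matrix, bedGraph, allele counts, HPO map, candidate regions, QC
# ---------------------------------------------------------------------------


def read_tpm_matrix(path: str | Path) -> TpmMatrix:
    """TSV with a ``gene_id`` first column and sample-id header (RSEM style)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TpmMatrix(df)


def write_tpm_matrix(matrix: TpmMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_bedgraph(path: str | Path) -> list[CoverageInterval]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            records.append(
                CoverageInterval(fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            )
    return records


def write_bedgraph(records: Iterable[CoverageInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            value = f"{r.value:g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{value}\n")


def read_allele_counts(path: str | Path) -> list[AlleleCountRecord]:
    """TSV with header chrom/pos/ref/alt/ref_reads/alt_reads/sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    required = {"chrom", "pos", "ref", "alt", "ref_reads", "alt_reads", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        AlleleCountRecord(
            row.chrom, int(row.pos), row.ref, row.alt,
            int(row.ref_reads), int(row.alt_reads), row.sample_id,
        )
        for row in df.itertuples()
    ]


def write_allele_counts(records: Iterable[AlleleCountRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tref_reads\talt_reads\tsample_id\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref_allele}\t{r.alt_allele}"
                f"\t{r.ref_reads}\t{r.alt_reads}\t{r.sample_id}\n"
            )


def read_hpo_map(path: str | Path) -> dict[str, set[str]]:
    """TSV of ``hpo_id<TAB>gene_id`` pairs, one per line (header optional)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.lower().startswith("hpo_id"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def read_candidate_regions(path: str | Path) -> list[CandidateRegion]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "case_id", "gene_id", "chrom", "region_start", "region_end",
        "variant_description", "variant_class",
    }
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        CandidateRegion(
            row.case_id, row.gene_id, row.chrom,
            int(row.region_start), int(row.region_end),
            row.variant_description, row.variant_class,
        )
        for row in df.itertuples()
    ]


def read_sample_qc(path: str | Path) -> list[SampleQc]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return [
        SampleQc(
            row.sample_id, float(row.rin), float(row.mapping_rate),
            float(row.intergenic_rate), float(row.rrna_pct),
            getattr(row, "autolysis_grade", "none"),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Packaged cohort fixture
# ---------------------------------------------------------------------------

FIXTURE_N_CASES = 53
FIXTURE_N_CANDIDATE = 33
FIXTURE_N_WGS_NEGATIVE = 20


class FixtureIntegrityError(ValueError):
    """The packaged cohort fixture does not match its documented shape."""


def fixture_path() -> Path:
    return Path(resources.files("rnadx").joinpath("data/cohort_cases.tsv"))


def read_fixture_cases(path: str | Path | None = None):
    """Load the packaged 53-proband adjudication fixture.

    Returns a list of :class:`rnadx.outcomes.CaseAdjudication`, exactly 53
    records: 33 candidate-variant probands and 20 WGS-negative probands.
    """
    from rnadx.outcomes import CaseAdjudication  # local import avoids a cycle

    if path is None:
        path = fixture_path()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def as_bool(v: str) -> bool:
        return v == "true"

    cases = []
    for row in df.itertuples():
        sig = row.effect_significant
        cases.append(
            CaseAdjudication(
                case_id=row.case_id,
                group=row.group,
                gene=row.gene,
                n_splice_vus=int(row.n_splice_vus),
                analysis_successful=as_bool(row.analysis_successful),
                effect_present=as_bool(row.effect_present),
                effect_significant=None if sig == "NA" else as_bool(sig),
                protein_mechanism_possible=as_bool(row.protein_mechanism_possible),
                hi_analysis=as_bool(row.hi_analysis),
                hi_candidate_found=as_bool(row.hi_candidate_found),
                citation=row.citation,
            )
        )
    if len(cases) != FIXTURE_N_CASES:
        raise FixtureIntegrityError(
            f"fixture has {len(cases)} rows, expected {FIXTURE_N_CASES}"
        )
    n_wgs = sum(1 for c in cases if c.group == "wgs_negative")
    if n_wgs != FIXTURE_N_WGS_NEGATIVE:
        raise FixtureIntegrityError(
            f"fixture has {n_wgs} WGS-negative rows, expected {FIXTURE_N_WGS_NEGATIVE}"
        )
    if len(cases) - n_wgs != FIXTURE_N_CANDIDATE:
        raise FixtureIntegrityError("candidate-variant row count mismatch")
    return cases
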