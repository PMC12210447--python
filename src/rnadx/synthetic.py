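"""Seeded synthetic cohorts: gene models, control samples, and a patient
with injected splicing/expression/allelic aberrations.

The generator emulates the statistical structure a diagnostic junction
pipeline assumes: a control cohort with stable isoform usage (per-gene
Dirichlet-distributed usage around canonical proportions, multinomial
read sampling at a configured junction depth), and one patient sample in
which a stated fraction of a gene's transcripts is re-routed through an
injected aberration (exon skip, exon extension, intron retention, tandem
duplication back-junction).  TPM matrices are log-normal per gene, allele
counts binomial at a configured true skew.  Everything is deterministic
given the seed, and every injected event is recorded in a truth table so
recovery can be scored.

Real data differ in ways the generator does not model: mapping artifacts,
read-level noise correlated across junctions, tissue composition, and
library-depth variation.  Passing recovery tests therefore demonstrates
the pipeline's statistical behaviour, not performance on patient data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from rnadx import cohort as cohort_mod
from rnadx.aberrance import classify_junctions
from rnadx.events import (
    backjunction_for_dup,
    detect_tandem_dup,
    infer_events,
    intron_retention_ratio,
)
from rnadx.formats import (
    CoverageInterval,
    GeneModel,
    SpliceJunction,
    Transcript,
    TpmMatrix,
    write_bedgraph,
    write_gtf,
    write_sj_tab,
    write_tpm_matrix,
    write_allele_counts,
    AlleleCountRecord,
    read_gtf_subset,
    read_sj_tab,
    read_bedgraph,
)
from rnadx.junctions import score_junctions

import pandas as pd


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Injection:
    """One aberration injected into the patient sample.

    ``gene_index`` is the 0-based index into the generated gene list;
    exon/intron indices are 1-based in transcription order.
    ``fraction`` is the fraction of the gene's transcripts affected.
    """

    gene_index: int
    event_type: str  # exon_skip | exon_extension | intron_retention | tandem_dup
    fraction: float
    exon: Optional[int] = None  # exon_skip: skipped exon
    intron: Optional[int] = None  # exon_extension / intron_retention target
    extension_nt: int = 0  # exon_extension: nt gained from the intron
    dup_first_exon: Optional[int] = None  # tandem_dup span
    dup_last_exon: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError("injection fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 10)
    exon_length: tuple[int, int] = (60, 300)
    intron_length: tuple[int, int] = (200, 2000)
    n_controls: int = 50
    depth: int = 500  # mean junction reads per gene
    dirichlet_concentration: float = 200.0  # tight cohort usage (score SD of a few %)
    alt_isoform_prob: float = 0.5  # genes carrying an annotated skip isoform
    alt_usage_mean: float = 0.2
    tpm_log2_mean_range: tuple[float, float] = (1.0, 7.0)
    tpm_log2_sd: float = 0.25
    injections: tuple[Injection, ...] = ()
    tpm_outliers: tuple[tuple[int, float], ...] = ()  # (gene_index, true z)
    allele_sites: tuple[tuple[float, int], ...] = ()  # (true skew, depth)


@dataclass
class SimBundle:
    """Paths and in-memory truth for one simulated cohort."""

    outdir: Path
    gtf: Path
    sj_dir: Path
    tpm: Path
    bedgraph: Optional[Path]
    allele_counts: Optional[Path]
    truth: dict
    control_ids: list[str]
    patient_id: str = "patient"


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def make_gene_models(rng: np.random.Generator, config: SimConfig) -> list[GeneModel]:
    """Random multi-exon genes on one chromosome, alternating strands.

    Each gene's primary transcript is coding (CDS from inside the first
    to inside the last exon, length a multiple of 3); about half the genes
    carry an annotated alternative isoform skipping one middle exon, which
    gives the cohort its isoform-usage variation.
    """
    models = []
    pos = 10_000
    # an alt isoform must not skip an exon that an injection will skip,
    # otherwise the injected junction would be annotated
    avoid_skip: dict[int, set[int]] = {}
    for inj in config.injections:
        if inj.event_type == "exon_skip" and inj.exon is not None:
            avoid_skip.setdefault(inj.gene_index, set()).add(inj.exon)
    for g in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((pos, pos + length - 1))
            pos += length + int(
                rng.integers(config.intron_length[0], config.intron_length[1] + 1)
            )
        pos += 50_000  # intergenic gap
        strand = "+" if g % 2 == 0 else "-"
        exons = [tuple(e) for e in exons]
        # transcription-order first/last exon
        first = exons[0] if strand == "+" else exons[-1]
        last = exons[-1] if strand == "+" else exons[0]
        utr5, utr3 = 30, 30
        if strand == "+":
            cds_start = first[0] + utr5
            cds_end = last[1] - utr3
        else:
            cds_start = last[0] + utr3
            cds_end = first[1] - utr5
        # trim the 3' end so the CDS length is a codon multiple
        tx_probe = Transcript("probe", tuple(exons), cds_start, cds_end)
        excess = tx_probe.cds_length() % 3
        if excess:
            if strand == "+":
                cds_end -= excess
            else:
                cds_start += excess
        transcripts = [Transcript(f"T{g}.1", tuple(exons), cds_start, cds_end)]
        if n_exons >= 4 and rng.random() < config.alt_isoform_prob:
            avoided_g = {
                _genomic_exon_index(n_exons, strand, tx_i)
                for tx_i in avoid_skip.get(g, set())
            }
            choices = [i for i in range(1, n_exons - 1) if i not in avoided_g]
            if choices:
                skip_g = int(choices[int(rng.integers(len(choices)))])
                alt_exons = tuple(e for i, e in enumerate(exons) if i != skip_g)
                transcripts.append(Transcript(f"T{g}.2", alt_exons, cds_start, cds_end))
        models.append(
            GeneModel(f"GENE{g:03d}", f"Gene{g}", "chr1", strand, tuple(transcripts))
        )
    return models


def _tx_order(exons: list[tuple[int, int]], strand: str) -> list[tuple[int, int]]:
    return exons if strand == "+" else exons[::-1]


def _genomic_exon_index(n_exons: int, strand: str, tx_index: int) -> int:
    """0-based genomic index of a 1-based transcription-order exon index."""
    return tx_index - 1 if strand == "+" else n_exons - tx_index


# ---------------------------------------------------------------------------
# junction sampling
# ---------------------------------------------------------------------------


def _canonical_junction_counts(
    rng: np.random.Generator, model: GeneModel, config: SimConfig
) -> tuple[dict[tuple[int, int], int], int]:
    """Per-intron junction read counts for one sample of one gene."""
    primary = model.transcripts[0]
    introns = primary.introns()
    n_total = int(rng.poisson(config.depth))
    counts = {i: 0 for i in introns}
    if len(model.transcripts) > 1:
        alt = model.transcripts[1]
        conc = config.dirichlet_concentration
        u = float(rng.beta(conc * config.alt_usage_mean, conc * (1 - config.alt_usage_mean)))
        n_alt = int(rng.binomial(n_total, u))
        n_can = n_total - n_alt
        alt_introns = set(alt.introns())
        for intron in introns:
            counts[intron] += n_can
        for intron in alt.introns():
            if intron in counts:
                counts[intron] += n_alt
            else:
                counts[intron] = n_alt  # the skip junction
    else:
        for intron in introns:
            counts[intron] = n_total
    return counts, n_total


def _junction_records(
    model: GeneModel,
    counts: dict[tuple[int, int], int],
    annotated: set[tuple[int, int]],
) -> list[SpliceJunction]:
    motif = 1 if model.strand == "+" else 2
    records = []
    for (s, e), n in sorted(counts.items()):
        if n <= 0:
            continue
        records.append(
            SpliceJunction(
                chrom=model.chrom,
                intron_start=s,
                intron_end=e,
                strand=model.strand,
                motif=motif if (s, e) in annotated else 0,
                annotated=(s, e) in annotated,
                unique_reads=int(n),
                multi_reads=0,
                max_overhang=50,
            )
        )
    return records


def _apply_injection(
    rng: np.random.Generator,
    model: GeneModel,
    counts: dict[tuple[int, int], int],
    n_total: int,
    inj: Injection,
) -> tuple[dict[tuple[int, int], int], dict]:
    """Re-route a fraction of the gene's reads through the aberration."""
    primary = model.transcripts[0]
    exons = list(primary.exons)
    introns = primary.introns()
    n_exons = len(exons)
    truth: dict = {"gene_id": model.gene_id, "event_type": inj.event_type,
                   "fraction": inj.fraction}

    if inj.event_type == "exon_skip":
        if inj.exon is None or not 2 <= inj.exon <= n_exons - 1:
            raise ConfigError(f"exon_skip needs a middle exon index, got {inj.exon}")
        g = _genomic_exon_index(n_exons, model.strand, inj.exon)
        skip_key = (introns[g - 1][0], introns[g][1])
        if any(skip_key in set(t.introns()) for t in model.transcripts):
            raise ConfigError(
                f"{model.gene_id}: skip of exon {inj.exon} collides with an annotated isoform"
            )
        # the stated fraction is the junction usage score, i.e. relative to
        # junction reads at the shared splice sites, not to all gene reads
        base = max(counts[introns[g - 1]], counts[introns[g]])
        n_skip = int(rng.binomial(base, inj.fraction))
        counts = dict(counts)
        counts[skip_key] = counts.get(skip_key, 0) + n_skip
        for adjacent in (introns[g - 1], introns[g]):
            counts[adjacent] = max(counts[adjacent] - n_skip, 0)
        if primary.coding:
            lo, hi = max(exons[g][0], primary.cds_start), min(exons[g][1], primary.cds_end)
            delta = -(hi - lo + 1) if lo <= hi else 0
        else:
            delta = 0
        truth.update(
            junction=[model.chrom, skip_key[0], skip_key[1], model.strand],
            affected_exons=[inj.exon],
            delta_nt=delta,
            frame="in_frame" if delta % 3 == 0 else "frameshift",
            n_injected_reads=n_skip,
        )
    elif inj.event_type == "exon_extension":
        if inj.intron is None:
            raise ConfigError("exon_extension needs an intron index")
        n_introns = len(introns)
        if not 1 <= inj.intron <= n_introns:
            raise ConfigError(f"intron index {inj.intron} out of range")
        g = inj.intron - 1 if model.strand == "+" else n_introns - inj.intron
        s, e = introns[g]
        d = inj.extension_nt
        if d <= 0 or d >= e - s:
            raise ConfigError("extension_nt must fall inside the intron")
        novel_key = (s, e - d)  # the genomically downstream exon gains d nt
        n_novel = int(rng.binomial(counts[(s, e)], inj.fraction))
        counts = dict(counts)
        counts[novel_key] = counts.get(novel_key, 0) + n_novel
        counts[(s, e)] = max(counts[(s, e)] - n_novel, 0)
        extended_g = g + 1  # the genomically downstream exon gains the bases
        ext_tx = extended_g + 1 if model.strand == "+" else n_exons - extended_g
        truth.update(
            junction=[model.chrom, novel_key[0], novel_key[1], model.strand],
            affected_exons=[ext_tx],
            delta_nt=d,
            frame="in_frame" if d % 3 == 0 else "frameshift",
            n_injected_reads=n_novel,
        )
    elif inj.event_type == "intron_retention":
        if inj.intron is None:
            raise ConfigError("intron_retention needs an intron index")
        n_introns = len(introns)
        if not 1 <= inj.intron <= n_introns:
            raise ConfigError(f"intron index {inj.intron} out of range")
        g = inj.intron - 1 if model.strand == "+" else n_introns - inj.intron
        key = introns[g]
        n_retained = int(rng.binomial(n_total, inj.fraction))
        counts = dict(counts)
        counts[key] = max(counts[key] - n_retained, 0)
        truth.update(intron=inj.intron, retained_interval=list(key),
                     n_injected_reads=n_retained)
    elif inj.event_type == "tandem_dup":
        if inj.dup_first_exon is None or inj.dup_last_exon is None:
            raise ConfigError("tandem_dup needs dup_first_exon/dup_last_exon")
        if not 1 <= inj.dup_first_exon <= inj.dup_last_exon <= n_exons:
            raise ConfigError("duplicated exon span out of range")
        g_idx = sorted(
            _genomic_exon_index(n_exons, model.strand, i)
            for i in (inj.dup_first_exon, inj.dup_last_exon)
        )
        dup_lo = exons[g_idx[0]][0]
        dup_hi = exons[g_idx[1]][1]
        chrom, bs, be = backjunction_for_dup(model, (dup_lo, dup_hi))
        n_back = int(rng.binomial(n_total, inj.fraction))
        counts = dict(counts)
        counts[(bs, be)] = counts.get((bs, be), 0) + n_back
        if primary.coding:
            dup_cds = 0
            for gi in range(g_idx[0], g_idx[1] + 1):
                lo = max(exons[gi][0], primary.cds_start)
                hi = min(exons[gi][1], primary.cds_end)
                if lo <= hi:
                    dup_cds += hi - lo + 1
        else:
            dup_cds = 0
        truth.update(
            junction=[chrom, bs, be, model.strand],
            dup_region=[dup_lo, dup_hi],
            affected_exons=list(range(inj.dup_first_exon, inj.dup_last_exon + 1)),
            in_frame=dup_cds % 3 == 0,
            n_injected_reads=n_back,
        )
    else:
        raise ConfigError(f"unknown injection event_type {inj.event_type!r}")
    return counts, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimConfig, outdir: str | Path) -> SimBundle:
    """Write a complete on-disk bundle: GTF, per-sample SJ tables, TPM
    matrix, patient coverage bedGraph (when a retention is injected),
    allele counts, and a JSON truth table.  Byte-identical for equal
    configs."""
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sj_dir = outdir / "sj"
    sj_dir.mkdir(exist_ok=True)

    models = make_gene_models(rng, config)
    for inj in config.injections:
        if not 0 <= inj.gene_index < len(models):
            raise ConfigError(f"injection references gene index {inj.gene_index}")
    gtf_path = outdir / "annotation.gtf"
    write_gtf(models, gtf_path)

    annotated_by_gene = [
        {intron for t in m.transcripts for intron in t.introns()} for m in models
    ]

    control_ids = [f"control_{i:03d}" for i in range(config.n_controls)]
    truth: dict = {"seed": config.seed, "injections": [], "tpm_outliers": [],
                   "allele_sites": []}

    # ---- junction tables -------------------------------------------------
    for sid in control_ids:
        records: list[SpliceJunction] = []
        for m, annotated in zip(models, annotated_by_gene):
            counts, _ = _canonical_junction_counts(rng, m, config)
            records.extend(_junction_records(m, counts, annotated))
        write_sj_tab(records, sj_dir / f"{sid}.SJ.out.tab")

    patient_records: list[SpliceJunction] = []
    injections_by_gene: dict[int, list[Injection]] = {}
    for inj in config.injections:
        injections_by_gene.setdefault(inj.gene_index, []).append(inj)
    retention_truths = []
    for gi, (m, annotated) in enumerate(zip(models, annotated_by_gene)):
        counts, n_total = _canonical_junction_counts(rng, m, config)
        for inj in injections_by_gene.get(gi, ()):
            counts, t = _apply_injection(rng, m, counts, n_total, inj)
            truth["injections"].append(t)
            if inj.event_type == "intron_retention":
                retention_truths.append((m, inj, t))
        patient_records.extend(_junction_records(m, counts, annotated))
    write_sj_tab(patient_records, sj_dir / "patient.SJ.out.tab")

    # ---- patient coverage for retention checks ---------------------------
    bed_path = None
    if retention_truths:
        bed_records: list[CoverageInterval] = []
        for m, inj, t in retention_truths:
            primary = m.transcripts[0]
            introns = primary.introns()
            n_introns = len(introns)
            g = inj.intron - 1 if m.strand == "+" else n_introns - inj.intron
            s, e = introns[g]
            left, right = primary.exons[g], primary.exons[g + 1]
            # Poisson-noisy coverage in a few sub-intervals per feature
            for (lo, hi), mean_cov in (
                (left, float(config.depth)),
                ((s, e), float(config.depth) * inj.fraction),
                (right, float(config.depth)),
            ):
                bounds = np.linspace(lo - 1, hi, 5).astype(int)
                for a, b in zip(bounds[:-1], bounds[1:]):
                    if b > a:
                        value = float(rng.poisson(mean_cov)) if mean_cov > 0 else 0.0
                        bed_records.append(CoverageInterval(m.chrom, int(a), int(b), value))
        bed_path = outdir / "patient.coverage.bedGraph"
        write_bedgraph(bed_records, bed_path)

    # ---- TPM matrix ------------------------------------------------------
    lo, hi = config.tpm_log2_mean_range
    gene_log2_means = rng.uniform(lo, hi, size=config.n_genes)
    control_log2 = rng.normal(
        gene_log2_means[:, None], config.tpm_log2_sd,
        size=(config.n_genes, config.n_controls),
    )
    control_tpm = np.power(2.0, control_log2)
    patient_tpm = np.power(2.0, rng.normal(gene_log2_means, config.tpm_log2_sd))
    for gene_index, z_true in config.tpm_outliers:
        if not 0 <= gene_index < config.n_genes:
            raise ConfigError(f"tpm outlier references gene index {gene_index}")
        mean = control_tpm[gene_index].mean()
        sd = control_tpm[gene_index].std(ddof=1)
        patient_tpm[gene_index] = max(mean + z_true * sd, 0.0)
        truth["tpm_outliers"].append(
            {"gene_id": models[gene_index].gene_id, "z_true": z_true}
        )
    tpm_df = pd.DataFrame(
        np.column_stack([control_tpm, patient_tpm]),
        index=[m.gene_id for m in models],
        columns=control_ids + ["patient"],
    )
    tpm_path = outdir / "tpm.tsv"
    write_tpm_matrix(TpmMatrix(tpm_df), tpm_path)

    # ---- allele counts ---------------------------------------------------
    allele_path = None
    if config.allele_sites:
        allele_records = []
        for i, (skew, depth) in enumerate(config.allele_sites):
            ref = int(rng.binomial(depth, skew))
            allele_records.append(
                AlleleCountRecord("chr1", 1_000_000 + i, "A", "G", ref, depth - ref, "patient")
            )
            truth["allele_sites"].append({"pos": 1_000_000 + i, "true_skew": skew,
                                          "depth": depth})
        allele_path = outdir / "allele_counts.tsv"
        write_allele_counts(allele_records, allele_path)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))

    return SimBundle(
        outdir=outdir,
        gtf=gtf_path,
        sj_dir=sj_dir,
        tpm=tpm_path,
        bedgraph=bed_path,
        allele_counts=allele_path,
        truth=truth,
        control_ids=control_ids,
    )


# ---------------------------------------------------------------------------
# end-to-end recovery
# ---------------------------------------------------------------------------


def end_to_end_recovery(config: SimConfig, outdir: str | Path) -> dict:
    """Simulate a bundle, run the full junction pipeline on it, and score
    every injected event against the truth table.

    Returns a report with, per injection: whether an aberrant junction of
    the expected class was detected at |z| >= 3, the estimated aberrant
    fraction, and the frame call versus truth; plus genome-wide counts for
    null calibration.
    """
    bundle = simulate_cohort(config, outdir)
    models = read_gtf_subset(bundle.gtf)
    by_gene = {m.gene_id: m for m in models}
    annotation = set()
    for m in models:
        annotation |= m.annotated_junction_keys()

    control_scores = {
        sid: score_junctions(read_sj_tab(bundle.sj_dir / f"{sid}.SJ.out.tab"), min_unique=1)
        for sid in bundle.control_ids
    }
    stats = cohort_mod.build_cohort_stats(control_scores, annotation)
    patient_junctions = read_sj_tab(bundle.sj_dir / "patient.SJ.out.tab")
    patient_scores = score_junctions(patient_junctions)
    zs = cohort_mod.junction_z(patient_scores, stats)
    aberrant = classify_junctions(zs, genes=models)

    coverage = read_bedgraph(bundle.bedgraph) if bundle.bedgraph else []

    report = {"n_junctions_tested": len(zs), "n_aberrant": len(aberrant),
              "events": []}
    for t in bundle.truth["injections"]:
        entry = {"gene_id": t["gene_id"], "event_type": t["event_type"],
                 "true_fraction": t["fraction"]}
        model = by_gene[t["gene_id"]]
        if t["event_type"] == "intron_retention":
            ratio = intron_retention_ratio(coverage, model, t["intron"])
            entry.update(detected=ratio is not None and ratio > 0.1,
                         estimated_fraction=ratio)
        elif t["event_type"] == "tandem_dup":
            call = detect_tandem_dup(patient_junctions, model, tuple(t["dup_region"]))
            entry.update(
                detected=call.in_tandem,
                recovered_exons=list(range(call.dup_exon_first, call.dup_exon_last + 1)),
                exons_match=list(range(call.dup_exon_first, call.dup_exon_last + 1))
                == t["affected_exons"],
                in_frame=call.in_frame,
                frame_match=call.in_frame == t["in_frame"],
            )
        else:
            key = tuple(t["junction"])
            hits = [a for a in aberrant if a.junction_key == key]
            entry["detected"] = bool(hits) and all(a.klass == "novel" for a in hits)
            if hits:
                hit = hits[0]
                gene_events = infer_events([hit], model)
                entry.update(
                    klass=hit.klass,
                    z=hit.z,
                    estimated_fraction=hit.patient_score,
                    fraction_error=abs(hit.patient_score - t["fraction"]),
                )
                if gene_events:
                    ev = gene_events[0]
                    entry.update(
                        called_event=ev.event_type,
                        called_frame=ev.frame,
                        frame_match=ev.frame == t.get("frame"),
                        exons_match=list(ev.affected_exons) == t.get("affected_exons"),
                    )
        report["events"].append(entry)

    # junctions disrupted by an injection legitimately include the injected
    # gene's neighbouring junctions; the false-positive count covers only
    # genes with no injection at all
    injected_genes = {t["gene_id"] for t in bundle.truth["injections"]}
    report["n_false_aberrant"] = sum(
        1
        for a in aberrant
        if not (set(a.gene_ids) & injected_genes)
    )
    return report
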