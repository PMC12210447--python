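import numpy as np
import pytest
from Bio.Seq import Seq

from rnadx.aberrance import AberrantJunction
from rnadx.cohort import CohortJunctionStats, JunctionZ
from rnadx.events import (
    detect_tandem_dup,
    frame_consequence,
    infer_events,
    intron_retention_ratio,
    isoform_switch_screen,
    nmd_rule,
)
from rnadx.formats import CoverageInterval, GeneModel, Transcript

from tests.conftest import make_junction, random_gene_with_sequence


def aberrant_for(key, klass="novel", score=0.3, z=10.0):
    stats = CohortJunctionStats(key, 50, 50, 0, 0.0, 0.0, annotated=False)
    jz = JunctionZ(key, score, z, stats)
    return AberrantJunction(jz, klass, "increased" if z > 0 else "decreased")


# ---------------------------------------------------------------------------
# pattern rules on the toy gene (+ strand, 5 x 90nt exons, introns of 500)
# ---------------------------------------------------------------------------


class TestInferEvents:
    def test_exact_skip_of_exon_three(self, toy_gene):
        tx = toy_gene.transcripts[0]
        introns = tx.introns()
        key = ("chr1", introns[1][0], introns[2][1], "+")
        (ev,) = infer_events([aberrant_for(key)], toy_gene)
        assert ev.event_type == "exon_skip"
        assert ev.affected_exons == (3,)
        assert ev.delta_nt == -90
        assert ev.frame == "in_frame"  # 90 nt is a codon multiple
        assert ev.aberrant_fraction == pytest.approx(0.3)

    def test_acceptor_shift_five_nt_is_out_of_frame_extension(self, toy_gene):
        tx = toy_gene.transcripts[0]
        s, e = tx.introns()[0]
        key = ("chr1", s, e - 5, "+")
        (ev,) = infer_events([aberrant_for(key)], toy_gene)
        assert ev.event_type == "exon_extension"
        assert ev.affected_exons == (2,)
        assert ev.delta_nt == 5
        assert ev.frame == "frameshift"

    def test_acceptor_shift_twelve_nt_is_in_frame_extension(self, toy_gene):
        s, e = toy_gene.transcripts[0].introns()[0]
        key = ("chr1", s, e - 12, "+")
        (ev,) = infer_events([aberrant_for(key)], toy_gene)
        assert ev.event_type == "exon_extension"
        assert ev.delta_nt == 12
        assert ev.frame == "in_frame"

    def test_one_nt_exon_shortening_is_frameshift(self, toy_gene):
        s, e = toy_gene.transcripts[0].introns()[0]
        key = ("chr1", s, e + 1, "+")  # removal eats 1 nt of the next exon
        (ev,) = infer_events([aberrant_for(key)], toy_gene)
        assert ev.event_type == "exon_truncation"
        assert ev.affected_exons == (2,)
        assert ev.delta_nt == -1
        assert ev.frame == "frameshift"

    def test_multi_exon_skip(self, toy_gene):
        introns = toy_gene.transcripts[0].introns()
        key = ("chr1", introns[0][0], introns[3][1], "+")  # skips exons 2..4
        (ev,) = infer_events([aberrant_for(key)], toy_gene)
        assert ev.event_type == "exon_skip"
        assert ev.affected_exons == (2, 3, 4)

    def test_missing_annotated_junction_with_retention_becomes_intron_retention(
        self, toy_gene
    ):
        s, e = toy_gene.transcripts[0].introns()[1]
        key = ("chr1", s, e, "+")
        ab = aberrant_for(key, klass="missing", score=0.4, z=-9.0)
        (ev,) = infer_events([ab], toy_gene, retention_ratios={2: 0.6})
        assert ev.event_type == "intron_retention"
        assert ev.aberrant_fraction == pytest.approx(0.6)
        assert ev.frame == "frameshift"  # a 500-nt intron is not a codon multiple

    def test_unattributable_junction_is_unclassified_with_note(self, toy_gene):
        key = ("chr1", 20_000, 30_000, "+")
        (ev,) = infer_events([aberrant_for(key)], toy_gene)
        assert ev.event_type == "unclassified"
        assert ev.note

    def test_no_event_without_input_junction(self, toy_gene):
        assert infer_events([], toy_gene) == []

    def test_every_event_traces_back_to_an_input_junction(self, toy_gene):
        tx = toy_gene.transcripts[0]
        introns = tx.introns()
        keys = [
            ("chr1", introns[0][0], introns[1][1], "+"),
            ("chr1", introns[2][0], introns[2][1] - 7, "+"),
            ("chr1", 20_000, 30_000, "+"),
        ]
        events = infer_events([aberrant_for(k) for k in keys], toy_gene)
        assert {e.junction for e in events} <= set(keys)


# ---------------------------------------------------------------------------
# frame consequence vs a brute-force sequence oracle
# ---------------------------------------------------------------------------


def oracle_edited_cds(gene: GeneModel, seq: str, junction: tuple[int, int]) -> tuple[str, str]:
    """Brute-force per-base splicing of the edited transcript.

    Returns (edited_cds, edited_utr5) as nucleotide strings in reading
    orientation, built by walking every genomic base and applying the
    splicing rules literally.
    """
    tx = gene.transcripts[0]
    js, je = junction
    span = range(tx.exons[0][0], tx.exons[-1][1] + 1)
    introns = tx.introns()

    def kept(pos: int) -> bool:
        if js <= pos <= je:
            return False
        for s, e in introns:
            if s <= pos <= e:
                # an intron untouched by the junction is spliced out
                return not (e < js or s > je)
        return True

    cds, utr5 = [], []
    for pos in span:
        if not kept(pos):
            continue
        base = seq[pos - 1]
        if tx.cds_start <= pos <= tx.cds_end:
            cds.append(base)
        elif (gene.strand == "+" and pos < tx.cds_start) or (
            gene.strand == "-" and pos > tx.cds_end
        ):
            utr5.append(base)
    cds_s = "".join(cds)
    utr5_s = "".join(utr5)
    if gene.strand == "-":
        cds_s = str(Seq(cds_s).reverse_complement())
        utr5_s = str(Seq(utr5_s).reverse_complement())
    return cds_s, utr5_s


def random_event_junction(rng, gene: GeneModel):
    tx = gene.transcripts[0]
    introns = tx.introns()
    kind = rng.choice(["skip", "extension", "truncation"])
    if kind == "skip" and len(introns) >= 2:
        g = int(rng.integers(0, len(introns) - 1))
        return (introns[g][0], introns[g + 1][1])
    g = int(rng.integers(0, len(introns)))
    s, e = introns[g]
    if kind == "extension":
        d = int(rng.integers(1, min(30, e - s)))
        return (s, e - d)
    next_exon = tx.exons[g + 1]
    d = int(rng.integers(1, next_exon[1] - next_exon[0]))
    return (s, e + d)


class TestFrameOracle:
    @pytest.mark.parametrize("seed", range(200))
    def test_mod3_call_matches_translated_edited_sequence(self, seed):
        rng = np.random.default_rng(10_000 + seed)
        gene, seq = random_gene_with_sequence(rng)
        tx = gene.transcripts[0]
        junction = random_event_junction(rng, gene)
        key = (gene.chrom, junction[0], junction[1], gene.strand)
        events = infer_events([aberrant_for(key)], gene)
        assert len(events) == 1
        ev = events[0]
        call = frame_consequence(gene, ev, genome={gene.chrom: seq})

        edited_cds, edited_utr5 = oracle_edited_cds(gene, seq, junction)
        ref_len = tx.cds_length()
        if len(edited_cds) == ref_len and call.frame == "noncoding":
            return  # event fell entirely outside the CDS
        expected = "in_frame" if (len(edited_cds) - ref_len) % 3 == 0 else "frameshift"
        assert call.frame == expected

        # an in-frame event preserves the protein tail, provided the edit
        # itself does not reach into the last few codons
        near_terminus = (
            junction[1] >= tx.cds_end - 45
            if gene.strand == "+"
            else junction[0] <= tx.cds_start + 45
        )
        if call.frame == "in_frame" and not near_terminus:
            ref_cds = oracle_edited_cds(gene, seq, (tx.exons[-1][1] + 10,
                                                    tx.exons[-1][1] + 10))[0]
            tail_ref = str(Seq(ref_cds).translate())[-5:]
            tail_edit = str(Seq(edited_cds[: len(edited_cds) // 3 * 3]).translate())[-5:]
            assert tail_edit == tail_ref
        elif call.ptc_position is not None:
            protein = str(Seq(edited_cds[: len(edited_cds) // 3 * 3]).translate())
            first_stop = protein.find("*")
            assert first_stop >= 0
            assert call.ptc_position == len(edited_utr5) + 3 * first_stop


# ---------------------------------------------------------------------------
# NMD rule
# ---------------------------------------------------------------------------


class TestNmdRule:
    def test_ptc_far_upstream_of_last_junction_triggers_nmd(self, toy_gene):
        # last junction at spliced position 4*90 = 360
        assert nmd_rule(toy_gene, 360 - 100) is True

    def test_ptc_in_last_exon_escapes_nmd(self, toy_gene):
        assert nmd_rule(toy_gene, 400) is False

    def test_single_exon_transcript_never_nmd(self):
        tx = Transcript("T", ((100, 400),), 130, 369)
        gene = GeneModel("G", "g", "chr1", "+", (tx,))
        assert nmd_rule(gene, 10) is False

    def test_no_ptc_means_no_nmd(self, toy_gene):
        assert nmd_rule(toy_gene, None) is False

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_coordinates(self, seed):
        rng = np.random.default_rng(20_000 + seed)
        gene, _ = random_gene_with_sequence(rng)
        tx = gene.transcripts[0]
        # brute force: spliced transcript as an explicit list of genomic
        # positions in reading order; the last junction is where the final
        # exon begins
        positions = [p for s, e in tx.exons for p in range(s, e + 1)]
        if gene.strand == "-":
            positions = positions[::-1]
        exon_of = {}
        for i, (s, e) in enumerate(tx.exons):
            for p in range(s, e + 1):
                exon_of[p] = i
        last_exon_genomic = len(tx.exons) - 1 if gene.strand == "+" else 0
        last_junction = next(
            idx for idx, p in enumerate(positions)
            if exon_of[p] == last_exon_genomic
        )
        total = len(positions)
        for ptc in rng.integers(0, total, size=5):
            expected = last_junction - int(ptc) > 55
            assert nmd_rule(gene, int(ptc)) == expected


# ---------------------------------------------------------------------------
# tandem duplications
# ---------------------------------------------------------------------------


class TestTandemDup:
    def dup_region(self, gene, first, last):
        tx = gene.transcripts[0]
        return (tx.exons[first - 1][0] - 40, tx.exons[last - 1][1] + 40)

    def test_supported_backjunction_confirms_tandem_and_frame(self, toy_gene):
        tx = toy_gene.transcripts[0]
        bj = make_junction(
            start=tx.exons[1][0] - 1, end=tx.exons[3][1] + 1, strand=".", unique=20,
            motif=0,
        )
        call = detect_tandem_dup([bj], toy_gene, self.dup_region(toy_gene, 2, 4))
        assert call.in_tandem
        assert (call.dup_exon_first, call.dup_exon_last) == (2, 4)
        assert call.split_read_support == 20
        assert call.in_frame  # 3 x 90 nt of CDS duplicated

    def test_no_backjunction_reads_means_not_in_tandem(self, toy_gene):
        call = detect_tandem_dup([], toy_gene, self.dup_region(toy_gene, 2, 4))
        assert not call.in_tandem
        assert call.split_read_support == 0

    def test_strand_mirror_gives_same_exons_and_frame(self, toy_gene, toy_gene_minus):
        region = self.dup_region(toy_gene, 2, 4)
        tx = toy_gene.transcripts[0]
        bj_plus = make_junction(start=tx.exons[1][0] - 1, end=tx.exons[3][1] + 1,
                                strand="+", unique=9, motif=0)
        bj_minus = make_junction(start=tx.exons[1][0] - 1, end=tx.exons[3][1] + 1,
                                 strand="-", unique=9, motif=0)
        call_plus = detect_tandem_dup([bj_plus], toy_gene, region)
        call_minus = detect_tandem_dup([bj_minus], toy_gene_minus, region)
        # exon 2..4 of a 5-exon gene is exons 2..4 from either direction
        assert (call_plus.dup_exon_first, call_plus.dup_exon_last) == (
            call_minus.dup_exon_first, call_minus.dup_exon_last,
        )
        assert call_plus.in_frame == call_minus.in_frame
        assert call_plus.backjunction_key == call_minus.backjunction_key

    def test_region_without_complete_exon_errors(self, toy_gene):
        tx = toy_gene.transcripts[0]
        mid = (tx.exons[0][0] + 10, tx.exons[0][1] - 10)
        with pytest.raises(ValueError):
            detect_tandem_dup([], toy_gene, mid)

    def test_backjunction_event_inferred_from_junction_table(self, toy_gene):
        tx = toy_gene.transcripts[0]
        key = ("chr1", tx.exons[1][0] - 1, tx.exons[3][1] + 1, "+")
        (ev,) = infer_events([aberrant_for(key, score=0.5)], toy_gene)
        assert ev.event_type == "tandem_dup_backjunction"
        assert ev.affected_exons == (2, 3, 4)
        assert ev.frame == "in_frame"


# ---------------------------------------------------------------------------
# intron retention
# ---------------------------------------------------------------------------


class TestIntronRetention:
    def coverage_for(self, gene, intron_cov, exon_cov=100.0):
        tx = gene.transcripts[0]
        s, e = tx.introns()[0]
        left, right = tx.exons[0], tx.exons[1]
        return [
            CoverageInterval("chr1", left[0] - 1, left[1], exon_cov),
            CoverageInterval("chr1", s - 1, e, intron_cov),
            CoverageInterval("chr1", right[0] - 1, right[1], exon_cov),
        ]

    def test_zero_intron_coverage_gives_zero(self, toy_gene):
        assert intron_retention_ratio(self.coverage_for(toy_gene, 0.0), toy_gene, 1) == 0.0

    def test_seventy_five_percent_retention(self, toy_gene):
        ratio = intron_retention_ratio(self.coverage_for(toy_gene, 75.0), toy_gene, 1)
        assert ratio == pytest.approx(0.75)

    def test_zero_exon_coverage_is_undefined(self, toy_gene):
        cov = self.coverage_for(toy_gene, 50.0, exon_cov=0.0)
        assert intron_retention_ratio(cov, toy_gene, 1) is None

    def test_ratio_truncated_to_one(self, toy_gene):
        ratio = intron_retention_ratio(self.coverage_for(toy_gene, 500.0), toy_gene, 1)
        assert ratio == 1.0

    @pytest.mark.parametrize("fraction", [0.1, 0.5, 0.9])
    def test_recovers_injected_retention_fraction(self, tmp_path, fraction):
        from rnadx.formats import read_bedgraph, read_gtf_subset
        from rnadx.synthetic import Injection, SimConfig, simulate_cohort

        config = SimConfig(
            seed=int(fraction * 100), n_genes=4, n_controls=5, depth=500,
            injections=(Injection(gene_index=1, event_type="intron_retention",
                                  intron=2, fraction=fraction),),
        )
        bundle = simulate_cohort(config, tmp_path / f"ret{fraction}")
        models = {m.gene_id: m for m in read_gtf_subset(bundle.gtf)}
        coverage = read_bedgraph(bundle.bedgraph)
        gene_id = bundle.truth["injections"][0]["gene_id"]
        ratio = intron_retention_ratio(coverage, models[gene_id], 2)
        assert ratio == pytest.approx(fraction, abs=0.05)


# ---------------------------------------------------------------------------
# isoform switches
# ---------------------------------------------------------------------------


class TestIsoformSwitch:
    def controls(self, rng, means, n=30):
        import pandas as pd

        data = {
            f"s{i}": np.clip(rng.normal(means, 0.02), 0, 1) for i in range(n)
        }
        return pd.DataFrame(data, index=[f"iso{k}" for k in range(len(means))])

    def test_patient_matching_controls_is_no_candidate(self):
        rng = np.random.default_rng(3)
        controls = {"G": self.controls(rng, [0.85, 0.08, 0.07])}
        patient = {"G": {"iso0": 0.85, "iso1": 0.08, "iso2": 0.07}}
        assert isoform_switch_screen(patient, controls) == []

    def test_marked_skew_away_from_major_isoform_is_candidate(self):
        # major isoform collapses from ~85% to 15% while a minor isoform
        # rises from ~8% to 56%
        rng = np.random.default_rng(4)
        controls = {"G": self.controls(rng, [0.85, 0.08, 0.07])}
        patient = {"G": {"iso0": 0.15, "iso1": 0.56, "iso2": 0.29}}
        (cand,) = isoform_switch_screen(patient, controls)
        assert cand.gene_id == "G"
        assert any(iso == "iso0" for iso, _ in cand.lost_isoforms)
        assert any(iso == "iso1" for iso, _ in cand.gained_isoforms)

    def test_single_isoform_gene_skipped(self):
        rng = np.random.default_rng(5)
        controls = {"G": self.controls(rng, [1.0])}
        patient = {"G": {"iso0": 1.0}}
        assert isoform_switch_screen(patient, controls) == []

    def test_injected_switch_recovered_among_null_genes(self):
        rng = np.random.default_rng(6)
        controls = {}
        patient = {}
        for g in range(10):
            means = [0.7, 0.2, 0.1]
            controls[f"G{g}"] = self.controls(rng, means)
            draw = np.clip(rng.normal(means, 0.02), 0, 1)
            patient[f"G{g}"] = {f"iso{k}": float(draw[k]) for k in range(3)}
        patient["G4"] = {"iso0": 0.2, "iso1": 0.7, "iso2": 0.1}
        candidates = isoform_switch_screen(patient, controls)
        assert [c.gene_id for c in candidates] == ["G4"]
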